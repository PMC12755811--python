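"""Model-evaluation procedures: growth-rate error, nutrient and carbon-source
screens, and confusion-matrix metrics.

Growth (G) is the "positive" class throughout, so a model that predicts
growth where the organism cannot grow scores a false positive.  Reported
percentages are truncated (not rounded) at two decimals, the convention used
for all reported values in this package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .fba import FEASIBILITY_TOL, fba
from .model import MetabolicModel

__all__ = [
    "ConfusionTable",
    "ScreenRow",
    "ScreenResult",
    "growth_error",
    "essentiality_screen",
    "carbon_source_screen",
    "confusion_metrics",
    "model_stats",
    "truncate",
    "GROWTH_CALL_TOL",
]

#: Predicted growth above this rate (h^-1) is called "G".
GROWTH_CALL_TOL = 1e-6


def truncate(value: float, decimals: int = 2) -> float:
    """Truncate toward zero at ``decimals`` decimals (reporting convention)."""
    factor = 10 ** decimals
    return math.trunc(value * factor) / factor


def growth_error(experimental: float, predicted: float) -> tuple:
    """Signed percent error and accuracy of a growth-rate prediction.

    error% = (experimental - predicted) / experimental x 100, reported to one
    decimal; accuracy% = 100 - error%.  Overprediction gives a negative error.
    """
    if experimental <= 0:
        raise ValueError("experimental growth rate must be positive")
    error = (experimental - predicted) / experimental * 100.0
    error = round(error, 1)
    return error, round(100.0 - error, 1)


@dataclass
class ConfusionTable:
    """TP/FP/TN/FN counts with growth as the positive class."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _phenotype(experimental: str, predicted: str) -> str:
    return {
        ("G", "G"): "TP",
        ("NG", "G"): "FP",
        ("NG", "NG"): "TN",
        ("G", "NG"): "FN",
    }[(experimental, predicted)]


@dataclass
class ScreenRow:
    """One screen condition with predicted (and optionally observed) growth calls."""

    condition: str
    predicted: str  # G | NG
    experimental: str | None = None
    growth_rate: float | None = None

    @property
    def phenotype(self) -> str | None:
        if self.experimental is None:
            return None
        return _phenotype(self.experimental, self.predicted)


@dataclass
class ScreenResult:
    """An ordered set of screen rows with a confusion tally."""

    rows: list = field(default_factory=list)
    name: str = ""

    def confusion(self) -> ConfusionTable:
        counts = {"TP": 0, "FP": 0, "TN": 0, "FN": 0}
        for row in self.rows:
            if row.phenotype is not None:
                counts[row.phenotype] += 1
        return ConfusionTable(counts["TP"], counts["FP"], counts["TN"], counts["FN"])

    def predictions(self) -> dict:
        return {row.condition: row.predicted for row in self.rows}


def _growth_call(model: MetabolicModel) -> tuple:
    sol = fba(model)
    mu = sol.objective_value if sol.optimal else 0.0
    return ("G" if mu > GROWTH_CALL_TOL else "NG"), max(mu, 0.0)


def essentiality_screen(
    model: MetabolicModel,
    removable_nutrients: dict,
    experimental: dict | None = None,
    include_baseline: bool = True,
) -> ScreenResult:
    """Single-omission nutrient essentiality by FBA.

    ``removable_nutrients`` maps a condition label to the exchange reaction of
    the nutrient; each nutrient's uptake is closed individually (lower bound
    0), growth is re-maximized, and the original bounds are restored between
    tests (the input model is never modified).  A nutrient is essential when
    its omission abolishes growth (NG).
    """
    experimental = experimental or {}
    rows = []
    if include_baseline:
        call, mu = _growth_call(model)
        rows.append(ScreenRow("baseline", call, experimental.get("baseline"), mu))
    for label, exchange_id in removable_nutrients.items():
        work = model.copy()
        rxn = work.reaction(exchange_id)
        if rxn.kind != "exchange":
            raise ValueError(f"{exchange_id} (for {label!r}) is not an exchange reaction")
        rxn.lower_bound = max(rxn.lower_bound, 0.0)
        call, mu = _growth_call(work)
        rows.append(ScreenRow(label, call, experimental.get(label), mu))
    return ScreenResult(rows, name="nutrient essentiality")


def carbon_source_screen(
    model: MetabolicModel,
    sources: dict,
    uptake_rate: float,
    glucose_exchange: str = "EX_glc__D_e",
    experimental: dict | None = None,
    include_no_sugar: bool = True,
) -> ScreenResult:
    """Growth calls on alternative carbon sources by FBA.

    For each source the glucose uptake is closed and the source's exchange is
    opened at ``uptake_rate``; a "No sugar" condition (all listed sugars and
    glucose closed) is included by default and is expected NG for a strictly
    saccharolytic network.
    """
    experimental = experimental or {}
    rows = []

    def run(label, open_exchange):
        work = model.copy()
        glc = work.reaction(glucose_exchange)
        glc.lower_bound = max(glc.lower_bound, 0.0)
        for ex in sources.values():
            rxn = work.reaction(ex)
            rxn.lower_bound = max(rxn.lower_bound, 0.0)
        if open_exchange is not None:
            work.reaction(open_exchange).lower_bound = -abs(uptake_rate)
        call, mu = _growth_call(work)
        rows.append(ScreenRow(label, call, experimental.get(label), mu))

    if include_no_sugar:
        run("No sugar", None)
    run("Glucose", glucose_exchange)
    for label, exchange_id in sources.items():
        run(label, exchange_id)
    return ScreenResult(rows, name="carbon sources")


def confusion_metrics(t: ConfusionTable) -> dict:
    """Precision, accuracy, sensitivity, specificity, NPV and F-score (%).

    Formulas: precision = TP/(TP+FP); accuracy = (TP+TN)/total; sensitivity =
    TP/(TP+FN); specificity = TN/(TN+FP); NPV = TN/(TN+FN); F-score is the
    harmonic mean of precision and sensitivity.  Metrics with a zero
    denominator are reported as None (undefined).  Values are percentages
    truncated at two decimals.
    """
    if t.total == 0:
        raise ValueError("empty confusion table")

    def ratio(num, den):
        return 100.0 * num / den if den > 0 else None

    precision = ratio(t.tp, t.tp + t.fp)
    sensitivity = ratio(t.tp, t.tp + t.fn)
    if precision is None or sensitivity is None or precision + sensitivity == 0:
        f_score = None
    else:
        f_score = 2 * precision * sensitivity / (precision + sensitivity)
    metrics = {
        "precision": precision,
        "accuracy": ratio(t.tp + t.tn, t.total),
        "sensitivity": sensitivity,
        "specificity": ratio(t.tn, t.tn + t.fp),
        "npv": ratio(t.tn, t.tn + t.fn),
        "f_score": f_score,
    }
    return {k: (None if v is None else truncate(v)) for k, v in metrics.items()}


def model_stats(model: MetabolicModel) -> dict:
    """Census of a model: genes, reactions by kind, metabolites by compartment.

    Gene coverage (% of genome genes captured by the model) is included when
    the model declares a genome gene count, truncated at two decimals.
    """
    by_kind: dict = {}
    for r in model.reactions:
        by_kind[r.kind] = by_kind.get(r.kind, 0) + 1
    by_comp: dict = {}
    for m in model.metabolites:
        key = "intracellular" if m.compartment == "c" else "extracellular"
        by_comp[key] = by_comp.get(key, 0) + 1
    stats = {
        "genes": len(model.genes),
        "reactions": len(model.reactions),
        "reactions_by_kind": by_kind,
        "metabolites": len(model.metabolites),
        "metabolites_by_compartment": by_comp,
    }
    if model.genome_gene_count:
        stats["gene_coverage_pct"] = truncate(
            100.0 * len(model.genes) / model.genome_gene_count
        )
    return stats
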