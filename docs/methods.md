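# Methods

## Scope and model

`hyaflux` implements constraint-based analysis of microbial hyaluronic-acid
(HA) production. The underlying model is the standard stoichiometric
steady-state formalism: a metabolic network with stoichiometric matrix **S**
(metabolites × reactions), flux vector **v**, and bounds **lb ≤ v ≤ ub**.
Flux balance analysis (FBA) maximizes one reaction's flux (usually the
biomass pseudo-reaction, whose flux is the specific growth rate μ in h⁻¹)
subject to **S v = 0**; minimization of metabolic adjustment (MOMA) predicts
a knockout phenotype as the feasible flux state closest to a wild-type
reference rather than a re-optimized one. Fluxes are in mmol·gDCW⁻¹·h⁻¹;
exchange reactions import at negative flux and secrete at positive flux;
reversible internal reactions default to (−1000, 1000) and irreversible ones
to (0, 1000).

Linear programs (FBA, L1-MOMA, parsimonious reference, alternate-optima
scans) are solved with HiGHS through `scipy.optimize.linprog`. Quadratic
MOMA is a strictly convex QP solved with OSQP (ADMM with solution polishing,
`eps_abs = eps_rel = 1e-9`); its solution is unique, unlike LP optima.

### Numerical conventions

* Feasibility/steady-state tolerance: `1e-6` (‖S·v‖∞); fluxes below it are
  treated as zero in summaries.
* LP degeneracy: `fba` returns one solver vertex; reproducibility comes from
  fixed solver settings and deterministic model ordering, not uniqueness.
  The MOMA reference resolves degeneracy explicitly: maximum growth first,
  then minimal total absolute flux (parsimonious selection) as a secondary
  LP with split variables.
* Deletion classification: lethal at relative growth rate (Rgr, mutant μ /
  wild-type μ) below `1e-6`; "sick" below `1 − 1e-3`. A gene pair interacts
  when the double Rgr falls below both single Rgrs minus the same guard;
  interaction with zero double growth (both singles viable) is synthetic
  lethal, any other interacting pair with Rgr < 1 synthetic sick. Interaction
  summaries report percentages of the total gene count, including the
  "at least 1 partner" and "at least 5 partners" degree classes.
* Reported percentages (confusion metrics, gene coverage) are **truncated**
  at two decimals, not rounded — e.g. 11/13 → 84.61%. This matches the
  reporting convention of the validation benchmarks the package reproduces.
* Robustness analysis sets the varied exchange's **lower bound** (an uptake
  allowance) at each grid point rather than pinning the flux, unless
  `fixed=True`; the allowance reading makes the curve a monotone function of
  a relaxation by LP theory, which is the property the oxygen-response check
  asserts. Infeasible grid points are recorded as missing, never fatal.
* ATP yield per glucose is computed at zero growth with glucose uptake
  pinned, maximizing the ATP-hydrolysis (maintenance) flux: it measures
  catabolic capacity only, not growth-coupled yield.

## Gene–protein–reaction rules and knockouts

GPR rules are infix boolean expressions over gene ids (AND = enzyme complex,
OR = isozymes) parsed by a small recursive-descent parser. A knockout sets
both bounds of every reaction whose rule evaluates false to zero; a reaction
with an empty rule (no known gene) is never affected. Knockouts are
idempotent and validated against the model's gene list.

## Strain-design procedures

**Iterative knockout search.** Breadth-first over rounds: round *r* evaluates
every additional single deletion in each surviving (*r*−1)-mutant background,
by quadratic MOMA against the **wild-type** reference (growth and product
rate are read off the projection). A deletion is kept when the product rate
improves by at least 1% relative to its parent (configurable; an absolute
floor of `1e-4` guards the relative test when the parent rate is ~0, as the
wild type's HA rate is). A round-one candidate losing more than 40% of the
wild-type growth rate is reported but not expanded into deeper rounds; the
40% rule is deliberately applied to round one only, a literal reading of the
procedure it operationalizes. Depth defaults to 3. Anchoring MOMA to the
wild-type reference in every round (rather than the parent mutant) is a
documented, revisitable choice.

**Alternate-optima regulation targets.** With growth constrained to ≥95% of
optimal and the product flux pinned to its extreme value (±1e-6), many
distinct optima are generated by maximizing random Gaussian secondary
objectives (seeded RNG) over the optimal face — a reproducible re-statement
of "enumerate multiple optimal solutions" with the same contract. A reaction
is an up-regulation target when its flux range over the max-product samples
lies strictly above its range over the min-product samples, and vice versa
for down-regulation; the reported separation is the gap between ranges. The
default sample count is 5000.

## Biomass and maintenance construction

DNA composition is counted double-stranded from the genome (A/T and G/C
fractions are equal by base pairing; ambiguous bases are skipped with a
warning). Protein composition comes from translating coding sequences
(standard code, stops dropped, internal-stop sequences skipped) or from a
codon-count table. Monomer coefficients use residue weights (monomer MW minus
one water per bond), and the polymerization water is released as a product,
so the net mass consumed per gram of biomass equals the mass-fraction sum
exactly; the mass-accounting check asserts this within 1%. Biomass
coefficients are rounded to 6 decimals (≈1 nmol·gDCW⁻¹) so that serialized
models round-trip exactly through text formats.

Growth-associated maintenance (GAM) hydrolyzes 39.4 mmol ATP per gDCW of
biomass formed, entering the biomass reaction itself (per-gram basis; the
h⁻¹ dimension arises through the growth flux). Non-growth-associated
maintenance (NGAM) is a separate ATP-hydrolysis reaction whose lower bound
fixes the maintenance rate; the synthetic models ship with NGAM = 1.0
mmol·gDCW⁻¹·h⁻¹, a placeholder in the realistic range for fermentative
bacteria, and a helper derives NGAM from a zero-growth glucose uptake times
the ATP yield.

## HA pathway and its cost report

The HA branch follows the canonical two-precursor topology: G6P → G1P →
UDP-glucose → UDP-glucuronate, and F6P → glucosamine-6P → GlcNAc-6P →
GlcNAc-1P → UDP-GlcNAc; hyaluronan synthase condenses one UDP-glucuronate
and one UDP-GlcNAc into one disaccharide unit, releasing 2 UDP. The
disaccharide unit is modeled as the polymer residue anion C₁₄H₂₀NO₁₁⁻ (the
free disaccharide minus the water lost per glycosidic bond), which makes the
condensation reaction elementally and charge balanced.

The cost report does not hard-code numbers: it solves the branch sub-network
stoichiometry (non-negative route fluxes producing exactly one HA unit, all
intermediates balanced, currency metabolites free) and tallies the net
consumption of ATP, acetyl-CoA and NAD. UTP/UDP are balanced *within* the
route by including nucleoside-diphosphate kinase, so every phosphoanhydride
bond is funneled to ATP — the sense in which UTP counts as one
ATP-equivalent. The amination of fructose-6-phosphate runs through glutamine
with glutamine synthetase in the route, contributing the fifth ATP; the
resulting ledger is 2 hexose phosphorylations + 2 UTP + 1 glutamine
regeneration = 5 ATP-equivalents, 1 acetyl-CoA (GlcNAc acetylation), 2 NAD
(UDP-glucose dehydrogenase) per disaccharide.

## The synthetic model pair

The generators produce a deterministic pair of ~100-reaction toy networks
whose *contrast* carries the biology; they emulate study conditions, not any
particular curated reconstruction.

**Native producer** (fastidious lactic fermenter): EMP glycolysis with
hexokinase entry; homolactic fermentation plus pyruvate-formate lyase and a
capacity-capped acetate branch (phosphotransacetylase/acetate kinase,
Vmax = 5 mmol·gDCW⁻¹·h⁻¹ — far below the homolactic glycolytic flux, so the
wild type ferments homolactically while lactate-branch knockouts can shift
to mixed-acid overflow, as observed in engineered streptococci); a
water-forming NADH oxidase as the minimal oxygen response; a
non-phosphorylating NADP-GAPDH (the streptococcal GapN) as the NADPH source,
since the oxidative pentose-phosphate branch is absent; non-oxidative
pentose-phosphate reactions; a truncated TCA branch ending at 2-oxoglutarate
(citrate synthase → isocitrate dehydrogenase) fed by PEP carboxylase;
synthesis routes for Glu/Gln/Ala/Asp/Asn/Ser and, via aspartate
semialdehyde, Thr and Lys; five amino-acid auxotrophies by construction
(Met, Leu, Arg, Ile, Val — importable only); nucleobase salvage (adenine and
uracil phosphoribosyltransferases) next to a lumped pyrimidine de-novo
route; catabolic funnels for fructose, sucrose, maltose and lactose; and the
chromosomal HA operon. Default medium: chemically defined, anaerobic,
glucose uptake 18.56 mmol·gDCW⁻¹·h⁻¹ (the chemostat-derived rate), all
protein amino acids at 10 and nucleobases at 5 mmol·gDCW⁻¹·h⁻¹.

**Recombinant producer** (prototrophic aerobe): the same glycolysis and HA
operon (heterologous), plus a lumped oxidative PPP (glucose-6-phosphate
dehydrogenase analog `zwf_syn`: G6P + 2 NADP⁺ → Ru5P + CO₂ + 2 NADPH), a
full TCA cycle, lumped oxidative phosphorylation at P/O = 2 (and succinate
oxidation at P/O = 1), NADP-isocitrate dehydrogenase as the alternative
NADPH source, fully de-novo amino-acid and nucleotide biosynthesis (lumped
multi-step reactions with exact C/N/P/S bookkeeping), and lactate
dehydrogenase as the overflow by-product route. Default medium: minimal
salts, aerobic, glucose uptake 4.67 mmol·gDCW⁻¹·h⁻¹, sulfide as sulfur
source. The resulting catabolic ATP yields are 2 ATP/glucose (native,
anaerobic homolactic) versus 26 ATP/glucose (recombinant, respiring) — the
qualitative fermenter-vs-respirer contrast the analyses depend on.

Lumped biosynthesis reactions are written with exact carbon, nitrogen,
phosphorus and sulfur accounting; hydrogen, oxygen and charge residuals are
closed deterministically with water and protons by a generator helper that
raises if any heavier element is off. Every internal reaction of both models
therefore passes the elemental/charge balance check, which is itself a test.

Topology is fully deterministic: equal parameters give byte-identical
serialized models. The seed parameter is stored and forwarded to downstream
stochastic steps (alternate-optima sampling); it does not perturb
construction.

**What the toys do and do not show.** Passing tests on this pair demonstrate
that the machinery is correct (solver agreement, invariants, GPR semantics)
and that the documented qualitative physiology emerges from the encoded
mechanisms: zero HA flux at maximum growth, the growth–HA tradeoff of every
knockout strategy, rising HA optimum with oxygen availability, higher HA
flux and lower growth after deleting the oxidative-PPP gene analog, and the
HA synthase nominated for up-regulation. They say nothing about absolute
rates in any real organism: the toys lack kinetic regulation, most of the
real gene complement, realistic biomass detail (lipids and cell wall beyond
a two-precursor template pool, no DNA precursor pathway — DNA is folded into
the RNA mass fraction), and condition-dependent maintenance.

## Validation fixtures

The amino-acid-omission (22 conditions) and carbon-source (6 conditions)
screen fixtures carry published experimental growth calls side by side with
a curated model's predictions; they tally to TP=11/FP=2/TN=9/FN=0 and
TP=5/TN=1 and drive the confusion-metric arithmetic (precision 84.61%,
accuracy 90.90%, sensitivity 100%, specificity 81.81%, NPV 100%, F-score
91.66%; all 100% for the carbon screen). The same machinery runs live
screens on the synthetic models, where exactly the five constructed
auxotrophies score essential and all five sugars support growth.

## Problem sizes

The shipped analyses run at the following sizes: full single (58 genes) and
double (1653 pairs) FBA deletion screens of the native model; depth-3 MOMA
knockout search (~2000 QP solves); 5000 alternate-optima samples per
direction in the acceptance script (50 in the test suite); 20 random ≤15-
reaction models for LP cross-checks and 10 knockouts for QP cross-checks.

## Known limitations

* The SBML dialect is a Level 3 + fbc-v2 subset (species with
  formula/charge, flux-bound parameters, gene-product associations, one
  maximization objective, reaction kind/subsystem in notes); exotic FBC
  features are out of scope. Files are readable by standard COBRA tooling.
* Linear-vs-quadratic MOMA: quadratic is the default (original formulation,
  unique solution); the linear mode is provided but shares LP degeneracy.
* Charge balancing is report-only; automatic proton closure is used only
  inside the generators, never applied silently to user models.
* The alternate-optima sampler explores vertices of the optimal face; it is
  not a uniform sampler of that face, and range separations should be read
  as qualitative evidence, as the target-nomination rule intends.
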