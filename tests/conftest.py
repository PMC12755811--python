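"""Shared fixtures: synthetic models (session-scoped, they are deterministic)
and small hand-built networks with known solutions."""

import pytest

from hyaflux import (
    MetabolicModel,
    Metabolite,
    Reaction,
    apply_medium,
    make_native_model,
    make_recombinant_model,
)
from hyaflux.synth import native_cdm_medium


@pytest.fixture(scope="session")
def native_model():
    return make_native_model()


@pytest.fixture(scope="session")
def recombinant_model():
    return make_recombinant_model()


@pytest.fixture(scope="session")
def aerobic_native(native_model):
    return apply_medium(native_model, native_cdm_medium(native_model, aerobic=True))


def build_chain_model(uptake: float = 10.0, biomass_coeff: float = 10.0):
    """EX_A -> transport -> GROWTH consuming `biomass_coeff` A per unit growth.

    Max growth = uptake / biomass_coeff; the flux vector is unique.
    """
    mets = [
        Metabolite("A_e", "substrate", "C6H12O6", 0, "e"),
        Metabolite("A_c", "substrate", "C6H12O6", 0, "c"),
    ]
    rxns = [
        Reaction("EX_A_e", {"A_e": -1.0}, -uptake, 1000.0, kind="exchange"),
        Reaction("At", {"A_e": -1.0, "A_c": 1.0}, 0.0, 1000.0, kind="transport"),
        Reaction("GROWTH", {"A_c": -biomass_coeff}, 0.0, 1000.0, kind="pseudo"),
    ]
    m = MetabolicModel(
        id="chain", metabolites=mets, reactions=rxns, genes=[],
        objective_reaction="GROWTH",
    )
    m.validate()
    return m


def build_diamond_model():
    """Two equal-yield parallel routes from A to B feeding growth.

    The max-growth optimum is degenerate across the two branches.
    """
    mets = [
        Metabolite("A_e", compartment="e"),
        Metabolite("A_c", compartment="c"),
        Metabolite("B_c", compartment="c"),
    ]
    rxns = [
        Reaction("EX_A_e", {"A_e": -1.0}, -10.0, 1000.0, kind="exchange"),
        Reaction("At", {"A_e": -1.0, "A_c": 1.0}, 0.0, 1000.0, kind="transport"),
        Reaction("R1", {"A_c": -1.0, "B_c": 1.0}, 0.0, 1000.0, gpr="g1"),
        Reaction("R2", {"A_c": -1.0, "B_c": 1.0}, 0.0, 1000.0, gpr="g2"),
        Reaction("GROWTH", {"B_c": -1.0}, 0.0, 1000.0, kind="pseudo"),
    ]
    m = MetabolicModel(
        id="diamond", metabolites=mets, reactions=rxns, genes=["g1", "g2"],
        objective_reaction="GROWTH",
    )
    m.validate()
    return m


def build_branch_model():
    """A toy with growth/product competition and a gated overflow valve.

    Substrate A (uptake 10) can go to growth (via precursor P), to product Q
    (exported), or to an overflow sink W.  Deleting the overflow gene or one
    of two isozyme-covered growth genes redirects flux; used for exhaustive
    search oracles.
    """
    mets = [
        Metabolite("A_e", compartment="e"),
        Metabolite("A_c", compartment="c"),
        Metabolite("P_c", compartment="c"),
        Metabolite("Q_c", compartment="c"),
        Metabolite("Q_e", compartment="e"),
        Metabolite("W_e", compartment="e"),
        Metabolite("W_c", compartment="c"),
    ]
    rxns = [
        Reaction("EX_A_e", {"A_e": -1.0}, -10.0, 1000.0, kind="exchange"),
        Reaction("At", {"A_e": -1.0, "A_c": 1.0}, 0.0, 1000.0, gpr="tA"),
        # growth route: two isozymes for A -> P, then growth consumes 2 P
        Reaction("AP1", {"A_c": -1.0, "P_c": 1.0}, 0.0, 4.0, gpr="gp1"),
        Reaction("AP2", {"A_c": -1.0, "P_c": 1.0}, 0.0, 4.0, gpr="gp2"),
        Reaction("GROWTH", {"P_c": -2.0}, 0.0, 1000.0, kind="pseudo"),
        # product route
        Reaction("AQ", {"A_c": -1.0, "Q_c": 1.0}, 0.0, 1000.0, gpr="gq"),
        Reaction("Qt", {"Q_c": -1.0, "Q_e": 1.0}, 0.0, 1000.0),
        Reaction("EX_Q_e", {"Q_e": -1.0}, 0.0, 1000.0, kind="exchange"),
        # overflow valve
        Reaction("AW", {"A_c": -1.0, "W_c": 1.0}, 0.0, 1000.0, gpr="gw"),
        Reaction("Wt", {"W_c": -1.0, "W_e": 1.0}, 0.0, 1000.0),
        Reaction("EX_W_e", {"W_e": -1.0}, 0.0, 1000.0, kind="exchange"),
    ]
    m = MetabolicModel(
        id="branch", metabolites=mets, reactions=rxns,
        genes=["tA", "gp1", "gp2", "gq", "gw"],
        objective_reaction="GROWTH",
    )
    m.validate()
    return m
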