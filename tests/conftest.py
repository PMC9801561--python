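"""Shared fixtures: the synthetic template model and hand-solvable toys."""

from __future__ import annotations

import pytest

from gemforge.core import Metabolite, Model, Reaction, parse_formula
from gemforge.flux import apply_medium
from gemforge.gpr import parse_gpr
from gemforge.synth import default_medium, make_template_model


def build_model(mets, rxns, objective=None, model_id="toy"):
    """Compact toy-model builder.

    ``mets``: (id, compartment[, formula]) tuples;
    ``rxns``: (id, stoichiometry, lb, ub[, gpr]) tuples.
    """
    m = Model(id=model_id, compartments={"c": "cytosol", "e": "extracellular"})
    for spec in mets:
        mid, comp = spec[0], spec[1]
        formula = parse_formula(spec[2]) if len(spec) > 2 and spec[2] else None
        charge = 0 if formula is not None else None
        m.add_metabolite(
            Metabolite(id=mid, compartment=comp, formula=formula, charge=charge)
        )
    for spec in rxns:
        rid, stoich, lb, ub = spec[:4]
        rule = parse_gpr(spec[4]) if len(spec) > 4 else parse_gpr("")
        m.add_reaction(
            Reaction(id=rid, stoichiometry=stoich, lower_bound=float(lb),
                     upper_bound=float(ub), gpr=rule)
        )
    if objective:
        m.objective = dict(objective)
    m.validate()
    return m


@pytest.fixture(scope="session")
def template():
    return make_template_model(0)


@pytest.fixture(scope="session")
def medium():
    return default_medium()


@pytest.fixture(scope="session")
def grown_template(template, medium):
    """Template constrained to the default aerobic glucose medium."""
    return apply_medium(template, medium)


@pytest.fixture
def chain_toy():
    """EX_A(-10) -> T_A -> R1 -> BIO; FBA optimum 10."""
    return build_model(
        mets=[("A_e", "e"), ("A_c", "c"), ("B_c", "c")],
        rxns=[
            ("EX_A_e", {"A_e": -1}, -10, 1000),
            ("T_A", {"A_e": -1, "A_c": 1}, 0, 1000, "gT"),
            ("R1", {"A_c": -1, "B_c": 1}, 0, 1000, "g1 or g2"),
            ("BIO", {"B_c": -1}, 0, 1000),
        ],
        objective={"BIO": 1.0},
    )


@pytest.fixture
def parallel_toy():
    """Chain toy with a second A->B isozyme reaction (R1a)."""
    return build_model(
        mets=[("A_e", "e"), ("A_c", "c"), ("B_c", "c")],
        rxns=[
            ("EX_A_e", {"A_e": -1}, -10, 1000),
            ("T_A", {"A_e": -1, "A_c": 1}, 0, 1000, "gT"),
            ("R1", {"A_c": -1, "B_c": 1}, 0, 1000, "g1"),
            ("R1a", {"A_c": -1, "B_c": 1}, 0, 1000, "g2"),
            ("BIO", {"B_c": -1}, 0, 1000),
        ],
        objective={"BIO": 1.0},
    )


@pytest.fixture
def branch_toy():
    """Shared uptake (10) split between biomass (RB->BIO) and product
    (RP->EX_P): every unit of product displaces one unit of biomass."""
    return build_model(
        mets=[("A_e", "e"), ("A_c", "c"), ("B_c", "c"), ("P_c", "c"), ("P_e", "e")],
        rxns=[
            ("EX_A_e", {"A_e": -1}, -10, 1000),
            ("T_A", {"A_e": -1, "A_c": 1}, 0, 1000),
            ("RB", {"A_c": -1, "B_c": 1}, 0, 1000),
            ("BIO", {"B_c": -1}, 0, 1000),
            ("RP", {"A_c": -1, "P_c": 1}, 0, 1000),
            ("T_P", {"P_c": -1, "P_e": 1}, 0, 1000),
            ("EX_P_e", {"P_e": -1}, 0, 1000),
        ],
        objective={"BIO": 1.0},
    )


@pytest.fixture
def overflow_toy():
    """Biomass branch plus an optional overflow route R2 -> EX_C whose FVA
    interval at fraction f of the optimum is exactly [0, 10(1-f)]."""
    return build_model(
        mets=[("A_e", "e"), ("A_c", "c"), ("B_c", "c"), ("C_c", "c"), ("C_e", "e")],
        rxns=[
            ("EX_A_e", {"A_e": -1}, -10, 1000),
            ("T_A", {"A_e": -1, "A_c": 1}, 0, 1000),
            ("R1", {"A_c": -1, "B_c": 1}, 0, 1000),
            ("BIO", {"B_c": -1}, 0, 1000),
            ("R2", {"A_c": -1, "C_c": 1}, 0, 1000),
            ("T_C", {"C_c": -1, "C_e": 1}, 0, 1000),
            ("EX_C_e", {"C_e": -1}, 0, 1000),
        ],
        objective={"BIO": 1.0},
    )
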