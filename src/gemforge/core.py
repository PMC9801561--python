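"""Core domain types for genome-scale metabolic models (GEMs).

A model is a stoichiometric network: metabolites with elemental
formulas, reactions with rational stoichiometric coefficients, flux
bounds in mmol·gDW⁻¹·h⁻¹, GPR rules and a provenance tag recording the
origin model of every reaction, plus a linear objective (typically one
biomass pseudo-reaction with weight 1).

Structural audits live here too: elemental mass / charge balance of
single reactions (reactions touching metabolites with a rest-group "R"
pseudo-element or a missing formula are reported *unbalanceable* rather
than guessed at), and detection of duplicate reactions that differ only
in identifier, orientation, bounds or gene rule.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Mapping

from .gpr import EMPTY_RULE, GeneRule

DEFAULT_LOWER_BOUND = -1000.0
DEFAULT_UPPER_BOUND = 1000.0

#: pseudo-element marking a bound protein domain / undefined rest group
REST_GROUP = "R"


class ModelIntegrityError(ValueError):
    """A structural invariant of the model is violated."""


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> dict[str, int]:
    """Parse an elemental formula string into element -> count.

    Grammar: repeated (ElementSymbol, optional positive integer) tokens.
    "R" is accepted as a pseudo-element; unknown symbols are accepted and
    counted.  Raises ``ValueError`` on anything else.
    """
    if text is None:
        raise ValueError("formula is None")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if m is None or m.start() != pos:
            raise ValueError(f"malformed formula {text!r} at position {pos}")
        element, digits = m.group(1), m.group(2)
        n = int(digits) if digits else 1
        if n <= 0:
            raise ValueError(f"non-positive count in formula {text!r}")
        counts[element] = counts.get(element, 0) + n
        pos = m.end()
    return counts


def format_formula(counts: Mapping[str, int]) -> str:
    """Canonical string form (elements sorted; count 1 implicit)."""
    return "".join(
        f"{el}{n if n != 1 else ''}" for el, n in sorted(counts.items())
    )


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: dict[str, int] | None = None
    charge: int | None = None
    annotations: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.formula is not None:
            for el, n in self.formula.items():
                if n <= 0:
                    raise ModelIntegrityError(
                        f"metabolite {self.id}: non-positive count for {el}"
                    )

    @property
    def has_rest_group(self) -> bool:
        return self.formula is not None and REST_GROUP in self.formula


@dataclass
class Gene:
    id: str
    name: str = ""
    locus_tag: str = ""


def _coerce_coefficient(value) -> Fraction:
    if isinstance(value, Fraction):
        return value
    if isinstance(value, int):
        return Fraction(value)
    if isinstance(value, float):
        # exact rationalisation of the decimal literal, not of the binary float
        return Fraction(repr(value))
    return Fraction(value)


@dataclass
class Reaction:
    id: str
    name: str = ""
    stoichiometry: dict[str, Fraction] = field(default_factory=dict)
    lower_bound: float = DEFAULT_LOWER_BOUND
    upper_bound: float = DEFAULT_UPPER_BOUND
    gpr: GeneRule = EMPTY_RULE
    subsystem: str = ""
    annotations: dict[str, list[str]] = field(default_factory=dict)
    provenance: str = "manual"

    def __post_init__(self) -> None:
        self.stoichiometry = {
            m: _coerce_coefficient(c) for m, c in self.stoichiometry.items()
        }
        for m, c in self.stoichiometry.items():
            if c == 0:
                raise ModelIntegrityError(
                    f"reaction {self.id}: zero coefficient for {m}"
                )
        if self.lower_bound > self.upper_bound:
            raise ModelIntegrityError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            name=self.name,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            gpr=self.gpr,
            subsystem=self.subsystem,
            annotations={k: list(v) for k, v in self.annotations.items()},
            provenance=self.provenance,
        )


@dataclass
class Model:
    id: str
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    genes: dict[str, Gene] = field(default_factory=dict)
    compartments: dict[str, str] = field(default_factory=dict)
    objective: dict[str, float] = field(default_factory=dict)
    extracellular: str = "e"

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ModelIntegrityError(f"duplicate metabolite id {met.id!r}")
        if met.compartment not in self.compartments:
            self.compartments.setdefault(met.compartment, met.compartment)
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ModelIntegrityError(f"duplicate reaction id {rxn.id!r}")
        if not rxn.stoichiometry:
            raise ModelIntegrityError(f"reaction {rxn.id} has empty stoichiometry")
        for mid in rxn.stoichiometry:
            if mid not in self.metabolites:
                raise ModelIntegrityError(
                    f"reaction {rxn.id} references unknown metabolite {mid!r}"
                )
        for gid in rxn.gpr.genes:
            if gid not in self.genes:
                self.genes[gid] = Gene(gid)
        self.reactions[rxn.id] = rxn

    def remove_reaction(self, rxn_id: str) -> None:
        if rxn_id not in self.reactions:
            raise ModelIntegrityError(f"unknown reaction id {rxn_id!r}")
        del self.reactions[rxn_id]
        self.objective.pop(rxn_id, None)

    def validate(self) -> None:
        """Assert all cross-reference invariants, raising on violation."""
        for rxn in self.reactions.values():
            if not rxn.stoichiometry:
                raise ModelIntegrityError(f"reaction {rxn.id} empty")
            for mid in rxn.stoichiometry:
                if mid not in self.metabolites:
                    raise ModelIntegrityError(
                        f"reaction {rxn.id} references unknown metabolite {mid!r}"
                    )
            for gid in rxn.gpr.genes:
                if gid not in self.genes:
                    raise ModelIntegrityError(
                        f"reaction {rxn.id} references unknown gene {gid!r}"
                    )
        for met in self.metabolites.values():
            if met.compartment not in self.compartments:
                raise ModelIntegrityError(
                    f"metabolite {met.id} in undeclared compartment "
                    f"{met.compartment!r}"
                )
        for rid in self.objective:
            if rid not in self.reactions:
                raise ModelIntegrityError(f"objective reaction {rid!r} missing")

    def is_exchange(self, rxn_id: str) -> bool:
        """Boundary reaction of the form ``1 met_e ->`` (single metabolite
        in the extracellular compartment); negative flux denotes uptake."""
        rxn = self.reactions[rxn_id]
        if len(rxn.stoichiometry) != 1:
            return False
        (mid,) = rxn.stoichiometry
        return self.metabolites[mid].compartment == self.extracellular

    @property
    def exchanges(self) -> list[str]:
        return [rid for rid in self.reactions if self.is_exchange(rid)]

    def copy(self) -> "Model":
        return Model(
            id=self.id,
            metabolites={
                mid: replace(m, formula=dict(m.formula) if m.formula else None,
                             annotations={k: list(v) for k, v in m.annotations.items()})
                for mid, m in self.metabolites.items()
            },
            reactions={rid: r.copy() for rid, r in self.reactions.items()},
            genes={gid: replace(g) for gid, g in self.genes.items()},
            compartments=dict(self.compartments),
            objective=dict(self.objective),
            extracellular=self.extracellular,
        )


# ---------------------------------------------------------------------------
# balance audit
# ---------------------------------------------------------------------------

@dataclass
class BalanceReport:
    reaction_id: str
    element_residual: dict[str, Fraction]
    charge_residual: Fraction | None
    status: str  # "balanced" | "imbalanced" | "unbalanceable"

    @property
    def is_balanced(self) -> bool:
        return self.status == "balanced"


def check_balance(rxn: Reaction, model: Model) -> BalanceReport:
    """Elemental and charge residuals of one reaction (products − reactants).

    A reaction is *unbalanceable* (rather than imbalanced) when any
    participant lacks a formula or a charge, or carries the rest-group
    pseudo-element "R" — the convention for carrier-bound intermediates
    whose protein domain is not given an elemental composition.  Audits
    report such reactions; they never guess.
    """
    residual: dict[str, Fraction] = {}
    charge: Fraction | None = Fraction(0)
    unbalanceable = False
    for mid, coeff in rxn.stoichiometry.items():
        met = model.metabolites[mid]
        if met.formula is None or met.has_rest_group:
            return BalanceReport(rxn.id, {}, None, "unbalanceable")
        for el, n in met.formula.items():
            residual[el] = residual.get(el, Fraction(0)) + coeff * n
        if charge is not None:
            if met.charge is None:
                charge = None
            else:
                charge += coeff * met.charge
    residual = {el: r for el, r in residual.items() if r != 0}
    if charge is None:
        # elemental residuals are still informative; charge cannot be assessed
        return BalanceReport(rxn.id, residual, None, "unbalanceable")
    balanced = not residual and charge == 0
    status = "balanced" if balanced else "imbalanced"
    return BalanceReport(rxn.id, residual, charge, status)


# ---------------------------------------------------------------------------
# duplicate-reaction audit
# ---------------------------------------------------------------------------

@dataclass
class DuplicateGroup:
    reaction_ids: list[str]
    orientation: dict[str, str]  # reaction id -> "same" | "reversed"
    gpr_differs: bool
    bounds_differ: bool


def _canonical_stoichiometry(
    stoich: Mapping[str, Fraction]
) -> tuple[tuple[tuple[str, Fraction], ...], str]:
    """Orientation-independent canonical form plus the sign used.

    The representative orientation is whichever of (stoich, -stoich)
    compares lexicographically smaller, so a reaction and its mirror
    canonicalise identically.
    """
    fwd = tuple(sorted(stoich.items()))
    rev = tuple(sorted((m, -c) for m, c in stoich.items()))
    if fwd <= rev:
        return fwd, "same"
    return rev, "reversed"


def find_duplicate_reactions(model: Model) -> list[DuplicateGroup]:
    """Group reactions with identical stoichiometry up to orientation.

    GPR and bound differences never block grouping; they are reported
    per group so curation can decide which copy to keep.
    """
    buckets: dict[tuple, list[tuple[str, str]]] = {}
    for rid, rxn in model.reactions.items():
        key, orient = _canonical_stoichiometry(rxn.stoichiometry)
        buckets.setdefault(key, []).append((rid, orient))
    groups = []
    for members in buckets.values():
        if len(members) < 2:
            continue
        ids = sorted(rid for rid, _ in members)
        orientation = dict(members)
        gprs = {model.reactions[r].gpr.to_string() for r in ids}
        bounds = {
            (model.reactions[r].lower_bound, model.reactions[r].upper_bound)
            for r in ids
        }
        groups.append(
            DuplicateGroup(
                reaction_ids=ids,
                orientation=orientation,
                gpr_differs=len(gprs) > 1,
                bounds_differ=len(bounds) > 1,
            )
        )
    groups.sort(key=lambda g: g.reaction_ids)
    return groups
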