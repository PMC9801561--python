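"""Draft-model assembly from a reference panel, with provenance and curation.

The strain-specific draft is built in two moves mirroring the
multi-reference reconstruction workflow: (1) *reduce* a high-quality
base model to the reactions whose gene requirements survive the
orthology map (spontaneous reactions and designated artificial genes
are exempt), rewriting every GPR onto target-strain gene ids; (2)
*augment* the reduced model from an ordered panel of further reference
models, adding each absent reaction whose translated GPR is
satisfiable, with first-come provenance.  Curation utilities audit
energy-generating cycles, gap-fill infeasible objectives against a
universal reaction set (cardinality-minimal, MILP), and apply targeted
removals/deactivations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import LinearConstraint, milp
from scipy.optimize import Bounds as OptBounds

from .core import Metabolite, Model, ModelIntegrityError, Reaction
from .flux import REPORT_TOL, FluxResult, StoichiometricLP, fba, solve_lp
from .gpr import GeneRule, translate_gpr


# ---------------------------------------------------------------------------
# provenance
# ---------------------------------------------------------------------------

@dataclass
class ProvenanceLedger:
    """Origin accounting: every reaction has exactly one origin entry."""

    origins: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_model(cls, model: Model) -> "ProvenanceLedger":
        return cls({rid: rxn.provenance for rid, rxn in model.reactions.items()})

    def counts_by_origin(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for origin in self.origins.values():
            out[origin] = out.get(origin, 0) + 1
        return out

    def table(self, model: Model) -> pd.DataFrame:
        """Per-subsystem, per-origin reaction counts."""
        rows = [
            {
                "subsystem": model.reactions[rid].subsystem or "(none)",
                "origin": origin,
            }
            for rid, origin in self.origins.items()
        ]
        df = pd.DataFrame(rows)
        return (
            df.groupby(["subsystem", "origin"]).size().rename("n_reactions").reset_index()
        )

    def total(self) -> int:
        return len(self.origins)


# ---------------------------------------------------------------------------
# reduction and augmentation
# ---------------------------------------------------------------------------

def _prune_orphans(model: Model) -> None:
    """Drop metabolites and genes referenced by no reaction."""
    used_mets: set[str] = set()
    used_genes: set[str] = set()
    for rxn in model.reactions.values():
        used_mets |= set(rxn.stoichiometry)
        used_genes |= rxn.gpr.genes
    model.metabolites = {m: v for m, v in model.metabolites.items() if m in used_mets}
    model.genes = {g: v for g, v in model.genes.items() if g in used_genes}


def reduce_base_model(
    base: Model,
    ortholog_map: Mapping[str, str],
    artificial_genes: Iterable[str] = (),
    strict: bool = False,
) -> Model:
    """Keep base reactions whose gene requirement survives the orthology map.

    Default semantics: a reaction is retained iff its GPR is empty or
    its translated GPR is satisfiable (an isozyme pair with one
    surviving gene keeps its reaction).  ``strict=True`` removes any
    reaction mentioning a gene without an ortholog.  Artificial genes
    (e.g. the spontaneous-reaction pseudo-gene) are kept verbatim and
    always count as present.  Provenance of retained reactions is the
    base model id.
    """
    artificial = set(artificial_genes)
    unknown = artificial - set(base.genes)
    if unknown:
        raise ModelIntegrityError(f"artificial genes not in base model: {sorted(unknown)}")
    full_map = dict(ortholog_map)
    full_map.update({g: g for g in artificial})

    out = Model(id=f"{base.id}_reduced", extracellular=base.extracellular)
    out.compartments = dict(base.compartments)
    out.metabolites = {m: v for m, v in base.copy().metabolites.items()}
    for rid, rxn in base.reactions.items():
        if rxn.gpr.is_empty:
            new_rule: GeneRule = rxn.gpr
        else:
            if strict and not rxn.gpr.genes <= set(full_map):
                continue
            new_rule = translate_gpr(rxn.gpr, full_map)
            if new_rule.is_unsatisfiable:
                continue
        new = rxn.copy()
        new.gpr = new_rule
        new.provenance = base.id
        out.add_reaction(new)
    out.objective = {r: w for r, w in base.objective.items() if r in out.reactions}
    _prune_orphans(out)
    out.validate()
    return out


@dataclass
class AugmentationLog:
    added: dict[str, str] = field(default_factory=dict)  # reaction -> origin model
    skipped_conflicts: list[tuple[str, str]] = field(default_factory=list)


def augment_from_references(
    draft: Model,
    refs: Sequence[Model],
    maps: Mapping[str, Mapping[str, str]],
    include_spontaneous: bool = False,
) -> tuple[Model, ProvenanceLedger, AugmentationLog]:
    """Add reference reactions backed by orthologous genes to the draft.

    References are processed in the given order; a reaction id already
    present (from the draft or an earlier reference) is never
    overwritten — the first contributing model wins the provenance
    entry, and a later same-id reaction with different stoichiometry is
    logged as a skipped conflict.  Gene-independent (empty-GPR)
    reference reactions are only imported with
    ``include_spontaneous=True``, since augmentation is driven by gene
    homology.
    """
    out = draft.copy()
    log = AugmentationLog()
    for ref in refs:
        omap = dict(maps.get(ref.id, {}))
        for rid, rxn in ref.reactions.items():
            if rid in out.reactions:
                if out.reactions[rid].stoichiometry != rxn.stoichiometry:
                    log.skipped_conflicts.append((rid, ref.id))
                continue
            if rxn.gpr.is_empty:
                if not include_spontaneous:
                    continue
                new_rule = rxn.gpr
            else:
                new_rule = translate_gpr(rxn.gpr, omap)
                if new_rule.is_unsatisfiable:
                    continue
            for mid in rxn.stoichiometry:
                if mid not in out.metabolites:
                    met = ref.metabolites[mid]
                    out.add_metabolite(
                        Metabolite(
                            id=met.id,
                            name=met.name,
                            compartment=met.compartment,
                            formula=dict(met.formula) if met.formula else None,
                            charge=met.charge,
                            annotations={k: list(v) for k, v in met.annotations.items()},
                        )
                    )
            new = rxn.copy()
            new.gpr = new_rule
            new.provenance = ref.id  # bounds copied from the contributing reference
            out.add_reaction(new)
            log.added[rid] = ref.id
    out.validate()
    return out, ProvenanceLedger.from_model(out), log


# ---------------------------------------------------------------------------
# energy-generating cycles
# ---------------------------------------------------------------------------

#: default energy currencies probed for futile generation, as
#: (name, substrates, products) over metabolite ids; only currencies whose
#: metabolites all exist in the model are tested.
DEFAULT_CURRENCIES: list[tuple[str, dict[str, int], dict[str, int]]] = [
    ("ATP", {"atp_c": 1, "h2o_c": 1}, {"adp_c": 1, "pi_c": 1, "h_c": 1}),
    ("NADH", {"nadh_c": 1}, {"nad_c": 1, "h_c": 1}),
    ("NADPH", {"nadph_c": 1}, {"nadp_c": 1, "h_c": 1}),
    ("FADH2", {"fadh2_c": 1}, {"fad_c": 1, "h_c": 2}),
    ("PMF", {"h_e": 1}, {"h_c": 1}),
]


@dataclass
class EgcReport:
    currency: str
    dissipation_reaction: str
    optimum: float
    flagged: bool
    support: dict[str, float] = field(default_factory=dict)


def detect_energy_generating_cycles(
    model: Model,
    dissipation_reactions: Mapping[str, str] | None = None,
    currencies=None,
    tolerance: float = REPORT_TOL,
) -> list[EgcReport]:
    """Probe for futile cycles that generate energy currency from nothing.

    All exchange lower bounds are clamped to 0 (closed system) and each
    currency's dissipation reaction is maximised; a strictly positive
    optimum means some internal cycle regenerates the currency and is
    flagged together with the nonzero-flux support of one optimal
    solution.

    ``dissipation_reactions`` maps currency name -> existing reaction id;
    otherwise temporary dissipation reactions are created from
    ``currencies`` (default: ATP, NADH, NADPH, FADH2 and proton-motive
    force) for every currency whose metabolites the model contains.
    """
    closed = model.copy()
    for rid in closed.exchanges:
        closed.reactions[rid].lower_bound = 0.0
    # relax forced demands (e.g. maintenance lb > 0): the probe asks whether
    # cycles CAN generate currency, not whether demands are met
    for rxn in closed.reactions.values():
        rxn.lower_bound = min(rxn.lower_bound, 0.0)

    probes: list[tuple[str, str]] = []  # (currency, reaction id)
    if dissipation_reactions:
        for name, rid in dissipation_reactions.items():
            if rid not in closed.reactions:
                raise ModelIntegrityError(f"dissipation reaction {rid!r} not in model")
            rxn = closed.reactions[rid]
            rxn.lower_bound = 0.0
            rxn.upper_bound = 1000.0
            probes.append((name, rid))
    else:
        for name, subs, prods in (currencies or DEFAULT_CURRENCIES):
            mets = set(subs) | set(prods)
            if not mets <= set(closed.metabolites):
                continue
            rid = f"_EGC_DISS_{name}"
            stoich = {m: -c for m, c in subs.items()}
            for m, c in prods.items():
                stoich[m] = stoich.get(m, 0) + c
            closed.add_reaction(
                Reaction(id=rid, stoichiometry=stoich, lower_bound=0.0, upper_bound=1000.0)
            )
            probes.append((name, rid))

    reports = []
    for name, rid in probes:
        res = fba(closed, objective=rid, sense="max")
        if res.status == "unbounded":
            # cap the probe and re-solve to obtain a support
            res = fba(closed, objective=rid, sense="max")
        if not res.optimal:
            raise ModelIntegrityError(
                f"EGC probe for {name}: LP status {res.status} on closed model"
            )
        optimum = res.objective_value
        flagged = optimum > tolerance
        support = (
            {r: v for r, v in res.fluxes.items() if abs(v) > tolerance and r != rid}
            if flagged
            else {}
        )
        reports.append(EgcReport(name, rid, optimum, flagged, support))
    return reports


# ---------------------------------------------------------------------------
# gap filling
# ---------------------------------------------------------------------------

@dataclass
class GapfillSolution:
    feasible: bool
    solutions: list[frozenset[str]] = field(default_factory=list)
    objective_flux: dict[frozenset[str], float] = field(default_factory=dict)

    @property
    def best(self) -> frozenset[str] | None:
        return self.solutions[0] if self.solutions else None


def _combined_lp(model: Model, universal: Sequence[Reaction]):
    extended = model.copy()
    for rxn in universal:
        for mid in rxn.stoichiometry:
            if mid not in extended.metabolites:
                extended.add_metabolite(Metabolite(id=mid, compartment="c"))
        extended.add_reaction(rxn.copy())
    return extended


def gapfill(
    model: Model,
    universal: Sequence[Reaction],
    objective_rxn: str,
    min_flux: float = 1e-2,
    max_solutions: int = 1,
) -> GapfillSolution:
    """Cardinality-minimal universal-reaction sets restoring objective flux.

    MILP with one binary usage indicator per universal reaction:
    minimise Σy subject to S·v = 0, v_obj ≥ min_flux and
    lb_j·y_j ≤ v_j ≤ ub_j·y_j for universal j.  Returns the empty set
    when the model is already feasible, and a ``feasible=False`` result
    when even the full universal set cannot reach ``min_flux``.
    Additional equally-minimal sets are enumerated (up to
    ``max_solutions``) with no-good cuts.
    """
    if objective_rxn not in model.reactions:
        raise ModelIntegrityError(f"objective reaction {objective_rxn!r} not in model")
    clash = {r.id for r in universal} & set(model.reactions)
    if clash:
        raise ModelIntegrityError(f"universal ids already in model: {sorted(clash)}")

    base = fba(model, objective=objective_rxn, sense="max")
    if base.optimal and base.objective_value >= min_flux - REPORT_TOL:
        return GapfillSolution(True, [frozenset()], {frozenset(): base.objective_value})

    extended = _combined_lp(model, universal)
    lp = StoichiometricLP(extended)
    n = len(lp.reaction_ids)
    k = len(universal)
    univ_idx = [lp.rxn_index[r.id] for r in universal]

    n_var = n + k
    c = np.zeros(n_var)
    c[n:] = 1.0
    integrality = np.zeros(n_var)
    integrality[n:] = 1.0
    lo = np.concatenate([lp.lb, np.zeros(k)])
    hi = np.concatenate([lp.ub, np.ones(k)])
    # objective flux requirement
    obj_j = lp.rxn_index[objective_rxn]
    lo_extra = []

    cons = []
    S_ext = sparse.hstack([lp.S, sparse.csr_matrix((lp.S.shape[0], k))]).tocsr()
    cons.append(LinearConstraint(S_ext, 0.0, 0.0))
    row = np.zeros(n_var)
    row[obj_j] = 1.0
    cons.append(LinearConstraint(row[None, :], min_flux, np.inf))
    # indicator coupling: v_j - ub_j y_j <= 0 and v_j - lb_j y_j >= 0
    rows_u, rows_l = [], []
    for pos, j in enumerate(univ_idx):
        ru = np.zeros(n_var)
        ru[j] = 1.0
        ru[n + pos] = -lp.ub[j]
        rows_u.append(ru)
        rl = np.zeros(n_var)
        rl[j] = 1.0
        rl[n + pos] = -lp.lb[j]
        rows_l.append(rl)
    if rows_u:
        cons.append(LinearConstraint(np.array(rows_u), -np.inf, 0.0))
        cons.append(LinearConstraint(np.array(rows_l), 0.0, np.inf))

    result = GapfillSolution(False)
    cuts: list[LinearConstraint] = []
    k_min: int | None = None
    for _ in range(max_solutions):
        res = milp(
            c,
            constraints=cons + cuts,
            integrality=integrality,
            bounds=OptBounds(lo, hi),
        )
        if not res.success:
            break
        chosen = frozenset(
            universal[pos].id for pos in range(k) if res.x[n + pos] > 0.5
        )
        if k_min is None:
            k_min = len(chosen)
            # pin cardinality so later enumerations stay minimal
            card = np.zeros(n_var)
            card[n:] = 1.0
            cuts.append(LinearConstraint(card[None, :], k_min, k_min))
        elif len(chosen) > k_min:
            break
        result.feasible = True
        result.solutions.append(chosen)
        result.objective_flux[chosen] = float(res.x[obj_j])
        # no-good cut: exclude this exact set
        cut = np.zeros(n_var)
        for pos in range(k):
            if universal[pos].id in chosen:
                cut[n + pos] = 1.0
        cuts.append(LinearConstraint(cut[None, :], -np.inf, len(chosen) - 1))
        if len(chosen) == 0:
            break
    return result


# ---------------------------------------------------------------------------
# targeted edits
# ---------------------------------------------------------------------------

@dataclass
class EditResult:
    model: Model
    log: list[tuple[str, str]] = field(default_factory=list)  # (action, reaction)


def apply_edits(
    model: Model,
    removals: Iterable[str] = (),
    deactivations: Iterable[str] = (),
) -> EditResult:
    """Delete ``removals`` and pin ``deactivations`` to zero flux."""
    removals = list(removals)
    deactivations = list(deactivations)
    unknown = [r for r in removals + deactivations if r not in model.reactions]
    if unknown:
        raise ModelIntegrityError(f"unknown reaction id(s): {unknown}")
    out = model.copy()
    log: list[tuple[str, str]] = []
    for rid in removals:
        out.remove_reaction(rid)
        log.append(("removed", rid))
    for rid in deactivations:
        out.reactions[rid].lower_bound = 0.0
        out.reactions[rid].upper_bound = 0.0
        log.append(("deactivated", rid))
    _prune_orphans(out)
    return EditResult(out, log)
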