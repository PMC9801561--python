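"""Constraint-based flux analysis on a stoichiometric model.

Everything here is phrased over one LP template: maximise or minimise a
linear objective c·v subject to steady state S·v = 0 and flux bounds
lb ≤ v ≤ ub.  The solver sits behind a minimal contract
(:func:`solve_lp`, currently the HiGHS backend of scipy) so results are
reproducible across LP libraries.  Flux units are mmol·gDW⁻¹·h⁻¹; the
objective value of a biomass reaction is the growth rate in h⁻¹.

Degenerate optima are a fact of FBA: plain :func:`fba` returns *an*
optimal vertex, and all downstream claims should be made on objective
values, pFBA flux totals or FVA intervals, never on individual FBA
fluxes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from scipy import sparse
from scipy.optimize import linprog

from .core import Model, ModelIntegrityError

#: reporting tolerance: mass balance and bound violations above this are bugs
REPORT_TOL = 1e-6
#: numerical tolerance used when fixing fluxes at previously solved optima
FIX_TOL = 1e-9

OXYGEN_EXCHANGE = "EX_o2_e"


class FluxAnalysisError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# LP contract
# ---------------------------------------------------------------------------

@dataclass
class LPSolution:
    status: str  # "optimal" | "infeasible" | "unbounded" | "failed"
    objective: float | None
    x: np.ndarray | None


def solve_lp(
    c: np.ndarray,
    A_eq: sparse.spmatrix,
    b_eq: np.ndarray,
    bounds: Sequence[tuple[float, float]],
    sense: str = "max",
    A_ub: sparse.spmatrix | None = None,
    b_ub: np.ndarray | None = None,
) -> LPSolution:
    """Solve max/min c·v s.t. A_eq v = b_eq, A_ub v ≤ b_ub, bounds.

    This is the whole backend contract: load the matrix, set bounds and
    objective, solve, read the primal.
    """
    sign = -1.0 if sense == "max" else 1.0
    res = linprog(
        sign * np.asarray(c, dtype=float),
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=list(bounds),
        method="highs",
    )
    if res.status == 0:
        return LPSolution("optimal", sign * res.fun, res.x)
    if res.status == 2:
        return LPSolution("infeasible", None, None)
    if res.status == 3:
        return LPSolution("unbounded", None, None)
    return LPSolution("failed", None, None)


class StoichiometricLP:
    """Indexed LP view of a model: S matrix, bounds, named objectives."""

    def __init__(self, model: Model):
        model.validate()
        self.model = model
        self.reaction_ids = list(model.reactions)
        self.metabolite_ids = list(model.metabolites)
        self.rxn_index = {rid: j for j, rid in enumerate(self.reaction_ids)}
        met_index = {mid: i for i, mid in enumerate(self.metabolite_ids)}
        rows, cols, vals = [], [], []
        lb = np.empty(len(self.reaction_ids))
        ub = np.empty(len(self.reaction_ids))
        for j, rid in enumerate(self.reaction_ids):
            rxn = model.reactions[rid]
            if rxn.lower_bound > rxn.upper_bound:
                raise ModelIntegrityError(
                    f"reaction {rid}: lower bound exceeds upper bound"
                )
            lb[j], ub[j] = rxn.lower_bound, rxn.upper_bound
            for mid, coeff in rxn.stoichiometry.items():
                rows.append(met_index[mid])
                cols.append(j)
                vals.append(float(coeff))
        self.S = sparse.csr_matrix(
            (vals, (rows, cols)),
            shape=(len(self.metabolite_ids), len(self.reaction_ids)),
        )
        self.lb = lb
        self.ub = ub

    def objective_vector(self, objective: Mapping[str, float]) -> np.ndarray:
        c = np.zeros(len(self.reaction_ids))
        for rid, w in objective.items():
            if rid not in self.rxn_index:
                raise FluxAnalysisError(f"objective reaction {rid!r} not in model")
            c[self.rxn_index[rid]] = w
        return c

    def check_solution(self, v: np.ndarray) -> None:
        """Assert ‖S·v‖∞ ≤ tolerance and bound feasibility on every solve."""
        residual = np.abs(self.S @ v).max() if v.size else 0.0
        if residual > REPORT_TOL:
            raise FluxAnalysisError(
                f"mass-balance violation ‖Sv‖∞ = {residual:.2e} > {REPORT_TOL}"
            )
        if (v < self.lb - REPORT_TOL).any() or (v > self.ub + REPORT_TOL).any():
            raise FluxAnalysisError("flux bounds violated beyond tolerance")


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class FluxResult:
    status: str
    objective_value: float | None = None
    fluxes: dict[str, float] = field(default_factory=dict)
    total_flux: float | None = None  # Σ|v|, set by pFBA

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class FvaRange:
    minimum: float
    maximum: float
    fraction: float

    def contains(self, value: float, tol: float = REPORT_TOL) -> bool:
        return self.minimum - tol <= value <= self.maximum + tol


# ---------------------------------------------------------------------------
# media
# ---------------------------------------------------------------------------

Medium = dict[str, float]


def read_medium(path: str | Path) -> Medium:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return {str(k): float(v) for k, v in data.items()}


def write_medium(medium: Medium, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dict(medium), sort_keys=True))


def apply_medium(
    model: Model,
    medium: Medium,
    aerobic: bool = True,
    oxygen_exchange: str = OXYGEN_EXCHANGE,
) -> Model:
    """Return a copy with uptake limited to the stated medium.

    Every exchange lower bound is first closed to 0, then each medium
    entry ``EX_x: u`` opens uptake to −u (BiGG sign convention: negative
    exchange flux is uptake).  Anaerobic conditions are simulated by
    closing the oxygen exchange lower bound after the medium is applied.
    """
    for rid, uptake in medium.items():
        if rid not in model.reactions:
            raise FluxAnalysisError(f"medium reaction {rid!r} not in model")
        if not model.is_exchange(rid):
            raise FluxAnalysisError(f"medium reaction {rid!r} is not an exchange")
        if uptake <= 0:
            raise FluxAnalysisError(f"medium uptake for {rid!r} must be positive")
    out = model.copy()
    for rid in out.exchanges:
        out.reactions[rid].lower_bound = 0.0
    for rid, uptake in medium.items():
        out.reactions[rid].lower_bound = -float(uptake)
    if not aerobic and oxygen_exchange in out.reactions:
        out.reactions[oxygen_exchange].lower_bound = 0.0
    return out


# ---------------------------------------------------------------------------
# FBA / pFBA / FVA
# ---------------------------------------------------------------------------

def _resolve_objective(model: Model, objective: str | Mapping[str, float] | None):
    if objective is None:
        if not model.objective:
            raise FluxAnalysisError("model has no objective and none was given")
        return dict(model.objective)
    if isinstance(objective, str):
        return {objective: 1.0}
    return dict(objective)


def fba(
    model: Model,
    objective: str | Mapping[str, float] | None = None,
    sense: str = "max",
) -> FluxResult:
    """Flux balance analysis: one LP, an optimal vertex if feasible."""
    lp = StoichiometricLP(model)
    c = lp.objective_vector(_resolve_objective(model, objective))
    sol = solve_lp(c, lp.S, np.zeros(lp.S.shape[0]), list(zip(lp.lb, lp.ub)), sense)
    if sol.status != "optimal":
        return FluxResult(status=sol.status)
    lp.check_solution(sol.x)
    return FluxResult(
        status="optimal",
        objective_value=sol.objective,
        fluxes=dict(zip(lp.reaction_ids, sol.x.tolist())),
    )


def pfba(
    model: Model,
    objective: str | Mapping[str, float] | None = None,
    fraction: float = 1.0,
) -> FluxResult:
    """Parsimonious FBA: minimise Σ|v| at ≥ ``fraction`` of the optimum.

    Reversible fluxes are split into non-negative forward/backward
    parts; the reported ``total_flux`` is the unique minimum of Σ|v|
    even when individual fluxes remain degenerate.
    """
    obj = _resolve_objective(model, objective)
    first = fba(model, obj, "max")
    if not first.optimal:
        return first
    lp = StoichiometricLP(model)
    n = len(lp.reaction_ids)
    c_obj = lp.objective_vector(obj)
    # v = p - q with p, q >= 0
    A_eq = sparse.hstack([lp.S, -lp.S]).tocsr()
    bounds = [(max(lb, 0.0), max(ub, 0.0)) for lb, ub in zip(lp.lb, lp.ub)]
    bounds += [(max(-ub, 0.0), max(-lb, 0.0)) for lb, ub in zip(lp.lb, lp.ub)]
    # keep the objective at (a fraction of) its optimum
    target = fraction * first.objective_value
    A_ub = sparse.csr_matrix(np.concatenate([-c_obj, c_obj])[None, :])
    b_ub = np.array([-target + FIX_TOL])
    sol = solve_lp(
        np.ones(2 * n),
        A_eq,
        np.zeros(A_eq.shape[0]),
        bounds,
        sense="min",
        A_ub=A_ub,
        b_ub=b_ub,
    )
    if sol.status != "optimal":
        return FluxResult(status=sol.status)
    v = sol.x[:n] - sol.x[n:]
    lp.check_solution(v)
    return FluxResult(
        status="optimal",
        objective_value=float(c_obj @ v),
        fluxes=dict(zip(lp.reaction_ids, v.tolist())),
        total_flux=float(sol.objective),
    )


def fva(
    model: Model,
    reactions: Iterable[str] | None = None,
    fraction: float = 1.0,
    objective: str | Mapping[str, float] | None = None,
) -> dict[str, FvaRange]:
    """Flux variability analysis at a fraction of the objective optimum.

    Two LPs per reaction (min and max) with c·v ≥ fraction·optimum
    appended as an extra constraint row.
    """
    if not 0 <= fraction <= 1:
        raise FluxAnalysisError("FVA fraction must lie in [0, 1]")
    obj = _resolve_objective(model, objective)
    first = fba(model, obj, "max")
    if not first.optimal:
        raise FluxAnalysisError(f"FVA reference FBA not optimal: {first.status}")
    lp = StoichiometricLP(model)
    c_obj = lp.objective_vector(obj)
    A_ub = sparse.csr_matrix(-c_obj[None, :])
    b_ub = np.array([-fraction * first.objective_value + FIX_TOL])
    bounds = list(zip(lp.lb, lp.ub))
    targets = list(reactions) if reactions is not None else list(lp.reaction_ids)
    out: dict[str, FvaRange] = {}
    b_eq = np.zeros(lp.S.shape[0])
    for rid in targets:
        if rid not in lp.rxn_index:
            raise FluxAnalysisError(f"FVA reaction {rid!r} not in model")
        c = np.zeros(len(lp.reaction_ids))
        c[lp.rxn_index[rid]] = 1.0
        lo = solve_lp(c, lp.S, b_eq, bounds, "min", A_ub, b_ub)
        hi = solve_lp(c, lp.S, b_eq, bounds, "max", A_ub, b_ub)
        if lo.status != "optimal" or hi.status != "optimal":
            raise FluxAnalysisError(f"FVA subproblem for {rid!r}: {lo.status}/{hi.status}")
        vmin = min(lo.objective, hi.objective)
        vmax = max(lo.objective, hi.objective)
        out[rid] = FvaRange(minimum=vmin, maximum=vmax, fraction=fraction)
    return out


# ---------------------------------------------------------------------------
# knockouts and essentiality screens
# ---------------------------------------------------------------------------

def knockout(model: Model, genes: Iterable[str]) -> Model:
    """Copy of the model with every reaction disabled whose GPR fails.

    A reaction closes (bounds 0,0) iff its GPR evaluates false with the
    deleted genes removed; empty-GPR (spontaneous) reactions are never
    affected.
    """
    genes = set(genes)
    unknown = genes - set(model.genes)
    if unknown:
        raise FluxAnalysisError(f"unknown gene id(s): {sorted(unknown)}")
    present = frozenset(set(model.genes) - genes)
    out = model.copy()
    for rxn in out.reactions.values():
        if not rxn.gpr.evaluate(present):
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    return out


def _wild_type_growth(model: Model, objective) -> float:
    wt = fba(model, objective)
    if not wt.optimal or wt.objective_value is None or wt.objective_value <= REPORT_TOL:
        raise FluxAnalysisError(
            "wild-type growth is zero or infeasible; essentiality undefined"
        )
    return wt.objective_value


@dataclass
class DeletionScreen:
    wild_type_growth: float
    growth: dict  # gene / reaction / pair -> growth rate
    essential: set
    threshold: float


def single_gene_deletion(
    model: Model,
    threshold: float = 0.05,
    objective: str | Mapping[str, float] | None = None,
) -> DeletionScreen:
    """Knock out each gene; essential iff growth < threshold·WT."""
    wt = _wild_type_growth(model, objective)
    growth: dict[str, float] = {}
    essential: set[str] = set()
    for gid in sorted(model.genes):
        res = fba(knockout(model, {gid}), objective)
        g = res.objective_value if res.optimal else 0.0
        growth[gid] = g
        if g < threshold * wt:
            essential.add(gid)
    return DeletionScreen(wt, growth, essential, threshold)


def double_gene_deletion(
    model: Model,
    threshold: float = 0.05,
    objective: str | Mapping[str, float] | None = None,
    genes: Iterable[str] | None = None,
    single: DeletionScreen | None = None,
) -> DeletionScreen:
    """Synthetic-lethal screen over pairs of individually viable genes.

    Genes essential on their own are excluded from the candidate pairs
    (a synthetic lethal is by definition a pair of non-essential genes).
    ``genes`` restricts the candidate set (e.g. a subsample for large
    models).
    """
    if single is None:
        single = single_gene_deletion(model, threshold, objective)
    wt = single.wild_type_growth
    candidates = sorted(
        (set(genes) if genes is not None else set(model.genes)) - single.essential
    )
    growth: dict[tuple[str, str], float] = {}
    lethal: set[tuple[str, str]] = set()
    for ga, gb in itertools.combinations(candidates, 2):
        res = fba(knockout(model, {ga, gb}), objective)
        g = res.objective_value if res.optimal else 0.0
        growth[(ga, gb)] = g
        if g < threshold * wt:
            lethal.add((ga, gb))
    return DeletionScreen(wt, growth, lethal, threshold)


def single_reaction_deletion(
    model: Model,
    threshold: float = 0.05,
    objective: str | Mapping[str, float] | None = None,
) -> DeletionScreen:
    """Close each reaction (bounds 0,0); essential iff growth < threshold·WT."""
    wt = _wild_type_growth(model, objective)
    growth: dict[str, float] = {}
    essential: set[str] = set()
    for rid in sorted(model.reactions):
        variant = model.copy()
        variant.reactions[rid].lower_bound = 0.0
        variant.reactions[rid].upper_bound = 0.0
        res = fba(variant, objective)
        g = res.objective_value if res.optimal else 0.0
        growth[rid] = g
        if g < threshold * wt:
            essential.add(rid)
    return DeletionScreen(wt, growth, essential, threshold)
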