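"""Flux scanning with enforced objective function (FSEOF) and
biomass-constraint sensitivity sweeps.

FSEOF steps the flux of a product exchange from its level at the
unconstrained biomass optimum up to a fraction of its theoretical
maximum; at every step biomass is re-maximised and a parsimonious FBA
fixes a representative flux distribution (pFBA rather than plain FBA,
so profiles are not polluted by degenerate-optimum noise).  Reactions
whose flux co-varies monotonically with enforced production are
engineering targets: amplification for positive slope, attenuation for
negative.  The complementary sensitivity sweep pins biomass to a grid
of fractions of its optimum while maximising the product, recording
pFBA fluxes and FVA intervals for a watch list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import Model
from .flux import REPORT_TOL, FluxAnalysisError, FvaRange, fba, fva, pfba

SLOPE_TOL = 1e-6


@dataclass
class FseofResult:
    product_exchange: str
    grid: list[float]  # enforced product fluxes, strictly increasing
    profiles: dict[str, list[float]]  # reaction -> flux at each step
    slopes: dict[str, float]
    classification: dict[str, str]  # amplification | attenuation | none
    excluded: list[str]
    diagnostics: str = ""

    @property
    def feasible(self) -> bool:
        return not self.diagnostics

    def targets(self, kind: str) -> list[str]:
        return sorted(r for r, c in self.classification.items() if c == kind)


def compute_slope(profile: Sequence[float], grid: Sequence[float]) -> float:
    """Ordinary least-squares slope of reaction flux against product flux."""
    if len(profile) != len(grid) or len(grid) < 2:
        raise ValueError("profile and grid must have equal length >= 2")
    x = np.asarray(grid, dtype=float)
    y = np.asarray(profile, dtype=float)
    var = np.var(x)
    if var == 0:
        raise ValueError("degenerate grid: zero variance in product flux")
    return float(np.cov(x, y, bias=True)[0, 1] / var)


def _monotone_direction(profile: Sequence[float], tol: float = SLOPE_TOL) -> str | None:
    diffs = np.diff(np.asarray(profile, dtype=float))
    if (diffs >= -tol).all():
        return "up"
    if (diffs <= tol).all():
        return "down"
    return None


def fseof_scan(
    model: Model,
    biomass_rxn: str,
    product_ex: str,
    n_steps: int = 10,
    max_fraction: float = 0.9,
    exclude: Iterable[str] = (),
) -> FseofResult:
    """Scan enforced product flux; classify sign-consistent co-varying
    reactions as amplification (slope > 0) or attenuation (slope < 0).

    The grid runs linearly from the product flux at the unconstrained
    biomass optimum to ``max_fraction`` of the product's theoretical
    maximum; at each point the product flux is fixed, biomass is
    maximised, and pFBA pins the fluxes recorded in the profiles.
    Excluded reaction ids are reported but never classified.  A product
    with zero theoretical maximum yields a diagnostic result rather
    than an error (e.g. an oxygen-dependent pathway under an anaerobic
    medium).
    """
    exclude = sorted(set(exclude))
    for rid in (biomass_rxn, product_ex):
        if rid not in model.reactions:
            raise FluxAnalysisError(f"reaction {rid!r} not in model")
    vmax_res = fba(model, objective=product_ex, sense="max")
    if not vmax_res.optimal or vmax_res.objective_value <= REPORT_TOL:
        cause = (
            f"product maximum is {0.0 if vmax_res.optimal else vmax_res.status}; "
            "check medium composition (e.g. oxygen requirement) and pathway bounds"
        )
        return FseofResult(product_ex, [], {}, {}, {}, exclude, diagnostics=cause)
    v_max = vmax_res.objective_value

    base = pfba(model, objective=biomass_rxn)
    if not base.optimal:
        return FseofResult(
            product_ex, [], {}, {}, {}, exclude,
            diagnostics=f"biomass optimisation failed: {base.status}",
        )
    v0 = base.fluxes[product_ex]
    top = max_fraction * v_max
    if top <= v0 + REPORT_TOL:
        return FseofResult(
            product_ex, [], {}, {}, {}, exclude,
            diagnostics="enforced range is empty: product already at its scan ceiling",
        )
    grid = list(np.linspace(v0, top, n_steps))

    profiles: dict[str, list[float]] = {rid: [] for rid in model.reactions}
    for p in grid:
        step = model.copy()
        step.reactions[product_ex].lower_bound = p
        step.reactions[product_ex].upper_bound = p
        sol = pfba(step, objective=biomass_rxn)
        if not sol.optimal:
            return FseofResult(
                product_ex, grid, {}, {}, {}, exclude,
                diagnostics=f"step at product flux {p:.4g} failed: {sol.status}",
            )
        for rid in profiles:
            profiles[rid].append(sol.fluxes[rid])

    slopes = {rid: compute_slope(prof, grid) for rid, prof in profiles.items()}
    classification: dict[str, str] = {}
    for rid, slope in slopes.items():
        if rid in exclude:
            continue
        direction = _monotone_direction(profiles[rid])
        if slope > SLOPE_TOL and direction == "up":
            classification[rid] = "amplification"
        elif slope < -SLOPE_TOL and direction == "down":
            classification[rid] = "attenuation"
        else:
            classification[rid] = "none"
    return FseofResult(product_ex, grid, profiles, slopes, classification, exclude)


def rank_targets(
    result: FseofResult, top_n: int = 10
) -> tuple[list[tuple[str, float]], list[tuple[str, float]]]:
    """Top-n highest- and lowest-slope targets, exclusion list removed.

    Ties in slope are ordered by lexicographically smaller reaction id.
    """
    targets = [
        (rid, result.slopes[rid])
        for rid, cls in result.classification.items()
        if cls != "none" and rid not in result.excluded
    ]
    if not targets:
        raise ValueError("FSEOF result contains no classified targets")
    highest = sorted(targets, key=lambda t: (-t[1], t[0]))[:top_n]
    lowest = sorted(targets, key=lambda t: (t[1], t[0]))[:top_n]
    return highest, lowest


@dataclass
class SensitivityResult:
    fractions: list[float]
    product_optimum: dict[float, float | None]  # None where the LP failed
    pfba_fluxes: dict[float, dict[str, float]]
    fva_intervals: dict[float, dict[str, FvaRange]]
    failures: dict[float, str] = field(default_factory=dict)


def biomass_sensitivity(
    model: Model,
    biomass_rxn: str,
    product_ex: str,
    fractions: Sequence[float] = tuple(round(0.1 * i, 1) for i in range(11)),
    watch: Iterable[str] = (),
    fva_fraction: float = 1.0,
) -> SensitivityResult:
    """Product optimum vs pinned biomass fraction, with watch-list detail.

    For each fraction f the biomass bounds are fixed to f·μ* and the
    product exchange is maximised; pFBA fluxes and FVA intervals are
    recorded for the watch list.  LP failures at individual grid points
    are collected without aborting the sweep.
    """
    watch = sorted(set(watch))
    mu_res = fba(model, objective=biomass_rxn, sense="max")
    if not mu_res.optimal or mu_res.objective_value <= REPORT_TOL:
        raise FluxAnalysisError("biomass optimum is zero; sensitivity sweep undefined")
    mu_star = mu_res.objective_value

    result = SensitivityResult(list(fractions), {}, {}, {})
    for f in fractions:
        if not 0 <= f <= 1:
            raise ValueError(f"biomass fraction {f} outside [0, 1]")
        pinned = model.copy()
        target = f * mu_star
        pinned.reactions[biomass_rxn].lower_bound = max(
            target - 1e-9, pinned.reactions[biomass_rxn].lower_bound
        )
        pinned.reactions[biomass_rxn].upper_bound = target + 1e-9
        try:
            opt = fba(pinned, objective=product_ex, sense="max")
            if not opt.optimal:
                raise FluxAnalysisError(opt.status)
            result.product_optimum[f] = opt.objective_value
            if watch:
                point = pfba(pinned, objective=product_ex)
                result.pfba_fluxes[f] = {rid: point.fluxes[rid] for rid in watch}
                ranges = fva(pinned, reactions=watch, fraction=fva_fraction,
                             objective=product_ex)
                result.fva_intervals[f] = ranges
            else:
                result.pfba_fluxes[f] = {}
                result.fva_intervals[f] = {}
        except FluxAnalysisError as exc:
            result.product_optimum[f] = None
            result.failures[f] = str(exc)
    return result
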