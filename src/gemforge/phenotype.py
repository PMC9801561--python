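"""Phenotype-microarray concordance and ¹³C flux-containment validation.

Phenotype plates (Biolog PM1–PM4 style) score growth on arrayed carbon /
nitrogen / phosphorus / sulfur sources with an activity index between 0
and 9; an index of 3 and above is called growth.  In-silico predictions
swap the plate well's nutrient for the base medium's default source of
the same element class, run FBA, and call growth at ≥ 5% of wild-type
growth.  Observed vs predicted calls summarise to a confusion matrix
whose accuracy is reported to one decimal.

¹³C-derived net fluxes (mean ± sd, normalised to the carbon uptake
rate) are validated by containment: the model's flux is rescaled so the
normalisation-basis uptake equals 100 units, and each measurement is
checked against FVA intervals over a grid of fraction-of-optimum
thresholds (90–99%), with the pFBA point estimate reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import Model
from .flux import (
    REPORT_TOL,
    FluxAnalysisError,
    FvaRange,
    Medium,
    apply_medium,
    fba,
    fva,
    pfba,
)

ELEMENT_CLASSES = ("C", "N", "P", "S")


@dataclass
class WellRecord:
    plate: str
    well: str
    nutrient: str
    element_class: str  # C | N | P | S
    activity: float
    exchange_id: str | None = None

    def __post_init__(self) -> None:
        if self.element_class not in ELEMENT_CLASSES:
            raise ValueError(f"element class must be one of {ELEMENT_CLASSES}")
        if not 0 <= self.activity <= 9:
            raise ValueError(f"activity {self.activity} outside [0, 9]")


def read_plate(path: str | Path) -> list[WellRecord]:
    """Read a TSV/CSV plate table with the canonical header names."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    records = []
    for r in df.itertuples(index=False):
        ex = getattr(r, "exchange_id", None)
        if pd.isna(ex) or ex == "":
            ex = None
        records.append(
            WellRecord(
                plate=str(r.plate),
                well=str(r.well),
                nutrient=str(r.nutrient),
                element_class=str(r.element_class),
                activity=float(r.activity),
                exchange_id=ex,
            )
        )
    return records


def write_plate(wells: Iterable[WellRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "plate": w.plate,
                "well": w.well,
                "nutrient": w.nutrient,
                "element_class": w.element_class,
                "activity": w.activity,
                "exchange_id": w.exchange_id or "",
            }
            for w in wells
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def classify_growth(activity: float, threshold: float = 3.0) -> bool:
    """Growth call from an activity index: ≥ threshold (inclusive)."""
    if not 0 <= activity <= 9:
        raise ValueError(f"activity {activity} outside [0, 9]")
    return activity >= threshold


def predict_plate(
    model: Model,
    plate: Sequence[WellRecord],
    base_medium: Medium,
    default_sources: Mapping[str, str],
    uptake: float = 10.0,
    growth_frac: float = 0.05,
    aerobic: bool = True,
) -> tuple[dict[str, bool], list[WellRecord]]:
    """Per-well growth predictions by element-class nutrient swap.

    For each mapped well, the base medium's default source of the
    well's element class is removed, the well's exchange is opened at
    the stated uptake, and FBA growth ≥ growth_frac·WT is called
    growth.  Wells without an exchange mapping are excluded and
    returned as the unmapped list.
    """
    wt = fba(apply_medium(model, base_medium, aerobic=aerobic))
    if not wt.optimal or wt.objective_value is None or wt.objective_value <= REPORT_TOL:
        raise FluxAnalysisError("wild-type growth on the base medium is zero")
    predictions: dict[str, bool] = {}
    unmapped: list[WellRecord] = []
    cache: dict[tuple[str, str], bool] = {}
    for well in plate:
        if well.exchange_id is None:
            unmapped.append(well)
            continue
        key = (well.exchange_id, well.element_class)
        if key not in cache:
            medium = dict(base_medium)
            default = default_sources.get(well.element_class)
            if default is not None:
                medium.pop(default, None)
            if well.exchange_id not in model.reactions:
                raise FluxAnalysisError(
                    f"well {well.well}: exchange {well.exchange_id!r} not in model"
                )
            medium[well.exchange_id] = uptake
            res = fba(apply_medium(model, medium, aerobic=aerobic))
            grown = res.optimal and res.objective_value >= growth_frac * wt.objective_value
            cache[key] = bool(grown)
        predictions[well.well] = cache[key]
    return predictions, unmapped


@dataclass
class ConcordanceReport:
    tp: int
    tn: int
    fp: int
    fn: int
    calls: pd.DataFrame  # columns: well, observed, predicted
    unmapped: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        """Percent correct, rounded to one decimal for display."""
        return round(100.0 * (self.tp + self.tn) / self.n, 1)


def concordance(
    observed: Mapping[str, bool],
    predicted: Mapping[str, bool],
    unmapped: Iterable[str] = (),
) -> ConcordanceReport:
    """Confusion matrix of observed vs predicted growth calls."""
    if set(observed) != set(predicted):
        raise ValueError("observed and predicted cover different well sets")
    if not observed:
        raise ValueError("empty call sets")
    tp = tn = fp = fn = 0
    rows = []
    for well in sorted(observed):
        o, p = bool(observed[well]), bool(predicted[well])
        if o and p:
            tp += 1
        elif not o and not p:
            tn += 1
        elif not o and p:
            fp += 1
        else:
            fn += 1
        rows.append({"well": well, "observed": o, "predicted": p})
    return ConcordanceReport(
        tp=tp, tn=tn, fp=fp, fn=fn,
        calls=pd.DataFrame(rows), unmapped=sorted(unmapped),
    )


# ---------------------------------------------------------------------------
# 13C flux containment
# ---------------------------------------------------------------------------

@dataclass
class FluxMeasurement:
    reaction_id: str
    mean: float
    sd: float
    basis_exchange: str  # uptake exchange the fluxes are normalised to

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


def read_measurements(path: str | Path, basis_exchange: str) -> list[FluxMeasurement]:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    return [
        FluxMeasurement(str(r.reaction_id), float(r.mean), float(r.sd), basis_exchange)
        for r in df.itertuples(index=False)
    ]


@dataclass
class ContainmentResult:
    fractions: list[float]
    containment: pd.DataFrame  # reactions × fractions, boolean
    pfba_fluxes: dict[str, float]  # rescaled point estimates
    intervals: dict[float, dict[str, FvaRange]]  # rescaled FVA ranges
    scale: float  # multiplier taking model fluxes onto the 100-unit basis

    def rate(self, fraction: float) -> float:
        """Share of measured reactions contained at one FVA fraction."""
        return float(self.containment[fraction].mean())


def flux_containment(
    model: Model,
    medium: Medium,
    measurements: Sequence[FluxMeasurement],
    fractions: Sequence[float] = tuple(round(0.90 + 0.01 * i, 2) for i in range(10)),
    objective: str | None = None,
    fixed_fluxes: Mapping[str, float] | None = None,
    aerobic: bool = True,
) -> ContainmentResult:
    """FVA containment of measured fluxes over fraction-of-optimum grid.

    Model fluxes are rescaled so the normalisation-basis uptake equals
    100 units (matching measurement normalisation); a measurement is
    contained at fraction f iff its mean lies within the rescaled FVA
    interval at f.  ``fixed_fluxes`` optionally pins reactions (e.g. a
    measured acetate efflux) before analysis.
    """
    if not measurements:
        raise ValueError("no measurements given")
    basis = {m.basis_exchange for m in measurements}
    if len(basis) != 1:
        raise ValueError("all measurements must share one normalisation basis")
    basis_ex = basis.pop()
    constrained = apply_medium(model, medium, aerobic=aerobic)
    if fixed_fluxes:
        for rid, value in fixed_fluxes.items():
            if rid not in constrained.reactions:
                raise FluxAnalysisError(f"fixed-flux reaction {rid!r} not in model")
            constrained.reactions[rid].lower_bound = value
            constrained.reactions[rid].upper_bound = value
    unknown = [m.reaction_id for m in measurements if m.reaction_id not in constrained.reactions]
    if unknown:
        raise FluxAnalysisError(f"measured reaction(s) not in model: {unknown}")
    if basis_ex not in constrained.reactions:
        raise FluxAnalysisError(f"normalisation exchange {basis_ex!r} not in model")

    point = pfba(constrained, objective=objective)
    if not point.optimal:
        raise FluxAnalysisError(f"pFBA failed: {point.status}")
    uptake = point.fluxes[basis_ex]
    if abs(uptake) <= REPORT_TOL:
        raise FluxAnalysisError(
            f"normalisation exchange {basis_ex!r} carries zero flux"
        )
    scale = 100.0 / abs(uptake)

    rxn_ids = [m.reaction_id for m in measurements]
    intervals: dict[float, dict[str, FvaRange]] = {}
    table = {}
    for f in fractions:
        ranges = fva(constrained, reactions=rxn_ids, fraction=f, objective=objective)
        scaled = {
            rid: FvaRange(r.minimum * scale, r.maximum * scale, f)
            for rid, r in ranges.items()
        }
        intervals[f] = scaled
        table[f] = [scaled[m.reaction_id].contains(m.mean) for m in measurements]
    containment = pd.DataFrame(table, index=rxn_ids)
    return ContainmentResult(
        fractions=list(fractions),
        containment=containment,
        pfba_fluxes={rid: point.fluxes[rid] * scale for rid in rxn_ids},
        intervals=intervals,
        scale=scale,
    )
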