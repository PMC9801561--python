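"""Deterministic generators for every input class the pipeline consumes.

Each generator is a pure function of (parameters, seed) with a named
pseudorandom stream, so adding a generator never perturbs existing
fixtures and regenerating with the same seed reproduces outputs
byte-for-byte.  The generators plant ground truth (which reactions a
strain kept, which hits are real orthologs, which wells truly grow,
what the true fluxes are) so every downstream stage is testable with
zero external downloads.

The template model emulates a reference-quality bacterial network in
miniature: a glucose uptake chain feeding two parallel glycolytic
isozymes, a branch between respiration (efficient, oxygen-dependent)
and fermentation (inefficient, oxygen-free), amino-acid synthesis and a
biomass pseudo-reaction, an ATP maintenance drain, and a three-step
siderophore pathway whose carrier-bound intermediates carry the
rest-group pseudo-element "R" — so the balance audit always exercises
the unbalanceable branch that real secondary-metabolite pathways
produce.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .core import Metabolite, Model, Reaction, parse_formula
from .flux import Medium, apply_medium, fba, pfba, single_reaction_deletion
from .gpr import parse_gpr
from .orthology import AlignmentHit
from .phenotype import WellRecord, FluxMeasurement, predict_plate

BIOMASS_ID = "BIOMASS"
GLUCOSE_EXCHANGE = "EX_glc__D_e"
OXYGEN_EXCHANGE = "EX_o2_e"
AMMONIUM_EXCHANGE = "EX_nh4_e"
SIDEROPHORE_EXCHANGE = "EX_sid_e"
ARTIFICIAL_GENE = "s0001"


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named pseudorandom stream derived from one integer seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(stream.encode())])
    )


def default_medium() -> Medium:
    """Aerobic glucose minimal medium for the template model."""
    return {
        GLUCOSE_EXCHANGE: 10.0,
        OXYGEN_EXCHANGE: 20.0,
        AMMONIUM_EXCHANGE: 50.0,
        "EX_h2o_e": 1000.0,
    }


def default_sources() -> dict[str, str]:
    """Default nutrient source per element class in the base medium."""
    return {"C": GLUCOSE_EXCHANGE, "N": AMMONIUM_EXCHANGE}


_METABOLITES = [
    # id, name, compartment, formula, charge
    ("glc__D_e", "D-glucose", "e", "C6H12O6", 0),
    ("glc__D_c", "D-glucose", "c", "C6H12O6", 0),
    ("pyr_c", "triose intermediate", "c", "C3H6O3", 0),
    ("lac__L_e", "L-lactate", "e", "C3H6O3", 0),
    ("lac__L_c", "L-lactate", "c", "C3H6O3", 0),
    ("ala__L_c", "L-alanine", "c", "C3H7NO2", 0),
    ("nh4_e", "ammonia", "e", "H3N", 0),
    ("nh4_c", "ammonia", "c", "H3N", 0),
    ("o2_e", "oxygen", "e", "O2", 0),
    ("o2_c", "oxygen", "c", "O2", 0),
    ("co2_e", "carbon dioxide", "e", "CO2", 0),
    ("co2_c", "carbon dioxide", "c", "CO2", 0),
    ("h2o_e", "water", "e", "H2O", 0),
    ("h2o_c", "water", "c", "H2O", 0),
    ("h_c", "proton", "c", "H", 1),
    ("atp_c", "ATP", "c", "C10H12N5O13P3", -4),
    ("adp_c", "ADP", "c", "C10H12N5O10P2", -3),
    ("pi_c", "phosphate", "c", "HO4P", -2),
    ("car_c", "siderophore carrier protein", "c", "R", 0),
    ("sidc1_c", "carrier-bound precursor 1", "c", "C3H7NO2R", 0),
    ("sidc2_c", "carrier-bound precursor 2", "c", "C3H7NO2R", 0),
    ("sid_c", "siderophore", "c", "C3H7NO2", 0),
    ("sid_e", "siderophore", "e", "C3H7NO2", 0),
]

# id, stoichiometry, lb, ub, gpr, subsystem
_REACTIONS = [
    (GLUCOSE_EXCHANGE, {"glc__D_e": -1}, -10, 1000, "", "exchange"),
    (OXYGEN_EXCHANGE, {"o2_e": -1}, -20, 1000, "", "exchange"),
    (AMMONIUM_EXCHANGE, {"nh4_e": -1}, -50, 1000, "", "exchange"),
    ("EX_lac__L_e", {"lac__L_e": -1}, 0, 1000, "", "exchange"),
    ("EX_co2_e", {"co2_e": -1}, 0, 1000, "", "exchange"),
    ("EX_h2o_e", {"h2o_e": -1}, -1000, 1000, "", "exchange"),
    (SIDEROPHORE_EXCHANGE, {"sid_e": -1}, 0, 1000, "", "exchange"),
    ("GLCt", {"glc__D_e": -1, "glc__D_c": 1}, 0, 1000, "gT", "transport"),
    ("O2t", {"o2_e": -1, "o2_c": 1}, 0, 1000, ARTIFICIAL_GENE, "transport"),
    ("NH4t", {"nh4_e": -1, "nh4_c": 1}, 0, 1000, "gN", "transport"),
    ("LACt", {"lac__L_c": -1, "lac__L_e": 1}, -1000, 1000, "", "transport"),
    ("CO2t", {"co2_c": -1, "co2_e": 1}, -1000, 1000, "", "transport"),
    ("H2Ot", {"h2o_c": -1, "h2o_e": 1}, -1000, 1000, "", "transport"),
    ("SIDt", {"sid_c": -1, "sid_e": 1}, 0, 1000, "", "transport"),
    # parallel glycolytic isozymes
    ("GLYA", {"glc__D_c": -1, "pyr_c": 2}, 0, 1000, "g1", "glycolysis"),
    ("GLYB", {"glc__D_c": -1, "pyr_c": 2}, 0, 1000, "g2", "glycolysis"),
    # respiration: combustion of one triose coupled to 5 ATP
    ("RESP",
     {"pyr_c": -1, "o2_c": -3, "adp_c": -5, "pi_c": -5, "h_c": -5,
      "co2_c": 3, "h2o_c": 8, "atp_c": 5},
     0, 1000, "gR", "energy metabolism"),
    # fermentation: 1 ATP per triose, reversible (supports growth on lactate)
    ("FERM",
     {"pyr_c": -1, "adp_c": -1, "pi_c": -1, "h_c": -1,
      "lac__L_c": 1, "atp_c": 1, "h2o_c": 1},
     -1000, 1000, "gF", "fermentation"),
    ("AMIN", {"pyr_c": -1, "nh4_c": -1, "ala__L_c": 1, "h2o_c": 1},
     0, 1000, "gA", "amino acid metabolism"),
    ("ATPM", {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1, "h_c": 1},
     1, 1000, "", "maintenance"),
    (BIOMASS_ID,
     {"pyr_c": -1, "ala__L_c": -1, "atp_c": -30, "h2o_c": -30,
      "adp_c": 30, "pi_c": 30, "h_c": 30},
     0, 1000, "", "biomass"),
    # toy siderophore pathway with an R-group carrier intermediate
    ("SID1", {"ala__L_c": -1, "car_c": -1, "sidc1_c": 1},
     0, 1000, "gS1", "secondary metabolism"),
    ("SID2", {"sidc1_c": -1, "atp_c": -1, "h2o_c": -1,
              "sidc2_c": 1, "adp_c": 1, "pi_c": 1, "h_c": 1},
     0, 1000, "gS2", "secondary metabolism"),
    ("SID3", {"sidc2_c": -1, "h2o_c": -1, "sid_c": 1, "car_c": 1},
     0, 1000, "gS3", "secondary metabolism"),
]


def make_template_model(seed: int = 0) -> Model:
    """Miniature reference-quality model (~25 reactions), growth-positive
    on the default medium, free of energy-generating cycles, with an
    R-group secondary-metabolite branch.  Deterministic (the topology
    does not depend on the seed)."""
    model = Model(id="template", compartments={"c": "cytosol", "e": "extracellular"})
    for mid, name, comp, formula, charge in _METABOLITES:
        model.add_metabolite(
            Metabolite(id=mid, name=name, compartment=comp,
                       formula=parse_formula(formula), charge=charge)
        )
    for rid, stoich, lb, ub, rule, subsystem in _REACTIONS:
        model.add_reaction(
            Reaction(
                id=rid,
                name=rid,
                stoichiometry=stoich,
                lower_bound=float(lb),
                upper_bound=float(ub),
                gpr=parse_gpr(rule),
                subsystem=subsystem,
                provenance="template",
            )
        )
    # the carrier is catalytic: consumed by SID1 and regenerated by SID3,
    # so the pathway cycles at steady state without a carrier source
    model.objective = {BIOMASS_ID: 1.0}
    model.validate()
    return model


# ---------------------------------------------------------------------------
# reference panel
# ---------------------------------------------------------------------------

@dataclass
class PanelTruth:
    """Planted ground truth for a synthetic reference panel."""

    template: Model
    retained_reactions: dict[str, set[str]]  # strain -> reaction ids kept
    strain_genes: dict[str, dict[str, str]]  # strain -> {template gene -> strain gene}
    seed: int

    def reconstructable_reactions(self) -> set[str]:
        """Union of panel reactions — what a perfect pipeline recovers."""
        out: set[str] = set()
        for rids in self.retained_reactions.values():
            out |= rids
        return out


def core_reactions(template: Model, medium: Medium | None = None) -> set[str]:
    """Reactions essential for growth on the default medium (never dropped)."""
    constrained = apply_medium(template, medium or default_medium())
    screen = single_reaction_deletion(constrained)
    return set(screen.essential) | {BIOMASS_ID}


def make_reference_panel(
    template: Model,
    n_strains: int,
    dropout: float,
    seed: int,
) -> tuple[dict[str, Model], PanelTruth]:
    """Panel of strain models: independent per-strain reaction dropout.

    Each strain drops each non-core reaction with probability
    ``dropout`` (core = reactions essential on the default medium, kept
    always) and renames every gene with a strain prefix.
    """
    if not 0 <= dropout < 1:
        raise ValueError("dropout must lie in [0, 1)")
    rng = _rng(seed, "panel")
    core = core_reactions(template)
    droppable = sorted(set(template.reactions) - core)
    panel: dict[str, Model] = {}
    truth = PanelTruth(template=template.copy(), retained_reactions={},
                       strain_genes={}, seed=seed)
    for i in range(n_strains):
        strain = f"S{i + 1:02d}"
        drops = {rid for rid in droppable if rng.random() < dropout}
        kept = set(template.reactions) - drops
        gene_map = {g: f"{strain}_{g}" for g in sorted(template.genes)}
        model = template.copy()
        model.id = strain
        for rid in sorted(drops):
            model.remove_reaction(rid)
        for rxn in model.reactions.values():
            rxn.gpr = _rename_rule(rxn.gpr, gene_map)
            rxn.provenance = strain
        from .reconstruct import _prune_orphans  # orphan cleanup after dropout

        _prune_orphans(model)
        used = {g for rxn in model.reactions.values() for g in rxn.gpr.genes}
        panel[strain] = model
        truth.retained_reactions[strain] = kept
        truth.strain_genes[strain] = {
            g: sg for g, sg in gene_map.items() if sg in used
        }
    return panel, truth


def _rename_rule(rule, mapping):
    from .gpr import translate_gpr

    return translate_gpr(rule, mapping)


# ---------------------------------------------------------------------------
# alignment hit tables
# ---------------------------------------------------------------------------

def _gene_length(gene: str) -> int:
    """Deterministic pseudo-length for a gene id (residues)."""
    return 150 + (zlib.crc32(gene.encode()) % 40) * 10


def make_hit_tables(
    panel_truth: PanelTruth,
    pid_ortholog: float = 95.0,
    pid_decoy: float = 50.0,
    seed: int = 0,
    n_decoys_per_strain: int = 10,
) -> dict[str, tuple[list[AlignmentHit], list[AlignmentHit]]]:
    """Forward/reverse hit tables per strain with planted orthologs.

    True ortholog pairs get ``pid_ortholog`` with full-length
    alignments and dominant bitscores; decoy pairs get ``pid_decoy``
    and/or short alignments so they fail the identity or coverage
    filter, with bitscores below every true hit so best-hit mutuality
    is preserved even if the filters are loosened.
    """
    rng = _rng(seed, "hits")
    tables: dict[str, tuple[list[AlignmentHit], list[AlignmentHit]]] = {}
    template_genes = sorted(panel_truth.template.genes)
    for strain, gene_map in panel_truth.strain_genes.items():
        fwd: list[AlignmentHit] = []
        rev: list[AlignmentHit] = []
        strain_genes = sorted(gene_map.values())
        for g, sg in sorted(gene_map.items()):
            length = _gene_length(g)
            fwd.append(AlignmentHit(g, sg, pid_ortholog, length, length, length,
                                    1e-80, 2.0 * length))
            rev.append(AlignmentHit(sg, g, pid_ortholog, length, length, length,
                                    1e-80, 2.0 * length))
        for _ in range(n_decoys_per_strain):
            if not strain_genes:
                break
            q = template_genes[rng.integers(len(template_genes))]
            s = strain_genes[rng.integers(len(strain_genes))]
            length = _gene_length(q)
            if rng.random() < 0.5:
                # identity failure: full-length but low-identity alignment
                hit = AlignmentHit(q, s, pid_decoy, length, length, length,
                                   1e-5, 0.4 * length)
            else:
                # coverage failure: high identity over a short stretch
                aln = max(1, length // 10)
                hit = AlignmentHit(q, s, pid_ortholog, aln, length, length,
                                   1e-5, 0.4 * length)
            fwd.append(hit)
            rev.append(AlignmentHit(hit.subject_id, hit.query_id, hit.pid,
                                    hit.aln_len, hit.subject_len, hit.query_len,
                                    hit.evalue, hit.bitscore))
        tables[strain] = (fwd, rev)
    return tables


# ---------------------------------------------------------------------------
# phenotype plates
# ---------------------------------------------------------------------------

def _plate_candidates(model: Model) -> list[tuple[str, str]]:
    """(exchange id, element class) pairs usable as plate nutrients:
    extracellular metabolites contributing carbon or nitrogen, excluding
    the inorganic gas/water/proton background."""
    background = {"EX_co2_e", "EX_h2o_e", "EX_h_e", OXYGEN_EXCHANGE}
    out = []
    for rid in model.exchanges:
        if rid in background:
            continue
        (mid,) = model.reactions[rid].stoichiometry
        formula = model.metabolites[mid].formula or {}
        if "C" in formula:
            out.append((rid, "C"))
        elif "N" in formula:
            out.append((rid, "N"))
    return sorted(out)


def make_plate(
    model: Model,
    n_wells: int,
    flip_rate: float,
    seed: int,
    unmapped_fraction: float = 0.2,
    base_medium: Medium | None = None,
    sources: dict[str, str] | None = None,
    uptake: float = 10.0,
) -> tuple[list[WellRecord], dict[str, bool]]:
    """Synthetic phenotype plate with planted growth truth.

    Wells are mapped to the model's nutrient exchanges; the true call
    is the model's own prediction, the observed activity index is drawn
    from {5..9} for growth and {0..2} for no-growth, and observed calls
    are flipped at ``flip_rate``.  A fixed fraction of wells is left
    unmapped (no exchange id).  Returns the wells and the truth calls
    for the mapped wells.
    """
    rng = _rng(seed, "plate")
    base_medium = base_medium or default_medium()
    sources = sources or default_sources()
    candidates = _plate_candidates(model)
    probe_wells = [
        WellRecord(plate="PMX", well=f"probe{i}", nutrient=ex,
                   element_class=cls, activity=0.0, exchange_id=ex)
        for i, (ex, cls) in enumerate(candidates)
    ]
    predictions, _ = predict_plate(model, probe_wells, base_medium, sources,
                                   uptake=uptake)
    truth_by_exchange = {
        (ex, cls): predictions[f"probe{i}"]
        for i, (ex, cls) in enumerate(candidates)
    }

    n_unmapped = int(round(unmapped_fraction * n_wells))
    unmapped_idx = set(rng.choice(n_wells, size=n_unmapped, replace=False).tolist())
    wells: list[WellRecord] = []
    truth: dict[str, bool] = {}
    for i in range(n_wells):
        well_id = f"W{i + 1:03d}"
        ex, cls = candidates[rng.integers(len(candidates))]
        true_call = truth_by_exchange[(ex, cls)]
        observed_call = (not true_call) if rng.random() < flip_rate else true_call
        activity = float(rng.integers(5, 10) if observed_call else rng.integers(0, 3))
        if i in unmapped_idx:
            wells.append(WellRecord(plate="PMX", well=well_id, nutrient=ex,
                                    element_class=cls, activity=activity,
                                    exchange_id=None))
        else:
            wells.append(WellRecord(plate="PMX", well=well_id, nutrient=ex,
                                    element_class=cls, activity=activity,
                                    exchange_id=ex))
            truth[well_id] = true_call
    return wells, truth


# ---------------------------------------------------------------------------
# flux measurements
# ---------------------------------------------------------------------------

def make_flux_measurements(
    model: Model,
    medium: Medium | None = None,
    noise_cv: float = 0.05,
    seed: int = 0,
    basis_exchange: str = GLUCOSE_EXCHANGE,
    include_basis: bool = True,
) -> list[FluxMeasurement]:
    """Measurement table = pFBA fluxes rescaled to uptake 100 + noise.

    Gaussian noise with coefficient of variation ``noise_cv`` is added
    per reaction; the sd column records the nominal noise sd.  At
    ``noise_cv = 0`` the means equal the model's own (rescaled) pFBA
    solution exactly.
    """
    rng = _rng(seed, "fluxes")
    medium = medium or default_medium()
    constrained = apply_medium(model, medium)
    point = pfba(constrained)
    if not point.optimal:
        raise RuntimeError(f"pFBA on the measurement medium failed: {point.status}")
    uptake = point.fluxes[basis_exchange]
    if abs(uptake) < 1e-9:
        raise RuntimeError(f"basis exchange {basis_exchange!r} carries no flux")
    scale = 100.0 / abs(uptake)
    out: list[FluxMeasurement] = []
    for rid in sorted(model.reactions):
        if model.is_exchange(rid) and rid != basis_exchange:
            continue
        if rid == basis_exchange and not include_basis:
            continue
        value = point.fluxes[rid] * scale
        if abs(value) < 1e-9:
            continue
        sd = noise_cv * abs(value)
        mean = value + (rng.normal(0.0, sd) if noise_cv > 0 else 0.0)
        out.append(FluxMeasurement(rid, mean, sd, basis_exchange))
    return out
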