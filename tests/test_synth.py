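"""Generator determinism and planted-ground-truth recovery."""

from __future__ import annotations

import json

import pytest

from gemforge.core import check_balance
from gemforge.flux import apply_medium, fba, pfba
from gemforge.io import write_model
from gemforge.orthology import orthology_from_tables, write_hit_table
from gemforge.phenotype import flux_containment
from gemforge.reconstruct import (
    augment_from_references,
    detect_energy_generating_cycles,
    reduce_base_model,
)
from gemforge.synth import (
    default_medium,
    make_flux_measurements,
    make_hit_tables,
    make_plate,
    make_reference_panel,
    make_template_model,
)


class TestTemplate:
    def test_growth_positive_on_default_medium(self, grown_template):
        res = fba(grown_template)
        assert res.status == "optimal" and res.objective_value > 0

    def test_no_energy_generating_cycles(self, template):
        assert all(not r.flagged for r in detect_energy_generating_cycles(template))

    def test_carrier_bound_reactions_unbalanceable(self, template):
        for rid in ("SID1", "SID2", "SID3"):
            rep = check_balance(template.reactions[rid], template)
            assert rep.status == "unbalanceable"

    def test_non_carrier_metabolism_mass_balanced(self, template):
        """Every reaction outside the carrier pathway, biomass and the
        boundary is elementally and charge balanced."""
        skip = {"SID1", "SID2", "SID3", "BIOMASS"} | set(template.exchanges)
        for rid, rxn in template.reactions.items():
            if rid in skip:
                continue
            assert check_balance(rxn, template).status == "balanced", rid


class TestPanel:
    def test_zero_dropout_identical_up_to_gene_renaming(self, template):
        panel, truth = make_reference_panel(template, 3, 0.0, seed=5)
        for strain, model in panel.items():
            assert set(model.reactions) == set(template.reactions)
            for rid, rxn in model.reactions.items():
                t = template.reactions[rid]
                assert rxn.stoichiometry == t.stoichiometry
                assert (rxn.lower_bound, rxn.upper_bound) == (t.lower_bound, t.upper_bound)
            assert truth.retained_reactions[strain] == set(template.reactions)

    def test_union_matches_truth(self, template):
        panel, truth = make_reference_panel(template, 6, 0.5, seed=8)
        union = set()
        for model in panel.values():
            union |= set(model.reactions)
        assert union == truth.reconstructable_reactions()

    def test_core_reactions_never_dropped(self, template):
        from gemforge.synth import core_reactions

        core = core_reactions(template)
        panel, _ = make_reference_panel(template, 8, 0.7, seed=2)
        for model in panel.values():
            assert core <= set(model.reactions)

    def test_same_seed_reproduces_byte_identical_panels(self, template, tmp_path):
        out = []
        for run in range(2):
            panel, _ = make_reference_panel(template, 4, 0.4, seed=13)
            blob = {}
            for strain, model in sorted(panel.items()):
                path = tmp_path / f"{run}_{strain}.json"
                write_model(model, path, "json")
                blob[strain] = path.read_bytes()
            out.append(blob)
        assert out[0] == out[1]


class TestHitTables:
    def test_pipeline_recovers_planted_membership(self, template):
        panel, truth = make_reference_panel(template, 5, 0.4, seed=21)
        tables = make_hit_tables(truth, seed=21)
        for strain, (fwd, rev) in tables.items():
            bbh = orthology_from_tables(fwd, rev)
            assert bbh == truth.strain_genes[strain]

    def test_decoys_rejected_even_with_loose_identity(self, template):
        """Coverage-failing decoys stay rejected when the identity
        threshold is dropped below their pid."""
        panel, truth = make_reference_panel(template, 3, 0.2, seed=4)
        tables = make_hit_tables(truth, pid_decoy=85.0, seed=4)
        for strain, (fwd, rev) in tables.items():
            bbh = orthology_from_tables(fwd, rev, pid_min=80.0, cov_min=0.25)
            assert bbh == truth.strain_genes[strain]

    def test_empty_panel_gives_empty_tables(self, template):
        panel, truth = make_reference_panel(template, 0, 0.2, seed=1)
        assert make_hit_tables(truth, seed=1) == {}

    def test_byte_identical_for_same_seed(self, template, tmp_path):
        _, truth = make_reference_panel(template, 3, 0.3, seed=6)
        blobs = []
        for run in range(2):
            tables = make_hit_tables(truth, seed=6)
            path = tmp_path / f"hits{run}.tsv"
            write_hit_table(
                [h for s in sorted(tables) for h in tables[s][0] + tables[s][1]],
                path,
            )
            blobs.append(path.read_bytes())
        assert blobs[0] == blobs[1]


class TestEndToEndRecovery:
    """Hit tables -> orthology -> reduce + augment recovers the planted
    reconstructable reaction set: exact at dropout 0, and with zero false
    additions at any dropout."""

    def reconstruct(self, template, dropout, seed):
        panel, truth = make_reference_panel(template, 5, dropout, seed=seed)
        tables = make_hit_tables(truth, seed=seed)
        # BBH maps are target->strain; translation needs strain->target
        inverse = {
            strain: {sg: g for g, sg in orthology_from_tables(f, r).items()}
            for strain, (f, r) in tables.items()
        }
        strains = sorted(panel)
        base = panel[strains[0]]
        reduced = reduce_base_model(base, inverse[strains[0]])
        out, ledger, _ = augment_from_references(
            reduced,
            [panel[s] for s in strains[1:]],
            {s: inverse[s] for s in strains[1:]},
            include_spontaneous=True,
        )
        return out, truth

    def test_exact_recovery_at_zero_dropout(self, template):
        out, truth = self.reconstruct(template, 0.0, seed=3)
        assert set(out.reactions) == truth.reconstructable_reactions()

    @pytest.mark.parametrize("dropout", [0.3, 0.6])
    def test_no_false_or_missed_reactions_at_any_dropout(self, template, dropout):
        out, truth = self.reconstruct(template, dropout, seed=17)
        recovered = set(out.reactions)
        target = truth.reconstructable_reactions()
        assert recovered - target == set()  # zero false reactions
        assert target - recovered == set()  # zero missed reactions


class TestPlateGenerator:
    def test_zero_flip_rate_gives_perfect_concordance(self, template, medium):
        from gemforge.phenotype import classify_growth, concordance, predict_plate
        from gemforge.synth import default_sources

        wells, truth = make_plate(template, 60, 0.0, seed=10)
        observed = {w.well: classify_growth(w.activity) for w in wells if w.exchange_id}
        predicted, _ = predict_plate(template, wells, medium, default_sources())
        assert concordance(observed, predicted).accuracy == 100.0
        assert observed == truth

    def test_unmapped_fraction_controls_confusion_total(self, template):
        wells, truth = make_plate(template, 100, 0.1, seed=11, unmapped_fraction=0.4)
        mapped = [w for w in wells if w.exchange_id]
        assert len(mapped) == 60 and len(truth) == 60

    def test_activity_bands_encode_calls(self, template):
        wells, _ = make_plate(template, 80, 0.0, seed=12)
        for w in wells:
            assert (w.activity >= 5) or (w.activity <= 2)


class TestFluxMeasurements:
    def test_noise_free_measurements_contained_everywhere(self, template, medium):
        ms = make_flux_measurements(template, medium, noise_cv=0.0, seed=1)
        res = flux_containment(template, medium, ms)
        assert bool(res.containment.values.all())

    def test_containment_rate_nested_under_noise(self, template, medium):
        ms = make_flux_measurements(template, medium, noise_cv=0.05, seed=7)
        res = flux_containment(template, medium, ms)
        assert res.rate(0.90) >= res.rate(0.99)

    def test_basis_uptake_is_100_at_zero_noise(self, template, medium):
        ms = make_flux_measurements(template, medium, noise_cv=0.0, seed=1)
        basis = [m for m in ms if m.reaction_id == "EX_glc__D_e"]
        assert len(basis) == 1
        assert abs(basis[0].mean) == pytest.approx(100.0)

    def test_sd_column_is_nominal_noise_sd(self, template, medium):
        ms = make_flux_measurements(template, medium, noise_cv=0.05, seed=3)
        noise_free = {
            m.reaction_id: m.mean
            for m in make_flux_measurements(template, medium, noise_cv=0.0, seed=3)
        }
        for m in ms:
            assert m.sd == pytest.approx(0.05 * abs(noise_free[m.reaction_id]), rel=1e-6)
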