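"""Reduction, augmentation, provenance, EGC audit, gapfill, targeted edits."""

from __future__ import annotations

import itertools

import pytest

from gemforge.core import Metabolite, Model, ModelIntegrityError, Reaction
from gemforge.flux import fba
from gemforge.gpr import parse_gpr
from gemforge.reconstruct import (
    ProvenanceLedger,
    apply_edits,
    augment_from_references,
    detect_energy_generating_cycles,
    gapfill,
    reduce_base_model,
)
from gemforge.synth import make_reference_panel, make_template_model

from conftest import build_model


def toy_base():
    return build_model(
        mets=[("a_c", "c"), ("b_c", "c"), ("x_c", "c")],
        rxns=[
            ("R_keep", {"a_c": -1, "b_c": 1}, 0, 1000, "g1"),
            ("R_iso", {"a_c": -1, "x_c": 1}, 0, 1000, "g1 or g9"),
            ("R_lost", {"b_c": -1, "x_c": 1}, 0, 1000, "g9"),
            ("R_spont", {"x_c": -1, "a_c": 1}, 0, 1000),
            ("R_art", {"b_c": -1, "a_c": 1}, 0, 1000, "S0001"),
        ],
        model_id="base",
    )


class TestReduce:
    def test_mapped_gene_retained_translated(self):
        out = reduce_base_model(toy_base(), {"g1": "t1"}, artificial_genes={"S0001"})
        assert out.reactions["R_keep"].gpr.to_string() == "t1"
        assert out.reactions["R_keep"].provenance == "base"

    def test_unmapped_gene_reaction_removed(self):
        out = reduce_base_model(toy_base(), {"g1": "t1"}, artificial_genes={"S0001"})
        assert "R_lost" not in out.reactions

    def test_artificial_gene_exempt_verbatim(self):
        out = reduce_base_model(toy_base(), {"g1": "t1"}, artificial_genes={"S0001"})
        assert out.reactions["R_art"].gpr.to_string() == "S0001"

    def test_spontaneous_reaction_always_kept(self):
        out = reduce_base_model(toy_base(), {}, artificial_genes=set())
        assert "R_spont" in out.reactions

    def test_isozyme_survives_partial_homology_unless_strict(self):
        out = reduce_base_model(toy_base(), {"g1": "t1"})
        assert out.reactions["R_iso"].gpr.to_string() == "t1"
        strict = reduce_base_model(toy_base(), {"g1": "t1"}, strict=True)
        assert "R_iso" not in strict.reactions  # mentions the unmapped g9


def ref_model(model_id, rxns):
    mets = sorted({m for _, stoich, *_ in rxns for m in stoich})
    return build_model([(m, "c") for m in mets], rxns, model_id=model_id)


class TestAugment:
    def test_new_reaction_added_with_translated_gpr(self):
        draft = ref_model("draft", [("R0", {"a_c": -1, "b_c": 1}, 0, 1000)])
        ref = ref_model("ref1", [("R_new", {"b_c": -1, "c_c": 1}, -5, 5, "h7")])
        out, ledger, log = augment_from_references(draft, [ref], {"ref1": {"h7": "t7"}})
        assert out.reactions["R_new"].gpr.to_string() == "t7"
        assert out.reactions["R_new"].provenance == "ref1"
        # bounds copied from the contributing reference, not reset
        assert (out.reactions["R_new"].lower_bound, out.reactions["R_new"].upper_bound) == (-5, 5)

    def test_first_come_provenance(self):
        draft = ref_model("draft", [("R0", {"a_c": -1, "b_c": 1}, 0, 1000)])
        rx = ("R_new", {"b_c": -1, "c_c": 1}, 0, 1000, "h1")
        ref2 = ref_model("ref2", [rx])
        ref5 = ref_model("ref5", [rx])
        out, ledger, _ = augment_from_references(
            draft, [ref2, ref5], {"ref2": {"h1": "t1"}, "ref5": {"h1": "t1"}}
        )
        assert ledger.origins["R_new"] == "ref2"

    def test_conflicting_stoichiometry_skipped_and_logged(self):
        draft = ref_model("draft", [("R0", {"a_c": -1, "b_c": 1}, 0, 1000)])
        ref = ref_model("ref1", [("R0", {"a_c": -2, "b_c": 1}, 0, 1000, "h1")])
        out, _, log = augment_from_references(draft, [ref], {"ref1": {"h1": "t1"}})
        assert out.reactions["R0"].stoichiometry == draft.reactions["R0"].stoichiometry
        assert ("R0", "ref1") in log.skipped_conflicts

    def test_unsatisfiable_translation_not_added(self):
        draft = ref_model("draft", [("R0", {"a_c": -1, "b_c": 1}, 0, 1000)])
        ref = ref_model("ref1", [("R_new", {"b_c": -1, "c_c": 1}, 0, 1000, "h1 and h2")])
        out, _, _ = augment_from_references(draft, [ref], {"ref1": {"h1": "t1"}})
        assert "R_new" not in out.reactions

    def test_reduce_then_augment_from_base_alone_is_idempotent(self):
        base = toy_base()
        omap = {"g1": "t1", "g9": "t9"}
        reduced = reduce_base_model(base, omap, artificial_genes={"S0001"})
        # the panel {base} adds nothing the reduction did not already keep
        ref = base.copy()
        out, _, _ = augment_from_references(reduced, [ref], {"base": omap})
        assert set(out.reactions) == set(reduced.reactions)
        for rid in reduced.reactions:
            assert out.reactions[rid] == reduced.reactions[rid]

    def test_provenance_counts_conserve_reaction_total(self, template):
        panel, truth = make_reference_panel(template, 4, 0.3, seed=11)
        strains = sorted(panel)
        base = panel[strains[0]]
        inv = {
            s: {sg: g for g, sg in truth.strain_genes[s].items()} for s in strains
        }
        reduced = reduce_base_model(base, inv[strains[0]])
        refs = [panel[s] for s in strains[1:]]
        out, ledger, _ = augment_from_references(
            reduced, refs, {s: inv[s] for s in strains[1:]}
        )
        assert ledger.total() == len(out.reactions)
        assert sum(ledger.counts_by_origin().values()) == len(out.reactions)
        table = ledger.table(out)
        assert int(table["n_reactions"].sum()) == len(out.reactions)


class TestEgc:
    def cycle_model(self, with_cycle=True):
        rxns = [
            ("RXY", {"x_c": -1, "y_c": 1}, 0, 1000),
            ("DISS", {"atp_c": -1}, 0, 1000),
            ("EX_x_e", {"x_e": -1}, -10, 1000),
            ("TX", {"x_e": -1, "x_c": 1}, 0, 1000),
        ]
        if with_cycle:
            rxns.append(("RYX_ATP", {"y_c": -1, "x_c": 1, "atp_c": 1}, 0, 1000))
        return build_model(
            [("x_e", "e"), ("x_c", "c"), ("y_c", "c"), ("atp_c", "c")], rxns
        )

    def test_constructed_cycle_flagged_with_support(self):
        m = self.cycle_model(True)
        (report,) = detect_energy_generating_cycles(m, {"ATP": "DISS"})
        assert report.flagged and report.optimum > 1e-6
        assert {"RXY", "RYX_ATP"} <= set(report.support)

    def test_no_cycle_not_flagged(self):
        m = self.cycle_model(False)
        (report,) = detect_energy_generating_cycles(m, {"ATP": "DISS"})
        assert not report.flagged and report.optimum == pytest.approx(0.0, abs=1e-9)

    def test_template_has_no_cycles_across_currencies(self, template):
        reports = detect_energy_generating_cycles(template)
        assert reports, "at least one currency probed"
        assert all(not r.flagged for r in reports)

    def test_detector_stable_under_rerun(self, template):
        first = detect_energy_generating_cycles(template)
        second = detect_energy_generating_cycles(template)
        assert [(r.currency, r.flagged) for r in first] == [
            (r.currency, r.flagged) for r in second
        ]


def gap_toy(missing=True):
    rxns = [
        ("EX_A_e", {"A_e": -1}, -10, 1000),
        ("T_A", {"A_e": -1, "A_c": 1}, 0, 1000),
        ("BIO", {"B_c": -1}, 0, 1000),
    ]
    if not missing:
        rxns.append(("R1", {"A_c": -1, "B_c": 1}, 0, 1000))
    m = build_model([("A_e", "e"), ("A_c", "c"), ("B_c", "c"), ("C_c", "c")], rxns,
                    objective={"BIO": 1.0})
    return m


def universal_set(extra=0):
    rxns = [
        Reaction(id="R1", stoichiometry={"A_c": -1, "B_c": 1}, lower_bound=0, upper_bound=1000),
        Reaction(id="R_irrelevant", stoichiometry={"A_c": -1, "C_c": 1}, lower_bound=0, upper_bound=1000),
    ]
    for i in range(extra):
        rxns.append(
            Reaction(id=f"R_pad{i}", stoichiometry={"C_c": -1, "A_c": 1},
                     lower_bound=0, upper_bound=1000)
        )
    return rxns


def exhaustive_gapfill_oracle(model, universal, objective_rxn, min_flux):
    """Smallest subset of the universal set restoring objective flux,
    found by exhaustive subset enumeration."""
    from gemforge.reconstruct import _combined_lp

    for k in range(len(universal) + 1):
        for combo in itertools.combinations(universal, k):
            trial = _combined_lp(model, list(combo))
            res = fba(trial, objective=objective_rxn)
            if res.optimal and res.objective_value >= min_flux:
                return k
    return None


class TestGapfill:
    def test_single_missing_reaction_found(self):
        sol = gapfill(gap_toy(), universal_set(), "BIO")
        assert sol.feasible
        assert sol.best == frozenset({"R1"})

    def test_already_feasible_returns_empty_set(self):
        universal = [u for u in universal_set() if u.id != "R1"]  # avoid id clash
        sol = gapfill(gap_toy(missing=False), universal, "BIO")
        assert sol.feasible and sol.best == frozenset()

    def test_no_solution_reported_explicitly(self):
        sol = gapfill(gap_toy(), [], "BIO")
        assert not sol.feasible and sol.solutions == []

    def test_cardinality_matches_exhaustive_search(self):
        """On universes <= 15 reactions the MILP minimum equals the
        brute-force subset-search minimum."""
        model = gap_toy()
        universal = universal_set(extra=8)  # 10 candidates
        sol = gapfill(model, universal, "BIO")
        oracle_k = exhaustive_gapfill_oracle(model, universal, "BIO", 1e-2)
        assert sol.feasible and len(sol.best) == oracle_k

    def test_id_clash_rejected(self):
        m = gap_toy(missing=False)
        with pytest.raises(ModelIntegrityError):
            gapfill(m, [Reaction(id="BIO", stoichiometry={"C_c": -1})], "BIO")


class TestEdits:
    def test_removals_and_counts(self, parallel_toy):
        result = apply_edits(parallel_toy, removals=["R1a"])
        assert "R1a" not in result.model.reactions
        assert len(result.model.reactions) == len(parallel_toy.reactions) - 1
        assert ("removed", "R1a") in result.log

    def test_deactivation_pins_zero_flux(self, parallel_toy):
        result = apply_edits(parallel_toy, deactivations=["R1a"])
        res = fba(result.model)
        assert res.fluxes["R1a"] == 0.0
        assert res.objective_value == pytest.approx(10.0)

    def test_unknown_id_named_in_error(self, parallel_toy):
        with pytest.raises(ModelIntegrityError, match="R_missing"):
            apply_edits(parallel_toy, removals=["R_missing"])
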