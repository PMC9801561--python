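"""FBA / pFBA / FVA / media / knockouts against hand-solved LPs and cobra.

The hand-solved expectations come from LPs small enough to do on paper
(single chains and two-path parallels); the template-model screens are
cross-checked against cobrapy as an independent implementation.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from gemforge.core import ModelIntegrityError, Reaction
from gemforge.flux import (
    FluxAnalysisError,
    apply_medium,
    double_gene_deletion,
    fba,
    fva,
    knockout,
    pfba,
    single_gene_deletion,
    single_reaction_deletion,
)
from gemforge.io import write_model
from gemforge.synth import default_medium

from conftest import build_model


class TestFba:
    def test_chain_optimum_is_uptake_bound(self, chain_toy):
        res = fba(chain_toy)
        assert res.status == "optimal"
        assert res.objective_value == pytest.approx(10.0)
        # the chain is a single path: all fluxes pinned
        assert res.fluxes["EX_A_e"] == pytest.approx(-10.0)
        assert res.fluxes["T_A"] == pytest.approx(10.0)

    def test_closed_exchanges_zero_growth(self, chain_toy):
        closed = apply_medium(chain_toy, {})
        assert fba(closed).objective_value == pytest.approx(0.0)

    def test_inverted_bounds_rejected_before_solve(self, chain_toy):
        chain_toy.reactions["BIO"].upper_bound = -1.0
        with pytest.raises(ModelIntegrityError):
            fba(chain_toy)

    def test_mass_balance_invariant_on_every_solve(self, grown_template):
        from gemforge.flux import StoichiometricLP

        res = fba(grown_template)
        lp = StoichiometricLP(grown_template)
        v = np.array([res.fluxes[r] for r in lp.reaction_ids])
        assert np.abs(lp.S @ v).max() <= 1e-6


class TestPfba:
    def test_parallel_total_flux_unique(self, parallel_toy):
        """Σ|v| = 40 however the R1/R1a split degenerates."""
        res = pfba(parallel_toy)
        assert res.total_flux == pytest.approx(40.0, abs=1e-6)
        assert res.fluxes["R1"] + res.fluxes["R1a"] == pytest.approx(10.0, abs=1e-6)

    def test_single_path_pfba_equals_fba(self, chain_toy):
        f, p = fba(chain_toy), pfba(chain_toy)
        for rid in chain_toy.reactions:
            assert p.fluxes[rid] == pytest.approx(f.fluxes[rid], abs=1e-6)

    def test_half_optimum_fraction(self, parallel_toy):
        res = pfba(parallel_toy, fraction=0.5)
        assert res.objective_value == pytest.approx(5.0, abs=1e-6)
        assert res.total_flux == pytest.approx(20.0, abs=1e-6)

    def test_total_flux_never_exceeds_plain_fba(self, grown_template):
        plain = fba(grown_template)
        total_plain = sum(abs(v) for v in plain.fluxes.values())
        assert pfba(grown_template).total_flux <= total_plain + 1e-6


class TestFva:
    def test_parallel_paths_full_range(self, parallel_toy):
        ranges = fva(parallel_toy, ["R1", "R1a"], fraction=1.0)
        for rid in ("R1", "R1a"):
            assert ranges[rid].minimum == pytest.approx(0.0, abs=1e-6)
            assert ranges[rid].maximum == pytest.approx(10.0, abs=1e-6)

    def test_blocked_reaction_is_zero_zero(self, parallel_toy):
        parallel_toy.add_reaction(
            Reaction(id="DEAD", stoichiometry={"A_c": -1},
                     lower_bound=0, upper_bound=0)
        )
        r = fva(parallel_toy, ["DEAD"], fraction=0.9)["DEAD"]
        assert (r.minimum, r.maximum) == (0.0, 0.0)

    def test_overflow_interval_closed_form(self, overflow_toy):
        """R2 interval at fraction f is exactly [0, 10(1-f)]."""
        for f in (0.9, 0.95, 0.99):
            r = fva(overflow_toy, ["R2"], fraction=f)["R2"]
            assert r.minimum == pytest.approx(0.0, abs=1e-6)
            assert r.maximum == pytest.approx(10 * (1 - f), abs=1e-5)

    def test_nestedness_and_pfba_containment(self, grown_template):
        """Intervals shrink monotonically over 0.90..0.99 and the pFBA
        flux lies inside every same-fraction interval."""
        fractions = [round(0.90 + 0.01 * i, 2) for i in range(10)]
        rxns = list(grown_template.reactions)
        ranges = {f: fva(grown_template, rxns, fraction=f) for f in fractions}
        for lo, hi in itertools.pairwise(fractions):
            for rid in rxns:
                assert ranges[hi][rid].minimum >= ranges[lo][rid].minimum - 1e-6
                assert ranges[hi][rid].maximum <= ranges[lo][rid].maximum + 1e-6
        for f in fractions:
            point = pfba(grown_template, fraction=f)
            for rid in rxns:
                assert ranges[f][rid].contains(point.fluxes[rid], tol=1e-5)


class TestMedium:
    def test_apply_medium_semantics(self, chain_toy):
        out = apply_medium(chain_toy, {"EX_A_e": 5.0})
        assert out.reactions["EX_A_e"].lower_bound == -5.0

    def test_anaerobic_switch_closes_oxygen(self, template, medium):
        out = apply_medium(template, medium, aerobic=False)
        assert out.reactions["EX_o2_e"].lower_bound == 0.0
        aerobic = apply_medium(template, medium, aerobic=True)
        assert aerobic.reactions["EX_o2_e"].lower_bound == -20.0

    def test_unknown_or_invalid_medium_entries(self, chain_toy):
        with pytest.raises(FluxAnalysisError):
            apply_medium(chain_toy, {"EX_missing": 10.0})
        with pytest.raises(FluxAnalysisError):
            apply_medium(chain_toy, {"T_A": 10.0})  # not an exchange
        with pytest.raises(FluxAnalysisError):
            apply_medium(chain_toy, {"EX_A_e": -3.0})


class TestKnockout:
    def test_isozyme_rule_keeps_reaction_open(self, chain_toy):
        ko = knockout(chain_toy, {"g1"})
        assert ko.reactions["R1"].upper_bound > 0
        ko2 = knockout(chain_toy, {"g1", "g2"})
        assert ko2.reactions["R1"].upper_bound == 0

    def test_empty_knockout_is_identity(self, chain_toy):
        assert knockout(chain_toy, set()) == chain_toy

    def test_unknown_gene_rejected(self, chain_toy):
        with pytest.raises(FluxAnalysisError):
            knockout(chain_toy, {"nope"})

    def test_deactivated_reaction_carries_no_flux(self, parallel_toy):
        parallel_toy.reactions["R1a"].lower_bound = 0.0
        parallel_toy.reactions["R1a"].upper_bound = 0.0
        res = fba(parallel_toy)
        assert res.fluxes["R1a"] == 0.0
        assert res.objective_value == pytest.approx(10.0)


class TestDeletions:
    def test_transporter_gene_essential_isozyme_not(self, chain_toy):
        screen = single_gene_deletion(chain_toy)
        assert screen.essential == {"gT"}
        assert screen.growth["g1"] == pytest.approx(10.0)

    def test_isozyme_pair_synthetic_lethal(self, parallel_toy):
        double = double_gene_deletion(parallel_toy)
        assert ("g1", "g2") in double.essential

    def test_essential_genes_excluded_from_pairs(self, parallel_toy):
        single = single_gene_deletion(parallel_toy)
        assert "gT" in single.essential
        double = double_gene_deletion(parallel_toy, single=single)
        assert all("gT" not in pair for pair in double.growth)

    def test_reaction_deletion_toy(self, parallel_toy):
        screen = single_reaction_deletion(parallel_toy)
        assert "T_A" in screen.essential
        assert "EX_A_e" in screen.essential  # sole carbon source
        assert "R1" not in screen.essential  # parallel path

    def test_zero_wild_type_growth_is_an_error(self, chain_toy):
        closed = apply_medium(chain_toy, {})
        with pytest.raises(FluxAnalysisError):
            single_gene_deletion(closed)

    def test_results_independent_of_iteration_order(self, grown_template):
        a = single_gene_deletion(grown_template)
        b = single_gene_deletion(grown_template)
        assert a.essential == b.essential and a.growth == b.growth


@pytest.fixture(scope="module")
def cobra_model(grown_template, tmp_path_factory):
    cobra = pytest.importorskip("cobra")
    path = tmp_path_factory.mktemp("cobra") / "model.json"
    write_model(grown_template, path, "json")
    return cobra.io.load_json_model(str(path))


class TestCobraOracle:
    """Independent implementation cross-checks on the template model."""

    def test_fba_optimum_matches(self, grown_template, cobra_model):
        ours = fba(grown_template).objective_value
        theirs = cobra_model.optimize().objective_value
        assert ours == pytest.approx(theirs, abs=1e-6)

    def test_pfba_total_matches(self, grown_template, cobra_model):
        from cobra.flux_analysis import pfba as cobra_pfba

        ours = pfba(grown_template).total_flux
        theirs = cobra_pfba(cobra_model).objective_value
        assert ours == pytest.approx(theirs, abs=1e-4)

    def test_fva_intervals_match(self, grown_template, cobra_model):
        from cobra.flux_analysis import flux_variability_analysis

        rxns = sorted(grown_template.reactions)
        ours = fva(grown_template, rxns, fraction=0.95)
        theirs = flux_variability_analysis(
            cobra_model, rxns, fraction_of_optimum=0.95
        )
        for rid in rxns:
            assert ours[rid].minimum == pytest.approx(theirs.loc[rid, "minimum"], abs=1e-5)
            assert ours[rid].maximum == pytest.approx(theirs.loc[rid, "maximum"], abs=1e-5)

    def test_gene_essentiality_matches(self, grown_template, cobra_model):
        from cobra.flux_analysis import single_gene_deletion as cobra_sgd

        ours = single_gene_deletion(grown_template)
        wt = cobra_model.optimize().objective_value
        frame = cobra_sgd(cobra_model)
        theirs = set()
        for row in frame.itertuples(index=False):
            growth = row.growth if row.status == "optimal" else 0.0
            if (0.0 if growth != growth else growth) < 0.05 * wt:  # NaN -> 0
                theirs.add(next(iter(row.ids)))
        assert ours.essential == theirs
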