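"""Filters, binned scoring, block caps, candidate assembly."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from genedep import scoring
from genedep.scoring import BlockSpec, FeatureSpec

from conftest import make_profile


def _profile_gains(cn_row, n_tnbc):
    gex = np.linspace(5, 6, n_tnbc)
    return make_profile([cn_row], [gex], ["TNBC"] * n_tnbc)


class TestGainFilter:
    def test_gain_in_12_percent_retained(self):
        cn = np.full(40, 2.0)
        cn[:5] = 3.0  # 12.5% of TNBC
        out = scoring.cn_gain_filter(_profile_gains(cn, 40))
        assert bool(out["passed"].iloc[0])
        assert out["gain_freq"].iloc[0] == pytest.approx(0.125)

    def test_just_below_cn_threshold_excluded(self):
        out = scoring.cn_gain_filter(_profile_gains(np.full(40, 2.37), 40))
        assert not out["passed"].iloc[0]

    def test_inclusive_boundaries_on_both_cuts(self):
        cn = np.full(40, 2.0)
        cn[:4] = 2.38  # exactly 10% at exactly the CN threshold
        out = scoring.cn_gain_filter(_profile_gains(cn, 40))
        assert bool(out["passed"].iloc[0])

    def test_requires_tnbc_samples(self):
        prof = make_profile([[2, 2]], [[5, 5]], ["normal", "normal"])
        with pytest.raises(ValueError):
            scoring.cn_gain_filter(prof)


class TestCisFilter:
    def test_monotone_relation_gives_rho_one(self):
        cn = np.linspace(1.5, 4.0, 30)
        gex = np.sqrt(cn)  # strictly increasing transform
        prof = make_profile([cn], [gex], ["TNBC"] * 30)
        out = scoring.cis_correlation_filter(prof)
        assert out["rho"].iloc[0] == pytest.approx(1.0)
        assert bool(out["passed"].iloc[0])

    def test_rho_below_minimum_fails_despite_tiny_p(self):
        # large n with correlation just under 0.30: significant but filtered
        rng = np.random.default_rng(4)
        n = 2000
        cn = rng.normal(2, 0.5, n)
        gex = 0.25 * (cn - 2) / 0.5 + rng.normal(0, np.sqrt(1 - 0.25**2), n)
        rho, p = sps.spearmanr(cn, gex)
        assert rho < 0.30 and p < 1e-3  # constructed regime
        prof = make_profile([cn], [gex], ["TNBC"] * n)
        out = scoring.cis_correlation_filter(prof)
        assert not out["passed"].iloc[0]

    def test_constant_vector_flagged_not_passed(self):
        prof = make_profile(
            [np.full(10, 2.0)], [np.linspace(4, 5, 10)], ["TNBC"] * 10
        )
        out = scoring.cis_correlation_filter(prof)
        assert bool(out["undefined"].iloc[0])
        assert not out["passed"].iloc[0]

    def test_null_pass_rate_is_calibrated(self, rng):
        n_genes, n = 1000, 140
        cn = 2.0 + rng.normal(0, 0.3, (n_genes, n))
        gex = rng.normal(6, 1, (n_genes, n))
        prof = make_profile(cn, gex, ["TNBC"] * n)
        out = scoring.cis_correlation_filter(prof)
        se = np.sqrt(0.01 * 0.99 / n_genes)
        assert out["passed"].mean() <= 0.01 + 3 * se

    def test_exact_permutation_small_n(self):
        cn = np.array([1.8, 2.0, 2.4, 2.6, 3.0, 3.4])
        gex = np.array([4.0, 4.2, 4.1, 4.8, 5.0, 5.2])
        prof = make_profile([cn], [gex], ["TNBC"] * 6)
        out = scoring.cis_correlation_filter(prof, method="exact")
        # oracle: enumerate all 6! rank permutations
        import itertools

        rx, ry = sps.rankdata(cn), sps.rankdata(gex)
        obs = sps.spearmanr(cn, gex).statistic
        hits = sum(
            abs(np.corrcoef(rx, ry[list(p)])[0, 1]) >= abs(obs) - 1e-12
            for p in itertools.permutations(range(6))
        )
        assert out["p"].iloc[0] == pytest.approx(hits / 720)


class TestCnStateTest:
    def test_flat_expression_not_significant(self):
        cn = np.r_[np.full(20, 2.0), np.full(20, 3.0)]
        gex = np.tile([5.0, 5.1], 20)
        prof = make_profile([cn], [gex], ["TNBC"] * 40)
        out = scoring.cn_state_expression_test(prof)
        assert out["p_raw"].iloc[0] > 0.5
        assert not out["significant"].iloc[0]

    def test_shifted_gain_state_significant(self, rng):
        cn = np.r_[np.full(20, 2.0), np.full(20, 3.0)]
        gex = np.r_[rng.normal(5, 1, 20), rng.normal(10, 1, 20)]  # +5 SD
        prof = make_profile([cn], [gex], ["TNBC"] * 40)
        out = scoring.cn_state_expression_test(prof)
        assert out["significant"].iloc[0]

    def test_single_state_returns_na(self):
        prof = make_profile(
            [np.full(10, 2.0)], [np.linspace(4, 5, 10)], ["TNBC"] * 10
        )
        out = scoring.cn_state_expression_test(prof)
        assert np.isnan(out["p_raw"].iloc[0])

    def test_bh_hand_stepped_example(self):
        from genedep.stats import bh_adjust

        adj = bh_adjust([0.001, 0.02, 0.04, 0.9])
        assert adj == pytest.approx([0.004, 0.04, 0.0533333333, 0.9])


class TestDifferentialExpression:
    def test_identical_groups(self):
        vals = np.array([4.0, 5.0, 6.0])
        prof = make_profile(
            [np.full(6, 2.0)],
            [np.r_[vals, vals]],
            ["TNBC"] * 3 + ["normal"] * 3,
        )
        out = scoring.differential_expression(prof)
        assert out["fold_change"].iloc[0] == pytest.approx(1.0)
        assert out["p"].iloc[0] > 0.99

    def test_exact_unit_log2_shift_gives_twofold(self):
        vals = np.array([4.0, 5.0, 6.0])
        prof = make_profile(
            [np.full(6, 2.0)],
            [np.r_[vals + 1.0, vals]],
            ["TNBC"] * 3 + ["normal"] * 3,
        )
        out = scoring.differential_expression(prof)
        assert out["fold_change"].iloc[0] == pytest.approx(2.0)

    def test_planted_threefold_recovered_across_seeds(self):
        recovered = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n_genes, planted = 200, 10
            gex = rng.normal(6, 0.5, (n_genes, 29))
            gex[:planted, :20] += np.log2(3.0)
            cn = np.full_like(gex, 2.0)
            prof = make_profile(cn, gex, ["TNBC"] * 20 + ["normal"] * 9)
            out = scoring.differential_expression(prof)
            recovered.append(
                (out["p_adj"].iloc[:planted] < 0.05).all()
            )
        assert np.mean(recovered) >= 0.95


class TestExpressionCentered:
    def _prof(self, fold):
        # one gene at exactly `fold` linear ratio between TNBC and normals
        norm = np.full(4, 5.0)
        tnbc = np.full(4, 5.0 + np.log2(fold))
        return make_profile(
            [np.full(8, 2.0)], [np.r_[tnbc, norm]], ["TNBC"] * 4 + ["normal"] * 4
        )

    def test_exactly_twofold_excluded(self):
        out = scoring.expression_centered_candidates(self._prof(2.0))
        assert not out["passed"].iloc[0]

    def test_just_over_twofold_included(self):
        out = scoring.expression_centered_candidates(self._prof(2.01))
        assert bool(out["passed"].iloc[0])

    def test_flat_cohort_empty(self):
        out = scoring.expression_centered_candidates(self._prof(1.0))
        assert not out["passed"].any()

    def test_requires_normals(self):
        prof = make_profile([[2, 2]], [[5, 5]], ["TNBC", "TNBC"])
        with pytest.raises(ValueError):
            scoring.expression_centered_candidates(prof)


class TestBinning:
    spec = FeatureSpec("f", "A_gex", 1.0, 2.0, weight=2.0)

    def test_three_bins(self):
        assert scoring.bin_feature_score(0.5, self.spec) == 0.0
        assert scoring.bin_feature_score(1.0, self.spec) == 2.0
        assert scoring.bin_feature_score(2.0, self.spec) == 2.0
        assert scoring.bin_feature_score(2.5, self.spec) == 4.0

    def test_degenerate_middle_bin(self):
        spec = FeatureSpec("f", "A_gex", 1.0, 1.0, weight=1.0)
        assert scoring.bin_feature_score(1.0, spec) == 1.0

    def test_missing_value_contributes_zero(self):
        assert scoring.bin_feature_score(np.nan, self.spec) == 0.0

    def test_smaller_is_better_direction(self):
        spec = FeatureSpec("p", "A_gex", 0.01, 0.05, direction="smaller")
        assert scoring.bin_feature_score(0.001, spec) == 2.0
        assert scoring.bin_feature_score(0.03, spec) == 1.0
        assert scoring.bin_feature_score(0.5, spec) == 0.0

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            FeatureSpec("f", "A_gex", 2.0, 1.0)
        with pytest.raises(ValueError):
            FeatureSpec("f", "A_gex", 1.0, 2.0, weight=0.0)
        with pytest.raises(ValueError):
            FeatureSpec("f", "nope", 1.0, 2.0)
        with pytest.raises(ValueError):
            BlockSpec("A_gex", 0.0)


class TestScoreBlocks:
    specs = [
        FeatureSpec("x", "A_gex", 1.0, 2.0, weight=2.0),
        FeatureSpec("y", "A_gex", 1.0, 2.0, weight=4.0),
        FeatureSpec("z", "B_cn", 0.1, 0.3),
    ]
    blocks = [BlockSpec("A_gex", 8.0), BlockSpec("B_cn", 2.0)]

    def test_all_below_threshold_scores_zero(self):
        feats = pd.DataFrame({"x": [0.0], "y": [0.0], "z": [0.0]}, index=["g"])
        card = scoring.score_blocks(feats, self.specs, self.blocks)
        assert card["total"].iloc[0] == 0.0

    def test_cap_binds(self):
        # raw A sum = 2*2 + 4*2 = 12 against cap 8 -> normalized exactly 1
        feats = pd.DataFrame({"x": [3.0], "y": [3.0], "z": [0.0]}, index=["g"])
        card = scoring.score_blocks(feats, self.specs, self.blocks)
        assert card["block_raw::A_gex"].iloc[0] == 12.0
        assert card["block_norm::A_gex"].iloc[0] == 1.0

    def test_identical_genes_tie_broken_by_id(self):
        feats = pd.DataFrame(
            {"x": [3.0, 3.0], "y": [0.0, 0.0], "z": [0.5, 0.5]},
            index=["gB", "gA"],
        )
        card = scoring.score_blocks(feats, self.specs, self.blocks)
        assert card["total"].nunique() == 1
        assert list(card.index) == ["gA", "gB"]

    def test_unknown_block_rejected(self):
        specs = [FeatureSpec("x", "C_cn_gex", 1.0, 2.0)]
        feats = pd.DataFrame({"x": [1.0]}, index=["g"])
        with pytest.raises(ValueError):
            scoring.score_blocks(feats, specs, self.blocks)

    def test_totals_bounded(self, rng):
        feats = pd.DataFrame(
            rng.normal(1, 2, (50, 3)), columns=["x", "y", "z"],
            index=[f"g{i}" for i in range(50)],
        )
        card = scoring.score_blocks(feats, self.specs, self.blocks)
        for block in ("A_gex", "B_cn"):
            col = card[f"block_norm::{block}"]
            assert col.between(0, 1).all()
        assert card["total"].between(0, len(self.blocks)).all()


class TestFiltersCompose:
    def test_order_independence(self, rng):
        from genedep.simulate import CohortSimConfig, simulate_cohort

        prof = simulate_cohort(
            CohortSimConfig(n_genes=200, n_cis_driver_genes=10, seed=13)
        )
        gains = scoring.cn_gain_filter(prof)
        cis = scoring.cis_correlation_filter(prof)
        joint = set(prof.genes[(gains["passed"] & cis["passed"])])
        sequential = scoring.cis_correlation_filter(
            prof, genes=list(prof.genes[gains["passed"]])
        )
        assert set(sequential.index[sequential["passed"]]) == joint


class TestAssemble:
    def _card(self, genes):
        card = pd.DataFrame(index=pd.Index(genes, name="gene"))
        card["total"] = np.linspace(5, 0, len(genes))
        card["rank"] = np.arange(1, len(genes) + 1)
        return card

    def test_disjoint_arms_sum(self):
        card = self._card([f"a{i:03d}" for i in range(100)])
        arm2 = [f"b{i:03d}" for i in range(45)]
        out = scoring.assemble_candidates(card, arm2, k_top=85)
        assert len(out) == 130
        assert (out["source"] == "score").sum() == 85

    def test_empty_second_arm(self):
        card = self._card([f"a{i:03d}" for i in range(100)])
        out = scoring.assemble_candidates(card, [], k_top=85)
        assert len(out) == 85

    def test_overlap_labelled_both(self):
        card = self._card(["g1", "g2", "g3"])
        out = scoring.assemble_candidates(card, ["g2", "g9"], k_top=2)
        assert out.loc["g2", "source"] == "both"
        assert out.loc["g9", "source"] == "expression"
        assert len(out) == 3

    def test_curated_intersection_and_manual(self):
        card = self._card(["g1"])
        out = scoring.assemble_candidates(
            card, ["g2", "g3"], curated=["g3"], manual=["g4"], k_top=1
        )
        assert set(out.index) == {"g1", "g3", "g4"}
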