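"""Normalization, NPI, Z', replicate QC and the hit-calling rules."""

import numpy as np
import pandas as pd
import pytest

from genedep import screen
from genedep.screen import ControlStats, OligoResult

from conftest import exact_stats_vector


def _plate(sample_vals, pos=None, neg=None, plate_id="P1"):
    rows = []
    for i, v in enumerate(sample_vals):
        rows.append((plate_id, 1, 1, 1, i, "sample", f"g{i}", "pool", "L1", v))
    for i, v in enumerate(pos or []):
        rows.append((plate_id, 1, 1, 2, i, "pos_ctrl", "", "", "L1", v))
    for i, v in enumerate(neg or []):
        rows.append((plate_id, 1, 1, 3, i, "neg_ctrl", "", "", "L1", v))
    return pd.DataFrame(
        rows,
        columns=["plate_id", "lot", "replicate", "row", "col", "reagent_type",
                 "gene", "oligo", "cell_line", "raw_value"],
    )


class TestNormalization:
    def test_constant_plate_normalizes_to_one(self):
        out = screen.plate_median_normalize(_plate([3.0, 3.0, 3.0]))
        assert (out["normalized_value"] == 1.0).all()

    def test_scale_invariance(self):
        a = screen.plate_median_normalize(_plate([1.0, 2.0, 3.0], neg=[2.0]))
        b = screen.plate_median_normalize(_plate([2.0, 4.0, 6.0], neg=[4.0]))
        np.testing.assert_allclose(
            a["normalized_value"].to_numpy(), b["normalized_value"].to_numpy()
        )

    def test_median_of_sample_wells(self):
        out = screen.plate_median_normalize(_plate([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(
            out["normalized_value"].to_numpy(), [0.5, 1.0, 1.5]
        )

    def test_zero_median_rejected(self):
        with pytest.raises(ValueError):
            screen.plate_median_normalize(_plate([0.0, 0.0, 0.0]))


class TestNPI:
    stats = ControlStats(mu_pos=0.2, mu_neg=1.0, sd_pos=0.0, sd_neg=0.0)

    def test_endpoints(self):
        assert screen.compute_npi(1.0, self.stats) == pytest.approx(0.0)
        assert screen.compute_npi(0.2, self.stats) == pytest.approx(100.0)

    def test_interior_value(self):
        assert screen.compute_npi(0.5, self.stats) == pytest.approx(62.5)

    def test_no_clamping(self):
        assert screen.compute_npi(1.2, self.stats) < 0
        assert screen.compute_npi(0.0, self.stats) > 100

    def test_equal_control_means_rejected(self):
        bad = ControlStats(1.0, 1.0, 0.1, 0.1)
        with pytest.raises(ValueError):
            screen.compute_npi(0.5, bad)


class TestZPrime:
    def test_zero_sds_give_one(self):
        z = screen.zprime([100.0, 100.0, 100.0], [0.0, 0.0, 0.0])
        assert z.zprime == pytest.approx(1.0)
        assert z.valid

    def test_printed_example_point_seven(self):
        pos = exact_stats_vector(100.0, 5.0)
        neg = exact_stats_vector(0.0, 5.0)
        z = screen.zprime(pos, neg)
        assert z.zprime == pytest.approx(0.7)
        assert z.valid

    def test_wide_controls_invalid(self):
        z = screen.zprime(exact_stats_vector(100, 12), exact_stats_vector(0, 12))
        assert z.zprime == pytest.approx(0.28)
        assert not z.valid

    def test_equal_means_undefined(self):
        z = screen.zprime([1.0, 2.0], [1.0, 2.0])
        assert np.isnan(z.zprime) and not z.valid


class TestThreshold:
    def test_published_control_summary(self):
        thr = screen.hit_threshold(mean=0.18, sd=5.94)
        assert abs(thr - 18.01) <= 0.01 + 1e-9

    def test_degenerate_and_simple(self):
        assert screen.hit_threshold(mean=0.0, sd=0.0) == 0.0
        assert screen.hit_threshold(mean=1.0, sd=2.0) == 7.0

    def test_raw_values(self):
        vals = exact_stats_vector(0.18, 5.94, n=8)
        assert screen.hit_threshold(vals) == pytest.approx(18.0, abs=1e-9)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            screen.hit_threshold([1.0])


class TestReplicateQC:
    def test_identical_replicates_all_kept(self, rng):
        v = rng.normal(0, 10, 30)
        df = pd.DataFrame({1: v, 2: v, 3: v})
        qc = screen.replicate_qc(df)
        assert qc.kept == [1, 2, 3]
        assert qc.mean_r2 == pytest.approx(1.0)

    def test_noise_replicate_excluded_over_seeds(self):
        excluded = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            signal = rng.normal(0, 20, 60)
            df = pd.DataFrame(
                {
                    1: signal + rng.normal(0, 5, 60),
                    2: signal + rng.normal(0, 5, 60),
                    3: rng.normal(0, 20, 60),  # independent noise
                }
            )
            qc = screen.replicate_qc(df)
            excluded += 3 in qc.excluded and qc.kept == [1, 2]
        assert excluded >= 19

    def test_anticorrelated_replicate_fails_despite_r2(self):
        v = np.arange(10, dtype=float)
        df = pd.DataFrame({1: v, 2: -v})
        qc = screen.replicate_qc(df)
        # r = -1 so r^2 = 1: squared concordance is perfect yet the
        # replicate pair is discordant and must not survive
        assert set(qc.excluded) == {1, 2}
        assert qc.failed


class TestPrimaryRule:
    def test_clause_a(self):
        call = screen.primary_hit(5.0, {"l1": 20.0, "l2": 25.0, "l3": 3.0}, 18.01)
        assert call.verdict == "hit" and call.evidence["clause"] == "A"
        assert call.evidence["lines_above"] == ["l1", "l2"]

    def test_clause_b(self):
        call = screen.primary_hit(
            30.0, {"l1": 2.0, "l2": 5.0, "l3": 40.0, "l4": 50.0}, 18.01
        )
        assert call.verdict == "hit" and call.evidence["clause"] == "B"

    def test_clause_b_needs_two_spared_lines(self):
        call = screen.primary_hit(30.0, {"l1": 20.0, "l2": 25.0, "l3": 30.0}, 18.01)
        assert call.verdict == "no_hit"

    def test_missing_hmec_cannot_call(self):
        call = screen.primary_hit(np.nan, {"l1": 20.0, "l2": 25.0}, 18.01)
        assert call.verdict == "fail"


class TestTop10Rule:
    def _oligo(self, kd, hmec, lines):
        return OligoResult("o", kd, hmec, dict(enumerate(lines)))

    def test_two_qualifying_oligos_validated(self):
        oligos = [
            self._oligo(80.0, 3.0, [20.0, 25.0]),
            self._oligo(85.0, 6.0, [30.0, 22.0]),
            self._oligo(50.0, 1.0, [1.0, 2.0]),
        ]
        assert screen.top10_hit(oligos, 18.01).verdict == "validated"

    def test_low_knockdown_disqualifies(self):
        oligos = [
            self._oligo(80.0, 3.0, [20.0, 25.0]),
            self._oligo(65.0, 6.0, [30.0, 22.0]),
            self._oligo(50.0, 1.0, [1.0, 2.0]),
        ]
        assert screen.top10_hit(oligos, 18.01).verdict == "no_hit"

    def test_single_qualifying_oligo_not_validated(self):
        oligos = [
            self._oligo(80.0, 3.0, [20.0, 25.0]),
            self._oligo(40.0, 6.0, [3.0, 2.0]),
            self._oligo(50.0, 1.0, [1.0, 2.0]),
        ]
        assert screen.top10_hit(oligos, 18.01).verdict == "no_hit"

    def test_no_knockdown_data_cannot_call(self):
        oligos = [self._oligo(np.nan, 3.0, [20.0, 25.0])] * 3
        assert screen.top10_hit(oligos, 18.01).verdict == "fail"


class TestSecondaryRule:
    def test_fail_takes_precedence(self):
        pairs = [(75.0, 5.0), (80.0, 3.0), (45.0, 30.0), (50.0, 25.0)]
        assert screen.secondary_verdict(pairs, 18.01).verdict == "fail"

    def test_validated(self):
        pairs = [(45.0, 30.0), (50.0, 25.0), (72.0, 4.0), (30.0, 1.0)]
        assert screen.secondary_verdict(pairs, 18.01).verdict == "validated"

    def test_inconclusive_without_knockdown(self):
        pairs = [(30.0, 30.0), (35.0, 25.0), (20.0, 5.0), (10.0, 2.0)]
        assert screen.secondary_verdict(pairs, 18.01).verdict == "inconclusive"


class TestTableWrappers:
    def test_call_primary_on_frame(self):
        gl = pd.DataFrame(
            {
                "gene": ["g1"] * 4,
                "cell_line": ["HMEC", "l1", "l2", "l3"],
                "mean_npi": [5.0, 20.0, 25.0, 3.0],
            }
        )
        out = screen.call_primary_hits(gl, 18.01)
        assert out.loc["g1", "verdict"] == "hit"
        assert out.loc["g1", "lines_above"] == "l1;l2"

    def test_call_secondary_on_frame(self):
        df = pd.DataFrame(
            {
                "gene": ["g1"] * 4,
                "oligo": [f"o{i}" for i in range(4)],
                "kd_pct": [45.0, 50.0, 72.0, 30.0],
                "npi": [30.0, 25.0, 4.0, 1.0],
            }
        )
        out = screen.call_secondary(df, 18.01)
        assert out.loc["g1", "verdict"] == "validated"
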