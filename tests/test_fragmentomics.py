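import numpy as np
import pandas as pd
import pytest

from fragsig.coverage import FragmentLengthDistribution
from fragsig.fragmentomics import (
    arm_zscores,
    depth_features,
    global_size_features,
    proportion_short,
    sl_bin_table,
    sl_normalize_and_test,
)


def point_mass(length):
    return FragmentLengthDistribution.point_mass(length)


def uniform_fld(lo, hi):
    lengths = np.arange(lo, hi + 1)
    return FragmentLengthDistribution(lengths=lengths, probs=np.ones(len(lengths)))


class TestGlobalSizeFeatures:
    def test_point_mass_167(self):
        f = global_size_features(point_mass(167))
        assert f.p_160_180 == 1.0
        assert f.p_100_150 == 0.0
        assert f.ratio_100_150_over_163_169 == 0.0

    def test_uniform_100_220(self):
        f = global_size_features(uniform_fld(100, 220))
        assert f.p_100_150 == pytest.approx(51 / 121)

    def test_flat_histogram_has_zero_amplitude(self):
        f = global_size_features(uniform_fld(50, 300))
        assert f.amplitude_10bp == pytest.approx(0.0, abs=1e-12)

    def test_oscillation_gives_positive_amplitude(self):
        lengths = np.arange(20, 801)
        probs = 1.0 + 0.5 * np.cos(2 * np.pi * (lengths - 81) / 10.4)
        fld = FragmentLengthDistribution(lengths=lengths, probs=probs)
        assert global_size_features(fld).amplitude_10bp > 0

    @pytest.mark.parametrize(
        "fld,expected",
        [(point_mass(100), 1.0), (point_mass(167), 0.0)],
    )
    def test_proportion_short_point_masses(self, fld, expected):
        assert proportion_short(fld) == expected

    def test_proportion_short_mixture(self):
        fld = FragmentLengthDistribution(
            lengths=np.array([100, 200]), probs=np.array([0.5, 0.5])
        )
        assert proportion_short(fld) == pytest.approx(0.5)


def make_bins_frame(n, short, long_, gc=None, rng=None):
    gc = gc if gc is not None else np.full(n, 0.45)
    return pd.DataFrame(
        {
            "chrom": "c",
            "start": np.arange(n) * 100_000,
            "end": (np.arange(n) + 1) * 100_000,
            "short": short,
            "long": long_,
            "gc": gc,
        }
    )


class TestSLBinTable:
    def test_equal_counts_give_zero_log_ratio(self, rng):
        n = 200
        counts = rng.poisson(2000, n).astype(float)
        t = sl_bin_table(make_bins_frame(n, counts, counts))
        np.testing.assert_allclose(t["log2_sl"], 0.0)

    def test_doubled_short_gives_log_ratio_one(self, rng):
        n = 200
        long_ = np.full(n, 1500.0)
        t = sl_bin_table(make_bins_frame(n, 2 * long_, long_))
        np.testing.assert_allclose(t["log2_sl"], 1.0)

    def test_gc_trend_removed(self, rng):
        n = 400
        gc = rng.uniform(0.35, 0.55, n)
        long_ = rng.poisson(2000, n).astype(float)
        short = rng.poisson(2000 + 4000 * (gc - 0.45), n).astype(float)  # trend on S only
        t = sl_bin_table(make_bins_frame(n, short, long_, gc=gc))
        slope = np.polyfit(gc[~t["excluded"]], t.loc[~t["excluded"], "log2_sl"], 1)[0]
        raw_slope = np.polyfit(gc, np.log2(short / long_), 1)[0]
        assert abs(slope) < 0.05 * abs(raw_slope)

    def test_low_count_bins_excluded(self):
        t = sl_bin_table(make_bins_frame(20, np.full(20, 100.0), np.full(20, 100.0)),
                         min_total=500)
        assert t["excluded"].all()

    def test_blacklist_overlap_excluded(self, rng):
        n = 50
        counts = np.full(n, 2000.0)
        bl = pd.DataFrame({"chrom": ["c"], "start": [150_000], "end": [250_000]})
        t = sl_bin_table(make_bins_frame(n, counts, counts), blacklist=bl)
        assert t.loc[1, "excluded"] and t.loc[2, "excluded"]
        assert not t.loc[3, "excluded"]
        assert np.isnan(t.loc[1, "log2_sl"])

    def test_gc_correction_near_identity_without_trend(self, rng):
        n = 300
        counts = rng.poisson(3000, n).astype(float)
        t = sl_bin_table(make_bins_frame(n, counts, counts.copy(),
                                         gc=rng.uniform(0.4, 0.5, n)))
        rel = np.abs(t["short_corrected"] - t["short"]) / t["short"]
        assert np.nanmedian(rel) < 0.01


def control_tables(rng, n_bins=400, n_controls=10, sd=0.1):
    base = rng.normal(0, 0.3, n_bins)
    out = []
    for _ in range(n_controls):
        log2 = base + rng.normal(0, sd, n_bins)
        t = make_bins_frame(n_bins, np.full(n_bins, 2000.0), np.full(n_bins, 2000.0))
        t["excluded"] = False
        t["cna_state"] = "neutral"
        t["log2_sl"] = log2
        out.append(t)
    return base, out


class TestSLNormalizeAndTest:
    def test_sample_at_control_mean_is_null(self, rng):
        base, ctrls = control_tables(rng)
        sample = ctrls[0].copy()
        sample["log2_sl"] = base
        out = sl_normalize_and_test(sample, ctrls)
        assert not out["significant"].any()
        assert np.nanmax(np.abs(out["z"])) < 4

    def test_z_formula_on_constructed_bin(self, rng):
        base, ctrls = control_tables(rng, sd=0.25)
        sample = ctrls[0].copy()
        ctrl_vals = np.vstack([
            c["log2_sl"].to_numpy() - c["log2_sl"].mean() for c in ctrls
        ])
        sample_vals = ctrl_vals.mean(axis=0).copy()
        sample_vals[7] += 1.0 * ctrl_vals[:, 7].std(ddof=1)
        sample["log2_sl"] = sample_vals + sample["log2_sl"].mean() * 0  # already centered
        out = sl_normalize_and_test(sample, ctrls)
        # centering shifts all bins identically; z at bin 7 ~ injected 1 sd
        assert out.loc[7, "z"] == pytest.approx(1.0, abs=0.35)

    def test_leave_one_out_for_controls(self, rng):
        # a control scored against the remaining 21 controls should flag at
        # most a stray bin (heavy t-tails at finite control counts)
        base, ctrls = control_tables(rng, n_controls=22)
        out = sl_normalize_and_test(ctrls[0], ctrls, leave_one_out_index=0)
        assert out["significant"].mean() <= 0.01

    def test_excluded_bins_carry_no_statistics(self, rng):
        base, ctrls = control_tables(rng)
        sample = ctrls[0].copy()
        sample.loc[3, "excluded"] = True
        out = sl_normalize_and_test(sample, ctrls)
        assert np.isnan(out.loc[3, "z"])
        assert not out.loc[3, "significant"]

    def test_filtered_cna_state_excluded(self, rng):
        base, ctrls = control_tables(rng)
        sample = ctrls[0].copy()
        sample.loc[5, "cna_state"] = "filtered"
        out = sl_normalize_and_test(sample, ctrls)
        assert np.isnan(out.loc[5, "z"])


class TestArmZscores:
    def arm_map(self, n_bins):
        half = n_bins // 2 * 100_000
        return pd.DataFrame(
            {"chrom": ["c", "c"], "start": [0, half],
             "end": [half, n_bins * 100_000], "arm": ["p", "q"]}
        )

    def test_all_equal_samples_give_zero(self, rng):
        base, ctrls = control_tables(rng, n_bins=100)
        sample = ctrls[0].copy()
        sample["log2_sl"] = base
        out = arm_zscores(sample, ctrls, self.arm_map(100))
        assert np.all(np.abs(out["z"]) < 4)
        assert not out["cna_affected"].any()

    def test_one_cna_bin_marks_arm_affected(self, rng):
        base, ctrls = control_tables(rng, n_bins=100)
        sample = ctrls[0].copy()
        sample.loc[10, "cna_state"] = "gain"
        out = arm_zscores(sample, ctrls, self.arm_map(100))
        assert out.set_index("arm").loc["p", "cna_affected"]
        assert not out.set_index("arm").loc["q", "cna_affected"]

    def test_shifted_arm_detected(self, rng):
        base, ctrls = control_tables(rng, n_bins=100)
        sample = ctrls[0].copy()
        vals = base.copy()
        vals[:50] += 0.3
        sample["log2_sl"] = vals
        out = arm_zscores(sample, ctrls, self.arm_map(100)).set_index("arm")
        assert out.loc["p", "z"] > 3


class TestDepthFeatures:
    def test_constant_counts_give_zero_z(self, rng):
        n = 80
        bins = make_bins_frame(n, np.full(n, 5000.0), np.full(n, 5000.0))
        f = depth_features(bins)
        np.testing.assert_allclose(f.bins["depth_z"], 0.0, atol=1e-9)

    def test_z_vector_standardized(self, rng):
        n = 80
        bins = make_bins_frame(
            n, rng.poisson(5000, n).astype(float), rng.poisson(5000, n).astype(float),
            gc=rng.uniform(0.4, 0.5, n),
        )
        f = depth_features(bins)
        assert f.bins["depth_z"].mean() == pytest.approx(0.0, abs=1e-9)
        assert f.bins["depth_z"].std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_arm_share_sums_to_one_and_gain_dominates(self, rng):
        n = 80
        short = rng.poisson(5000, n).astype(float)
        long_ = rng.poisson(5000, n).astype(float)
        short[:20] *= 1.5
        long_[:20] *= 1.5
        bins = make_bins_frame(n, short, long_)
        arm_map = pd.DataFrame(
            {"chrom": ["c"] * 4,
             "start": [i * 20 * 100_000 for i in range(4)],
             "end": [(i + 1) * 20 * 100_000 for i in range(4)],
             "arm": ["1p", "1q", "2p", "2q"]}
        )
        f = depth_features(bins, arm_map)
        assert f.arm_share.sum() == pytest.approx(1.0)
        assert f.arm_share.idxmax() == "1p"

    def test_feature_vector_assembly(self, rng):
        n = 40
        bins = make_bins_frame(n, rng.poisson(5000, n).astype(float),
                               rng.poisson(5000, n).astype(float))
        f = depth_features(bins)
        v = f.feature_vector(include_arms=False)
        assert len(v) == 2 * n
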