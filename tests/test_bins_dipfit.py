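"""Region binning, CNA normalization, dip-model fitting, and z-score detection."""

import numpy as np
import pandas as pd
import pytest

from fragsig.io_formats import CopyRatioTable, RegionSet
from fragsig.liquorice import (
    DEFAULT_SIGMA_BOUNDS,
    bin_regions,
    cna_normalize,
    cohort_refit,
    detect_signal,
    fit_dip_model,
    make_bins,
)
from fragsig.liquorice.dipfit import dip_model


class TestMakeBins:
    def test_core_widths_1000(self):
        br = make_bins("c", 50_000, 51_000)
        widths = (br.bins[br.bins.is_core].end - br.bins[br.bins.is_core].start).tolist()
        assert widths == [100, 150, 500, 150, 100]

    def test_bin_count_at_defaults(self):
        br = make_bins("c", 50_000, 51_000)
        assert br.n_bins == 40 + 5 + 40

    def test_largest_remainder_rounding(self):
        br = make_bins("c", 30_000, 30_021)
        widths = (br.bins[br.bins.is_core].end - br.bins[br.bins.is_core].start).tolist()
        assert widths == [2, 3, 11, 3, 2]
        assert sum(widths) == 21

    def test_bins_contiguous_and_nonoverlapping(self):
        br = make_bins("c", 50_000, 51_337)
        assert (br.bins["start"].to_numpy()[1:] == br.bins["end"].to_numpy()[:-1]).all()

    def test_edge_regions_dropped_with_count(self):
        rs = RegionSet("x", pd.DataFrame(
            {"chrom": ["c", "c"], "start": [100, 50_000], "end": [1_100, 51_000]}
        ))
        out = bin_regions(rs, {"c": 200_000})
        assert len(out) == 1
        assert out[0].start == 50_000


class TestCnaNormalize:
    def make_region(self):
        return make_bins("c", 600_000, 601_000)

    def test_neutral_table_is_identity(self):
        br = self.make_region()
        table = CopyRatioTable.uniform({"c": 2_000_000})
        v = np.ones(br.n_bins) * 1.7
        np.testing.assert_allclose(cna_normalize(v, br, table), 1.7)

    def test_division_by_window_value(self):
        br = self.make_region()
        table = CopyRatioTable.uniform({"c": 2_000_000})
        table.windows.loc[1, "copy_ratio"] = 2.0  # window 500k-1M holds the region
        v = np.full(br.n_bins, 2.0)
        np.testing.assert_allclose(cna_normalize(v, br, table), 1.0)

    def test_missing_window_marks_bins_invalid(self):
        br = self.make_region()
        table = CopyRatioTable.uniform({"c": 500_000})  # does not reach the region
        out = cna_normalize(np.ones(br.n_bins), br, table)
        assert np.isnan(out).all()

    def test_filtered_state_excluded(self):
        br = self.make_region()
        table = CopyRatioTable.uniform({"c": 2_000_000})
        table.windows.loc[1, "state"] = "filtered"
        out = cna_normalize(np.ones(br.n_bins), br, table)
        assert np.isnan(out).all()


@pytest.fixture(scope="module")
def bin_grid():
    return make_bins("c", 100_000, 101_000).bins["center_offset"].to_numpy()


class TestDipFit:
    def test_flat_profile(self, bin_grid):
        fit = fit_dip_model(bin_grid, np.full(len(bin_grid), 0.8))
        assert fit.intercept == pytest.approx(0.8, abs=1e-6)
        assert np.all(np.abs(fit.amplitudes) < 1e-6)
        assert abs(fit.aoc) < 1e-4

    def test_single_gaussian_closed_form(self, bin_grid):
        y = 1 - 0.2 * np.exp(-bin_grid**2 / (2 * 1000.0**2))
        fit = fit_dip_model(bin_grid, y)
        aoc_true = 0.2 * 1000 * np.sqrt(2 * np.pi)
        assert fit.aoc == pytest.approx(aoc_true, rel=0.01)
        assert fit.aoc_analytic == pytest.approx(aoc_true, rel=0.01)
        assert fit.dip_depth == pytest.approx(0.2, rel=0.01)

    def test_sigma_bounds_honored(self, bin_grid, rng):
        y = 1 - 0.1 * np.exp(-bin_grid**2 / (2 * 700.0**2)) + rng.normal(0, 0.005, len(bin_grid))
        fit = fit_dip_model(bin_grid, y)
        for s, (lo, hi) in zip(fit.sigmas, DEFAULT_SIGMA_BOUNDS):
            assert lo - 1e-6 <= s <= hi + 1e-6

    def test_aoc_consistent_with_analytic_form(self, bin_grid):
        y = 1 - 0.15 * np.exp(-bin_grid**2 / (2 * 900.0**2))
        fit = fit_dip_model(bin_grid, y)
        # trapezoid area over the finite binned domain vs closed form
        assert fit.aoc == pytest.approx(fit.aoc_analytic, rel=0.02)

    def test_too_few_points_is_error(self):
        with pytest.raises(ValueError):
            fit_dip_model(np.arange(10.0), np.ones(10))

    def test_depletion_positive_sign_convention(self, bin_grid):
        y = 1 - 0.2 * np.exp(-bin_grid**2 / (2 * 1000.0**2))
        fit = fit_dip_model(bin_grid, y)
        assert fit.aoc > 0 and fit.dip_depth > 0
        bump = 1 + 0.2 * np.exp(-bin_grid**2 / (2 * 1000.0**2))
        fit2 = fit_dip_model(bin_grid, bump)
        assert fit2.aoc < 0 and fit2.dip_depth < 0


class TestCohortRefit:
    def test_identical_samples_unchanged(self, bin_grid):
        y = 1 - 0.2 * np.exp(-bin_grid**2 / (2 * 1000.0**2))
        fits = [fit_dip_model(bin_grid, y) for _ in range(3)]
        refits, sigmas = cohort_refit(fits)
        np.testing.assert_allclose(sigmas, fits[0].sigmas)
        for f in refits:
            assert f.dip_depth == pytest.approx(0.2, rel=0.01)

    def test_median_sigma_fixed_for_all(self, bin_grid, rng):
        fits = []
        for s2 in (700.0, 900.0, 1_300.0):
            y = 1 - 0.2 * np.exp(-bin_grid**2 / (2 * s2**2))
            fits.append(fit_dip_model(bin_grid, y))
        refits, sigmas = cohort_refit(fits)
        assert sigmas[1] == pytest.approx(900.0, rel=0.02)
        for f in refits:
            np.testing.assert_allclose(f.sigmas, sigmas)

    def test_refit_moves_only_amplitudes_and_intercept(self, bin_grid, rng):
        y = 1 - 0.2 * np.exp(-bin_grid**2 / (2 * 800.0**2)) + rng.normal(0, 0.01, len(bin_grid))
        fits = [fit_dip_model(bin_grid, y + rng.normal(0, 0.005, len(bin_grid)))
                for _ in range(4)]
        refits, sigmas = cohort_refit(fits)
        for f in refits:
            np.testing.assert_array_equal(f.sigmas, sigmas)


class TestDetectSignal:
    def test_sample_at_control_mean(self):
        z, flag = detect_signal(0.5, np.array([0.2, 0.5, 0.8, 0.5]))
        assert z == pytest.approx(0.0)
        assert not flag

    def test_documented_example(self):
        z, flag = detect_signal(2.5, np.array([0.0, 0.0, 1.0, 1.0]))
        assert z == pytest.approx((2.5 - 0.5) / np.std([0, 0, 1, 1], ddof=1))
        assert z == pytest.approx(3.4641, abs=1e-3)
        assert flag

    def test_threshold_is_strict(self):
        controls = np.array([-1.0, 0.0, 1.0, 0.0])
        sd = np.std(controls, ddof=1)
        z, flag = detect_signal(3.0 * sd, controls)
        assert z == pytest.approx(3.0)
        assert not flag

    def test_zero_spread_is_error(self):
        with pytest.raises(ValueError):
            detect_signal(1.0, np.array([0.5, 0.5, 0.5]))

    def test_leave_one_out_removes_self(self):
        controls = np.array([0.0, 0.0, 1.0, 1.0, 10.0])
        z_with, _ = detect_signal(10.0, controls)
        z_loo, _ = detect_signal(10.0, controls, leave_one_out_index=4)
        assert z_loo > z_with


def test_dip_model_evaluates_sum_of_components():
    x = np.linspace(-500, 500, 101)
    y = dip_model(x, 1.0, np.array([-0.1, -0.05, 0.0]), np.array([50.0, 400.0, 5000.0]))
    center = 1.0 - 0.1 - 0.05
    assert y[np.argmin(np.abs(x))] == pytest.approx(center, abs=1e-6)
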