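"""Reproducible synthetic validation studies.

Each function runs one end-to-end study on data generated in-package and
returns plain summary numbers. The studies mirror the designs a method
validation would use:

* exact enumeration checks for the weight-vector construction;
* closed-form recovery for the dip model;
* a null cohort (GC bias injected, no tumor) for bias-correction flatness
  and false-positive control of the dip z-scores;
* a tumor-fraction titration for dip-signal recovery;
* a regional S/L null cohort plus a shifted sample for calibration and
  power;
* spiked fusion-fragment mixtures for the breakpoint estimator;
* separable / label-shuffled / jointly-normalized-null cohorts for the
  classification harness;
* a repeated run for end-to-end determinism.

Cohort sizes follow the scaled-down study design described in
docs/methods.md: 20-22 controls (matching a typical healthy-donor arm),
20 cases per tumor-fraction level, a megabase-scale genome at ~12x
fragment coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classification import bootstrap_evaluate, harmonize
from .coverage import FragmentLengthDistribution
from .fragmentomics import sl_normalize_and_test
from .liquorice import (
    coverage_weight_vector,
    endpoint_weight_vectors,
    fit_dip_model,
    liquorice_cohort,
    make_bins,
)
from .synthetic_data import (
    SimulationConfig,
    make_cohort,
    make_genome,
    simulate_fusion_spans,
)
from .tumor_quant import Breakpoint, count_breakpoint_support, fusion_tumor_content


# ---------------------------------------------------------------------------
# Weight vectors vs exhaustive enumeration
# ---------------------------------------------------------------------------


def weight_vector_oracle_error(max_length: int = 5, max_bin: int = 5) -> tuple[float, int]:
    """Max |difference| between the weight vectors and brute-force
    enumeration over all point-mass lengths <= max_length and bin sizes
    <= max_bin. Returns (max_error, number of vectors compared)."""
    worst = 0.0
    n = 0
    for length in range(1, max_length + 1):
        for bin_size in range(1, max_bin + 1):
            cov: dict[int, float] = {}
            fwd: dict[int, float] = {}
            rev: dict[int, float] = {}
            for p in range(-length, bin_size + length):
                infl = max(0, min(p + length, bin_size) - max(p, 0)) / bin_size
                fwd[p] = fwd.get(p, 0.0) + infl
                rev[p + length] = rev.get(p + length, 0.0) + infl
                for o in range(p, p + length):
                    cov[o] = cov.get(o, 0.0) + infl
            fld = FragmentLengthDistribution.point_mass(length)
            cwv = coverage_weight_vector(fld, bin_size, n_draws=1, mode="expectation")
            fw, rv = endpoint_weight_vectors(fld, bin_size, n_draws=1, mode="expectation")
            for wv, oracle in ((cwv, cov), (fw, fwd), (rv, rev)):
                got = {int(o): w for o, w in zip(wv.offsets, wv.weights)}
                offsets = set(got) | set(oracle)
                worst = max(
                    worst,
                    max(abs(got.get(o, 0.0) - oracle.get(o, 0.0)) for o in offsets),
                )
                n += 3
    return worst, n


# ---------------------------------------------------------------------------
# Closed-form dip recovery
# ---------------------------------------------------------------------------


def dip_closed_form_study(
    amplitude: float = 0.2, sigma: float = 1_000.0, region_length: int = 1_000
) -> dict[str, float]:
    """Fit an analytically generated single-Gaussian dip profile and
    report the relative recovery errors of AOC and dip depth (percent)."""
    x = make_bins("c", 10**6, 10**6 + region_length).bins["center_offset"].to_numpy()
    y = 1.0 - amplitude * np.exp(-(x**2) / (2 * sigma**2))
    fit = fit_dip_model(x, y)
    aoc_true = amplitude * sigma * np.sqrt(2 * np.pi)
    return {
        "aoc_true": aoc_true,
        "aoc_fitted": fit.aoc,
        "aoc_error_pct": 100.0 * abs(fit.aoc - aoc_true) / aoc_true,
        "dip_depth_fitted": fit.dip_depth,
        "dip_depth_error_pct": 100.0 * abs(fit.dip_depth - amplitude) / amplitude,
        "n_points": float(len(x)),
    }


# ---------------------------------------------------------------------------
# Dip cohort: null flatness and tumor-fraction titration
# ---------------------------------------------------------------------------


@dataclass
class DipCohortStudy:
    """Joint result of the null-control and titration arms."""

    table: pd.DataFrame          # per-sample metrics + truth + z/flag
    flatness: pd.DataFrame       # per-control profile sd before/after correction
    levels: tuple[float, ...]

    @property
    def controls(self) -> pd.DataFrame:
        return self.table[self.table["is_control_truth"]]

    @property
    def cases(self) -> pd.DataFrame:
        return self.table[~self.table["is_control_truth"]]

    def level_means(self) -> pd.Series:
        return self.cases.groupby("tumor_fraction")["aoc"].mean()

    def summary(self) -> dict[str, float]:
        ctrl = self.controls
        cases = self.cases
        means = self.level_means()
        high = cases[cases["tumor_fraction"] >= 0.2]
        r = float(np.corrcoef(cases["tumor_fraction"], cases["aoc"])[0, 1])
        return {
            "n_controls_flagged": float(ctrl["flag"].sum()),
            "n_controls": float(len(ctrl)),
            "sd_ratio_uncorrected_over_corrected": float(
                (self.flatness["uncorrected_sd"] / self.flatness["corrected_sd"]).mean()
            ),
            "aoc_level_means_strictly_increasing": float(
                bool(np.all(np.diff(means.to_numpy()) > 0))
            ),
            "high_fraction_cases_flagged_pct": 100.0 * float(high["flag"].mean()),
            "n_high_fraction_cases": float(len(high)),
            "pearson_r_aoc_vs_fraction": r,
        }


def dip_cohort_study(
    seed: int = 0,
    n_controls: int = 20,
    cases_per_level: int = 20,
    levels: tuple[float, ...] = (0.0, 0.05, 0.2, 0.5, 0.95),
    config: SimulationConfig | None = None,
) -> DipCohortStudy:
    """Simulate a control + titration cohort and run the full dip workflow.

    Controls are scored leave-one-out; every sample's aggregated profile
    standard deviation is recorded before and after bias correction.
    """
    cfg = config if config is not None else SimulationConfig()
    cfg.seed = seed
    genome = make_genome(cfg)
    fractions = [tf for tf in levels for _ in range(cases_per_level)]
    samples, truth = make_cohort(genome, n_controls, fractions, master_seed=seed)
    control_ids = truth.loc[truth["is_control"], "sample"].tolist()
    results, table = liquorice_cohort(
        samples,
        genome.regions,
        {cfg.chrom: genome.sequence},
        genome.mappability,
        control_ids=control_ids,
        seed=seed,
    )
    table = table.merge(truth, on="sample", suffixes=("", "_truth"))
    flatness = pd.DataFrame(
        {
            "sample": control_ids,
            "uncorrected_sd": [
                float(np.std(results[s].profile_uncorrected)) for s in control_ids
            ],
            "corrected_sd": [
                float(np.std(results[s].profile_corrected)) for s in control_ids
            ],
        }
    )
    return DipCohortStudy(table=table, flatness=flatness, levels=levels)


# ---------------------------------------------------------------------------
# Regional S/L calibration and power
# ---------------------------------------------------------------------------


def _sl_table(log2_values: np.ndarray) -> pd.DataFrame:
    n = len(log2_values)
    return pd.DataFrame(
        {
            "chrom": "c",
            "start": np.arange(n) * 100_000,
            "end": (np.arange(n) + 1) * 100_000,
            "excluded": False,
            "cna_state": "neutral",
            "log2_sl": log2_values,
        }
    )


def sl_study(
    seed: int = 0,
    n_bins: int = 10_000,
    n_controls: int = 22,
    bin_sd: float = 0.1,
    shifted_fraction: float = 0.01,
    shift_sds: float = 5.0,
) -> dict[str, float]:
    """Null calibration and power of the per-bin S/L z-test.

    Controls carry per-bin noise of ``bin_sd`` around a shared baseline.
    Null calibration pools leave-one-out z-scores of every control. The
    power arm scores one sample constructed as the baseline with
    ``shift_sds`` * ``bin_sd`` added to a random 1% of bins (the shift is
    injected on the noise-free expected value, so the measured power
    isolates the detection step).
    """
    rng = np.random.default_rng(seed)
    base = rng.normal(0.0, 0.3, n_bins)
    controls = [_sl_table(base + rng.normal(0.0, bin_sd, n_bins)) for _ in range(n_controls)]

    zs = []
    for i in range(n_controls):
        out = sl_normalize_and_test(controls[i], controls, leave_one_out_index=i)
        zs.append(out["z"].to_numpy())
    zs = np.concatenate(zs)
    zs = zs[np.isfinite(zs)]

    n_shift = int(round(shifted_fraction * n_bins))
    shifted = rng.choice(n_bins, size=n_shift, replace=False)
    case_values = base.copy()
    case_values[shifted] += shift_sds * bin_sd
    case = sl_normalize_and_test(_sl_table(case_values), controls)
    hit = case.loc[shifted, "significant"]
    unshifted_mask = np.ones(n_bins, bool)
    unshifted_mask[shifted] = False
    false_flags = case.loc[unshifted_mask, "significant"]
    return {
        "null_z_mean": float(zs.mean()),
        "null_z_sd": float(zs.std(ddof=1)),
        "n_null_z": float(len(zs)),
        "sensitivity_pct": 100.0 * float(hit.mean()),
        "n_shifted_bins": float(n_shift),
        "false_flag_pct": 100.0 * float(false_flags.mean()),
        "n_unshifted_bins": float(unshifted_mask.sum()),
    }


# ---------------------------------------------------------------------------
# Fusion-breakpoint estimator
# ---------------------------------------------------------------------------


def fusion_study(seed: int = 0, tumor_fraction: float = 0.4, depth: int = 4_000
                 ) -> dict[str, float]:
    """Exact formula cases plus recovery of a spiked mixture fraction."""
    exact = [
        (fusion_tumor_content(0, 10, 10), 0.0),
        (fusion_tumor_content(10, 10, 10), 1.0),
        (fusion_tumor_content(5, 10, 20), 0.5),
    ]
    formula_err = max(abs(got - want) for got, want in exact)

    spans = simulate_fusion_spans(tumor_fraction, depth, seed=seed, microhomology=2)
    bp = Breakpoint("chrA", 1_000, "chrB", 1_000, microhomology=2)
    f, g1, g2 = count_breakpoint_support(
        spans, bp, junctions={"fusion": 1_000, "germline_a": 1_000, "germline_b": 1_000}
    )
    est = fusion_tumor_content(f, g1, g2)
    return {
        "formula_max_error": formula_err,
        "true_fraction": tumor_fraction,
        "estimated_fraction": est,
        "recovery_abs_error": abs(est - tumor_fraction),
        "n_fragments": float(f + g1 + g2),
    }


# ---------------------------------------------------------------------------
# Classification harness studies
# ---------------------------------------------------------------------------


def ml_separable_study(seed: int = 0, n_iter: int = 30, n_per_class: int = 30,
                       n_features: int = 7, effect: float = 3.0) -> dict[str, float]:
    """Mean bootstrap ROC AUC on a cleanly separable two-class cohort."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    y = np.array([0] * n_per_class + [1] * n_per_class)
    X = pd.DataFrame(rng.normal(size=(n, n_features)) + y[:, None] * effect)
    res = bootstrap_evaluate({"f": X}, y, np.arange(n), n_iter=n_iter, seed=seed)["f"]
    return {"auc": res.auc, "n_iterations": float(n_iter), "n_samples": float(n)}


def ml_shuffled_study(seed: int = 0, n_iter: int = 30, n_per_class: int = 30,
                      n_features: int = 7) -> dict[str, float]:
    """Mean bootstrap ROC AUC with class labels randomly shuffled."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    y = rng.permutation(np.array([0] * n_per_class + [1] * n_per_class))
    X = pd.DataFrame(rng.normal(size=(n, n_features)))
    res = bootstrap_evaluate({"f": X}, y, np.arange(n), n_iter=n_iter, seed=seed)["f"]
    return {"auc": res.auc, "n_iterations": float(n_iter), "n_samples": float(n)}


def ml_joint_normalization_study(seed: int = 0, n_iter: int = 100, n_source_a: int = 24,
                                 n_source_b: int = 22, n_features: int = 100
                                 ) -> dict[str, float]:
    """Training to separate two identically distributed control sources
    after whole-dataset (per-source control) normalization.

    Because the normalization forces equal class means on the full data
    set, random train-set differences are mirrored with opposite sign in
    the test set, and the classifier scores systematically below chance.
    Also audits patient-level train/test disjointness per iteration.
    """
    rng = np.random.default_rng(seed)
    n = n_source_a + n_source_b
    X = pd.DataFrame(rng.normal(size=(n, n_features)))
    src = np.array(["a"] * n_source_a + ["b"] * n_source_b)
    Xh = harmonize(X, np.ones(n, bool), src)
    y = (src == "b").astype(int)
    res = bootstrap_evaluate({"f": Xh}, y, np.arange(n), n_iter=n_iter, seed=seed)["f"]
    violations = sum(
        len(np.intersect1d(tr, te)) > 0 for tr, te in res.splits
    )
    return {
        "mean_iteration_auc": float(res.per_iteration_auc.mean()),
        "mean_curve_auc": res.auc,
        "n_iterations": float(n_iter),
        "split_violations": float(violations),
    }


# ---------------------------------------------------------------------------
# Determinism
# ---------------------------------------------------------------------------


def determinism_study(seed: int = 0) -> dict[str, float]:
    """Run a small end-to-end cohort twice with the same seed and report
    the largest absolute difference over all metric-table entries."""
    def run() -> pd.DataFrame:
        cfg = SimulationConfig(
            genome_length=600_000, n_regions=8, edge_clearance=26_000, depth=6.0,
            dip_sigmas=(150.0, 800.0, 3_500.0), dip_amplitudes=(0.25, 0.3, 0.15),
            seed=seed,
        )
        genome = make_genome(cfg)
        samples, truth = make_cohort(genome, n_controls=4, case_fractions=[0.5],
                                     master_seed=seed)
        _, table = liquorice_cohort(
            samples, genome.regions, {cfg.chrom: genome.sequence}, genome.mappability,
            control_ids=truth.loc[truth["is_control"], "sample"].tolist(), seed=seed,
        )
        return table

    a, b = run(), run()
    num = a.select_dtypes("number")
    diff = float(np.max(np.abs(num.to_numpy() - b[num.columns].to_numpy())))
    same_shape = a.shape == b.shape and (a["sample"] == b["sample"]).all()
    return {
        "max_metric_difference": diff if same_shape else float("inf"),
        "n_metric_values": float(num.size),
    }
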