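"""Per-sample and per-cohort orchestration of the dip-quantification workflow."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ..coverage import build_coverage_track, fragment_length_distribution
from ..io_formats import CopyRatioTable, RegionSet, SignalTrack
from .bias import BiasModel, compute_bias_features, correct_coverage, train_bias_model
from .bins import bin_regions, cna_normalize
from .dipfit import DEFAULT_SIGMA_BOUNDS, DipModelFit, cohort_refit, detect_signal, fit_dip_model

logger = logging.getLogger(__name__)


def aggregate_profile(features: pd.DataFrame, value_column: str = "corrected"
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Mean profile across regions, aligned by ordinal bin position.

    Returns (x, y): x is the mean center offset (bp from the region
    midpoint) per ordinal position, y the mean of ``value_column`` over
    regions, ignoring bins excluded upstream (NaN).
    """
    valid = features[np.isfinite(features[value_column])]
    if valid["region_id"].nunique() == 0:
        raise ValueError("no valid regions to aggregate")
    g = valid.groupby("ordinal")
    x = g["center_offset"].mean().to_numpy()
    y = g[value_column].mean().to_numpy()
    return x, y


@dataclass
class SampleResult:
    """Everything the dip workflow derives from one sample and region set."""

    sample_id: str
    features: pd.DataFrame = field(repr=False)
    bias_model: BiasModel = field(repr=False)
    profile_x: np.ndarray = field(repr=False)
    profile_corrected: np.ndarray = field(repr=False)
    profile_uncorrected: np.ndarray = field(repr=False)
    fit: DipModelFit = field(repr=False)

    def profile_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "center_offset": self.profile_x,
                "uncorrected": self.profile_uncorrected,
                "corrected": self.profile_corrected,
                "fitted": self.fit.fitted,
            }
        )


def liquorice_sample(
    sample_id: str,
    fragments: pd.DataFrame,
    regions: RegionSet,
    sequences: Mapping[str, str],
    mappability: SignalTrack,
    copy_ratios: CopyRatioTable | None = None,
    mapq_min: int = 20,
    flank: int = 20_000,
    flank_bin: int = 500,
    n_draws: int = 200,
    seed: int | np.random.SeedSequence | None = 0,
    weight_mode: str = "sample",
    n_trees: int = 50,
    sigma_bounds=DEFAULT_SIGMA_BOUNDS,
    reference=None,
    blacklist=None,
) -> SampleResult:
    """Run the full bias-corrected dip quantification for one sample.

    ``reference`` (from :func:`~fragsig.liquorice.bias.prepare_reference`)
    lets cohort runs reuse the genome-level sequence/mappability arrays.
    ``blacklist`` (a :class:`~fragsig.io_formats.RegionSet`, off by
    default) excludes bins overlapping its intervals from training and
    aggregation.
    """
    sizes = {c: len(s) for c, s in sequences.items()}
    cov = build_coverage_track(fragments, sizes, mapq_min=mapq_min)
    fld = fragment_length_distribution(fragments)
    binned = bin_regions(regions, sizes, flank=flank, flank_bin=flank_bin)
    if not binned:
        raise ValueError("no usable regions")

    features = compute_bias_features(
        sequences, mappability, binned, fld, n_draws=n_draws, seed=seed, mode=weight_mode,
        reference=reference,
    )
    coverage = np.concatenate(
        [
            cna_normalize(
                cov.bin_means(
                    br.chrom, br.bins["start"].to_numpy(), br.bins["end"].to_numpy()
                ),
                br,
                copy_ratios,
            )
            for br in binned
        ]
    )
    features = features.copy()
    features["coverage"] = coverage
    if blacklist is not None and len(blacklist):
        mask = np.zeros(len(features), dtype=bool)
        for row in blacklist.intervals.itertuples(index=False):
            mask |= (
                (features["chrom"] == row.chrom)
                & (features["start"] < row.end)
                & (features["end"] > row.start)
            ).to_numpy()
        if mask.any():
            logger.info("%s: %d bins excluded by blacklist", sample_id, int(mask.sum()))
            features.loc[mask, "coverage"] = np.nan

    if isinstance(seed, np.random.SeedSequence):
        rf_seed = int(seed.generate_state(1)[0] % (2**31))
    else:
        rf_seed = None if seed is None else int(seed) % (2**31)
    model = train_bias_model(features, n_trees=n_trees, seed=rf_seed)
    features["predicted"] = model.predict(features)
    features["corrected"] = correct_coverage(features, model)

    x, y_corr = aggregate_profile(features, "corrected")
    _, y_raw = aggregate_profile(features, "coverage")
    fit = fit_dip_model(x, y_corr, sigma_bounds=sigma_bounds)
    if not fit.success:
        logger.warning("%s: dip fit did not converge: %s", sample_id, fit.message)
    return SampleResult(
        sample_id=sample_id,
        features=features,
        bias_model=model,
        profile_x=x,
        profile_corrected=y_corr,
        profile_uncorrected=y_raw,
        fit=fit,
    )


def liquorice_cohort(
    samples: Sequence[tuple[str, pd.DataFrame]],
    regions: RegionSet,
    sequences: Mapping[str, str],
    mappability: SignalTrack,
    control_ids: Sequence[str],
    copy_ratios: CopyRatioTable | None = None,
    metric: str = "aoc",
    threshold: float = 3.0,
    refit: bool = True,
    seed: int = 0,
    **sample_kwargs,
) -> tuple[dict[str, SampleResult], pd.DataFrame]:
    """Run the dip workflow on a cohort and score every sample vs controls.

    A second fitting pass fixes the sigma parameters at their
    across-sample medians before metrics are computed. ``metric`` selects
    the z-scored quantity (``aoc`` for broad regulatory region sets,
    ``dip_depth`` for sharp DHS-type dips). Controls are scored
    leave-one-out against the remaining controls.
    """
    from ..synthetic_data import sample_seed  # deterministic per-sample streams
    from .bias import prepare_reference

    reference = sample_kwargs.pop("reference", None)
    if reference is None:
        reference = prepare_reference(sequences, mappability)

    results: dict[str, SampleResult] = {}
    for i, (sid, fragments) in enumerate(samples):
        results[sid] = liquorice_sample(
            sid, fragments, regions, sequences, mappability,
            copy_ratios=copy_ratios, seed=sample_seed(seed, i),
            reference=reference, **sample_kwargs
        )

    ids = [sid for sid, _ in samples]
    fits = [results[sid].fit for sid in ids]
    if refit:
        fits, fixed = cohort_refit(fits)
        for sid, f in zip(ids, fits):
            results[sid].fit = f

    rows = []
    for sid, f in zip(ids, fits):
        row = {"sample": sid, "is_control": sid in set(control_ids), "converged": f.success}
        row.update(f.metrics())
        rows.append(row)
    table = pd.DataFrame(rows)

    control_values = table.loc[table["is_control"], metric].to_numpy()
    control_order = list(table.loc[table["is_control"], "sample"])
    zs, flags = [], []
    for _, row in table.iterrows():
        loo = control_order.index(row["sample"]) if row["is_control"] else None
        z, flag = detect_signal(row[metric], control_values, threshold=threshold,
                                leave_one_out_index=loo)
        zs.append(z)
        flags.append(flag)
    table["z"] = zs
    table["flag"] = flags
    return results, table
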