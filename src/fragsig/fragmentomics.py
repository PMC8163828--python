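"""Fragment-size analytics: global size features, regional S/L profiles, depth features.

Three families of metrics, matching the feature sets consumed by the
classification harness:

* global fragment-size features computed from a sample's length histogram
  (range proportions, two proportion ratios, and the 10 bp oscillation
  amplitude at fixed local minima/maxima positions);
* regional short/long (S/L) fragment-ratio profiles in 100 kb genome
  tiles: LOWESS GC correction per size class, log2(S/L), centering on
  CNA-neutral bins, per-bin z-scores against healthy controls with
  Benjamini-Hochberg FDR, and chromosome-arm summaries;
* read-depth features in 5 Mb tiles: LOESS GC-corrected counts,
  z-transformed within each sample, plus per-arm shares normalized to
  sum 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .coverage import FragmentLengthDistribution

logger = logging.getLogger(__name__)

LOWESS_FRAC = 0.75
SL_BIN_SIZE = 100_000
DEPTH_BIN_SIZE = 5_000_000

#: fixed positions (bp) of the ~10 bp oscillation in the sub-nucleosomal
#: part of the cfDNA length histogram
AMPLITUDE_MINIMA = (84, 96, 106, 116, 126, 137, 148)
AMPLITUDE_MAXIMA = (81, 92, 102, 112, 122, 134, 144)


# ---------------------------------------------------------------------------
# Global fragment-size features
# ---------------------------------------------------------------------------


@dataclass
class GlobalSizeFeatures:
    p_100_150: float
    p_160_180: float
    p_180_220: float
    p_250_320: float
    ratio_100_150_over_163_169: float
    ratio_160_180_over_180_220: float
    amplitude_10bp: float

    def to_dict(self) -> dict[str, float]:
        return dict(vars(self))


def _safe_ratio(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def global_size_features(fld: FragmentLengthDistribution) -> GlobalSizeFeatures:
    """Size-range proportions, ratios, and the 10 bp amplitude.

    amplitude_10bp is the mean histogram value at the listed local maxima
    minus the mean at the listed local minima.
    """
    p = fld.range_mass
    amp = float(
        np.mean([fld.prob(v) for v in AMPLITUDE_MAXIMA])
        - np.mean([fld.prob(v) for v in AMPLITUDE_MINIMA])
    )
    return GlobalSizeFeatures(
        p_100_150=p(100, 150),
        p_160_180=p(160, 180),
        p_180_220=p(180, 220),
        p_250_320=p(250, 320),
        ratio_100_150_over_163_169=_safe_ratio(p(100, 150), p(163, 169)),
        ratio_160_180_over_180_220=_safe_ratio(p(160, 180), p(180, 220)),
        amplitude_10bp=amp,
    )


def proportion_short(fld: FragmentLengthDistribution, low: int = 20, high: int = 150) -> float:
    """Proportion of short fragments, default 20-150 bp."""
    return fld.range_mass(low, high)


# ---------------------------------------------------------------------------
# Regional S/L tables
# ---------------------------------------------------------------------------


def _lowess_correct(counts: np.ndarray, gc: np.ndarray, frac: float = LOWESS_FRAC) -> np.ndarray:
    """count - fit(gc) + mean(count): removes the GC trend, keeps the scale."""
    fit = lowess(counts, gc, frac=frac, return_sorted=False)
    return counts - fit + counts.mean()


def _intervals_overlap_mask(bins: pd.DataFrame, other: pd.DataFrame | None) -> np.ndarray:
    if other is None or len(other) == 0:
        return np.zeros(len(bins), dtype=bool)
    mask = np.zeros(len(bins), dtype=bool)
    for chrom, sub in other.groupby("chrom"):
        sel = bins["chrom"] == chrom
        if not sel.any():
            continue
        bs = bins.loc[sel, "start"].to_numpy()
        be = bins.loc[sel, "end"].to_numpy()
        hit = np.zeros(len(bs), dtype=bool)
        for s, e in zip(sub["start"], sub["end"]):
            hit |= (bs < e) & (be > s)
        mask[np.flatnonzero(sel)] = hit
    return mask


def sl_bin_table(
    bins: pd.DataFrame,
    blacklist: pd.DataFrame | None = None,
    gaps: pd.DataFrame | None = None,
    min_total: int = 500,
    lowess_frac: float = LOWESS_FRAC,
) -> pd.DataFrame:
    """Per-bin corrected log2(S/L) table.

    ``bins`` needs columns chrom, start, end, short, long, gc (and
    optionally cna_state). Bins overlapping the blacklist or gap intervals,
    with fewer than ``min_total`` total fragments, or with non-positive
    corrected counts are excluded and carry no statistics.
    """
    out = bins.copy().reset_index(drop=True)
    excluded = _intervals_overlap_mask(out, blacklist) | _intervals_overlap_mask(out, gaps)
    excluded |= (out["short"] + out["long"]).to_numpy() < min_total
    out["excluded"] = excluded

    ok = ~excluded
    s_corr = np.full(len(out), np.nan)
    l_corr = np.full(len(out), np.nan)
    if ok.sum() >= 10:
        s_corr[ok] = _lowess_correct(
            out.loc[ok, "short"].to_numpy(dtype=float), out.loc[ok, "gc"].to_numpy(),
            frac=lowess_frac,
        )
        l_corr[ok] = _lowess_correct(
            out.loc[ok, "long"].to_numpy(dtype=float), out.loc[ok, "gc"].to_numpy(),
            frac=lowess_frac,
        )
    else:
        s_corr[ok] = out.loc[ok, "short"].to_numpy(dtype=float)
        l_corr[ok] = out.loc[ok, "long"].to_numpy(dtype=float)
    nonpos = ok & ((s_corr <= 0) | (l_corr <= 0))
    if nonpos.any():
        logger.warning("%d bins excluded: non-positive corrected counts", int(nonpos.sum()))
        out.loc[nonpos, "excluded"] = True
        s_corr[nonpos] = np.nan
        l_corr[nonpos] = np.nan
    out["short_corrected"] = s_corr
    out["long_corrected"] = l_corr
    with np.errstate(invalid="ignore", divide="ignore"):
        out["log2_sl"] = np.log2(s_corr / l_corr)
    if "cna_state" not in out.columns:
        out["cna_state"] = "neutral"
    return out


def _center_on_neutral(table: pd.DataFrame) -> np.ndarray:
    """log2(S/L) minus the sample's mean over usable CNA-neutral bins."""
    usable = (~table["excluded"]) & (table["cna_state"] == "neutral")
    if usable.sum() == 0:
        raise ValueError("no CNA-neutral bins to normalize on")
    return table["log2_sl"].to_numpy() - table.loc[usable, "log2_sl"].mean()


def sl_normalize_and_test(
    sample: pd.DataFrame,
    controls: list[pd.DataFrame],
    fdr: float = 0.05,
    leave_one_out_index: int | None = None,
) -> pd.DataFrame:
    """Center the sample on its CNA-neutral bins, z-score each bin against
    the control distribution, and mark FDR-significant bins.

    Controls are centered the same way. When scoring a control against its
    own cohort, pass its index so it is removed from the reference
    distribution. Bins excluded in the sample, CNA-indeterminate, or with
    zero control spread carry no statistics.
    """
    if leave_one_out_index is not None:
        controls = controls[:leave_one_out_index] + controls[leave_one_out_index + 1 :]
    if len(controls) < 3:
        raise ValueError("need >= 3 controls")
    out = sample.copy().reset_index(drop=True)
    out["norm_log2_sl"] = _center_on_neutral(out)
    ctrl = np.vstack([_center_on_neutral(c) for c in controls])
    ctrl_excluded = np.vstack([c["excluded"].to_numpy() for c in controls])
    ctrl = np.where(ctrl_excluded, np.nan, ctrl)

    with np.errstate(invalid="ignore"):
        mean = np.nanmean(ctrl, axis=0)
        sd = np.nanstd(ctrl, axis=0, ddof=1)
        n_ctrl = np.sum(~np.isnan(ctrl), axis=0)

    usable = (
        (~out["excluded"]).to_numpy()
        & (out["cna_state"] != "filtered").to_numpy()
        & (n_ctrl >= 3)
        & (sd > 0)
    )
    z = np.full(len(out), np.nan)
    z[usable] = (out.loc[usable, "norm_log2_sl"].to_numpy() - mean[usable]) / sd[usable]
    p = np.full(len(out), np.nan)
    p[usable] = 2.0 * stats.norm.sf(np.abs(z[usable]))
    q = np.full(len(out), np.nan)
    if usable.any():
        _, q_u, _, _ = multipletests(p[usable], method="fdr_bh")
        q[usable] = q_u
    out["z"] = z
    out["p"] = p
    out["q"] = q
    out["significant"] = (q < fdr) & usable
    out.loc[~usable, "significant"] = False
    return out


def arm_zscores(
    sample: pd.DataFrame,
    controls: list[pd.DataFrame],
    arm_map: pd.DataFrame,
    leave_one_out_index: int | None = None,
) -> pd.DataFrame:
    """Per-arm mean log2(S/L) compared to controls via z-scores.

    ``arm_map`` has columns chrom, start, end, arm. An arm is labelled
    CNA-affected if at least one of its usable bins is non-neutral.
    """
    if leave_one_out_index is not None:
        controls = controls[:leave_one_out_index] + controls[leave_one_out_index + 1 :]

    def arm_means(table: pd.DataFrame) -> pd.Series:
        t = table.copy()
        t["value"] = _center_on_neutral(t)
        t = t[~t["excluded"]]
        mids = (t["start"] + t["end"]) // 2
        arms = pd.Series(index=t.index, dtype=object)
        for row in arm_map.itertuples(index=False):
            sel = (t["chrom"] == row.chrom) & (mids >= row.start) & (mids < row.end)
            arms[sel] = row.arm
        t = t.assign(arm=arms).dropna(subset=["arm"])
        return t.groupby("arm")["value"].mean()

    sample_means = arm_means(sample)
    ctrl_means = pd.concat([arm_means(c) for c in controls], axis=1)

    rows = []
    t = sample[~sample["excluded"]]
    mids = (t["start"] + t["end"]) // 2
    for row in arm_map.itertuples(index=False):
        arm = row.arm
        if arm not in sample_means.index or arm not in ctrl_means.index:
            rows.append({"arm": arm, "z": np.nan, "cna_affected": False})
            continue
        ref = ctrl_means.loc[arm].dropna().to_numpy()
        sd = ref.std(ddof=1) if len(ref) >= 3 else 0.0
        z = (sample_means[arm] - ref.mean()) / sd if sd > 0 else np.nan
        in_arm = (t["chrom"] == row.chrom) & (mids >= row.start) & (mids < row.end)
        affected = bool((t.loc[in_arm, "cna_state"] != "neutral").any())
        rows.append({"arm": arm, "z": z, "cna_affected": affected})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Read-depth feature sets (5 Mb bins)
# ---------------------------------------------------------------------------


@dataclass
class DepthFeatures:
    """GC-corrected, within-sample z-transformed 5 Mb depth features."""

    bins: pd.DataFrame          # chrom, start, end, gc, arm, depth_z, short_z
    arm_share: pd.Series        # per-arm mean depth normalized to sum 1

    def feature_vector(self, include_short: bool = True, include_arms: bool = True
                       ) -> pd.Series:
        parts = [pd.Series(self.bins["depth_z"].to_numpy(),
                           index=[f"depth_{i}" for i in range(len(self.bins))])]
        if include_short:
            parts.append(pd.Series(self.bins["short_z"].to_numpy(),
                                   index=[f"short_{i}" for i in range(len(self.bins))]))
        if include_arms:
            parts.append(self.arm_share.rename(lambda a: f"arm_{a}"))
        return pd.concat(parts)


def depth_features(
    bins: pd.DataFrame,
    arm_map: pd.DataFrame | None = None,
    lowess_frac: float = LOWESS_FRAC,
) -> DepthFeatures:
    """Depth features from per-5 Mb short (100-150) and long (151-220) counts.

    ``bins`` needs columns chrom, start, end, gc, short, long. Each size
    class is LOESS GC-corrected separately; their sum (100-220 bp) is
    z-transformed within the sample. Arm shares are computed from the
    pre-z corrected depth, averaged per arm and normalized to sum 1.
    """
    out = bins.copy().reset_index(drop=True)
    gc = out["gc"].to_numpy()
    s_corr = _lowess_correct(out["short"].to_numpy(dtype=float), gc, frac=lowess_frac)
    l_corr = _lowess_correct(out["long"].to_numpy(dtype=float), gc, frac=lowess_frac)
    depth = s_corr + l_corr

    def ztrans(v: np.ndarray) -> np.ndarray:
        sd = v.std(ddof=0)
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    out["depth_corrected"] = depth
    out["depth_z"] = ztrans(depth)
    out["short_z"] = ztrans(s_corr)

    mids = (out["start"] + out["end"]) // 2
    arms = pd.Series("unassigned", index=out.index, dtype=object)
    if arm_map is not None:
        for row in arm_map.itertuples(index=False):
            sel = (out["chrom"] == row.chrom) & (mids >= row.start) & (mids < row.end)
            arms[sel] = row.arm
    out["arm"] = arms
    per_arm = out[out["arm"] != "unassigned"].groupby("arm")["depth_corrected"].mean()
    if len(per_arm) == 0:
        per_arm = pd.Series(dtype=float)
        share = per_arm
    else:
        share = per_arm / per_arm.sum()
    return DepthFeatures(bins=out, arm_share=share)
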