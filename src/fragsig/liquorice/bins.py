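"""Region binning and CNA normalization.

Each region-of-interest is split into five core bins covering 10, 15, 50,
15, and 10 % of the region length (largest-remainder rounding for lengths
not divisible by the fractions), and the 20 kb on each side into 500 bp
flank bins. Bin positions are tracked as center offsets from the region
midpoint so that profiles from regions of different lengths align by
ordinal bin position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..io_formats import CopyRatioTable, RegionSet

logger = logging.getLogger(__name__)

CORE_FRACTIONS = (0.10, 0.15, 0.50, 0.15, 0.10)
DEFAULT_FLANK = 20_000
DEFAULT_FLANK_BIN = 500


def _largest_remainder_split(total: int, fractions: tuple[float, ...]) -> np.ndarray:
    """Integer widths summing exactly to ``total``, proportional to fractions."""
    raw = np.asarray(fractions) * total
    widths = np.floor(raw).astype(int)
    remainder = total - widths.sum()
    order = np.argsort(-(raw - widths), kind="stable")
    widths[order[:remainder]] += 1
    return widths


@dataclass
class BinnedRegion:
    """One region split into core + flank bins.

    ``bins`` columns: start, end, is_core, ordinal (0-based left to right),
    center_offset (bp of the bin center relative to the region midpoint).
    """

    region_id: int
    chrom: str
    start: int
    end: int
    bins: pd.DataFrame

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def n_bins(self) -> int:
        return len(self.bins)


def make_bins(
    chrom: str,
    start: int,
    end: int,
    region_id: int = 0,
    flank: int = DEFAULT_FLANK,
    core_fractions: tuple[float, ...] = CORE_FRACTIONS,
    flank_bin: int = DEFAULT_FLANK_BIN,
) -> BinnedRegion:
    """Split one region into core and flank bins.

    Core widths follow largest-remainder rounding of the fractional split
    and sum exactly to the region length; each side gets flank/flank_bin
    bins of ``flank_bin`` bp.
    """
    length = end - start
    if length < len(core_fractions) * 4:
        raise ValueError(f"region too short to split: {length} bp")
    if abs(sum(core_fractions) - 1.0) > 1e-9:
        raise ValueError("core fractions must sum to 1")
    core_widths = _largest_remainder_split(length, core_fractions)
    n_flank = flank // flank_bin

    starts, ends, is_core = [], [], []
    pos = start - n_flank * flank_bin
    for _ in range(n_flank):
        starts.append(pos); ends.append(pos + flank_bin); is_core.append(False)
        pos += flank_bin
    for w in core_widths:
        starts.append(pos); ends.append(pos + int(w)); is_core.append(True)
        pos += int(w)
    for _ in range(n_flank):
        starts.append(pos); ends.append(pos + flank_bin); is_core.append(False)
        pos += flank_bin

    bins = pd.DataFrame(
        {
            "start": np.array(starts, dtype=np.int64),
            "end": np.array(ends, dtype=np.int64),
            "is_core": np.array(is_core),
        }
    )
    bins["ordinal"] = np.arange(len(bins))
    mid = (start + end) // 2
    bins["center_offset"] = (bins["start"] + bins["end"]) / 2.0 - mid
    return BinnedRegion(region_id=region_id, chrom=chrom, start=start, end=end, bins=bins)


def bin_regions(
    regions: RegionSet,
    chrom_sizes: dict[str, int],
    flank: int = DEFAULT_FLANK,
    core_fractions: tuple[float, ...] = CORE_FRACTIONS,
    flank_bin: int = DEFAULT_FLANK_BIN,
) -> list[BinnedRegion]:
    """Bin every region; regions whose flanks cross a chromosome edge are
    dropped with a logged count."""
    out = []
    n_skipped = 0
    for i, row in enumerate(regions.intervals.itertuples(index=False)):
        size = chrom_sizes.get(row.chrom)
        if size is None or row.start - flank < 0 or row.end + flank > size:
            n_skipped += 1
            continue
        out.append(
            make_bins(row.chrom, row.start, row.end, region_id=i, flank=flank,
                      core_fractions=core_fractions, flank_bin=flank_bin)
        )
    if n_skipped:
        logger.warning("dropped %d regions too close to a chromosome edge", n_skipped)
    return out


def cna_normalize(
    bin_coverages: np.ndarray,
    binned: BinnedRegion,
    copy_ratios: CopyRatioTable | None,
) -> np.ndarray:
    """Divide each bin's coverage by its copy-ratio window value.

    Bins whose midpoint falls in a missing, filtered, or non-positive
    window become NaN and are excluded downstream.
    """
    values = np.asarray(bin_coverages, dtype=float).copy()
    if copy_ratios is None:
        return values
    mids = ((binned.bins["start"] + binned.bins["end"]) // 2).to_numpy()
    cw = copy_ratios.windows
    sub = cw[cw["chrom"] == binned.chrom]
    if len(sub) == 0:
        logger.warning("region %s: no copy-ratio windows on %s", binned.region_id, binned.chrom)
        return np.full_like(values, np.nan)
    win_starts = sub["start"].to_numpy()
    idx = np.searchsorted(win_starts, mids, side="right") - 1
    ratio = np.full(len(mids), np.nan)
    ok = idx >= 0
    in_win = np.zeros(len(mids), dtype=bool)
    in_win[ok] = mids[ok] < sub["end"].to_numpy()[idx[ok]]
    ratio[in_win] = sub["copy_ratio"].to_numpy()[idx[in_win]]
    state = np.full(len(mids), "missing", dtype=object)
    state[in_win] = sub["state"].to_numpy()[idx[in_win]]
    bad = (~in_win) | (ratio <= 0) | (state == "filtered")
    if bad.any():
        logger.warning("region %s: %d bins excluded by CNA normalization",
                       binned.region_id, int(bad.sum()))
    values[bad] = np.nan
    values[~bad] = values[~bad] / ratio[~bad]
    return values
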