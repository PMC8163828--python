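"""Coverage engine: fragment streams -> coverage tracks, length histograms, binned counts.

Conventions (all exposed as parameters):

* fragments with mapping quality below 20 are not counted in coverage;
* coverage is fragment-wide (every base under the fragment counts once) and
  is normalized so the genome-wide mean is 1;
* the fragment-length histogram support defaults to 20-800 bp;
* a fragment belongs to the bin containing its midpoint (midpoint rule,
  avoids double counting at bin boundaries);
* in-silico size selection keeps fragments with length in the closed
  interval [low, high], default 90-150 bp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .io_formats import SignalTrack

logger = logging.getLogger(__name__)

DEFAULT_SUPPORT = (20, 800)
DEFAULT_MAPQ_MIN = 20
SIZE_SELECT_RANGE = (90, 150)
SHORT_RANGE = (100, 150)
LONG_RANGE = (151, 220)


@dataclass
class FragmentLengthDistribution:
    """Normalized histogram of fragment lengths over a bounded support."""

    lengths: np.ndarray  # contiguous integer lengths
    probs: np.ndarray    # probabilities, sum to 1
    n_dropped: int = 0   # fragments outside the support

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=np.int64)
        self.probs = np.asarray(self.probs, dtype=float)
        if np.any(self.probs < 0):
            raise ValueError("negative probabilities")
        total = self.probs.sum()
        if total <= 0:
            raise ValueError("empty fragment length distribution")
        self.probs = self.probs / total

    @property
    def support(self) -> tuple[int, int]:
        return int(self.lengths[0]), int(self.lengths[-1])

    @property
    def mode(self) -> int:
        return int(self.lengths[np.argmax(self.probs)])

    @property
    def mean(self) -> float:
        return float(np.sum(self.lengths * self.probs))

    def prob(self, length: int) -> float:
        lo, hi = self.support
        if length < lo or length > hi:
            return 0.0
        return float(self.probs[length - lo])

    def range_mass(self, low: int, high: int) -> float:
        """P(low <= length <= high), closed interval."""
        mask = (self.lengths >= low) & (self.lengths <= high)
        return float(self.probs[mask].sum())

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.choice(self.lengths, size=n, replace=True, p=self.probs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"length": self.lengths, "probability": self.probs})

    @classmethod
    def point_mass(cls, length: int) -> "FragmentLengthDistribution":
        return cls(lengths=np.array([length]), probs=np.array([1.0]))


def fragment_length_distribution(
    fragments: pd.DataFrame,
    support: tuple[int, int] = DEFAULT_SUPPORT,
) -> FragmentLengthDistribution:
    """Normalized length histogram; lengths outside the support are dropped
    and counted in ``n_dropped``."""
    lengths = (fragments["end"] - fragments["start"]).to_numpy()
    if len(lengths) == 0:
        raise ValueError("no fragments")
    lo, hi = support
    in_support = (lengths >= lo) & (lengths <= hi)
    n_dropped = int((~in_support).sum())
    kept = lengths[in_support]
    if len(kept) == 0:
        raise ValueError("no fragments within histogram support")
    counts = np.bincount(kept - lo, minlength=hi - lo + 1)
    return FragmentLengthDistribution(
        lengths=np.arange(lo, hi + 1), probs=counts.astype(float), n_dropped=n_dropped
    )


def size_select(
    fragments: pd.DataFrame,
    low: int = SIZE_SELECT_RANGE[0],
    high: int = SIZE_SELECT_RANGE[1],
) -> pd.DataFrame:
    """In-silico size selection: keep fragments with low <= length <= high."""
    if low > high:
        raise ValueError("low must be <= high")
    lengths = fragments["end"] - fragments["start"]
    return fragments[(lengths >= low) & (lengths <= high)].reset_index(drop=True)


class CoverageTrack:
    """Per-base fragment coverage, normalized to genome-wide mean 1.

    Stores dense per-chromosome arrays plus their cumulative sums so that
    per-bin mean coverage is an O(1) query.
    """

    def __init__(self, data: Mapping[str, np.ndarray]):
        self.data = {c: np.asarray(a, dtype=float) for c, a in data.items()}
        total = sum(a.sum() for a in self.data.values())
        n = sum(len(a) for a in self.data.values())
        if n == 0 or total <= 0:
            raise ValueError("empty coverage track")
        scale = n / total
        self.data = {c: a * scale for c, a in self.data.items()}
        self._cum = {c: np.concatenate([[0.0], np.cumsum(a)]) for c, a in self.data.items()}

    @property
    def genome_mean(self) -> float:
        total = sum(a.sum() for a in self.data.values())
        return total / sum(len(a) for a in self.data.values())

    def mean(self, chrom: str, start: int, end: int) -> float:
        """Mean coverage over [start, end)."""
        cum = self._cum[chrom]
        start = max(start, 0)
        end = min(end, len(cum) - 1)
        if end <= start:
            raise ValueError("empty interval")
        return float((cum[end] - cum[start]) / (end - start))

    def bin_means(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        cum = self._cum[chrom]
        starts = np.clip(starts, 0, len(cum) - 1)
        ends = np.clip(ends, 0, len(cum) - 1)
        widths = ends - starts
        if np.any(widths <= 0):
            raise ValueError("empty bin")
        return (cum[ends] - cum[starts]) / widths

    def to_signal_track(self) -> SignalTrack:
        return SignalTrack.from_dense(self.data)


def build_coverage_track(
    fragments: pd.DataFrame,
    genome_sizes: Mapping[str, int],
    mapq_min: int = DEFAULT_MAPQ_MIN,
) -> CoverageTrack:
    """Fragment-wide coverage of mapq >= ``mapq_min`` fragments, scaled to
    genome-wide mean 1."""
    kept = fragments[fragments["mapq"] >= mapq_min]
    if len(kept) == 0:
        raise ValueError("no fragments pass the mapping-quality filter")
    data = {}
    for chrom, size in genome_sizes.items():
        sub = kept[kept["chrom"] == chrom]
        if len(sub):
            starts = np.clip(sub["start"].to_numpy(), 0, size)
            ends = np.clip(sub["end"].to_numpy(), 0, size)
            diff = (
                np.bincount(starts, minlength=size + 1)
                - np.bincount(ends, minlength=size + 1)
            ).astype(float)
        else:
            diff = np.zeros(size + 1)
        data[chrom] = np.cumsum(diff[:-1])
    return CoverageTrack(data)


def bin_counts(
    fragments: pd.DataFrame,
    genome_sizes: Mapping[str, int],
    bin_size: int,
    length_range: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Per-bin fragment counts on a genome tiling.

    A fragment is assigned to the single bin containing its midpoint.
    ``length_range`` restricts counting to fragments whose length lies in
    the closed interval.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    sub = fragments
    if length_range is not None:
        lengths = sub["end"] - sub["start"]
        sub = sub[(lengths >= length_range[0]) & (lengths <= length_range[1])]
    out = []
    for chrom, size in genome_sizes.items():
        n_bins = int(np.ceil(size / bin_size))
        frag = sub[sub["chrom"] == chrom]
        mids = ((frag["start"] + frag["end"]) // 2).to_numpy()
        idx = np.clip(mids // bin_size, 0, n_bins - 1)
        counts = np.bincount(idx, minlength=n_bins)
        starts = np.arange(n_bins) * bin_size
        out.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": np.minimum(starts + bin_size, size),
                    "count": counts,
                }
            )
        )
    return pd.concat(out, ignore_index=True)
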