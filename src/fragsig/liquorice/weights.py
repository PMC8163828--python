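"""Coverage and endpoint weight vectors derived from a fragment-length distribution.

The coverage weight vector quantifies how much each genomic position
relative to a bin influences the bin's expected fragment coverage. It is
built by sliding fragments of lengths drawn from the sample's
fragment-length distribution (FLD) over a generic bin: for every fragment
length L and every start position p in [-L, bin_size + L), the fragment's
influence is the fraction of bin bases it overlaps, and that influence is
added to the weight of every position the fragment covers. For a given FLD
the vector is universal: it does not depend on genomic content, so it is
computed once per (sample, bin size) and reused.

The endpoint variants assign the same influence only to the fragment start
(forward) or end (reverse) position; they weight the mappability factors.

Two modes are provided: ``sample`` draws ``n_draws`` lengths with
replacement from the FLD (seeded), and ``expectation`` weights every length
by its probability times ``n_draws`` — the deterministic limit, used for
exact tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..coverage import FragmentLengthDistribution

DEFAULT_N_DRAWS = 200


@dataclass
class WeightVector:
    """Non-negative weights over integer offsets relative to the bin start."""

    offset0: int          # offset of weights[0]
    weights: np.ndarray
    bin_size: int

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("negative weights")

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(self.offset0, self.offset0 + len(self.weights))

    @property
    def total(self) -> float:
        return float(self.weights.sum())

    def __len__(self) -> int:
        return len(self.weights)

    def __getitem__(self, offset: int) -> float:
        i = offset - self.offset0
        if 0 <= i < len(self.weights):
            return float(self.weights[i])
        return 0.0


def _length_weights(
    fld: FragmentLengthDistribution,
    n_draws: int,
    seed: int | np.random.SeedSequence | None,
    mode: str,
) -> dict[int, float]:
    if mode == "expectation":
        return {
            int(l): float(p) * n_draws
            for l, p in zip(fld.lengths, fld.probs)
            if p > 0
        }
    if mode != "sample":
        raise ValueError("mode must be 'sample' or 'expectation'")
    rng = np.random.default_rng(seed)
    draws = fld.sample(n_draws, rng)
    lengths, counts = np.unique(draws, return_counts=True)
    return {int(l): float(c) for l, c in zip(lengths, counts)}


def _domain(fld: FragmentLengthDistribution, bin_size: int) -> tuple[int, int]:
    lmax = int(fld.lengths[fld.probs > 0].max())
    # offsets -Lmax .. bin_size + Lmax (inclusive) cover every position a
    # fragment (or its endpoint) can touch
    return -lmax, bin_size + lmax


def _influence(p: np.ndarray, length: int, bin_size: int) -> np.ndarray:
    """Fraction of bin bases overlapped by a fragment [p, p+L)."""
    overlap = np.minimum(p + length, bin_size) - np.maximum(p, 0)
    return np.clip(overlap, 0, None) / bin_size


def coverage_weight_vector(
    fld: FragmentLengthDistribution,
    bin_size: int,
    n_draws: int = DEFAULT_N_DRAWS,
    seed: int | np.random.SeedSequence | None = None,
    mode: str = "sample",
) -> WeightVector:
    """Per-offset influence on the bin's mean coverage.

    For each drawn length L and each start p in [-L, bin_size + L), the
    influence |[p, p+L) ∩ [0, bin_size)| / bin_size is added to every
    offset in [p, p+L).
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    lw = _length_weights(fld, n_draws, seed, mode)
    off0, off_end = _domain(fld, bin_size)
    weights = np.zeros(off_end - off0 + 1)
    for length, w in lw.items():
        p = np.arange(-length, bin_size + length)
        infl = _influence(p, length, bin_size) * w
        # each start position spreads its influence over the L offsets it
        # covers; summing over starts is a convolution with a length-L boxcar
        spread = np.convolve(infl, np.ones(length))
        # spread[j] corresponds to offset p0 + j with p0 = -length; entries
        # beyond the domain stem from zero-influence starts and are zero
        i0 = -length - off0
        spread = spread[: len(weights) - i0]
        weights[i0 : i0 + len(spread)] += spread
    return WeightVector(offset0=off0, weights=weights, bin_size=bin_size)


def endpoint_weight_vectors(
    fld: FragmentLengthDistribution,
    bin_size: int,
    n_draws: int = DEFAULT_N_DRAWS,
    seed: int | np.random.SeedSequence | None = None,
    mode: str = "sample",
) -> tuple[WeightVector, WeightVector]:
    """(forward, reverse) endpoint weight vectors.

    The forward vector puts each fragment's influence on its start offset
    p; the reverse vector puts it on the end offset p + L. The two are
    mirror images and carry equal total mass.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    lw = _length_weights(fld, n_draws, seed, mode)
    off0, off_end = _domain(fld, bin_size)
    fwd = np.zeros(off_end - off0 + 1)
    rev = np.zeros(off_end - off0 + 1)
    for length, w in lw.items():
        p = np.arange(-length, bin_size + length)
        infl = _influence(p, length, bin_size) * w
        nz = infl > 0
        np.add.at(fwd, p[nz] - off0, infl[nz])
        np.add.at(rev, p[nz] + length - off0, infl[nz])
    return (
        WeightVector(offset0=off0, weights=fwd, bin_size=bin_size),
        WeightVector(offset0=off0, weights=rev, bin_size=bin_size),
    )
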