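"""Sequence and mappability bias factors, and the random-forest bias model.

Each bin gets 46 predictors of technical coverage variation, all in [0, 1]:

* 1 GC factor: per-position GC weight (A/T = 0, G/C = 1, N = 0.461, the
  genome-wide mean GC content) averaged under the coverage weight vector;
* 10 dinucleotide and 32 trinucleotide factors (reverse complements share
  a factor): occupancy of the k-mer starting at each position, averaged
  under the coverage weight vector;
* 3 mappability factors: forward mappability (of a read starting at p)
  under the forward endpoint vector, reverse mappability (forward
  mappability of p - read_length) under the reverse endpoint vector, and
  the per-position maximum of the two under the mean endpoint vector.

A 50-tree random forest regression (coverage ~ 46 factors) is trained on
the flank bins only — the five core bins are excluded so the model cannot
absorb the biological signal — and its predictions are subtracted from the
observed coverage of every bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from ..coverage import FragmentLengthDistribution
from ..io_formats import SignalTrack
from .bins import BinnedRegion
from .weights import WeightVector, coverage_weight_vector, endpoint_weight_vectors

N_GC_WEIGHT = 0.461  # genome-wide mean GC content, used for N bases
READ_LENGTH = 75     # mappability track read length

_CODE = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i
    _CODE[ord(chr(b).lower())] = i

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def encode_sequence(seq: str) -> np.ndarray:
    """A=0, C=1, G=2, T=3, anything else 4."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def gc_weight_array(codes: np.ndarray) -> np.ndarray:
    out = np.zeros(len(codes))
    out[(codes == 1) | (codes == 2)] = 1.0
    out[codes == 4] = N_GC_WEIGHT
    return out


def _revcomp(kmer: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(kmer))


@lru_cache(maxsize=None)
def kmer_classes(k: int) -> tuple[tuple[str, ...], np.ndarray]:
    """Reverse-complement k-mer classes.

    Returns (class names like ``"AC/GT"``, array mapping the base-4 k-mer
    code to its class index). 10 classes for k=2, 32 for k=3.
    """
    kmers = [""]
    for _ in range(k):
        kmers = [p + b for p in kmers for b in "ACGT"]
    canon: dict[str, int] = {}
    names: list[str] = []
    code_to_class = np.zeros(4 ** k, dtype=np.int64)
    for code, kmer in enumerate(kmers):
        rc = _revcomp(kmer)
        key = min(kmer, rc)
        if key not in canon:
            canon[key] = len(names)
            names.append(key if kmer == rc else f"{key}/{_revcomp(key)}")
        code_to_class[code] = canon[key]
    return tuple(names), code_to_class


def kmer_class_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Per-position class index of the k-mer starting there.

    Positions whose k-mer runs off the array or contains a non-ACGT base
    get the sentinel value ``n_classes``.
    """
    names, code_to_class = kmer_classes(k)
    n_classes = len(names)
    n = len(codes)
    kcode = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        shifted = np.full(n, 4, dtype=np.uint8)
        shifted[: n - j] = codes[j:]
        valid &= shifted < 4
        kcode = kcode * 4 + np.minimum(shifted, 3)
    out = np.full(n, n_classes, dtype=np.int64)
    out[valid] = code_to_class[kcode[valid]]
    return out


def gc_bias_factor(seq_window: str | np.ndarray, cwv: WeightVector) -> float:
    """GC weight of the window averaged under the coverage weight vector."""
    if isinstance(seq_window, str):
        seq_window = gc_weight_array(encode_sequence(seq_window))
    if len(seq_window) != len(cwv):
        raise ValueError(
            f"sequence window length {len(seq_window)} != weight vector domain {len(cwv)}"
        )
    return float(np.dot(seq_window, cwv.weights) / cwv.total)


def kmer_bias_factors(seq_window: str, cwv: WeightVector, k: int) -> dict[str, float]:
    """Weighted occupancy of each reverse-complement k-mer class."""
    codes = encode_sequence(seq_window)
    if len(codes) != len(cwv):
        raise ValueError(
            f"sequence window length {len(codes)} != weight vector domain {len(cwv)}"
        )
    names, _ = kmer_classes(k)
    cls = kmer_class_codes(codes, k)
    sums = np.bincount(cls, weights=cwv.weights, minlength=len(names) + 1)[: len(names)]
    return {name: float(s / cwv.total) for name, s in zip(names, sums)}


def mappability_bias_factors(
    map_window: np.ndarray,
    fwd: WeightVector,
    rev: WeightVector,
    read_length: int = READ_LENGTH,
) -> tuple[float, float, float]:
    """(forward, reverse, max) mappability factors for one bin.

    ``map_window`` must hold per-base forward mappability over offsets
    ``fwd.offset0 - read_length`` .. ``fwd.offset0 + len(fwd) - 1``, i.e.
    ``len(fwd) + read_length`` values. Reverse mappability at p is the
    forward mappability of p - read_length; the max factor weights the
    per-position maximum by the mean of the two endpoint vectors.
    """
    n = len(fwd)
    map_window = np.asarray(map_window, dtype=float)
    if len(map_window) != n + read_length:
        raise ValueError("map window must cover the weight domain plus read_length upstream")
    m_fwd = map_window[read_length:]
    m_rev = map_window[:n]
    f = float(np.dot(m_fwd, fwd.weights) / fwd.total)
    r = float(np.dot(m_rev, rev.weights) / rev.total)
    mean_w = (fwd.weights + rev.weights) / 2.0
    mx = float(np.dot(np.maximum(m_fwd, m_rev), mean_w) / mean_w.sum())
    return f, r, mx


@dataclass
class ReferenceArrays:
    """Genome-level arrays reused across samples: padded GC weights,
    di-/trinucleotide class codes, and dense mappability per chromosome."""

    pad: int
    arrays: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]


def prepare_reference(
    sequences: Mapping[str, str],
    mappability: SignalTrack,
    pad: int = 800 + READ_LENGTH + 1,
) -> ReferenceArrays:
    """Precompute the per-chromosome arrays consumed by
    :func:`compute_bias_features`; ``pad`` must cover the largest fragment
    length plus the mappability read length."""
    arrays = {}
    for chrom, seq in sequences.items():
        codes = encode_sequence(seq)
        padded = np.concatenate([np.full(pad, 4, np.uint8), codes, np.full(pad, 4, np.uint8)])
        arrays[chrom] = (
            gc_weight_array(padded),
            kmer_class_codes(padded, 2),
            kmer_class_codes(padded, 3),
            np.concatenate(
                [
                    np.full(pad, mappability.fill),
                    mappability.dense(chrom, len(codes)),
                    np.full(pad, mappability.fill),
                ]
            ),
        )
    return ReferenceArrays(pad=pad, arrays=arrays)


DI_NAMES = tuple(f"di_{n}" for n in kmer_classes(2)[0])
TRI_NAMES = tuple(f"tri_{n}" for n in kmer_classes(3)[0])
FACTOR_COLUMNS = ("gc",) + DI_NAMES + TRI_NAMES + ("map_fwd", "map_rev", "map_max")


def compute_bias_features(
    sequences: Mapping[str, str],
    mappability: SignalTrack,
    binned_regions: list[BinnedRegion],
    fld: FragmentLengthDistribution,
    n_draws: int = 200,
    seed: int | np.random.SeedSequence | None = None,
    mode: str = "sample",
    read_length: int = READ_LENGTH,
    reference: ReferenceArrays | None = None,
) -> pd.DataFrame:
    """Per-bin table of all 46 bias factors for a set of binned regions.

    Weight vectors are derived from the sample's fragment-length
    distribution once per distinct bin width and cached. Positions outside
    the chromosome sequence are treated as N. Pass a precomputed
    ``reference`` (from :func:`prepare_reference`) to reuse the
    genome-level arrays across samples.
    """
    lmax = int(fld.lengths[fld.probs > 0].max())
    pad = lmax + read_length + 1
    if reference is None:
        reference = prepare_reference(sequences, mappability, pad=pad)
    if reference.pad < pad:
        raise ValueError(f"reference pad {reference.pad} < required {pad}")
    pad = reference.pad

    def chrom_arrays(chrom: str):
        return reference.arrays[chrom]

    vec_cache: dict[int, tuple[WeightVector, WeightVector, WeightVector]] = {}

    def vectors(width: int):
        if width not in vec_cache:
            cwv = coverage_weight_vector(fld, width, n_draws=n_draws, seed=seed, mode=mode)
            fw, rv = endpoint_weight_vectors(fld, width, n_draws=n_draws, seed=seed, mode=mode)
            vec_cache[width] = (cwv, fw, rv)
        return vec_cache[width]

    n_di, n_tri = len(DI_NAMES), len(TRI_NAMES)
    records = []
    factors = []
    for br in binned_regions:
        gcw, di, tri, mp = chrom_arrays(br.chrom)
        for row in br.bins.itertuples(index=False):
            width = int(row.end - row.start)
            cwv, fw, rv = vectors(width)
            n = len(cwv)
            s = int(row.start) + cwv.offset0 + pad
            w = cwv.weights
            wsum = cwv.total
            gc = np.dot(gcw[s : s + n], w) / wsum
            di_f = np.bincount(di[s : s + n], weights=w, minlength=n_di + 1)[:n_di] / wsum
            tri_f = np.bincount(tri[s : s + n], weights=w, minlength=n_tri + 1)[:n_tri] / wsum
            mwin = mp[s - read_length : s + n]
            f, r, mx = mappability_bias_factors(mwin, fw, rv, read_length=read_length)
            records.append(
                (br.region_id, br.chrom, int(row.start), int(row.end),
                 bool(row.is_core), int(row.ordinal), float(row.center_offset))
            )
            factors.append(np.concatenate([[gc], di_f, tri_f, [f, r, mx]]))

    meta = pd.DataFrame(
        records,
        columns=["region_id", "chrom", "start", "end", "is_core", "ordinal", "center_offset"],
    )
    fac = pd.DataFrame(np.array(factors), columns=list(FACTOR_COLUMNS))
    return pd.concat([meta, fac], axis=1)


@dataclass
class BiasModel:
    """Random-forest regression of coverage on the 46 bias factors."""

    model: RandomForestRegressor
    feature_names: tuple[str, ...]
    n_training_rows: int

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        return self.model.predict(features[list(self.feature_names)].to_numpy())

    @property
    def oob_r2(self) -> float:
        return float(self.model.oob_score_)


def train_bias_model(
    features: pd.DataFrame,
    n_trees: int = 50,
    seed: int | None = 0,
    min_rows: int = 100,
) -> BiasModel:
    """Train the bias model on non-core bins with finite coverage.

    The five core bins per region are excluded so a genuine central dip
    cannot be learned away as 'bias'.
    """
    train = features[~features["is_core"] & np.isfinite(features["coverage"])]
    if len(train) < min_rows:
        raise ValueError(f"need >= {min_rows} non-core rows to train, got {len(train)}")
    X = train[list(FACTOR_COLUMNS)].to_numpy()
    y = train["coverage"].to_numpy()
    # per-split feature subsampling at p/3, the regression-forest default
    rf = RandomForestRegressor(
        n_estimators=n_trees, random_state=seed, oob_score=True, n_jobs=1,
        max_features=1.0 / 3.0,
    )
    rf.fit(X, y)
    return BiasModel(model=rf, feature_names=FACTOR_COLUMNS, n_training_rows=len(train))


def correct_coverage(features: pd.DataFrame, model: BiasModel) -> np.ndarray:
    """observed - predicted coverage for every bin (core bins included)."""
    predicted = model.predict(features)
    observed = features["coverage"].to_numpy(dtype=float)
    return observed - predicted
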