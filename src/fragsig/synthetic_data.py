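"""Synthetic genomes, region sets, mappability tracks, and cfDNA cohorts.

The generator emulates the data-generating assumptions behind cfDNA
fragmentomics of solid tumors:

* healthy-derived fragments follow a nucleosome-protected length
  distribution with a mode near 167 bp; tumor-derived fragments are
  shifted toward shorter lengths (mode near 145 bp);
* tumor-derived fragments are depleted at tumor-specific open-chromatin
  regions; the depletion follows a sum of Gaussians centered on region
  midpoints (the same functional family the downstream dip fitter
  assumes), with an optional hard-mask mode for misspecification tests;
* fragment sampling carries a GC bias (logistic acceptance in the
  fragment's GC content) and a mappability bias (acceptance proportional
  to the mappability at the fragment start);
* region-of-interest neighborhoods are GC-rich relative to the genomic
  background, so the GC bias confounds the coverage signal at regions
  unless corrected.

Everything is deterministic given the master seed; per-sample seeds are
derived with :class:`numpy.random.SeedSequence` spawn keys.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.special import expit

from .coverage import FragmentLengthDistribution
from .io_formats import RegionSet, SignalTrack

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# stream-separation keys for seed derivation
_GENOME_KEY = 0x6E0
_SAMPLE_KEY = 0xC047


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic cfDNA cohort.

    Scaled-down analogue of a deep-WGS liquid-biopsy study: a megabase-scale
    genome stands in for the full genome, a few dozen kilobase-scale
    open-chromatin regions stand in for a tumor-specific DHS set, and depth
    matches the ~12x fragment coverage of deep cfDNA sequencing.
    """

    genome_length: int = 2_500_000
    chrom: str = "chrS"
    # GC landscape: smooth background waves + GC enrichment at regions
    gc_mean: float = 0.42
    gc_wave_amplitude: float = 0.05
    gc_wave_periods: tuple[float, ...] = (11_000.0, 37_000.0, 149_000.0)
    gc_region_boost: float = 0.10
    gc_boost_sigma: float = 2_000.0
    # region set
    n_regions: int = 40
    region_width: int = 1_000
    edge_clearance: int = 30_000  # keeps region +- flank inside the genome
    # mappability track
    n_lowmap_patches: int = 30
    lowmap_width: int = 1_500
    lowmap_value: float = 0.4
    # fragment length distributions (discretized skew-normal around the mode)
    healthy_mode: int = 167
    healthy_spread: float = 28.0
    healthy_skew: float = 3.0
    tumor_mode: int = 145
    tumor_spread: float = 32.0
    tumor_skew: float = 3.0
    fld_support: tuple[int, int] = (20, 800)
    # injected tumor dip at regions: amplitude and sigma per Gaussian component
    dip_amplitudes: tuple[float, ...] = (0.25, 0.35, 0.3)
    dip_sigmas: tuple[float, ...] = (150.0, 1_200.0, 6_000.0)
    dip_mode: str = "gaussian"  # or "hard" (flat mask over the region)
    # biases
    gc_bias_strength: float = 8.0  # logistic slope on fragment GC
    mappability_bias: bool = True
    # sampling
    depth: float = 12.0  # mean fragment coverage of the genome
    mapq_high: int = 60
    mapq_low: int = 10
    frac_low_mapq: float = 0.03
    tumor_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ValueError("tumor_fraction must be in [0, 1]")
        if self.region_width <= 0 or self.genome_length <= 0:
            raise ValueError("widths must be > 0")
        if self.dip_mode == "gaussian":
            for s in self.dip_sigmas:
                if not 20.0 <= s <= 40_000.0:
                    raise ValueError("dip sigmas must lie within 20-40000 bp")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("gc_wave_periods", "dip_amplitudes", "dip_sigmas", "fld_support"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def make_fld(
    mode: int,
    spread: float,
    skew: float = 3.0,
    support: tuple[int, int] = (20, 800),
) -> FragmentLengthDistribution:
    """Discretized skew-normal fragment-length distribution with the given mode.

    The skew-normal location is shifted numerically so that the discrete
    mode lands exactly on ``mode``.
    """
    lo, hi = support
    grid = np.arange(lo, hi + 1)
    # mode offset of skewnorm(a, loc=0, scale=spread)
    fine = np.linspace(-3 * spread, 3 * spread, 2001)
    m0 = fine[np.argmax(stats.skewnorm.pdf(fine, skew, loc=0, scale=spread))]
    probs = stats.skewnorm.pdf(grid, skew, loc=mode - m0, scale=spread)
    return FragmentLengthDistribution(lengths=grid, probs=probs)


@dataclass
class SyntheticGenome:
    """A synthetic chromosome with its region set and ancillary tracks."""

    config: SimulationConfig
    sequence: str
    regions: RegionSet
    mappability: SignalTrack
    gc_table: pd.DataFrame  # windowed GC of the realized sequence
    is_gc_cumsum: np.ndarray = field(repr=False, default=None)
    dip_profile: np.ndarray = field(repr=False, default=None)  # per-base thinning of tumor fragments
    mappability_dense: np.ndarray = field(repr=False, default=None)

    @property
    def sizes(self) -> dict[str, int]:
        return {self.config.chrom: len(self.sequence)}

    def fragment_gc(self, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        cs = self.is_gc_cumsum
        return (cs[ends] - cs[starts]) / (ends - starts)


def _gc_landscape(config: SimulationConfig, region_mids: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Smooth per-base target-GC function over the genome."""
    x = np.arange(config.genome_length, dtype=float)
    gc = np.full(config.genome_length, config.gc_mean)
    for period in config.gc_wave_periods:
        phase = rng.uniform(0, 2 * np.pi)
        gc += (config.gc_wave_amplitude / len(config.gc_wave_periods)) * np.sin(
            2 * np.pi * x / period + phase
        )
    # open-chromatin neighborhoods are GC-rich: add a bump at each region
    if config.gc_region_boost != 0.0:
        s = config.gc_boost_sigma
        halo = int(4 * s)
        offs = np.arange(-halo, halo + 1, dtype=float)
        bump = config.gc_region_boost * np.exp(-(offs ** 2) / (2 * s * s))
        for mid in region_mids:
            a, b = mid - halo, mid + halo + 1
            lo, hi = max(a, 0), min(b, config.genome_length)
            gc[lo:hi] += bump[lo - a : bump.size - (b - hi)]
    return np.clip(gc, 0.0, 1.0)


def make_genome(config: SimulationConfig, gc_window: int = 100_000) -> SyntheticGenome:
    """Generate a genome whose windowed GC tracks the configured landscape,
    a non-overlapping region set, and a mappability track.

    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, _GENOME_KEY)))
    L = config.genome_length
    # evenly spaced region midpoints with jitter, clear of the edges
    usable = L - 2 * config.edge_clearance
    if config.n_regions > 0:
        spacing = usable / config.n_regions
        mids = (config.edge_clearance + spacing * (np.arange(config.n_regions) + 0.5)
                + rng.uniform(-0.15, 0.15, config.n_regions) * spacing)
        mids = np.sort(mids.astype(np.int64))
    else:
        mids = np.array([], dtype=np.int64)
    half = config.region_width // 2
    regions = RegionSet(
        name="synthetic_open_chromatin",
        intervals=pd.DataFrame(
            {"chrom": config.chrom, "start": mids - half, "end": mids - half + config.region_width}
        ),
    )

    gc = _gc_landscape(config, mids, rng)
    is_gc = rng.random(L) < gc
    seq_codes = np.where(
        is_gc,
        rng.choice(np.array([1, 2], dtype=np.uint8), size=L),  # C or G
        rng.choice(np.array([0, 3], dtype=np.uint8), size=L),  # A or T
    )
    sequence = _BASES[seq_codes].tobytes().decode("ascii")

    n_win = int(np.ceil(L / gc_window))
    win_starts = np.arange(n_win) * gc_window
    win_ends = np.minimum(win_starts + gc_window, L)
    cs = np.concatenate([[0], np.cumsum(is_gc)])
    gc_table = pd.DataFrame(
        {
            "chrom": config.chrom,
            "start": win_starts,
            "end": win_ends,
            "gc": (cs[win_ends] - cs[win_starts]) / (win_ends - win_starts),
        }
    )

    # mappability: 1.0 with low-mappability patches away from region cores
    mp = np.ones(L)
    placed = 0
    while placed < config.n_lowmap_patches:
        s = int(rng.integers(0, L - config.lowmap_width))
        if config.n_regions and np.min(np.abs(mids - s)) < config.region_width:
            continue
        mp[s : s + config.lowmap_width] = config.lowmap_value
        placed += 1
    mappability = SignalTrack.from_dense({config.chrom: mp})

    dip = _dip_profile(config, mids)
    return SyntheticGenome(
        config=config,
        sequence=sequence,
        regions=regions,
        mappability=mappability,
        gc_table=gc_table,
        is_gc_cumsum=cs,
        dip_profile=dip,
        mappability_dense=mp,
    )


def _dip_profile(config: SimulationConfig, mids: np.ndarray) -> np.ndarray:
    """Per-base tumor-fragment thinning probability (0 = no depletion)."""
    L = config.genome_length
    dip = np.zeros(L)
    if len(mids) == 0:
        return dip
    if config.dip_mode == "hard":
        half = config.region_width // 2
        for mid in mids:
            dip[max(mid - half, 0) : min(mid + half, L)] = sum(config.dip_amplitudes)
    else:
        halo = int(4 * max(config.dip_sigmas))
        offs = np.arange(-halo, halo + 1, dtype=float)
        kernel = np.zeros_like(offs)
        for a, s in zip(config.dip_amplitudes, config.dip_sigmas):
            kernel += a * np.exp(-(offs ** 2) / (2 * s * s))
        for mid in mids:
            a, b = mid - halo, mid + halo + 1
            lo, hi = max(a, 0), min(b, L)
            dip[lo:hi] += kernel[lo - a : kernel.size - (b - hi)]
    if np.any(dip > 1.0):
        raise ValueError("dip amplitudes yield negative sampling probabilities")
    return dip


def simulate_sample(
    genome: SyntheticGenome,
    tumor_fraction: float | None = None,
    seed: int | np.random.SeedSequence | None = None,
    n_fragments: int | None = None,
) -> pd.DataFrame:
    """Draw one cfDNA sample as a healthy/tumor fragment mixture.

    Tumor fragments use the tumor length distribution and are thinned at
    regions-of-interest by the configured dip profile; all fragments pass
    through the logistic GC-bias and mappability acceptance filters.
    Sampling continues until the target fragment count is reached, so the
    output size is independent of the biases.
    """
    config = genome.config
    if tumor_fraction is None:
        tumor_fraction = config.tumor_fraction
    if not 0.0 <= tumor_fraction <= 1.0:
        raise ValueError("tumor_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    healthy = make_fld(config.healthy_mode, config.healthy_spread, config.healthy_skew,
                       config.fld_support)
    tumor = make_fld(config.tumor_mode, config.tumor_spread, config.tumor_skew,
                     config.fld_support)
    L = config.genome_length
    if n_fragments is None:
        n_fragments = int(config.depth * L / healthy.mean)

    out_start = np.empty(n_fragments, dtype=np.int64)
    out_end = np.empty(n_fragments, dtype=np.int64)
    got = 0
    while got < n_fragments:
        batch = max(int((n_fragments - got) * 2.5), 10_000)
        is_tumor = rng.random(batch) < tumor_fraction
        lengths = np.where(
            is_tumor, tumor.sample(batch, rng), healthy.sample(batch, rng)
        ).astype(np.int64)
        starts = rng.integers(0, L - lengths, dtype=np.int64)
        ends = starts + lengths
        accept = np.ones(batch)
        if config.gc_bias_strength != 0.0:
            gc = genome.fragment_gc(starts, ends)
            accept *= expit(config.gc_bias_strength * (gc - config.gc_mean))
        else:
            accept *= 0.5
        if config.mappability_bias:
            accept *= genome.mappability_dense[starts]
        mids = (starts + ends) // 2
        thin = genome.dip_profile[mids]
        accept[is_tumor] *= 1.0 - thin[is_tumor]
        keep = rng.random(batch) < accept
        k = min(int(keep.sum()), n_fragments - got)
        idx = np.flatnonzero(keep)[:k]
        out_start[got : got + k] = starts[idx]
        out_end[got : got + k] = ends[idx]
        got += k

    mapq = np.where(
        rng.random(n_fragments) < config.frac_low_mapq, config.mapq_low, config.mapq_high
    )
    order = np.argsort(out_start, kind="stable")
    return pd.DataFrame(
        {
            "chrom": config.chrom,
            "start": out_start[order],
            "end": out_end[order],
            "mapq": mapq[order],
        }
    )


def sample_seed(master_seed: int, sample_index: int) -> np.random.SeedSequence:
    """Deterministic per-sample seed derived from the master seed."""
    return np.random.SeedSequence((master_seed, _SAMPLE_KEY, sample_index))


def make_cohort(
    genome: SyntheticGenome,
    n_controls: int,
    case_fractions: Sequence[float] = (),
    master_seed: int | None = None,
) -> tuple[list[tuple[str, pd.DataFrame]], pd.DataFrame]:
    """Simulate a cohort of control and case samples on a shared genome.

    Returns (samples, truth) where samples is a list of (sample_id,
    fragment table) and truth records the injected tumor fraction per
    sample. Per-sample seeds derive from the master seed.
    """
    if master_seed is None:
        master_seed = genome.config.seed
    fractions = [0.0] * n_controls + list(case_fractions)
    ids = [f"control_{i:02d}" for i in range(n_controls)] + [
        f"case_{i:02d}" for i in range(len(case_fractions))
    ]
    samples = []
    for i, (sid, tf) in enumerate(zip(ids, fractions)):
        frags = simulate_sample(genome, tumor_fraction=tf, seed=sample_seed(master_seed, i))
        samples.append((sid, frags))
    truth = pd.DataFrame(
        {
            "sample": ids,
            "tumor_fraction": fractions,
            "is_control": [i < n_controls for i in range(len(ids))],
        }
    )
    return samples, truth


def simulate_fusion_spans(
    tumor_fraction: float,
    depth: int,
    seed: int | None = None,
    junction: int = 1_000,
    microhomology: int = 0,
    read_length: int = 100,
) -> pd.DataFrame:
    """Read spans around a heterozygous fusion junction and its two germline loci.

    With tumor fraction t, the fusion allele is present at t/2 of genome
    copies and each germline partner locus at 1 - t/2, so the breakpoint
    tumor-content estimator should recover t up to binomial noise. Returns a
    table with columns ref (fusion / germline_a / germline_b), start, end.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for ref, rate in (
        ("fusion", tumor_fraction / 2),
        ("germline_a", 1 - tumor_fraction / 2),
        ("germline_b", 1 - tumor_fraction / 2),
    ):
        n = rng.poisson(depth * rate)
        starts = rng.integers(junction - read_length + 1, junction + microhomology, size=n)
        for s in starts:
            rows.append((ref, int(s), int(s) + read_length))
    return pd.DataFrame(rows, columns=["ref", "start", "end"])
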