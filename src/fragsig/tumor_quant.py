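"""Genetic tumor-content quantification from fusion breakpoints.

Given a known rearrangement junction, fragments re-mapped to the fusion
allele and to the two germline partner loci are counted as supporting an
allele only if a read fully spans the junction, its microhomology window,
and at least one clearly distinguishing base on each side. For a
heterozygous fusion, tumor content follows

    t = 2 f / (((g1 + g2) / 2) + f)

where f is the fusion-supporting fragment count and g1, g2 the
germline-spanning counts at the two partner loci (averaged to damp local
coverage and sequence-composition fluctuations). Multiple breakpoints
(main, reciprocal, complex) are averaged; the result is clamped to [0, 1]
after averaging, since sampling noise can push the raw formula above 1.

A consensus over independent genetic evidence sources (read-depth/CNA,
WGS fusion counting, ddPCR) is the mean of the available estimates, with
any positive fusion evidence forcing a nonzero consensus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EVENT_CLASSES = ("main", "reciprocal", "complex")


@dataclass
class Breakpoint:
    """A rearrangement junction between two partner loci."""

    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int
    microhomology: int = 0
    event_class: str = "main"

    def __post_init__(self) -> None:
        if self.pos_a < 0 or self.pos_b < 0:
            raise ValueError("positions must be >= 0")
        if self.microhomology < 0:
            raise ValueError("microhomology must be >= 0")
        if self.event_class not in EVENT_CLASSES:
            raise ValueError(f"event class must be one of {EVENT_CLASSES}")


@dataclass
class FusionQuant:
    """Support counts and the derived tumor-content fraction."""

    f: int
    g1: int
    g2: int
    tumor_content: float


def read_spans_breakpoint(starts: np.ndarray, ends: np.ndarray, junction: int,
                          microhomology: int = 0) -> np.ndarray:
    """True where a read span [start, end) covers the junction, the
    microhomology window, and >=1 distinguishing base on each side.

    With the junction at j and microhomology m, a read must cover base
    j - 1 (left of the junction) through base j + m (first base past the
    ambiguous window): start <= j - 1 and end >= j + m + 1.
    """
    starts = np.asarray(starts)
    ends = np.asarray(ends)
    return (starts <= junction - 1) & (ends >= junction + microhomology + 1)


def count_breakpoint_support(
    spans: pd.DataFrame,
    breakpoint: Breakpoint,
    junctions: dict[str, int] | None = None,
) -> tuple[int, int, int]:
    """(f, g1, g2): spanning-fragment counts at the fusion and the two
    germline partner loci.

    ``spans`` has columns ref (fusion / germline_a / germline_b), start,
    end — read spans in the coordinates of the re-mapped allele
    references. ``junctions`` gives the junction position per reference;
    by default the germline junctions sit at the breakpoint coordinates
    and the fusion reference keeps partner A's coordinates up to the
    junction, so its junction is pos_a.
    """
    if junctions is None:
        junctions = {
            "fusion": breakpoint.pos_a,
            "germline_a": breakpoint.pos_a,
            "germline_b": breakpoint.pos_b,
        }
    counts = {}
    for ref in ("fusion", "germline_a", "germline_b"):
        sub = spans[spans["ref"] == ref]
        counts[ref] = int(
            read_spans_breakpoint(
                sub["start"].to_numpy(), sub["end"].to_numpy(),
                junctions[ref], breakpoint.microhomology,
            ).sum()
        ) if len(sub) else 0
    return counts["fusion"], counts["germline_a"], counts["germline_b"]


def fusion_tumor_content(f: int, g1: int, g2: int) -> float:
    """2f / (((g1+g2)/2) + f), clamped to [0, 1]."""
    if f < 0 or g1 < 0 or g2 < 0:
        raise ValueError("counts must be >= 0")
    denom = (g1 + g2) / 2.0 + f
    if denom == 0:
        raise ValueError("tumor content undefined: all counts are zero")
    raw = 2.0 * f / denom
    if raw > 1.0:
        logger.warning("raw tumor content %.3f > 1; clamped", raw)
    return float(np.clip(raw, 0.0, 1.0))


def fusion_tumor_content_multi(counts: list[tuple[int, int, int]]) -> float:
    """Mean over breakpoints, clamped to [0, 1] after averaging."""
    if not counts:
        raise ValueError("no breakpoints")
    raw = []
    for f, g1, g2 in counts:
        denom = (g1 + g2) / 2.0 + f
        if denom == 0:
            raise ValueError("tumor content undefined: all counts are zero")
        raw.append(2.0 * f / denom)
    return float(np.clip(np.mean(raw), 0.0, 1.0))


def combined_genetic_estimate(
    ichor_fraction: float | None = None,
    wgs_fusion_fraction: float | None = None,
    ddpcr_fraction: float | None = None,
) -> tuple[float, list[str]]:
    """Consensus tumor content over the available genetic evidence.

    Mean of the available estimates; any positive fusion evidence (WGS or
    ddPCR) forces a nonzero consensus (the mean of the positive fusion
    estimates when the plain mean would be zero). Returns (estimate,
    contributing sources).
    """
    inputs = {
        "ichorCNA": ichor_fraction,
        "wgs_fusion": wgs_fusion_fraction,
        "ddpcr": ddpcr_fraction,
    }
    available = {k: v for k, v in inputs.items() if v is not None}
    if not available:
        raise ValueError("no genetic evidence provided")
    for k, v in available.items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{k} estimate outside [0, 1]: {v}")
    estimate = float(np.mean(list(available.values())))
    fusion_positive = [
        v for k, v in available.items() if k in ("wgs_fusion", "ddpcr") and v > 0
    ]
    if estimate == 0.0 and fusion_positive:
        estimate = float(np.mean(fusion_positive))
    return estimate, sorted(available)


def read_breakpoints(path: str | Path) -> list[Breakpoint]:
    """Breakpoint TSV: chrom_a, pos_a, chrom_b, pos_b, microhomology, event_class."""
    df = pd.read_csv(path, sep="\t")
    return [
        Breakpoint(
            chrom_a=row.chrom_a, pos_a=int(row.pos_a),
            chrom_b=row.chrom_b, pos_b=int(row.pos_b),
            microhomology=int(row.microhomology), event_class=str(row.event_class),
        )
        for row in df.itertuples(index=False)
    ]
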