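"""Readers and writers for the external formats the toolkit touches.

One canonical in-memory representation per concept:

* fragments  -> :class:`pandas.DataFrame` with columns ``chrom, start, end, mapq``
  (0-based half-open intervals, one row per sequenced cfDNA fragment)
* region set -> :class:`RegionSet`
* per-base signal (mappability, coverage) -> :class:`SignalTrack`
* per-window copy ratios with CNA state -> :class:`CopyRatioTable`

Coordinates are 0-based half-open everywhere; BED ingestion is pass-through
with no +-1 shifts. Chromosome names are matched by exact string equality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FRAGMENT_COLUMNS = ["chrom", "start", "end", "mapq"]

#: closed label set for per-window copy-number state
CNA_STATES = ("neutral", "gain", "loss", "filtered")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Region sets (BED)
# ---------------------------------------------------------------------------


@dataclass
class RegionSet:
    """A named collection of genomic intervals (0-based half-open).

    Intervals may overlap; no merging is implied.
    """

    name: str
    intervals: pd.DataFrame  # columns chrom, start, end

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.intervals, columns=["chrom", "start", "end"])
        if len(df) and not (df["end"] > df["start"]).all():
            bad = df.index[df["end"] <= df["start"]][0]
            raise FormatError(f"region {bad}: start must be < end")
        self.intervals = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return self.intervals.itertuples(index=False)

    @property
    def midpoints(self) -> np.ndarray:
        return ((self.intervals["start"] + self.intervals["end"]) // 2).to_numpy()


def read_regions(path: str | Path, name: str | None = None) -> RegionSet:
    """Read a BED file (>=3 tab-separated columns) into a :class:`RegionSet`.

    Extra columns are ignored. Malformed lines raise :class:`FormatError`
    naming the offending line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start must be < end ({start} >= {end})")
            if start < 0:
                raise FormatError(f"{path}:{lineno}: negative start")
            rows.append((parts[0], start, end))
    return RegionSet(
        name=name or Path(path).stem,
        intervals=pd.DataFrame(rows, columns=["chrom", "start", "end"]),
    )


def write_regions(regions: RegionSet, path: str | Path) -> None:
    regions.intervals.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Fragments (TSV table is canonical; BAM is an adapter over the same stream)
# ---------------------------------------------------------------------------


def read_fragments(path: str | Path, format: str = "auto") -> pd.DataFrame:
    """Read fragments as a DataFrame with columns ``chrom, start, end, mapq``.

    ``format`` is one of ``table`` (TSV with a header line), ``bam``
    (paired-end records collapsed to template intervals; requires pysam),
    or ``auto`` (by file extension). Records with ``end <= start`` are
    rejected and counted in the log; in BAM mode unpaired reads are skipped
    with a logged count.
    """
    path = Path(path)
    if format == "auto":
        format = "bam" if path.suffix in {".bam", ".sam", ".cram"} else "table"
    if format == "table":
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in FRAGMENT_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: fragment table missing columns {missing}")
        df = df[FRAGMENT_COLUMNS]
    elif format == "bam":
        df = _read_fragments_bam(path)
    else:
        raise ValueError(f"unknown fragment format: {format!r}")
    bad = df["end"] <= df["start"]
    if bad.any():
        logger.warning("%s: rejected %d fragments with end <= start", path, int(bad.sum()))
        df = df[~bad]
    return df.reset_index(drop=True)


def _read_fragments_bam(path: Path) -> pd.DataFrame:
    import pysam  # optional adapter dependency

    rows = []
    n_unpaired = 0
    mode = "r" if path.suffix == ".sam" else "rb"
    with pysam.AlignmentFile(str(path), mode) as bam:
        for read in bam.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if not read.is_proper_pair:
                n_unpaired += 1
                continue
            # count each template once, from its leftmost mate
            if read.template_length <= 0:
                continue
            rows.append(
                (
                    read.reference_name,
                    read.reference_start,
                    read.reference_start + read.template_length,
                    read.mapping_quality,
                )
            )
    if n_unpaired:
        logger.warning("%s: skipped %d unpaired reads", path, n_unpaired)
    return pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)


def write_fragments(fragments: pd.DataFrame, path: str | Path) -> None:
    fragments[FRAGMENT_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Signal tracks (bedGraph / fixed-step wiggle)
# ---------------------------------------------------------------------------


@dataclass
class SignalTrack:
    """Per-chromosome runs of (start, end, value); non-overlapping, sorted.

    Positions not covered by any run take a configurable fill value
    (default 0) when queried.
    """

    runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(default_factory=dict)
    fill: float = 0.0

    @classmethod
    def from_runs(
        cls,
        runs: Mapping[str, Iterable[tuple[int, int, float]]],
        fill: float = 0.0,
    ) -> "SignalTrack":
        out: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, items in runs.items():
            arr = sorted(items)
            starts = np.array([r[0] for r in arr], dtype=np.int64)
            ends = np.array([r[1] for r in arr], dtype=np.int64)
            values = np.array([r[2] for r in arr], dtype=float)
            if np.any(ends <= starts):
                raise FormatError(f"{chrom}: run with end <= start")
            if np.any(starts[1:] < ends[:-1]):
                raise FormatError(f"{chrom}: overlapping runs")
            if not np.all(np.isfinite(values)):
                raise FormatError(f"{chrom}: non-finite values")
            out[chrom] = (starts, ends, values)
        return cls(runs=out, fill=fill)

    @classmethod
    def from_dense(cls, arrays: Mapping[str, np.ndarray], fill: float = 0.0) -> "SignalTrack":
        """Run-length encode dense per-base arrays."""
        runs: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, arr in arrays.items():
            arr = np.asarray(arr, dtype=float)
            if len(arr) == 0:
                runs[chrom] = []
                continue
            change = np.flatnonzero(np.diff(arr) != 0) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(arr)]])
            runs[chrom] = [(int(s), int(e), float(arr[s])) for s, e in zip(starts, ends)]
        return cls.from_runs(runs, fill=fill)

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base values over [start, end); uncovered positions = fill."""
        if end <= start:
            raise ValueError("end must be > start")
        out = np.full(end - start, self.fill, dtype=float)
        if chrom not in self.runs:
            return out
        starts, ends, values = self.runs[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        for i in range(lo, hi):
            a = max(int(starts[i]), start) - start
            b = min(int(ends[i]), end) - start
            if b > a:
                out[a:b] = values[i]
        return out

    def mean(self, chrom: str, start: int, end: int) -> float:
        """Per-base mean over [start, end)."""
        return float(self.values(chrom, start, end).mean())

    def dense(self, chrom: str, length: int) -> np.ndarray:
        return self.values(chrom, 0, length)


def read_signal_track(path: str | Path, fill: float = 0.0) -> SignalTrack:
    """Read a bedGraph or fixed-step wiggle file (sorted input required)."""
    runs: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        chrom: str | None = None
        pos = 0
        step = span = 1
        mode = "bedgraph"
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                mode = "wig"
                fields = dict(kv.split("=") for kv in line.split()[1:])
                chrom = fields["chrom"]
                pos = int(fields["start"]) - 1  # wiggle is 1-based
                step = int(fields.get("step", 1))
                span = int(fields.get("span", step))
                continue
            if mode == "wig":
                if chrom is None:
                    raise FormatError(f"{path}:{lineno}: value before fixedStep header")
                runs.setdefault(chrom, []).append((pos, pos + span, float(line)))
                pos += step
            else:
                parts = line.split("\t")
                if len(parts) < 4:
                    raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
                runs.setdefault(parts[0], []).append(
                    (int(parts[1]), int(parts[2]), float(parts[3]))
                )
    return SignalTrack.from_runs(runs, fill=fill)


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.runs):
            starts, ends, values = track.runs[chrom]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


# ---------------------------------------------------------------------------
# Copy-ratio tables (ichorCNA-style output, consumed not produced)
# ---------------------------------------------------------------------------


@dataclass
class CopyRatioTable:
    """Fixed-size windows with a copy-ratio value and a CNA-state label."""

    windows: pd.DataFrame  # columns chrom, start, end, copy_ratio, state
    window_size: int = 500_000

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.windows)
        required = ["chrom", "start", "end", "copy_ratio", "state"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"copy-ratio table missing columns {missing}")
        sizes = (df["end"] - df["start"]).unique()
        if len(df) and len(sizes) > 1:
            raise FormatError("copy-ratio windows must have uniform size")
        bad = set(df["state"]) - set(CNA_STATES)
        if bad:
            raise FormatError(f"unknown CNA states: {sorted(bad)}")
        if len(df):
            self.window_size = int(sizes[0])
        self.windows = df.reset_index(drop=True)

    def lookup(self, chrom: str, pos: int) -> tuple[float, str] | None:
        """(copy_ratio, state) of the window containing pos, or None."""
        df = self.windows
        hit = df[(df["chrom"] == chrom) & (df["start"] <= pos) & (pos < df["end"])]
        if len(hit) == 0:
            return None
        row = hit.iloc[0]
        return float(row["copy_ratio"]), str(row["state"])

    @classmethod
    def uniform(cls, genome_sizes: Mapping[str, int], window_size: int = 500_000,
                copy_ratio: float = 1.0, state: str = "neutral") -> "CopyRatioTable":
        """A copy-neutral table tiling the given genome."""
        rows = []
        for chrom, size in genome_sizes.items():
            for s in range(0, size, window_size):
                rows.append((chrom, s, min(s + window_size, size), copy_ratio, state))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "copy_ratio", "state"])
        # pad the trailing partial window so sizes stay uniform
        df["end"] = df["start"] + window_size
        return cls(windows=df, window_size=window_size)


def read_copy_ratios(path: str | Path) -> CopyRatioTable:
    return CopyRatioTable(windows=pd.read_csv(path, sep="\t"))


def write_copy_ratios(table: CopyRatioTable, path: str | Path) -> None:
    table.windows.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read all sequences of a FASTA file as upper-case strings."""
    from pyfaidx import Fasta

    with Fasta(str(path), rebuild=True, build_index=True) as fa:
        return {name: str(fa[name][:]).upper() for name in fa.keys()}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
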