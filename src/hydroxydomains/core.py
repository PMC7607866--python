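"""Genomic interval arithmetic, binned signal tracks and flat-file IO.

All coordinates are 0-based half-open (BED convention). Loci printed in the
literature as 1-based inclusive spans must be converted on input by passing
``one_based=True`` to :func:`read_bed`. Chromosome names are passed through
verbatim; no "chr" normalisation is attempted.

Strand is carried but ignored by all signal operations except transcription
start site derivation: 5hmC is a symmetric DNA modification and its signal is
unstranded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "BinnedTrack",
    "GeneModel",
    "TADMap",
    "ChromStateSegmentation",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "flatten",
    "mean_signal",
    "region_sum",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic region ``[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


class IntervalSet:
    """A sorted collection of intervals with optional names and scores.

    Intervals on one chromosome may overlap unless the set is ``flattened``
    (then pairwise disjoint). Internally a pandas DataFrame with columns
    ``chrom, start, end, name, score, strand``.
    """

    COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]

    def __init__(self, df: pd.DataFrame | None = None, flattened: bool = False):
        if df is None:
            df = pd.DataFrame(columns=self.COLUMNS)
        df = df.copy()
        for col, default in (("name", "."), ("score", np.nan), ("strand", ".")):
            if col not in df.columns:
                df[col] = default
        df = df[self.COLUMNS]
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if len(df) and not (df["start"] < df["end"]).all():
            bad = df[~(df["start"] < df["end"])].iloc[0]
            raise ValueError(
                f"invalid interval {bad['chrom']}:{bad['start']}-{bad['end']}"
            )
        if len(df) and (df["start"] < 0).any():
            raise ValueError("negative start coordinate")
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
        self.df = df.reset_index(drop=True)
        self.flattened = flattened

    @classmethod
    def from_intervals(
        cls, intervals: Iterable[GenomicInterval], flattened: bool = False
    ) -> "IntervalSet":
        rows = [
            (iv.chrom, iv.start, iv.end, ".", np.nan, iv.strand) for iv in intervals
        ]
        return cls(pd.DataFrame(rows, columns=cls.COLUMNS), flattened=flattened)

    @classmethod
    def from_arrays(
        cls,
        chroms: Sequence[str],
        starts: Sequence[int],
        ends: Sequence[int],
        names: Sequence[str] | None = None,
        scores: Sequence[float] | None = None,
        flattened: bool = False,
    ) -> "IntervalSet":
        df = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})
        if names is not None:
            df["name"] = list(names)
        if scores is not None:
            df["score"] = list(scores)
        return cls(df, flattened=flattened)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[GenomicInterval]:
        for row in self.df.itertuples(index=False):
            yield GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        a = self.df[["chrom", "start", "end"]].reset_index(drop=True)
        b = other.df[["chrom", "start", "end"]].reset_index(drop=True)
        return a.equals(b)

    def covered_bp(self) -> int:
        """Total base pairs covered (overlaps counted once)."""
        return int(
            (flatten(self).df["end"] - flatten(self).df["start"]).sum()
        )

    def total_bp(self) -> int:
        """Sum of interval lengths (overlaps counted multiply)."""
        return int((self.df["end"] - self.df["start"]).sum())

    def chroms(self) -> list[str]:
        return list(self.df["chrom"].unique())

    def by_chrom(self) -> Iterator[tuple[str, np.ndarray, np.ndarray]]:
        for chrom, sub in self.df.groupby("chrom", sort=True):
            yield chrom, sub["start"].to_numpy(), sub["end"].to_numpy()


@dataclass
class BinnedTrack:
    """Fixed-width binned non-negative signal over a genome.

    ``values[chrom]`` holds one value per bin; the last bin is truncated to
    the chromosome end, so ``len(values[c]) == ceil(size / bin_width)``.
    """

    chrom_sizes: dict[str, int]
    bin_width: int
    values: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        for chrom, size in self.chrom_sizes.items():
            n = -(-size // self.bin_width)
            if chrom not in self.values:
                self.values[chrom] = np.zeros(n)
            elif len(self.values[chrom]) != n:
                raise ValueError(
                    f"{chrom}: expected {n} bins, got {len(self.values[chrom])}"
                )
            if np.any(self.values[chrom] < 0):
                raise ValueError(f"{chrom}: negative signal values")

    def n_bins(self, chrom: str) -> int:
        return -(-self.chrom_sizes[chrom] // self.bin_width)

    def total_signal(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def copy(self) -> "BinnedTrack":
        return BinnedTrack(
            dict(self.chrom_sizes),
            self.bin_width,
            {c: v.copy() for c, v in self.values.items()},
        )

    def rebin(self, new_width: int) -> "BinnedTrack":
        """Length-weighted aggregation into coarser bins.

        ``new_width`` must be a multiple of the current ``bin_width``.
        """
        if new_width % self.bin_width:
            raise ValueError("new_width must be a multiple of bin_width")
        k = new_width // self.bin_width
        out: dict[str, np.ndarray] = {}
        for chrom, vals in self.values.items():
            size = self.chrom_sizes[chrom]
            n_new = -(-size // new_width)
            padded = np.zeros(n_new * k)
            # weight by true base span of each fine bin (last one truncated)
            widths = np.full(len(vals), float(self.bin_width))
            widths[-1] = size - (len(vals) - 1) * self.bin_width
            padded[: len(vals)] = vals * widths
            wpad = np.zeros(n_new * k)
            wpad[: len(vals)] = widths
            sums = padded.reshape(n_new, k).sum(axis=1)
            ws = wpad.reshape(n_new, k).sum(axis=1)
            out[chrom] = np.where(ws > 0, sums / np.maximum(ws, 1), 0.0)
        return BinnedTrack(dict(self.chrom_sizes), new_width, out)


@dataclass(frozen=True)
class GeneModel:
    """A gene body with a strand-derived transcription start site."""

    gene_id: str
    interval: GenomicInterval

    @property
    def tss(self) -> int:
        if self.interval.strand == "-":
            return self.interval.end - 1
        return self.interval.start

    @property
    def strand(self) -> str:
        return self.interval.strand


class TADMap:
    """Disjoint topologically associating domains; locate the TAD of a point."""

    def __init__(self, intervals: IntervalSet):
        flat = flatten(intervals)
        self.intervals = flat
        self._starts = {
            c: (s, e) for c, s, e in flat.by_chrom()
        }

    def tad_of(self, chrom: str, pos: int) -> GenomicInterval | None:
        if chrom not in self._starts:
            return None
        starts, ends = self._starts[chrom]
        i = np.searchsorted(starts, pos, side="right") - 1
        if i >= 0 and pos < ends[i]:
            return GenomicInterval(chrom, int(starts[i]), int(ends[i]))
        return None

    def tad_id_of(self, chrom: str, pos: int) -> str | None:
        tad = self.tad_of(chrom, pos)
        return None if tad is None else str(tad)


class ChromStateSegmentation:
    """Chromatin-state segmentation: labelled intervals, free-text vocabulary."""

    def __init__(self, intervals: IntervalSet):
        self.intervals = intervals
        self.states = sorted(intervals.df["name"].unique())

    def intervals_of(self, state: str) -> pd.DataFrame:
        return self.intervals.df[self.intervals.df["name"] == state]


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected two columns")
        sizes[parts[0]] = int(parts[1])
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


def read_bed(path: str | Path, one_based: bool = False) -> IntervalSet:
    """Read BED3/4/5(/6) into a sorted :class:`IntervalSet`.

    With ``one_based=True``, start coordinates are decremented by one so that
    1-based inclusive spans (the convention of printed loci) become 0-based
    half-open.
    """
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    names: list[str] = []
    scores: list[float] = []
    strands: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if one_based:
                start -= 1
            if start >= end or start < 0:
                raise ValueError(
                    f"{path}:{lineno}: invalid interval [{start}, {end}) "
                    "after coordinate conversion"
                )
            chroms.append(parts[0])
            starts.append(start)
            ends.append(end)
            names.append(parts[3] if len(parts) > 3 else ".")
            scores.append(float(parts[4]) if len(parts) > 4 else np.nan)
            strands.append(parts[5] if len(parts) > 5 else ".")
    df = pd.DataFrame(
        {
            "chrom": chroms,
            "start": starts,
            "end": ends,
            "name": names,
            "score": scores,
            "strand": strands,
        }
    )
    return IntervalSet(df)


def write_bed(intervals: IntervalSet, path: str | Path) -> None:
    """Write sorted BED; emits name/score/strand columns when informative."""
    df = intervals.df
    has_strand = len(df) > 0 and (df["strand"] != ".").any()
    has_score = len(df) > 0 and df["score"].notna().any()
    has_name = has_score or has_strand or (len(df) > 0 and (df["name"] != ".").any())
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            fields = [row.chrom, str(row.start), str(row.end)]
            if has_name:
                fields.append(str(row.name))
            if has_score or has_strand:
                score = row.score
                fields.append("0" if pd.isna(score) else f"{score:g}")
            if has_strand:
                fields.append(row.strand)
            fh.write("\t".join(fields) + "\n")


def read_bedgraph(
    path: str | Path, chrom_sizes: Mapping[str, int], bin_width: int
) -> BinnedTrack:
    """Average bedGraph records (length-weighted) into fixed-width bins.

    Uncovered bases count as zero, i.e. a record covering half a bin at value
    4 yields a bin value of 2.
    """
    track = BinnedTrack(dict(chrom_sizes), bin_width)
    acc = {c: np.zeros_like(v) for c, v in track.values.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: fewer than 4 columns")
            chrom, start, end, value = (
                parts[0],
                int(parts[1]),
                int(parts[2]),
                float(parts[3]),
            )
            if chrom not in chrom_sizes:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom}")
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative value {value}")
            if end > chrom_sizes[chrom] or start < 0 or start >= end:
                raise ValueError(
                    f"{path}:{lineno}: interval [{start},{end}) outside "
                    f"{chrom} of size {chrom_sizes[chrom]}"
                )
            _accumulate(acc[chrom], start, end, value, bin_width)
    for chrom, sums in acc.items():
        widths = _bin_widths(chrom_sizes[chrom], bin_width)
        track.values[chrom] = sums / widths
    return track


def _bin_widths(size: int, bin_width: int) -> np.ndarray:
    n = -(-size // bin_width)
    widths = np.full(n, float(bin_width))
    widths[-1] = size - (n - 1) * bin_width
    return widths


def _accumulate(
    acc: np.ndarray, start: int, end: int, value: float, bin_width: int
) -> None:
    b0 = start // bin_width
    b1 = (end - 1) // bin_width
    if b0 == b1:
        acc[b0] += value * (end - start)
        return
    acc[b0] += value * ((b0 + 1) * bin_width - start)
    acc[b1] += value * (end - b1 * bin_width)
    if b1 - b0 > 1:
        acc[b0 + 1 : b1] += value * bin_width


def write_bedgraph(track: BinnedTrack, path: str | Path, omit_zero: bool = True) -> None:
    """Write the track as bedGraph, merging equal-valued adjacent bins."""
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            vals = track.values[chrom]
            size = track.chrom_sizes[chrom]
            w = track.bin_width
            if len(vals) == 0:
                continue
            change = np.flatnonzero(np.diff(vals)) + 1
            run_starts = np.concatenate(([0], change))
            run_ends = np.concatenate((change, [len(vals)]))
            for rs, re_ in zip(run_starts, run_ends):
                v = vals[rs]
                if omit_zero and v == 0:
                    continue
                fh.write(
                    f"{chrom}\t{rs * w}\t{min(re_ * w, size)}\t{v:g}\n"
                )


# ---------------------------------------------------------------------------
# Interval arithmetic and signal extraction
# ---------------------------------------------------------------------------

def flatten(intervals: IntervalSet) -> IntervalSet:
    """Minimal disjoint cover of the input (overlapping/abutting runs merged)."""
    if intervals.flattened:
        return intervals
    rows = []
    for chrom, starts, ends in intervals.by_chrom():
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        rows.append((chrom, cur_s, cur_e))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return IntervalSet(df, flattened=True)


def _check_region(track: BinnedTrack, region: GenomicInterval) -> None:
    if region.chrom not in track.chrom_sizes:
        raise KeyError(f"unknown chromosome {region.chrom}")
    if region.end > track.chrom_sizes[region.chrom]:
        raise ValueError(f"region {region} beyond chromosome end")


def _overlap_weights(
    track: BinnedTrack, region: GenomicInterval
) -> tuple[np.ndarray, np.ndarray]:
    """Bin values overlapping the region and their overlap lengths in bp."""
    w = track.bin_width
    b0 = region.start // w
    b1 = (region.end - 1) // w
    vals = track.values[region.chrom][b0 : b1 + 1]
    edges = np.arange(b0, b1 + 2) * w
    lo = np.maximum(edges[:-1], region.start)
    hi = np.minimum(edges[1:], region.end)
    return vals, (hi - lo).astype(float)


def mean_signal(track: BinnedTrack, region: GenomicInterval) -> float:
    """Per-base mean signal over ``region`` (partial bins weighted by overlap)."""
    _check_region(track, region)
    vals, weights = _overlap_weights(track, region)
    return float((vals * weights).sum() / weights.sum())


def region_sum(track: BinnedTrack, region: GenomicInterval) -> float:
    """Signal integral over ``region`` in bin units.

    Each bin contributes its value times the fraction of the bin overlapped,
    so summing disjoint regions tiling a chromosome reproduces the track
    total exactly (no signal invented or lost by stitching).
    """
    _check_region(track, region)
    vals, weights = _overlap_weights(track, region)
    return float((vals * weights / track.bin_width).sum())
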