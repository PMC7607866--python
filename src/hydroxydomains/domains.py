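"""ROSE-style 5hmC-enriched domain calling.

Large 5hmC-enriched domains are built exactly like H3K27ac super-enhancers:
per-sample peaks closer than a stitching distance (default 12.5 kb, chosen
from the stitching-distance curve) are merged into domains, domains are
ranked by library-normalised aggregate signal, and an optional tangent-rule
cutoff separates the "super" tail of the ranked curve. Cross-sample
consensus keeps every stitched region supported by at least ``min_support``
samples (default 2) and scores all samples on the consensus coordinates.

The stitching gap is measured between peak edges (``next.start - prev.end``),
exclusive of peak lengths, and peaks are merged transitively within one
chromosome only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import BinnedTrack, GenomicInterval, IntervalSet, flatten, region_sum

__all__ = [
    "DomainCallParams",
    "DomainSet",
    "ConsensusDomainSet",
    "StitchingCurve",
    "stitch_peaks",
    "stitching_curve",
    "score_domains",
    "rose_cutoff",
    "consensus_domains",
    "call_peaks",
    "default_library_scale",
]


@dataclass
class DomainCallParams:
    stitch_distance: int = 12_500
    top_n: int | str = 500           # integer or "auto" (tangent cutoff)
    min_peaks_per_domain: int = 1

    def __post_init__(self) -> None:
        if self.stitch_distance < 0:
            raise ValueError("stitch_distance must be >= 0")
        if self.top_n != "auto" and (not isinstance(self.top_n, int) or self.top_n < 1):
            raise ValueError("top_n must be a positive integer or 'auto'")


@dataclass
class DomainSet:
    """Ranked stitched domains of one sample (rank 1 = strongest signal)."""

    sample_id: str
    domains: pd.DataFrame  # chrom, start, end, signal, rank

    def __len__(self) -> int:
        return len(self.domains)

    def top(self, n: int) -> "DomainSet":
        kept = self.domains.nsmallest(n, "rank")
        return DomainSet(self.sample_id, kept.reset_index(drop=True))

    def intervals(self) -> IntervalSet:
        return IntervalSet(self.domains[["chrom", "start", "end"]])


@dataclass
class ConsensusDomainSet:
    """Cross-sample consensus domains with support counts and a signal matrix.

    ``domains`` columns: chrom, start, end, domain_id, support.
    ``signal_matrix``: domains (rows, indexed by domain_id) x samples,
    library-normalised, entries >= 0.
    """

    domains: pd.DataFrame
    signal_matrix: pd.DataFrame = field(default_factory=pd.DataFrame)
    min_support: int = 2

    def __len__(self) -> int:
        return len(self.domains)

    def intervals(self) -> IntervalSet:
        return IntervalSet(self.domains[["chrom", "start", "end"]], flattened=True)

    def interval_of(self, domain_id: str) -> GenomicInterval:
        row = self.domains.set_index("domain_id").loc[domain_id]
        return GenomicInterval(row["chrom"], int(row["start"]), int(row["end"]))


def domain_id(chrom: str, start: int, end: int) -> str:
    return f"{chrom}:{start}-{end}"


def stitch_peaks(peaks: IntervalSet, distance: int) -> IntervalSet:
    """Merge peaks whose gap is at most ``distance`` bp, transitively."""
    if distance < 0:
        raise ValueError("stitch distance must be >= 0")
    if len(peaks) == 0:
        return IntervalSet(flattened=True)
    rows = []
    for chrom, starts, ends in peaks.by_chrom():
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s - cur_e <= distance:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        rows.append((chrom, cur_s, cur_e))
    return IntervalSet(
        pd.DataFrame(rows, columns=["chrom", "start", "end"]), flattened=True
    )


@dataclass
class StitchingCurve:
    distances: np.ndarray
    n_domains: np.ndarray
    knee: int

    def as_pairs(self) -> list[tuple[int, int]]:
        return list(zip(self.distances.tolist(), self.n_domains.tolist()))


def stitching_curve(peaks: IntervalSet, distances: Sequence[int]) -> StitchingCurve:
    """Domain count versus stitching distance, with a knee estimate.

    The knee is the grid point maximising the perpendicular distance to the
    chord joining the first and last points of the (min-max scaled) curve —
    the bend where further merging stops collapsing domains.
    """
    if len(distances) == 0:
        raise ValueError("empty distance grid")
    ds = np.asarray(sorted(distances), dtype=float)
    ns = np.array([len(stitch_peaks(peaks, int(d))) for d in ds], dtype=float)
    if len(ds) < 3 or ns[0] == ns[-1]:
        knee = int(ds[0])
    else:
        x = (ds - ds[0]) / (ds[-1] - ds[0])
        y = (ns - ns.min()) / (ns.max() - ns.min())
        # perpendicular distance from each point to the first-last chord
        x0, y0, x1, y1 = x[0], y[0], x[-1], y[-1]
        dist = np.abs((y1 - y0) * x - (x1 - x0) * y + x1 * y0 - y1 * x0)
        knee = int(ds[int(np.argmax(dist))])
    return StitchingCurve(ds.astype(int), ns.astype(int), knee)


def default_library_scale(track: BinnedTrack) -> float:
    """CPM-like scale: total track signal divided by 1e6."""
    total = track.total_signal()
    if total <= 0:
        raise ValueError("track has zero total signal")
    return total / 1e6


def score_domains(
    stitched: IntervalSet,
    track: BinnedTrack,
    library_scale: float,
    sample_id: str = "",
) -> DomainSet:
    """Rank stitched domains by library-normalised aggregate signal.

    Ties are broken leftmost-first ((chrom, start) order), so ranks are a
    deterministic permutation of 1..n.
    """
    if library_scale <= 0:
        raise ValueError("library_scale must be positive")
    df = stitched.df[["chrom", "start", "end"]].copy()
    signals = [
        region_sum(track, GenomicInterval(r.chrom, r.start, r.end)) / library_scale
        for r in df.itertuples(index=False)
    ]
    df["signal"] = signals
    # stable sort on descending signal preserves (chrom, start) order in ties
    order = df.sort_values("signal", ascending=False, kind="mergesort")
    df["rank"] = 0
    df.loc[order.index, "rank"] = np.arange(1, len(df) + 1)
    return DomainSet(sample_id, df.reset_index(drop=True))


def rose_cutoff(scores: Sequence[float]) -> tuple[float, int]:
    """Tangent-rule cutoff on the ranked signal curve.

    Scores are sorted ascending and both axes are min-max scaled to [0, 1].
    Scanning from the right, we follow the curve while the discrete slope
    between consecutive points exceeds 1; the cutoff is the score at the
    point where the slope first drops to <= 1 (the point a unit-slope
    tangent touches). ``n_super`` counts scores strictly above the cutoff.

    All-equal scores are degenerate: no point stands out, ``n_super = 0``.
    """
    s = np.sort(np.asarray(scores, dtype=float))
    n = len(s)
    if n < 2:
        raise ValueError("need at least two scores")
    if s[0] == s[-1]:
        return float(s[0]), 0
    x = np.arange(n) / (n - 1)
    y = (s - s[0]) / (s[-1] - s[0])
    slopes = np.diff(y) / np.diff(x)
    idx = 0
    for i in range(n - 1, 0, -1):
        if slopes[i - 1] <= 1:
            idx = i
            break
    cutoff = float(s[idx])
    n_super = int((np.asarray(scores) > cutoff).sum())
    return cutoff, n_super


def consensus_domains(
    domain_sets: Sequence[DomainSet],
    min_support: int = 2,
    tracks: Mapping[str, BinnedTrack] | None = None,
    library_scales: Mapping[str, float] | None = None,
) -> ConsensusDomainSet:
    """Flatten the cross-sample union and keep regions seen in >= min_support samples.

    Support of a flattened region is the number of distinct samples with at
    least 1 bp of domain overlap. If per-sample ``tracks`` are given, the
    consensus signal matrix is filled by scoring every sample on the kept
    consensus coordinates (library-normalised; ``library_scales`` defaults to
    total-signal / 1e6 per sample).
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    if len(domain_sets) == 0:
        raise ValueError("need at least one DomainSet")
    union = IntervalSet(
        pd.concat(
            [ds.domains[["chrom", "start", "end"]] for ds in domain_sets],
            ignore_index=True,
        )
    )
    if len(union) == 0:
        return ConsensusDomainSet(
            pd.DataFrame(columns=["chrom", "start", "end", "domain_id", "support"]),
            min_support=min_support,
        )
    flat = flatten(union)
    support = np.zeros(len(flat), dtype=int)
    flat_by_chrom = {c: (s, e) for c, s, e in flat.by_chrom()}
    offsets: dict[str, int] = {}
    off = 0
    for chrom, sub in flat.df.groupby("chrom", sort=True):
        offsets[chrom] = sub.index[0]
    for ds in domain_sets:
        hit = np.zeros(len(flat), dtype=bool)
        for chrom, starts, ends in ds.intervals().by_chrom():
            if chrom not in flat_by_chrom:
                continue
            fs, fe = flat_by_chrom[chrom]
            base = offsets[chrom]
            # flattened intervals are disjoint+sorted: each sample interval
            # overlaps a contiguous run of them
            lo = np.searchsorted(fe, starts, side="right")
            hi = np.searchsorted(fs, ends, side="left")
            for a, b in zip(lo, hi):
                if b > a:
                    hit[base + a : base + b] = True
        support += hit
    keep = support >= min_support
    kept = flat.df.loc[keep, ["chrom", "start", "end"]].reset_index(drop=True)
    kept["domain_id"] = [
        domain_id(r.chrom, r.start, r.end) for r in kept.itertuples(index=False)
    ]
    kept["support"] = support[keep]

    matrix = pd.DataFrame()
    if tracks is not None and len(kept) > 0:
        cols = {}
        for sid, track in tracks.items():
            scale = (
                library_scales[sid]
                if library_scales is not None
                else default_library_scale(track)
            )
            cols[sid] = [
                region_sum(track, GenomicInterval(r.chrom, r.start, r.end)) / scale
                for r in kept.itertuples(index=False)
            ]
        matrix = pd.DataFrame(cols, index=kept["domain_id"].to_numpy())
    return ConsensusDomainSet(kept, matrix, min_support=min_support)


def call_peaks(
    track: BinnedTrack,
    fold: float = 2.0,
    p_threshold: float = 1e-5,
) -> IntervalSet:
    """Minimal Poisson bin-caller for synthetic tracks.

    A bin is significant when its value is at least ``fold`` times the
    genome-wide mean and its upper Poisson tail probability (at the mean
    rate) is below ``p_threshold``; adjacent significant bins are merged.
    Intended for the synthetic pipeline only — it makes no claim of
    reproducing any published peak caller.
    """
    mean = track.total_signal() / sum(len(v) for v in track.values.values())
    if mean <= 0:
        return IntervalSet(flattened=True)
    rows = []
    w = track.bin_width
    for chrom, vals in track.values.items():
        sig = (vals >= fold * mean) & (
            stats.poisson.sf(np.floor(vals) - 1, mean) < p_threshold
        )
        if not sig.any():
            continue
        idx = np.flatnonzero(sig)
        breaks = np.flatnonzero(np.diff(idx) > 1) + 1
        for run in np.split(idx, breaks):
            rows.append(
                (chrom, run[0] * w, min((run[-1] + 1) * w, track.chrom_sizes[chrom]))
            )
    if not rows:
        return IntervalSet(flattened=True)
    return IntervalSet(
        pd.DataFrame(rows, columns=["chrom", "start", "end"]), flattened=True
    )
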