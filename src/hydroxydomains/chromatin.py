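"""Descriptive chromatin-context computations for 5hmC signal.

Covers the landscape views of a hydroxymethylome: per-ChromHMM-state signal
distributions, track-track correlation matrices on coarse bins, peak-centred
meta-profiles, and expression-stratified metagene profiles (gene bodies
rescaled to a common length, flanks in absolute bp, strand-oriented).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    BinnedTrack,
    ChromStateSegmentation,
    GeneModel,
    GenomicInterval,
    IntervalSet,
    mean_signal,
)

__all__ = [
    "MetaProfile",
    "state_signal_distribution",
    "binned_correlation_matrix",
    "peak_metaprofile",
    "metagene_by_expression",
    "EXPRESSION_CLASSES",
]

# RPKM class boundaries, closed on the left
EXPRESSION_CLASSES = [
    ("<1", 0.0, 1.0),
    ("1-10", 1.0, 10.0),
    ("10-100", 10.0, 100.0),
    (">100", 100.0, np.inf),
]


@dataclass
class MetaProfile:
    """Mean signal along an axis of relative positions, over n regions."""

    positions: np.ndarray
    mean: np.ndarray
    n: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position": self.positions, "mean": self.mean, "n": self.n})


def state_signal_distribution(
    track: BinnedTrack, seg: ChromStateSegmentation
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Per-interval mean signal grouped by chromatin state.

    Returns the raw per-state value vectors and a quartile summary frame
    (state, n, q25, median, q75, mean). Unknown/free-text state labels pass
    through unchanged.
    """
    values: dict[str, list[float]] = {}
    for rec in seg.intervals.df.itertuples(index=False):
        if rec.chrom not in track.chrom_sizes:
            continue
        v = mean_signal(track, GenomicInterval(rec.chrom, int(rec.start), int(rec.end)))
        values.setdefault(rec.name, []).append(v)
    arrays = {state: np.asarray(v) for state, v in values.items()}
    rows = [
        {
            "state": state,
            "n": len(v),
            "q25": float(np.percentile(v, 25)),
            "median": float(np.median(v)),
            "q75": float(np.percentile(v, 75)),
            "mean": float(v.mean()),
        }
        for state, v in sorted(arrays.items())
    ]
    return arrays, pd.DataFrame(rows)


def binned_correlation_matrix(
    tracks: dict[str, BinnedTrack], bin_width: int = 10_000
) -> pd.DataFrame:
    """Pearson correlation of log2(signal + 1) between tracks on coarse bins.

    Tracks are rebinned to ``bin_width``; bins where every track is zero are
    dropped (uncovered genome would otherwise inflate correlations). A
    zero-variance track yields missing values off-diagonal.
    """
    if len(tracks) < 2:
        raise ValueError("need at least two tracks")
    names = list(tracks)
    chroms = sorted(next(iter(tracks.values())).chrom_sizes)
    for t in tracks.values():
        if sorted(t.chrom_sizes) != chroms:
            raise ValueError("tracks cover different genomes")
    columns = []
    for name in names:
        rb = tracks[name].rebin(bin_width)
        columns.append(np.concatenate([rb.values[c] for c in chroms]))
    data = np.vstack(columns)
    keep = (data != 0).any(axis=0)
    data = np.log2(data[:, keep] + 1.0)
    n = len(names)
    out = np.full((n, n), np.nan)
    sds = data.std(axis=1)
    for i in range(n):
        out[i, i] = 1.0
        for j in range(i + 1, n):
            if sds[i] > 0 and sds[j] > 0:
                r = float(np.corrcoef(data[i], data[j])[0, 1])
                out[i, j] = out[j, i] = r
    return pd.DataFrame(out, index=names, columns=names)


def peak_metaprofile(
    track: BinnedTrack,
    peaks: IntervalSet,
    half_window: int = 5000,
    step: int = 100,
) -> MetaProfile:
    """Mean signal around peak centres on a ±half_window grid.

    Peaks whose window would extend past a chromosome edge are dropped.
    """
    if half_window <= 0:
        raise ValueError("half_window must be positive")
    if len(peaks) == 0:
        raise ValueError("no peaks")
    offsets = np.arange(-half_window, half_window + 1, step)
    profiles = []
    for rec in peaks.df.itertuples(index=False):
        if rec.chrom not in track.chrom_sizes:
            continue
        center = (int(rec.start) + int(rec.end)) // 2
        pos = center + offsets
        if pos[0] < 0 or pos[-1] >= track.chrom_sizes[rec.chrom]:
            continue
        vals = track.values[rec.chrom][pos // track.bin_width]
        profiles.append(vals)
    if not profiles:
        raise ValueError("no peaks fit inside chromosome bounds")
    stack = np.vstack(profiles)
    return MetaProfile(offsets, stack.mean(axis=0), len(profiles))


def _gene_body_profile(
    track: BinnedTrack, gene: GeneModel, n_body_bins: int, flank: int, flank_bin: int
) -> np.ndarray | None:
    iv = gene.interval
    if iv.length < n_body_bins:
        return None
    if iv.start - flank < 0 or iv.end + flank > track.chrom_sizes[iv.chrom]:
        return None
    up = [
        mean_signal(track, GenomicInterval(iv.chrom, s, s + flank_bin))
        for s in range(iv.start - flank, iv.start, flank_bin)
    ]
    edges = np.linspace(iv.start, iv.end, n_body_bins + 1).round().astype(int)
    body = [
        mean_signal(track, GenomicInterval(iv.chrom, int(a), int(b)))
        for a, b in zip(edges[:-1], edges[1:])
    ]
    down = [
        mean_signal(track, GenomicInterval(iv.chrom, s, s + flank_bin))
        for s in range(iv.end, iv.end + flank, flank_bin)
    ]
    profile = np.array(up + body + down)
    if gene.strand == "-":
        profile = profile[::-1]
    return profile


def metagene_by_expression(
    track: BinnedTrack,
    genes: list[GeneModel],
    expr: pd.DataFrame,
    n_body_bins: int = 100,
    flank: int = 2000,
    flank_bin: int = 200,
    samples: list[str] | None = None,
) -> dict[str, MetaProfile]:
    """Strand-oriented metagene profiles stratified by mean RPKM class.

    Gene bodies are rescaled to ``n_body_bins`` length-weighted positions,
    flanks kept in absolute bp; classes are [0,1), [1,10), [10,100),
    [100,inf) on mean RPKM across ``samples`` (default: all expression
    columns). Classes with no usable gene are omitted. The position axis is
    flank-bin indices < 0, body bins 0..n_body_bins-1, downstream indices
    >= n_body_bins.
    """
    cols = samples if samples is not None else list(expr.columns)
    means = expr[cols].mean(axis=1)
    n_flank = flank // flank_bin
    positions = np.arange(-n_flank, n_body_bins + n_flank)
    out: dict[str, MetaProfile] = {}
    for label, lo, hi in EXPRESSION_CLASSES:
        members = [
            g
            for g in genes
            if g.gene_id in means.index and lo <= means[g.gene_id] < hi
        ]
        profiles = []
        for g in members:
            p = _gene_body_profile(track, g, n_body_bins, flank, flank_bin)
            if p is not None:
                profiles.append(p)
        if not profiles:
            continue
        stack = np.vstack(profiles)
        out[label] = MetaProfile(positions, stack.mean(axis=0), len(profiles))
    return out
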