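"""Stitching, ranking, tangent cutoff and cross-sample consensus."""

import numpy as np
import pandas as pd
import pytest

from hydroxydomains.core import BinnedTrack, GenomicInterval, IntervalSet, flatten, region_sum
from hydroxydomains.domains import (
    DomainSet,
    call_peaks,
    consensus_domains,
    rose_cutoff,
    score_domains,
    stitch_peaks,
    stitching_curve,
)

from conftest import coverage_mask, random_intervals, random_track


def brute_force_stitch(peaks: IntervalSet, distance: int) -> set:
    """O(n^2) transitive-closure merge oracle."""
    items = [(iv.chrom, iv.start, iv.end) for iv in peaks]
    merged = True
    while merged:
        merged = False
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                a, b = items[i], items[j]
                if a[0] != b[0]:
                    continue
                gap = max(b[1] - a[2], a[1] - b[2])
                if gap <= distance:
                    items[i] = (a[0], min(a[1], b[1]), max(a[2], b[2]))
                    items.pop(j)
                    merged = True
                    break
            if merged:
                break
    return set(items)


class TestStitchPeaks:
    def test_distance_zero_separated_identity(self):
        peaks = IntervalSet.from_intervals(
            [GenomicInterval("c", 0, 100), GenomicInterval("c", 200, 300)]
        )
        assert stitch_peaks(peaks, 0) == peaks

    def test_default_distance_merges_10kb_gap(self):
        peaks = IntervalSet.from_intervals(
            [GenomicInterval("c", 0, 100), GenomicInterval("c", 10_100, 10_200)]
        )
        out = stitch_peaks(peaks, 12_500)
        assert [(iv.start, iv.end) for iv in out] == [(0, 10_200)]

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            stitch_peaks(IntervalSet(), -1)

    def test_matches_transitive_closure_oracle(self):
        rng = np.random.default_rng(3)
        for distance in (0, 50, 400):
            peaks = random_intervals(rng, 200)
            got = {(iv.chrom, iv.start, iv.end) for iv in stitch_peaks(peaks, distance)}
            assert got == brute_force_stitch(peaks, distance)

    def test_monotone_and_idempotent(self):
        rng = np.random.default_rng(11)
        peaks = random_intervals(rng, 100)
        sizes = [len(stitch_peaks(peaks, d)) for d in (0, 10, 100, 1000, 5000)]
        assert sizes == sorted(sizes, reverse=True)
        once = stitch_peaks(peaks, 300)
        assert stitch_peaks(once, 300) == once


class TestStitchingCurve:
    def test_single_peak_flat(self):
        peaks = IntervalSet.from_intervals([GenomicInterval("c", 0, 10)])
        curve = stitching_curve(peaks, [0, 100, 200])
        assert list(curve.n_domains) == [1, 1, 1]

    def test_curve_non_increasing(self):
        rng = np.random.default_rng(2)
        peaks = random_intervals(rng, 150)
        curve = stitching_curve(peaks, list(range(0, 2000, 100)))
        assert (np.diff(curve.n_domains) <= 0).all()

    def test_knee_recovers_planted_gap_structure(self, small_cohort):
        # intra-domain gaps are planted below 12.5 kb, inter-domain gaps far
        # above: the bend of the curve sits at the stitching distance
        sid = small_cohort.tumor_ids[0]
        grid = list(range(0, 25_001, 1250))
        curve = stitching_curve(small_cohort.peaks[sid], grid)
        assert abs(curve.knee - 12_500) <= 1250


class TestScoreDomains:
    def test_constant_track_ranks_by_length(self):
        track = BinnedTrack({"c": 1000}, 10, {"c": np.full(100, 2.0)})
        doms = IntervalSet.from_intervals(
            [GenomicInterval("c", 0, 100), GenomicInterval("c", 200, 600)]
        )
        ds = score_domains(doms, track, 1.0)
        longest = ds.domains.loc[ds.domains["rank"] == 1].iloc[0]
        assert (longest["start"], longest["end"]) == (200, 600)
        assert ds.domains["signal"].iloc[1] == pytest.approx(2.0 * 40)

    def test_equal_signal_tie_leftmost_first(self):
        track = BinnedTrack({"c": 1000}, 10, {"c": np.full(100, 1.0)})
        doms = IntervalSet.from_intervals(
            [GenomicInterval("c", 500, 600), GenomicInterval("c", 100, 200)]
        )
        ds = score_domains(doms, track, 1.0)
        first = ds.domains.loc[ds.domains["rank"] == 1].iloc[0]
        assert first["start"] == 100

    def test_ranks_match_sort_oracle(self):
        rng = np.random.default_rng(8)
        track = random_track(rng, {"chrA": 10_000}, bin_width=10)
        doms = flatten(random_intervals(rng, 30, chroms=("chrA",), max_pos=9000))
        ds = score_domains(doms, track, 2.5)
        order = np.argsort(-ds.domains["signal"].to_numpy(), kind="stable") + 1
        ranks = np.empty(len(order), dtype=int)
        ranks[np.argsort(-ds.domains["signal"].to_numpy(), kind="stable")] = np.arange(
            1, len(order) + 1
        )
        assert (ds.domains["rank"].to_numpy() == ranks).all()

    def test_signal_conserved_by_stitching(self):
        rng = np.random.default_rng(13)
        track = random_track(rng, {"chrA": 10_000}, bin_width=10)
        peaks = random_intervals(rng, 40, chroms=("chrA",), max_pos=9000)
        stitched = stitch_peaks(peaks, 200)
        ds = score_domains(stitched, track, 1.0)
        per_base = np.repeat(track.values["chrA"], 10)
        mask = coverage_mask(stitched, "chrA", 10_000)
        assert ds.domains["signal"].sum() == pytest.approx(
            per_base[mask].sum() / 10, rel=1e-9
        )


class TestRoseCutoff:
    def test_single_spike(self):
        cutoff, n_super = rose_cutoff([0, 0, 0, 0, 100])
        assert n_super == 1

    def test_all_equal_degenerate(self):
        assert rose_cutoff([5, 5, 5, 5]) == (5.0, 0)

    def test_too_few_scores(self):
        with pytest.raises(ValueError):
            rose_cutoff([1.0])

    def test_matches_exhaustive_tangent_oracle_on_convex_curves(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            increments = np.sort(rng.gamma(1.0, 1.0, 20))
            scores = np.cumsum(increments)  # convex ascending
            cutoff, n_super = rose_cutoff(scores)
            x = np.arange(20) / 19
            y = (scores - scores[0]) / (scores[-1] - scores[0])
            oracle_idx = int(np.argmin(y - x))
            assert cutoff == pytest.approx(scores[oracle_idx])
            assert n_super == int((scores > scores[oracle_idx]).sum())


class TestConsensus:
    def _ds(self, sid, rows):
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        df["signal"] = 1.0
        df["rank"] = np.arange(1, len(df) + 1)
        return DomainSet(sid, df)

    def test_single_sample_below_support(self):
        ds = self._ds("s1", [("c", 0, 100)])
        assert len(consensus_domains([ds], min_support=2)) == 0

    def test_identical_domain_in_three_samples(self):
        sets = [self._ds(f"s{i}", [("c", 10, 100)]) for i in range(3)]
        cons = consensus_domains(sets, min_support=2)
        assert len(cons) == 1
        assert cons.domains["support"].iloc[0] == 3

    def test_support_matches_bitmap_oracle(self):
        rng = np.random.default_rng(17)
        sets = [
            self._ds(f"s{i}", [
                (iv.chrom, iv.start, iv.end)
                for iv in flatten(random_intervals(rng, 10))
            ])
            for i in range(5)
        ]
        cons = consensus_domains(sets, min_support=1)
        for rec in cons.domains.itertuples(index=False):
            support = 0
            for ds in sets:
                mask = coverage_mask(ds.intervals(), rec.chrom, 11_000)
                if mask[rec.start : rec.end].any():
                    support += 1
            assert support == rec.support

    def test_size_non_increasing_in_min_support(self):
        rng = np.random.default_rng(19)
        sets = [
            self._ds(f"s{i}", [
                (iv.chrom, iv.start, iv.end)
                for iv in flatten(random_intervals(rng, 8))
            ])
            for i in range(6)
        ]
        sizes = [len(consensus_domains(sets, m)) for m in (1, 2, 3, 4)]
        assert sizes == sorted(sizes, reverse=True)
        with pytest.raises(ValueError):
            consensus_domains(sets, min_support=0)

    def test_signal_matrix_filled_from_tracks(self):
        rng = np.random.default_rng(23)
        tracks = {f"s{i}": random_track(rng, {"c": 1000}, 10) for i in range(2)}
        sets = [self._ds(f"s{i}", [("c", 100, 300)]) for i in range(2)]
        cons = consensus_domains(
            sets, 2, tracks=tracks, library_scales={"s0": 1.0, "s1": 2.0}
        )
        iv = GenomicInterval("c", 100, 300)
        did = cons.domains["domain_id"].iloc[0]
        assert cons.signal_matrix.loc[did, "s0"] == pytest.approx(
            region_sum(tracks["s0"], iv)
        )
        assert cons.signal_matrix.loc[did, "s1"] == pytest.approx(
            region_sum(tracks["s1"], iv) / 2.0
        )


class TestCallPeaks:
    def test_recovers_planted_block(self):
        rng = np.random.default_rng(31)
        vals = rng.gamma(2.0, 1.0, 1000)
        vals[400:450] *= 20
        track = BinnedTrack({"c": 10_000}, 10, {"c": vals})
        peaks = stitch_peaks(call_peaks(track), 200)
        mask = coverage_mask(peaks, "c", 10_000)
        assert mask[4000:4500].mean() > 0.9
        assert mask[:3900].mean() < 0.02
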