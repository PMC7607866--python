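"""Chromatin-state distributions, track correlations and meta-profiles."""

import numpy as np
import pandas as pd
import pytest

from hydroxydomains.chromatin import (
    binned_correlation_matrix,
    metagene_by_expression,
    peak_metaprofile,
    state_signal_distribution,
)
from hydroxydomains.core import (
    BinnedTrack,
    ChromStateSegmentation,
    GeneModel,
    GenomicInterval,
    IntervalSet,
)

from conftest import random_track


def seg(rows):
    return ChromStateSegmentation(
        IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]))
    )


class TestStateDistribution:
    def test_constant_track_degenerate(self):
        track = BinnedTrack({"c": 100}, 10, {"c": np.full(10, 4.0)})
        arrays, summary = state_signal_distribution(
            track, seg([("c", 0, 50, "promoter"), ("c", 50, 100, "het")])
        )
        for vals in arrays.values():
            assert np.allclose(vals, 4.0)
        assert (summary["median"] == 4.0).all()

    def test_two_state_toy_matches_per_base_oracle(self):
        vals = np.arange(10, dtype=float)
        track = BinnedTrack({"c": 100}, 10, {"c": vals})
        segments = [
            ("c", 0, 25, "a"), ("c", 25, 40, "b"), ("c", 40, 90, "a"), ("c", 90, 100, "b"),
        ]
        arrays, _ = state_signal_distribution(track, seg(segments))
        per_base = np.repeat(vals, 10)
        for chrom, start, end, state in segments:
            assert per_base[start:end].mean() in [
                pytest.approx(v) for v in arrays[state]
            ]

    def test_planted_enhancer_states_exceed_heterochromatin(self, small_cohort):
        sid = small_cohort.tumor_ids[0]
        _, summary = state_signal_distribution(
            small_cohort.tracks[sid], small_cohort.states
        )
        med = summary.set_index("state")["median"]
        assert med["strong_enhancer"] > med["heterochromatin"]


class TestCorrelationMatrix:
    def test_self_and_anticorrelation(self):
        rng = np.random.default_rng(0)
        t1 = random_track(rng, {"c": 100_000}, bin_width=100)
        inv = BinnedTrack(
            {"c": 100_000}, 100, {"c": t1.values["c"].max() - t1.values["c"]}
        )
        m = binned_correlation_matrix({"a": t1, "b": t1, "inv": inv}, bin_width=1000)
        assert m.loc["a", "a"] == 1.0
        assert m.loc["a", "b"] == pytest.approx(1.0)
        assert m.loc["a", "inv"] < -0.5
        assert np.allclose(m.values, m.values.T, equal_nan=True)

    def test_matches_textbook_pearson(self):
        rng = np.random.default_rng(1)
        tracks = {f"t{i}": random_track(rng, {"c": 5000}, 100) for i in range(3)}
        m = binned_correlation_matrix(tracks, bin_width=500)
        data = np.vstack(
            [tracks[f"t{i}"].rebin(500).values["c"] for i in range(3)]
        )
        keep = (data != 0).any(axis=0)
        logd = np.log2(data[:, keep] + 1)
        for i in range(3):
            for j in range(3):
                x, y = logd[i], logd[j]
                r = ((x - x.mean()) * (y - y.mean())).sum() / (
                    np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
                )
                assert m.iloc[i, j] == pytest.approx(r, abs=1e-9)

    def test_positive_semidefinite(self, small_cohort):
        ids = small_cohort.tumor_ids[:3] + small_cohort.normal_ids[:1]
        m = binned_correlation_matrix(
            {s: small_cohort.tracks[s] for s in ids}, bin_width=10_000
        )
        eig = np.linalg.eigvalsh(m.to_numpy())
        assert eig.min() > -1e-8

    def test_zero_variance_track_reported_missing(self):
        rng = np.random.default_rng(2)
        t1 = random_track(rng, {"c": 10_000}, 100)
        flat = BinnedTrack({"c": 10_000}, 100, {"c": np.full(100, 3.0)})
        m = binned_correlation_matrix({"a": t1, "flat": flat}, bin_width=1000)
        assert np.isnan(m.loc["a", "flat"])
        assert m.loc["flat", "flat"] == 1.0


class TestPeakMetaprofile:
    def test_constant_track_flat_profile(self):
        track = BinnedTrack({"c": 100_000}, 100, {"c": np.full(1000, 2.0)})
        peaks = IntervalSet(
            pd.DataFrame([("c", 50_000, 50_200)], columns=["chrom", "start", "end"])
        )
        mp = peak_metaprofile(track, peaks, half_window=2000, step=100)
        assert np.allclose(mp.mean, 2.0)

    def test_single_triangular_peak_reproduced(self):
        vals = np.zeros(1000)
        center = 500
        for i in range(100):
            vals[center - 50 + i] = 50 - abs(i - 50)
        track = BinnedTrack({"c": 100_000}, 100, {"c": vals})
        peaks = IntervalSet(
            pd.DataFrame([("c", 49_900, 50_100)], columns=["chrom", "start", "end"])
        )
        mp = peak_metaprofile(track, peaks, half_window=5000, step=100)
        assert mp.n == 1
        assert np.allclose(mp.mean, vals[450:551])

    def test_edge_peaks_dropped_and_validation(self):
        track = BinnedTrack({"c": 10_000}, 100, {"c": np.ones(100)})
        peaks = IntervalSet(
            pd.DataFrame([("c", 0, 100), ("c", 5000, 5100)], columns=["chrom", "start", "end"])
        )
        mp = peak_metaprofile(track, peaks, half_window=2000, step=100)
        assert mp.n == 1
        with pytest.raises(ValueError):
            peak_metaprofile(track, peaks, half_window=0)

    def test_planted_domain_centre_enrichment(self, small_cohort):
        sid = small_cohort.tumor_ids[0]
        mp = peak_metaprofile(
            small_cohort.tracks[sid], small_cohort.peaks[sid], half_window=5000
        )
        mid = len(mp.mean) // 2
        centre = mp.mean[mid - 5 : mid + 5].mean()
        flank = np.concatenate([mp.mean[:10], mp.mean[-10:]]).mean()
        assert centre >= 2 * flank


class TestMetagene:
    def _genes(self):
        return [
            GeneModel("plus", GenomicInterval("c", 10_000, 20_000, "+")),
            GeneModel("minus", GenomicInterval("c", 40_000, 50_000, "-")),
        ]

    def test_constant_signal_flat_profiles(self):
        track = BinnedTrack({"c": 100_000}, 100, {"c": np.full(1000, 3.0)})
        expr = pd.DataFrame({"s": [5.0, 5.0]}, index=["plus", "minus"])
        out = metagene_by_expression(track, self._genes(), expr)
        assert list(out) == ["1-10"]
        assert np.allclose(out["1-10"].mean, 3.0)

    def test_strand_mirrored_signal_identical_profiles(self):
        vals = np.zeros(1000)
        vals[100:200] = np.linspace(0, 9.9, 100)       # ascending over + gene
        vals[400:500] = np.linspace(9.9, 0, 100)       # mirrored over - gene
        track = BinnedTrack({"c": 100_000}, 100, {"c": vals})
        genes = self._genes()
        expr = pd.DataFrame({"s": [5.0, 5.0]}, index=["plus", "minus"])
        a = metagene_by_expression(track, [genes[0]], expr)["1-10"]
        b = metagene_by_expression(track, [genes[1]], expr)["1-10"]
        assert np.allclose(a.mean, b.mean, atol=1e-9)

    def test_concatenation_is_weighted_average(self):
        rng = np.random.default_rng(3)
        track = random_track(rng, {"c": 200_000}, 100)
        genes_a = [GeneModel(f"a{i}", GenomicInterval("c", 10_000 + 20_000 * i, 15_000 + 20_000 * i, "+")) for i in range(3)]
        genes_b = [GeneModel(f"b{i}", GenomicInterval("c", 100_000 + 20_000 * i, 112_000 + 20_000 * i, "+")) for i in range(2)]
        ids = [g.gene_id for g in genes_a + genes_b]
        expr = pd.DataFrame({"s": 5.0}, index=ids)
        pa = metagene_by_expression(track, genes_a, expr)["1-10"]
        pb = metagene_by_expression(track, genes_b, expr)["1-10"]
        pab = metagene_by_expression(track, genes_a + genes_b, expr)["1-10"]
        want = (pa.mean * pa.n + pb.mean * pb.n) / (pa.n + pb.n)
        assert np.allclose(pab.mean, want, atol=1e-9)

    def test_expression_class_ordering_on_planted_coupling(self, small_cohort):
        sid = small_cohort.tumor_ids[0]
        out = metagene_by_expression(
            small_cohort.tracks[sid],
            small_cohort.genes,
            small_cohort.expression,
            samples=small_cohort.tumor_ids,
        )
        body = {
            label: mp.mean[10:110].mean() for label, mp in out.items()
        }
        order = ["<1", "1-10", "10-100", ">100"]
        present = [label for label in order if label in body]
        vals = [body[label] for label in present]
        assert vals == sorted(vals)
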