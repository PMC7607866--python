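"""TAD-constrained domain-gene assignment and enhancer-pair flagging."""

import numpy as np
import pandas as pd
import pytest

from hydroxydomains.core import GeneModel, GenomicInterval, IntervalSet, TADMap
from hydroxydomains.domain_gene import (
    assign_domain_gene,
    domain_pair_correlation,
    flag_enhancer_candidates,
)
from hydroxydomains.domains import ConsensusDomainSet


def make_consensus(rows, matrix):
    doms = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    doms["domain_id"] = [f"{r.chrom}:{r.start}-{r.end}" for r in doms.itertuples()]
    doms["support"] = 2
    return ConsensusDomainSet(doms, pd.DataFrame(matrix, index=doms["domain_id"]))


def make_tads(rows):
    return TADMap(IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end"])))


SAMPLES = [f"s{i}" for i in range(10)]


class TestAssign:
    def test_single_candidate_assigned_regardless_of_r2(self):
        rng = np.random.default_rng(0)
        cons = make_consensus(
            [("c", 1000, 2000)], {s: [rng.random()] for s in SAMPLES}
        )
        genes = [GeneModel("g1", GenomicInterval("c", 5000, 6000, "+"))]
        expr = pd.DataFrame(
            {s: [rng.random() * 10 + 1] for s in SAMPLES}, index=["g1"]
        )
        tads = make_tads([("c", 0, 10_000)])
        out = assign_domain_gene(cons, expr, genes, tads)
        assert out["gene_id"].iloc[0] == "g1"

    def test_identical_vectors_win_with_r2_one(self):
        rng = np.random.default_rng(1)
        sig = rng.gamma(2.0, 10.0, 10)
        cons = make_consensus([("c", 1000, 2000)], dict(zip(SAMPLES, sig[None].T)))
        genes = [
            GeneModel("match", GenomicInterval("c", 5000, 6000, "+")),
            GeneModel("noise", GenomicInterval("c", 7000, 8000, "+")),
        ]
        expr = pd.DataFrame(
            [sig, rng.gamma(2.0, 10.0, 10) + 1], index=["match", "noise"], columns=SAMPLES
        )
        tads = make_tads([("c", 0, 10_000)])
        out = assign_domain_gene(cons, expr, genes, tads)
        assert out["gene_id"].iloc[0] == "match"
        assert out["r2"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_requires_three_shared_samples(self):
        cons = make_consensus([("c", 0, 10)], {"s0": [1.0], "s1": [2.0]})
        expr = pd.DataFrame({"s0": [1.0], "s1": [1.0]}, index=["g"])
        genes = [GeneModel("g", GenomicInterval("c", 0, 5, "+"))]
        with pytest.raises(ValueError, match="shared samples"):
            assign_domain_gene(cons, expr, genes, make_tads([("c", 0, 100)]))

    def test_no_genes_all_unassigned(self):
        cons = make_consensus([("c", 0, 10)], {s: [1.0] for s in SAMPLES})
        expr = pd.DataFrame(columns=SAMPLES, dtype=float)
        out = assign_domain_gene(cons, expr, [], make_tads([("c", 0, 100)]))
        assert out["gene_id"].isna().all() or (out["gene_id"] == None).all()  # noqa: E711

    def test_never_assigns_across_tads(self, small_cohort, small_consensus):
        out = assign_domain_gene(
            small_consensus,
            small_cohort.expression,
            small_cohort.genes,
            small_cohort.tads,
            samples=small_cohort.tumor_ids,
        )
        genes = {g.gene_id: g for g in small_cohort.genes}
        for rec in out.dropna(subset=["r2"]).itertuples(index=False):
            if rec.gene_id is None:
                continue
            g = genes[rec.gene_id]
            gene_tad = small_cohort.tads.tad_id_of(g.interval.chrom, g.tss)
            assert gene_tad == rec.tad_id

    def test_gene_specific_partition(self, small_cohort, small_consensus):
        out = assign_domain_gene(
            small_consensus,
            small_cohort.expression,
            small_cohort.genes,
            small_cohort.tads,
            samples=small_cohort.tumor_ids,
        )
        assigned = out[out["gene_id"].notna()]
        multi = assigned.groupby("gene_id").size()
        n_specific = int(assigned["gene_specific"].sum())
        assert n_specific == (multi == 1).sum()
        assert n_specific + multi[multi > 1].sum() == len(assigned)

    def test_recovers_planted_link(self, small_cohort, small_consensus):
        out = assign_domain_gene(
            small_consensus,
            small_cohort.expression,
            small_cohort.genes,
            small_cohort.tads,
            samples=small_cohort.tumor_ids,
        ).set_index("domain_id")
        links = small_cohort.truth.links
        hits = sum(
            out.loc[l.domain_id, "gene_id"] == l.gene_id
            for l in links.itertuples(index=False)
            if l.domain_id in out.index
        )
        assert hits >= 0.75 * len(links)


class TestPairsAndEnhancers:
    def test_pearson_affine_invariance(self):
        rng = np.random.default_rng(5)
        sig = rng.gamma(2.0, 5.0, (2, 10))
        cons = make_consensus(
            [("c", 0, 100), ("c", 5000, 5100)], dict(zip(SAMPLES, sig.T))
        )
        # r^2 between rows is invariant when one row is rescaled affinely
        # on the log scale used internally
        log_sig = np.log2(sig + 1)
        base = np.corrcoef(log_sig)[0, 1] ** 2
        scaled = np.corrcoef(3.0 * log_sig[0] + 2.0, log_sig[1])[0, 1] ** 2
        assert scaled == pytest.approx(base, abs=1e-12)

    def test_no_self_pairs_and_identical_signals(self):
        rng = np.random.default_rng(2)
        sig = rng.gamma(2.0, 10.0, 10)
        cons = make_consensus(
            [("c", 0, 100), ("c", 5000, 5100)],
            dict(zip(SAMPLES, np.vstack([sig, sig]).T)),
        )
        pairs = domain_pair_correlation(cons, make_tads([("c", 0, 10_000)]))
        assert len(pairs) == 1
        assert pairs["pair_r2"].iloc[0] == pytest.approx(1.0)
        assert pairs["domain_a"].iloc[0] != pairs["domain_b"].iloc[0]

    def test_null_calibration_of_pair_r2(self):
        # independent signals at n = 40 samples: intra-TAD pair r^2 is small
        rng = np.random.default_rng(3)
        cols = [f"s{i}" for i in range(40)]
        n_dom = 30
        sig = rng.gamma(2.0, 10.0, (n_dom, 40))
        cons = make_consensus(
            [("c", i * 1000, i * 1000 + 500) for i in range(n_dom)],
            dict(zip(cols, sig.T)),
        )
        pairs = domain_pair_correlation(
            cons, make_tads([("c", 0, 100_000)]), min_r2=0.0
        )
        assert np.percentile(pairs["pair_r2"], 95) < 0.25

    def test_ccnd2_like_locus_flags_one_candidate(self):
        # genic domain, extragenic domain 114 kb upstream, one TAD
        rng = np.random.default_rng(6)
        base = rng.gamma(2.0, 10.0, 10)
        noisy = base * np.exp(rng.normal(0, 0.05, 10))
        cons = make_consensus(
            [("chr12", 4_106_500, 4_164_700), ("chr12", 4_278_700, 4_312_900)],
            dict(zip(SAMPLES, np.vstack([noisy, base]).T)),
        )
        gene = GeneModel("CCND2", GenomicInterval("chr12", 4_278_700, 4_312_900, "+"))
        expr = pd.DataFrame([base * 2], index=["CCND2"], columns=SAMPLES)
        tads = make_tads([("chr12", 3_850_000, 4_800_000)])
        assignments = assign_domain_gene(cons, expr, [gene], tads)
        pairs = domain_pair_correlation(cons, tads)
        assert pairs["pair_r2"].iloc[0] > 0.8
        cands = flag_enhancer_candidates(assignments, pairs, [gene])
        assert len(cands) == 1
        row = cands.iloc[0]
        assert row["gene_id"] == "CCND2"
        assert row["extragenic_domain_id"] == "chr12:4106500-4164700"
        assert row["distance_bp"] == 4_278_700 - 4_164_700 == 114_000

    def test_both_domains_genic_no_candidate(self):
        rng = np.random.default_rng(7)
        base = rng.gamma(2.0, 10.0, 10)
        cons = make_consensus(
            [("c", 1000, 2000), ("c", 8000, 9000)],
            dict(zip(SAMPLES, np.vstack([base, base]).T)),
        )
        genes = [
            GeneModel("g1", GenomicInterval("c", 1000, 2000, "+")),
            GeneModel("g2", GenomicInterval("c", 8000, 9000, "+")),
        ]
        expr = pd.DataFrame(
            [base, base * 1.5], index=["g1", "g2"], columns=SAMPLES
        )
        tads = make_tads([("c", 0, 10_000)])
        assignments = assign_domain_gene(cons, expr, genes, tads)
        pairs = domain_pair_correlation(cons, tads)
        cands = flag_enhancer_candidates(assignments, pairs, genes)
        assert len(cands) == 0

    def test_planted_enhancer_pair_recovered(self, small_cohort, small_consensus):
        truth = small_cohort.truth.enhancer_pair
        assert truth is not None
        pairs = domain_pair_correlation(
            small_consensus, small_cohort.tads, samples=small_cohort.tumor_ids,
            min_r2=0.0,
        )
        top = pairs.iloc[0]
        assert {top["domain_a"], top["domain_b"]} == {
            truth["genic_domain_id"],
            truth["extragenic_domain_id"],
        }
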