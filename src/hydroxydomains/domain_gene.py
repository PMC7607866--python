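"""TAD-constrained assignment of 5hmC-enriched domains to genes.

Each consensus domain is linked to the most expression-correlated gene
inside its topologically associating domain (TAD): candidate genes have
their TSS in the TAD of the domain midpoint and a mean expression above a
floor (default 1 RPKM); Pearson correlation is computed between
log2(domain signal + 1) and log2(RPKM + 1) across the shared tumor
(diagnosis) samples. A domain pair inside one TAD where exactly one member
overlaps the assigned gene body and the other is extragenic, with a high
signal-signal correlation, is flagged as a putative enhancer-gene pair.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import GeneModel, GenomicInterval, TADMap
from .domains import ConsensusDomainSet

__all__ = [
    "assign_domain_gene",
    "domain_pair_correlation",
    "flag_enhancer_candidates",
]

PSEUDOCOUNT = 1.0


def _log(x: np.ndarray) -> np.ndarray:
    return np.log2(np.asarray(x, dtype=float) + PSEUDOCOUNT)


def _pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(stats.pearsonr(x, y).statistic)


def _shared_samples(
    consensus: ConsensusDomainSet, expr: pd.DataFrame, samples: Sequence[str] | None
) -> list[str]:
    cols = [c for c in consensus.signal_matrix.columns if c in expr.columns]
    if samples is not None:
        cols = [c for c in cols if c in set(samples)]
    if len(cols) < 3:
        raise ValueError(
            f"only {len(cols)} shared samples between signal matrix and "
            "expression; need at least 3"
        )
    return cols


def _distance(iv: GenomicInterval, pos: int) -> int:
    if pos < iv.start:
        return iv.start - pos
    if pos >= iv.end:
        return pos - iv.end + 1
    return 0


def assign_domain_gene(
    consensus: ConsensusDomainSet,
    expr: pd.DataFrame,
    genes: Sequence[GeneModel],
    tads: TADMap,
    min_mean_rpkm: float = 1.0,
    samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Assign each consensus domain to its most-correlated intra-TAD gene.

    ``expr`` is a genes x samples RPKM frame indexed by gene_id; ``samples``
    restricts the correlation to a sample subset (e.g. tumor diagnosis
    samples). Returns one row per domain: domain_id, chrom, start, end,
    gene_id (None if unassigned), r2, n_samples, tad_id, gene_specific.
    Ties in r² are broken by TSS proximity to the domain. ``gene_specific``
    marks domains whose assigned gene is assigned to exactly one domain.
    """
    cols = _shared_samples(consensus, expr, samples)
    sig = np.asarray(consensus.signal_matrix[cols], dtype=float)
    log_sig = _log(sig)
    gene_by_id = {g.gene_id: g for g in genes}
    expr_genes = [g for g in genes if g.gene_id in expr.index]
    mean_rpkm = expr.loc[[g.gene_id for g in expr_genes], cols].mean(axis=1)
    expressed = [g for g in expr_genes if mean_rpkm[g.gene_id] >= min_mean_rpkm]
    log_expr = {g.gene_id: _log(expr.loc[g.gene_id, cols].to_numpy()) for g in expressed}

    # index expressed-gene TSSs by TAD
    genes_by_tad: dict[str, list[GeneModel]] = {}
    for g in expressed:
        tid = tads.tad_id_of(g.interval.chrom, g.tss)
        if tid is not None:
            genes_by_tad.setdefault(tid, []).append(g)

    rows = []
    for i, rec in enumerate(consensus.domains.itertuples(index=False)):
        iv = GenomicInterval(rec.chrom, int(rec.start), int(rec.end))
        tad_id = tads.tad_id_of(iv.chrom, iv.midpoint)
        best: tuple[float, int, str] | None = None  # (r2, -proximity, gene_id)
        if tad_id is not None:
            for g in genes_by_tad.get(tad_id, []):
                r = _pearson_r(log_sig[i], log_expr[g.gene_id])
                r2 = r * r
                dist = _distance(iv, g.tss)
                key = (r2, -dist, g.gene_id)
                if best is None or key[:2] > best[:2]:
                    best = key
        rows.append(
            {
                "domain_id": rec.domain_id,
                "chrom": rec.chrom,
                "start": rec.start,
                "end": rec.end,
                "gene_id": best[2] if best else None,
                "r2": best[0] if best else np.nan,
                "n_samples": len(cols),
                "tad_id": tad_id,
            }
        )
    out = pd.DataFrame(rows)
    counts = out["gene_id"].value_counts()
    out["gene_specific"] = out["gene_id"].map(
        lambda g: bool(g is not None and counts.get(g, 0) == 1)
    )
    return out


def domain_pair_correlation(
    consensus: ConsensusDomainSet,
    tads: TADMap,
    min_r2: float = 0.5,
    samples: Sequence[str] | None = None,
    expr: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """All intra-TAD domain pairs with signal-signal r² above ``min_r2``.

    Correlation on log2(signal + 1) across tumor samples; self-pairs are
    excluded, pairs sorted by descending r². ``expr`` is only used to pick
    the shared sample columns when ``samples`` is None.
    """
    if len(consensus) < 2:
        return pd.DataFrame(
            columns=["domain_a", "domain_b", "tad_id", "pair_r2", "distance_bp"]
        )
    matrix = consensus.signal_matrix
    cols = list(matrix.columns if samples is None else [c for c in matrix.columns if c in set(samples)])
    log_sig = _log(np.asarray(matrix[cols], dtype=float))
    doms = consensus.domains
    by_tad: dict[str, list[int]] = {}
    for i, rec in enumerate(doms.itertuples(index=False)):
        tid = tads.tad_id_of(rec.chrom, (int(rec.start) + int(rec.end)) // 2)
        if tid is not None:
            by_tad.setdefault(tid, []).append(i)
    rows = []
    for tid, idxs in by_tad.items():
        for a_pos, i in enumerate(idxs):
            for j in idxs[a_pos + 1 :]:
                r = _pearson_r(log_sig[i], log_sig[j])
                r2 = r * r
                if r2 >= min_r2:
                    a, b = doms.iloc[i], doms.iloc[j]
                    gap = max(int(b["start"]) - int(a["end"]), int(a["start"]) - int(b["end"]), 0)
                    rows.append(
                        {
                            "domain_a": a["domain_id"],
                            "domain_b": b["domain_id"],
                            "tad_id": tid,
                            "pair_r2": r2,
                            "distance_bp": gap,
                        }
                    )
    out = pd.DataFrame(rows, columns=["domain_a", "domain_b", "tad_id", "pair_r2", "distance_bp"])
    return out.sort_values("pair_r2", ascending=False).reset_index(drop=True)


def flag_enhancer_candidates(
    assignments: pd.DataFrame,
    pairs: pd.DataFrame,
    genes: Sequence[GeneModel],
) -> pd.DataFrame:
    """Putative enhancer calls from correlated genic/extragenic domain pairs.

    For each intra-TAD pair where exactly one member overlaps its assigned
    gene's body and the other overlaps no gene body at all, emit the
    extragenic member as the putative enhancer of that gene, with the
    distance between the facing edges of the two domains.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    dom = assignments.set_index("domain_id")

    def interval_of(did: str) -> GenomicInterval:
        row = dom.loc[did]
        return GenomicInterval(row["chrom"], int(row["start"]), int(row["end"]))

    def overlaps_any_gene(iv: GenomicInterval) -> bool:
        return any(iv.overlaps(g.interval) for g in genes)

    rows = []
    for rec in pairs.itertuples(index=False):
        iv_a, iv_b = interval_of(rec.domain_a), interval_of(rec.domain_b)
        flags = []
        for did, iv in ((rec.domain_a, iv_a), (rec.domain_b, iv_b)):
            gid = dom.loc[did, "gene_id"]
            genic = (
                gid is not None
                and gid in gene_by_id
                and iv.overlaps(gene_by_id[gid].interval)
            )
            flags.append((did, iv, gid, genic))
        genic_members = [f for f in flags if f[3]]
        extragenic_members = [f for f in flags if not f[3] and not overlaps_any_gene(f[1])]
        if len(genic_members) == 1 and len(extragenic_members) == 1:
            gdid, giv, gid, _ = genic_members[0]
            edid, eiv, _, _ = extragenic_members[0]
            distance = max(giv.start - eiv.end, eiv.start - giv.end, 0)
            rows.append(
                {
                    "gene_id": gid,
                    "genic_domain_id": gdid,
                    "extragenic_domain_id": edid,
                    "pair_r2": rec.pair_r2,
                    "distance_bp": distance,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "genic_domain_id", "extragenic_domain_id", "pair_r2", "distance_bp"],
    )
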