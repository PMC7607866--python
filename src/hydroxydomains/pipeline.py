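"""End-to-end orchestration of the synthetic 5hmC study.

``run_all`` wires every stage together: simulate a cohort, call per-sample
domains, build the cross-sample consensus, assign genes within TADs, score
group-specific and relapse-differential domains, run the CpG overlap null,
profile chromatin context, and compute the clinical statistics. Stage
outputs are plain files under the output directory; a machine-readable
``summary.json`` collects counts, top hits and statistics, and
``pipeline.log`` records every parameter that affects any output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .chromatin import metagene_by_expression, peak_metaprofile, state_signal_distribution
from .clinical import compare_conditions, covariate_association, dichotomized_survival, iss_trend
from .core import IntervalSet, write_bed
from .domain_gene import assign_domain_gene, domain_pair_correlation, flag_enhancer_candidates
from .domains import (
    DomainCallParams,
    call_peaks,
    consensus_domains,
    default_library_scale,
    rose_cutoff,
    score_domains,
    stitch_peaks,
    stitching_curve,
)
from .group_analysis import differential_domains, group_specific_domains
from .overlap_null import resampling_null
from .synthetic import SyntheticCohort, SyntheticCohortConfig, simulate_cohort, simulate_cpg_sets

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all", "patient_differential", "build_consensus"]


@dataclass
class PipelineConfig:
    seed: int
    outdir: str = "hydroxydomains_out"
    domain_params: DomainCallParams = field(default_factory=DomainCallParams)
    min_support: int = 2
    min_mean_rpkm: float = 1.0
    fdr_threshold: float = 0.05
    n_resamples: int = 1000
    cpg_inside_fraction: float = 0.41
    cpg_background_inside_fraction: float | None = None
    write_tracks: bool = False
    cohort_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.fdr_threshold < 1):
            raise ValueError("fdr_threshold must be in (0, 1)")
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")

    def cohort_config(self) -> SyntheticCohortConfig:
        return SyntheticCohortConfig(seed=self.seed, **self.cohort_overrides)


def build_consensus(
    cohort: SyntheticCohort,
    params: DomainCallParams,
    min_support: int = 2,
    sample_ids: list[str] | None = None,
):
    """Per-sample stitching + ranking, then the cross-sample consensus."""
    if sample_ids is None:
        sample_ids = list(cohort.tracks)
    domain_sets = []
    for sid in sample_ids:
        stitched = stitch_peaks(cohort.peaks[sid], params.stitch_distance)
        ds = score_domains(
            stitched, cohort.tracks[sid], default_library_scale(cohort.tracks[sid]), sid
        )
        if params.top_n == "auto" and len(ds) >= 2:
            _, n_super = rose_cutoff(ds.domains["signal"].to_numpy())
            if n_super:
                ds = ds.top(n_super)
        elif isinstance(params.top_n, int):
            ds = ds.top(params.top_n)
        domain_sets.append(ds)
    tracks = {sid: cohort.tracks[sid] for sid in sample_ids}
    return consensus_domains(domain_sets, min_support=min_support, tracks=tracks)


def patient_differential(
    cohort: SyntheticCohort,
    patient_id: str,
    params: DomainCallParams,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Diagnosis-versus-relapse moderated test on a per-patient consensus.

    Peaks are called on each technical replicate with the Poisson bin
    caller, stitched, and merged into a per-patient consensus (support >= 2
    of 4 replicates); the moderated t runs on the raw consensus signal of
    the four replicates.
    """
    if patient_id not in cohort.relapse:
        raise KeyError(f"no relapse pair for patient {patient_id}")
    pair = cohort.relapse[patient_id]
    reps = {}
    for cond in ("diagnosis", "relapse"):
        for i, track in enumerate(pair[cond], 1):
            reps[f"{cond}_{i}"] = track
    sets = []
    for rid, track in reps.items():
        # peak-call on 1 kb count bins: sparse per-100bp counts are below the
        # Poisson test's resolution, sums over coarser bins are not
        coarse = track.rebin(1000)
        k = 1000 // track.bin_width
        counts = {c: v * k for c, v in coarse.values.items()}
        count_track = type(track)(dict(track.chrom_sizes), 1000, counts)
        stitched = stitch_peaks(call_peaks(count_track), params.stitch_distance)
        sets.append(score_domains(stitched, track, 1.0, rid))
    consensus = consensus_domains(
        sets, min_support=2, tracks=reps, library_scales={r: 1.0 for r in reps}
    )
    if len(consensus) == 0:
        raise ValueError(f"no consensus domains for patient {patient_id}")
    # library size from signal OUTSIDE consensus domains: unbiased even when
    # most of a patient's domains move in one direction at relapse
    library_sizes = {
        rid: reps[rid].total_signal() - consensus.signal_matrix[rid].sum()
        for rid in reps
    }
    return differential_domains(
        consensus.signal_matrix,
        diagnosis=["diagnosis_1", "diagnosis_2"],
        relapse=["relapse_1", "relapse_2"],
        fdr_threshold=fdr_threshold,
        library_sizes=library_sizes,
    )


def _write_matrix(matrix: pd.DataFrame, path: Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="domain_id")


def run_all(config: PipelineConfig) -> dict:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("hydroxydomains")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    summary: dict = {"version": __version__, "seed": config.seed}
    try:
        params = dataclasses.asdict(config)
        logger.info("parameters: %s", json.dumps(params, default=str, sort_keys=True))

        cohort_cfg = config.cohort_config()
        logger.info("cohort config: %s", json.dumps(dataclasses.asdict(cohort_cfg), default=str, sort_keys=True))
        cohort = simulate_cohort(cohort_cfg)
        cohort.write(out / "inputs", write_tracks=config.write_tracks)
        logger.info("simulated cohort: %d samples", len(cohort.tracks))

        dp = config.domain_params
        first_tumor = cohort.tumor_ids[0]
        curve = stitching_curve(
            cohort.peaks[first_tumor], list(range(0, 25_001, 1250))
        )
        pd.DataFrame(curve.as_pairs(), columns=["distance", "n_domains"]).to_csv(
            out / "stitching_curve.tsv", sep="\t", index=False
        )
        summary["stitching_knee_bp"] = curve.knee

        consensus = build_consensus(cohort, dp, config.min_support)
        bed = IntervalSet(
            consensus.domains.rename(columns={"domain_id": "name", "support": "score"})[
                ["chrom", "start", "end", "name", "score"]
            ],
            flattened=True,
        )
        write_bed(bed, out / "consensus_domains.bed")
        _write_matrix(consensus.signal_matrix, out / "consensus_matrix.tsv")
        summary["n_consensus_domains"] = len(consensus)

        assignments = assign_domain_gene(
            consensus,
            cohort.expression,
            cohort.genes,
            cohort.tads,
            min_mean_rpkm=config.min_mean_rpkm,
            samples=cohort.tumor_ids,
        )
        assignments.to_csv(out / "domain_gene_assignments.tsv", sep="\t", index=False)
        assigned = assignments.dropna(subset=["r2"])
        summary["n_assigned_domains"] = int(len(assigned))
        summary["n_gene_specific"] = int(assignments["gene_specific"].sum())
        if len(assigned):
            top = assigned.loc[assigned["r2"].idxmax()]
            summary["max_r2"] = float(top["r2"])
            summary["max_r2_gene"] = top["gene_id"]

        pairs = domain_pair_correlation(consensus, cohort.tads, samples=cohort.tumor_ids)
        pairs.to_csv(out / "domain_pairs.tsv", sep="\t", index=False)
        candidates = flag_enhancer_candidates(assignments, pairs, cohort.genes)
        candidates.to_csv(out / "enhancer_candidates.tsv", sep="\t", index=False)
        summary["n_enhancer_candidates"] = int(len(candidates))

        groups = group_specific_domains(
            consensus, cohort.sample_table, fdr_threshold=config.fdr_threshold
        )
        groups.to_csv(out / "group_specific.tsv", sep="\t", index=False)
        summary["n_group_specific_calls"] = int(groups["specific"].sum())

        diff_summary = {}
        for pid in cohort.relapse:
            diff = patient_differential(cohort, pid, dp, config.fdr_threshold)
            diff.to_csv(out / f"differential_{pid}.tsv", sep="\t", index=False)
            sig = diff["significant"]
            diff_summary[pid] = {
                "n_domains": int(len(diff)),
                "n_down": int((sig & (diff["log2fc"] < 0)).sum()),
                "n_up": int((sig & (diff["log2fc"] > 0)).sum()),
            }
        summary["differential"] = diff_summary

        target, universe = simulate_cpg_sets(
            cohort.truth,
            inside_fraction=config.cpg_inside_fraction,
            background_inside_fraction=config.cpg_background_inside_fraction,
            seed=config.seed,
        )
        null = resampling_null(
            target,
            universe,
            consensus.intervals(),
            n_resamples=config.n_resamples,
            seed=config.seed,
        )
        (out / "overlap_null.json").write_text(json.dumps(null.as_dict(), indent=1))
        summary["cpg_overlap"] = null.as_dict()

        track = cohort.tracks[first_tumor]
        _, state_summary = state_signal_distribution(track, cohort.states)
        state_summary.to_csv(out / "state_signal.tsv", sep="\t", index=False)
        profile = peak_metaprofile(track, cohort.peaks[first_tumor])
        profile.as_frame().to_csv(out / "peak_metaprofile.tsv", sep="\t", index=False)
        metas = metagene_by_expression(
            track, cohort.genes, cohort.expression, samples=cohort.tumor_ids
        )
        meta_frames = []
        for label, mp in metas.items():
            f = mp.as_frame()
            f.insert(0, "class", label)
            meta_frames.append(f)
        pd.concat(meta_frames, ignore_index=True).to_csv(
            out / "metagene.tsv", sep="\t", index=False
        )

        clinical: dict = {}
        for analyte in ("mc", "hmc"):
            reduction, p = compare_conditions(cohort.sample_table, analyte)
            clinical[f"{analyte}_reduction_pct"] = reduction
            clinical[f"{analyte}_condition_p"] = p
        trend = iss_trend(cohort.sample_table, "hmc")
        trend.to_csv(out / "iss_trend.tsv", sep="\t", index=False)
        clinical["iss_II_reduction_pct"] = float(
            trend.loc[trend["stage"] == "II", "reduction_vs_I"].iloc[0]
        )
        clinical["iss_III_reduction_pct"] = float(
            trend.loc[trend["stage"] == "III", "reduction_vs_I"].iloc[0]
        )
        for cov in ("age", "sex"):
            stat, p = covariate_association(cohort.sample_table, "hmc", cov)
            clinical[f"hmc_{cov}_p"] = p
        surv, km = dichotomized_survival(cohort.sample_table, "hmc")
        clinical["survival"] = surv.as_dict()
        for label, curve_df in km.items():
            curve_df.to_csv(out / f"km_{label}.tsv", sep="\t", index=False)
        summary["clinical"] = clinical

        (out / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
        logger.info("pipeline complete: %s", out / "summary.json")
        return summary
    finally:
        root.removeHandler(handler)
        handler.close()
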