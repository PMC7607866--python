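"""Fully synthetic 5hmC cohort with planted, recoverable effects.

The generator emulates the study design every downstream stage consumes:
~5 normal plasma-cell samples and ~40 tumor samples over a small multi-
chromosome genome, with

* planted 5hmC-enriched domains (clusters of peaks with intra-domain gaps
  below the 12.5 kb stitching distance) receiving multiplicative enrichment
  over a Gamma background;
* molecular-group structure (MMSET 9 / CCND1 11 / hyperdiploid 16 / other 4)
  with group-specific gain domains, plus one CCND1 loss domain and
  normal-specific domains;
* domain-gene links inside TADs whose expression tracks the measured domain
  signal at a target squared correlation (default 0.78), and one
  genic/extragenic enhancer pair at fixed coordinates mirroring a CCND2-like
  locus (pair r² target 0.88);
* global 5mC/5hmC percentages drawn per condition/ISS stage around means
  that plant a 69% (5hmC) and 34% (5mC) tumor-versus-normal reduction and
  25%/31% stage II/III-versus-I reductions;
* exponential survival whose hazard is multiplied by ``survival_hr``
  (default 2.6) in the below-median-5hmC half, administratively censored to
  give roughly 40% events;
* four diagnosis/relapse pairs with planted fold changes and two Poisson
  technical replicates per condition.

Each output category draws from its own seeded RNG stream so adding samples
or categories never shifts the others; identical seeds give byte-identical
output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    BinnedTrack,
    ChromStateSegmentation,
    GeneModel,
    GenomicInterval,
    IntervalSet,
    TADMap,
    mean_signal,
    write_bed,
    write_bedgraph,
    write_chrom_sizes,
)

__all__ = [
    "SyntheticCohortConfig",
    "PlantedTruth",
    "SyntheticCohort",
    "simulate_cohort",
    "simulate_cpg_sets",
    "simulate_survival",
    "simulate_differential_counts",
]

_BACKGROUND_STATES = [
    ("heterochromatin", 0.40),
    ("quiescent", 0.25),
    ("polycomb_repressed", 0.15),
    ("insulator", 0.10),
    ("repetitive", 0.10),
]

# fixed CCND2-like locus: genic domain, upstream extragenic enhancer, TAD
_PAIR_GENIC = (4_278_700, 4_312_900)
_PAIR_EXTRAGENIC = (4_106_500, 4_164_700)
_PAIR_TAD = (3_850_000, 4_800_000)


def _default_genome() -> tuple[tuple[str, int], ...]:
    return (("chr1", 10_000_000), ("chr2", 10_000_000), ("chr3", 10_000_000))


@dataclass
class SyntheticCohortConfig:
    seed: int = 0
    n_normal: int = 5
    n_tumor: int = 40
    n_relapse_pairs: int = 4
    genome: tuple[tuple[str, int], ...] = field(default_factory=_default_genome)
    bin_width: int = 100
    tad_size: int = 1_000_000
    n_planted_domains: int = 80
    n_linked_domains: int = 20
    n_group_specific: int = 3  # per specificity group (MMSET, CCND1, HD, normal)
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"MMSET": 9, "CCND1": 11, "HD": 16, "other": 4}
    )
    iss_sizes: dict[str, int] = field(
        default_factory=lambda: {"I": 9, "II": 17, "III": 13, "NA": 1}
    )
    hmc_global_means: dict[str, float] = field(
        default_factory=lambda: {
            "NPC": 0.127,
            "I": 0.050,
            "II": 0.0375,
            "III": 0.0345,
            "NA": 0.040,
        }
    )
    mc_global_means: dict[str, float] = field(
        default_factory=lambda: {"NPC": 4.5, "NDMM": 2.97}
    )
    analyte_noise_sd: float = 0.10     # lognormal sigma on global levels
    survival_hr: float = 2.6
    baseline_hazard: float = 0.01      # events / month, high-5hmC half
    followup_months: float = 30.0
    domain_gene_r2: float = 0.78
    enhancer_pair_r2: float = 0.88
    enrichment: float = 8.0            # domain fold over background
    noise_sd: float = 0.4              # per-domain per-sample log2 jitter
    n_genes_per_chrom: int = 60
    n_noise_peaks: int = 3             # spurious peak calls per sample
    relapse_down_fraction: float = 0.48
    relapse_up_fraction: float = 0.04
    relapse_fold_down: float = 0.5
    relapse_fold_up: float = 2.0
    replicate_depth: float = 0.08   # sequencing-depth factor for replicates
    background_shape: float = 2.0
    background_scale: float = 1.0

    def __post_init__(self) -> None:
        if sum(self.group_sizes.values()) != self.n_tumor:
            raise ValueError("group sizes must sum to n_tumor")
        if sum(self.iss_sizes.values()) != self.n_tumor:
            raise ValueError("ISS sizes must sum to n_tumor")
        if min(self.n_normal, self.n_tumor, self.n_relapse_pairs) < 0:
            raise ValueError("sample counts must be >= 0")
        if self.n_tumor == 0:
            raise ValueError("n_tumor must be positive")
        if self.survival_hr <= 0:
            raise ValueError("survival_hr must be > 0")
        if self.n_relapse_pairs > len(self.group_sizes):
            raise ValueError("at most one relapse pair per molecular group")

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return dict(self.genome)

    @property
    def background_mean(self) -> float:
        return self.background_shape * self.background_scale


@dataclass
class PlantedTruth:
    """Ground truth of all planted effects, for recovery checks."""

    chrom_sizes: dict[str, int]
    domains: pd.DataFrame          # chrom, start, end, domain_id, role, group, gene_id
    links: pd.DataFrame            # domain_id, gene_id, target_r2
    enhancer_pair: dict | None
    relapse_folds: dict[str, dict[str, float]]
    survival_log_hr: float
    group_of_sample: dict[str, str]

    def domain_intervals(self) -> IntervalSet:
        return IntervalSet(self.domains[["chrom", "start", "end"]])

    def as_json(self) -> str:
        return json.dumps(
            {
                "chrom_sizes": self.chrom_sizes,
                "domains": self.domains.to_dict(orient="records"),
                "links": self.links.to_dict(orient="records"),
                "enhancer_pair": self.enhancer_pair,
                "relapse_folds": self.relapse_folds,
                "survival_log_hr": self.survival_log_hr,
                "group_of_sample": self.group_of_sample,
            },
            indent=1,
        )


@dataclass
class SyntheticCohort:
    config: SyntheticCohortConfig
    tracks: dict[str, BinnedTrack]
    peaks: dict[str, IntervalSet]
    expression: pd.DataFrame
    genes: list[GeneModel]
    tads: TADMap
    states: ChromStateSegmentation
    sample_table: pd.DataFrame
    relapse: dict[str, dict]
    truth: PlantedTruth

    @property
    def normal_ids(self) -> list[str]:
        return [s for s in self.tracks if s.startswith("NPC")]

    @property
    def tumor_ids(self) -> list[str]:
        return [s for s in self.tracks if s.startswith("MM")]

    def write(self, outdir: str | Path, write_tracks: bool = False) -> None:
        """Emit every input format the pipeline readers consume."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_chrom_sizes(self.config.chrom_sizes, out / "genome.chrom.sizes")
        self.sample_table.to_csv(out / "samples.tsv", sep="\t")
        self.expression.to_csv(out / "expression.tsv", sep="\t")
        write_bed(self.tads.intervals, out / "tads.bed")
        write_bed(self.states.intervals, out / "chromhmm.bed")
        gene_rows = [
            (g.interval.chrom, g.interval.start, g.interval.end, g.gene_id, 0.0, g.strand)
            for g in self.genes
        ]
        write_bed(
            IntervalSet(pd.DataFrame(gene_rows, columns=IntervalSet.COLUMNS)),
            out / "genes.bed",
        )
        peak_dir = out / "peaks"
        peak_dir.mkdir(exist_ok=True)
        for sid, pk in self.peaks.items():
            write_bed(pk, peak_dir / f"{sid}.bed")
        if write_tracks:
            track_dir = out / "tracks"
            track_dir.mkdir(exist_ok=True)
            for sid, tr in self.tracks.items():
                write_bedgraph(tr, track_dir / f"{sid}.bedgraph")
        (out / "truth.json").write_text(self.truth.as_json())


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([seed, *key])


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------

def _build_tads(config: SyntheticCohortConfig, pair_chrom: str | None) -> list[GenomicInterval]:
    tads = []
    for chrom, size in config.genome:
        bounds = set(range(0, size, config.tad_size)) | {size}
        if chrom == pair_chrom:
            lo, hi = _PAIR_TAD
            bounds = {b for b in bounds if not (lo < b < hi)} | {lo, hi}
        edges = sorted(bounds)
        for a, b in zip(edges[:-1], edges[1:]):
            if b > a:
                tads.append(GenomicInterval(chrom, a, b))
    return tads


def _pair_chrom(config: SyntheticCohortConfig) -> str | None:
    """Chromosome hosting the fixed enhancer-pair locus, if any fits."""
    for chrom, size in reversed(config.genome):
        if size >= _PAIR_TAD[1]:
            return chrom
    return None


def _domain_peaks(rng: np.random.Generator, start: int, end: int) -> list[tuple[int, int]]:
    """Split a domain span into peaks with sub-stitching-distance gaps."""
    peaks = []
    pos = start
    while pos < end - 1000:
        length = int(rng.integers(1000, 3001))
        peak_end = min(pos + length, end)
        peaks.append((pos, peak_end))
        pos = peak_end + int(rng.integers(500, 12001))
    if not peaks:
        peaks.append((start, end))
    # extend the final peak to the domain end so the stitched domain covers
    # the planted span exactly
    peaks[-1] = (peaks[-1][0], end)
    return peaks


def _place_layout(config: SyntheticCohortConfig, rng: np.random.Generator):
    """Plant domain slots, genes and the enhancer pair inside TADs."""
    pair_chrom = _pair_chrom(config)
    tads = _build_tads(config, pair_chrom)
    special = (
        GenomicInterval(pair_chrom, *_PAIR_TAD) if pair_chrom is not None else None
    )

    slots = []  # (tad_index, start, end)
    for ti, tad in enumerate(tads):
        if special is not None and tad == special:
            continue
        L = tad.length
        for frac in (0.05, 0.35, 0.62):
            off = int(frac * L + rng.uniform(0, 0.08 * L))
            length = int(min(rng.uniform(0.02, 0.05) * L, 50_000))
            if length < 4000:
                continue
            slots.append((ti, tad.start + off, tad.start + off + length))
    rng.shuffle(slots)

    groups_with_specific = [
        g for g in ("MMSET", "CCND1", "HD") if g in config.group_sizes
    ] + ["normal"]
    n_pair = 2 if special is not None else 0
    n_specific = config.n_group_specific * len(groups_with_specific)
    n_specific += 1 if "CCND1" in config.group_sizes and config.n_group_specific else 0
    n_needed = config.n_planted_domains - n_pair
    if n_needed < config.n_linked_domains + n_specific:
        raise ValueError("n_planted_domains too small for requested roles")
    if n_needed > len(slots):
        raise ValueError(
            f"infeasible config: {n_needed} planted domains exceed genome "
            f"capacity of {len(slots)} slots"
        )

    roles: list[tuple[int, int, int, str, str]] = []  # ti, start, end, role, group
    used_tads: set[int] = set()
    remaining = []
    linked = 0
    for slot in slots:
        if linked < config.n_linked_domains and slot[0] not in used_tads:
            roles.append((*slot, "linked", ""))
            used_tads.add(slot[0])
            linked += 1
        else:
            remaining.append(slot)
    if linked < config.n_linked_domains:
        raise ValueError("not enough TADs for the requested linked domains")
    it = iter(remaining)
    for g in groups_with_specific:
        for _ in range(config.n_group_specific):
            roles.append((*next(it), "group_up", g))
    if "CCND1" in config.group_sizes and config.n_group_specific:
        roles.append((*next(it), "group_down", "CCND1"))
    for slot in it:
        if len(roles) >= n_needed:
            break
        roles.append((*slot, "shared", ""))

    # genes: a dedicated zone in the 3' end of every TAD
    genes: list[GeneModel] = []
    genes_by_tad: dict[int, list[str]] = {}
    per_tad = max(1, round(config.n_genes_per_chrom * config.tad_size / max(s for _, s in config.genome)))
    for ti, tad in enumerate(tads):
        L = tad.length
        cursor = tad.start + int(0.78 * L)
        zone_end = tad.start + int(0.99 * L)
        for gi in range(per_tad):
            length = int(min(rng.uniform(5000, 15000), 0.03 * L))
            if length < 500 or cursor + length > zone_end:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"g_{tad.chrom}_{ti}_{gi}"
            genes.append(
                GeneModel(gid, GenomicInterval(tad.chrom, cursor, cursor + length, strand))
            )
            genes_by_tad.setdefault(ti, []).append(gid)
            cursor += length + int(min(rng.uniform(2000, 5000), 0.01 * L))

    # assemble domain table with peaks
    rows = []
    peaks_of: dict[str, list[tuple[int, int]]] = {}
    link_rows = []
    for ti, start, end, role, group in roles:
        chrom = tads[ti].chrom
        did = f"{chrom}:{start}-{end}"
        gene_id = ""
        if role == "linked":
            candidates = genes_by_tad.get(ti, [])
            if candidates:
                gene_id = candidates[int(rng.integers(len(candidates)))]
                link_rows.append(
                    {"domain_id": did, "gene_id": gene_id, "target_r2": config.domain_gene_r2}
                )
            else:
                role = "shared"
        rows.append(
            {
                "chrom": chrom,
                "start": start,
                "end": end,
                "domain_id": did,
                "role": role,
                "group": group,
                "gene_id": gene_id,
            }
        )
        peaks_of[did] = _domain_peaks(rng, start, end)

    enhancer_pair = None
    if special is not None:
        genic = GenomicInterval(pair_chrom, *_PAIR_GENIC)
        extra = GenomicInterval(pair_chrom, *_PAIR_EXTRAGENIC)
        target_gene = GeneModel("g_enh_target", GenomicInterval(pair_chrom, genic.start, genic.end, "+"))
        genes.append(target_gene)
        for iv, role in ((genic, "pair_genic"), (extra, "pair_extragenic")):
            did = f"{iv.chrom}:{iv.start}-{iv.end}"
            rows.append(
                {
                    "chrom": iv.chrom,
                    "start": iv.start,
                    "end": iv.end,
                    "domain_id": did,
                    "role": role,
                    "group": "",
                    "gene_id": target_gene.gene_id if role == "pair_genic" else "",
                }
            )
            peaks_of[did] = _domain_peaks(rng, iv.start, iv.end)
        link_rows.append(
            {
                "domain_id": f"{pair_chrom}:{genic.start}-{genic.end}",
                "gene_id": target_gene.gene_id,
                "target_r2": config.domain_gene_r2,
            }
        )
        enhancer_pair = {
            "chrom": pair_chrom,
            "genic_domain_id": f"{pair_chrom}:{genic.start}-{genic.end}",
            "extragenic_domain_id": f"{pair_chrom}:{extra.start}-{extra.end}",
            "gene_id": target_gene.gene_id,
            "target_r2": config.enhancer_pair_r2,
            "tad": [pair_chrom, *_PAIR_TAD],
        }

    domains = pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    links = pd.DataFrame(link_rows, columns=["domain_id", "gene_id", "target_r2"])
    tad_set = IntervalSet.from_intervals(tads, flattened=True)
    return domains, peaks_of, links, enhancer_pair, genes, TADMap(tad_set)


def _build_states(
    config: SyntheticCohortConfig,
    domains: pd.DataFrame,
    genes: Sequence[GeneModel],
    rng: np.random.Generator,
    resolution: int = 200,
) -> ChromStateSegmentation:
    labels, probs = zip(*_BACKGROUND_STATES)
    rows = []
    for chrom, size in config.genome:
        n = -(-size // resolution)
        paint = np.empty(n, dtype=object)
        pos = 0
        while pos < n:
            block = int(rng.integers(10, 101))  # 2-20 kb at 200 bp
            state = rng.choice(labels, p=probs)
            paint[pos : pos + block] = state
            pos += block
        for g in genes:
            if g.interval.chrom != chrom:
                continue
            paint[g.interval.start // resolution : g.interval.end // resolution] = "transcribed"
            t0 = max(g.tss - 1000, 0) // resolution
            t1 = min(g.tss + 1000, size) // resolution
            paint[t0:t1] = "promoter"
        for rec in domains.itertuples(index=False):
            if rec.chrom != chrom:
                continue
            paint[rec.start // resolution : rec.end // resolution] = "strong_enhancer"
        change = np.flatnonzero(paint[1:] != paint[:-1]) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [n]))
        for a, b in zip(starts, ends):
            rows.append((chrom, a * resolution, min(b * resolution, size), paint[a]))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    return ChromStateSegmentation(IntervalSet(df, flattened=True))


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(config: SyntheticCohortConfig) -> SyntheticCohort:
    """Generate the full synthetic cohort; deterministic given ``config.seed``."""
    seed = config.seed
    layout_rng = _rng(seed, 1)
    domains, peaks_of, links, enhancer_pair, genes, tads = _place_layout(config, layout_rng)
    states = _build_states(config, domains, genes, _rng(seed, 2))

    normal_ids = [f"NPC{i + 1:02d}" for i in range(config.n_normal)]
    tumor_ids = [f"MM{i + 1:02d}" for i in range(config.n_tumor)]
    sample_ids = normal_ids + tumor_ids

    clinical_rng = _rng(seed, 3)
    group_labels = np.repeat(
        list(config.group_sizes), list(config.group_sizes.values())
    )
    clinical_rng.shuffle(group_labels)
    iss_labels = np.repeat(list(config.iss_sizes), list(config.iss_sizes.values()))
    clinical_rng.shuffle(iss_labels)
    group_of = dict(zip(tumor_ids, group_labels))

    hmc = {}
    mc = {}
    for sid in normal_ids:
        hmc[sid] = config.hmc_global_means["NPC"] * np.exp(
            clinical_rng.normal(0, config.analyte_noise_sd)
        )
        mc[sid] = config.mc_global_means["NPC"] * np.exp(
            clinical_rng.normal(0, config.analyte_noise_sd)
        )
    for sid, stage in zip(tumor_ids, iss_labels):
        hmc[sid] = config.hmc_global_means[stage] * np.exp(
            clinical_rng.normal(0, config.analyte_noise_sd)
        )
        mc[sid] = config.mc_global_means["NDMM"] * np.exp(
            clinical_rng.normal(0, config.analyte_noise_sd)
        )
    failed = tumor_ids[int(clinical_rng.integers(config.n_tumor))] if config.n_tumor > 4 else None
    if failed is not None:
        hmc[failed] = np.nan
    sexes = {sid: ("F" if clinical_rng.random() < 0.5 else "M") for sid in sample_ids}
    ages = {sid: float(np.round(clinical_rng.normal(65, 8), 1)) for sid in sample_ids}

    # survival: hazard multiplied for the below-median-5hmC half
    survival_rng = _rng(seed, 4)
    hmc_t = pd.Series({sid: hmc[sid] for sid in tumor_ids})
    med = hmc_t.median()
    os_months = {}
    os_event = {}
    for sid in tumor_ids:
        low = not np.isnan(hmc[sid]) and hmc[sid] <= med
        hazard = config.baseline_hazard * (config.survival_hr if low else 1.0)
        t = survival_rng.exponential(1.0 / hazard)
        os_months[sid] = float(min(t, config.followup_months))
        os_event[sid] = int(t <= config.followup_months)

    # per-domain per-sample multipliers
    track_rng = _rng(seed, 5)
    n_dom = len(domains)
    n_samp = len(sample_ids)
    base = np.ones((n_dom, n_samp))
    jitter = 2.0 ** track_rng.normal(0.0, config.noise_sd, size=(n_dom, n_samp))
    is_normal = np.array([sid in normal_ids for sid in sample_ids])
    sample_group = np.array(
        ["normal" if sid in normal_ids else group_of[sid] for sid in sample_ids]
    )
    genic_row = extra_row = None
    for d, rec in enumerate(domains.itertuples(index=False)):
        if rec.role in ("shared", "linked"):
            base[d, :] = config.enrichment
        elif rec.role == "group_up":
            base[d, sample_group == rec.group] = config.enrichment
        elif rec.role == "group_down":
            base[d, sample_group != rec.group] = config.enrichment
        elif rec.role == "pair_genic":
            genic_row = d
            base[d, :] = config.enrichment
        elif rec.role == "pair_extragenic":
            extra_row = d
            base[d, :] = config.enrichment
    if genic_row is not None:
        rho = np.sqrt(config.enhancer_pair_r2)
        z_g = track_rng.normal(0.0, 0.6, n_samp)
        z_e = rho * z_g + np.sqrt(1 - rho * rho) * track_rng.normal(0.0, 0.6, n_samp)
        jitter[genic_row, :] = 2.0 ** z_g
        jitter[extra_row, :] = 2.0 ** z_e
    mult = base * jitter

    # gene-body signal coupled (multiplicatively) to expected expression
    expr_rng = _rng(seed, 6)
    base_log10 = {
        g.gene_id: float(expr_rng.uniform(-1.0, 2.5)) for g in genes
    }
    linked_gene_ids = set(links["gene_id"])
    for gid in linked_gene_ids:
        base_log10[gid] = np.log10(30.0)
    body_factor = {
        gid: 1.0 + 0.25 * np.log2(1.0 + 10.0 ** b) for gid, b in base_log10.items()
    }

    peak_arrays = {
        did: np.array(p, dtype=int) for did, p in peaks_of.items()
    }

    def sample_factor(s_idx: int) -> dict[str, np.ndarray]:
        w = config.bin_width
        factors = {}
        for chrom, size in config.genome:
            n = -(-size // w)
            f = np.ones(n)
            factors[chrom] = f
        for g in genes:
            f = factors[g.interval.chrom]
            f[g.interval.start // w : -(-g.interval.end // w)] *= body_factor[g.gene_id]
        for d, rec in enumerate(domains.itertuples(index=False)):
            m = mult[d, s_idx]
            if m == 1.0:
                continue
            f = factors[rec.chrom]
            for ps, pe in peak_arrays[rec.domain_id]:
                f[ps // w : -(-pe // w)] *= m
        return factors

    tracks: dict[str, BinnedTrack] = {}
    for s_idx, sid in enumerate(sample_ids):
        rng_s = _rng(seed, 7, s_idx)
        factors = sample_factor(s_idx)
        values = {}
        for chrom, size in config.genome:
            n = -(-size // config.bin_width)
            values[chrom] = (
                rng_s.gamma(config.background_shape, config.background_scale, n)
                * factors[chrom]
            )
        tracks[sid] = BinnedTrack(config.chrom_sizes, config.bin_width, values)

    # peak calls: planted peaks where the domain is enriched, plus noise peaks
    peaks: dict[str, IntervalSet] = {}
    for s_idx, sid in enumerate(sample_ids):
        rng_p = _rng(seed, 8, s_idx)
        rows = []
        for d, rec in enumerate(domains.itertuples(index=False)):
            if base[d, s_idx] > 1.5:
                for ps, pe in peak_arrays[rec.domain_id]:
                    rows.append((rec.chrom, ps, pe))
        chrom_names = [c for c, _ in config.genome]
        sizes = np.array([s for _, s in config.genome], dtype=float)
        for _ in range(config.n_noise_peaks):
            ci = int(rng_p.choice(len(chrom_names), p=sizes / sizes.sum()))
            length = int(rng_p.integers(600, 1201))
            start = int(rng_p.integers(0, int(sizes[ci]) - length))
            rows.append((chrom_names[ci], start, start + length))
        peaks[sid] = IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))

    # expression: background lognormal; linked genes track measured signal
    expression = pd.DataFrame(
        index=[g.gene_id for g in genes], columns=sample_ids, dtype=float
    )
    for g in genes:
        if g.gene_id in linked_gene_ids:
            continue
        expression.loc[g.gene_id] = 10.0 ** (
            base_log10[g.gene_id] + expr_rng.normal(0, 0.2, n_samp)
        )
    rho = np.sqrt(config.domain_gene_r2)
    mu, tau = np.log2(31.0), 1.5
    dom_iv = {
        rec.domain_id: GenomicInterval(rec.chrom, rec.start, rec.end)
        for rec in domains.itertuples(index=False)
    }
    for link in links.itertuples(index=False):
        x = np.array(
            [np.log2(1.0 + mean_signal(tracks[sid], dom_iv[link.domain_id])) for sid in tumor_ids]
        )
        z = (x - x.mean()) / x.std() if x.std() > 0 else np.zeros_like(x)
        eps = expr_rng.normal(0, 1, len(tumor_ids))
        y = rho * z + np.sqrt(max(1 - rho * rho, 0.0)) * eps
        rpkm_t = np.maximum(2.0 ** (mu + tau * y) - 1.0, 0.0)
        expression.loc[link.gene_id, tumor_ids] = rpkm_t
        expression.loc[link.gene_id, normal_ids] = np.maximum(
            2.0 ** (mu + tau * expr_rng.normal(0, 1, len(normal_ids))) - 1.0, 0.0
        )

    # relapse pairs: first patient of each group, planted fold changes,
    # Poisson technical replicates of the expected (noise-free) signal
    pair_ids = []
    for g in config.group_sizes:
        members = [sid for sid in tumor_ids if group_of[sid] == g]
        if members:
            pair_ids.append(members[0])
    pair_ids = pair_ids[: config.n_relapse_pairs]
    relapse: dict[str, dict] = {}
    relapse_folds: dict[str, dict[str, float]] = {}
    relapse_hmc: dict[str, float] = {}
    for k, pid in enumerate(pair_ids):
        rng_r = _rng(seed, 9, k)
        s_idx = sample_ids.index(pid)
        folds = {}
        for d, rec in enumerate(domains.itertuples(index=False)):
            if base[d, s_idx] <= 1.5:
                continue
            u = rng_r.random()
            if u < config.relapse_down_fraction:
                folds[rec.domain_id] = config.relapse_fold_down
            elif u < config.relapse_down_fraction + config.relapse_up_fraction:
                folds[rec.domain_id] = config.relapse_fold_up
        relapse_folds[pid] = folds
        factors = sample_factor(s_idx)
        expected_diag = {
            c: f * config.background_mean for c, f in factors.items()
        }
        expected_rel = {c: v.copy() for c, v in expected_diag.items()}
        w = config.bin_width
        for did, fold in folds.items():
            rec = dom_iv[did]
            for ps, pe in peak_arrays[did]:
                expected_rel[rec.chrom][ps // w : -(-pe // w)] *= fold
        def _replicates(expected: dict[str, np.ndarray]) -> list[BinnedTrack]:
            # Poisson resampling of the same expected counts at a realistic
            # sequencing depth: per-domain totals land near a few hundred
            reps = []
            for _ in range(2):
                vals = {
                    c: rng_r.poisson(v * config.replicate_depth).astype(float)
                    for c, v in expected.items()
                }
                reps.append(BinnedTrack(config.chrom_sizes, config.bin_width, vals))
            return reps
        relapse[pid] = {
            "diagnosis": _replicates(expected_diag),
            "relapse": _replicates(expected_rel),
        }
        relapse_hmc[pid] = hmc[pid] * (1.05 if k == 3 else 0.8)

    rows = []
    for sid in sample_ids:
        is_npc = sid in normal_ids
        rows.append(
            {
                "sample_id": sid,
                "condition": "NPC" if is_npc else "NDMM",
                "group": "normal" if is_npc else group_of[sid],
                "iss": "" if is_npc else dict(zip(tumor_ids, iss_labels))[sid],
                "sex": sexes[sid],
                "age": ages[sid],
                "mc_percent": mc[sid],
                "hmc_percent": hmc[sid],
                "os_months": np.nan if is_npc else os_months[sid],
                "os_event": 0 if is_npc else os_event[sid],
                "pair_id": sid if sid in pair_ids else "",
                "replicate": 0,
            }
        )
    for pid in pair_ids:
        rows.append(
            {
                "sample_id": f"{pid}_REL",
                "condition": "relapse",
                "group": group_of[pid],
                "iss": "",
                "sex": sexes[pid],
                "age": ages[pid],
                "mc_percent": mc[pid],
                "hmc_percent": relapse_hmc[pid],
                "os_months": os_months[pid],
                "os_event": os_event[pid],
                "pair_id": pid,
                "replicate": 0,
            }
        )
    sample_table = pd.DataFrame(rows).set_index("sample_id")

    truth = PlantedTruth(
        chrom_sizes=config.chrom_sizes,
        domains=domains,
        links=links,
        enhancer_pair=enhancer_pair,
        relapse_folds=relapse_folds,
        survival_log_hr=float(np.log(config.survival_hr)),
        group_of_sample={**group_of, **{sid: "normal" for sid in normal_ids}},
    )
    return SyntheticCohort(
        config=config,
        tracks=tracks,
        peaks=peaks,
        expression=expression,
        genes=genes,
        tads=tads,
        states=states,
        sample_table=sample_table,
        relapse=relapse,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# auxiliary simulators
# ---------------------------------------------------------------------------

def _place_points(
    rng: np.random.Generator,
    n: int,
    inside_fraction: float,
    domains: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
) -> IntervalSet:
    lengths = (domains["end"] - domains["start"]).to_numpy(dtype=float)
    if inside_fraction > 0 and (len(domains) == 0 or lengths.sum() == 0):
        raise ValueError("no planted domains to place CpGs inside")
    k = int(round(inside_fraction * n))
    rows = []
    if k:
        picks = rng.choice(len(domains), size=k, p=lengths / lengths.sum())
        for d in picks:
            rec = domains.iloc[int(d)]
            pos = int(rng.integers(rec["start"], rec["end"]))
            rows.append((rec["chrom"], pos, pos + 1))
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    if sizes.sum() < n:
        raise ValueError("CpG count exceeds genome capacity")
    dom_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in domains.groupby("chrom"):
        dom_by_chrom[chrom] = (
            sub["start"].to_numpy(),
            sub["end"].to_numpy(),
        )
    while len(rows) < n:
        ci = int(rng.choice(len(chroms), p=sizes / sizes.sum()))
        pos = int(rng.integers(0, int(sizes[ci])))
        chrom = chroms[ci]
        if chrom in dom_by_chrom:
            s, e = dom_by_chrom[chrom]
            i = np.searchsorted(s, pos, side="right") - 1
            if i >= 0 and pos < e[i]:
                continue
        rows.append((chrom, pos, pos + 1))
    return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))


def simulate_cpg_sets(
    truth: PlantedTruth,
    n_target: int = 2000,
    n_background: int = 20000,
    inside_fraction: float = 0.41,
    background_inside_fraction: float | None = None,
    seed: int | None = None,
) -> tuple[IntervalSet, IntervalSet]:
    """Target CpG set with a planted in-domain fraction, plus a universe.

    The universe is uniform over the genome by default; pass
    ``background_inside_fraction`` to construct it at a chosen in-domain
    fraction instead (e.g. to mirror an array whose CpGs overlap domains at
    a known rate).
    """
    if not 0 <= inside_fraction <= 1:
        raise ValueError("inside_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    target = _place_points(rng, n_target, inside_fraction, truth.domains, truth.chrom_sizes)
    if background_inside_fraction is None:
        rows = []
        chroms = list(truth.chrom_sizes)
        sizes = np.array([truth.chrom_sizes[c] for c in chroms], dtype=float)
        ci = rng.choice(len(chroms), size=n_background, p=sizes / sizes.sum())
        pos = (rng.random(n_background) * sizes[ci]).astype(int)
        universe = IntervalSet(
            pd.DataFrame(
                {"chrom": [chroms[i] for i in ci], "start": pos, "end": pos + 1}
            )
        )
    else:
        universe = _place_points(
            rng, n_background, background_inside_fraction, truth.domains, truth.chrom_sizes
        )
    return target, universe


def simulate_survival(
    n: int,
    hr: float,
    baseline_hazard: float = 0.01,
    followup_months: float = 30.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Two-arm exponential survival cohort (low arm hazard multiplied by hr).

    The low arm gets ceil(n/2) subjects, mirroring a median split with the
    median sample assigned low. Administrative censoring at the follow-up
    horizon yields roughly 40% events at the defaults.
    """
    rng = np.random.default_rng(seed)
    n_low = -(-n // 2)
    low = np.concatenate([np.ones(n_low, dtype=int), np.zeros(n - n_low, dtype=int)])
    hazard = baseline_hazard * np.where(low == 1, hr, 1.0)
    t = rng.exponential(1.0 / hazard)
    return pd.DataFrame(
        {
            "os_months": np.minimum(t, followup_months),
            "os_event": (t <= followup_months).astype(int),
            "low": low,
        }
    )


def simulate_differential_counts(
    n_domains: int = 500,
    n_changed: int = 50,
    fold: float = 2.0,
    mean_count: float = 200.0,
    nrep: int = 2,
    seed: int | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Domain-level Poisson replicate counts with planted fold changes.

    Returns a domains x replicates frame (columns diag_1.., rel_1..) and the
    boolean planted-change mask. Baseline rates are lognormal around
    ``mean_count``; changed domains are multiplied by ``fold`` at relapse.
    """
    rng = np.random.default_rng(seed)
    lam = np.exp(rng.normal(np.log(mean_count), 0.5, n_domains))
    changed = np.zeros(n_domains, dtype=bool)
    changed[rng.choice(n_domains, size=n_changed, replace=False)] = True
    cols = {}
    for r in range(nrep):
        cols[f"diag_{r + 1}"] = rng.poisson(lam).astype(float)
    lam_rel = lam * np.where(changed, fold, 1.0)
    for r in range(nrep):
        cols[f"rel_{r + 1}"] = rng.poisson(lam_rel).astype(float)
    frame = pd.DataFrame(cols, index=[f"dom_{i}" for i in range(n_domains)])
    return frame, changed
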