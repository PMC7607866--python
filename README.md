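# hydroxydomains

Analysis of 5-hydroxymethylcytosine (5hmC) sequencing data in plasma-cell
cohorts: calling large **5hmC-enriched domains**, linking them to the genes
they likely regulate, and relating global 5hmC levels to disease stage and
survival. The package targets the study design of a multiple-myeloma (MM)
5hmC-seq cohort — a handful of normal plasma-cell samples against ~40
newly diagnosed tumors with molecular subgroups (MMSET/t(4;14), CCND1,
hyperdiploid) and diagnosis/relapse pairs — but every component is generic
over BED/bedGraph/TSV inputs.

## What it computes

**Domain calling (ROSE-style).** Per-sample 5hmC peaks closer than a
stitching distance *d* are merged transitively into domains
(gap = `next.start − prev.end`; default *d* = 12.5 kb, selected as the knee
of the domain-count-versus-distance curve). Domains are ranked by
library-normalised aggregate signal; on the min–max-scaled ranked curve the
tangent rule (the point where the discrete slope crosses 1, as for H3K27ac
super-enhancers) separates the "super" tail. Cross-sample consensus keeps
every region supported by ≥ 2 samples and scores all samples on the
consensus coordinates.

**Domain–gene assignment.** Each consensus domain is assigned the most
correlated expressed gene within its topologically associating domain
(TAD): candidates have their TSS in the TAD of the domain midpoint and mean
expression ≥ 1 RPKM; the statistic is the squared Pearson correlation of
log2(signal + 1) versus log2(RPKM + 1) across tumor samples. Highly
correlated intra-TAD domain pairs where one member is genic and the other
extragenic are flagged as putative enhancer–gene pairs.

**Statistics.** Group-specific domains by one-vs-rest Welch tests with
Benjamini–Hochberg control; diagnosis-versus-relapse changes by a
moderated t on two technical replicates per condition (per-domain variances
shrunk halfway to the across-domain median, df = 2(nrep−1)+4); CpG-set
overlap enrichment by resampling equal-size CpG draws from an array
universe; global 5mC/5hmC levels by percent reduction + Mann–Whitney,
ISS-stage trends, and median-split survival (Kaplan–Meier, log-rank, Cox
hazard ratio of the low-5hmC half).

**Synthetic cohort.** `hydroxydomains.synthetic` simulates the entire study
— genome, signal tracks, peak calls, expression, TADs, ChromHMM states,
CpG sets, clinical table — with planted, recoverable effects (enriched
domains, R² = 0.78 domain–gene links, an R² = 0.88 genic/extragenic
enhancer pair, group-specific domains, 69%/34% global reductions,
HR = 2.6 survival). Every pipeline stage runs with no external data.

## Worked example

```python
from hydroxydomains.synthetic import SyntheticCohortConfig, simulate_cohort
from hydroxydomains.pipeline import build_consensus
from hydroxydomains.domains import DomainCallParams
from hydroxydomains.domain_gene import assign_domain_gene
from hydroxydomains.clinical import compare_conditions, dichotomized_survival

cohort = simulate_cohort(SyntheticCohortConfig(seed=1))
consensus = build_consensus(cohort, DomainCallParams(), min_support=2)
print(f"consensus domains: {len(consensus)}")

assignments = assign_domain_gene(
    consensus, cohort.expression, cohort.genes, cohort.tads,
    samples=cohort.tumor_ids,
)
top = assignments.loc[assignments["r2"].idxmax()]
print(f"best domain-gene link: {top.domain_id} -> {top.gene_id} (R^2 = {top.r2:.2f})")

reduction, p = compare_conditions(cohort.sample_table, "hmc")
print(f"global 5hmC reduction NDMM vs NPC: {reduction:.0f}% (Mann-Whitney p = {p:.2g})")

surv, _ = dichotomized_survival(cohort.sample_table, "hmc")
print(f"low-vs-high 5hmC Cox HR = {surv.hr:.2f} "
      f"[{surv.ci_low:.2f}, {surv.ci_high:.2f}], log-rank p = {surv.p:.2f} "
      f"(n = {surv.n_low}/{surv.n_high})")
```

prints

```
consensus domains: 81
best domain-gene link: chr1:390610-415298 -> g_chr1_0_2 (R^2 = 0.84)
global 5hmC reduction NDMM vs NPC: 70% (Mann-Whitney p = 1.8e-06)
low-vs-high 5hmC Cox HR = 1.16 [0.36, 3.81], log-rank p = 0.80 (n = 20/19)
```

80 domains were planted and 81 consensus regions recovered (one spurious
peak collision); the strongest link's R² of 0.84 is one cohort's estimate
of the planted 0.78; the 70% global 5hmC drop recovers the planted 69%;
and a single 39-patient cohort with ~16 events gives a noisy hazard-ratio
estimate with a wide confidence interval — exactly why the CI, not the
point estimate, is the meaningful output at this sample size.

The same pipeline is available from the shell:

```sh
hydroxydomains run-all --seed 1 --out study/
hydroxydomains simulate --seed 1 --out cohort/ --write-tracks
hydroxydomains domains --peaks cohort/peaks/MM01.bed \
    --track cohort/tracks/MM01.bedgraph \
    --chrom-sizes cohort/genome.chrom.sizes --out MM01_domains.tsv
```

`run-all` writes consensus BED + signal matrix, domain–gene assignments,
group-specific and differential tables, the CpG overlap null, chromatin
profiles, clinical statistics, Kaplan–Meier curves, a `summary.json` and a
parameter log.

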