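# Methods

## Coordinates and data containers

All intervals are 0-based half-open (BED convention); loci printed in the
literature as 1-based inclusive spans are converted on input
(`read_bed(..., one_based=True)`). Strand is retained only to derive
transcription start sites — 5hmC is an unstranded DNA mark, so every signal
operation ignores strand. Chromosome names pass through verbatim; callers
are responsible for "chr" conventions. Signal lives in fixed-width binned
tracks (default 100 bp, the resolution needed to resolve kb-scale domains;
10 kb bins for track–track correlation matrices, where finer bins mostly
add sampling noise). bedGraph records are length-weighted into bins with
uncovered bases counting as zero.

## Domain calling

Stitching merges peaks whose edge-to-edge gap is at most the stitching
distance, transitively and per chromosome, following the super-enhancer
(ROSE) convention of measuring the gap exclusive of peak lengths. The
distance is chosen from the stitching curve — domain count versus distance
— whose knee we estimate as the grid point furthest (perpendicular
distance) from the chord joining the curve's endpoints. 12.5 kb is the
default. No promoter-proximal exclusion is applied (a flag exists, off by
default): the source protocol never removes TSS peaks.

Domain score = sum of bin signal over the domain (partial bins weighted by
overlap fraction) divided by a library scale, by default total track signal
/ 1e6 (CPM-like); a spike-in-derived factor can be supplied instead. Ties
rank leftmost-first so ranks are a deterministic permutation. The
tangent cutoff sorts scores ascending, min–max scales both axes to [0, 1],
and walks from the right while the discrete slope between consecutive
points exceeds 1; the score at the stopping point is the cutoff and domains
strictly above it are "super". All-equal scores are degenerate and yield
zero super domains. On convex ranked curves this scanning rule coincides
with the exhaustive tangent construction (argmin of y − x), which the tests
use as an independent oracle.

Consensus flattens the union of all samples' domains, counts for each
flattened region the number of distinct samples contributing ≥ 1 bp, keeps
regions with support ≥ 2 (configurable), and scores every sample on the
kept coordinates. Consensus identity is the flattened coordinate span, so
each domain has a single `chrom:start-end` id. The consensus used for group
analysis includes the normal samples (their specific domains must be able
to appear); domain–gene correlation uses tumor-diagnosis columns only.

## Domain–gene assignment

A domain belongs to the TAD containing its midpoint (an any-overlap
variant is available for boundary-spanning domains). Candidate genes have
their TSS inside that TAD — the enhancer–gene pairing convention — and
mean RPKM ≥ 1 across the correlated samples. Both domain signal and RPKM
are log2(x + 1) transformed before Pearson correlation: both quantities
are heavy-tailed, and the pseudocount keeps zeros finite. The argmax-r²
gene wins; r² ties break to the nearest TSS. A gene assigned to exactly
one domain marks that domain "gene-specific". Putative enhancers are
intra-TAD pairs with pair r² ≥ 0.5 where exactly one member overlaps the
assigned gene body and the other overlaps no gene body; the reported
distance is between facing domain edges.

## Group-specific and differential statistics

Group specificity uses a two-sided Welch t-test per domain of
log2(signal + 1), one group against all other samples, with BH correction
per group across domains. Welch rather than a rank test: groups run as
small as four samples, where rank tests are degenerate. Rows with zero
variance in both groups get p = 1 (identical means) by convention. Both
directions are reported, so loss of hydroxymethylation in a group is a
first-class call.

The relapse test is a fully specified moderated t substituting for
count-model differential-binding machinery: replicates are scaled to a
common library size, log2(x + 1) transformed; per-domain pooled variances
are shrunk with equal weight toward the across-domain median and the
statistic uses df = 2(nrep − 1) + 4. Size factors matter more than the
test itself: equalising *total* domain signal forces Σ log-fold-changes
toward zero and biases every unchanged domain when changes are one-sided,
so the default factor equalises the *median* domain signal (robust while
fewer than half the domains change), and callers with access to the tracks
should pass explicit library sizes — the pipeline uses signal *outside*
the consensus domains, the only estimator that stays unbiased when most of
a patient's domains move one way (as happens at relapse, where roughly
half the domains lose 5hmC). With equal-weight shrinkage and strongly
heteroscedastic baselines the realised false-discovery proportion can
exceed the nominal BH level even when the per-domain false-positive rate
is ~1–2%; a variance-trend prior would fix this but is beyond the defined
statistic.

## Overlap null

The observed fraction of a CpG set inside flattened domains is compared
with draws of the same size from the CpG universe, without replacement
("random CpGs from the same chip"). The reported null SD is the SD of the
resample fractions; the one-sided empirical p uses the add-one rule, so
its floor is 1/(n_resamples + 1). The null mean converges to the
hypergeometric expectation (fraction of universe CpGs inside domains),
which the tests verify to 4 standard errors.

## Chromatin context

Per-state signal distributions take the per-base mean of each segmentation
interval, grouped by free-text state label. Correlation matrices rebin to
10 kb, drop bins where every track is zero (uncovered genome would inflate
r), and correlate log2(x + 1). Peak meta-profiles sample a ±5 kb window on
a 100 bp grid around peak centres, dropping peaks truncated by chromosome
edges. Metagene profiles rescale each gene body to 100 length-weighted
bins with 2 kb absolute flanks (200 bp flank bins), orient by strand, and
stratify by mean RPKM with left-closed classes [0,1), [1,10), [10,100),
[100,∞).

## Clinical statistics

Percent reduction is defined on means, 100·(mean_ref − mean_test)/mean_ref
(medians available behind a flag). Condition and stage comparisons use
two-sided Mann–Whitney (small groups, no normality assumption; a t-test is
exposed as an alternative). Survival dichotomises tumor samples at the
median analyte level with ties-low and the odd median sample assigned low
— reproducing a 20/19 split at n = 39 — then fits Kaplan–Meier curves per
group, a log-rank test, and a univariate Cox model whose hazard ratio is
oriented low-versus-high, so HR > 1 means less 5hmC, worse outcome. A
group with zero events flags the HR as unstable.

## Synthetic cohort

The generator plants every effect the pipeline is meant to recover, at the
magnitudes the study design states, over a 3 × 10 Mb genome with 1 Mb
TADs:

* **Domains.** 80 planted domains (20–50 kb) built from peaks with gaps
  uniform on [0.5, 12] kb — below the 12.5 kb stitching distance, so each
  domain stitches whole and the stitching-curve knee lands at the chosen
  distance. Background signal is Gamma(shape 2) per bin (non-negative, a
  Gaussian is not); enriched peaks multiply it 8-fold with per-sample
  log2-normal jitter (sd 0.4). Three spurious 0.6–1.2 kb peaks per sample
  emulate caller noise; their cross-sample collisions produce the ~1%
  false consensus rate.
* **Groups.** 9/11/16/4 tumors in MMSET/CCND1/HD/other plus 5 normals;
  three gain domains per group (MMSET, CCND1, HD, normal) and one CCND1
  loss domain.
* **Links.** 20 domains in distinct TADs plus one genic/extragenic pair at
  fixed coordinates inside a dedicated TAD (58.2 kb and 34.2 kb domains,
  114 kb apart). Linked-gene expression is built from the *measured*
  domain log-signal: standardised, mixed with unit Gaussian noise at
  weight √r² (target 0.78; pair latent correlation √0.88), then mapped to
  RPKM around ~30. At r² = 1 the construction is exactly affine, so the
  recovered correlation is exactly 1 — the generator's calibration is
  checked at that limit.
* **Clinical.** Global 5hmC (% of C) means 0.127 for normals and
  0.050/0.0375/0.0345 for ISS I/II/III (0.040 for unstaged) with 10%
  lognormal noise: these plant a 69% tumor-versus-normal reduction and
  25%/31% stage reductions given the 9/17/13/1 stage composition; one of
  40 tumors has a missing 5hmC measurement, so 39 enter 5hmC analyses and
  the median split is 20/19. 5mC means 4.5%/2.97% plant the 34% reduction
  with no stage effect. Survival is exponential with baseline hazard
  0.01/month, multiplied by 2.6 for the below-median-5hmC half, censored
  at 30 months (≈ 40% events, ~16 of 39).
* **Relapse.** Four pair patients (the first member of each group); 48% of
  a patient's domains get fold 0.5 and 4% fold 2.0 at relapse. Technical
  replicates are Poisson resamples of the expected (noise-free) track at a
  sequencing-depth factor of 0.08, putting per-domain replicate totals
  near 200 counts — the regime where replicate noise, not numerical
  round-off, limits detection.
* **Streams.** Each output category (layout, states, clinical, survival,
  multipliers, tracks, peaks, expression, relapse) draws from its own
  seeded RNG stream, so adding samples or categories never shifts other
  outputs, and identical seeds give byte-identical files.

What the generator does **not** emulate: read-level noise and mappability,
sequence content and CpG density, copy-number distortion of signal,
correlated biological replicate variation (replicates are pure Poisson),
batch effects, and any dependence between global MS levels and the
genome-wide track. Passing recovery tests therefore demonstrates the
pipeline's correctness and statistical calibration under the planted
model, not robustness to those real-data artefacts.

## Problem sizes and determinism

The recovery evaluation (`hydroxydomains.evaluation`, used by
`scripts/acceptance.py` and the acceptance tests) analyses twenty
independent default-size cohorts (45 samples × 30 Mb at 100 bp bins),
runs the moderated-test simulation at the 500-domain/50-changed/mean-200
design over twenty seeds, and checks Cox confidence-interval coverage over
200 simulated 39-patient cohorts — a few minutes end to end on one CPU.
Every stochastic step takes an explicit seed; the CLI requires one.

## Known limitations

* The tangent-rule scanning cutoff is defined for the convex ranked curves
  real signal produces; on non-convex curves it returns the rightmost
  slope-1 crossing.
* Domain-to-TAD assignment by midpoint ignores boundary-spanning domains
  (any-overlap mode exists but is not the default).
* The moderated t controls the per-domain false-positive rate but not
  exactly the false-discovery proportion under strong baseline
  heteroscedasticity (see above).
* No CNV-aware signal correction: copy-number gains read as 5hmC gains.
* The CpG resampling null does not match CpGs by GC or island context.
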