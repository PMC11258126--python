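# Methods

## Genomic scaffold

CpG probes are collapsed into clusters by complete-linkage agglomeration
per chromosome with an inclusive 200 bp diameter: the closest pair merges
first and merging stops when no merge keeps the maximum pairwise probe
span ≤ 200 bp (backed by `scipy.cluster.hierarchy`, which implements
exactly this rule when the dendrogram is cut at the diameter). Cluster
beta values are arithmetic means of member probes per sample. The anchor
point of a cluster for all distance computations is the floor of the mean
member position; the paper-gap choices here (inclusive boundaries,
midpoint anchor, island flag true if *any* member probe is in a CpG
island) are fixed once and used pipeline-wide.

Candidate edges connect a gene to every cluster with
|TSS − midpoint| ≤ 1 Mb (inclusive). Signed distances are strand-oriented
(negative = upstream of the promoter). `overlaps_promoter` marks clusters
within 2 kb of *any* TSS; this single promoter definition is reused by
the GAM exclusion, the loop-count enrichment, and the Hi-C analyses.
Distance ranks (−1 = nearest upstream element, +1 = nearest past the TES)
are assigned per gene separately for island and non-island clusters;
gene-body edges stay unranked.

Coordinates are 0-based internally; probe manifests are 1-based on disk
(array convention) and converted on ingest; BED/BEDPE are half-open.

## Per-cohort expression models

Genes with per-cohort expression standard deviation < 1 (sample sd,
boundary inclusive) are dropped. The elastic net is fitted with
scikit-learn coordinate descent. Unpenalized sample-type intercepts are
handled exactly by group-centering: minimizing the objective over the
intercept block reduces it to the penalized problem on group-centered
`y` and `X` (Frisch–Waugh), after which the intercepts are the group
means of the linear residual. Predictors are standardized internally for
the penalty; coefficients are reported on the original beta-value scale,
so a coefficient is the expression change for a full unmethylated →
methylated switch.

`(λ, α)` are chosen to minimize mean CV error over α ∈ {0.1, …, 1.0}
with an automatic 30-point λ path per α (30 rather than a longer path is
a resolution choice: planted-network recovery is identical at 50).
Folds are stratified by sample type when present and seeded, so fits are
deterministic and permutation-exchangeable. The out-of-fold
`R² = 1 − CV-MSE / Var(y)` may be negative; it is clipped at zero only
when used as a consensus weight. A cohort must have ≥ 100 complete
paired samples; samples with any missing value are dropped.

## Consensus, scores, potential

Consensus coefficients are weighted means over the cohorts in which the
gene was modelled (zero when modelled but unselected; missing when the
gene failed the variance filter), with weights `max(R², 0)`. Robustness
counts cohorts with a nonzero coefficient; edges nonzero nowhere are
dropped, as are edges whose weighted coefficient cancels to exactly zero
(opposite signs across cohorts) — they carry no effect size to score.

The contribution score uses the natural log; its denominator runs over
the gene's retained consensus edges while `k_g` is the *full* candidate
count, so a gene with one association among 400 candidates scores
`ln 400`. The distance trend is a Gaussian GAM with a cubic B-spline
basis (≤ 20 basis functions), penalty weight selected by GCV
(statsmodels `select_penweight`); distance is rescaled to [0, 1] before
fitting because the curvature penalty scales with the cube of the
predictor range, and the fitted curve is re-centered so training
residuals average exactly zero. Outside the training range `f` is
clamped to its boundary values, which lets the potential sum run over
*every* edge, including the gene-body/promoter edges excluded from the
fit. With fewer than 50 usable training edges `f` falls back to a
constant with a warning.

## Hubs and enrichment

Hub calling sorts potentials descending and thresholds at the point of
maximum perpendicular distance from the chord joining the curve's
endpoints, ties toward the stricter threshold; an exactly linear curve
has no elbow, so the threshold falls back to the midpoint with a
low-confidence warning. Enrichment of potential across chromatin states
is an OLS on state indicators against a "Low Signal" reference (equal to
group-mean differences on balanced designs); TF-binding enrichment is a
single joint regression over possibly-overlapping factor indicators with
perfectly collinear factors dropped; loop-count enrichment removes
promoter-overlapping elements first and bins counts into
0 / 1 / [2,4) / [4,13) / [13,209), counts above the top bound clamped
into the top group. Hub-vs-non-hub enrichment is a logistic regression
restricted to elements with positive potential, with a ridge-penalized
fallback under complete separation.

## Survival

Per element, a Cox proportional-hazards model with cohort-stratified
baseline hazard, Efron tie handling, and a varying slope: the
methylation effect is sum-to-zero deviation-coded across cohorts, so the
main coefficient is the mean effect across cohorts and per-cohort
effects are deviations around it (treatment coding would instead report
the reference cohort). Analysis elements exclude the bottom variance
quartile; all hubs passing that filter plus a seeded random draw of
non-hubs enter. Hub and non-hub elements are compared by a two-sided
continuity-corrected Wilcoxon rank-sum test on |mean effect| — absolute
values because hazard effects of either sign indicate clinical impact.
P-values across elements are Benjamini–Hochberg adjusted.

## Chromatin-loop concordance

Loops are half-open BEDPE anchor pairs at 5 kb resolution; only
associations ≥ 10 kb (twice the anchor size) are informative. An
association overlaps a loop when one anchor intersects the element
interval and the other intersects the promoter window (TSS ± resolution);
anchor order is irrelevant. Overlap probability is reported per score
decile via a saturated logistic model (Wilson interval when a bin is
single-class). For hub prediction the genome is tiled at the anchor
resolution, bin potential sums the member clusters' potentials, and
bins with ≥ T loops are positives in an ROC/AUC sweep over
T ∈ {1, 2, 3, 5, 8}; an optional promoter-only restriction counters the
promoter-capture bias of the assay.

## Perturb-seq deconvolution

Because cells carry multiple guides, all guide indicators enter one
linear model per gene (intercept included); on disjoint designs each
coefficient reduces exactly to carrier-mean minus no-guide-baseline-mean.
Per-coefficient t-tests use empirical-Bayes moderation: residual
variances are shrunk toward a scaled inverse-chi-squared prior whose
scale and degrees of freedom are estimated from the distribution of
log-variances across genes (moment matching with digamma/trigamma
corrections, Newton solve for the prior df); a plain-OLS mode exists for
oracle checks. BH adjustment pools all tested (guide, gene) pairs;
calls use adjusted p < 0.05. Non-targeting guides are modelled (they
absorb delivery effects) but never validate a region. Testable genes
must lie within 1 Mb of a targeted region and exceed a mean normalized
expression of 0.0002 (strict). The bootstrap null permutes each guide
column of the detection matrix independently — per-guide detection
totals are conserved — refits, recounts validated regions, and reports
`p = (1 + #{null ≥ observed}) / (1 + B)`. This p is *valid*
(P(p ≤ t) ≤ t) but, because the count statistic is discrete and
concentrated at zero under a global null, it is super-uniform rather
than uniform there: with well-calibrated per-pair tests, BH keeps the
probability of any null discovery near the FDR level, so ~95% of global-
null datasets observe zero validated regions and receive p = 1. A
Kolmogorov–Smirnov uniformity check against the continuous uniform will
therefore reject under the global null by construction; the calibration
property that can and does hold is type-I validity at conventional
levels.

## Synthetic data

The generator emulates the study conditions end to end on one synthetic
chromosome (default 20 Mb, 40 genes, 600 CpG clusters, 3 cohorts of 150
samples, 80% tumor). Probe groups are spaced far beyond the cluster
diameter so the planted partition is recoverable exactly. True edges are
sampled on the candidate adjacency with probability
`0.25 · exp(−d / 200 kb)`, half shared across cohorts ("core") and half
cohort-specific; effect sizes |β| ∈ [1, 2] with 70% activating
(negative); five hub clusters get core edges to their six nearest genes.
Beta values follow a bimodal mixture (Beta(1,10) vs Beta(10,1) states
with cluster-specific state probability), expression follows the planted
linear model with Gaussian noise (sd 0.5) and a tumor intercept shift of
2 — large enough that genes with planted edges typically pass the sd ≥ 1
filter, as strongly regulated genes do in real cohorts. Loops are
anchored on strong planted edges with probability 0.8 (else random
pairs); survival times are exponential with log-hazard proportional to
mean hub methylation and independent censoring; the perturb-seq screen
gives each guide ~25 cells with a 30% multi-guide rate and knocks
predicted targets down by 30% in carriers. Each sub-generator draws from
its own RNG stream split from the master seed, so adding one data type
never perturbs another.

What the generator does *not* emulate: copy-number and purity artifacts,
batch effects, probe-level noise and cross-reactivity, correlated
co-methylation beyond the cluster scale, dropout and library-size
variation in the single-cell data. Passing tests therefore demonstrate
correctness of the inference machinery under the assumed generative
structure, not robustness to those real-data artifacts.

## Problem sizes and numerics

Tests and the acceptance script run the study at desk scale (hundreds of
clusters, tens of genes, 3–5 cohorts; bootstrap B = 200–500 with the
20,000-replicate default reserved for real analyses). Degenerate inputs
are contracts, not crashes: all-constant designs give intercept-only
fits, empty manifests give empty cluster maps, eventless strata are
dropped with a warning, complete separation falls back to a penalized
logistic fit, and an elbow-less potential curve yields a low-confidence
midpoint threshold.
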