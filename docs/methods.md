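# Methods

This note records what the pipeline computes, the modeling choices
behind the synthetic study, and what the tests do and do not
demonstrate.

## Quantification model and filtering

LFQ intensities are treated as non-negative with **zero ≡ not
detected** (the convention of label-free output tables); "quantified in
all samples" therefore means nonzero everywhere.  The three
major-protein criteria are applied per protein: ≥ 2 unique peptides;
nonzero intensity in every sample; CV = 100·sd/mean < 100% within every
stage, with the sample (n−1) standard deviation on **linear**
intensities — the standard CV definition; a `cv_on_log` switch is
provided because the scale is a genuine modeling choice for LFQ data.
Gene collapse keeps the protein with the highest total signal; exact
ties go to the lexicographically smallest protein id so outputs are
deterministic.  "All ages" means every stage present in the metadata,
so the same rule covers the 4-stage mouse design and the 5-age marmoset
design unchanged.

Stage-specific proteins must be detected in *every* replicate of at
least one stage and *no* replicate of at least one other.  Grouping is
by the location of the fully-detected stages: among the earliest two →
Young, among the latest two → Adult; proteins fully detected at both
ends (or only in middle stages) remain stage-specific but join neither
group.  This deliberately allows the Young + Adult counts to fall short
of the stage-specific total.

## Trajectory clustering

Clustering operates on per-protein **stage means of relative
abundance** (each protein scaled to mean 1 across samples), not on
per-sample values: replicate noise should not shape trajectory
membership.  The cluster count is chosen by a fixed, deterministic
panel of five validity indices — silhouette, Calinski–Harabasz,
Davies–Bouldin, the within-SS elbow (maximum discrete curvature of the
WSS curve), and the gap statistic (uniform reference in the feature
box, B = 10, Tibshirani's one-standard-error rule) — each nominating
one k in 2..8, majority vote, ties toward smaller k.  A fixed small
panel replaces larger index-voting suites for reproducibility; on
structureless data the vote carries no signal, so a weak-silhouette
(< 0.25) warning is the real contract there, and all-identical input
short-circuits to k = 1 with a warning.  K-means uses k-means++ with 50
restarts and a fixed seed; clusters are relabelled by the slope of
their centroid against stage index so cluster 1 is always the most
decreasing and cluster k the most increasing trajectory, making labels
stable across seeds for separated data.

PCA ordinates samples with proteins as variables, mean-centred, no
additional scaling — the input is already relative abundance, so
per-protein variance differences are meaningful.

## Differential expression

The across-stage test is **Welch's** one-way ANOVA (the
unequal-variance form; it is the default of the R function this kind
of analysis conventionally uses), computed on raw linear intensities;
both the classical equal-variance form and a log2 scale are exposed as
switches because neither choice is forced by the data model.  Zero
within-group variance is guarded: identical group means give p = 1,
separated means with zero variance give the smallest positive float.
BH adjustment is the statsmodels step-up implementation, validated
against a brute-force oracle to 1e-12.  DE requires q < 0.05 **and**
max fold change > 1.5; DDP/DIP labels then follow cluster membership,
and DE proteins in intermediate clusters are counted but unlabelled.
The late marmoset comparison (2 vs 24 months, n = 2 per age) makes no
significance claim: it applies a strict > 2-fold rule to the ratio of
means, with boundary ratios assigned to neither side.

## Cross-species cascade

"Protein change correlates with mRNA change in both datasets" is
operationalized as **per-gene sign concordance** of the mRNA log-ratio
(adult vs. the earliest shared postnatal timepoint) with the protein
group, in every dataset; a thresholded contribution to a set-level ρ
would be an alternative reading, but ρ is a property of the set, not
of a gene.  The primate filters use the perinatal ratio
R = mean(postnatal)/mean(prenatal); R = 1 exactly is excluded from
both directions.  Genes with any zero abundance are removed before
ratio analyses (the log-ratio is undefined there).  Homolog matching
joins on exact identifier first with a case-insensitive symbol
fallback; unmapped genes are counted and warned about, never silently
dropped.  All correlation statements use Spearman's ρ with average
ranks, so they are invariant under monotone transforms.

## Turnover kinetics

The lag between an mRNA step and the new protein steady state is
modelled with the minimal first-order synthesis–degradation equation
dP/dt = k_s·m(t) − k_d·P with k_d = ln2/t½ (days).  For an
instantaneous fold-change step the closed form is
P(t) = P∞ + (P0 − P∞)·e^(−k_d(t−t0)), normalized so P0 = 1 and
P∞ = fold.  Two consequences are used as self-tests: the half-time of
the transition equals the half-life, and the time to traverse a
fraction f of the change is t½·log₂(1/(1−f)).  No gene-level rate
fitting is attempted; the module quantifies the lag argument, nothing
more.

## Enrichment

Gene-set tests are one-sided Fisher exact tests (enrichment
alternative) on the 2×2 table against an explicit background, BH
across sets with the same adjustment function as the DE module.  Odds
ratios are the sample ad/bc, with the Haldane +0.5 correction applied
only when a cell is zero and only for display — p-values always come
from the exact conditional distribution.  Because exact conditional
p-values are discrete and super-uniform, calibration is checked via
the randomized-p transform (exactly uniform under the null) plus
super-uniformity at fixed levels.  Web enrichment services' p-value
variants are not re-derived; external annotation semantics enter only
as ordinary GMT sets.

## The synthetic study

The generator plants, per protein: a base log2 intensity ~
Normal(20, 2) (a realistic LFQ dynamic range), a trajectory class
(decreasing/flat/increasing, defaults 15%/70%/15%), a monotone
log-linear stage-mean ramp of total ±1.5 log2 units for the non-flat
classes, log-normal replicate noise at 20% CV, and 5% stage-specific
proteins structurally detected only in the first (Young) or last
(Adult) stage.  Non-structural missingness is logistic in log2
intensity (missing-not-at-random, midpoint 12, steepness 1 — dropout
is rare above the midpoint, so it mainly removes low-abundance
proteins).  The study-scale design constants — 4 stages × 4 replicates
at 2/3/6/12 weeks for mouse, 5 ages × 2 replicates at 0–24 months for
marmoset — are the defaults.  Real LFQ dropout mechanisms are rarely
characterized; logistic-MNAR is a modeling assumption of the
generator, not a claim about any particular dataset.

Cognate mRNAs execute a steep sigmoidal step of the same sign and
magnitude, centred `mrna_lead_timepoints` (default 2) grid indices
*earlier* than the protein change; for the primate-like courses the
step falls before the birth marker, reproducing the perinatal switch.
Half-lives are log-normal (median 9 days, log-sd 0.8, the scale of
measured neuronal proteome turnover).  The ASD table draws log-ratios
from a Gaussian copula on the realized human perinatal log-ratio with
the Pearson parameter 2·sin(πρ_s/6), the exact bivariate-normal
relation between Spearman and Pearson correlation, so a planted
ρ = −0.48 is recovered without tuning; planted ASD-DE genes (30%, the
strongest changes) receive p < 0.05.  One integer seed drives
everything through documented `seed + k` offsets per output, and
written datasets are byte-identical across runs.

What the generator does **not** emulate: peptide-level structure,
between-run normalization artifacts, correlated noise across proteins,
partially concordant mRNA (every non-flat gene's mRNA agrees by
construction at low noise), and real homolog ambiguity (identifiers are
shared across the synthetic species).  Passing recovery tests therefore
demonstrates that the machinery is correct and well-calibrated under
the planted model, not that real datasets will yield any particular
counts.

## Problem sizes and numerical choices

The default study is 2000 proteins — large enough for stable cluster
and FDR behavior, small enough that the full pipeline runs in seconds;
the bundled test fixture uses 200.  The null-FDR check uses 20
all-flat studies of 2000 proteins.  Oracle comparisons cover 1000
random p-vectors (BH) and every 2×2 table with grand total ≤ 50
(Fisher), both at 1e-12.  End-to-end label recovery is measured
against *all* planted non-flat proteins, so filter losses (dropout,
single-peptide low-abundance proteins) count against recall; the
filtered-universe recall is reported alongside.  Degenerate inputs are
decided, not left to chance: empty filter results warn rather than
fail, ratio boundaries are excluded by strict inequalities, and the
smallest representable float stands in for p = 0.

## Known limitations

Exact reproduction of real-data counts (retained proteins, cluster
sizes, group cardinalities) depends on upstream search-engine output,
homolog tables and the authors' exact index panel and k-means settings,
none of which are part of this package; the pipeline reproduces the
*rules*, and its quantitative guarantees are stated over the synthetic
model where truth is known.  The kinetic model is deliberately minimal
(no translational regulation, no localization dynamics), and the local
Fisher enrichment is not a substitute for the semantics of curated
pathway tools — it consumes whatever gene sets the user supplies.
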