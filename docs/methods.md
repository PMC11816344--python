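# Methods

This note records the statistical model behind each stage, the defaults and
their rationale, what the synthetic generator does and does not emulate, and
the numerical choices a maintainer should know about.

## Survival primitives

**Kaplan–Meier / log-rank.** `km_fit` and `log_rank` wrap lifelines
(product-limit estimate with right censoring; samples censored at an event
time are counted at risk for that time; 1-df chi-square log-rank).  The
`KMCurve` container exposes a right-continuous step accessor and its left
limit, which the ROC weighting below needs.

**Cox proportional hazards.** `cox_fit` is an in-package Newton–Raphson
maximizer of the partial likelihood with Efron's tie correction and Wald
inference.  It is implemented here rather than delegated because the screen
fits it tens of thousands of times (one or more fits per gene per cohort)
and per-fit overhead dominates at that scale; when event times are distinct
(the generic case for continuous follow-up — ties among *censored* times,
e.g. at an administrative horizon, are handled by ordering censored samples
into the risk set) the score and information reduce to cumulative sums and
the fit costs microseconds.  Agreement with lifelines to ~1e-4 in
coefficients and standard errors, with and without ties, is enforced by the
test suite, and a 1-covariate grid-search oracle pins the maximizer at
small n.  A monotone likelihood (a group with zero events) is reported as
`converged=False` with the coefficient clamped at |β| ≤ 15, never as a
silent large number.

**Time-dependent ROC.** `survival_auc` is the cumulative-case /
dynamic-control estimator at a fixed horizon: cases are subjects with an
observed event by the horizon weighted 1/Ĝ(Tᵢ⁻), controls are subjects
still at risk past it weighted 1/Ĝ(t), where Ĝ is the Kaplan–Meier estimate
of the censoring distribution.  AUC is the weighted two-sample
concordance (ties credited ½), which equals the trapezoid area of the
weighted ROC.  Under zero censoring it reduces exactly to the empirical
ROC of "event by horizon" vs the marker, which is how the tests oracle it;
it also agrees with scikit-survival's cumulative/dynamic AUC on censored
data.  The screening horizon is fixed at 36 months.

## Cutpoint dichotomization

The event label for cutpoint selection is the OS event indicator over the
full follow-up (the simplest reading of an "ROC of OS data"; the 36-month
time-dependent gates are applied later as their own filter, so both readings
of "survival ROC" are exercised in the chain).  Candidate thresholds are
midpoints between consecutive distinct values; the group-size constraint is
n_high, n_low ≥ ⌈0.2·n⌉; ties in J are broken toward the threshold closest
to the median expression, and exact distance ties toward the lower
threshold, making the choice deterministic.  The 50-resample bootstrap is a
stability report, not part of selection; an aggregation variant (median of
resample optima) is available as `select="bootstrap-median"`.  The selection
is invariant under strictly increasing transforms of expression.

**Cutpoint optimism.** Because the threshold maximizes association with the
event label, downstream tests on the dichotomized group are anticonservative
under the null: the univariate Cox stage rejects ~12–13% of null genes at
α=0.05 instead of 5% (the classic maximally-selected-statistic inflation;
no correction is applied, mirroring the screen's design).  The package's
robustness argument is therefore *not* per-stage type-I control but the
compounding of filters plus the dual-cohort intersection: the measured null
full-chain pass rate is ~0.5% per cohort, and the expected null cross-cohort
intersection over 500 genes is ≪ 1 (tested).  A companion test verifies
that the same Cox machinery is exactly nominal on a pre-specified median
split, isolating the inflation to cutoff optimization.

## Power filter

Schoenfeld's formula for a binary covariate, power = Φ(√(d·p(1−p))·|log HR|
− z₁₋α/₂), evaluated per endpoint at the observed event count d, observed
high-group proportion p, and the univariate HR estimate; both endpoints must
reach 80%.  α = 0.05 two-sided throughout.  The formula is symmetric in
HR ↔ 1/HR and equals α/2 at HR = 1.  It agrees with Monte-Carlo Wald-test
power (exponential PH simulation, d = 60, p = 0.5, HR = 2.5, 5000
replicates) within ~2.5 percentage points; the formula's small upward bias
at strong effects is expected from its asymptotic derivation.

## Association tables

Fisher's exact test with the probability-ordering two-sided rule; r×c
tables use the Freeman–Halton generalization by full enumeration over
margin-preserving tables (log-space hypergeometric probabilities, a 1+1e-7
relative slack absorbing float ties).  Missing categorical values form an
explicit "Unknown" level that participates in the test like any other level
— this choice is what reproduces the reference tables' printed p-values.
Mann–Whitney is exact for tie-free samples up to n = 20 per group,
otherwise the tie-corrected normal approximation.

## Enrichment and redundancy

Genes are ranked by Spearman correlation with the index gene (average ranks
for ties; constant genes get correlation 0 with a warning; the index gene is
excluded from its own ranking).  The enrichment score is the signed maximum
deviation of the weighted KS-type running sum (hits advance by
|metric|^w normalized over hits, default w = 1 with w = 0 giving the classic
KS form; misses retreat by 1/(N−Nh)).  Significance uses a gene-label
permutation null — the standard preranked analogue of phenotype
permutation — with the +1-corrected one-sided p against the observed sign,
cached per set size, and Benjamini–Hochberg FDR across sets.  Null p-values
are verified uniform by KS test.  Cross-cohort "common enrichment" requires
FDR q < 0.05 in every cohort with the same ES sign.  Redundancy clustering
converts meet–min similarity (|A∩B|/min(|A|,|B|)) to distance 1−s and
applies average-linkage agglomeration, cut at a requested k or height.

## Subtype-score clustering and cell-score comparison

K-means (10 restarts, seeded) for k = 2…6 on the four subtype score
columns, k chosen by maximal mean silhouette; the cluster with the highest
mean CIN score is labeled MSI-CIN.  Scores are used on their native scale by
default: the four scores come from one classifier on a common scale, and
z-scoring a column that carries genuine cluster structure inflates its
scale estimate and shrinks exactly the separation being sought (a 5σ
bimodal CIN column standardizes to ~1.9σ, at which point silhouette prefers
partitioning noise).  `standardize=True` remains available for
heterogeneous score tables.  Cell-score matrices are compared column-wise
between expression groups by two-sided Mann–Whitney with direction from the
median difference; a signature is "common" when p < α in every cohort with
one direction.  As in the screen, no across-column multiplicity correction
is applied; the cross-cohort intersection is the control device.

## Synthetic cohort generator

Two independent cohorts (default n = 68 each, the size of the reference
design; larger sizes configurable) sharing gene identifiers.  Null genes
are Gaussian with gene-level means U(2,12) and SDs U(0.3,1.5) on a
log2-like scale, independent of survival.  Planted genes are two-component
Gaussian mixtures (low mean 6, separation 2, within-component SD 0.5 — a
4σ split with a recoverable midpoint threshold) whose high component
multiplies the hazard by the configured HR.  Survival is exponential
proportional hazards (the simplest PH-consistent baseline; the screen
assumes nothing beyond PH) with baseline 0.005 events/month, i.e. ~74%
5-year survival in the low-risk group, matching the favorable prognosis of
the MSI gastric-cancer population the generator emulates.  DFS is OS ×
U(0.5,1) for relapsing samples and equals the censored OS time otherwise —
a stand-in coupling chosen because the reference design analyzes both
endpoints without specifying their joint law; it makes DFS informative and
correlated with OS, which is all the screen requires.  Censoring is
administrative at the 120-month horizon plus independent uniform dropout;
the dropout fraction has a closed form calibrated to the target censoring
rate, which is attainable only above the administrative floor
(mean exp(−rate·horizon) ≈ 0.55 for null cohorts at the defaults); below
the floor the generator warns and applies no dropout.  Clinical covariates
are drawn independently of the planted genes (non-confounding by
construction) with frequencies shaped like MSI gastric-cancer tables.  All
randomness flows from one seed through per-cohort substreams; the same
seed reproduces the pair bit for bit.

What the generator does **not** emulate: microarray-vs-RNA-seq platform
effects, batch effects, gene–gene correlation among null genes, confounded
covariates, MSI mutational processes, or informative censoring.  Passing
tests therefore demonstrate the screen's operating characteristics under
clean PH data with independent nulls — they do not certify behavior under
correlated transcriptomes or confounding.

## Problem sizes used in tests and the acceptance script

Screen recovery runs 2 cohorts × 200 samples × 500 genes × 20 seeds
(planted HR 3.5, censoring target 0.3) and the same again with no planted
genes; null calibration uses ~1000 null genes at n = 68; the power
simulation uses 5000 replicates at 60 events; enrichment calibration uses
200 random sets against 1000 permutations on an 800-gene ranking.  These
sizes make the full suite run in minutes while keeping every Monte-Carlo
margin comfortably wider than its standard error.

## Known limitations

- Wald inference throughout; likelihood-ratio or score tests are not
  exposed.
- The Freeman–Halton enumeration is exponential in table size; it is meant
  for clinical characteristic tables (a handful of levels), not large
  sparse tables.
- The time-dependent ROC assumes censoring independent of the marker
  (standard for KM-weighted estimators).
- `ClusterAssignment` silhouette selection can be unstable when no real
  cluster structure exists; k is still reported, so inspect the silhouette
  profile before interpreting MSI-CIN labels.
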