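# Methods

This note documents the statistical machinery implemented in `stresstypo`,
the choices made where the design was genuinely open, and what the synthetic
cohorts do and do not demonstrate.

## Cohort model and cleaning

A cohort is a flat table of respondents in which every variable carries a
declared measurement level (`nominal`, `ordinal`, `numeric`); ordinal
categories are listed in the order the analysis must preserve.  Cleaning is
listwise: a record is dropped when any field is missing ("incomplete") or
when a numeric value falls outside its configured plausibility range
("unrealistic"; defaults such as glucose 40–500 mg/dL or height 120–220 cm
are ordinary clinical sanity bounds and are config-overridable).  No
imputation is performed.  Standardization uses the sample SD (n−1 in the
denominator), the convention of descriptive cohort tables; a `ddof` flag
exposes the population convention.

## Clinical derivations

* **Friedewald LDL** (mg/dL): `LDL = TC − HDL − TG/5`, undefined at
  triglycerides ≥ 400 mg/dL (the standard validity bound of lipid
  practice).  The relation is linear, so batch means map through it.
* **MET-minutes/week**: per intensity category, multiplier × minutes/day ×
  days/week, with multipliers walking 3.3, moderate 4.0, vigorous 8.0 (the
  standard convention of validated activity questionnaires); total is the
  sum.
* **ATP III metabolic syndrome**: five criteria — blood pressure ≥ 130/85
  mmHg (systolic OR diastolic), triglycerides ≥ 150 mg/dL, HDL < 40/50
  mg/dL (male/female), fasting glucose > 100 mg/dL, waist > 102/88 cm
  (male/female).  Three or more criteria is the syndrome, one or two is
  preclinical, none is normal.  The glucose cut is implemented as the
  strict "> 100" rather than the alternative ≥ 110 convention.

## Nonlinear PCA with optimal scaling

Mixed measurement levels are handled by replacing the categories of every
qualitative variable with metric quantifications, fitted jointly with the
respondent scores by alternating least squares:

* object scores `X` (N×p) are kept centered with `X'X = N·I`;
* each variable's transformed column `t_j` is normalized to mean 0,
  variance 1 (variable-principal normalization), so the loadings
  `a_j = X' t_j / N` are plain correlations between dimensions and scaled
  variables;
* nominal variables are quantified by the centroid principle (category
  value = mean projected score of its members); ordinal variables pass the
  same targets through weighted monotone regression
  (pool-adjacent-violators, weights = category frequencies, ties pooled by
  weighted mean), so quantifications never decrease in the declared
  category order; numeric variables stay fixed at their z-scores.

Each sweep conditionally minimizes the least-squares loss
`Σ_j ‖X − t_j a_j'‖² / (N·m)`; the object-score update is the orthogonal
Procrustes projection of `T A / m`.  The loss trace is asserted
nonincreasing at every iteration.  Convergence: relative loss change below
1e-6, cap 500 iterations.  Initialization is deterministic (classical PCA
of the integer-coded, z-scored data); a seeded random start is available.

On convergence the dimensions are rotated to the principal axes of the
transformed data, which makes the identities exact: `λ_d = Σ_j a_jd²`
equals the d-th eigenvalue of the correlation matrix of the transformed
columns, per-dimension VAF is `100·λ_d/m`, and with all-numeric input the
fit reproduces classical PCA of the z-scored matrix.  Signs are fixed so
the largest-|loading| variable of each dimension loads positively.

Two internal-consistency summaries are provided: the eigenvalue-based
Cronbach alpha `m(λ−1)/((m−1)λ)` (applied to the eigenvalue sum for the
multi-dimension total), and the classical covariance-based alpha for item
batteries with/without an indicator.  Loadings with |a| ≥ 0.4 are flagged
essential, below it negligible.

Spline transforms, optimal scaling under missing data, and supplementary
variables are out of scope.

## Typology construction

Classification runs on six z-scored variables: the stress, control,
activity, smoking and alcohol indicators plus reported absenteeism.

* **k-means with random starts**: each start seeds the k centroids with k
  distinct respondents drawn at random without replacement, then iterates
  assignment/centroid updates to a fixed point (cap 300); the minimum
  within-deviance partition over all starts is kept, which removes the
  algorithm's dependence on row order.  A cluster emptied during iteration
  is re-seeded with the point farthest from the centroid of the largest
  cluster.  With a fixed seed, restart sequences are prefix-nested, so the
  best deviance is nonincreasing in the number of starts.
* **Calinski-Harabasz selection**: `CH = (B/k) / (W/(N−k))` — the
  deviance-ratio degrees-of-freedom convention, with the textbook `k−1`
  numerator available behind a flag.  The scan covers k = 2..15 by
  default; when several k fall within 0.5% of the maximum they are
  reported as near ties and the larger k is selected by default
  (`prefer_larger_k`), favoring the finer, more interpretable partition.
* **Outlier screening**: clusters of size ≤ max(1, 1% of N) whose exact
  membership recurs in the best solutions for ≥ 3 consecutive k values are
  declared outliers (both defaults configurable; exact-membership
  stability is the implemented criterion).  The pipeline removes them,
  restandardizes the remaining rows, and only then scans k and fits the
  final partition.

## Association profiles

Typologies are cross-classified against external categorical variables.
Within-typology percentage distributions are compared with total
percentages (which equal the count-weighted means of the within-typology
ones).  An overall Pearson chi-square test (no continuity correction) is
followed by cellwise adjusted Pearson residuals
`(O − E) / sqrt(E (1 − r/n)(1 − c/n))`, asymptotically standard normal
under independence; cells are flagged at |APR| ≥ 2, 3, 3.5 (two-tailed
P = .046, .003, < .001).  No multiple-testing correction is applied across
cells — raising the per-cell threshold to 3.5 plays that role — though a
Bonferroni option exists.  Cells with expected count < 1 trigger a
warning.

## Validation battery

Group differences are only called *sufficiently revealing* when parametric
and nonparametric procedures agree at α = .05.  For two groups: one-way
ANOVA plus Mann-Whitney (exact enumeration for untied samples of ≤ 20,
tie-corrected normal approximation otherwise) and two-sample
Kolmogorov-Smirnov; the default rule is ANOVA AND at least one
nonparametric test, with a strict all-three mode behind a flag.  For k
clusters: per-variable ANOVA and Kruskal-Wallis; one-way MANOVA with
Wilks' lambda (Rao's F approximation) and the Hotelling-Lawley trace
(McKeon's F approximation — the SAS/statsmodels conventions, verified
against statsmodels to 1e-8); and all k(k−1)/2 pairwise squared
Mahalanobis distances `D² = (m_a−m_b)' S⁻¹ (m_a−m_b)` with the pooled
within-cluster covariance (N−k df), tested through the two-sample
Hotelling T² / exact-F transform, unadjusted for multiplicity (an
adjustment flag exists).

## Synthetic cohorts

The generator produces cohorts with the structure the pipeline assumes,
with full ground truth:

* **Latent model**: five independent standard-normal factors — stress,
  control (perception domain) and activity, smoking, alcohol (lifestyle
  domain).  Item scores are loading-weighted factor combinations plus
  Gaussian noise (noise variance `1 − Σℓ²`; an infeasible loading row is
  rejected).  Default loading patterns follow the published two-domain and
  three-domain structures (e.g. activity items .57–.98 on one factor,
  smoking items ≈ .96 on a second, alcohol items ≈ .80 on a third).
* **Ordinal items** are produced by cutting the continuous item score at
  empirical quantiles — equal-probability by default; the published survey
  marginals (70.4% nonsmokers, 78.9% no spirits, …) are available as the
  `STUDY_ITEM_MARGINALS` preset, under which heavy-consumption categories
  are rare and their quantifications correspondingly extreme.
* **Numeric marginals**: biochemistry/anthropometrics are per-sex normals
  with the published mean/SD targets; triglycerides use a moment-matched
  lognormal; MET volumes a zero-censored normal (the zero-heavy,
  right-skewed shape of self-reported weekly activity), coupled to the
  activity factor by ranks.  Weekly total MET is the structural sum of its
  three components.
* **Absenteeism**: zero-inflated negative binomial (π = 0.5, base mean
  10.9, variance 125), linked to the stress factor through a Gaussian
  copula with coefficient 0.30 — calibrated so the observed Pearson
  correlation with stress is ≈ 0.2 (the published cohort reported 0.24)
  and the full cohort including the injected 300-day case has mean ≈ 5.9
  and SD ≈ 14.8 lost days, putting that case near z = 20.
* **Planted structure**: seven typologies as centroids in the
  six-dimensional classification space (alcohol, smoking, high stress,
  physical activity, high control, low stress-and-control, absenteeism),
  minimum pairwise separation ≈ 3.7 within-cluster SDs, mixing weights
  matching the published cluster shares; an injected outlier block of five
  tightly similar heavy smoker/drinkers plus one isolated 300-day
  absentee; optional demographic links (more females in the high-stress
  typology, more illness among absentees).  A single cross-link
  coefficient (default 0) can couple the alcohol factor into the metabolic
  components, since the real dependence is unknown.

**What passing recovery tests show — and what they do not.**  Under these
conditions the optimal-scaling fits recover each latent factor with
|correlation| ≥ 0.8, the pipeline recovers the planted typologies with
ARI ≥ 0.8 when clustering the true indicator columns, the outlier screen
recovers the 5+1 block with recall 1 in ≥ 95% of seeds, and the CH scan
selects the true k for well-separated mixtures.  Real questionnaire data
differ in ways the generator does not emulate: risk factors are mutually
correlated within subject (so the generator's metabolic-syndrome mix
skews more preclinical than a real cohort), items may violate the linear
latent model, and self-selection biases the margins.  End-to-end runs
under the survey-skewed marginals also show a real phenomenon: the
extreme 5-row block inflates the smoking–alcohol item covariance enough
to mix those two dimensions until the outliers are removed — the very
reason the pipeline screens outliers before the final classification.

## Problem sizes and runtime choices

The bundled analyses and tests run k-means with tens of restarts per k
(the CLI default is 1000, matching the published procedure; the scripts
use 200) and simulation suites of 100 seeds/replicates; these sizes keep
the full pipeline on a single CPU in minutes while leaving every selection
rule identical.  All randomness flows through a single seeded
`numpy.random.Generator` per run; per-stage seeds are spawned from one
`SeedSequence`, so every pipeline output is bit-reproducible given its
seed.

## Known limitations

* Monotone regression fits nondecreasing quantifications only; decreasing
  relationships are absorbed by loading signs, which is equivalent for
  rank-one (single-variable) scaling but would matter for multiple nominal
  scaling, which is not implemented.
* The CH statistic with the deviance-ratio df convention penalizes large k
  slightly more than the textbook form; selections can differ near ties.
* Mahalanobis pairwise tests reuse the pooled covariance from all
  clusters, as in the classical discriminant setting; heteroscedastic
  clusters would call for a Welch-type variant, not provided.
* The generator's demographics are linked to typologies by simple
  probability shifts; it makes no attempt to model self-selection.
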