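# Methods

## Setting

A muscle-biopsy score tool for juvenile dermatomyositis (JDM) grades 18
histological items on small ordinal scales (0–2, or 0–1 for infarction and
neonatal myosin) across four domains — inflammatory, vascular, muscle fibre,
connective tissue — plus a continuous 0–10 Visual Analogue Score (VAS) for
overall severity. Validating such an instrument requires (i) allocation
designs that balance which scorer reads which case in which order, (ii)
reliability and agreement statistics over a panel of scorers, (iii) a rule
for keeping only the items that perform consistently, and (iv) association
analyses against clinical severity. This package implements all four
stages; because the raw scorer-level exercise data are not public, it also
implements a generative simulator so that every estimator can be exercised
and checked against known ground truth.

## Reliability model and estimators

Ratings form a case × scorer table per item (one session, one rating per
cell). The working model is two-way random effects without interaction:

    y_ij = μ + c_i + s_j + e_ij,
    c_i ~ N(0, σ²_case), s_j ~ N(0, σ²_scorer), e_ij ~ N(0, σ²_error),

all effects independent. Assumptions worth stating: no case × scorer
interaction (a scorer's bias is a level shift, the same for every case), and
ordinal scores treated as numeric. The latter is standard practice for
instruments with few ordered levels, but it is an approximation: the
discretisation attenuates the ICC of an ordinal item relative to the ICC of
the underlying continuous judgement (with the default simulator settings,
≈ 0.75 on the latent scale vs ≈ 0.64 observed on a 3-level item).

**Balanced complete tables** use the ANOVA moment estimators: with n cases
and k scorers, σ̂²_error = MSE, σ̂²_scorer = (MS_scorer − MSE)/n,
σ̂²_case = (MS_case − MSE)/k, each truncated at zero. Truncation is why an
item scored identically by every scorer (no scorer spread) reports α = 0,
and an item with no case-to-case spread reports ICC = 0.

**Incomplete tables** (partial designs) use REML: the restricted likelihood
of V = σ²_case·Z_cZ_cᵀ + σ²_scorer·Z_sZ_sᵀ + σ²_error·I is maximised by
L-BFGS-B over the three non-negative variances, started from moment-style
estimates (dense Cholesky; tables here have at most a few hundred cells).
On balanced complete data the REML optimum coincides with the ANOVA
estimators; the test suite enforces agreement to 1e-6 relative, and the REML
path is cross-checked against an independent mixed-model implementation on
incomplete data. Components smaller than 1e-9 of the total are snapped to
exactly zero to absorb floating-point cancellation in the sums of squares.

From the components:

* ICC = σ̂²_case / (σ̂²_case + σ̂²_scorer + σ̂²_error). This is the
  single-rater, absolute-agreement, two-way-random form: the same variance
  decomposition yields both the ICC and α, which is why this form was
  chosen over the consistency-type ICC (which ignores scorer variance).
* α = σ̂_scorer / σ̂_case. Edge cases: σ̂²_scorer = 0 gives α = 0 whatever
  the case variance; σ̂²_case = 0 with σ̂²_scorer > 0 is reported as
  flagged-infinite, never as a number.
* Classification: **good** iff ICC > 0.6 and α < 0.4; **good\*** iff exactly
  one of the two holds; **poor** otherwise. Inequalities are strict: an item
  at ICC = 0.60 does not reach high reliability.

**Confidence intervals** are nonparametric case-bootstrap percentile
intervals (default B = 1000): cases are resampled with replacement, each
keeping all its ratings, and the 2.5/97.5 percentiles of the resampled
statistic are reported. Resamples that collapse to fewer than two distinct
cases or to an all-identical table are skipped and counted in a debug log.
When infinite α resamples occur, percentiles are taken as nearest order
statistics rather than interpolated. The bootstrap is seeded and
deterministic.

**Intra-observer agreement** (pA) compares two reading sessions covering
identical (scorer, case, item) triples: per scorer and item, pA = exact
matches / cases read; the per-item median and range across scorers are
reported.

The reliability estimator is exposed sklearn-style
(`InterRaterReliability().fit(table)`, fitted attributes `icc_`, `alpha_`,
`classification_`, `icc_ci_`, …) so it composes with sklearn tooling;
module-level functions wrap the same code.

## Allocation designs

The full n × n Latin square (scorer s reads case L[s, p] at position p)
guarantees every scorer reads every case once and every case occupies every
reading position exactly once across scorers, neutralising order effects.
Construction is the cyclic square (i + j) mod n followed by seeded row,
column and symbol permutations — the randomisation mechanics are a package
choice, fixed for reproducibility. The partial design deals scorers to
cases from a seeded cyclic order, giving each case exactly k scorers and
balancing scorer loads to within one case; with k equal to the roster size
its support is the full crossing. Reading position is generated and checked
but unused by the estimators (no order/carry-over modelling; the design
exists to neutralise such effects, not to estimate them).

## Consensus and the modified tool

Per case, the consensus score of an item is the mode across scorers; ties
are broken toward the higher (more severe) score and flagged in the output
so affected cases can be audited. Domain totals use medians, and the
per-case VAS consensus is the median across scorers (a package choice; only
group-level medians are fixed by the published analysis). An item enters
the modified tool only if it classified good or good\* in **every** supplied
scoring exercise and was degenerate in none. Degeneracy is operationalised
as ICC = 0 with α = 0 — items with nominally perfect agreement but no
case-to-case variability (near-ubiquitous MHC class I overexpression,
near-absent infarction) — replacing a subjective "low variability" judgement
with a reproducible rule; on the packaged reference tables it reproduces
exactly the published six-item modified tool. Modified domain totals are
unweighted sums of the retained items' consensus scores: 0–6 for the
inflammatory trio (three 0–2 items) and 0–5 for the muscle-fibre trio
(0–2 + 0–1 + 0–2).

## Association tests

* Pearson χ² without continuity correction for group comparisons of ordinal
  and binary scores; the six published contingency-table p-values are
  reproduced only without the correction, including tables with expected
  counts below 1. One caveat: the neonatal myosin table gives χ² = 0.511
  (1 df), p = 0.4748, which rounds to 0.47 against a printed 0.48 — within
  one unit in the last printed digit and attributed to upstream rounding.
* Fisher's exact test for sparse tables, two-sided by the point-probability
  convention (sum of hypergeometric probabilities no larger than the
  observed table's). The "as appropriate" rule routes only 2 × 2 tables
  with an expected count < 5 to Fisher; r × c tables always use χ².
* Mann–Whitney U from mid-ranks: exact enumeration when the pooled sample
  has ≤ 12 untied observations, otherwise the normal approximation with
  tie-corrected variance and no continuity correction (so the two-group
  Kruskal–Wallis H equals z²).
* Kruskal–Wallis with tie correction, p from χ² on k − 1 df.
* Spearman rank correlation with the t-approximation test of independence
  (t = r√((n−2)/(1−r²))), plus a seeded permutation alternative used for
  validation. Missing values are dropped pairwise per test.
* No multiple-testing adjustment anywhere, matching the published analysis;
  reports should be read accordingly.

## Synthetic cohort simulator

The simulator emulates the study's structure: two groups (default 33
quadriceps/UK and 22 biceps/Brazil cases), a panel of 11 scorers, an 11×11
full square per group, a 5-scorers-per-case partial design for the
remaining cases, and an 8×8 intra-observer repeat on quadriceps cases.
Generatively, case severity θ_i ~ N(0, σ²_case) plus a biceps mean shift;
the latent rating is u_ij = loading·θ_i + b_j + e_ij with scorer bias
b_j ~ N(0, σ²_scorer) shared across items and residual e_ij redrawn per
item and session. Ordinal scores count the item's thresholds below u_ij
(a common-threshold graded model: bias shifts the latent, not the
thresholds — the simplest structure consistent with a single α per item);
the VAS is an affine map of the same latent clamped to 0–10. Clinical
measures couple to θ: MMT grades 2–5 through decreasing cutpoints
(−1, 0, 1 on the θ scale), CMAS = clamp(53 − 8θ + N(0, 5²), 0, 53) and
PGA = clamp(5 + 1.5θ + N(0, 1²), 0, 10) for UK cases only, and complication
flags Bernoulli(logistic(intercept + θ)) with intercepts −3…−1 (the flags
are severity-coupled only; no mechanistic calcinosis model).

Defaults: σ_case = 1.0, σ_scorer = 0.3, σ_error = 0.5 (latent-scale SDs),
unit loadings, 3-level thresholds at ±0.5 and binary thresholds at 0.
These place the continuous-scale ICC at 1/(1 + 0.09 + 0.25) ≈ 0.75 and
α at 0.3 — the "good" region in which the informative items of the
published exercises sit — and give observed ordinal-item ICCs around 0.64
after discretisation. No effect sizes for the severity → score mapping are
published; these are the package's calibration choices, fixed once. The
biceps severity shift is 0.8 latent SD, reproducing the direction (more
severe biceps pathology) of the published group comparison. The same seed
yields bitwise-identical tables; session 2 redraws residuals only.

What the simulator does **not** emulate: item-specific scorer biases or
scorer × case interaction, correlated residuals across items beyond the
shared bias, drift between sessions, non-normal severity distributions,
cohort differences other than the mean shift, and missing clinical data
beyond the structural CMAS/PGA absence in the biceps group. Tests passing
on simulated data therefore demonstrate estimator correctness under the
stated model, not robustness to these real-data features.

## Numerical and reporting choices

Degenerate inputs: all-identical ratings yield (0, 0, 0) with a degeneracy
flag; tables smaller than 2 × 2 are rejected; zero-variance Spearman inputs
are flagged rather than given an r. Reported p-values are rounded to two
decimals in the Markdown summary while CSVs keep full precision. Problem
sizes in the test suite and acceptance script — 200 replicates of 30 × 11
panels for parameter recovery, 100 simulated cohorts for the association
sign structure, B of a few hundred for bootstrap checks — were chosen to
make Monte-Carlo error small relative to the tolerances tested.

## Known limitations

* Ordinal scores enter the variance decomposition as numeric; the ICC of an
  ordinal item is attenuated relative to the latent judgement.
* The plug-in ICC is a ratio and carries a small negative finite-sample
  bias (≈ −0.01 at 30 cases × 11 scorers); the recovery check bounds the
  deviation from truth at 0.02 to cover Monte-Carlo error plus this bias,
  while α is mean-unbiased within Monte-Carlo error.
* The bootstrap resamples cases only; scorer-level uncertainty is treated
  as fixed-panel, consistent with a consensus group of named experts.
* The published per-item CI method is not recoverable from the source
  tables; percentile case-bootstrap is the package's choice, so packaged
  reference CIs and recomputed CIs are not interchangeable.
* VAS is modelled on 0–10 (the range used in the published score
  distributions); the instrument's printed 1.0–10.0 cm line is
  representable by configuring `vas_range`.
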