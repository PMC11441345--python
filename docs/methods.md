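# Methods

This note documents the models, algorithms, numerical conventions and design
choices behind `symptomnet`, and what the synthetic-data tests do and do not
establish about real questionnaire data.

## 1. Profile catalog

An instrument with `k` items scored `0..max_item_score` is dichotomized per
item at score ≥ 1. A *profile* is the resulting presence/absence pattern.
Two eligibility rules decide which of the `2^k` patterns enter the catalog:

* **threshold** — a pattern is eligible iff its *maximum achievable* total
  (every present item at the maximum score, absent items at 0) reaches the
  cutoff: `n_present × max_item_score ≥ threshold`. For the PHQ-9
  (k = 9, max 3, cutoff 10) this retains patterns with ≥ 4 present items,
  i.e. `Σ_{r=4}^{9} C(9, r) = 382`. This is the only reading of
  "profiles that can score ≥ 10" consistent with that count: a respondent
  matched to a profile scores *at least* 1 on each present item, so a
  profile is clinically reachable precisely when its best case reaches the
  cutoff.
* **dsm** — at least `min_count` symptoms present, at least one of them a
  designated core symptom (defaults: 5 of 9, core = {anhedonia, depressed
  mood}), giving 227 combinations. This rule generalizes the catalog to
  interview-style polythetic criteria; it is not a PHQ-9 scoring rule.

Catalog IDs are assigned in canonical order: descending symptom count, then
descending lexicographic pattern with item 1 most significant. This makes
ID 1 the all-present profile, ID 2 the profile missing only item 9, and
ID 11 the profile missing items 8–9 — the three patterns most prevalent in
community samples — and keeps IDs stable across runs and machines.
Frequency *rank* (data-dependent) is deliberately separate from catalog
*ID* (theoretical); ranks break ties by ascending catalog ID.

Enumeration is exhaustive over `2^k` bit patterns (vectorized popcount),
capped at k = 24; the closed-form binomial sum provides an independent
route for threshold rules and the two are cross-checked in the tests.

## 2. Cohort handling

Inclusion applies to the raw total score (0–27), not the dichotomized
count. Missing or out-of-range item values trigger listwise exclusion of
the respondent, with a warning and a count kept on the matrix — imputation
would inject modelling assumptions into a purely descriptive step.
Non-numeric or fractional cells are treated as file-format defects (an
error naming the row and column) rather than as missing data.

Matching is a dictionary lookup of the dichotomized pattern; any included
respondent (total ≥ 10, hence ≥ 4 present items under max score 3) is
mathematically guaranteed a catalog hit, so a miss raises a consistency
error that signals a rule/threshold mismatch rather than a data problem.

Severity bands are reported for included respondents as "moderate" (≤ 14),
"moderately severe" (15–19), "severe" (≥ 20). Note the lower edge: the
screening literature usually brackets moderate as 10–14; since only
totals ≥ 10 are banded here the two conventions coincide in practice.
Covariates are pass-through descriptive columns (per-profile means); they
never enter estimation.

## 3. Network estimation

### Input correlations

Pearson correlations on the raw 0–3 scores of the profile's *present*
items, listwise-complete. Absent items are constant 0 in the subsample and
are removed (a Gaussian model is undefined for constant variables); the
dropped labels are recorded on the result. A polychoric option is
deliberately omitted: treating the ordinal scores as continuous is the
convention of the applied literature this package serves, and it keeps the
estimand aligned with the latent-Gaussian generator (§5). Estimation
refuses subsamples below 10 members and warns below 100, where network
estimates are known to be unstable.

### Regularized estimator (`ebic_glasso`)

The graphical lasso is solved (scikit-learn's coordinate-descent solver) at
100 log-spaced penalties from `λ_max` — the largest absolute off-diagonal
sample correlation, at which the solution is exactly diagonal — down to
`0.01 λ_max`. The ratio 0.01 and γ = 0.5 are the conventional defaults for
EBIC-based network estimation. Penalty points where the solver fails
numerically (non-finite or non-PD output) are flagged and skipped; loose
dual-gap warnings at tiny penalties are tolerated and counted.

Each *distinct sparsity pattern* appearing on the path is then refit by
constrained maximum likelihood and scored by

```
EBIC(E) = -2 ℓ(K̂_E) + |E| log n + 4 γ |E| log p,
ℓ(K) = (n/2) (log det K - tr(S K)),
```

where `K̂_E` is the constrained MLE with support `E`. The minimum-EBIC
pattern wins; exact ties go to the larger penalty (sparser model). This is
the criterion's original formulation — EBIC compares *models*, each at its
maximized likelihood. The widely-used shortcut of plugging the penalized
path estimate itself into the likelihood is not selection-consistent when
strong edges are present: relaxing the penalty keeps buying likelihood on
the strong edges, so the minimum drifts toward models carrying small
spurious extras. In our simulations the shortcut kept 3–6 false edges at
n = 2000 (and still ~3 at n = 128000), while the refit criterion recovers
the planted support with specificity ≥ 0.96 across seeds. The refit
convention also makes the path selection provably comparable to an
exhaustive search over all sparsity patterns, which the tests exploit as
an oracle at p = 3, 4.

The constrained MLE uses iterative proportional fitting over the maximal
cliques of the support graph: each sweep resets the model covariance on a
clique block to the sample block, leaving off-support precision entries
exactly zero; iteration stops when clique marginals match to 1e-8. The
fitted precision is converted to partial correlations
`pr_ij = -K_ij/√(K_ii K_jj)`; entries whose precision is zero stay exactly
zero, so "no edge" is a hard zero, not a small number.

### Non-regularized estimator (`nonreg_threshold`)

Full partial correlations from the inverted correlation matrix; each edge
tested by the Fisher z-transform with effective degrees of freedom
`n - p` (two focal variables plus `p - 2` conditioning variables; the
z-statistic is `atanh(r)·√(n - p - 1)`). Edges with two-sided p ≥ α
(default 0.05) are set to zero; no multiplicity correction, matching the
descriptive use of this fallback. A (near-)singular correlation matrix
(condition number > 1e12) aborts with advice to use the regularized
method. The pipeline falls back to this estimator automatically when the
glasso path fails on a small profile subsample, and logs the fallback.

### Centrality and layout

Strength centrality is the sum of absolute incident partial correlations;
the standardized version is z-scored across items (population SD), with an
explicit "undefined" flag when all strengths are equal (e.g. the empty
network). Ranks break ties by item order. Layouts use the seeded
Fruchterman–Reingold algorithm with |pr| as attraction weights, rescaled to
the unit square; the default seed is 1 and every stochastic step accepts an
explicit seed.

## 4. Stability diagnostics

* **Edge accuracy** — `n_boot` (default 1000) row resamples with
  replacement, each re-estimated under the same configuration; per-edge
  bootstrap mean and 2.5/97.5 percentile interval. Resamples where
  estimation fails (e.g. a column going constant) are dropped and counted;
  more than 50% failures aborts.
* **CS coefficient** — case-dropping subset bootstrap over drop proportions
  0.05–0.75 in steps of 0.05 (the customary grid; CS is conventionally
  reported up to 75% dropped). For each proportion, `n_boot` subsamples of
  size `round((1 - q) n)` are drawn without replacement and the Pearson
  correlation between subsample and full-sample strength vectors recorded;
  CS is the largest proportion at which ≥ 95% of resamples reach a
  correlation of 0.7, 0 if none qualifies, and None when no proportion is
  usable at all. Correlations are computed on raw strengths —
  standardization is affine per vector and cannot change a Pearson
  correlation, while raw values avoid zero-variance corner cases. The
  interpretability flag uses the conventional 0.25 rule.

Identical seed and configuration reproduce the report bit-for-bit; the
pipeline derives per-stage seeds from the global seed via
`SeedSequence([seed, stage, profile])` so stages can be re-run in
isolation.

## 5. Synthetic cohorts and what the tests show

Each subpopulation plants a profile and a partial-correlation network over
its present items. The precision matrix is `K = I - pr` (unit diagonal;
validated positive definite), inverted and rescaled to unit variances —
partial correlations are invariant to that rescaling, so the planted `pr`
*is* the estimand on the latent scale. Present items are discretized by
strictly increasing cut points into scores 1..3 (never 0), so a generated
respondent's dichotomized pattern equals the planted profile exactly; this
separates profile-identification tests from network-estimation tests.
Default cut points are standard-normal tertiles (equal thirds on 1/2/3);
skewed items (e.g. rare suicidal ideation) can be emulated with higher cut
points.

The generator reproduces the *structure* assumed by the estimation model —
ordinal scores from a latent Gaussian with a sparse precision matrix, and
clean mixture membership. Real questionnaire data depart from this in ways
the generator does not emulate: item marginals are skewed rather than
uniform-tertile unless configured, profile membership is itself noisy,
latent associations need not be Gaussian, and discretization attenuates
Pearson correlations relative to their latent values. Passing tests
therefore certify the pipeline's correctness and its behaviour under the
model's own assumptions — not that a 9-item screening instrument measures
depression, nor that real-data edge weights are recovered without bias.

Problem sizes used by the test harness were chosen to be informative at
desk scale: recovery experiments at n = 2000 with 8 planted edges of
weight 0.25–0.35; stability comparisons at n = 2000 vs 150 with 200
bootstrap resamples (the full 1000 remains the library default); the
sample-size comparison of the CS coefficient runs the fast
significance-threshold estimator, whose stability behaviour with n is the
same qualitative phenomenon while keeping 60,000 re-estimations tractable.
At n = 150 the resulting CS values (roughly 0.05–0.4 across seeds) bracket
the instability that motivates cautious interpretation of small-profile
centralities.

## 6. Known limitations

* Only undirected, cross-sectional networks; no temporal or directed
  models, no cross-profile comparison tests, and no centrality indices
  beyond strength.
* Uniform per-item score range; instruments with heterogeneous item scales
  are out of scope.
* The DSM-style rule counts symptom *combinations* only; it does not model
  duration, impairment or exclusion criteria of a clinical interview.
* Pearson-on-ordinal input attenuates associations relative to polychoric
  treatment; this is a deliberate fidelity-to-practice choice, not a
  statistical recommendation.
* Exhaustive enumeration is capped at 24 items (16.7M patterns); larger
  instruments would need a combinatorial counting route instead.
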