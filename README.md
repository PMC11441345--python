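# symptomnet

Symptom-profile enumeration and per-profile partial-correlation networks
for ordinal questionnaires, following the PHQ-9 convention (9 items scored
0–3, clinical cutoff ≥ 10).

## The problem

A polythetic diagnosis such as major depression can be met by many
different symptom combinations: dichotomizing each PHQ-9 item (present if
scored 1–3, absent if 0), there are 382 distinct presence/absence patterns
that can reach the screening cutoff of 10, and 227 combinations satisfy a
DSM-style rule (≥ 5 of 9 symptoms including a core symptom). Yet respondents
who *share* a profile may still differ in how their symptoms hang together.
`symptomnet` is for epidemiologists and clinical researchers who want to
(1) enumerate the theoretical profile catalog, (2) match survey respondents
to profiles and quantify which few profiles carry most of the sample, and
(3) estimate, within each prevalent profile, a network of conditional
associations among the symptoms, with honest stability diagnostics.

## The model

Within one profile's subsample, the continuous 0–3 item scores are modelled
as a Gaussian graphical model: nodes are symptoms, and an edge between
symptoms *i* and *j* carries their partial correlation

```
pr_ij = -K_ij / sqrt(K_ii K_jj),      K = Σ⁻¹ (precision matrix)
```

so missing edges encode conditional independence given all other symptoms.
Sparse estimation uses the graphical lasso on a 100-point log-spaced penalty
path (λ_min/λ_max = 0.01); every candidate sparsity pattern on the path is
refit by constrained maximum likelihood, and the model minimizing the
extended Bayesian information criterion,

```
EBIC = -2 ℓ(K̂) + E log n + 4 E γ log p,       γ = 0.5,
```

is selected. For subsamples too small for the path to converge, a
non-regularized fallback keeps every edge whose partial correlation passes a
two-sided Fisher-z test at α = 0.05. Node importance is summarized by
strength centrality (the sum of absolute incident edge weights), and its
robustness by nonparametric bootstrap edge intervals and the case-dropping
correlation-stability (CS) coefficient: the largest fraction of cases that
can be dropped while 95% of resampled strength vectors still correlate
≥ 0.7 with the full-sample one (conventionally interpretable above 0.25).

Because real survey microdata are rarely shareable, the package ships a
synthetic-cohort generator with exact ground truth: mixtures of
subpopulations, each planting a profile (absent items are structurally
zero) and a latent-Gaussian network over the present items, discretized
into ordinal scores.

## Worked example

```python
import numpy as np
import symptomnet as sn

catalog = sn.enumerate_catalog(sn.ProfileRule())      # 382 profiles
rng = np.random.default_rng(7)
subs = []
for pattern, weight in (("111111111", 0.5), ("111111110", 0.3),
                        ("111111100", 0.2)):
    profile = sn.SymptomProfile.from_pattern(pattern)
    m = profile.n_present
    subs.append(sn.Subpopulation(profile, weight,
                                 sn.random_network(m, m - 1, (0.2, 0.35), rng)))
spec = sn.SyntheticSpec(n_respondents=1200, subpopulations=tuple(subs), seed=42)
matched = sn.match_profiles(sn.sample_cohort(spec), catalog)
table = sn.frequency_table(matched, catalog)
print(table.table.head(3)[["rank", "profile_id", "pattern", "n", "percent"]])
print("top-2 coverage: %.1f%%" % table.coverage(2))

res = sn.SymptomNetwork.from_cohort(matched, 2, catalog=catalog).fit()
print(res.summary())
```

prints

```
 rank  profile_id   pattern   n   percent
    1           1 111111111 602 50.503356
    2           2 111111110 354 29.697987
    3          11 111111100 236 19.798658
top-2 coverage: 80.2%
        Symptom Network Results
==============================================
Method:            ebic_glasso
No. observations:  354
No. items:         8
Edges (nonzero):   5  (density 0.18)
Selected lambda:   0.2347
EBIC at selection: 2727.8
Dropped items:     phq9
----------------------------------------------
Strength centrality (rank order):
   1. phq7             strength 0.832  z +2.17
   2. phq8             strength 0.516  z +0.78
   ...
```

The frequency table recovers the planted mixture (50/30/20% on catalog IDs
1, 2 and 11); the fitted network for profile 2 spans the 8 present symptoms
(item 9, absent by construction, is dropped), and the strength column ranks
symptoms by their total conditional connectivity. Stability diagnostics
hang off the same results object: `res.bootstrap_edges(n_boot=1000)` and
`res.cs(n_boot=1000)`.

The same steps are scriptable from a shell:

```bash
symptomnet enumerate --items 9 --max-score 3 --threshold 10 --out catalog.csv
symptomnet simulate --spec spec.yaml --out synthetic.csv --truth truth.csv
symptomnet match --input synthetic.csv --out matched.csv
symptomnet summarize --matched matched.csv --top 8
symptomnet network --matched matched.csv --profile-rank 1 --out net1/
symptomnet run --config run.yaml         # full pipeline + report
```

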