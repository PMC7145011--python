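# costtraj

Latent cost-trajectory analysis of end-of-life hospital costs.

Health-economic studies of terminal illness usually report a single average
spending curve over the last year of life. That average hides enormous
between-patient variability: some patients' costs surge in the final
months, others' stay flat or decline. `costtraj` implements the full
analysis chain for uncovering that structure in event-level hospital cost
data from deceased patients — built around advanced breast cancer cohorts,
but applicable to any population with dated resource-consumption records
and death dates. It is written for health economists and biostatisticians
working with registry or hospital-record cost data.

## What it computes

1. **Cost allocation** (`costtraj.ledger`). A ledger of resource events
   (drug administrations, admissions, consultations, diagnostics, each with
   dates, quantities and unit-cost codes) is priced with a unit-cost table,
   inflated to reference-year euros via a CPI series, spread uniformly over
   each event's administration span, and aggregated into a patients × 12
   matrix of monthly costs. Months are 30-day windows counted backwards
   from death (month 1 ends at death); months before the advanced-disease
   diagnosis are masked, so a patient surviving *s* days contributes
   `min(12, ⌈s/30⌉)` observed months. Total spend is conserved up to
   integer rounding. Missing quantities/dates are imputed (category
   medians, sequence midpoints) and flagged.

2. **Group-based trajectory modelling** (`costtraj.gbtm`). Monthly cost
   counts are modelled as a finite mixture of zero-inflated Poisson
   regressions. For latent group *j* and scaled time *t* ∈ [0, 1]
   (increasing toward death):

   ```
   y_im ~ ZIP(λ_j(t_m), p_j(t_m))
   log λ_j(t) = Σ_k β_jk t^k          (polynomial of degree d)
   logit p_j(t) = Σ_k γ_jk t^k        (or a per-group constant)
   ```

   `ZipTrajectoryModel` is a scikit-learn-style estimator fitted by an EM
   algorithm whose M-step collapses to 12-row weighted GLMs, giving a
   provably monotone log-likelihood. It exposes mixing proportions
   `weights_`, coefficient matrices, per-month fitted curves, the n × J
   posterior membership matrix `posterior_`, MAP labels, and AIC/BIC.

3. **Model selection** (`costtraj.selection`). `fit_grid` brute-forces the
   (number of groups, polynomial degree) grid and scores every cell by
   AIC, BIC and leave-one-out cross-validated mean absolute error
   (exact refits or warm-started fast mode). The grid is reported for
   human model choice; nothing is auto-selected.

4. **Group profiling** (`costtraj.profiling`). Covariate distributions are
   compared across latent groups with Kruskal–Wallis (continuous) and
   Pearson chi-square (categorical) tests. Two fits of the same model on
   different cohorts can be aligned by trajectory shape
   (`match_classes`, exact assignment) and their class allocations
   compared with (weighted) Cohen's kappa.

5. **Membership regression** (`costtraj.membership`).
   `PosteriorWeightedMultinomial` explains group membership from
   covariates by a multinomial logit in which every patient contributes
   one pseudo-observation per group, weighted by posterior membership
   probability — propagating classification uncertainty. Inference by
   Wald z-tests, effects as odds ratios with 95% CIs, model reduction by
   backward elimination on AIC, fit summarised by McFadden pseudo-R² and
   classification accuracy (Wilson CI) against the modal-group null model.

6. **Synthetic cohorts** (`costtraj.simulate`). Because registry data of
   this kind is not public, the package ships a generator that emulates
   the published cohort: ~558 patients in six trajectory archetypes with
   the published group shares, survival from a truncated log-normal
   calibrated to a 466-day median with 42% dying within 12 months,
   ZIP monthly costs whose group totals match the published group-level
   spending, group-linked covariates, and an optional raw event ledger
   with configurable missingness.

## Worked example

```python
import numpy as np
from costtraj import SimConfig, simulate_cohort, ZipTrajectoryModel, summarize_trend

patients, matrix, truth = simulate_cohort(SimConfig(n_patients=558, seed=1))

trend = summarize_trend(matrix)
print(round(trend["grand_mean"].iloc[0]))        # 2222
print(round(trend.loc[0, "mean"]))               # 3698  (last month)

model = ZipTrajectoryModel(n_groups=6, degree=3, random_state=1).fit(matrix)
print(np.round(model.weights_, 3))
# [0.068 0.122 0.195 0.177 0.181 0.256]
print(np.bincount(model.labels_))                # [ 38  68 109  99 101 143]
```

The cohort's mean monthly hospital cost is ~€2.2k, rising to ~€3.7k in the
last month before death — yet the six fitted trajectory groups show that
the rise is concentrated in a minority of patients: the two rising
archetypes hold about a quarter of the cohort, while the largest group
(26%) stays flat and low throughout. `model.posterior_` feeds
`backward_eliminate` for the membership regression, and
`sensitivity_subgroup` refits on the ≥12-month survivors and reports the
weighted-kappa agreement with the full fit.

The same pipeline is scriptable from the shell:

```bash
costtraj simulate --n 558 --seed 1 --outdir run/ --with-ledger
costtraj cost --ledger run/ledger.csv --patients run/patients.csv \
              --prices run/unit_costs.csv --cpi run/cpi.csv --outdir run/
costtraj select --matrix run/matrix.csv --max-groups 6 --max-degree 3 \
                --loocv fast --out run/grid.csv
costtraj all --n 558 --seed 1 --sensitivity --outdir run/
```

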