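# Methods

This note documents the models, numerical choices and known limits of
`costtraj`, in the spirit of the methods documentation of packages like
statsmodels or msprime: what is assumed, what is configurable, and what
passing the test suite does and does not demonstrate.

## Death-anchored monthly cost windows

Costs are analysed over the last twelve months before death, or from the
advanced-disease diagnosis to death when survival is shorter. A "month" is
a 30-day retrospective window anchored at the death date — month *m*
collects days (30(m−1), 30m] before death, with costs dated on the death
day itself assigned to month 1. Calendar months would make "the month
before death" depend on the patient's date of death; fixed 30-day windows
make the observation mask a deterministic function of survival time
(`min(12, ⌈s/30⌉)` observed months) and the whole allocation
translation-invariant (shifting every date by *k* days changes nothing).

The earliest observed month of a short survivor is typically partial; it
stays observed and carries the **unadjusted** sum of its observed days —
no per-day rescaling — so partially observed months genuinely carry less
cost. Event costs are spread uniformly over the inclusive administration
span (single-day events map to their date); costs with only
sequence-level timing are spread over the whole sequence interval. All
amounts are inflated to reference-year (2017) euros by the CPI ratio.

Monthly euro totals are rounded half-up to integers before modelling,
because the zero-inflated Poisson likelihood needs counts. A coarser
count unit (e.g. €10 per count) is available via the `scale` argument of
`aggregate_monthly`; the default models whole euros. The source of the
original analysis never states its discretization, so this is a package
choice, made configurable.

Missing-data defaults: a missing quantity becomes the median observed
quantity of its resource category (error if the category has no observed
quantities); missing dates become the midpoint of the patient's enclosing
treatment-sequence interval. Every imputed field is flagged so analyses
can be rerun excluding imputed events. These rules are deliberately
simple stand-ins for whatever richer registry-specific logic a user may
have; they are applied before allocation, never silently inside it.

## The zero-inflated Poisson trajectory mixture

Patients fall into J latent groups; within group *j*, monthly counts are
independent ZIP draws whose log-rate (and, by default, zero-mass logit)
are degree-d polynomials in scaled time t = (12 − m)/11 ∈ [0, 1], so t
increases toward death. The zero-inflation component absorbs the excess
of zero-cost months (no hospital contact) that a Poisson with a large
rate would make essentially impossible. Masked pre-diagnosis months
contribute nothing to the likelihood — the "patients only contribute
where observed" principle is carried into estimation, not just into
description.

**Estimation.** EM over two latent layers: group membership, and (within
each observed zero) the structural-zero indicator. Conditional on both,
the complete-data likelihood separates into a weighted Poisson log-link
regression and a weighted binomial logit regression, and because rates
and zero-probabilities depend only on the month, both collapse to
12-row problems. They are solved by damped Newton ascent with step
halving, so every M-step weakly increases the EM objective and the
observed-data log-likelihood is monotone non-decreasing (asserted in
tests at 1e-8). Linear predictors are clipped at ±30 to keep `exp`
finite; with no zeros in a group the zero-mass intercept drifts to the
clipped boundary, which is harmless (p ≈ 0).

**Initialisation.** Start 1: k-means on log1p-transformed cost rows
(masked cells mean-filled), softened to 0.95/0.05 responsibilities.
Remaining starts: seeded Dirichlet-random responsibilities. The best of
`n_starts` runs by final log-likelihood is kept. The likelihood surface
of mixtures is multimodal; occasional convergence to a local optimum
that merges similarly shaped groups is expected and is why multiple
starts (and inspecting fitted curves) matter.

**Identifiability convention.** Groups are relabelled in decreasing
order of mean fitted cost (mean over months of (1 − p)λ), which makes
refits with a fixed seed bit-reproducible and gives agreement statistics
a meaningful common ordering.

**Parameter count.** (J − 1) mixing + J(d + 1) rate + J·q zero-inflation
coefficients (q = d + 1 polynomial, 1 constant, 0 none). AIC = −2ℓ + 2k;
BIC = −2ℓ + k·ln n with n = number of patients (subjects) by default —
configurable to observed cells, since the literature is split on the
right BIC sample size for longitudinal mixtures.

**Defaults.** `tol=1e-6` on the log-likelihood change, `max_iter=500`,
`n_starts=2`. Zero inflation defaults to the polynomial structure (the
more general variant used by ZIP trajectory software); the constant
variant is cheaper and is what several tests use.

## Model selection

`fit_grid` fits every (J, d) cell with a shared seed. Cells that fail or
do not converge are recorded with missing criteria rather than raised —
a realistic grid has such holes at large J. Leave-one-out
cross-validation predicts each held-out patient's monthly counts as the
mixture mean Σ_j w_j (1 − p_j(m)) λ_j(m). Two design axes are exposed
because the referenced LOOCV estimator for trajectory models is not
fully specified in the source literature:

* **weights**: `prior` (default) uses only the refitted mixing
  proportions — the held-out patient's own data never informs their
  group weight — or `posterior`, which computes the held-out row's
  posterior under the refitted model;
* **mode**: `exact` refits the mixture n times; `fast` warm-starts each
  held-out fit from the full-data parameters and runs a few EM sweeps
  (25 by default). On test cohorts the two agree within 5% relative.

The prediction uses the ZIP mean (1 − p)λ, i.e. the model's expected
count, rather than λ alone. The grid never declares a winner: the final
(J, d) is an analyst's decision recorded in configuration, reflecting
that parsimony and interpretability legitimately enter model choice.

## Profiling and cross-fit agreement

Continuous covariates are tested across groups with Kruskal–Wallis,
categorical ones with Pearson's chi-square (no Yates correction — the
plain Pearson statistic keeps the type-I rate at its nominal level, as
the calibration test verifies). p ≤ 0.05 is flagged; no multiplicity
adjustment is applied, matching the exploratory framing. Covariates
constant across the cohort are skipped with a note.

When the model is refit on a subgroup (the ≥12-month survivors in the
sensitivity analysis), its groups are aligned to the full-cohort fit by
minimising the total absolute difference between fitted mean curves over
months — an assignment problem solved exactly — and the class
allocation agreement of shared patients is summarised by weighted
Cohen's kappa. Linear disagreement weights on the cost-ordered groups
are the default (confusing adjacent cost levels is penalised less than
confusing extremes); quadratic and unweighted schemes are available
because "weighted kappa" alone does not pin down a scheme. Matching on
fitted curves rather than shared memberships keeps the procedure defined
even for disjoint patient sets.

## Posterior-weighted multinomial membership model

Each patient enters as J pseudo-observations weighted by posterior
membership probabilities, keeping total weight 1 per patient so
information is neither duplicated nor lost. The weighted log-likelihood
is concave; Newton–Raphson with step halving converges to the unique
maximum (tolerance 1e-8), and the observed information at the optimum
supplies Wald standard errors. Perfect separation and rank-deficient
designs are detected and raised with the offending covariate named.

The intercepts-only null model has a closed form — its fitted
probabilities are the column means of the weight matrix — which anchors
McFadden's R² = 1 − ℓ/ℓ₀ (exactly 0 when no covariates are retained).
Backward elimination drops whole covariates (all J − 1 coefficients
jointly), removing at each round the covariate whose removal most
decreases AIC, with ties broken by declaration order. Survival enters in
years as a continuous covariate; a dichotomised "<12 months" indicator
is deliberately excluded from the default candidate set as it would be
collinear with survival time. Classification accuracy against MAP labels
is reported with a Wilson score interval (Clopper–Pearson via
`ci_method="beta"`), compared with the modal-group null accuracy.

## The synthetic cohort generator

The generator defines the study conditions under which the pipeline is
validated:

* **Cohort**: 558 patients in six trajectory archetypes (moderate
  rising, high declining, fluctuating early-peak, fluctuating late-peak,
  low with end peak, low stable) with shares 7/12/17/18/19/26% — the
  published group sizes.
* **Survival**: log-normal, truncated to [30, 2700] days (a registry
  whose inclusion window both requires some survival after diagnosis and
  caps the observable maximum), with per-group log-scale shifts derived
  from the published group survival means. The global (μ, σ) are solved
  by bisection at configuration time so the mixture has a 466-day median
  and 42% short (<360-day) survivors. Monte-Carlo tests check both at
  n=5000 within ±3 points.
* **Costs**: cubic log-rate curves per archetype with constant
  per-group zero inflation (10–35%, larger in cheaper groups). The
  intercepts were calibrated once, against published anchors only, so
  the realized truncated cohort reproduces a mean monthly cost of
  ~€2.25k and per-group 12-month totals of roughly
  53k/44k/18.5k/24k/19k/4.6k euros (realized within about 7%).
* **Covariates**: drawn conditionally on the group from the published
  within-group distributions (age, metastatic sites, receptor status,
  comorbidity and treatment flags). Note the generative direction is
  group → covariates; the membership regression estimates the inverse
  conditional, so its coefficients are not the generator's parameters
  and are validated only qualitatively plus by null-calibration tests.
* **Ledger**: each patient-month's total is decomposed into a
  month-spanning medication event, a single-day admission, a
  consultation, and a diagnostic with month-level vague timing;
  quantities are set so the allocation pipeline reproduces the matrix
  exactly under zero missingness. Missing quantities/dates can be
  injected at configurable rates.

What the generator does **not** emulate: overdispersion beyond ZIP
(real cost data is far noisier than Poisson at euro scale, so real
posteriors are much softer than the near-hard ones seen here — which is
why the simulated subgroup-agreement kappa, ~0.8–0.96 depending on seed,
sits at or above what real data yields), within-month cost clustering on
single days beyond the ledger decomposition, calendar-time price drift
beyond CPI, informative missingness, or real Dutch price lists.
Passing tests therefore demonstrates correctness of the machinery and
recoverability under the assumed model, not performance on registry
data.

## Problem sizes in the test and reproduction runs

The recovery study uses 20 replicates of n=400 patients from a
well-separated three-group quadratic design (rates ~25/9/3 counts per
month, 20% zero inflation), fitting a J=1..5 grid at d=2: BIC recovers
J=3 in ≥16/20 replicates, mixing proportions within ±0.05, adjusted Rand
of MAP labels vs truth >0.9 per replicate. EM guarantees are asserted on
every cell of a {1..4}×{1..3} grid over a 250-patient cohort.
Null-calibration uses 2000 replicates at n=120–150. These sizes were
chosen as the smallest at which the checked asymptotic properties are
comfortably expressed.

## Known limitations

* Shared polynomial degree across groups (varying degrees per group is
  out of scope, mirroring the constraint of existing trajectory
  software); no covariates inside the mixture; ZIP is the only outcome
  family.
* The EM finds local optima; multi-start with k-means seeding is a
  mitigation, not a guarantee.
* Wald inference and McFadden R² are asymptotic; with few patients per
  group the odds-ratio CIs are approximate.
* The LOOCV fast mode shares initialisation with the full fit and can
  inherit its local optimum.
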