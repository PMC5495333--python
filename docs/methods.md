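# Methods

This note documents the statistical models behind `adgfs`, the choices made
where the design was genuinely open, and the limits of what the synthetic
cohorts can show.

## The score and its components

AdGFS is a conditional risk score for kidney-graft failure (return to
dialysis; death with a functioning graft is censoring) computable from one
year post-transplant and updatable afterwards. It has two parts:

* a **baseline branch score**: the patient is routed down a conditional
  survival tree built on baseline factors (donor age, ScrM12, first-year
  creatinine cluster, month-12 proteinuria, pre-transplant NDSA); every
  split where the route takes the adverse daughter — the one with the lower
  ten-year Kaplan–Meier survival — adds that factor's weight. The
  all-favorable branch scores 0. A factor splitting twice along one path is
  counted once.
* **event weights** for factors ranked by the forest but not in the tree
  (in practice dnDSA onset and first acute rejection): added the moment the
  event's onset time is at or before the evaluation landmark. Defaults are
  4 (dnDSA) and 2 (rejection); `augment_with_events` can re-derive them on
  data by greedy ten-year AUC maximization over {2, 4, 6} (an improvement
  must exceed 0.001 to count, avoiding Monte-Carlo chasing). If an event
  factor *does* split the tree, it is priced by the branch and receives no
  extra weight — the update then happens through re-routing at the landmark.

The **landmark convention**: at evaluation time `t ≥ 1` (years), event
times strictly greater than `t` are masked; an onset exactly at `t` counts
as known (same-day availability of clinically-indicated screening). Scores
are monotone non-decreasing in `t`.

**Weights.** `weight(v) = round(VIMP(v) / VIMP(reference))`, clipped to
≥ 1, doubled onto the even scale; factors splitting at the same (smallest)
tree depth share the rounded mean of their raw ratios. The *reference* is
the weakest-VIMP variable that actually splits the tree. Taking instead the
weakest variable of the whole final ranking makes the ratios explode
whenever that variable's VIMP is near zero (a ratio of ~50 was observed on
synthetic data), which destroys the interpretability of the 0–12 scale; the
tree-variable reference guarantees the weakest retained factor weighs
exactly 2. On derived systems the attainable scores can still exceed 12, so
`stratify(..., clip=True)` maps the tail onto the top risk group.

**Known limitation.** VIMP is prevalence-weighted: a common moderate risk
factor (ScrM12 > 160 µmol/L, ~25% of patients) can out-rank a rarer but
individually more severe one (dnDSA). On roughly one synthetic cohort in
ten, the resulting branch weight for creatinine exceeds the capped event
weight while per-patient severity runs the other way, and the four risk
groups are then not strictly ordered in survival. This is a property of
ratio-of-importance weighting itself, not of the implementation.

## Random survival forest

1000 trees by default (tests and the acceptance script use 100–150; the
qualitative behavior is unchanged and a fit stays in seconds). Each tree is
grown on a bootstrap sample of size n drawn with replacement (≈ 63.2%
unique patients; the rest are out-of-bag). At each node, `mtry = ⌈√p⌉`
candidate variables are drawn; for each, `nsplit = 3` random cutpoints
(random level subsets for categoricals); the winner maximizes the absolute
standardized two-sample log-rank statistic (Breslow tie handling). A split
is admissible if both daughters keep ≥ `min_terminal_events` (default 3)
*patients*; recursion stops when a node holds fewer than that many events —
an all-censored daughter is allowed and simply carries a flat cumulative
hazard. Terminal nodes store the Nelson–Aalen cumulative hazard of their
in-bag members; a patient's *mortality* is the OOB-averaged sum of the leaf
hazard over the unique training event times. Prediction error is
`1 − Harrell's c` on OOB mortality; VIMP permutes a variable's OOB values
per tree and takes the error increase.

**Backward elimination.** Drop all non-positive-VIMP variables, then the
weakest positive one per refit. Refits share the forest seed (common random
numbers), so successive OOB errors are directly comparable. The returned
set is the *minimal combination with the smallest error* in the
one-standard-error sense: errors within one (rough, binomial-on-events)
concordance SE of the minimum tie, resolved toward the smaller set. Strict
minimization is available (`parsimony_se=0`) but measurably selects noise:
on simulated data, adding pure-noise variables *lowers* OOB error by
~0.005–0.01 because extra split diversity decorrelates the trees, while
dropping a truly informative variable costs several SE. Selection
simulations use `mtry=1`; with 2–5 candidates the default `⌈√p⌉` makes
trees nearly identical.

## Conditional inference tree

At each node the log-rank scores `sᵢ = δᵢ − Ĥ(tᵢ)` (Nelson–Aalen on the
node sample) are tested against each candidate covariate with the
Strasser–Weber permutation moments: a standardized linear statistic
(normal reference) for continuous covariates, a quadratic form with
Moore–Penrose inverse (χ², levels − 1 df) for categoricals. The smallest
p-value is Bonferroni-multiplied by the number of testable candidates;
splitting stops when it exceeds α = 0.05. The winning variable is split at
the observed midpoint maximizing the two-sample standardized statistic
(exhaustive search — the tree is fit once on the full sample, so no random
cutpoint subsetting here), subject to ≥ 20 patients per daughter. Boundary
values route to the "≤" daughter; there are no surrogate splits — a missing
split variable is an error.

On null data (independent covariates) the tree stays a single node in at
least 93% of runs at α = 0.05 (the suite asserts this over 150 replicates),
slightly conservative because of the Bonferroni step.

## Validation metrics

* **Kaplan–Meier / log-rank** are delegated to `lifelines` (Greenwood
  variance assembled from the event table); a hand product-limit oracle
  checks the wrapper to 1e-12.
* **Time-dependent ROC** uses the cumulative-cases / dynamic-controls
  definition at horizon t with inverse-probability-of-censoring weights
  from the Kaplan–Meier estimate of the censoring distribution: cases
  (events by t) weigh `1/Ĝ(Tᵢ−)`, controls (event-free beyond t) weigh
  `1/Ĝ(t−)`. A patient censored exactly *at* the horizon is a control —
  they are known event-free at t; this matters when administrative
  censoring ends follow-up exactly at the analysis horizon, as in the
  synthetic design. Without censoring the estimator reduces exactly to the
  Mann–Whitney AUC; with censoring it matches
  `sksurv.metrics.cumulative_dynamic_auc` to 1e-9.
* **Standard errors** come from a linearized (Hájek) representation of the
  weighted ratio estimators with the censoring weights treated as fixed —
  exactly DeLong under no censoring, mildly approximate otherwise; a seeded
  bootstrap (B = 200) is available. The paired AUC comparison uses the
  joint linearization; identical markers return p = 1 by construction.
* **Se/Sp/PPV/NPV at a cutpoint** are the corresponding IPCW-weighted
  proportions ("positive" means score > cutpoint); PPV/NPV are reported as
  NaN — not silently zero — when no test is positive/negative.
* **Calibration (D'Agostino–Nam).** Per risk group, expected failures are
  `Eᵢ = nᵢ(1 − KMᵢ,ref(t))` under the reference (development) survival, and
  the statistic sums `(O−E)²/E` over both the failure and non-failure
  margins, compared to χ² with groups − 2 df — the printed convention,
  reproduced here. Note the statistic's actual null distribution under an
  *external* reference is ≈ χ² with *g* df (the groups are independent;
  verified by simulation: mean 3.98 for g = 4), so the g − 2 convention is
  anti-conservative for external validation: ~19% rejection at nominal 5%
  even without censoring. The implementation keeps the published df; the
  test suite documents both facts. The per-interval variant (summing
  interval contributions over [0–2), …, [8–10]) is out of scope here; the
  aggregate-at-horizon form reproduces the published table.

## Synthetic cohorts

The generator encodes the design assumptions the analysis rests on, not any
real dataset:

* **Trajectories.** Three latent clusters with mean curves A (stable,
  ending 115 µmol/L), B (stable, ending 180), C (transient improvement then
  progressive rise to 345), probabilities (0.72, 0.19, 0.09), multiplicative
  lognormal noise with total CV 0.15 split between a patient-level factor
  (36% of the variance) and visit noise. ScrM12 is the month-12 trajectory
  value, so P(ScrM12 > 160) ≈ 0.25 follows from the mixture. These choices
  make the Calinski–Harabasz criterion recover k = 3 reliably at n = 600;
  they do not reproduce the real cohort's cluster shares.
* **Events.** dnDSA with 15% ten-year cumulative incidence; onset from a
  truncated exponential with median 1.42 y in pre-transplant-NDSA carriers
  vs 4.87 y otherwise. Rejection in 33% of dnDSA patients plus a background
  rate (18.4%) tuned so total first-rejection incidence ≈ 20.6%, onsets
  early (median 0.26 y).
* **Failure.** Exponential within stratum with per-patient multipliers
  (donor age > 60: ×1.5; proteinuria > 0.5 g/L: ×1.5; cluster C acts
  through its creatinine, not an extra multiplier), switching to the dnDSA
  stratum's rate at the latent onset. Rates are calibrated by root-finding
  on fixed-seed Monte-Carlo expectations so that ten-year survival,
  *conditional on surviving the one-year inclusion landmark* (patients
  failing earlier are discarded and redrawn, as a development cohort
  requires), hits 70/60/40/25% in the impaired / dnDSA / dnDSA+impaired /
  dnDSA+rejection strata, while the lowest-risk stratum's rate is solved so
  the population ten-year survival is 82%. Death with a functioning graft
  is an independent exponential (rate 0.0105/y, ≈ 9% by ten years);
  administrative censoring at 10 y.
* **Not modelled:** visit-schedule irregularity (all 13 monthly visits are
  generated; the schema accepts any), informative censoring,
  center/era effects, measured-covariate error, and any association between
  the extra candidate columns (cold-ischemia time, HLA mismatch) and
  failure beyond their correlation with clusters — they exist precisely to
  be *rejected* by variable selection.

Passing tests on these cohorts show the pipeline recovers structure it was
told to plant, at the planted effect sizes; they say nothing about real
transplant data, and the real cohort's headline AUCs (0.83/0.79) are not
targets.

## Problem sizes and determinism

Test and acceptance runs use n = 600–1000 cohorts, 100–150 trees, 10–20
k-means restarts, and a single 20 000-patient cohort for design-target
recovery; these sizes put every Monte-Carlo band in the tests at ≥ 2.5
standard errors. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical seeds give byte-identical cohorts,
weights and scores (asserted in the suite).
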