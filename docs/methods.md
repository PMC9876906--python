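# Methods

## Structural growth model

A treated lesion is modelled as two non-interacting cell populations: a
drug-sensitive fraction `1−F` killed with first-order rate `Kd` (log-kill
assumption) and a resistant fraction `F` regrowing exponentially at `Kg`:

    V(t) = V0 · [F·e^{Kg t} + (1−F)·e^{−Kd t}],   V0 > 0, F ∈ [0,1], Kg, Kd ≥ 0.

Longest CT diameters are converted to volume with a rotational ellipsoid,
`V = long·short²/2`, `short = long/1.31`; the conversion is exactly
invertible and the inverse is provided.

Event times are defined on this curve:

- **nadir**: `t* = ln[Kd(1−F)/(Kg F)]/(Kg+Kd)` when interior; 0 when the
  curve is non-decreasing from baseline; +∞ (volume → V0·F) for pure decay.
- **response**: smallest `t > 0` with `V(t) ≤ 0.8·V0`.  Unattainable when
  `F ≥ 0.8` since `V(t) ≥ F·V0`.
- **progression**: smallest `t ≥ t*` with `V(t) ≥ min(1.3·Vn, Vn + 200 mm³)`
  above the nadir volume `Vn`.  The default "or" semantics (either
  criterion triggers; min of thresholds) follows the volumetric adaptation
  used with these data; a `rule="and"` switch (max of thresholds) gives the
  RECIST-1.1-style conjunction.  Never reached when `F = 0` or `Kg = 0`.

Roots are found by bisection on analytically guaranteed brackets (response
on the decreasing branch `(0, t*)`; progression bracketed above by the
crossing of the pure-growth minorant `V0·F·e^{Kg t}`), absolute tolerance
1e−6 days; `F ∈ {0, 1}` short-circuit to closed forms to avoid degenerate
brackets.  Note the 20% volumetric response threshold is deliberately not
the RECIST 30%-diameter rule (≈ 65.7% volume); organ-level orderings are
insensitive to this choice, which is taken as given here, not re-verified.

## Population model and estimation

Lesion `j` draws its parameters as

    ln Kg_j = ln θ_Kg + η1_j,  ln Kd_j = ln θ_Kd + η2_j,  logit F_j = logit θ_F + η3_j,

`η ~ N(0, diag(ω²))` (diagonal: only variances are identifiable at the
sizes considered; correlations are not modelled).  Observed volumes carry
proportional error `y = f·(1+ε)`, `ε ~ N(0, σ²)`, with residual SD `σ·f`
computed from the *predicted* volume, the standard proportional-error
convention.  Volumes below the LOQ (200 mm³) are treated as left-censored:
their likelihood contribution is `Φ((LOQ − f)/(σ f))` (M3).  `σ = 0` with
censored rows present is rejected as degenerate.  Lesions whose every
measurement is below the LOQ carry no usable size information and are
excluded with a logged count.  Non-evaluable visits never enter the
likelihood.  Observations up to 84 days before treatment start are
included with the model extrapolated backward.

`V0` is a lesion-level nuisance parameter: a latent `ln V0` with a weak
normal prior (sd 1.0 on the log scale) centred at the lesion's first
quantified volume.  `pin_v0=True` pins it to that value instead.  The
default estimates it, because pinning to a noisy baseline propagates the
full measurement error of one observation into every derived event time.

Estimation is SAEM: per iteration, a coordinate-wise random-walk
Metropolis kernel refreshes each lesion's latent vector (ln Kg, ln Kd,
logit F, ln V0) — vectorized across lesions, two chains, step sizes
adapted toward 35% acceptance during the exploratory phase and frozen
afterwards — then sufficient statistics for (μ, ω) are updated with gain 1
for the 300 exploratory iterations and gain `1/k` for the 200 smoothing
iterations.  The censored terms break the closed-form exponential-family
update for σ, so σ is re-estimated each iteration by a bounded Brent
search on the pooled conditional log-likelihood and smoothed with the same
gain (with no censored rows the closed form is used directly).  Lesions
are processed in canonical (patient, lesion) order, so estimates are
exactly invariant to input row order and deterministic given the seed.
ω is floored at 1e−3 to keep the kernel mixing when variance components
collapse.

Empirical-Bayes lesion parameters are per-lesion posterior modes, found by
a vectorized Levenberg–Marquardt ascent (batched 4×4 Hessians by central
differences of the analytic gradient, per-lesion adaptive damping).  The
reported shrinkage diagnostic is `1 − Var_post/ω²` averaged over the three
random-effect coordinates, clipped to [0, 1]; single-observation lesions
return population-typical values flagged `full_shrinkage`.  The marginal
log-likelihood is evaluated by a per-lesion Laplace approximation at those
modes, independently of the SAEM trajectory, and is used to verify that
the returned estimate improves on the conventional initial values
(Kg = Kd = 0.01/day, F = 0.1, which are also the fit's defaults).

## Event dataset

Target-lesion events are model-derived continuous times from the
empirical-Bayes curves, not snapped to visit dates.  Non-target lesions
respond at their first CR/PR visit and progress at their first PD visit.
New lesions progress at their detection time and contribute no response
record; response analyses therefore exclude them while progression
analyses include them.  Lesions without an event are censored at the
patient's last day in the trial, read literally as the end of on-study
follow-up (death or censoring day) rather than the last imaging visit; a
new lesion recorded after that day is clamped to it with a warning.

## Frailty Cox models

For each endpoint a Cox model with organ fixed effects (reference organ:
abdomen), screened clinical covariates and a Gaussian patient-level random
intercept `b_i ~ N(0, θ)` (log-normal frailty) is fitted by penalized
partial likelihood: for fixed θ, Newton iterations maximize the Efron-tied
partial log-likelihood minus `b'b/(2θ)` jointly in (β, b); θ maximizes the
Laplace-integrated likelihood

    L(θ) = l_part(β̂, b̂) − b̂'b̂/(2θ) − ½ log det(H_bb + I/θ) − (q/2) ln θ

by Brent search on ln θ ∈ [ln 1e−4, ln 4].  Efron's tie correction is the
default, appropriate for the visit-grid ties of status-code events.
Confidence intervals are Wald intervals from the inverse penalized
information; per-term p-values are likelihood-ratio tests refitting
without the term at the estimated θ (a profile approximation that avoids
re-estimating the variance per contrast).  The frailty-free limit of the
fitter agrees with an independent Cox implementation (lifelines) to 1e−4,
and the Efron kernel is verified against a naive O(n²) reference.

Covariate selection is forward univariable screening: each candidate is
added singly to the organ-only model and kept when the likelihood-ratio
p-value is below 0.05; the final model refits jointly with the selected
set.  Organs with zero events for an endpoint cannot be contrasted and are
dropped with a warning.

Phenotypes: an organ is "high" on an axis when its HR against the
reference exceeds 1; the reference organ itself is labelled by comparing 1
with the median HR of the other organs.  The HR = 1 cut is a design choice
(no numeric threshold is standard); it is logged with the output.

## Progression sequences, clustering, survival

A patient's sequence is the time-ordered list of organs with at least one
progression event (earliest event per organ, ties broken lexicographically
and logged).  Sequences are embedded with one coordinate per catalog
organ: the progression rank (1 = first), with non-progressing organs at
sentinel rank (max observed rank + 1), columns standardized.  This
encoding preserves the two axes the clinical group names use — how many
organs progressed and which progressed first.  k-means (25 restarts,
seeded) clusters the embedding; per-k diagnostics report WSS (elbow), mean
silhouette, and AIC = WSS + 2kd / BIC = WSS + ln(n)·kd.  The automatic
recommendation is the silhouette argmax; the pipeline default is k = 5,
the externally adjudicated choice for this grouping, since survival-based
adjudication inside the pipeline would be circular.  Clusters are named by
majority composition: Mono-Organ (majority exactly one progressing
organ), Hetero-Organ (majority ≥ 4, configurable), otherwise
Liver-First / Lung-First / Other-First by the modal first-progressing
organ; ties follow a fixed preference order and duplicate names get
numeric suffixes so the names partition the cohort.  Sub-clustering the
Hetero-Organ group is the same operation applied to the subset.

Group survival uses Kaplan–Meier estimates with overall and pairwise
log-rank tests (lifelines).  Inter-progression gaps (first progression
time, 2nd−1st, 3rd−2nd, 4th−3rd, mean) are compared across groups by
Kruskal–Wallis with Dunn's rank-based pairwise z-tests (tie-corrected,
Bonferroni family adjustment) — implemented here because no installed
package provides Dunn's procedure.

The baseline predictor is a gradient-boosting classifier on demographics
plus the baseline metastatic profile (organs involved, lesion count, total
baseline target volume) — nothing else, since the informative feature set
is deliberately restricted to what is known at diagnosis.  Continuous
features are standardized and categorical features one-hot encoded inside
an sklearn pipeline; hyperparameters come from an F1-macro grid search
with 5-fold inner CV inside each of 5 outer folds (a 4:1 split with test
rotation); the reported macro AUC pools one-vs-rest scores over the outer
test folds.  Classes below 10 members merge into the nearest group by
feature centroid.

## Synthetic cohort generator

The generator emulates the data structure the analysis assumes, with
ground truth returned for scoring: per-organ occupancy and lesion counts;
organ-specific typical values around Kg = Kd = 0.01/day with multipliers
within [0.3, 3] planting the clinically described phenotype geography
(liver: high regression, low resistant fraction, high regrowth →
high-high; lung/LN: high-low; bone and brain/CNS: low-high; GR fastest
regrowth; kidney slowest regression); random effects ω = 0.4, proportional
noise σ = 0.2, V0 lognormal with median 3000 mm³; visits every 42 days to
336 days plus a baseline scan up to 28 days pre-treatment, 5% missed
visits; BLQ flagging below 200 mm³ with the numeric value withheld;
non-target lesions reported as status codes derived from their own latent
curves; new lesions appearing as a Poisson process whose rate grows with
the patient's progression burden, detected at the next scheduled visit;
treatment-arm effects multiplying (θ_F, θ_Kg) for the targeted-therapy
arm (0.70, 0.75), mirroring deeper response and slower regrowth.  OS is
exponential with log-hazard = baseline + first-progression-organ term
(liver +0.7, lung −0.3) + 0.10 per additional progressing organ; PFS is
min(first progression, OS); dropout hazard 8e−4/day and administrative
censoring at 730 days apply to both.  Patients leaving before the first
post-baseline scan are excluded, mirroring the no-longitudinal-data
exclusion criterion.  An optional shared patient-level shift on η (default
off) exists because inter-lesion correlation beyond the Cox frailty is not
otherwise modelled.

What the generator does **not** emulate: real lesion-number distributions
(ours average ~5 lesions/patient vs ~9 clinically), imaging re-read
variability beyond proportional noise, non-exponential survival shapes,
informative visit schedules, or trial-to-trial heterogeneity.  Passing
tests therefore demonstrate that the machinery recovers structure it is
pointed at, not that real cohorts satisfy the model.

A separate archetype generator plants the five progression-sequence
groups as well-separated patterns in near-disjoint organ pools (the
Hetero-Organ group as a permutation continuum over five organs, the other
groups as fixed short patterns) for cluster-recovery testing; its
`liver_first_gap_scale` shortens Liver-First follow-up gaps to plant
faster subsequent progression.

## Problem sizes and numerical choices

Default analyses run at 300 simulated patients (~700–1,500 target
lesions); the parameter-recovery experiment uses 250 patients with all
lesions measured (~1,500 lesions, ~20% BLQ, single organ so θ is
well-defined); frailty-Cox recovery uses 250 patients × 8 lesions; cluster
recovery 1,000 patients.  These sizes give each experiment enough
information for its stated tolerance while keeping a full run in minutes
on one CPU.  Bisection tolerance 1e−6 days; SAEM 300+200 iterations, two
chains; ω floor 1e−3, σ floor 1e−4; exponent clipping at ±500 guards
overflow on extreme random-effect draws; frailty variance searched in
[1e−4, 4] with profile values below the boundary snapped to it.

## Known limitations

- The SAEM σ update is a numeric M-step with stochastic averaging rather
  than an exponential-family update; it converges to the same stationary
  points but is not the textbook schedule.
- LRT p-values profile at the full-model frailty variance instead of
  re-estimating θ per reduced model.
- Clinical-trial-scale quantities (thousands of patients, real organ
  hazard ratios, cross-cancer validation) require access to the original
  trial repositories; everything quantitative here is property-based on
  synthetic cohorts with known truth.
- k-means on small messy cohorts tends to produce one dominant mixed
  cluster; group naming remains deterministic but suffixed duplicates
  signal that the grouping is weakly separated at that sample size.
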