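# lesiondyn

Lesion-level analysis of metastatic response and progression dynamics.

Metastatic cancer patients carry many lesions in different organs, and those
lesions often respond and progress very differently under one systemic
treatment.  `lesiondyn` implements, as a tested pipeline, the lesion-level
view of that heterogeneity for oncology biostatisticians and pharmacometric
modellers working with longitudinal RECIST-style tumor measurements:

1. **Growth modelling.** Each target lesion's volume trajectory follows the
   bi-exponential regression/regrowth model

   V(t) = V0 · [F·e^{Kg·t} + (1−F)·e^{−Kd·t}],

   with `F` the fraction of non-responding (resistant) cells, `Kd` the
   regression (kill) rate and `Kg` the regrowth rate.  Longest diameters are
   converted to volumes via a rotational ellipsoid with long/short axis
   ratio 1.31.  Parameters carry lognormal / logit-normal random effects,

   ln Kg_j = ln θ_Kg + η_j,  ln Kd_j = ln θ_Kd + η_j,  logit F_j = logit θ_F + η_j,

   and observations carry proportional error; volumes below the 200 mm³
   quantification limit contribute censored-likelihood terms
   Φ((LOQ − f)/(σf)) — the M3 method.  Estimation is SAEM (stochastic
   approximation EM), with empirical-Bayes lesion parameters.
2. **Event derivation.** Lesion-level time-to-response (−20% of baseline
   volume) and time-to-progression (+30% of nadir or +200 mm³, whichever is
   crossed first) are solved on the fitted curves; non-target lesions use
   their recorded CR/PR/PD status codes, new lesions progress at detection.
3. **Organ hazards.** Cox proportional-hazards models with a Gaussian
   patient-level random effect (log-normal frailty) contrast response and
   progression hazards across organs against an abdominal reference, with
   p<0.05 likelihood-ratio covariate screening, and classify each organ
   into a high/low response × progression phenotype.
4. **Progression sequences.** Per-patient organ-level first-progression
   sequences are embedded as progression ranks, clustered with k-means
   (elbow/silhouette/AIC/BIC for k), named Mono-Organ / Hetero-Organ /
   Liver-First / Lung-First / Other-First, and linked to overall survival
   by Kaplan–Meier / log-rank analysis and to inter-progression gap times
   by Kruskal–Wallis with Dunn's adjustment.  A gradient-boosting
   classifier predicts the group from baseline characteristics.

A synthetic-cohort generator with known ground truth (organ-specific
parameter distributions, BLQ censoring, new-lesion appearance, survival
coupled to the progression sequence) makes every stage testable without
access to clinical-trial data.

## Worked example

Run the full pipeline on the default 300-patient synthetic cohort:

```bash
lesiondyn run-all --seed 1 --out artifacts/
```

(about half a minute on one CPU; `lesiondyn simulate|fit|events|hazards|cluster|predict`
run stages individually, all driven by an optional `--config config.yaml`).
The report printed at the end summarizes, among other things:

```
theta_Kg = 0.008661 /day, theta_Kd = 0.01507 /day, theta_F = 0.116;
omega = (0.67, 0.64, 0.76); sigma = 0.200
```

the population typical values pooled over organs — regrowth ~0.0087/day,
regression ~0.015/day, ~12% typical resistant fraction, 20% proportional
measurement noise (exactly the generative value); the inflated ω reflect
organ-to-organ differences that the growth model deliberately leaves to the
random effects.  The organ hazard table then localizes those differences,
e.g. with abdomen as reference:

```
organ   endpoint     hr   ci_low  ci_high  p
liver   response     2.84   2.24    3.60   0.000
liver   progression  2.86   2.22    3.67   0.000
lung    response     4.13   3.22    5.30   0.000
lung    progression  0.25   0.19    0.33   0.000
```

so liver lesions both respond *and* progress fast (`high-high` in
`phenotypes.csv`), while lung lesions respond well and rarely progress
(`high-low`) — the phenotype structure planted in the generator.  Patients
whose first organ progression is hepatic inherit the planted survival
deficit (`km_medians.csv`, `sequences.csv`), and the baseline-feature
classifier reaches a pooled one-vs-rest macro AUC of 0.90 on the derived
progression groups (`classifier_report.csv`).

Ad-hoc event-time evaluation for one parameter set:

```bash
$ lesiondyn events --from-params 1000 0.2 0.005 0.05
nadir_time: 67.071 d
time_to_response: 5.956 d
time_to_progression: 138.206 d
```

## Library use

```python
from lesiondyn import (simulate_cohort, CohortConfig, TumorGrowthMixedModel,
                       derive_all_events, fit_frailty_cox)

measurements, patients, truth = simulate_cohort(CohortConfig(n_patients=300, seed=1))
model = TumorGrowthMixedModel(seed=1).fit(measurements)
events = derive_all_events(model.lesion_params_, measurements,
                           patients.set_index("patient_id")["os_time"])
cox = fit_frailty_cox(events, patients, "progression")
print(cox.organ_hazards_)
```

The estimator classes (`TumorGrowthMixedModel`, `FrailtyCoxPH`,
`ProgressionSequenceClusterer`, `ProgressionGroupClassifier`) follow
scikit-learn conventions (`fit`, `get_params`, fitted attributes with a
trailing underscore) and compose with sklearn tooling.

## Data formats

`measurements.csv` (one observation per row: patient_id, lesion_id, organ,
lesion_class target/nontarget/new, time in days, long_diameter mm and/or
volume mm³, below_loq flag, status_code for non-target rows) and
`patients.csv` (arm, demographics, surgery/line-of-therapy covariates,
OS/PFS with event flags); comma-separated UTF-8, empty fields for missing
values.  See `docs/methods.md` for the model, assumptions, and design
decisions.
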