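# littkinetics

Volumetric and diffusion MRI response kinetics of brain metastases after
laser interstitial thermal therapy (LITT).

LITT-treated brain metastases follow an unusual radiographic course: the
lesion *enlarges* immediately after ablation (transient heat-induced
blood-brain-barrier permeability) and its apparent diffusion coefficient
(ADC) drops, before responders shrink over months-to-years and progressors
regrow. Standard response reads that treat early enlargement as progression
get this wrong. `littkinetics` implements a quantitative pipeline for this
setting, aimed at neuro-imaging researchers and biostatisticians working
with longitudinal lesion measurements:

* **response categorization** — mRANO / RANO 2.0 volumetric rules adapted to
  LITT (progression = +40% over the after-LITT nadir, confirmed; durable
  partial response = -65% vs pre-LITT, maintained >= 4 weeks; long-term
  disease control; early-censored stable disease), with the day-0
  enlargement treated as baseline;
* **lesion-specific bi-exponential volume kinetics** — for progressors
  `V(t) = beta0 [alpha e^(-beta1 t) + (1-alpha) e^(+beta2 t)]`, for
  responders `V(t) = plateau + (beta0 - plateau)[alpha e^(-beta1 t) +
  (1-alpha) e^(-beta2 t)]` with `beta1 >= beta2`, both anchored at
  `beta0 = 100%` of the post-LITT volume and with rates bounded to
  [0, 0.1]/day; derived metrics: time to tumor growth (closed-form argmin),
  depth of shrinkage, pseudo-half-life, residual plateau;
* **follow-up schedule optimization** — earliest theoretical scan-day pair
  (t1, t2) separating progressors from responders on the fitted curves with
  accuracy >= 0.8 and a significant Fisher exact test;
* **group-level ADC trends** — cubic fit of `dADC(t) = ADC(t) -
  ADC(pre-LITT)` pooled per response group, plus paired pre/post/first
  follow-up summaries with Wilcoxon signed-rank tests;
* **subregion segmentation** (reduced scope) — CE mask by 0.7-thresholding
  the locally normalized post-contrast T1, whole lesion by morphological
  closing, central non-CE core by subtraction; volume and ADC extraction
  from NIfTI inputs sharing one grid;
* **a synthetic cohort generator** — first-class, tested code that emulates
  the statistical structure of a 47-lesion LITT cohort (category mix, scan
  schedules, dropout, noise, dip-then-rise ADC), so every downstream module
  is testable without patient data, with ground truth recorded for
  parameter-recovery studies;
* **the nonparametric statistics battery** — Wilcoxon signed-rank (exact
  null to n = 25, ties included), Mann-Whitney U, Spearman's rho (exact
  permutation p to n = 10), Fisher's exact test.

The bi-exponential fitting follows the statsmodels idiom: a model class
built from data whose `fit()` returns a results object with parameters,
R^2, `predict`, `metrics()`, `summary()` and `plot()`.

See `docs/methods.md` for the models, assumptions, numerical choices and
limitations.

## Worked example

```python
import littkinetics as lk

# synthetic cohort: 6 responders, 6 progressors, 2 early-censored lesions
config = lk.CohortConfig(n_pr=6, n_pd=6, n_ltdc=0, n_sd=2, seed=8)
trajectories, truths = lk.simulate_cohort(config)

categories = lk.categorize_cohort(trajectories)
labels = {lid: c.label for lid, c in categories.items()}

fits = lk.fit_cohort_kinetics(trajectories, labels)
print(fits["L001"].summary())
```

```
Bi-exponential fit (decay_decay) — lesion L001
  n timepoints : 11
  alpha        : 0.2309
  beta1 [/day] : 0.04264
  beta2 [/day] : 0.00753
  plateau [%]  : 3.653
  R^2          : 1.00
  depth of shrinkage [%] : 96.3
  pseudo-half-life [d]   : 66.2
```

Lesion L001 is a durable responder: 23% of its post-LITT enhancing volume
resolves with a fast ~16-day-half-life component (the blood-brain-barrier
surge washing out), the rest shrinks slowly (~92-day half-life component)
toward a 3.7% residual scar, and the curve reaches half of the post-LITT
volume 66 days after ablation. R^2 = 1.00 on the 11 post-LITT timepoints.

```python
print(lk.optimize_followup_schedule(fits, labels)["earliest_pair"])
```

```
{'t1': 34.0, 't2': 65.0, 'tp': 5, 'fp': 0, 'tn': 6, 'fn': 1,
 'accuracy': 0.9166666666666666, 'sensitivity': 0.8333333333333334,
 'specificity': 1.0, 'fisher_p': 0.01515151515151515}
```

On this small cohort, scans at days 34 and 65 are the earliest pair that
flags progression (fitted volume at t2 >= 140% of the t1 nadir proxy) with
accuracy above 0.8 and Fisher p < 0.05: 5 of 6 progressors flagged, no
responder falsely flagged.

The same pipeline runs from the shell:

```sh
littkinetics simulate --seed 8 --cohort cohort.csv --truth truth.json
littkinetics categorize --cohort cohort.csv --out categories.json
littkinetics fit --cohort cohort.csv --categories categories.json --out fits.json
littkinetics optimize --cohort cohort.csv --categories categories.json --out schedule.json
littkinetics adc-trends --cohort cohort.csv --categories categories.json --out adc.json
```

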