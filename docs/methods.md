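# Methods

`littkinetics` analyzes longitudinal MRI of brain metastases treated with
laser interstitial thermal therapy (LITT). This note describes the models,
the synthetic-data generator, the numerical choices, and the limits of what
the test suite demonstrates.

## Lesion model and subregions

Each lesion is tracked as an ordered scan series relative to the LITT day:
one pre-LITT scan (day < 0), the immediate post-LITT scan (day 0), and
follow-ups. Three subregions are measured per scan: the contrast-enhancing
(CE) component on post-contrast T1, the central non-CE component (necrotic
or cystic core; whole lesion minus CE), and the whole lesion. Volumes are in
cc; ADC (apparent diffusion coefficient) summaries are in 1e-6 mm^2/s.
Perilesional edema is never included.

## Volumetric response categories

Categories follow mRANO / RANO 2.0 volumetric thresholds applied to CE
volumes. The immediate post-LITT enlargement is expected (heat-induced
blood-brain-barrier permeability) and is the baseline, not an event.

* **PD < 1 y** — at a scan no later than day 365, CE volume >= 140% of the
  running after-LITT nadir (smallest measured CE volume from day 0 on),
  confirmed by a clinical re-treat decision (an input flag; it is not
  computable from imaging) or by a further >= 40% increase measured >= 28
  days after the first progression scan. The confirmatory increase is
  referenced to the first progression scan; the alternative reading
  (referenced to the nadir) is not used.
* **durable PR** — CE volume <= 35% of the pre-LITT volume on two
  consecutive scans whose days differ by >= 28, checked only when PD < 1 y
  never fired.
* **LTDC** — follow-up reaches day 365 without progression inside the first
  year (later progression still counts as long-term disease control).
* **SD < 1 y** — everything else (censored early, no event).

"Four weeks" is implemented as 28 days and "one year" as 365 days. All rules
are ratio-based, so the label is invariant to rescaling a lesion's volumes.

## Bi-exponential volume kinetics

CE volume is expressed as percent of the post-LITT scan (day 0 = 100%) and
fitted per lesion:

* progressors: `V(t) = beta0 [alpha e^(-beta1 t) + (1 - alpha) e^(+beta2 t)]`
  — resolution of the transient BBB opening plus exponential regrowth;
* responders: `V(t) = plateau + (beta0 - plateau) [alpha e^(-beta1 t) +
  (1 - alpha) e^(-beta2 t)]` — a steeper early decay plus a milder late
  decay toward a residual-scar plateau, with `beta1 >= beta2` enforced by
  the reparameterization `beta2 = beta1 * s`, `s in [0, 1]`.

`beta0` is fixed at 100, so both curves pass through 100% at day 0 exactly.
Rates are bounded to [0, 0.1]/day: a faster rate would mean a half-life or
doubling time under 7 days (`ln 2 / 0.1 ~= 6.93` d), biologically
implausible here. The plateau is bounded by [0, min observed percent].
Eligibility: >= 3 timepoints (progressors), >= 4 (responders), both
including day 0. LTDC lesions did not necessarily shrink and are excluded
from responder fitting by default; an override fits late-progressing LTDC
lesions with the progressor model.

Fitting is bounded nonlinear least squares (scipy `least_squares`, trf) over
a deterministic multi-start grid (`alpha in {0.1, ..., 0.9}`, rates in
`{0.001, 0.005, 0.01, 0.05, 0.1}`, decay-ratio starts `{0.05, 0.5, 1.0}`),
coarse tolerance with a capped iteration budget per start, then a tight
(1e-14) polish of the winner; ties go to the earlier start in grid order.
Fits are unweighted and on the percent scale; R^2 = 1 - SSE/SST about the
mean observed percent. A flat series (SST = 0) yields R^2 = 1 only for a
perfect fit, NaN otherwise.

Derived metrics, evaluated on a 1095-day horizon (~3 years of follow-up,
configurable):

* **time to tumor growth (TTG)** — argmin of the progressor curve, from the
  closed form `t* = ln(alpha beta1 / ((1-alpha) beta2)) / (beta1 + beta2)`
  clipped to [0, horizon]; `alpha = 1` or `beta2 = 0` flags "no regrowth"
  (TTG = horizon), `alpha = 0` or `t* <= 0` flags "immediate regrowth"
  (TTG = 0).
* **depth of shrinkage** — 100 minus the minimum fitted percent volume.
* **pseudo-half-life** — first day the responder curve reaches 50% of the
  post-LITT volume, by bracketed root-finding on the monotone curve
  (`brentq`, xtol 1e-8); undefined (NaN, not an error) when the plateau is
  >= 50% or 50% is not reached on the horizon. This is distinct from a
  mono-exponential half-life.

Identifiability: a bi-exponential's individual coefficients are only weakly
identified from a dozen points, and a progressor sampled at exactly 3
post-LITT timepoints is interpolated exactly but non-uniquely. Fitted
*curves* on the sampled span, and the rank ordering of the derived metrics,
are stable; extrapolation far beyond a progressor's last scan is not, which
is why the recovery checks are metric-based (Spearman correlation against
generator truth), not coefficient-based.

## Follow-up schedule optimization

Given the fitted curves of progressors and durable responders, candidate
scan pairs (t1, t2) on an integer-day grid (default 7..365, 1-day
resolution) are classified per lesion: nadir proxy = min(100, predict(t1));
flag progression iff predict(t2) >= 1.4 x proxy, or predict(t1) >= 140.
This applies the 40%-over-nadir volumetric threshold to the fitted values;
it is a stated proxy for an unavailable reference rule and is isolated in
one function so alternatives can be swapped. Consequently the package's
optimal pair is structurally comparable to, but not a numerical replication
of, any particular cohort's published pair.

A pair qualifies when accuracy >= 0.8 (configurable) and the two-sided
Fisher exact p < 0.05; among qualifying pairs the result minimizes t2 (the
decision-gating later scan), then t1. The search precomputes per-day
predictions but is exhaustively equivalent to a naive double loop (tested).
Confidence intervals on accuracy/sensitivity/specificity are out of scope.

## ADC trend model

Per lesion and subregion, `dADC(t) = ADC(t) - ADC(pre-LITT)`. Group-pooled
(responders PR/LTDC vs progressors PD < 1 y) pairs (day, dADC) are fitted
with an ordinary-least-squares cubic, the pre-LITT anchor included at its
true negative day with dADC = 0 rather than forcing the intercept — this
keeps the fit plain OLS while honoring the anchor. The cubic is a
group-level visualization of the dip-then-rise trend, not a lesion-level
model; it needs >= 5 points on >= 4 distinct days. Scans missing DWI and
subregions absent on a scan are excluded; paired pre/post/FU1 summaries
(median difference + two-sided Wilcoxon signed-rank) exclude lesions
pairwise. Both median and mean per-subregion ADC are stored; the median is
the default summary (robust to necrotic-core outliers).

## Statistics battery

Two-sided p-values throughout. Wilcoxon signed-rank (paired and one-sample)
drops zero differences and uses an exact null for n <= 25 nonzero
differences — enumerated by an integer shift-sum dynamic program over
doubled (possibly tied, half-integer) ranks — and a tie-corrected normal
approximation beyond. Mann-Whitney U is exact for min(n) <= 8 without ties,
asymptotic otherwise (scipy). Spearman's rho uses average ranks on ties,
with an exact permutation p for n <= 10 and the t approximation beyond.
Fisher's exact test is the usual two-sided hypergeometric tail-mass sum
(scipy). No multiple-testing correction is applied.

## Synthetic cohort generator

The generator is the package's study-conditions stand-in for patient data.
Defaults emulate a 47-lesion cohort: 17 durable PR, 12 PD < 1 y, 4 LTDC,
14 SD < 1 y; nominal follow-ups at days 33, 63, 95, 130, 180, 270, 365,
550, 730, 1000 with +/- 3 days of uniform integer jitter; pre-LITT scan at
a sampled day in [-30, -1]. Follow-up truncation is deterministic per
category: SD lesions censored after day 70; progressors followed until the
noise-free curve first exceeds 140% of its running nadir (where the
re-treat flag is set) plus one confirmatory scan; responders/LTDC keep the
full schedule. This reproduces the follow-up-duration contrast (responders
~3 years, progressors a few months).

Ground-truth curves are sampled from uniform priors chosen once to land on
a realistic cohort scale (pre-LITT CE volume 0.7-4.7 cc; post/pre
enlargement factor 1.3-2.3, i.e. a median surge near +80%; progressor
alpha 0.6-0.95, beta1 0.02-0.1, beta2 0.015-0.05; responder alpha
0.15-0.45, beta1 0.02-0.08, beta2 0.004-0.009, plateau 0-8%; LTDC/SD
plateaus 45-85% / 70-95%). The responder plateau ceiling stays below the
durable-PR threshold implied by the smallest enlargement factor, so every
noise-free responder trajectory can fire the -65% rule, while the high
LTDC/SD plateaus cannot; every progressor curve eventually exceeds 140% of
its running minimum. These priors put the median pseudo-half-life at
roughly two to three months and the median TTG near one month.

Measurement noise: volumes are multiplied by lognormal noise with CV equal
to `volume_noise_cv` (sigma = sqrt(ln(1 + cv^2)), so the ratio CV matches
the parameter exactly); ADC noise is additive Gaussian. Volumes are
positive by construction; errors scale with size.

ADC trajectories follow a piecewise-cubic monotone (PCHIP) template through
anchor points: baseline at the pre-LITT day; a day-0 drop centered on the
observed medians (CE -101, central non-CE -224, whole -137, each scaled by
a per-lesion factor); an optional further dip at ~35-55 days; and, for
responders, a rise crossing baseline at a sampled day in 180-270 that
plateaus ~150 days later at an elevated long-term level (+250 x a
per-lesion factor, debris clearance complete within the first year).
Progressors stay at or below baseline over their short follow-up. The
anchor magnitudes beyond the day-0 medians are invented, calibrated once so
that the pooled cubic fit of a default responder group is negative over the
first ~3 months and crosses zero between roughly 6 and 9 months. A small
fraction of scans lack DWI (4%) and of lesions lack a pre-LITT central
non-CE component (8%), exercising the pairwise-exclusion paths.

What the generator does **not** emulate: scanner/protocol heterogeneity,
registration or segmentation error structure, informative dropout beyond
the deterministic truncation rules, atypical responders (e.g. a ~6-month
stable phase before late shrinkage), correlated noise across subregions,
or MRI physics of any kind. Tests passing on this generator demonstrate
the pipeline's internal correctness under its stated assumptions, not
performance on clinical data.

## Digital phantom and segmentation

The phantom is an analytic spherical shell: enhancing rim (inner < d <=
outer radius, default 6/10 mm) around a hypointense core on a darker
background, with a contour mask padded 2 mm and known analytic plus
voxel-count volumes. Segmentation normalizes T1 to [0, 1] over the contour
dilated by 10 mm of Euclidean distance (a local reference keeps the fixed
0.7 threshold meaningful on cropped images), thresholds at 0.7 inside the
contour, closes the CE mask (dilate -> fill holes -> erode, 6-connected
3x3x3 cross, one iteration each — the cited closing chain's defaults), and
subtracts to get the central non-CE mask. The manual-adjustment step is
replaced by an optional user-supplied override mask. Inputs must share one
voxel grid; no resampling or registration is performed. Recovery of the
shell volumes is expected within a 2-voxel boundary shell of discretization
error; whole = CE + non-CE holds exactly by construction.

## Problem sizes and reproduction

The default test suite and the reproduction script use the 47-lesion
default cohort, a 20-lesion cohort for the optimizer-oracle check, eight
pooled default cohorts (at volume CV 5%) for the metric-recovery study —
pooling keeps the Spearman-rho estimate's Monte-Carlo error small relative
to the quantity itself — 1000 random parameter draws for the closed-form
TTG check, and 10,000 replicates for the type-I-error calibration.
`scripts/acceptance.py --seed <int> --out <path>` recomputes all headline
quantities from scratch; all randomness derives from the single seed.

## Known limitations

* Progressor fits at the minimum 3 timepoints interpolate exactly but are
  not identifiable coefficient-wise; extrapolated curves can be wild.
* The pair-classification rule at theoretical timepoints is a constructed
  proxy (see above).
* The generator's priors are free parameters of the package; no
  distributional information beyond bounds and reported medians exists to
  pin them down.
* The cubic ADC trend is a visualization device; it can cross zero twice
  and diverges outside the sampled day range.
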