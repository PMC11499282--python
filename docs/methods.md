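# Methods

This note documents the models, algorithms and design choices behind
`pedgait`, and what the synthetic-data experiments do and do not
demonstrate.

## Gait model and event detection

The analyzer works on the vertical acceleration of a lumbar-worn tri-axial
accelerometer. The gravity-bearing axis and its sign are auto-detected
from the low-pass (0.5 Hz) component with the largest absolute mean, so
device orientation is never assumed.

Events are detected with the established trunk-accelerometry recipe:
detrend, low-pass (4th-order Butterworth, 10 Hz, zero phase), cumulative
trapezoidal integration, then a continuous wavelet transform with a
first-derivative-of-Gaussian wavelet (`gaus1`). The wavelet scale is tied
to the dominant frequency of the integrated signal's periodogram within
0.6–4 Hz, so the smoothing bandwidth tracks the walker's step frequency
across natural, fast and slow walking. Initial contacts (IC) are local
minima of the first transform; final contacts (FC) are local maxima of the
transform of its derivative. The transform sign is normalized against the
filtered acceleration so "minimum" always means an impact deceleration.

Candidate events are screened by static physiological bounds held constant
across speed classes: step time in [0.1, 1.5] s and stride time in
[0.25, 2.25] s by default (all exposed in `GaitParams`). Of two IC
candidates closer than the minimum step time, the less prominent one is
discarded. Feet are assigned by alternation; laterality is relative (the
left/right labels are arbitrary up to a swap).

Temporal metrics follow directly: one stride per consecutive same-foot IC
pair, cadence = 120 / stride time, step times from alternating ICs, double
support from the FC-to-contralateral-IC overlaps; strides spanning a
detected gap are not formed, and fewer than three ICs yields "no strides"
rather than an error.

## Inverted-pendulum spatial metrics

Vertical center-of-mass displacement is reconstructed by high-pass
filtering the vertical acceleration, integrating twice, and re-applying
the same high-pass after each integration to suppress drift. The per-step
excursion *h* is the max − min of displacement within the step, and the
step length follows the pendulum chord

    step_length = 2 * sqrt(2 * l * h - h**2),    l = 0.53 * height,

with stride length the sum of its two step lengths and speed = stride
length / stride time (an exact identity in the output). Steps with
*h* ≥ 2 *l* are geometrically impossible and the stride is excluded.

The displacement high-pass default is 0.7 Hz (zero-phase, 4th order). A
corner well below the step band was tried first; double integration
amplifies low-frequency content so strongly (white accelerometer noise has
an f⁻⁴ displacement spectrum, and each impact transient carries net
velocity) that a 0.1 Hz corner leaves drift that dominates the per-step
excursion. 0.7 Hz sits safely below the slowest step frequency this
population produces (~1.4 Hz at slow walking) while attenuating the drift
band; at 2× the corner the 4th-order response is within 0.5% of unity.

## Synthetic walkway passes

The generator plants a minimal walking signal sharing the analyzer's
pendulum geometry so that spatial recovery is well-posed: gravity on a
configurable vertical axis, a sinusoidal CoM component at step frequency
whose per-step excursion equals the value the pendulum model implies for
the planted step length, and a 50 ms half-sine impulse at each IC. The
CoM phase puts acceleration minima exactly at the planted IC times. The
impulse amplitude defaults to 0.1 g — a small perturbation on the CoM
component (~0.3 g at natural speed), as a lumbar sensor sees after soft
heel strikes; a dominant impulse would cancel part of the CoM fundamental
and bias the excursion channel. Cadence and step length default to age-
and speed-class-typical values (e.g. natural cadence 132/122/112 spm for
the 3–5, 6–11 and 12–17 strata; step length 0.41 × height) and are
overridable per call. All randomness flows from one seeded generator per
call; planted truth is independent of the noise realization.

These passes exercise the detector and the integration chain, not real
biomechanics: no turning, asymmetry, stride-to-stride variability or
sensor misalignment. Passing recovery tests shows the pipeline is
internally consistent and noise-tolerant (median errors ~0.3% cadence,
~1.2% stride length at 0.05 g noise), not that it is accurate on real
children.

## Free-living days

Days start at local midnight and are half-open. Each day has a 14 h wake
span (07:00–21:00 by default), log-normal gait-bout lengths (median 60 s,
σ = 0.6 log-units, 8 bouts/day), one 120-min off-body block, and the rest
filled with activity segments whose per-axis movement sd is ordered by
class (sedentary 0.05 g, light 0.15 g, moderate 0.4 g, vigorous 0.8 g,
band-limited to 0.3–4 Hz). The study's wear instructions are honored:
lumbar devices are removed for sleep (nights are gravity-only non-wear),
wrist devices stay on with brief position shifts every ~20 min so
sustained-zero logic does not mistake sleep for non-wear. All schedule
intervals are snapped to whole epochs, which is what makes exact
wear-time bookkeeping achievable downstream. The at-home activity
composition is not described by any reference protocol; these defaults
are package choices, exposed in `SimConfig`.

## Bout detection

Windows are 3 s with 50% overlap. Features per window: per-axis mean/sd,
signal magnitude area, and — from the gravity-bearing axis — dominant
frequency, its power, spectral concentration (peak/total), and the
autocorrelation at the dominant-period lag. The signed axis signal is used
for spectral features because a vector norm rectifies the walking
sinusoid and doubles its apparent frequency.

The primary detector is a LightGBM gradient-boosted tree classifier
(`BoutClassifier`, scikit-learn API, seeded and deterministic), trained on
generator-labeled windows; no weights are bundled — training is
reproducible from the generator instead. The deterministic fallback
requires dominant frequency in 1–3 Hz, spectral concentration ≥ 0.5,
step-lag autocorrelation ≥ 0.6 and motion sd ≥ 0.05 g. Positive windows
merge into bouts, bridging gaps ≤ 3 s; each bout is then run through the
gait module to populate strides and gait-cycle counts.

## Counts, wear and intensity

Counts are an open surrogate for proprietary device counts: per axis,
band-pass 0.25–2.5 Hz, rectify with a 0.075 g dead band (so a stationary
device yields exactly zero), clip at 8 g, and sum per 60 s epoch
(units g·s). Each epoch is filtered in isolation so movement cannot leak
across an epoch boundary — zero epochs are exactly zero. The vector
magnitude is the Euclidean norm of the three axis counts.

Non-wear uses the sustained-zero-run algorithm with its canonical
parameters: runs ≥ 90 min of zero vector magnitude are non-wear, allowing
≤ 2 min of nonzero spikes flanked by ≥ 30 min of zeros on both sides.

Intensity classes come from vector-magnitude cut-points c1 = 4, c2 = 14,
c3 = 35 g·s/epoch, calibrated once against the generator's class energies
(simulated epoch distributions: sedentary ≤ 1.3, light 7–9, walking
~19–27, moderate 20–27, vigorous 47–55). They are meaningful only within
this artifact — real-device cut-points depend on the device's count
definition and would be configured here. An optional two-regression mode
splits epochs on the coefficient of variation of sub-epoch counts and
applies one of two configurable MET regression equations before MET
thresholds (1.5 / 3 / 6 METs). Non-wear epochs are excluded from all
daily totals; MVPA = moderate + vigorous minutes.

## Study rules and aggregation

Exactly as specified by the protocol: bouts kept iff 10 s ≤ duration ≤
3000 s (boundaries retained) and ≥ 4 gait cycles; lumbar days valid at
≥ 10 h wear, wrist days at ≥ 18 h (thresholds inclusive); daily gait
values are the mean across bouts of per-bout stride medians; compliance
= 100 × compliant / observed days, inclusion at ≥ 4 compliant days; no
imputation. The 95th-percentile gait speed uses linear interpolation
between order statistics. Whether the percentile is taken over per-bout
medians or pooled strides is genuinely ambiguous; the default is per-bout
medians, consistent with the bout-then-day hierarchy, with the pooled
alternative behind a flag.

## Statistics

- **ICC(2,1)** is computed from the two-way ANOVA decomposition,
  (MSR − MSE) / (MSR + (k−1) MSE + k(MSC − MSE)/n), with the F-based
  confidence interval for the absolute-agreement single-measure form. An
  all-equal table is defined as ICC 1 with a degenerate interval and a
  warning. Benchmarks: ≤ 0.4 poor, 0.4–0.59 moderate, 0.6–0.74 good,
  0.75–1 excellent (0.4 itself is poor). Tests verify agreement with an
  independent longhand sums-of-squares oracle (1e−10) and with pingouin.
- **Paired Wilcoxon signed-rank**: zeros dropped, ties mid-ranked. With
  ≤ 12 nonzero pairs the null distribution of W⁺ is built exactly from
  the sign-flip generating function over doubled (integer) ranks — valid
  under ties, unlike table lookups; otherwise a normal approximation with
  tie-corrected variance and continuity correction. The exact branch is
  test-locked to full 2ⁿ enumeration.
- **Setting contrast (MMRM)**: a linear mixed model with fixed effects
  for setting and age group and a subject random intercept, REML-fitted
  (statsmodels MixedLM). The in-clinic − at-home contrast uses a t
  reference with between-within degrees of freedom (subjects − fixed
  effects); a plain normal Wald interval under-covers at typical cohort
  sizes (~93% observed at n = 40 vs ~95–97% with the t reference).
- **Age-group ANOVA**: one-way ANOVA on per-subject summaries with all
  three pairwise comparisons; multiplicity adjustment is configurable
  (Tukey HSD default, Bonferroni or none).
- **Comfort score**: 10 Likert items mapped to 0–4 with 4 most favorable;
  negatively-worded items are reverse-keyed via a configurable key (the
  item key is questionnaire-specific and is supplied as config, not
  hard-coded); total in 0–40.

## Problem sizes and determinism

The validation harness uses sizes chosen to make the Monte-Carlo noise
floor small relative to the tolerances: 200 noisy walkway passes for
recovery error, 1000/500 replicates for ICC recovery, ANOVA size/power
and CI coverage, one 14-day subject for exact compliance bookkeeping.
Identical configs (including seeds) give bit-identical generator output
and byte-identical pipeline CSVs.

## Known limitations

- Trained on and validated against the package's own generator; no claim
  of transfer to real pediatric accelerometry is made or testable here.
- Counts and cut-points are artifact-internal surrogates, not comparable
  to any commercial count scale.
- Turning, stairs, asymmetry and wrist-based gait are out of scope; foot
  laterality is relative.
- The non-wear detector assumes 60 s epochs and a contiguous epoch index.
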