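# pedgait

Gait and physical-activity analytics for pediatric wearable-accelerometer
studies.

Wrist- and lumbar-worn tri-axial accelerometers are increasingly used to
measure how children (ages 3–17) walk and move, both during staged
in-clinic walking tasks against an instrumented walkway and across ~2-week
free-living wear at home. `pedgait` implements the full analysis chain for
such a study, plus a synthetic-data generator with planted ground truth so
that every stage can be verified end to end:

- **Gait metrics from lumbar accelerometry** — initial/final contact
  events via a continuous wavelet transform of the integrated vertical
  acceleration (Gaussian-derivative wavelet, scale tied to the dominant
  step frequency), temporal metrics (stride time, step time, cadence
  = 120 / stride time, double support), and spatial metrics from the
  inverted-pendulum model: step length = 2·√(2 l h − h²), where *h* is the
  vertical center-of-mass excursion from double integration and
  *l* = 0.53 × height is the pendulum length.
- **Free-living gait-bout detection** — a gradient-boosted tree window
  classifier (LightGBM) over spectral/temporal window features, plus a
  deterministic band-power fallback so the pipeline runs untrained.
- **Wear time and activity intensity** — surrogate activity counts
  (band-pass, rectify, dead-band, epoch sum), the Choi sustained-zero
  non-wear algorithm (90/2/30-min parameters), and vector-magnitude
  cut-points yielding sedentary / light / moderate / vigorous minutes,
  daily MVPA and total vector magnitude.
- **Study rules** — bouts kept iff 10 s ≤ duration ≤ 3000 s and ≥ 4 gait
  cycles; valid days need ≥ 10 h (lumbar) / ≥ 18 h (wrist) wear; daily
  gait values are the mean over bouts of per-bout stride medians, plus the
  95th-percentile gait speed; subjects need ≥ 4 valid compliant days.
- **Validation statistics** — ICC(2,1) (two-way random effects, absolute
  agreement, single measurement) with F-based CIs and the standard
  benchmarks (≤ 0.4 poor, 0.4–0.59 moderate, 0.6–0.74 good, 0.75–1
  excellent), Pearson r, an exact paired Wilcoxon signed-rank test, a
  repeated-measures mixed-model (random subject intercept, REML) contrast
  of in-clinic vs at-home gait adjusted for age group, one-way age-group
  ANOVA with pairwise comparisons, and 0–40 comfort-questionnaire scoring.

## Worked example

Simulate a noise-free 30 s walkway pass at 110 steps/min for an
8-year-old of height 1.30 m, and recover the planted gait metrics:

```python
from pedgait import SimConfig, SubjectProfile, analyze_pass, simulate_walk_pass
import numpy as np

profile = SubjectProfile("S001", age_years=8.0, height_m=1.30)
cfg = SimConfig(noise_sd_g=0.0, seed=1)
rec, truth = simulate_walk_pass(profile, "natural", 30.0, cfg, cadence_spm=110.0)

strides = analyze_pass(rec, profile.height_m)
print(len(truth.ic_times), len(strides))
print(round(float(np.median([s.stride_time_s for s in strides])), 3),
      round(float(truth.stride_times_s[0]), 3))
print(round(float(np.median([s.stride_length_m for s in strides])), 3),
      round(float(truth.stride_lengths_m[0]), 3))
```

prints

```
55 53
1.094 1.091
1.044 1.066
```

55 planted initial contacts yield 53 full strides; the estimated median
stride time matches the planted 1.091 s to within a sample period, and the
inverted-pendulum stride length (1.044 m) recovers the planted 1.066 m to
about 2%.

The same stages are exposed on the command line:

```bash
pedgait simulate pass --duration 20 --seed 1 --out pass.csv
pedgait gait --input pass.csv --height 1.30 --out strides.csv
pedgait validate --seed 1 --out clinic_report/
```

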