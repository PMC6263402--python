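# stepmatch

Template-based step detection for foot-worn inertial measurement units
(IMUs), with an adapted Pan-Tompkins baseline, event-level evaluation
metrics, and a ground-truthed synthetic gait simulator.

## The problem

Quantifying gait from a foot-mounted IMU starts with finding the steps: the
intervals between one foot-flat and the next heel-off in which the foot
actually moves. Threshold- and peak-based detectors need per-cohort
calibration and degrade on pathological gaits. An alternative is to
recognise whole step shapes: slide a library of exemplar steps (templates)
along the signal and place a step wherever a template fits well. Because
the fit measure is the Pearson correlation, detection is invariant to
signal amplitude and to sensor-orientation DC offsets, which is what lets
one template library serve healthy and pathological walkers alike.

## Method

A recording is a `3×Nx` signal `x` (Z-axis acceleration, recalibrated
vertical acceleration, Y-axis angular velocity); each template `p` in the
library `P` is a `3×Np` exemplar of one step. The detector:

1. **Correlation.** For every component `k`, template `p` and lag `t`,
   compute the sliding Pearson correlation
   `r(k, p, t) = ρ(p(k), x(k)[t : t+Np])`.
2. **Candidates.** Keep the strict local maxima of each correlation track:
   `L = {(k, p, t) : r(k,p,t) > r(k,p,t−1) and r(k,p,t) > r(k,p,t+1)}`.
3. **Greedy placement.** Repeatedly accept the highest-scoring candidate
   whose interval `[t, t+Np)` overlaps no previously accepted step; stop
   when every sample is taken, `L` is exhausted, or the best remaining
   score falls below the threshold **λ** (default 0.6).
4. **Amplitude gate.** Discard any accepted step whose signal segment has
   `σ(x(k)[t_start:t_end]) < μ · σ(p(k))` (default **μ** = 0.1) — scale
   invariance would otherwise let near-zero rest segments match templates.

Detections are scored against annotations event-wise: a detected step is
correct iff the midpoint of its interval lies inside an (unclaimed)
annotated step, and symmetric for recall; timing errors ΔStart, ΔEnd,
ΔDuration are signed detected-minus-annotated differences in samples.

The Pan-Tompkins baseline (bandpass → derivative → squaring →
moving-window integration → local-maxima peak search → activity gate) is
included for comparison, with its five parameters tuned by grid search; it
locates step peaks only, not start/end times.

## Worked example

```python
import numpy as np
from stepmatch import (SimConfig, make_library, simulate_recording,
                       detect_steps, evaluate_detection)

library = make_library(10, rng=42)                     # 10 synthetic templates
rec, truth = simulate_recording(
    SimConfig(n_steps=30, noise_sigma=0.05, seed=7), library)
steps = detect_steps(rec, library)                     # defaults λ=0.6, μ=0.1
report = evaluate_detection(steps, truth.steps)

print(f"{len(steps)} steps detected in {rec.n_samples} samples")
print(f"precision = {report.precision:.3f}, recall = {report.recall:.3f}")
print(f"mean |dStart| = {np.mean(np.abs(report.delta_start)):.2f} samples")
s = steps[0]
print(f"first step: [{s.start}, {s.end}) template {s.template_index} "
      f"component {s.component} r = {s.score:.3f}")
```

prints

```
30 steps detected in 3664 samples
precision = 1.000, recall = 1.000
mean |dStart| = 1.07 samples
first step: [98, 187) template 1 component 2 r = 0.989
```

i.e. all 30 planted steps are recovered, starts are located to about one
sample on average, and the first step was matched by template 1 on the
angular-velocity component with correlation 0.989.

The same pipeline is available from the shell:

```
stepmatch simulate --seed 7 --n-steps 30 --out-signal s.csv \
    --out-annotations a.csv --out-library lib/
stepmatch detect --signal s.csv --library lib/manifest.json --out steps.json
stepmatch evaluate --detections steps.json --annotations a.csv --out report.json
stepmatch sweep --signal s.csv --annotations a.csv --library lib/manifest.json \
    --out sweep.csv
```

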