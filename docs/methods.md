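# Methods

## Detection model

The detector treats step finding as multivariate template matching. A
step exemplar (template) is a `3×Np` matrix over the canonical component
order — Z-axis acceleration, recalibrated vertical acceleration, Y-axis
angular velocity — and a recording is a `3×Nx` matrix in the same order.
For each component `k`, template `p` and lag `t`, the Pearson correlation
between `p(k)` and the signal window `x(k)[t : t+Np)` scores how step-like
the window is. The Pearson coefficient is used because step amplitude
varies across subjects and pathologies (scale invariance) and because the
orientation of a foot-worn sensor adds an arbitrary DC component to each
channel (offset invariance). Matching happens at each template's native
length only; duration variability is expected to be absorbed by a library
that spans the duration range, not by time warping.

Candidates are the strict local maxima of each correlation track. Placement
is greedy: best score first, an accepted step forbids all samples of its
half-open interval, overlapping candidates are discarded, and the loop
stops when the best remaining score drops below λ. A final pass removes
accepted steps whose segment standard deviation is below μ times the
matched template component's standard deviation: these are rest-period
matches that only exist because correlation ignores scale.

Assumptions: the three components are given in consistent units between
templates and recordings (correlation is unit-free; only the μ gate
compares amplitudes); steps do not overlap in time; each step is similar in
shape, at its own scale, to at least one library template.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| λ | minimum correlation for placement / greedy stop | 0.6 | flat response in [0.5, 0.8] on the benchmark |
| μ | minimum segment-to-template std ratio | 0.1 | flat response in [0.05, 0.15] |
| fs | sampling rate [Hz] | 100 | metadata for the detector (all thresholds in samples); used by the baseline's filters |

## Numerical choices

* **Population moments** (divide by `n`) everywhere a standard deviation or
  covariance appears. The correlation ratio is identical with sample
  moments; fixing one convention makes brute-force oracles bit-comparable.
* **Degenerate windows.** A constant signal window (foot-flat rest) has no
  defined correlation; it scores the sentinel 0 — "no evidence of a step" —
  and is flagged so it can never become a candidate. A window counts as
  degenerate when its variance is below 1e-13 of its mean square, which
  absorbs the cancellation error of the cumulative-sum implementation.
* **Fast sliding correlation** uses cumulative window sums plus a direct
  cross-correlation (`numpy.correlate`); the test suite holds it to within
  1e-9 of the per-lag definition on random signals.
* **Clipping.** Correlations are clipped to [−1, 1] after computation.
* **Plateaus.** Local maxima are strict on both sides; equal-valued
  neighbours yield no candidate. Plateaus are measure-zero on continuous
  data; fidelity to the printed definition wins over recall on synthetic
  corner cases.
* **Tie-breaking.** Equal scores are ordered by (earliest lag, lowest
  template index, component order), making the greedy output a total
  deterministic function of its input.
* **Intervals** are 0-based half-open `[start, end)`; abutting steps do not
  overlap, since consecutive real steps can abut.
* **The μ gate runs once**, after the greedy loop; samples freed by a
  rejection are not offered back to other candidates. This costs a little
  recall on genuinely low-amplitude steps (e.g. U-turns) but keeps the
  algorithm a single forward pass.

## Evaluation

Precision: a detected step is correct iff the midpoint `(start+end)/2` of
its interval lies inside an annotated interval not already claimed in the
pass; multiple detections on one annotation count once. Recall is the
symmetric rule with roles swapped; the passes are independent. Within a
pass, claiming proceeds in ascending start order (first claim wins) —
deterministic, and consistent with reading annotations as a timeline.
Midpoints are not rounded; "inside" is `start ≤ m < end`. Δ metrics
(signed, in samples) are computed over the precision-pass pairs. Aggregation
across recordings averages per-recording precision/recall (mean ± std) and
pools per-step absolute errors into medians, overall and by step type;
empty strata are reported as absent, not zero. With zero detections
(or zero annotations) precision (recall) is NaN rather than a fabricated 0
or 1.

The Pan-Tompkins baseline is scored by the peak-inside-annotation rule
(each peak and each annotation claimable once) and contributes no Δ
metrics, since it does not produce start/end times.

## Pan-Tompkins baseline

Chain: zero-phase Butterworth bandpass of order 4 (low-pass only when
`fmin = 0`), first difference scaled by `fs`, elementwise squaring, centered
moving average of `round(ninte·fs)` samples with shrinking edge windows (no
padding, hence no spurious edge peaks). Zero-phase filtering is chosen so
peak positions are not lag-shifted, which matters under the
peak-inside-annotation rule. Peaks are strict local maxima of the
transformed signal; an activity gate then keeps a peak only if the raw
component's std over `[peak−neigh, peak+neigh]` (symmetric, clipped to the
signal) reaches `noise_level`. The five parameters (fmin, fmax, ninte,
neigh, noise_level) are tuned by exhaustive grid search maximising
F-measure, ties broken by grid order. The baseline consumes the
vertical-acceleration component by default (selectable). A legacy preset
(fmin 0, fmax 20 Hz, ninte 0.1 s, every-other-peak selection starting with
the second) reproduces the older sequential peak-search heuristic and its
multiple-detection failure mode.

## Synthetic gait generator

The generator emulates what the detector assumes about foot-worn IMU data:
step-like waveforms of 65–96 samples separated by near-zero foot-flat
rests. Template morphology: the angular-velocity component is a smooth
positive swing lobe flanked by two negative dips (sum of three signed
Gaussians); the acceleration components are Gaussian-windowed oscillatory
bursts at both step ends (heel-off and heel-strike transients) plus a small
mid-stance oscillation. All components are zero-mean per template.

A recording plants uniformly chosen library templates, each resampled
(linear interpolation) to a duration jittered by ±10% of its native length
and clipped to [65, 96] samples — stride-to-stride duration varies by
roughly this much in steady walking — scaled by a per-step gain drawn from
U[0.8, 1.2]. Steps are separated by rests of U[25, 60] samples with
100-sample leading/trailing quiet segments (standing before and after the
bout). White Gaussian noise at `noise_sigma` (default 0.05) times the
per-component library standard deviation is added everywhere, plus a
per-component DC offset from U[−0.5, 0.5] emulating orientation bias.
Optionally a fraction of steps ("U-turn-like", default 0) is scaled to 3%
gain, below the μ gate. A fixed seed yields bit-identical output.

What the simulator does **not** model: colored or non-stationary sensor
noise, step shapes absent from the generating library, overlapping or
dragging steps, left/right coordination, magnetometer or full-3D channels,
and genuinely distinct U-turn morphology (modelled only as low gain).
Perfect benchmark scores therefore demonstrate parameter recovery under the
model's own assumptions — correct implementation and robustness to noise,
gain, offset and moderate time warping — not clinical performance.

## Benchmark problem sizes

The standard benchmark used by the test suite and the acceptance script is
20 recordings of 30 steps each (600 steps, ≈ 3,600 samples per recording at
100 Hz) with a 10-template generating library; oracle checks use 100
random signal/template pairs (correlation) and 50 random candidate sets
(greedy selection). These sizes give stable two-decimal precision/recall
estimates while keeping a full run in well under a minute.

## Known limitations

* Matching at native template lengths bounds detectable step durations by
  the library's duration range.
* The greedy pass with the once-only μ gate can miss a low-amplitude step
  whose samples were first claimed and then freed.
* On the synthetic benchmark the grid-searched Pan-Tompkins baseline
  plateaus near F ≈ 0.9: the generator concentrates acceleration energy in
  two bursts per step whose separation is comparable to the inter-step gap,
  so no integration window can merge within-step humps without merging
  across steps. Its relative ordering against the legacy peak selection is
  the meaningful comparison.
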