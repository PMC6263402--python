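"""Pan-Tompkins step detector: the classical filtering/peak-search baseline.

The chain — bandpass filter, derivative, squaring, moving-window integration
— was designed for QRS detection in ECG and later adapted to step counting
on the vertical acceleration of a foot-worn sensor.  Two peak-search modes
are provided:

* ``local-maxima`` (default): strict local maxima of the transformed signal,
  which prevents multiple detections inside one step;
* ``legacy`` (Ying et al. preset): every other peak starting with the
  second, mirroring the original small-peak/big-peak heuristic.  This mode
  exists to demonstrate its multiple-detection failure on multi-peaked
  steps, not as a recommended configuration.

Because the transformed signal also ripples during quiet standing, a
post-processing activity gate keeps only peaks whose raw-signal
neighbourhood has a standard deviation above a noise level.  The five free
parameters (fmin, fmax, Ninte, neighbourhood half-width, noise level) are
tuned by exhaustive grid search maximising the F-measure.

The baseline reports peak positions only — it does not retrieve step start
and end times, so peaks are scored with the peak-inside-annotation rule and
contribute no Δ metrics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import butter, filtfilt

from .evaluation import match_peaks
from .io import Recording, StepInterval

#: Component fed to the baseline by default: vertical acceleration.
DEFAULT_COMPONENT = 1

#: Ying et al. legacy preset: low-pass at 20 Hz, 0.1 s integration window,
#: every-other-peak selection starting with the second peak.
LEGACY_PRESET = {"fmin": 0.0, "fmax": 20.0, "ninte": 0.1}


@dataclass
class PTConfig:
    """Pan-Tompkins chain parameters.

    fmin, fmax : bandpass edges [Hz]; fmin = 0 means low-pass only.
    ninte : moving-window integrator length [s].
    neigh : activity-gate neighbourhood half-width [samples].
    noise_level : activity-gate std threshold [signal units].
    """

    fmin: float = 0.0
    fmax: float = 20.0
    ninte: float = 0.1
    neigh: int = 30
    noise_level: float = 0.0

    def validate(self, fs: float) -> None:
        if not 0 <= self.fmin < self.fmax:
            raise ValueError(f"need 0 <= fmin < fmax, got [{self.fmin}, {self.fmax}]")
        if self.fmax >= fs / 2:
            raise ValueError(
                f"fmax ({self.fmax} Hz) must be below the Nyquist rate ({fs / 2} Hz)"
            )
        if not self.ninte > 0:
            raise ValueError("integration window must be positive")
        if not self.neigh >= 1:
            raise ValueError("neighbourhood half-width must be >= 1 sample")
        if not self.noise_level >= 0:
            raise ValueError("noise level must be >= 0")


@dataclass(frozen=True)
class PTDetection:
    """A detected step, located by its peak sample only (no start/end)."""

    peak: int


def _moving_average_centered(s: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average; edge windows shrink instead of padding."""
    n = len(s)
    width = max(1, int(width))
    half_left = width // 2
    half_right = width - 1 - half_left
    cs = np.concatenate(([0.0], np.cumsum(s)))
    idx = np.arange(n)
    lo = np.maximum(idx - half_left, 0)
    hi = np.minimum(idx + half_right + 1, n)
    return (cs[hi] - cs[lo]) / (hi - lo)


def pt_transform(
    v: np.ndarray, fs: float, fmin: float, fmax: float, ninte: float
) -> np.ndarray:
    """Apply the Pan-Tompkins preprocessing chain to one signal component.

    Zero-phase Butterworth (order 4) bandpass — low-pass only when fmin is 0
    — then first difference scaled by fs, elementwise squaring, and a
    centered moving average of round(ninte * fs) samples.  Zero-phase
    filtering keeps peak positions unshifted, which matters because peaks
    are scored by their position inside annotated intervals.
    """
    v = np.asarray(v, dtype=float)
    cfg = PTConfig(fmin=fmin, fmax=fmax, ninte=ninte)
    cfg.validate(fs)
    if fmin <= 0:
        b, a = butter(4, fmax, btype="low", fs=fs)
    else:
        b, a = butter(4, [fmin, fmax], btype="band", fs=fs)
    filtered = filtfilt(b, a, v)
    deriv = np.empty_like(filtered)
    deriv[1:] = np.diff(filtered) * fs
    deriv[0] = deriv[1]
    squared = deriv * deriv
    return _moving_average_centered(squared, round(ninte * fs))


def pt_peak_search(transformed: np.ndarray) -> np.ndarray:
    """Strict local maxima of the transformed signal (interior samples only)."""
    t = np.asarray(transformed, dtype=float)
    if len(t) < 3:
        return np.array([], dtype=int)
    mid = t[1:-1]
    is_max = (mid > t[:-2]) & (mid > t[2:])
    return np.nonzero(is_max)[0] + 1


def pt_legacy_peak_select(peaks: Sequence[int]) -> np.ndarray:
    """Every-other-peak selection starting with the second peak."""
    return np.asarray(sorted(peaks), dtype=int)[1::2]


def pt_activity_gate(
    peaks: Sequence[int], v: np.ndarray, neigh: int, noise_level: float
) -> list[PTDetection]:
    """Keep peaks whose raw-signal neighbourhood shows activity.

    A peak survives iff the population std of v over [peak - neigh,
    peak + neigh] (clipped to signal bounds) is >= noise_level.  With
    noise_level = 0 the gate is the identity.
    """
    v = np.asarray(v, dtype=float)
    kept = []
    for p in peaks:
        p = int(p)
        if not 0 <= p < len(v):
            raise ValueError(f"peak {p} out of bounds for signal of length {len(v)}")
        lo = max(0, p - neigh)
        hi = min(len(v), p + neigh + 1)
        if v[lo:hi].std() >= noise_level:
            kept.append(PTDetection(peak=p))
    return kept


def pt_detect(
    rec: Recording,
    config: PTConfig,
    component: int = DEFAULT_COMPONENT,
    legacy: bool = False,
) -> list[PTDetection]:
    """Run the full baseline on one recording component."""
    config.validate(rec.fs)
    v = rec.samples[component]
    transformed = pt_transform(v, rec.fs, config.fmin, config.fmax, config.ninte)
    peaks = pt_peak_search(transformed)
    if legacy:
        peaks = pt_legacy_peak_select(peaks)
    return pt_activity_gate(peaks, v, config.neigh, config.noise_level)


def pt_grid_search(
    dataset: Sequence[tuple[Recording, Sequence[StepInterval]]],
    grids: dict[str, Sequence],
    component: int = DEFAULT_COMPONENT,
    legacy: bool = False,
) -> tuple[PTConfig, float]:
    """Exhaustive grid search over the five chain parameters.

    ``grids`` maps each of ``fmin``, ``fmax``, ``ninte``, ``neigh``,
    ``noise_level`` to a list of values.  Every configuration is scored on
    the whole dataset with the peak-inside-annotation rule; the config with
    the highest F-measure wins, ties broken by first-in-grid-order.
    """
    if not dataset:
        raise ValueError("grid search requires a nonempty evaluation set")
    names = ("fmin", "fmax", "ninte", "neigh", "noise_level")
    for name in names:
        if name not in grids or len(grids[name]) == 0:
            raise ValueError(f"empty or missing grid for parameter {name!r}")
    best_cfg: PTConfig | None = None
    best_f = -1.0
    for values in itertools.product(*(grids[n] for n in names)):
        cfg = PTConfig(**dict(zip(names, values)))
        precisions, recalls = [], []
        try:
            for rec, annotated in dataset:
                detections = pt_detect(rec, cfg, component=component, legacy=legacy)
                p, r = match_peaks([d.peak for d in detections], annotated)
                precisions.append(p)
                recalls.append(r)
        except ValueError:
            continue  # invalid for this fs (e.g. fmax above Nyquist)
        p_mean = float(np.nanmean(precisions))
        r_mean = float(np.nanmean(recalls))
        f = 0.0 if p_mean + r_mean == 0 else 2 * p_mean * r_mean / (p_mean + r_mean)
        if np.isnan(f):
            f = 0.0
        if f > best_f:
            best_f = f
            best_cfg = cfg
    if best_cfg is None:
        raise ValueError("no valid configuration in the grid")
    return best_cfg, best_f
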