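"""Sliding Pearson correlation between step templates and IMU signals.

Each template component is slid along the matching signal component and the
Pearson correlation is computed at every lag, yielding one correlation track
per (component, template) pair.  Candidate step positions are the strict
local maxima of these tracks.

Conventions (fixed for oracle reproducibility):

* Population moments (divide by n).  The correlation ratio is identical with
  sample moments; population is used so brute-force oracles match bit-level.
* A zero-variance signal window scores 0, not NaN: foot-flat rest produces
  constant windows, and 0 means "no evidence of a step", which keeps the
  greedy ordering total.  Such lags are flagged degenerate and never become
  candidates.
* Correlations are clipped to [-1, 1] after computation to absorb rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .io import Recording, TemplateLibrary

#: Relative tolerance below which a window variance is treated as zero.
DEGENERATE_REL_TOL = 1e-13


@dataclass
class CorrelationTrack:
    """Correlation values of one (component, template) pair over all lags.

    ``values[t]`` is the Pearson correlation between the template component
    and the signal window starting at lag ``t``; there are ``Nx - Np + 1``
    lags.  ``degenerate[t]`` marks constant signal windows (sentinel 0).
    """

    k: int
    p_index: int
    values: np.ndarray
    degenerate: np.ndarray


@dataclass(frozen=True)
class Candidate:
    """A strict local maximum of one correlation track: a possible step."""

    k: int
    p_index: int
    t: int
    score: float


def pearson(y: np.ndarray, z: np.ndarray, return_degenerate: bool = False):
    """Pearson correlation cov(y,z) / (sigma_y sigma_z), population moments.

    Returns the sentinel 0 (flagged degenerate when requested) if either
    vector is constant — this is a legitimate occurrence during foot-flat
    rest, not an error.
    """
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if y.shape != z.shape or y.ndim != 1 or len(y) < 2:
        raise ValueError("pearson requires two equal-length vectors of length >= 2")
    yc = y - y.mean()
    zc = z - z.mean()
    sy = np.sqrt(np.mean(yc * yc))
    sz = np.sqrt(np.mean(zc * zc))
    if sy == 0.0 or sz == 0.0:
        return (0.0, True) if return_degenerate else 0.0
    r = float(np.clip(np.mean(yc * zc) / (sy * sz), -1.0, 1.0))
    return (r, False) if return_degenerate else r


def sliding_correlation(
    x_k: np.ndarray, p_k: np.ndarray, k: int = -1, p_index: int = -1
) -> CorrelationTrack:
    """Correlation of template component ``p_k`` with ``x_k`` at every lag.

    Implemented with cumulative window sums and a direct cross-correlation,
    which matches the per-lag definition within 1e-9 (asserted by the test
    suite against a brute-force oracle).
    """
    x = np.asarray(x_k, dtype=float)
    p = np.asarray(p_k, dtype=float)
    n = len(p)
    if n < 2:
        raise ValueError("template component must have length >= 2")
    if n > len(x):
        raise ValueError(
            f"template longer than signal (Np={n} > Nx={len(x)})"
        )
    sp = p.std()
    if sp == 0.0:
        raise ValueError("template component has zero variance")
    mp = p.mean()

    cs = np.concatenate(([0.0], np.cumsum(x)))
    cs2 = np.concatenate(([0.0], np.cumsum(x * x)))
    win_sum = cs[n:] - cs[:-n]
    win_sumsq = cs2[n:] - cs2[:-n]
    mean_x = win_sum / n
    var_x = win_sumsq / n - mean_x**2
    mean_sq = win_sumsq / n

    degenerate = var_x <= DEGENERATE_REL_TOL * np.maximum(mean_sq, 0.0)
    var_x = np.where(degenerate, 1.0, var_x)  # placeholder, masked below

    cross = np.correlate(x, p, mode="valid")
    cov = cross / n - mp * mean_x
    values = np.clip(cov / (sp * np.sqrt(var_x)), -1.0, 1.0)
    values[degenerate] = 0.0
    return CorrelationTrack(k=k, p_index=p_index, values=values, degenerate=degenerate)


def correlation_tensor(x: Recording, library: TemplateLibrary) -> list[CorrelationTrack]:
    """All correlation tracks: one per (component, template) pair.

    Templates longer than the signal are skipped with a warning; if no
    template fits, an error is raised.
    """
    tracks: list[CorrelationTrack] = []
    any_fit = False
    for p_index, tpl in enumerate(library):
        if tpl.n_samples > x.n_samples:
            warnings.warn(
                f"template {p_index} ({tpl.label!r}) longer than signal "
                f"(Np={tpl.n_samples} > Nx={x.n_samples}); skipped"
            )
            continue
        any_fit = True
        for k in range(x.samples.shape[0]):
            tracks.append(
                sliding_correlation(x.samples[k], tpl.samples[k], k=k, p_index=p_index)
            )
    if not any_fit:
        raise ValueError("no usable template: all templates longer than the signal")
    return tracks


def find_local_maxima(tracks: list[CorrelationTrack]) -> list[Candidate]:
    """Extract the candidate set: strict local maxima of every track.

    A lag t is a candidate iff r(t) > r(t-1) and r(t) > r(t+1) — strict on
    both sides, so plateaus yield no candidate.  Boundary lags are never
    candidates, and degenerate (constant-window) lags are excluded.
    """
    candidates: list[Candidate] = []
    for tr in tracks:
        v = tr.values
        if len(v) < 3:
            continue
        mid = v[1:-1]
        is_max = (mid > v[:-2]) & (mid > v[2:]) & ~tr.degenerate[1:-1]
        for t in np.nonzero(is_max)[0] + 1:
            candidates.append(
                Candidate(k=tr.k, p_index=tr.p_index, t=int(t), score=float(v[t]))
            )
    return candidates
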