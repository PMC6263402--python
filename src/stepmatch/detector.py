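"""Greedy non-overlapping step placement and the low-amplitude rejection gate.

The detector visits candidates in decreasing score order and accepts a
candidate iff its interval contains no sample already claimed by an accepted
step; on acceptance the whole interval becomes forbidden.  Iteration stops
when every sample is forbidden, the candidate list is exhausted, or the best
remaining score falls below the correlation threshold λ.

A single post-processing pass then discards accepted steps whose signal
segment has a standard deviation below μ times that of the matched template
component — scale invariance of the correlation otherwise lets near-zero
rest segments match templates perfectly.  Samples freed by this gate are not
returned to the pool for re-detection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .correlation import Candidate, correlation_tensor, find_local_maxima
from .io import Recording, StepInterval, TemplateLibrary


@dataclass
class DetectorConfig:
    """Detector thresholds.

    lam : minimum correlation score for a step to be placed (greedy stop
        threshold), default 0.6.
    mu : minimum ratio of detected-segment std to template std, default 0.1.
    """

    lam: float = 0.6
    mu: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lam must be in [0, 1], got {self.lam}")
        if not self.mu >= 0.0:
            raise ValueError(f"mu must be >= 0, got {self.mu}")


def greedy_select(
    candidates: Sequence[Candidate],
    template_lengths: Sequence[int],
    nx: int,
    lam: float = 0.6,
    library: TemplateLibrary | None = None,
) -> list[StepInterval]:
    """Greedily place non-overlapping steps from the candidate set.

    Equal scores are broken by (earliest lag, lowest template index,
    component order) so the output is a total deterministic function of the
    input.  "Overlap" means sharing at least one sample under half-open
    intervals, so abutting steps are allowed.  Returned intervals are
    pairwise disjoint and sorted by start time.
    """
    order = sorted(candidates, key=lambda c: (-c.score, c.t, c.p_index, c.k))
    forbidden = np.zeros(nx, dtype=bool)
    n_forbidden = 0
    accepted: list[StepInterval] = []
    for c in order:
        if c.score < lam:
            break
        if n_forbidden == nx:
            break
        np_c = template_lengths[c.p_index]
        end = c.t + np_c
        if end > nx:
            continue
        if forbidden[c.t : end].any():
            continue
        forbidden[c.t : end] = True
        n_forbidden += np_c
        step_type = library[c.p_index].step_type if library is not None else "unknown"
        accepted.append(
            StepInterval(
                start=c.t,
                end=end,
                kind="detected",
                step_type=step_type,
                template_index=c.p_index,
                component=c.k,
                score=c.score,
            )
        )
    accepted.sort(key=lambda s: s.start)
    return accepted


def reject_low_amplitude(
    steps: Sequence[StepInterval],
    x: Recording,
    library: TemplateLibrary,
    mu: float = 0.1,
) -> list[StepInterval]:
    """Drop steps whose segment std is below μ times the matched template std.

    Both are population standard deviations over the full interval, compared
    on the single component that produced the detection.
    """
    kept = []
    for s in steps:
        if s.template_index is None or s.component is None:
            raise ValueError("detected step is missing provenance (template/component)")
        seg = x.samples[s.component, s.start : s.end]
        sigma_tpl = library[s.template_index].sigma[s.component]
        if seg.std() >= mu * sigma_tpl:
            kept.append(s)
    return kept


def detect_steps(
    x: Recording,
    library: TemplateLibrary,
    config: DetectorConfig | None = None,
) -> list[StepInterval]:
    """Full detection pipeline: correlate, find maxima, greedy select, μ-gate.

    Deterministic: identical inputs yield identical outputs.
    """
    config = config or DetectorConfig()
    tracks = correlation_tensor(x, library)
    candidates = find_local_maxima(tracks)
    steps = greedy_select(
        candidates, library.lengths, x.n_samples, lam=config.lam, library=library
    )
    return reject_low_amplitude(steps, x, library, mu=config.mu)
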