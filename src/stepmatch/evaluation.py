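"""Event-level scoring of step detections against expert-style annotations.

Matching rule: a detected step is correct iff the mean of its start and end
times lies inside an annotated step, and each annotated step may be claimed
at most once — when several detected steps land in the same annotated step,
all but one are counted as false.  Recall applies the symmetric rule with
the roles swapped.  The two passes are independent, so precision and recall
may pair steps differently on the same input.

Timing errors (ΔStart, ΔEnd, ΔDuration) are signed detected-minus-annotated
differences in samples, computed over the precision-pass pairs.

Within a pass, steps are processed in ascending start order and the first
claim wins; midpoints of half-open intervals [s, e) are (s+e)/2, unrounded,
and "inside" means start <= m < end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import StepInterval


@dataclass
class MatchResult:
    """Pairing produced by one matching pass.

    ``pairs`` holds (detected index, annotated index) tuples; each index
    appears at most once within a pass.
    """

    pairs: list[tuple[int, int]]
    unmatched_detected: list[int]
    unmatched_annotated: list[int]
    direction: str  # "precision-pass" | "recall-pass"


@dataclass
class EvalReport:
    """Precision/recall and per-pair timing errors for one recording."""

    precision: float
    recall: float
    n_detected: int
    n_annotated: int
    delta_start: list[int] = field(default_factory=list)
    delta_end: list[int] = field(default_factory=list)
    delta_duration: list[int] = field(default_factory=list)
    #: annotated step type of each precision-pass pair, aligned with deltas
    pair_step_types: list[str] = field(default_factory=list)
    #: annotated step counts per type
    counts_by_type: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "n_detected": self.n_detected,
            "n_annotated": self.n_annotated,
            "delta_start": self.delta_start,
            "delta_end": self.delta_end,
            "delta_duration": self.delta_duration,
            "pair_step_types": self.pair_step_types,
            "counts_by_type": self.counts_by_type,
        }


def _claim_pass(
    claimers: Sequence[StepInterval],
    targets: Sequence[StepInterval],
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Each claimer (ascending start) claims the first unclaimed target
    interval containing its midpoint."""
    order = sorted(range(len(claimers)), key=lambda i: (claimers[i].start, claimers[i].end))
    target_order = sorted(
        range(len(targets)), key=lambda j: (targets[j].start, targets[j].end)
    )
    claimed: set[int] = set()
    pairs = []
    unmatched = []
    for i in order:
        m = claimers[i].midpoint
        hit = None
        for j in target_order:
            if j in claimed:
                continue
            if targets[j].start <= m < targets[j].end:
                hit = j
                break
        if hit is None:
            unmatched.append(i)
        else:
            claimed.add(hit)
            pairs.append((i, hit))
    unmatched_targets = [j for j in range(len(targets)) if j not in claimed]
    return pairs, unmatched, unmatched_targets


def match_precision_pass(
    detected: Sequence[StepInterval], annotated: Sequence[StepInterval]
) -> MatchResult:
    """Match detected steps to annotated steps for precision counting."""
    pairs, unmatched_det, unmatched_ann = _claim_pass(detected, annotated)
    return MatchResult(
        pairs=pairs,
        unmatched_detected=unmatched_det,
        unmatched_annotated=unmatched_ann,
        direction="precision-pass",
    )


def match_recall_pass(
    detected: Sequence[StepInterval], annotated: Sequence[StepInterval]
) -> MatchResult:
    """Match annotated steps to detected steps for recall counting."""
    pairs_rev, unmatched_ann, unmatched_det = _claim_pass(annotated, detected)
    pairs = [(d, a) for (a, d) in pairs_rev]
    return MatchResult(
        pairs=pairs,
        unmatched_detected=unmatched_det,
        unmatched_annotated=unmatched_ann,
        direction="recall-pass",
    )


def delta_metrics(
    pairs: Sequence[tuple[int, int]],
    detected: Sequence[StepInterval],
    annotated: Sequence[StepInterval],
) -> dict[str, list[int]]:
    """Signed timing errors (samples) for correctly detected steps."""
    ds, de, dd = [], [], []
    for i, j in pairs:
        d, a = detected[i], annotated[j]
        ds.append(d.start - a.start)
        de.append(d.end - a.end)
        dd.append(d.duration - a.duration)
    return {"delta_start": ds, "delta_end": de, "delta_duration": dd}


def evaluate_detection(
    detected: Sequence[StepInterval], annotated: Sequence[StepInterval]
) -> EvalReport:
    """Score one recording: precision, recall, and Δ metrics.

    Precision (recall) is NaN when there are no detected (annotated) steps —
    the ratio is undefined, and NaN keeps aggregation honest.
    """
    prec_match = match_precision_pass(detected, annotated)
    rec_match = match_recall_pass(detected, annotated)
    precision = (
        len(prec_match.pairs) / len(detected) if len(detected) else math.nan
    )
    recall = len(rec_match.pairs) / len(annotated) if len(annotated) else math.nan
    deltas = delta_metrics(prec_match.pairs, detected, annotated)
    counts: dict[str, int] = {}
    for a in annotated:
        counts[a.step_type] = counts.get(a.step_type, 0) + 1
    return EvalReport(
        precision=precision,
        recall=recall,
        n_detected=len(detected),
        n_annotated=len(annotated),
        delta_start=deltas["delta_start"],
        delta_end=deltas["delta_end"],
        delta_duration=deltas["delta_duration"],
        pair_step_types=[annotated[j].step_type for _, j in prec_match.pairs],
        counts_by_type=counts,
    )


def match_peaks(
    peaks: Sequence[int], annotated: Sequence[StepInterval]
) -> tuple[float, float]:
    """Score point detections (e.g. Pan-Tompkins peaks) against annotations.

    A peak is correct iff it lies inside an annotated interval not yet
    claimed; an annotated step is detected iff some peak (each usable once)
    lies inside it.  Both passes run in ascending order with first claim
    wins.  Returns (precision, recall); point detections carry no start/end
    so no Δ metrics exist for them.
    """
    peaks = sorted(int(p) for p in peaks)
    ann_order = sorted(range(len(annotated)), key=lambda j: annotated[j].start)
    # precision pass: peaks claim annotated intervals
    claimed_ann: set[int] = set()
    n_correct_peaks = 0
    for p in peaks:
        for j in ann_order:
            if j in claimed_ann:
                continue
            if annotated[j].start <= p < annotated[j].end:
                claimed_ann.add(j)
                n_correct_peaks += 1
                break
    # recall pass: annotated intervals claim peaks
    claimed_peaks: set[int] = set()
    n_detected_ann = 0
    for j in ann_order:
        for i, p in enumerate(peaks):
            if i in claimed_peaks:
                continue
            if annotated[j].start <= p < annotated[j].end:
                claimed_peaks.add(i)
                n_detected_ann += 1
                break
    precision = n_correct_peaks / len(peaks) if peaks else math.nan
    recall = n_detected_ann / len(annotated) if annotated else math.nan
    return precision, recall


def summarize(reports: Sequence[EvalReport]) -> dict:
    """Aggregate per-recording scores the way a multi-recording study would.

    Precision/recall are averaged across recordings (mean and std over the
    per-recording values, NaN-skipping); timing errors are pooled over all
    correct detections and summarised as medians of absolute values, overall
    and stratified by annotated step type.  Strata with zero steps are
    absent from the output, not reported as zero.
    """
    if not reports:
        raise ValueError("summarize requires >= 1 report")
    precisions = np.array([r.precision for r in reports], dtype=float)
    recalls = np.array([r.recall for r in reports], dtype=float)
    out: dict = {
        "n_recordings": len(reports),
        "precision_mean": float(np.nanmean(precisions)),
        "precision_std": float(np.nanstd(precisions)),
        "recall_mean": float(np.nanmean(recalls)),
        "recall_std": float(np.nanstd(recalls)),
    }
    all_ds, all_de, all_dd, all_types = [], [], [], []
    for r in reports:
        all_ds.extend(r.delta_start)
        all_de.extend(r.delta_end)
        all_dd.extend(r.delta_duration)
        all_types.extend(r.pair_step_types)
    if all_ds:
        out["median_abs_delta_start"] = float(np.median(np.abs(all_ds)))
        out["median_abs_delta_end"] = float(np.median(np.abs(all_de)))
        out["median_abs_delta_duration"] = float(np.median(np.abs(all_dd)))
        out["mean_abs_delta_start"] = float(np.mean(np.abs(all_ds)))
        out["mean_abs_delta_end"] = float(np.mean(np.abs(all_de)))
    by_type: dict[str, dict] = {}
    for step_type in sorted(set(all_types)):
        idx = [i for i, t in enumerate(all_types) if t == step_type]
        by_type[step_type] = {
            "n": len(idx),
            "median_abs_delta_start": float(np.median([abs(all_ds[i]) for i in idx])),
            "median_abs_delta_end": float(np.median([abs(all_de[i]) for i in idx])),
            "median_abs_delta_duration": float(
                np.median([abs(all_dd[i]) for i in idx])
            ),
        }
    out["by_step_type"] = by_type
    return out
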