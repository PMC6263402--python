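"""Data model and I/O for IMU recordings, step templates, annotations and detections.

A recording is a 3-component time series from one foot-worn inertial unit:
Z-axis acceleration (normal to the upper foot surface), recalibrated
vertical acceleration, and Y-axis angular velocity (swing in the walking
direction).  The same component order is used everywhere — recordings,
templates, correlation tracks — and is fixed by :data:`COMPONENTS`.

All intervals are 0-based and half-open ``[start, end)``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

#: Canonical component order: index 0 = Z-axis acceleration [m/s^2],
#: 1 = vertical acceleration [m/s^2], 2 = Y-axis angular velocity [deg/s].
COMPONENTS: tuple[str, str, str] = ("acc_z", "acc_vertical", "gyro_y")

N_COMPONENTS = len(COMPONENTS)

#: Recognised step-type labels for annotations and templates.
STEP_TYPES = ("normal", "initiation", "termination", "uturn", "unknown")


class FormatError(ValueError):
    """A file does not conform to the expected layout."""


def _check_samples(samples: np.ndarray, what: str) -> np.ndarray:
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[0] != N_COMPONENTS:
        raise ValueError(
            f"{what} must be a {N_COMPONENTS}xN matrix, got shape {samples.shape}"
        )
    if samples.shape[1] < 1:
        raise ValueError(f"empty {what.lower()}")
    if not np.isfinite(samples).all():
        raise ValueError(f"{what} contains NaN or Inf values")
    return samples


@dataclass
class Recording:
    """A 3xNx multivariate IMU signal to be searched for steps.

    Parameters
    ----------
    samples : (3, Nx) array
        Component rows in :data:`COMPONENTS` order.
    fs : float
        Sampling rate in Hz.  Metadata for the template detector (all its
        thresholds are in samples); required by the Pan-Tompkins bandpass.
    id : str
        Free-text identifier.
    """

    samples: np.ndarray
    fs: float = 100.0
    id: str = ""

    def __post_init__(self) -> None:
        self.samples = _check_samples(self.samples, "Recording")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass
class Template:
    """A 3xNp step exemplar used as the matching unit.

    Per-component population standard deviations are cached on construction;
    every component must be non-constant (the Pearson correlation against a
    zero-variance template is undefined).
    """

    samples: np.ndarray
    label: str = ""
    step_type: str = "normal"
    sigma: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.samples = _check_samples(self.samples, "Template")
        if self.samples.shape[1] < 2:
            raise ValueError("template must have at least 2 samples")
        self.sigma = self.samples.std(axis=1)  # population std
        if np.any(self.sigma == 0):
            bad = COMPONENTS[int(np.argmax(self.sigma == 0))]
            raise ValueError(
                f"template {self.label!r}: component {bad} has zero variance"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass
class TemplateLibrary:
    """An ordered set of step templates; the index is the deterministic tie-break key."""

    templates: list[Template]

    def __post_init__(self) -> None:
        if len(self.templates) < 1:
            raise ValueError("library must contain >= 1 template")

    def __len__(self) -> int:
        return len(self.templates)

    def __iter__(self) -> Iterator[Template]:
        return iter(self.templates)

    def __getitem__(self, i: int) -> Template:
        return self.templates[i]

    @property
    def lengths(self) -> list[int]:
        return [t.n_samples for t in self.templates]


@dataclass
class StepInterval:
    """A half-open step interval ``[start, end)`` in sample indices.

    ``kind`` distinguishes ground-truth annotations from detector output.
    Detected intervals carry their provenance: the matched template index,
    the component that produced the best correlation, and the score.
    """

    start: int
    end: int
    kind: str = "annotated"  # "annotated" | "detected"
    step_type: str = "unknown"
    template_index: int | None = None
    component: int | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        self.start = int(self.start)
        self.end = int(self.end)
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.kind not in ("annotated", "detected"):
            raise ValueError(f"unknown interval kind {self.kind!r}")
        if self.step_type not in STEP_TYPES:
            raise ValueError(f"unknown step type {self.step_type!r}")

    @property
    def duration(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_recording(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    fs: float = 100.0,
    id: str | None = None,
) -> Recording:
    """Load a recording from a delimited-text file (one sample per row).

    ``column_map`` maps canonical component names (:data:`COMPONENTS`) to the
    column names used in the file; by default the canonical names are looked
    up directly.  Rows with any missing value are dropped; non-numeric cells
    raise with the offending row number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recording file not found: {path}")
    column_map = column_map or {c: c for c in COMPONENTS}
    df = pd.read_csv(path)
    cols = []
    for comp in COMPONENTS:
        name = column_map.get(comp, comp)
        if name not in df.columns:
            raise FormatError(f"{path}: missing column {name!r} (component {comp})")
        cols.append(name)
    sub = df[cols]
    numeric = sub.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & sub.notna()
    if bad.to_numpy().any():
        row = int(bad.any(axis=1).idxmax())
        raise FormatError(
            f"{path}: non-numeric value in data row {row} "
            f"(column {bad.loc[row].idxmax()!r})"
        )
    n_before = len(numeric)
    numeric = numeric.dropna()
    if len(numeric) < n_before:
        warnings.warn(
            f"{path}: dropped {n_before - len(numeric)} rows with missing values"
        )
    if len(numeric) == 0:
        raise FormatError(f"{path}: empty recording (no data rows)")
    return Recording(
        samples=numeric.to_numpy().T, fs=fs, id=id if id is not None else path.stem
    )


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording as CSV with canonical column names."""
    df = pd.DataFrame(rec.samples.T, columns=list(COMPONENTS))
    df.to_csv(path, index=False, float_format="%.12g")


def read_library(manifest_path: str | Path) -> TemplateLibrary:
    """Load a template library from a JSON manifest.

    The manifest lists template CSV files (paths relative to the manifest)
    with labels and optional step types::

        {"templates": [{"file": "t01.csv", "label": "healthy",
                        "step_type": "normal"}, ...]}
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    entries = manifest.get("templates", [])
    if not entries:
        raise FormatError("library must contain >= 1 template")
    templates = []
    for entry in entries:
        tpath = manifest_path.parent / entry["file"]
        df = pd.read_csv(tpath)
        for comp in COMPONENTS:
            if comp not in df.columns:
                raise FormatError(f"{tpath}: missing component column {comp!r}")
        samples = df[list(COMPONENTS)].to_numpy().T
        try:
            tpl = Template(
                samples=samples,
                label=entry.get("label", Path(entry["file"]).stem),
                step_type=entry.get("step_type", "normal"),
            )
        except ValueError as exc:
            raise FormatError(
                f"template {entry.get('label', entry['file'])!r} rejected: {exc}"
            ) from exc
        templates.append(tpl)
    return TemplateLibrary(templates)


def write_library(library: TemplateLibrary, out_dir: str | Path) -> Path:
    """Write a library to a directory as per-template CSVs + manifest.json.

    Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, tpl in enumerate(library):
        fname = f"template_{i:03d}.csv"
        df = pd.DataFrame(tpl.samples.T, columns=list(COMPONENTS))
        df.to_csv(out_dir / fname, index=False, float_format="%.12g")
        entries.append(
            {"file": fname, "label": tpl.label or fname, "step_type": tpl.step_type}
        )
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump({"templates": entries}, fh, indent=2)
    return manifest_path


def write_detections(steps: Sequence[StepInterval], path: str | Path) -> None:
    """Write detected steps as JSON (start, end, provenance, score)."""
    records = [
        {
            "start": s.start,
            "end": s.end,
            "step_type": s.step_type,
            "template_index": s.template_index,
            "component": s.component,
            "score": s.score,
        }
        for s in steps
    ]
    with open(path, "w") as fh:
        json.dump(records, fh, indent=2)


def read_detections(path: str | Path) -> list[StepInterval]:
    with open(path) as fh:
        records = json.load(fh)
    return [
        StepInterval(
            start=r["start"],
            end=r["end"],
            kind="detected",
            step_type=r.get("step_type", "unknown"),
            template_index=r.get("template_index"),
            component=r.get("component"),
            score=r.get("score"),
        )
        for r in records
    ]


def read_annotations(path: str | Path) -> list[StepInterval]:
    """Read ground-truth step annotations from CSV (columns start,end[,step_type]).

    Overlapping annotated intervals are kept with a warning — real
    annotations may abut or slightly overlap.  A row with start >= end is
    rejected with its row number.
    """
    df = pd.read_csv(path)
    for col in ("start", "end"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    has_type = "step_type" in df.columns
    steps = []
    for row_number, row in enumerate(df.itertuples(index=False)):
        start, end = int(row.start), int(row.end)
        if start >= end:
            raise FormatError(
                f"{path}: row {row_number}: start ({start}) must be < end ({end})"
            )
        steps.append(
            StepInterval(
                start=start,
                end=end,
                kind="annotated",
                step_type=str(row.step_type) if has_type else "unknown",
            )
        )
    for a, b in zip(steps, steps[1:]):
        if b.start < a.end:
            warnings.warn(
                f"{path}: annotated intervals [{a.start},{a.end}) and "
                f"[{b.start},{b.end}) overlap; both kept"
            )
    return steps


def write_annotations(steps: Sequence[StepInterval], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "start": [s.start for s in steps],
            "end": [s.end for s in steps],
            "step_type": [s.step_type for s in steps],
        }
    )
    df.to_csv(path, index=False)
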