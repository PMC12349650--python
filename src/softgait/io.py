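"""Containers and readers/writers for traces, sessions and cohort tables.

On-disk formats
---------------
* Acceleration trace: CSV with header ``sample,az_g`` (sample index) or
  ``time_s,az_g`` (uniform timestamps). Values are vertical acceleration in g.
* Session metadata: JSON with the walked distance, stopwatch time, counted
  steps, participant height, pre/post label and a relative path to the trace
  CSV.
* Cohort table: long-format CSV, one row per (participant, pre/post label),
  metric columns free-form numeric.

The trace unit on disk is g, not m/s^2: the device workflow initializes the
vertical axis against standing gravity (1 g), so g is the native scale and
SI conversion is an explicit operation (:func:`softgait.signal.g_to_ms2`).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConsistencyError, ParseError, ValidationError

__all__ = [
    "AccelTrace",
    "GaitSession",
    "read_trace_csv",
    "write_trace_csv",
    "read_session",
    "write_session",
    "read_cohort_csv",
    "write_cohort_csv",
    "validate_cohort",
]

#: Required identifier columns of a cohort table.
COHORT_KEYS = ("participant_id", "label")
VALID_LABELS = ("pre", "post")


@dataclasses.dataclass(frozen=True)
class AccelTrace:
    """Uniformly sampled vertical (Z-axis) acceleration in g.

    Time is sample-index based: sample ``i`` is at ``t0_s + i / sample_rate_hz``.
    """

    samples_g: np.ndarray
    sample_rate_hz: float
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples_g, dtype=float)
        object.__setattr__(self, "samples_g", samples)
        if self.sample_rate_hz <= 0:
            raise ValidationError(f"sample_rate_hz must be positive, got {self.sample_rate_hz}")
        if samples.ndim != 1 or samples.size < 2:
            raise ValidationError("trace must be a 1-D array with at least 2 samples")
        if not np.all(np.isfinite(samples)):
            raise ValidationError("trace contains non-finite samples")

    def __len__(self) -> int:
        return self.samples_g.size

    @property
    def duration_s(self) -> float:
        """Time spanned by the samples (last minus first timestamp)."""
        return (len(self) - 1) / self.sample_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(len(self)) / self.sample_rate_hz


@dataclasses.dataclass(frozen=True)
class GaitSession:
    """One 10 m walking trial: trace plus instructor-recorded metadata.

    ``distance_m`` is the full walked distance (10 m plus the overshoot past
    the finish line); ``time_s`` the stopwatch time; ``step_count`` the
    manually counted steps. Sessions with fewer than 5 steps are rejected —
    the impact summary needs at least five peaks once the first and last two
    are excluded.
    """

    trace: AccelTrace
    distance_m: float
    time_s: float
    step_count: int
    height_cm: float
    label: str = "pre"
    participant_id: str = "P000"

    def __post_init__(self) -> None:
        if self.distance_m < 10.0:
            raise ValidationError(
                f"distance_m must be >= 10 (10 m course plus overshoot), got {self.distance_m}")
        if self.time_s <= 0:
            raise ValidationError(f"time_s must be positive, got {self.time_s}")
        if self.step_count < 5:
            raise ValidationError(
                f"step_count must be >= 5 (exclusion rule: first/last two steps "
                f"are dropped), got {self.step_count}")
        if not 100.0 < self.height_cm < 220.0:
            raise ValidationError(f"height_cm must lie in (100, 220), got {self.height_cm}")
        if self.label not in VALID_LABELS:
            raise ValidationError(f"label must be one of {VALID_LABELS}, got {self.label!r}")

    @property
    def speed_m_s(self) -> float:
        return self.distance_m / self.time_s


# ---------------------------------------------------------------------------
# trace CSV
# ---------------------------------------------------------------------------

def read_trace_csv(path: str | Path, *, sample_rate_hz: float | None = None) -> AccelTrace:
    """Read an acceleration trace CSV.

    The header must be ``sample,az_g`` or ``time_s,az_g``. With a ``sample``
    column the sampling rate must be supplied (default 60 Hz); with a
    ``time_s`` column the rate is inferred and the spacing must be uniform.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    cols = list(frame.columns)
    if cols not in (["sample", "az_g"], ["time_s", "az_g"]):
        raise ParseError(
            f"{path}: expected header 'sample,az_g' or 'time_s,az_g', got {','.join(cols)}")

    numeric = {}
    for col in cols:
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.index[converted.isna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise ParseError(f"{path}: non-numeric value in column {col!r} at line {bad[0] + 2}")
        numeric[col] = converted.to_numpy(dtype=float)

    values = numeric["az_g"]
    if cols[0] == "time_s":
        t = numeric["time_s"]
        dt = np.diff(t)
        if np.any(dt <= 0):
            row = int(np.argmax(dt <= 0))
            raise ParseError(f"{path}: non-monotone time at line {row + 3}")
        if dt.size and (dt.max() - dt.min()) > 1e-6 * dt.mean():
            raise ParseError(f"{path}: irregular time spacing; uniform sampling required")
        fs = 1.0 / float(dt.mean())
        t0 = float(t[0])
    else:
        sample = numeric["sample"]
        if not np.array_equal(sample, np.arange(len(sample))):
            raise ParseError(f"{path}: 'sample' column must be 0..n-1 consecutive integers")
        fs = float(sample_rate_hz) if sample_rate_hz is not None else 60.0
        t0 = 0.0
    try:
        return AccelTrace(values, fs, t0)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_trace_csv(trace: AccelTrace, path: str | Path) -> None:
    """Write a trace as ``sample,az_g`` CSV, lossless to ~9 significant digits."""
    frame = pd.DataFrame({"sample": np.arange(len(trace)), "az_g": trace.samples_g})
    frame.to_csv(path, index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# session JSON
# ---------------------------------------------------------------------------

_SESSION_KEYS = ("distance_m", "time_s", "step_count", "height_cm",
                 "label", "participant_id", "trace_csv", "sample_rate_hz")


def read_session(path: str | Path) -> GaitSession:
    """Load a session: JSON metadata plus the trace CSV it points to.

    The ``trace_csv`` path is resolved relative to the JSON file. All
    :class:`GaitSession` invariants are enforced on load, and the trace must
    be at least as long as the standing lead-in plus the timed walk.
    """
    path = Path(path)
    try:
        with open(path, encoding="utf-8") as fh:
            meta = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON ({exc})") from exc
    missing = [k for k in _SESSION_KEYS if k not in meta and k != "sample_rate_hz"]
    if missing:
        raise ParseError(f"{path}: missing keys {missing}")
    trace_path = path.parent / meta["trace_csv"]
    if not trace_path.exists():
        raise ParseError(f"{path}: trace file {trace_path} not found")
    trace = read_trace_csv(trace_path, sample_rate_hz=meta.get("sample_rate_hz"))
    session = GaitSession(
        trace=trace,
        distance_m=float(meta["distance_m"]),
        time_s=float(meta["time_s"]),
        step_count=int(meta["step_count"]),
        height_cm=float(meta["height_cm"]),
        label=str(meta["label"]),
        participant_id=str(meta["participant_id"]),
    )
    if trace.duration_s < session.time_s:
        raise ConsistencyError(
            f"{path}: trace spans {trace.duration_s:.2f} s but the timed walk "
            f"took {session.time_s:.2f} s")
    return session


def write_session(session: GaitSession, path: str | Path) -> None:
    """Write session metadata JSON and its trace CSV next to it."""
    path = Path(path)
    trace_name = path.stem + "_trace.csv"
    write_trace_csv(session.trace, path.parent / trace_name)
    meta = {
        "distance_m": session.distance_m,
        "time_s": session.time_s,
        "step_count": session.step_count,
        "height_cm": session.height_cm,
        "label": session.label,
        "participant_id": session.participant_id,
        "trace_csv": trace_name,
        "sample_rate_hz": session.trace.sample_rate_hz,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2)
        fh.write("\n")


# ---------------------------------------------------------------------------
# cohort CSV
# ---------------------------------------------------------------------------

def validate_cohort(table: pd.DataFrame, *, require_paired: bool = True) -> pd.DataFrame:
    """Validate a long-format cohort table.

    Each participant must appear exactly once per label, and (for paired
    analyses) with both a ``pre`` and a ``post`` row.
    """
    for key in COHORT_KEYS:
        if key not in table.columns:
            raise ValidationError(f"cohort table missing column {key!r}")
    bad_labels = set(table["label"].unique()) - set(VALID_LABELS)
    if bad_labels:
        raise ValidationError(f"unknown labels {sorted(bad_labels)}; expected {VALID_LABELS}")
    dup = table.duplicated(subset=list(COHORT_KEYS))
    if dup.any():
        pid, label = table.loc[dup.idxmax(), list(COHORT_KEYS)]
        raise ValidationError(f"duplicate row for participant {pid!r} label {label!r}")
    if require_paired:
        counts = table.groupby("participant_id")["label"].nunique()
        unpaired = counts.index[counts < 2]
        if len(unpaired):
            raise ValidationError(
                f"participant(s) without both pre and post rows: {list(unpaired[:5])}")
    return table


def read_cohort_csv(path: str | Path, *, require_paired: bool = True) -> pd.DataFrame:
    path = Path(path)
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    return validate_cohort(table, require_paired=require_paired)


def write_cohort_csv(table: pd.DataFrame, path: str | Path) -> None:
    validate_cohort(table, require_paired=False)
    table.to_csv(path, index=False, float_format="%.9g")


def paired_frames(table: pd.DataFrame, metrics: Iterable[str]) -> pd.DataFrame:
    """Pivot a long cohort table to one row per participant with
    ``<metric>_pre`` / ``<metric>_post`` columns, sorted by participant."""
    validate_cohort(table)
    wide = table.pivot(index="participant_id", columns="label", values=list(metrics))
    wide.columns = [f"{m}_{label}" for m, label in wide.columns]
    order = [f"{m}_{label}" for m in metrics for label in VALID_LABELS]
    return wide[order].sort_index()
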