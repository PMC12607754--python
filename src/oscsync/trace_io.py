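"""Reading, validation, normalization and protocol windowing of trace tables.

Fluorescence (or voltage) recordings are exchanged as wide delimited text:
a ``time_s`` column plus one column per ROI/well.  The ImageJ multi-measure
dialect (row-index first column, ``Mean1..MeanN`` columns, no time base) is
supported as a named special case and needs an explicit sampling rate.

Recordings follow a compound-application protocol: a baseline period, a
trigger application that starts network oscillations, and optionally later
applications (e.g. a gap-junction blocker).  ``segment_windows`` cuts a
recording into half-open analysis windows, skipping a configurable
transition period after each application during which the network state is
still changing and synchrony statistics would be biased.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import AnalysisError, ValidationError

__all__ = [
    "TraceKind",
    "Trace",
    "TraceSet",
    "ProtocolEvents",
    "Window",
    "read_trace_table",
    "write_trace_table",
    "compute_dff",
    "segment_windows",
]

#: Relative tolerance on sampling uniformity: max |dt - median dt| must stay
#: below this fraction of the median dt.
_UNIFORMITY_RTOL = 1e-6

#: Minimum number of samples an analysis window must retain.
MIN_WINDOW_SAMPLES = 10


class TraceKind(str, Enum):
    RAW_FLUORESCENCE = "raw_fluorescence"
    DFF = "dff"
    VOLTAGE = "voltage"


@dataclass(frozen=True)
class Trace:
    """One uniformly sampled signal with a label and a physical kind."""

    time_s: np.ndarray
    values: np.ndarray
    label: str
    kind: TraceKind = TraceKind.RAW_FLUORESCENCE

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or v.ndim != 1 or t.shape != v.shape:
            raise ValidationError(
                f"trace {self.label!r}: time and values must be 1-D of equal length"
            )
        if t.size < 2:
            raise ValidationError(f"trace {self.label!r}: needs at least 2 samples")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(v)):
            raise ValidationError(f"trace {self.label!r}: non-finite entries")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValidationError(f"trace {self.label!r}: time not strictly increasing")
        med = float(np.median(dt))
        if np.max(np.abs(dt - med)) >= _UNIFORMITY_RTOL * med:
            raise ValidationError(f"trace {self.label!r}: non-uniform sampling")

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.time_s)))

    @property
    def fs(self) -> float:
        return 1.0 / self.dt

    @property
    def n(self) -> int:
        return int(self.time_s.size)

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0] + self.dt)


@dataclass(frozen=True)
class TraceSet:
    """A set of traces sharing one time base (one well / field of view)."""

    traces: tuple[Trace, ...]
    well_id: str = ""
    condition: str = ""
    culture_format: str = "2D"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        traces = tuple(self.traces)
        object.__setattr__(self, "traces", traces)
        if len(traces) < 1:
            raise ValidationError("TraceSet requires at least one trace")
        t0 = traces[0].time_s
        for tr in traces[1:]:
            if tr.n != traces[0].n or not np.allclose(tr.time_s, t0, rtol=0, atol=1e-9):
                raise ValidationError("all traces must share one time base")
        labels = [tr.label for tr in traces]
        if len(set(labels)) != len(labels):
            raise ValidationError("trace labels must be unique")
        if self.culture_format not in ("2D", "3D"):
            raise ValidationError("culture_format must be '2D' or '3D'")

    @property
    def M(self) -> int:
        return len(self.traces)

    @property
    def time_s(self) -> np.ndarray:
        return self.traces[0].time_s

    @property
    def fs(self) -> float:
        return self.traces[0].fs

    @property
    def n(self) -> int:
        return self.traces[0].n

    @property
    def labels(self) -> list[str]:
        return [tr.label for tr in self.traces]

    def values(self) -> np.ndarray:
        """Stack values into an (M, N) array (rows follow trace order)."""
        return np.stack([tr.values for tr in self.traces])

    def mean_trace(self, label: str = "mean") -> Trace:
        """Average across traces — the whole-well / whole-field signal."""
        return Trace(self.time_s, self.values().mean(axis=0), label,
                     self.traces[0].kind)


@dataclass(frozen=True)
class ProtocolEvents:
    """Compound-application protocol of a recording.

    ``baseline_end_s`` is when the first (trigger) compound goes in;
    ``applications`` lists every application as (time_s, label);
    ``transition_exclusion_s`` seconds after each application are dropped
    from analysis windows because the network is mid-transition.
    """

    baseline_end_s: float = 150.0
    applications: tuple[tuple[float, str], ...] = (
        (150.0, "trigger"),
        (450.0, "compound"),
    )
    transition_exclusion_s: float = 60.0

    def __post_init__(self) -> None:
        apps = tuple((float(t), str(lbl)) for t, lbl in self.applications)
        object.__setattr__(self, "applications", apps)
        if self.baseline_end_s <= 0:
            raise ValidationError("baseline_end_s must be > 0")
        if self.transition_exclusion_s < 0:
            raise ValidationError("transition_exclusion_s must be >= 0")
        if not apps:
            raise ValidationError("at least one application is required")
        times = [t for t, _ in apps]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError("application times must be strictly increasing")
        if times[0] < self.baseline_end_s:
            raise ValidationError("applications must not precede baseline end")
        labels = [lbl for _, lbl in apps]
        if len(set(labels)) != len(labels):
            raise ValidationError("application labels must be unique")


@dataclass(frozen=True)
class Window:
    """Half-open analysis window [start_s, end_s) with its sample range."""

    name: str
    start_s: float
    end_s: float
    start_idx: int
    end_idx: int  # exclusive

    @property
    def n_samples(self) -> int:
        return self.end_idx - self.start_idx

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def slice(self) -> slice:
        return slice(self.start_idx, self.end_idx)


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        sample = fh.read(4096)
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def read_trace_table(
    path,
    dialect: str = "generic_wide",
    fs_hz: float | None = None,
    kind: TraceKind = TraceKind.RAW_FLUORESCENCE,
    well_id: str = "",
    condition: str = "",
    culture_format: str = "2D",
) -> TraceSet:
    """Read a wide delimited-text trace table into a :class:`TraceSet`.

    ``generic_wide`` expects a ``time_s`` column and one column per ROI.
    ``imagej_multimeasure`` expects a 1-based row-index first column plus
    ``Mean*`` columns (ImageJ multi-measure output) and requires ``fs_hz``
    to reconstruct the time base as ``(row - 1) / fs_hz``.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    df = pd.read_csv(path, sep=_sniff_delimiter(path))
    bad = df.isna()
    if bad.to_numpy().any():
        cells = [
            f"row {i}, column {c!r}"
            for i, row in bad.iterrows()
            for c in df.columns[row.to_numpy()]
        ]
        raise ValidationError("missing/NaN cells at: " + "; ".join(cells[:20]))

    if dialect == "generic_wide":
        if "time_s" not in df.columns:
            raise ValidationError("generic_wide table needs a 'time_s' column")
        time_s = df["time_s"].to_numpy(dtype=float)
        value_cols = [c for c in df.columns if c != "time_s"]
    elif dialect == "imagej_multimeasure":
        if fs_hz is None:
            raise ValidationError("imagej_multimeasure dialect requires fs_hz")
        rows = df.iloc[:, 0].to_numpy(dtype=float)
        time_s = (rows - rows[0]) / float(fs_hz)
        value_cols = [c for c in df.columns[1:] if str(c).startswith("Mean")]
        if not value_cols:
            raise ValidationError("imagej_multimeasure table has no 'Mean*' columns")
    else:
        raise ValidationError(f"unknown dialect: {dialect!r}")

    if not value_cols:
        raise ValidationError("trace table has no value columns")
    traces = tuple(
        Trace(time_s, df[c].to_numpy(dtype=float), str(c), kind) for c in value_cols
    )
    return TraceSet(traces, well_id=well_id, condition=condition,
                    culture_format=culture_format, metadata={"source": str(path)})


def write_trace_table(ts: TraceSet, path, delimiter: str = ",") -> None:
    """Write a TraceSet as wide delimited text (``time_s`` first column)."""
    df = pd.DataFrame({"time_s": ts.time_s})
    for tr in ts.traces:
        df[tr.label] = tr.values
    df.to_csv(path, sep=delimiter, index=False, float_format="%.10g")


def compute_dff(ts: TraceSet, baseline_window: tuple[float, float]) -> TraceSet:
    """Baseline-normalize: dF/F0(t) = (F(t) - F0) / F0, F0 = baseline mean.

    F0 is computed independently per trace over ``baseline_window``
    (seconds, half-open) and retained in the output metadata.
    """
    lo, hi = baseline_window
    if ts.traces[0].kind is not TraceKind.RAW_FLUORESCENCE:
        raise ValidationError("compute_dff expects raw_fluorescence traces")
    t = ts.time_s
    if lo < t[0] or hi > t[-1] + ts.traces[0].dt:
        raise ValidationError("baseline_window outside the recording")
    mask = (t >= lo) & (t < hi)
    if not mask.any():
        raise ValidationError("baseline_window contains no samples")
    f0s = {}
    out = []
    for tr in ts.traces:
        f0 = float(tr.values[mask].mean())
        if f0 <= 0:
            raise AnalysisError(
                f"trace {tr.label!r}: non-physical baseline F0={f0:g} <= 0"
            )
        f0s[tr.label] = f0
        out.append(Trace(t, (tr.values - f0) / f0, tr.label, TraceKind.DFF))
    meta = dict(ts.metadata)
    meta["f0"] = f0s
    meta["baseline_window_s"] = (float(lo), float(hi))
    return replace(ts, traces=tuple(out), metadata=meta)


def segment_windows(ts: TraceSet, ev: ProtocolEvents) -> dict[str, Window]:
    """Cut a recording into protocol windows with transition exclusion.

    Returns ``{"baseline": ..., "post_<label>": ...}``.  The baseline window
    is [0, baseline_end_s); each post-application window runs from
    application time + transition_exclusion_s to the next application (or
    the record end).  Windows shorter than 10 samples are rejected.
    """
    t = ts.time_s
    end_of_record = float(t[-1] + ts.traces[0].dt)
    for at, lbl in ev.applications:
        if at >= end_of_record:
            raise ValidationError(
                f"application {lbl!r} at {at:g}s lies outside the {end_of_record:g}s record"
            )

    def make(name: str, lo: float, hi: float) -> Window:
        i0 = int(np.searchsorted(t, lo - 1e-12, side="left"))
        i1 = int(np.searchsorted(t, hi - 1e-12, side="left"))
        w = Window(name, float(lo), float(hi), i0, i1)
        if w.n_samples < MIN_WINDOW_SAMPLES:
            raise ValidationError(
                f"window {name!r} [{lo:g}, {hi:g}) has {w.n_samples} samples "
                f"(< {MIN_WINDOW_SAMPLES}) after transition exclusion"
            )
        return w

    windows = {"baseline": make("baseline", float(t[0]), ev.baseline_end_s)}
    bounds = [at for at, _ in ev.applications] + [end_of_record]
    for (at, lbl), nxt in zip(ev.applications, bounds[1:]):
        windows[f"post_{lbl}"] = make(f"post_{lbl}", at + ev.transition_exclusion_s, nxt)
    return windows
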