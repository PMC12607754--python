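"""Depolarization-event detection and spike/spikelet classification.

Current-clamp traces from gap-junction-coupled cells show two event
classes: full action-potential-like spikes, and small "spikelets" —
attenuated, gap-junction-filtered copies of a neighbor's action potential.
Spikelets are defined by amplitude strictly below 30 mV; the boundary value
30 mV itself classifies as spike.  Amplitude is measured from a local
pre-event baseline (median of the preceding 100 ms), not absolute voltage,
because resting potential varies between cells and drifts within a
recording.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .errors import ValidationError
from .trace_io import Trace, TraceKind

__all__ = [
    "SPIKELET_MAX_MV",
    "EventClass",
    "EphysEvent",
    "ActivitySummary",
    "detect_events",
    "classify_events",
    "activity_summary",
]

#: Amplitudes strictly below this are spikelets; at or above, spikes.
SPIKELET_MAX_MV = 30.0

#: Length of the pre-event window whose median defines the local baseline.
BASELINE_WINDOW_S = 0.1


class EventClass(str, Enum):
    SPIKE = "spike"
    SPIKELET = "spikelet"


@dataclass(frozen=True)
class EphysEvent:
    """One depolarization event: peak time, baseline-relative amplitude."""

    time_s: float
    amplitude_mv: float
    cls: EventClass | None = None


@dataclass(frozen=True)
class ActivitySummary:
    """Fraction of cells active (>= 1 spike) plus per-cell class counts."""

    n_cells: int
    n_active: int
    fraction_active: float
    n_with_spikelets: int
    fraction_with_spikelets: float
    per_cell_counts: tuple[dict, ...]

    def __post_init__(self) -> None:
        if not (0 <= self.n_active <= self.n_cells):
            raise ValidationError("n_active must lie in [0, n_cells]")


def detect_events(
    tr: Trace,
    floor_mv: float = 2.0,
    min_separation_s: float = 0.01,
) -> list[EphysEvent]:
    """Find depolarization peaks rising >= floor_mv above the local baseline.

    A candidate is a local maximum (prominence >= floor_mv, separation >=
    min_separation_s); its amplitude is peak voltage minus the median of the
    preceding 100 ms.  Candidates below the floor are discarded.  Adding a
    constant offset to the trace leaves the result unchanged.
    """
    if tr.kind is not TraceKind.VOLTAGE:
        raise ValidationError(f"detect_events expects a voltage trace, got {tr.kind.value}")
    if floor_mv <= 0:
        raise ValidationError("floor_mv must be > 0")
    v = tr.values
    distance = max(1, int(round(min_separation_s * tr.fs)))
    idx, _ = find_peaks(v, prominence=floor_mv, distance=distance)
    w = max(1, int(round(BASELINE_WINDOW_S * tr.fs)))
    events = []
    for p in idx:
        base = float(np.median(v[max(0, p - w):p])) if p > 0 else float(v[0])
        amp = float(v[p] - base)
        if amp >= floor_mv:
            events.append(EphysEvent(float(tr.time_s[p]), amp))
    return events


def classify_events(events: Sequence[EphysEvent]) -> list[EphysEvent]:
    """Threshold classification: amplitude < 30 mV -> spikelet, else spike."""
    out = []
    for ev in events:
        cls = EventClass.SPIKELET if ev.amplitude_mv < SPIKELET_MAX_MV else EventClass.SPIKE
        out.append(replace(ev, cls=cls))
    return out


def activity_summary(
    per_cell_events: Sequence[Sequence[EphysEvent]],
    window: tuple[float, float] | None = None,
) -> ActivitySummary:
    """Summarize activity across cells within an optional time window.

    A cell counts as active iff it has at least one *spike* in the window;
    spikelet prevalence (cells with >= 1 spikelet) is reported alongside.
    Unclassified events are classified first.
    """
    if len(per_cell_events) == 0:
        raise ValidationError("activity_summary needs at least one cell")
    counts = []
    n_active = 0
    n_spikelet_cells = 0
    for cell_events in per_cell_events:
        evs = classify_events(
            [ev for ev in cell_events
             if window is None or window[0] <= ev.time_s < window[1]]
        )
        n_spikes = sum(ev.cls is EventClass.SPIKE for ev in evs)
        n_spikelets = sum(ev.cls is EventClass.SPIKELET for ev in evs)
        counts.append({"spike": n_spikes, "spikelet": n_spikelets})
        n_active += n_spikes > 0
        n_spikelet_cells += n_spikelets > 0
    n_cells = len(per_cell_events)
    return ActivitySummary(
        n_cells=n_cells,
        n_active=n_active,
        fraction_active=n_active / n_cells,
        n_with_spikelets=n_spikelet_cells,
        fraction_with_spikelets=n_spikelet_cells / n_cells,
        per_cell_counts=tuple(counts),
    )
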