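"""Periodogram frequency analysis of oscillatory traces.

The dominant-frequency estimator uses the classic (Schuster) periodogram at
the Fourier frequencies f_k = k / (N * dt), k = 1..floor(N/2):

    psd_k = (1/N) * | sum_t x_t exp(-2*pi*i*f_k*t*dt) |^2

computed on the detrended series, with no taper and no zero padding, so a
pure sinusoid at a Fourier frequency lands in exactly one bin.  The k = 0
(DC) term is excluded.  Dominant frequency is the in-band argmax of the
psd, with ties broken toward lower frequency; the default analysis band
(0.05 Hz, Nyquist) excludes slow baseline drift while keeping the ~0.2 Hz
network oscillation far from the band edges.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .errors import AnalysisError, ValidationError
from .trace_io import ProtocolEvents, Trace, TraceSet, segment_windows

__all__ = [
    "PeriodogramResult",
    "PeakList",
    "periodogram",
    "dominant_frequency",
    "average_periodograms",
    "detect_peaks",
    "frequency_summary",
]

MIN_PERIODOGRAM_SAMPLES = 16


@dataclass(frozen=True)
class PeriodogramResult:
    """Power spectral density at the positive Fourier frequencies."""

    freqs_hz: np.ndarray
    psd: np.ndarray
    dominant_freq_hz: float
    band_hz: tuple[float, float]
    n_samples: int
    window_id: str = ""

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs_hz, dtype=float)
        p = np.asarray(self.psd, dtype=float)
        object.__setattr__(self, "freqs_hz", f)
        object.__setattr__(self, "psd", p)
        if f.shape != p.shape or f.ndim != 1:
            raise ValidationError("freqs_hz and psd must be 1-D of equal length")
        if np.any(np.diff(f) <= 0):
            raise ValidationError("frequencies must be strictly increasing")
        if np.any(p < 0):
            raise ValidationError("psd must be non-negative")

    @property
    def df_hz(self) -> float:
        """Fourier bin width, 1 / (N * dt)."""
        return float(self.freqs_hz[0])


@dataclass(frozen=True)
class PeakList:
    """Detected local maxima of a trace, for oscillation QC."""

    times_s: np.ndarray
    amplitudes: np.ndarray
    prominences: np.ndarray
    min_prominence_frac: float
    min_separation_s: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValidationError("peak times must be strictly increasing")

    @property
    def n(self) -> int:
        return int(np.asarray(self.times_s).size)


def _detrend(x: np.ndarray, mode: str) -> np.ndarray:
    if mode == "mean":
        return x - x.mean()
    if mode == "linear":
        n = np.arange(x.size, dtype=float)
        coef = np.polyfit(n, x, 1)
        return x - np.polyval(coef, n)
    raise ValidationError(f"unknown detrend mode: {mode!r}")


def periodogram(tr: Trace, detrend: str = "mean", window_id: str = "",
                band_hz: tuple[float, float] | None = None) -> PeriodogramResult:
    """Classic periodogram of one uniformly sampled trace.

    Returns power at f_k = k/(N*dt) for k = 1..floor(N/2); the dominant
    frequency is evaluated over ``band_hz`` (default 0.05 Hz to Nyquist).
    """
    if tr.n < MIN_PERIODOGRAM_SAMPLES:
        raise ValidationError(
            f"trace too short for periodogram ({tr.n} < {MIN_PERIODOGRAM_SAMPLES})"
        )
    x = _detrend(tr.values.astype(float), detrend)
    n = x.size
    dt = tr.dt
    spec = np.fft.rfft(x)
    psd = (np.abs(spec) ** 2) / n
    freqs = np.fft.rfftfreq(n, d=dt)
    # drop k = 0; for even n the rfft also returns k = n/2 which we keep
    freqs, psd = freqs[1:], psd[1:]
    nyq = 0.5 / dt
    if band_hz is None:
        band_hz = (0.05, nyq)
    pg = PeriodogramResult(freqs, psd, np.nan, band_hz, n, window_id)
    dom = dominant_frequency(pg, band_hz)
    return replace(pg, dominant_freq_hz=dom)


def dominant_frequency(pg: PeriodogramResult,
                       band_hz: tuple[float, float] | None = None) -> float:
    """In-band psd argmax; exact ties break toward the lower frequency."""
    if band_hz is None:
        band_hz = pg.band_hz
    lo, hi = band_hz
    mask = (pg.freqs_hz >= lo) & (pg.freqs_hz <= hi)
    if not mask.any():
        raise AnalysisError(
            f"band ({lo:g}, {hi:g}) Hz contains no Fourier frequencies"
        )
    sub = pg.psd[mask]
    # np.argmax returns the first (= lowest-frequency) maximizer
    return float(pg.freqs_hz[mask][int(np.argmax(sub))])


def average_periodograms(pgs: Sequence[PeriodogramResult]) -> PeriodogramResult:
    """Pointwise-mean psd across wells; dominant recomputed on the mean."""
    if not pgs:
        raise ValidationError("no periodograms to average")
    f0 = pgs[0].freqs_hz
    for pg in pgs[1:]:
        if pg.freqs_hz.shape != f0.shape or not np.allclose(
            pg.freqs_hz, f0, rtol=1e-12, atol=0
        ):
            raise ValidationError("mismatched frequency grids")
    mean_psd = np.mean([pg.psd for pg in pgs], axis=0)
    out = PeriodogramResult(
        f0, mean_psd, np.nan, pgs[0].band_hz, pgs[0].n_samples,
        window_id=pgs[0].window_id,
    )
    return replace(out, dominant_freq_hz=dominant_frequency(out))


def detect_peaks(tr: Trace, min_prominence_frac: float = 0.1,
                 min_separation_s: float = 1.0) -> PeakList:
    """Local maxima with prominence >= frac * (max - min) of the trace.

    Conflicting peaks closer than ``min_separation_s`` are resolved greedily,
    keeping the higher one.
    """
    if not (0 < min_prominence_frac <= 1):
        raise ValidationError("min_prominence_frac must lie in (0, 1]")
    if tr.n < 3:
        raise ValidationError("trace too short for peak detection")
    v = tr.values
    rng = float(v.max() - v.min())
    if rng == 0:
        return PeakList(np.array([]), np.array([]), np.array([]),
                        min_prominence_frac, min_separation_s)
    distance = max(1, int(round(min_separation_s * tr.fs)))
    idx, props = find_peaks(v, prominence=min_prominence_frac * rng,
                            distance=distance)
    return PeakList(tr.time_s[idx], v[idx], props["prominences"],
                    min_prominence_frac, min_separation_s)


def frequency_summary(
    groups: dict[str, Sequence[TraceSet]],
    ev: ProtocolEvents,
    window: str = "post_trigger",
    band_hz: tuple[float, float] | None = None,
    detrend: str = "mean",
) -> dict[str, dict]:
    """Per-condition dominant-frequency summary (mean +/- SEM over wells).

    Each well's frequency is the dominant periodogram frequency of its
    across-ROI mean trace within the named protocol window.  SEM is
    sd/sqrt(n) (ddof=1) and is reported as None for n = 1.
    """
    out: dict[str, dict] = {}
    for label, wells in groups.items():
        if not wells:
            raise ValidationError(f"group {label!r} has no wells")
        per_well = []
        for k, ts in enumerate(wells):
            windows = segment_windows(ts, ev)
            if window not in windows:
                wid = ts.well_id or f"well{k}"
                raise ValidationError(
                    f"window {window!r} missing for well {wid!r} in group {label!r}"
                )
            w = windows[window]
            mt = ts.mean_trace()
            sub = Trace(mt.time_s[w.slice], mt.values[w.slice], mt.label, mt.kind)
            pg = periodogram(sub, detrend=detrend, window_id=w.name, band_hz=band_hz)
            per_well.append(
                {"well_id": ts.well_id or f"well{k}",
                 "dominant_freq_hz": pg.dominant_freq_hz}
            )
        vals = np.array([pw["dominant_freq_hz"] for pw in per_well])
        n = vals.size
        sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else None
        out[label] = {
            "mean_hz": float(vals.mean()),
            "sem_hz": sem,
            "n": int(n),
            "window": window,
            "per_well": per_well,
        }
    return out
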