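"""Global Synchronization Index (GSI) from multi-ROI recordings.

The statistic quantifies network-wide co-activity of M simultaneously
recorded signals (typically 10 ROIs of one well).  Each signal is z-scored
within the analysis window and the equal-time Pearson correlation matrix C
is formed.  Its largest eigenvalue lambda_M approaches M when all signals
move together and stays near the bulk of the spectrum for uncoordinated
activity.  To calibrate "uncoordinated", a surrogate null is built by
independently circular-shifting each signal (preserving every signal's
autocorrelation while destroying cross-signal alignment) and recording the
largest eigenvalue of each surrogate correlation matrix.  With mu' and
sigma' the mean and SD of the S surrogate draws and K a threshold
multiplier:

    GSI = 0                                   if lambda_M <= mu' + K*sigma'
    GSI = (lambda_M - mu') / (M - mu')        otherwise, clipped to [0, 1]

so 0 means indistinguishable from the null and 1 means a fully
interconnected network (ten identical signals give lambda_M = M and hence
GSI = 1 exactly, for any surrogate draw).

Signed correlations are used by default: anti-phase signals do not count as
synchrony.  An ``abs`` mode (|C| before the eigendecomposition) is provided
as a documented alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import ceil, floor

import numpy as np

from .errors import AnalysisError, ValidationError
from .trace_io import ProtocolEvents, TraceSet, Window, segment_windows

__all__ = [
    "CorrelationMatrix",
    "SurrogateNull",
    "GsiResult",
    "correlation_matrix",
    "surrogate_null",
    "gsi",
    "gsi_pre_post",
]

MIN_CORR_SAMPLES = 10


@dataclass(frozen=True)
class CorrelationMatrix:
    """Equal-time Pearson correlation matrix of z-scored window signals."""

    C: np.ndarray
    window_id: str = ""

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        object.__setattr__(self, "C", C)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValidationError("correlation matrix must be square")
        if not np.allclose(C, C.T, atol=1e-12):
            raise ValidationError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(C), 1.0, atol=1e-12):
            raise ValidationError("correlation matrix must have unit diagonal")
        if np.any(C < -1 - 1e-12) or np.any(C > 1 + 1e-12):
            raise ValidationError("correlation entries must lie in [-1, 1]")

    @property
    def M(self) -> int:
        return self.C.shape[0]

    def lambda_max(self) -> float:
        return float(np.linalg.eigvalsh(self.C)[-1])


@dataclass(frozen=True)
class SurrogateNull:
    """Largest-eigenvalue null distribution from surrogate data."""

    lambda_max_samples: np.ndarray
    mu_prime: float
    sigma_prime: float
    S: int
    method: str
    seed: int | None

    def __post_init__(self) -> None:
        draws = np.asarray(self.lambda_max_samples, dtype=float)
        object.__setattr__(self, "lambda_max_samples", draws)
        if self.S < 2 or draws.size != self.S:
            raise ValidationError("surrogate null needs S >= 2 draws")
        if self.sigma_prime < 0:
            raise ValidationError("sigma_prime must be >= 0")

    def threshold(self, K: float) -> float:
        return self.mu_prime + K * self.sigma_prime


@dataclass(frozen=True)
class GsiResult:
    """The synchronization index with all intermediates retained."""

    gsi: float
    lambda_max: float
    null: SurrogateNull
    threshold_k: float
    M: int
    window_id: str = ""
    correlation: CorrelationMatrix | None = None
    mode: str = "signed"
    signal_kind: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.gsi <= 1.0):
            raise ValidationError("gsi must lie in [0, 1]")


def _window_slice(ts: TraceSet, window) -> tuple[slice, str]:
    if isinstance(window, Window):
        return window.slice, window.name
    if window is None:
        return slice(0, ts.n), "full"
    lo, hi = window
    return slice(int(lo), int(hi)), f"[{int(lo)},{int(hi)})"


def correlation_matrix(ts: TraceSet, window=None) -> CorrelationMatrix:
    """Correlate all trace pairs over a window (sample-index range).

    Signals are z-scored over the window (population SD); C_ij is the mean
    of products, so C_ii = 1 exactly.  A zero-variance trace is a dead or
    saturated ROI and is reported by label.
    """
    sl, wid = _window_slice(ts, window)
    X = ts.values()[:, sl].astype(float)
    if X.shape[1] < MIN_CORR_SAMPLES:
        raise ValidationError(
            f"window {wid} has {X.shape[1]} samples (< {MIN_CORR_SAMPLES})"
        )
    sd = X.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = ", ".join(ts.labels[i] for i in dead)
        raise AnalysisError(f"zero-variance trace(s) in window {wid}: {names}")
    Z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    C = (Z @ Z.T) / X.shape[1]
    np.fill_diagonal(C, 1.0)
    C = np.clip(C, -1.0, 1.0)
    C = (C + C.T) / 2.0
    return CorrelationMatrix(C, wid)


def _lambda_max_of(X: np.ndarray) -> float:
    sd = X.std(axis=1)
    sd[sd == 0] = 1.0  # a flat surrogate row contributes zero correlation
    Z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    C = (Z @ Z.T) / X.shape[1]
    np.fill_diagonal(C, 1.0)
    return float(np.linalg.eigvalsh(C)[-1])


def surrogate_null(
    ts: TraceSet,
    window=None,
    S: int = 100,
    method: str = "circular_shift",
    seed: int | None = None,
    mode: str = "signed",
) -> SurrogateNull:
    """Null distribution of the largest eigenvalue under broken alignment.

    Each surrogate applies an independent transform per signal and records
    the largest eigenvalue of the resulting correlation matrix:

    - ``circular_shift``: roll each signal by a uniform shift in
      [ceil(T/8), floor(7T/8)] samples, preserving autocorrelation;
    - ``permutation``: independently shuffle each signal in time.
    """
    if S < 2:
        raise ValidationError("surrogate count S must be >= 2")
    if method not in ("circular_shift", "permutation"):
        raise ValidationError(f"unknown surrogate method: {method!r}")
    sl, wid = _window_slice(ts, window)
    X = ts.values()[:, sl].astype(float)
    M, T = X.shape
    if T < 10 * M:
        warnings.warn(
            f"window {wid}: only {T} samples for {M} signals; surrogate null "
            "may be poorly resolved (recommended T >= 10*M)",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    draws = np.empty(S)
    lo, hi = ceil(T / 8), floor(7 * T / 8)
    for s in range(S):
        if method == "circular_shift":
            shifts = rng.integers(lo, hi + 1, size=M)
            Xs = np.stack([np.roll(X[i], int(shifts[i])) for i in range(M)])
        else:
            Xs = np.stack([X[i, rng.permutation(T)] for i in range(M)])
        if mode == "abs":
            draws[s] = _lambda_max_abs(Xs)
        else:
            draws[s] = _lambda_max_of(Xs)
    return SurrogateNull(draws, float(draws.mean()), float(draws.std(ddof=1)),
                         S, method, seed)


def _lambda_max_abs(X: np.ndarray) -> float:
    sd = X.std(axis=1)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    C = np.abs((Z @ Z.T) / X.shape[1])
    np.fill_diagonal(C, 1.0)
    return float(np.linalg.eigvalsh(C)[-1])


def gsi(
    ts: TraceSet,
    window=None,
    S: int = 100,
    K: float = 3.0,
    seed: int | None = None,
    method: str = "circular_shift",
    mode: str = "signed",
) -> GsiResult:
    """Compute the Global Synchronization Index on one analysis window."""
    if ts.M < 2:
        raise ValidationError(
            "GSI needs at least 2 signals (a single trace is vacuously 'synchronized')"
        )
    cm = correlation_matrix(ts, window)
    if mode == "abs":
        C = np.abs(cm.C)
        np.fill_diagonal(C, 1.0)
        lam = float(np.linalg.eigvalsh(C)[-1])
    elif mode == "signed":
        lam = cm.lambda_max()
    else:
        raise ValidationError(f"unknown correlation mode: {mode!r}")
    null = surrogate_null(ts, window, S=S, method=method, seed=seed, mode=mode)
    M = ts.M
    if lam <= null.threshold(K):
        value = 0.0
    else:
        denom = M - null.mu_prime
        value = 1.0 if denom <= 0 else float(np.clip((lam - null.mu_prime) / denom, 0.0, 1.0))
    kind = ts.traces[0].kind.value
    return GsiResult(value, lam, null, K, M, cm.window_id, cm, mode, kind)


def gsi_pre_post(
    ts: TraceSet,
    ev: ProtocolEvents,
    application_label: str,
    S: int = 100,
    K: float = 3.0,
    seed: int | None = None,
    mode: str = "signed",
) -> tuple[GsiResult, GsiResult, float]:
    """GSI contrast around one compound application.

    The pre window is the protocol window that ends at the application (the
    preceding post-application window, or the baseline for the first
    application); the post window starts after the transition exclusion.
    Returns (pre, post, delta = pre - post).
    """
    labels = [lbl for _, lbl in ev.applications]
    if application_label not in labels:
        raise ValidationError(
            f"no application labelled {application_label!r} (have: {labels})"
        )
    windows = segment_windows(ts, ev)
    i = labels.index(application_label)
    if i == 0:
        pre_name = "baseline"
    else:
        pre_name = f"post_{labels[i - 1]}"
    post_name = f"post_{application_label}"
    pre = gsi(ts, windows[pre_name], S=S, K=K, seed=seed, mode=mode)
    post = gsi(ts, windows[post_name], S=S, K=K, seed=seed, mode=mode)
    return pre, post, pre.gsi - post.gsi
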