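"""Seeded generators for every input the analysis pipeline consumes.

Three generators emulate the statistical structure of the study system —
gap-junction-coupled neuronal cultures oscillating at ~0.2 Hz:

1. ``simulate_network_traces``: a Kuramoto network of phase oscillators.
   Cells are silent until a trigger application (TEA-like) resets all
   phases and starts the oscillation; while coupling is on, phases evolve
   with all-to-all sine coupling; a blocker application (CBX-like) sets the
   coupling to zero and re-draws the intrinsic frequencies, so cells stay
   active but desynchronize.  Every upward 2*pi phase crossing emits a
   calcium transient: a double-exponential indicator kernel with log-normal
   amplitude, on top of an exponentially bleaching baseline plus Gaussian
   observation noise.

2. ``simulate_voltage_traces``: Poisson action-potential-like spikes per
   cell; while coupling is on, each neighbor spike can inject an attenuated
   (< 30 mV) spikelet.  After a blocker event, spikelets cease and only a
   configurable fraction of cells retains spikes.

3. ``simulate_counts``: negative-binomial gene x sample count tables in
   which a designated gap-junction gene set decays monotonically across
   differentiation days, with configurable low-depth samples to exercise
   the library-size pre-filter.

One global seed drives independent per-component generators (via
``numpy.random.SeedSequence`` spawning), so adding a component never
perturbs the others; identical config + seed gives bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ephys import SPIKELET_MAX_MV, EphysEvent, EventClass
from .errors import ValidationError
from .expression import CountMatrix
from .trace_io import Trace, TraceKind, TraceSet, write_trace_table

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "VoltageSimConfig",
    "GAP_JUNCTION_GENES",
    "simulate_network_traces",
    "simulate_voltage_traces",
    "simulate_counts",
    "save_network_simulation",
]

#: Connexin (gap-junction subunit) genes carrying the engineered day decay.
GAP_JUNCTION_GENES = (
    "GJA1", "GJA5", "GJA8", "GJB1", "GJB2", "GJB6", "GJC1", "GJC2", "GJD2",
)


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the coupled-oscillator fluorescence simulation.

    Defaults mirror the study conditions: 10 ROIs per well, 15-minute
    recordings sampled at 5 Hz, intrinsic frequencies near 0.2 Hz, a
    trigger application at 150 s (end of the 2.5-min baseline), and an
    optional blocker application that abolishes coupling.
    """

    n_cells: int = 10
    duration_s: float = 900.0
    fs_hz: float = 5.0
    f0_hz: float = 0.2
    f_sd_hz: float = 0.02
    coupling: float = 2.0  # rad/s, all-to-all sine coupling strength
    phase_noise_sd: float = 0.1  # rad/sqrt(s), Wiener phase noise
    trigger_time_s: float = 150.0
    blocker_time_s: float | None = None
    transient_tau_rise_s: float = 0.3
    transient_tau_decay_s: float = 1.5
    amp_mean: float = 1.0
    amp_cv: float = 0.1
    baseline_f0: float = 1.0
    bleach_rate_per_s: float = 1e-4
    obs_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_cells >= 1, "n_cells must be a positive integer")
        _require(self.duration_s > 0, "duration_s must be > 0")
        _require(self.fs_hz > 2 * self.f0_hz,
                 "fs_hz must exceed twice f0_hz (Nyquist)")
        for name in ("f_sd_hz", "coupling", "phase_noise_sd", "amp_cv",
                     "bleach_rate_per_s", "obs_noise_sd"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")
        _require(self.f0_hz > 0, "f0_hz must be > 0")
        _require(self.amp_mean > 0, "amp_mean must be > 0")
        _require(self.baseline_f0 > 0, "baseline_f0 must be > 0")
        _require(self.transient_tau_rise_s > 0, "transient_tau_rise_s must be > 0")
        _require(self.transient_tau_decay_s > self.transient_tau_rise_s,
                 "transient_tau_decay_s must exceed transient_tau_rise_s")
        _require(0 < self.trigger_time_s < self.duration_s,
                 "trigger_time_s must lie inside the recording")
        if self.blocker_time_s is not None:
            _require(self.trigger_time_s < self.blocker_time_s < self.duration_s,
                     "blocker_time_s must lie between trigger_time_s and duration_s")


@dataclass(frozen=True)
class GroundTruth:
    """Latent truth of one network simulation."""

    spike_times: tuple[np.ndarray, ...]  # per cell, seconds, increasing
    phase_trajectories: np.ndarray  # (n_cells, n_samples), rad; 0 pre-trigger
    coupled: np.ndarray  # boolean over samples
    intrinsic_freqs: np.ndarray  # per-cell Hz, pre-blocker
    post_blocker_freqs: np.ndarray | None = None  # per-cell Hz after re-draw


@dataclass(frozen=True)
class VoltageSimConfig:
    """Parameters of the current-clamp-like voltage simulation."""

    n_cells: int = 12
    duration_s: float = 60.0
    fs_hz: float = 1000.0
    spike_amp_mv: float = 70.0
    spike_amp_sd_mv: float = 5.0
    spikelet_amp_range_mv: tuple[float, float] = (3.0, 25.0)
    spike_rate_hz: float = 0.5
    spikelet_rate_hz: float = 1.0
    blocker_time_s: float | None = None
    post_blocker_active_fraction: float = 0.25
    coupling_enabled: bool = True
    rest_mv: float = -60.0
    noise_sd_mv: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_cells >= 1, "n_cells must be a positive integer")
        _require(self.duration_s > 0, "duration_s must be > 0")
        _require(self.fs_hz > 0, "fs_hz must be > 0")
        lo, hi = self.spikelet_amp_range_mv
        _require(0 < lo < hi, "spikelet_amp_range_mv must satisfy 0 < low < high")
        _require(hi < SPIKELET_MAX_MV,
                 f"spikelet_amp_range_mv upper bound must be < {SPIKELET_MAX_MV} mV")
        _require(self.spike_amp_mv >= SPIKELET_MAX_MV,
                 "spike_amp_mv must be at least 30 mV")
        _require(0 <= self.post_blocker_active_fraction <= 1,
                 "post_blocker_active_fraction must lie in [0, 1]")
        _require(self.spike_rate_hz >= 0, "spike_rate_hz must be >= 0")
        _require(self.spikelet_rate_hz >= 0, "spikelet_rate_hz must be >= 0")
        if self.blocker_time_s is not None:
            _require(0 < self.blocker_time_s < self.duration_s,
                     "blocker_time_s must lie inside the recording")


def _kernel_peak(tau_rise: float, tau_decay: float) -> float:
    """Peak value of exp(-u/tau_decay) - exp(-u/tau_rise) (analytic)."""
    u_star = np.log(tau_decay / tau_rise) * tau_rise * tau_decay / (tau_decay - tau_rise)
    return float(np.exp(-u_star / tau_decay) - np.exp(-u_star / tau_rise))


def _add_transient(signal: np.ndarray, t_spike: float, amp: float, dt: float,
                   tau_rise: float, tau_decay: float, peak: float) -> None:
    """Add one unit-peak double-exponential transient at a continuous time.

    Transients are placed at the exact (interpolated) phase-crossing time,
    not snapped to the sample grid, so sub-sample timing offsets between
    coupled cells are preserved in the traces.
    """
    n = signal.size
    k0 = int(np.ceil(t_spike / dt - 1e-12))
    k1 = min(n, k0 + int(np.ceil(tau_decay * 8.0 / dt)))
    if k0 >= n:
        return
    u = np.arange(k0, k1) * dt - t_spike
    signal[k0:k1] += (amp / peak) * (np.exp(-u / tau_decay) - np.exp(-u / tau_rise))


def simulate_network_traces(config: SimulationConfig) -> tuple[TraceSet, GroundTruth]:
    """Simulate one well: coupled oscillators -> fluorescence traces.

    Before the trigger, traces are baseline (with slow bleaching) plus
    observation noise only.  At the trigger every phase is reset to zero
    (a common, plate-wide stimulus), after which phases follow

        dtheta_i = [omega_i + (K/N) * sum_j sin(theta_j - theta_i)] dt
                   + phase_noise_sd * dW_i

    integrated by Euler-Maruyama at the sampling rate, with K = coupling
    between trigger and blocker and K = 0 (plus re-drawn omega_i) after the
    blocker.  Each upward 2*pi crossing emits one calcium transient.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    rng_freq, rng_phase, rng_amp, rng_obs, rng_redraw = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    dt = 1.0 / cfg.fs_hz
    n = int(round(cfg.duration_s * cfg.fs_hz))
    t = np.arange(n) * dt
    m = cfg.n_cells
    trig = int(round(cfg.trigger_time_s * cfg.fs_hz))
    blk = None if cfg.blocker_time_s is None else int(round(cfg.blocker_time_s * cfg.fs_hz))

    def draw_freqs(rng):
        # f0_hz is the well's mean intrinsic frequency: center the draws so
        # the realized mean is exactly f0 and f_sd_hz is between-cell spread
        dev = cfg.f_sd_hz * rng.standard_normal(m)
        if m > 1:
            dev -= dev.mean()
        w = 2 * np.pi * (cfg.f0_hz + dev)
        return np.maximum(w, 2 * np.pi * 1e-3)  # keep oscillators forward-running

    omega = draw_freqs(rng_freq)
    omega_post = draw_freqs(rng_redraw) if blk is not None else None

    # Euler-Maruyama needs coupling * step << 1; substep the stiff term
    n_sub = int(min(1000, max(1, np.ceil(cfg.coupling * dt / 0.05))))
    dt_sub = dt / n_sub
    sq = cfg.phase_noise_sd * np.sqrt(dt_sub)
    theta = np.zeros((m, n))
    cur = np.zeros(m)
    for k in range(trig + 1, n):
        coupled_now = blk is None or k - 1 < blk
        w = omega if coupled_now else omega_post
        kcoup = cfg.coupling if coupled_now else 0.0
        for _ in range(n_sub):
            if kcoup > 0 and m > 1:
                # mean-field form of (K/N) * sum_j sin(theta_j - theta_i)
                z = np.exp(1j * cur).mean()
                drift = w + kcoup * np.abs(z) * np.sin(np.angle(z) - cur)
            else:
                drift = w
            cur = cur + drift * dt_sub + sq * rng_phase.standard_normal(m)
        theta[:, k] = cur

    # spikes: upward crossings of 2*pi multiples, at interpolated times
    wraps = np.floor(theta / (2 * np.pi)).astype(int)
    spike_times = []
    for i in range(m):
        idx = np.flatnonzero(np.diff(wraps[i]) > 0) + 1
        idx = idx[idx > trig]
        level = 2 * np.pi * wraps[i, idx]
        th0, th1 = theta[i, idx - 1], theta[i, idx]
        frac = np.clip((level - th0) / (th1 - th0), 0.0, 1.0)
        spike_times.append((idx - 1 + frac) * dt)

    peak = _kernel_peak(cfg.transient_tau_rise_s, cfg.transient_tau_decay_s)
    if cfg.amp_cv > 0:
        sigma2 = np.log1p(cfg.amp_cv ** 2)
        mu = np.log(cfg.amp_mean) - sigma2 / 2

    traces = []
    bleach = cfg.baseline_f0 * np.exp(-cfg.bleach_rate_per_s * t)
    for i in range(m):
        st = spike_times[i]
        if cfg.amp_cv > 0:
            amps = rng_amp.lognormal(mu, np.sqrt(sigma2), size=st.size)
        else:
            amps = np.full(st.size, cfg.amp_mean)
        signal = np.zeros(n)
        for t_sp, a in zip(st, amps):
            _add_transient(signal, t_sp, a, dt, cfg.transient_tau_rise_s,
                           cfg.transient_tau_decay_s, peak)
        obs = rng_obs.standard_normal(n) * cfg.obs_noise_sd
        traces.append(Trace(t, bleach + signal + obs, f"ROI{i + 1}",
                            TraceKind.RAW_FLUORESCENCE))

    coupled = (t >= cfg.trigger_time_s) & (cfg.coupling > 0)
    if cfg.blocker_time_s is not None:
        coupled &= t < cfg.blocker_time_s
    truth = GroundTruth(
        spike_times=tuple(spike_times),
        phase_trajectories=theta,
        coupled=coupled,
        intrinsic_freqs=omega / (2 * np.pi),
        post_blocker_freqs=None if omega_post is None else omega_post / (2 * np.pi),
    )
    ts = TraceSet(tuple(traces), well_id=f"sim-{cfg.seed}", condition="synthetic",
                  metadata={"config": asdict(cfg)})
    return ts, truth


def _poisson_times(rng, rate_hz, t0, t1, refractory_s=0.05):
    """Poisson event times in [t0, t1) with a hard refractory period."""
    if rate_hz <= 0 or t1 <= t0:
        return np.array([])
    n_exp = rng.poisson(rate_hz * (t1 - t0))
    times = np.sort(rng.uniform(t0, t1, size=n_exp))
    kept = []
    last = -np.inf
    for x in times:
        if x - last >= refractory_s:
            kept.append(x)
            last = x
    return np.asarray(kept)


def simulate_voltage_traces(
    config: VoltageSimConfig,
) -> tuple[list[Trace], list[list[EphysEvent]]]:
    """Simulate current-clamp-like voltage traces with spikes and spikelets.

    Each cell fires Poisson spikes.  While coupling is on (from t = 0 until
    the blocker, and only if ``coupling_enabled``), neighbor spikes are
    transmitted as attenuated spikelets (amplitude uniform within
    ``spikelet_amp_range_mv``, 2 ms delay), thinned so the per-cell
    spikelet rate is about ``spikelet_rate_hz``.  After the blocker exactly
    ``round(post_blocker_active_fraction * n_cells)`` cells retain spikes
    and spikelets cease.  Returns the traces and the per-cell ground-truth
    events (classified).
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    rng_spk, rng_let, rng_sel, rng_obs = (np.random.default_rng(s) for s in ss.spawn(4))

    dt = 1.0 / cfg.fs_hz
    n = int(round(cfg.duration_s * cfg.fs_hz))
    t = np.arange(n) * dt
    m = cfg.n_cells
    blk = cfg.blocker_time_s
    coupling_end = (blk if blk is not None else cfg.duration_s) if cfg.coupling_enabled else 0.0

    # pre-blocker spikes for every cell; post-blocker only for the active set
    pre_end = blk if blk is not None else cfg.duration_s
    spikes = [
        list(_poisson_times(rng_spk, cfg.spike_rate_hz, 0.0, pre_end)) for _ in range(m)
    ]
    if blk is not None:
        k_active = int(round(cfg.post_blocker_active_fraction * m))
        active = set(rng_sel.permutation(m)[:k_active].tolist())
        for i in range(m):
            if i in active:
                post = list(_poisson_times(rng_spk, cfg.spike_rate_hz, blk, cfg.duration_s))
                if not post:  # the active set must actually retain spikes
                    post = [float(rng_spk.uniform(blk + 0.1, cfg.duration_s - dt))]
                spikes[i].extend(post)

    # spikelets: thinned copies of neighbor spikes while coupling is on
    neighbor_rate = cfg.spike_rate_hz * max(m - 1, 0)
    p_transmit = 0.0 if neighbor_rate == 0 else min(1.0, cfg.spikelet_rate_hz / neighbor_rate)
    spikelets: list[list[float]] = [[] for _ in range(m)]
    for j in range(m):
        for s_time in spikes[j]:
            if s_time >= coupling_end:
                continue
            for i in range(m):
                if i != j and rng_let.uniform() < p_transmit:
                    s_let = s_time + 0.002
                    if s_let < coupling_end:
                        spikelets[i].append(s_let)

    # event bookkeeping with amplitudes; enforce per-cell separation
    lo, hi = cfg.spikelet_amp_range_mv
    sigma_samp = max(1, int(round(0.001 * cfg.fs_hz)))  # 1 ms waveform width
    support = np.arange(-4 * sigma_samp, 4 * sigma_samp + 1)
    template = np.exp(-0.5 * (support / sigma_samp) ** 2)

    traces = []
    truth: list[list[EphysEvent]] = []
    for i in range(m):
        cand = [(x, "spike") for x in spikes[i]] + [(x, "spikelet") for x in spikelets[i]]
        cand.sort()
        events: list[EphysEvent] = []
        v = np.full(n, cfg.rest_mv)
        last = -np.inf
        for x, what in cand:
            if x - last < 0.05 or x >= cfg.duration_s - dt:
                continue
            last = x
            if what == "spike":
                amp = float(np.clip(
                    rng_spk.normal(cfg.spike_amp_mv, cfg.spike_amp_sd_mv),
                    SPIKELET_MAX_MV + 10.0, 3 * cfg.spike_amp_mv))
                cls = EventClass.SPIKE
            else:
                amp = float(rng_let.uniform(lo, hi))
                cls = EventClass.SPIKELET
            k = int(round(x / dt))
            sel = (support + k >= 0) & (support + k < n)
            v[support[sel] + k] += amp * template[sel]
            events.append(EphysEvent(float(t[k]), amp, cls))
        v = v + rng_obs.standard_normal(n) * cfg.noise_sd_mv
        traces.append(Trace(t, v, f"cell{i + 1}", TraceKind.VOLTAGE))
        truth.append(events)
    return traces, truth


def simulate_counts(
    n_genes: int,
    samples_per_day: int,
    days: list[str],
    seed: int = 0,
    dispersion: float = 0.3,
    n_low_depth: int = 0,
    decay: float = 0.6,
) -> CountMatrix:
    """Simulate a gene x sample count table across differentiation days.

    The embedded gap-junction gene set receives a multiplicative day effect
    ``decay**day_index`` (strictly decreasing along the given day order);
    all other genes keep constant relative expression.  Counts are
    negative-binomial around library-size-scaled expected values
    (``dispersion = 0`` gives the deterministic rounded means).  The last
    ``n_low_depth`` samples get library sizes below 0.2 million to exercise
    the pre-filter.
    """
    if not days:
        raise ValidationError("day list must not be empty")
    if n_genes < len(GAP_JUNCTION_GENES):
        raise ValidationError(
            f"n_genes must be >= {len(GAP_JUNCTION_GENES)} (the embedded gene set)"
        )
    if samples_per_day < 1:
        raise ValidationError("samples_per_day must be >= 1")
    if dispersion < 0:
        raise ValidationError("dispersion must be >= 0")
    n_samples = samples_per_day * len(days)
    if not (0 <= n_low_depth <= n_samples):
        raise ValidationError("n_low_depth must lie in [0, n_samples]")

    ss = np.random.SeedSequence(seed)
    rng_expr, rng_lib, rng_counts = (np.random.default_rng(s) for s in ss.spawn(3))

    gene_ids = list(GAP_JUNCTION_GENES) + [
        f"gene_{k:05d}" for k in range(n_genes - len(GAP_JUNCTION_GENES))
    ]
    base = np.empty(n_genes)
    n_gj = len(GAP_JUNCTION_GENES)
    base[:n_gj] = rng_expr.uniform(100.0, 500.0, size=n_gj)
    base[n_gj:] = rng_expr.lognormal(np.log(20.0), 1.5, size=n_genes - n_gj)

    sample_ids, sample_days = [], []
    for day in days:
        for r in range(samples_per_day):
            sample_ids.append(f"{day}_s{r + 1}")
            sample_days.append(str(day))

    lib = rng_lib.integers(1_000_000, 4_000_000, size=n_samples).astype(float)
    if n_low_depth:
        lib[-n_low_depth:] = rng_lib.integers(50_000, 150_000, size=n_low_depth)

    counts = np.empty((n_genes, n_samples), dtype=np.int64)
    for s in range(n_samples):
        day_idx = days.index(sample_days[s])
        rel = base.copy()
        rel[:n_gj] *= decay ** day_idx
        p = rel / rel.sum()
        mean = lib[s] * p
        if dispersion == 0:
            counts[:, s] = np.round(mean).astype(np.int64)
        else:
            r = 1.0 / dispersion
            counts[:, s] = rng_counts.negative_binomial(r, r / (r + mean))
    df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    meta = pd.DataFrame({"day": sample_days}, index=sample_ids)
    return CountMatrix(df, meta)


def save_network_simulation(ts: TraceSet, truth: GroundTruth, out_dir) -> dict[str, Path]:
    """Write a simulated well as a trace table + ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trace_path = out / "traces.csv"
    truth_path = out / "ground_truth.json"
    write_trace_table(ts, trace_path)
    payload = {
        "spike_times_s": [st.tolist() for st in truth.spike_times],
        "intrinsic_freqs_hz": truth.intrinsic_freqs.tolist(),
        "post_blocker_freqs_hz": (
            None if truth.post_blocker_freqs is None
            else truth.post_blocker_freqs.tolist()
        ),
        "coupled": truth.coupled.astype(int).tolist(),
    }
    truth_path.write_text(json.dumps(payload, indent=1))
    return {"traces": trace_path, "ground_truth": truth_path}
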