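# Methods

## The synchronization index

The Global Synchronization Index condenses the coordination of M
simultaneously recorded signals into one number in [0, 1]. Within the
analysis window each signal is z-scored (population SD) and the equal-time
Pearson correlation matrix C is formed; C is symmetric, unit-diagonal and
positive semidefinite, so its eigenvalues are real and sum to M. When all
signals are proportional, the spectrum collapses onto a single eigenvalue
λ_M = M; for uncoordinated signals λ_M stays near the bulk predicted by
random-matrix behavior (≈ (1 + √(M/T))² for T samples).

"Uncoordinated" is calibrated empirically rather than asymptotically:
each of S surrogates applies an independent circular shift to every
signal, drawn uniformly from [⌈T/8⌉, ⌊7T/8⌋] samples. Circular shifting
preserves each signal's full autocorrelation (and hence its oscillatory
structure) while destroying cross-signal alignment. The S largest
eigenvalues of the surrogate correlation matrices give the null mean μ′
and SD σ′, and

    GSI = 0                         if λ_M ≤ μ′ + K σ′,
    GSI = (λ_M − μ′) / (M − μ′)     otherwise, clipped to [0, 1].

Defaults: S = 100, K = 3, signed correlations. All four choices are
configurable and recorded in the result object.

Design notes:

- **Signed vs absolute correlations.** Signed is the default: anti-phase
  signals should not count as synchrony under a global index. An `abs`
  mode is provided (null and observed eigenvalue both computed on |C|) for
  users who want phase-indifferent co-modulation.
- **Thresholding.** The K·σ′ gate makes the index exactly 0 for data
  indistinguishable from the null instead of reporting small spurious
  positives; K = 3 corresponds to a ≈ 0.1% one-sided false-positive rate
  under a normal approximation of the null.
- **Exact endpoint.** λ_M = M forces (λ_M − μ′)/(M − μ′) = 1 for *any*
  μ′ < M, so identical signals give GSI = 1 regardless of the surrogate
  seed — a useful internal consistency check.
- **Null conservatism for strictly periodic data.** For nearly perfectly
  periodic signals, a circular shift close to a multiple of the period
  re-aligns the signals, so the null is right-shifted and the index is
  conservative. This is intentional (the null preserves per-signal
  structure), but it means GSI values from highly regular recordings are
  lower bounds on synchrony. The `permutation` surrogate method is
  available when a fully alignment-destroying null is wanted.
- **Degenerate input.** M = 1 is rejected: a single trace is vacuously
  "synchronized" and the index would be meaningless.
- **Window z-scoring.** Signals are standardized within the analysis
  window, not globally, because protocol windows differ in baseline level
  by construction.

The production eigensolver is `numpy.linalg.eigvalsh`; tests verify it
against an independent power-iteration oracle to 1e-8 on random
correlation matrices.

## Protocol windows and transition exclusion

Recordings follow baseline → trigger application → (optional) second
application. Windows are half-open [start, end) in seconds with 0-based
sample indices, so no boundary sample is counted twice. Each
post-application window starts `transition_exclusion_s` (default 60 s)
after the application: while a blocker takes effect the network
desynchronizes gradually, and including that mixed epoch inflates the
measured post-application GSI (the transition-inflation property is
exercised in the tests). The default of 60 s takes the conservative end of
the 30–60 s over which synchrony is typically lost after a blocker.
Windows shorter than 10 samples after exclusion are rejected.

## Frequency analysis

The periodogram follows the classic (Schuster) convention at Fourier
frequencies f_k = k/(N·Δt): psd_k = |Σ_t x_t e^(−2πi f_k t Δt)|²/N on the
detrended series, k = 1..⌊N/2⌋, no taper, no zero-padding. Detrending
defaults to mean removal; linear detrend is recommended for bleached raw
fluorescence. The dominant frequency is the in-band argmax with exact ties
broken toward the lower frequency (deterministic); the default band
(0.05 Hz, Nyquist) excludes DC and slow drift while keeping a 0.2 Hz
signal far from both edges. Per-experiment averaging is pointwise in
power across wells sharing a frequency grid, with the dominant frequency
recomputed on the mean spectrum. The frequency resolution is one Fourier
bin, 1/(window length); with the default protocol (240 s post-trigger
window) that is ≈ 0.0042 Hz.

## Event detection and classification (voltage)

Candidate events are local maxima with prominence at least the detection
floor (default 2 mV — below the smallest expected 3 mV spikelets' range
but above instrument noise) and separation ≥ 10 ms. Amplitude is measured
from the median of the preceding 100 ms, not from absolute voltage,
because resting potential varies between cells; the median is robust to
the brief rising phase. Classification is a pure threshold: amplitude
< 30 mV → spikelet, ≥ 30 mV → spike (the boundary goes to spike because
spikelets are defined strictly below 30 mV). A cell counts as *active* if
it has at least one spike in the window; spikelet prevalence (cells with
≥ 1 spikelet) is reported alongside.

## Expression normalization

Pre-filtering removes samples with library size < 0.2 million reads or
mean count per gene < 1.5. Comparisons are strict, so equality survives;
"mean count per gene" averages over all rows of the table (not only
detected genes) — the plausible alternative reading is noted here and the
implemented one is asserted in tests. CPM divides each column by its sum
and multiplies by 10⁶, so retained columns sum to exactly one million.
The gene-set day matrix is log2 of the *mean* CPM per day
(log2-of-mean, matching heatmap conventions, not mean-of-log2); a zero
mean maps to a −∞ sentinel unless a pseudocount (configurable, e.g. 1) is
supplied, keeping the zero-handling choice visible.

## Group statistics

Welch's t (unequal-variance, Welch–Satterthwaite df), Wilcoxon rank sum
(as the equivalent Mann-Whitney U, exact p for small tie-free samples),
and paired t, all two-sided. No multiple-testing correction is applied by
default; raw p-values are reported. A summary-statistic Welch test
(mean, SEM, n per group) supports published summaries where raw values
are unavailable. Tests verify the Welch p against direct numerical
integration of the t density and the exact rank-sum p against complete
enumeration of rank assignments.

## The synthetic-data generator

The simulator exists so that every analysis can be exercised against
known ground truth at realistic signal scales; its defaults *are* the
study conditions the analyses assume.

**Model.** N all-to-all coupled phase oscillators (Kuramoto):

    dθ_i = [ω_i + (K/N) Σ_j sin(θ_j − θ_i)] dt + σ dW_i

Cells are silent before the trigger (baseline + noise only). The trigger
resets all phases to zero — a plate-wide common stimulus — after which
phases evolve with coupling K between trigger and blocker. The blocker
sets K = 0 **and** re-draws the intrinsic frequencies, so cells stay
rhythmically active but drift apart, matching the observed phenomenology
(individual activity persists, coordination does not). Each upward 2π
crossing emits one calcium transient: a causal double-exponential
indicator kernel (rise 0.3 s, decay 1.5 s) with log-normal amplitude
(mean 1, CV 0.1), added to an exponentially bleaching baseline
(1e-4 s⁻¹) plus Gaussian observation noise (SD 0.02).

**Defaults and why.** 10 cells (the standard ROI count per well), 900 s at
5 Hz (ample for a 0.2 Hz signal; acquisition rates were chosen, not
measured, and 5 Hz comfortably satisfies Nyquist), f0 = 0.2 Hz with
0.02 Hz between-cell spread, coupling 2 rad/s (an order of magnitude above
the frequency-dispersion scale 2π·f_sd ≈ 0.13 rad/s, so the default
network locks), phase noise 0.1 rad/√s, trigger at 150 s.

**Numerical choices.**

- *Frequency semantics:* `f0_hz` is the **well's** mean intrinsic
  frequency: each well's frequency draws are centered so their sample mean
  is exactly f0, with `f_sd_hz` the between-cell dispersion. A locked
  Kuramoto network rotates at the mean intrinsic frequency, so this makes
  the network frequency of a simulated well equal its configured value
  (up to phase-noise wander) rather than varying by f_sd/√N between
  wells.
- *Integration:* Euler–Maruyama with substeps chosen so K·Δt ≤ 0.05; at
  the raw 0.2 s sample step, strong coupling (K ≥ 5) would be numerically
  unstable and relative phases would be spuriously undamped.
- *Transient placement:* transients are placed at the exact interpolated
  phase-crossing time and the kernel is evaluated with fractional offset,
  so sub-sample timing differences between coupled cells survive into the
  traces instead of being quantized to the sample grid.
- *Seeding:* one global seed spawns independent per-component generators
  (frequencies, phase noise, amplitudes, observation noise, post-blocker
  re-draw), so changing one component's use of randomness does not perturb
  the others; identical config + seed is bit-identical.

**Voltage simulator.** Poisson spikes per cell (default 0.5 Hz, 50 ms
refractory); while coupling is on, each neighbor spike is transmitted as a
spikelet (uniform amplitude within 3–25 mV, 2 ms delay) with a thinning
probability set so the per-cell spikelet rate is about `spikelet_rate_hz`.
After a blocker, spikelets cease and exactly
round(`post_blocker_active_fraction` · N) cells retain spikes. Events are
1 ms Gaussian bumps on a −60 mV resting potential with 0.3 mV noise —
amplitudes, not waveforms, are the object of study.

**Counts simulator.** Negative-binomial counts (dispersion 0.3; 0 means
deterministic rounded expectations) around library-size-scaled relative
expression; the embedded connexin gene set carries a multiplicative decay
(default 0.6 per day step) across differentiation days, and a configurable
number of samples receives sub-0.2-million library sizes to exercise the
pre-filter.

**What the simulator does *not* emulate** — and hence what passing tests
do not show about real data: no spatial structure or wave propagation (the
coupling graph is all-to-all, not distance-dependent), no indicator
saturation or photon shot noise (noise is additive Gaussian), no slow
rundown of oscillation amplitude, no pacemaker heterogeneity, no
correlated motion artifacts, and no biophysical (conductance-based)
membrane dynamics. Validation against the simulator establishes that the
statistics measure what they claim under the stated generative model, not
that the model captures every property of real recordings.

## Problem sizes

The test suite and the acceptance script run simulations at the protocol
scale stated above (10 cells, 900 s at 5 Hz, 100 surrogates), with
reduced-duration variants (300–600 s) for unit tests where the full
protocol adds nothing; means over seeds use 9–20 recordings as stated per
test. The full suite completes in a couple of minutes on one CPU.

## Known limitations

- The surrogate null is conservative for strictly periodic signals (see
  above); comparisons across conditions with very different regularity
  should use the same surrogate method and window length.
- The exact surrogate scheme and threshold of the original in-house
  implementations of this index family are not published; the choices
  here (circular shift, S = 100, K = 3) are this package's own, stated
  defaults, and all are configurable.
- Whether well-average analyses should run on raw fluorescence or ΔF/F₀
  is a user choice; both are supported and the result objects record
  which was used (the index is invariant to per-trace affine rescaling,
  so the choice matters only through detrending interactions).
- The ImageJ multi-measure dialect needs an explicit sampling rate; no
  other vendor-native export formats are parsed.
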