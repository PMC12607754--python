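import numpy as np
import pytest

from oscsync import (
    AnalysisError,
    ProtocolEvents,
    SimulationConfig,
    Trace,
    TraceSet,
    ValidationError,
    correlation_matrix,
    gsi,
    gsi_pre_post,
    segment_windows,
    simulate_network_traces,
    surrogate_null,
)
from conftest import sinusoid_trace, white_noise_set


def power_iteration_lambda_max(C, iters=10000, tol=1e-14):
    """Independent largest-eigenvalue oracle (C is PSD, so the dominant
    eigenvalue in magnitude is the largest one)."""
    rng = np.random.default_rng(0)
    v = rng.normal(size=C.shape[0])
    v /= np.linalg.norm(v)
    lam = 0.0
    for _ in range(iters):
        w = C @ v
        lam_new = float(v @ w)
        v = w / np.linalg.norm(w)
        if abs(lam_new - lam) < tol:
            break
        lam = lam_new
    return lam


class TestCorrelationMatrix:
    def test_identical_traces_give_all_ones(self, identical_sinusoids):
        C = correlation_matrix(identical_sinusoids).C
        np.testing.assert_allclose(C, 1.0, atol=1e-12)

    def test_negated_trace_gives_minus_one(self):
        tr = sinusoid_trace(0.2, 100.0)
        neg = Trace(tr.time_s, -tr.values, "neg")
        C = correlation_matrix(TraceSet((tr, neg))).C
        assert C[0, 1] == pytest.approx(-1.0)

    def test_strong_coupling_high_mean_correlation(self):
        cfg = SimulationConfig(seed=2, coupling=10.0, phase_noise_sd=0.05)
        ts, _ = simulate_network_traces(cfg)
        w = segment_windows(ts, ProtocolEvents())["post_trigger"]
        C = correlation_matrix(ts, w).C
        off = C[~np.eye(ts.M, dtype=bool)]
        assert off.mean() > 0.9

    def test_zero_variance_trace_named(self):
        t = np.arange(100) / 5.0
        good = Trace(t, np.sin(t), "good")
        dead = Trace(t, np.full(100, 7.0), "deadroi")
        with pytest.raises(AnalysisError, match="deadroi"):
            correlation_matrix(TraceSet((good, dead)))

    def test_eigensolver_matches_power_iteration(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            m = rng.integers(3, 13)
            X = rng.normal(size=(m, 50))
            C = np.corrcoef(X)
            assert np.linalg.eigvalsh(C)[-1] == pytest.approx(
                power_iteration_lambda_max(C), abs=1e-8)


class TestSurrogateNull:
    def test_shifted_identical_sinusoids_below_m(self, identical_sinusoids):
        null = surrogate_null(identical_sinusoids, S=50, seed=0)
        assert np.all(null.lambda_max_samples < identical_sinusoids.M)

    def test_white_noise_null_near_one(self, noise_set):
        null = surrogate_null(noise_set, S=100, seed=1)
        assert 1.0 <= null.mu_prime <= 2.0

    def test_seed_reproducibility(self, noise_set):
        a = surrogate_null(noise_set, S=20, seed=3)
        b = surrogate_null(noise_set, S=20, seed=3)
        np.testing.assert_array_equal(a.lambda_max_samples, b.lambda_max_samples)

    def test_too_few_surrogates_rejected(self, noise_set):
        with pytest.raises(ValidationError):
            surrogate_null(noise_set, S=1)

    def test_short_window_warns(self):
        ts = white_noise_set(0, m=10, n=60)
        with pytest.warns(UserWarning, match="samples"):
            surrogate_null(ts, S=2, seed=0)


class TestGsi:
    def test_identical_copies_give_exactly_one(self, identical_sinusoids):
        for seed in (0, 1, 12345):
            res = gsi(identical_sinusoids, S=20, seed=seed)
            assert res.gsi == 1.0
            assert res.lambda_max == pytest.approx(10.0, abs=1e-9)

    def test_independent_noise_gives_zero(self, noise_set):
        res = gsi(noise_set, S=100, seed=7)
        assert res.gsi == 0.0

    def test_half_synchronized_matches_oracle(self):
        base = sinusoid_trace(0.2, 600.0)
        rng = np.random.default_rng(9)
        traces = [Trace(base.time_s, base.values, f"s{i}") for i in range(5)]
        traces += [Trace(base.time_s, rng.standard_normal(base.n), f"n{i}")
                   for i in range(5)]
        ts = TraceSet(tuple(traces))
        # permutation surrogates: the periodic structure would otherwise let
        # circularly shifted sinusoids re-align and raise the null
        res = gsi(ts, S=100, seed=9, method="permutation")
        assert res.lambda_max == pytest.approx(5.0, abs=0.3)
        # the eigenvalue feeding the index matches the independent oracle
        assert res.lambda_max == pytest.approx(
            power_iteration_lambda_max(res.correlation.C), abs=1e-8)
        assert res.lambda_max > res.null.threshold(3.0)
        expected = (res.lambda_max - res.null.mu_prime) / (10 - res.null.mu_prime)
        assert res.gsi == pytest.approx(np.clip(expected, 0, 1))

    def test_single_trace_rejected(self):
        tr = sinusoid_trace(0.2, 100.0)
        with pytest.raises(ValidationError):
            gsi(TraceSet((tr,)))

    def test_affine_rescaling_invariance(self, noise_set):
        res_a = gsi(noise_set, S=30, seed=4)
        rescaled = TraceSet(tuple(
            Trace(tr.time_s, (i + 1) * 2.5 * tr.values + 10 * i, tr.label)
            for i, tr in enumerate(noise_set.traces)
        ))
        res_b = gsi(rescaled, S=30, seed=4)
        assert res_a.gsi == pytest.approx(res_b.gsi, abs=1e-9)
        assert res_a.lambda_max == pytest.approx(res_b.lambda_max, abs=1e-9)

    def test_coupling_monotonicity(self):
        means = []
        for coupling in (0.0, 0.5, 1.0, 2.0, 5.0):
            vals = []
            for seed in range(20):
                cfg = SimulationConfig(seed=seed, coupling=coupling,
                                       duration_s=450.0)
                ts, _ = simulate_network_traces(cfg)
                ev = ProtocolEvents(applications=((150.0, "trigger"),))
                w = segment_windows(ts, ev)["post_trigger"]
                vals.append(gsi(ts, w, S=50, seed=seed).gsi)
            means.append(np.mean(vals))
        diffs = np.diff(means)
        assert np.all(diffs >= -0.05)  # Monte-Carlo slack on 20 seeds
        assert means[-1] > means[0] + 0.5


class TestGsiPrePost:
    def test_blocker_desynchronizes(self, blocker_events):
        cfg = SimulationConfig(seed=5, blocker_time_s=450.0)
        ts, _ = simulate_network_traces(cfg)
        pre, post, delta = gsi_pre_post(ts, blocker_events, "blocker", seed=5)
        assert pre.gsi >= 0.8
        assert post.gsi <= 0.1
        assert delta == pytest.approx(pre.gsi - post.gsi)

    def test_stationary_without_blocker(self):
        cfg = SimulationConfig(seed=6)
        ts, _ = simulate_network_traces(cfg)
        ev = ProtocolEvents()
        pre, post, _ = gsi_pre_post(ts, ev, "compound", seed=6)
        assert abs(pre.gsi - post.gsi) <= 0.1

    def test_transition_inflates_gsi(self, blocker_events):
        cfg = SimulationConfig(seed=8, blocker_time_s=450.0)
        ts, _ = simulate_network_traces(cfg)
        excl = segment_windows(ts, blocker_events)["post_blocker"]
        ev0 = ProtocolEvents(applications=blocker_events.applications,
                             transition_exclusion_s=0.0)
        incl = segment_windows(ts, ev0)["post_blocker"]
        g_incl = gsi(ts, incl, seed=8).gsi
        g_excl = gsi(ts, excl, seed=8).gsi
        assert g_incl >= g_excl

    def test_missing_application_label(self, blocker_events):
        cfg = SimulationConfig(seed=1, blocker_time_s=450.0)
        ts, _ = simulate_network_traces(cfg)
        with pytest.raises(ValidationError, match="cbx"):
            gsi_pre_post(ts, blocker_events, "cbx")
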