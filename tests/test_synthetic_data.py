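import numpy as np
import pytest

from oscsync import (
    GAP_JUNCTION_GENES,
    EventClass,
    ProtocolEvents,
    SimulationConfig,
    ValidationError,
    VoltageSimConfig,
    cpm,
    correlation_matrix,
    geneset_day_matrix,
    segment_windows,
    simulate_counts,
    simulate_network_traces,
    simulate_voltage_traces,
)
from oscsync.synthetic_data import save_network_simulation
from oscsync.trace_io import read_trace_table


class TestSimulationConfigValidation:
    @pytest.mark.parametrize(
        "kwargs, field",
        [
            (dict(n_cells=0), "n_cells"),
            (dict(fs_hz=0.3), "fs_hz"),
            (dict(coupling=-1.0), "coupling"),
            (dict(trigger_time_s=1000.0), "trigger_time_s"),
            (dict(blocker_time_s=100.0), "blocker_time_s"),
            (dict(obs_noise_sd=-0.1), "obs_noise_sd"),
        ],
    )
    def test_invalid_config_names_field(self, kwargs, field):
        with pytest.raises(ValidationError, match=field):
            SimulationConfig(**kwargs)


class TestNetworkSimulation:
    def test_deterministic_for_identical_seed(self):
        cfg = SimulationConfig(seed=13, duration_s=300.0)
        ts_a, tr_a = simulate_network_traces(cfg)
        ts_b, tr_b = simulate_network_traces(cfg)
        for a, b in zip(ts_a.traces, ts_b.traces):
            np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_array_equal(tr_a.phase_trajectories,
                                      tr_b.phase_trajectories)

    def test_silent_before_trigger(self):
        ts, _ = simulate_network_traces(SimulationConfig(seed=2, duration_s=300.0))
        pre = ts.values()[:, : int(150 * 5)]
        assert np.all(pre.var(axis=1) <= 0.02 ** 2 * 4)

    def test_no_spikes_before_trigger(self):
        _, truth = simulate_network_traces(SimulationConfig(seed=3, duration_s=300.0))
        for st in truth.spike_times:
            assert np.all(st >= 150.0)
            assert np.all(np.diff(st) > 0)

    def test_phase_locked_limit_identical_traces(self):
        cfg = SimulationConfig(seed=0, duration_s=300.0, coupling=50.0,
                               phase_noise_sd=0.0, f_sd_hz=0.0, amp_cv=0.0,
                               obs_noise_sd=0.0)
        ts, _ = simulate_network_traces(cfg)
        ref = ts.traces[0].values
        for tr in ts.traces[1:]:
            np.testing.assert_array_equal(tr.values, ref)

    def test_uncoupled_traces_decorrelate(self):
        offdiags = []
        for seed in range(20):
            cfg = SimulationConfig(seed=seed, coupling=0.0, f_sd_hz=0.05,
                                   duration_s=450.0)
            ts, _ = simulate_network_traces(cfg)
            ev = ProtocolEvents(applications=((150.0, "trigger"),))
            w = segment_windows(ts, ev)["post_trigger"]
            C = correlation_matrix(ts, w).C
            offdiags.append(np.abs(C[~np.eye(ts.M, dtype=bool)]).mean())
        assert np.mean(offdiags) < 0.2

    def test_transient_onsets_match_spike_times(self):
        cfg = SimulationConfig(seed=4, duration_s=300.0, obs_noise_sd=0.0,
                               bleach_rate_per_s=0.0)
        ts, truth = simulate_network_traces(cfg)
        dt = 1.0 / cfg.fs_hz
        for tr, spikes in zip(ts.traces, truth.spike_times):
            sig = tr.values - cfg.baseline_f0
            for s in spikes:
                k = int(np.ceil(s / dt))
                if k + 1 >= tr.n:
                    continue
                # the trace starts rising within one sample of the event
                assert sig[min(k + 1, tr.n - 1)] > sig[k - 1] - 1e-9

    def test_coupled_flag_respects_blocker(self):
        cfg = SimulationConfig(seed=1, duration_s=600.0, blocker_time_s=450.0)
        ts, truth = simulate_network_traces(cfg)
        t = ts.time_s
        assert not truth.coupled[t < 150.0].any()
        assert truth.coupled[(t >= 150.0) & (t < 450.0)].all()
        assert not truth.coupled[t >= 450.0].any()
        assert truth.post_blocker_freqs is not None

    def test_save_round_trip(self, tmp_path):
        ts, truth = simulate_network_traces(SimulationConfig(seed=6, duration_s=120.0,
                                                             trigger_time_s=30.0))
        paths = save_network_simulation(ts, truth, tmp_path)
        back = read_trace_table(paths["traces"])
        assert back.M == ts.M
        np.testing.assert_allclose(back.values(), ts.values(), rtol=1e-9)


class TestVoltageSimulation:
    def test_spikelet_amplitudes_below_30(self):
        cfg = VoltageSimConfig(n_cells=8, duration_s=30.0, seed=1)
        _, truth = simulate_voltage_traces(cfg)
        lets = [e for cell in truth for e in cell if e.cls is EventClass.SPIKELET]
        assert lets
        assert all(e.amplitude_mv < 30.0 for e in lets)

    def test_post_blocker_active_cell_count(self):
        cfg = VoltageSimConfig(n_cells=12, duration_s=40.0, blocker_time_s=20.0,
                               post_blocker_active_fraction=0.25, seed=2)
        _, truth = simulate_voltage_traces(cfg)
        active = sum(
            any(e.cls is EventClass.SPIKE and e.time_s >= 20.0 for e in cell)
            for cell in truth
        )
        assert active == 3

    def test_no_spikelets_without_coupling(self):
        cfg = VoltageSimConfig(n_cells=8, duration_s=30.0, coupling_enabled=False,
                               seed=3)
        _, truth = simulate_voltage_traces(cfg)
        assert not any(e.cls is EventClass.SPIKELET for cell in truth for e in cell)

    def test_spikelets_stop_at_blocker(self):
        cfg = VoltageSimConfig(n_cells=10, duration_s=40.0, blocker_time_s=20.0,
                               seed=4)
        _, truth = simulate_voltage_traces(cfg)
        lets = [e.time_s for cell in truth for e in cell
                if e.cls is EventClass.SPIKELET]
        assert lets and max(lets) < 20.0

    def test_deterministic(self):
        cfg = VoltageSimConfig(n_cells=5, duration_s=20.0, seed=9)
        tr_a, ev_a = simulate_voltage_traces(cfg)
        tr_b, ev_b = simulate_voltage_traces(cfg)
        for a, b in zip(tr_a, tr_b):
            np.testing.assert_array_equal(a.values, b.values)
        assert ev_a == ev_b

    def test_spikelet_range_upper_bound_enforced(self):
        with pytest.raises(ValidationError, match="spikelet"):
            VoltageSimConfig(spikelet_amp_range_mv=(3.0, 35.0))


class TestCountsSimulation:
    def test_deterministic(self):
        a = simulate_counts(50, 2, ["d0", "d4"], seed=11)
        b = simulate_counts(50, 2, ["d0", "d4"], seed=11)
        assert a.counts.equals(b.counts)
        assert a.sample_meta.equals(b.sample_meta)

    def test_gap_junction_decay_noiseless(self):
        cm = simulate_counts(60, 3, ["d0", "d2", "d6", "d9"], seed=1,
                             dispersion=0.0)
        mat = geneset_day_matrix(cpm(cm), list(GAP_JUNCTION_GENES)).values
        diffs = mat.to_numpy()[:, 1:] - mat.to_numpy()[:, :-1]
        assert (diffs < 0).all()

    def test_low_depth_sample_count_exact(self):
        cm = simulate_counts(100, 4, ["d0", "d9"], seed=2, n_low_depth=3)
        assert int((cm.library_sizes() < 200_000).sum()) == 3

    def test_empty_day_list_rejected(self):
        with pytest.raises(ValidationError, match="day"):
            simulate_counts(50, 2, [], seed=0)

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValidationError, match="n_genes"):
            simulate_counts(3, 2, ["d0"], seed=0)
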