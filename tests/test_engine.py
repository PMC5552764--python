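"""Engine behavior: delivery bookkeeping, determinism, averaging semantics."""

from dataclasses import replace

import numpy as np
import pytest

from lgnsim import (
    NetworkConfig,
    PeriodicStimulus,
    PopulationSpec,
    build_lgn,
    model_output,
    periodic_train,
    run_trial,
    run_trials,
    tonic_demo,
)


def _unconnected_config(base_config, i_dc=0.0):
    pops = {
        role: PopulationSpec(role=role, size=spec.size,
                             params=None if spec.params is None
                             else spec.params.with_bias(i_dc))
        for role, spec in base_config.populations.items()
    }
    return replace(base_config, populations=pops, projections={})


class TestRunTrial:
    def test_silent_at_rest(self, base_config):
        """No edges, no stimulus, zero bias: the network stays subthreshold."""
        net = build_lgn(_unconnected_config(base_config), seed=0)
        tr = run_trial(net, None, duration=1000.0)
        assert all(len(ev) == 0 for ev in tr.spikes.values())
        # every membrane trace settles near the (-70, -14)-type fixed points
        assert all(np.all(mat <= 30.0) for mat in tr.v.values())

    def test_reduces_to_tonic_demo(self, base_config):
        """With connectivity removed and constant bias the engine reproduces
        the per-neuron reference integrator exactly."""
        net = build_lgn(_unconnected_config(base_config, i_dc=5.0), seed=0)
        tr = run_trial(net, None, duration=500.0)
        reference = tonic_demo(i_dc=5.0, duration=500.0, n_per_population=1)
        for pop in ("TCR", "IN", "TRN"):
            ref_times = reference[pop][0]
            for neuron in range(net.populations[pop].size):
                ev = tr.spikes[pop]
                times = np.sort(ev.times[ev.channels == neuron])
                np.testing.assert_allclose(times, ref_times, atol=1e-9)

    def test_spike_conservation(self, base_config):
        """Arrivals delivered == sum over emitted spikes (and stimulus
        events) of the emitter's out-degree, counting only deliveries that
        fall inside the simulated window."""
        duration, dt = 1000.0, 0.1
        n_steps = int(duration / dt)
        net = build_lgn(base_config, seed=2)
        stim = periodic_train(20.0, duration, 144)
        tr = run_trial(net, stim, duration=duration)

        epre, epost, ew, edly, einh = net.neuron_edge_arrays()
        expected = 0
        for pop in net.populations.values():
            ev = tr.spikes[pop.name]
            steps = np.round(ev.times / dt).astype(int) - 1
            for neuron, step in zip(ev.channels + pop.start, steps):
                m = epre == neuron
                expected += int(np.sum(step + edly[m] < n_steps))
        schan, spost, sw, sdly = net.stimulus_edge_arrays()
        sim_steps = np.round(stim.times / dt).astype(int)
        for ch, step in zip(stim.channels, sim_steps):
            m = schan == ch
            expected += int(np.sum(step + sdly[m] < n_steps))
        assert tr.n_deliveries == expected

    def test_bit_exact_reproducibility(self, base_config):
        net = build_lgn(base_config, seed=4)
        stim = periodic_train(40.0, 800.0, 144)
        t1 = run_trial(net, stim, duration=800.0)
        t2 = run_trial(net, stim, duration=800.0)
        for pop in t1.v:
            np.testing.assert_array_equal(t1.v[pop], t2.v[pop])
            np.testing.assert_array_equal(t1.spikes[pop].times, t2.spikes[pop].times)

    def test_time_translation(self, base_config):
        """Starting from the network's resting fixed point, delaying the
        stimulus by delta shifts all output spikes by exactly delta."""
        pops = {
            role: spec if spec.params is None else PopulationSpec(
                role=role, size=spec.size,
                params=replace(spec.params, v_init=-70.0, u_init=-14.0),
            )
            for role, spec in base_config.populations.items()
        }
        cfg = replace(base_config, populations=pops)
        net = build_lgn(cfg, seed=6)
        delta = 50.0
        stim = periodic_train(40.0, 300.0, 144)
        t0 = run_trial(net, stim, duration=400.0)
        t1 = run_trial(net, stim.shifted(delta), duration=400.0 + delta)
        for pop in t0.spikes:
            a = np.sort(t0.spikes[pop].times)
            b = np.sort(t1.spikes[pop].times)
            np.testing.assert_allclose(b, a + delta, atol=1e-9)

    def test_recorded_v_clamped(self, base_config):
        net = build_lgn(base_config, seed=1)
        stim = periodic_train(20.0, 500.0, 144)
        tr = run_trial(net, stim, duration=500.0)
        assert max(mat.max() for mat in tr.v.values()) <= 30.0

    def test_dt_mismatch_rejected(self, base_config):
        net = build_lgn(base_config, seed=0)
        with pytest.raises(ValueError, match="dt"):
            run_trial(net, None, duration=100.0, dt=0.2)

    def test_stimulus_channel_mismatch_rejected(self, base_config):
        net = build_lgn(base_config, seed=0)
        stim = periodic_train(20.0, 100.0, n_channels=10)
        with pytest.raises(ValueError, match="channels"):
            run_trial(net, stim, duration=100.0)

    def test_hdf5_roundtrip(self, base_config, tmp_path):
        net = build_lgn(base_config, seed=0)
        tr = run_trial(net, periodic_train(20.0, 200.0, 144), duration=200.0, seed=3)
        p = tmp_path / "trial.h5"
        tr.save_hdf5(p)
        from lgnsim.engine import TrialResult

        back = TrialResult.load_hdf5(p)
        assert back.seed == 3
        for pop in tr.v:
            np.testing.assert_array_equal(back.v[pop], tr.v[pop])


class TestRunTrials:
    def test_single_trial_average_is_identity(self, base_config):
        avg = run_trials(base_config, PeriodicStimulus(20.0), n_trials=1,
                         base_seed=0, duration=600.0)
        net = build_lgn(base_config, seed=0)
        tr = run_trial(net, PeriodicStimulus(20.0).realize(600.0, seed=0),
                       duration=600.0)
        np.testing.assert_allclose(avg.mean["TCR"], tr.population_mean("TCR"))

    def test_frozen_wiring_deterministic_stimulus(self, base_config):
        """With wiring frozen and a deterministic stimulus every trial mean
        is identical and the average equals any one of them."""
        avg = run_trials(base_config, PeriodicStimulus(20.0), n_trials=3,
                         base_seed=5, duration=600.0, redraw_wiring=False)
        pt = avg.per_trial["TCR"]
        np.testing.assert_array_equal(pt[0], pt[1])
        np.testing.assert_array_equal(pt[0], pt[2])
        np.testing.assert_allclose(avg.mean["TCR"], pt[0])

    def test_average_is_mean_of_trial_means(self, base_config):
        avg = run_trials(base_config, PeriodicStimulus(30.0), n_trials=3,
                         base_seed=0, duration=600.0)
        np.testing.assert_allclose(avg.mean["IN"], avg.per_trial["IN"].mean(axis=0))


class TestModelOutput:
    def test_single_node_passthrough(self, base_config):
        avg = run_trials(base_config, PeriodicStimulus(20.0), n_trials=1,
                         base_seed=0, duration=600.0)
        np.testing.assert_array_equal(model_output(avg), avg.mean["TCR"])

    def test_multi_node_mean(self, base_config):
        cfg = replace(base_config, node_count=3)
        avg = run_trials(cfg, PeriodicStimulus(20.0), n_trials=1,
                         base_seed=0, duration=600.0)
        expected = (avg.mean["TCR1"] + avg.mean["TCR2"] + avg.mean["TCR3"]) / 3.0
        np.testing.assert_allclose(model_output(avg), expected)

    def test_missing_tcr_rejected(self):
        from lgnsim.engine import AveragedTrace

        trace = AveragedTrace(dt=0.1, duration=100.0, n_trials=1,
                              mean={"TRN": np.zeros(10)})
        with pytest.raises(ValueError, match="TCR"):
            model_output(trace)
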