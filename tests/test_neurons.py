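"""Single-neuron dynamics: integration accuracy, reset rule, synapse kinetics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from numba import njit

from lgnsim import (
    IntegrationBlowupError,
    IzhikevichParams,
    NeuronState,
    SynapseKinetics,
    decay_and_inject,
    step_neuron,
    tonic_demo,
    tonic_presets,
)


@njit(cache=False)
def _euler_oracle(a, b, c, d, v0, u0, i_const, duration, dt):
    """Independent fine-step forward-Euler integration (reference trajectory)."""
    n_steps = int(round(duration / dt))
    v, u = v0, u0
    spikes = []
    for k in range(n_steps):
        dv = 0.04 * v * v + 5.0 * v + 140.0 - u + i_const
        du = a * (b * v - u)
        v += dt * dv
        u += dt * du
        if v > 30.0:
            v = c
            u += d
            spikes.append((k + 1) * dt)
    return v, u, spikes


def _rk2_spike_times(params, i_dc, duration, dt=0.1):
    from lgnsim.neurons import simulate_single

    _, _, spikes = simulate_single(params, duration, dt=dt, i_dc=i_dc)
    return spikes


class TestIzhikevichStep:
    def test_table_presets(self):
        presets = tonic_presets()
        expected = {
            "TCR": (0.02, 0.2, -65, 6, -65, -13),
            "IN": (0.1, 0.2, -65, 6, -70, -14),
            "TRN": (0.02, 0.2, -65, 6, -75, -15),
        }
        for name, (a, b, c, d, vi, ui) in expected.items():
            p = presets[name]
            assert (p.a, p.b, p.c, p.d, p.v_init, p.u_init) == (a, b, c, d, vi, ui)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            IzhikevichParams(a=0.0, b=0.2, c=-65, d=6, v_init=-65, u_init=-13)
        with pytest.raises(ValueError):
            IzhikevichParams(a=0.02, b=0.2, c=35, d=6, v_init=-65, u_init=-13)

    def test_reset_exactness(self, tcr_params):
        """After a threshold crossing v equals c exactly and u gains exactly d."""
        state = NeuronState.from_params(tcr_params)
        state.v[:] = 29.5
        state.g_e[:] = 50.0  # strong drive forces a crossing this step
        # independent midpoint arithmetic for the expected pre-reset state
        p, dt = tcr_params, 0.1
        i_tot = 50.0
        v, u = 29.5, p.u_init
        dv1 = 0.04 * v * v + 5 * v + 140 - u + i_tot
        du1 = p.a * (p.b * v - u)
        vm, um = v + 0.05 * dv1, u + 0.05 * du1
        dv2 = 0.04 * vm * vm + 5 * vm + 140 - um + i_tot
        du2 = p.a * (p.b * vm - um)
        vn, un = v + dt * dv2, u + dt * du2
        assert vn > 30.0

        state, spiked = step_neuron(state, p, dt)
        assert spiked[0]
        assert state.v[0] == p.c
        assert state.u[0] == un + p.d

    def test_subthreshold_rest(self, tcr_params):
        """From (v=-65, u=-13) with no input the neuron never spikes and
        settles at the (-70, -14) fixed point."""
        v, u, spikes = _euler_oracle(
            tcr_params.a, tcr_params.b, tcr_params.c, tcr_params.d,
            -65.0, -13.0, 0.0, 1000.0, 0.0001,
        )
        assert len(spikes) == 0
        assert v == pytest.approx(-70.0, abs=0.05)

        rk2 = _rk2_spike_times(tcr_params, i_dc=0.0, duration=1000.0)
        assert rk2.size == 0

    @pytest.mark.parametrize("pop", ["TCR", "IN", "TRN"])
    def test_rk2_matches_fine_euler(self, pop):
        """Tonic spike trains from the dt=0.1 ms midpoint integrator agree
        with a 0.1 us forward-Euler reference: counts within 1, first spike
        within 1 ms, and every interspike interval within 1 ms (the
        per-cycle threshold quantization at dt=0.1 ms accumulates a small
        systematic phase lag, so absolute times drift while the firing
        pattern itself must not)."""
        p = tonic_presets()[pop]
        _, _, euler = _euler_oracle(p.a, p.b, p.c, p.d, p.v_init, p.u_init,
                                    5.0, 1000.0, 0.0001)
        euler = np.asarray(euler)
        rk2 = _rk2_spike_times(p, i_dc=5.0, duration=1000.0)
        assert abs(len(euler) - len(rk2)) <= 1
        n = min(len(euler), len(rk2))
        assert abs(euler[0] - rk2[0]) <= 1.0
        assert np.all(np.abs(np.diff(euler[:n]) - np.diff(rk2[:n])) <= 1.0)

    def test_blowup_reported(self, tcr_params):
        state = NeuronState.from_params(tcr_params)
        state.v[:] = 1e200
        with pytest.raises(IntegrationBlowupError, match="neuron"):
            step_neuron(state, tcr_params, 0.1)


class TestSynapse:
    def test_immediate_injection(self, tcr_params):
        state = NeuronState.from_params(tcr_params)
        decay_and_inject(state, SynapseKinetics(), 0.0001, arrivals_e=5.0)
        assert state.g_e[0] == pytest.approx(5.0, rel=1e-4)

    def test_decay_to_w_over_e(self, tcr_params):
        kin = SynapseKinetics(tau_e=2.0)
        state = NeuronState.from_params(tcr_params)
        state.g_e[:] = 7.0
        decay_and_inject(state, kin, 2.0)
        assert state.g_e[0] == pytest.approx(7.0 / np.e, rel=1e-9)

    def test_two_arrival_superposition(self, tcr_params):
        """w=2 at t=0 and t=tau: accumulator just after the second arrival is
        2/e + 2 (closed-form superposition)."""
        kin = SynapseKinetics(tau_e=2.0)
        state = NeuronState.from_params(tcr_params)
        state.g_e[:] = 2.0  # arrival at t=0
        decay_and_inject(state, kin, 2.0, arrivals_e=2.0)
        assert state.g_e[0] == pytest.approx(2.0 / np.e + 2.0, rel=1e-12)

    def test_negative_arrivals_rejected(self, tcr_params):
        state = NeuronState.from_params(tcr_params)
        with pytest.raises(ValueError):
            decay_and_inject(state, SynapseKinetics(), 0.1, arrivals_e=-1.0)

    @given(
        weights=st.lists(st.floats(0.0, 10.0), min_size=1, max_size=8),
        steps=st.lists(st.integers(0, 50), min_size=1, max_size=8),
    )
    def test_linearity(self, tcr_params, weights, steps):
        """The accumulator response to a set of arrivals equals the sum of
        single-arrival responses."""
        kin = SynapseKinetics()
        n = min(len(weights), len(steps))
        weights, steps = weights[:n], steps[:n]
        horizon = max(steps) + 5

        def respond(pairs):
            s = NeuronState.from_params(tcr_params)
            for k in range(horizon):
                arr = sum(w for w, at in pairs if at == k)
                decay_and_inject(s, kin, 0.1, arrivals_e=arr)
            return s.g_e[0]

        combined = respond(list(zip(weights, steps)))
        separate = sum(respond([(w, at)]) for w, at in zip(weights, steps))
        assert combined == pytest.approx(separate, rel=1e-9, abs=1e-12)


class TestTonicDemo:
    def test_homogeneity_and_rates(self):
        """All neurons of an unconnected population share identical spike
        trains; the fast-spiking IN outpaces the regular-spiking TCR."""
        rasters = tonic_demo(i_dc=5.0, duration=500.0, n_per_population=3)
        for pop, trains in rasters.items():
            assert len(trains) == 3
            for train in trains[1:]:
                np.testing.assert_array_equal(train, trains[0])
            assert len(trains[0]) > 0
        assert len(rasters["IN"][0]) > len(rasters["TCR"][0])

    def test_rate_monotonic_in_bias(self):
        counts = {
            pop: [] for pop in ("TCR", "IN", "TRN")
        }
        for i_dc in (3.0, 5.0, 7.0):
            rasters = tonic_demo(i_dc=i_dc, duration=500.0, n_per_population=1)
            for pop in counts:
                counts[pop].append(len(rasters[pop][0]))
        for pop, series in counts.items():
            assert series[0] <= series[1] <= series[2], (pop, series)
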