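"""Compiled inner loop of the clock-driven simulator.

One numba-jitted function advances the whole network: per step it (1) delivers
stimulus events due this step into the delay ring buffers, (2) reads the
current ring slot into the synaptic accumulators (exact exponential decay +
injection), (3) advances every neuron one explicit-midpoint step with the
step's total current held constant, and (4) schedules the outgoing arrivals
of neurons that crossed threshold.  Delays are integer step offsets on a ring
buffer of ``max_delay + 1`` slots; arrivals falling beyond the simulation end
are scheduled but never read.

The per-neuron update duplicates :mod:`lgnsim.neurons` arithmetic exactly
(same explicit-midpoint form, same reset rule); tests cross-check the two.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def simulate_core(
    n_steps, dt,
    a, b, c, d, idc,
    v, u, ge, gi,
    decay_e, decay_i,
    eptr, epost, ew, edelay, einh,
    stim_step, stim_chan,
    sptr, spost, sw, sdelay,
    ring_size,
    v_rec,
    spike_neuron, spike_step,
):
    """Advance the network ``n_steps`` steps in place.

    Returns ``(n_spikes, n_deliveries, err)`` where ``err < 0`` encodes a
    non-finite state as ``-(step * n + neuron) - 1`` and 0 means success.
    ``n_deliveries`` counts scheduled arrivals whose delivery step lies
    within the simulation (stimulus and recurrent alike).
    """
    n = v.shape[0]
    buf_e = np.zeros((ring_size, n))
    buf_i = np.zeros((ring_size, n))
    sp = 0
    n_stim = stim_step.shape[0]
    n_spikes = 0
    n_deliv = 0
    cap = spike_neuron.shape[0]

    for t in range(n_steps):
        while sp < n_stim and stim_step[sp] == t:
            ch = stim_chan[sp]
            for k in range(sptr[ch], sptr[ch + 1]):
                slot = (t + sdelay[k]) % ring_size
                buf_e[slot, spost[k]] += sw[k]
                if t + sdelay[k] < n_steps:
                    n_deliv += 1
            sp += 1

        slot = t % ring_size
        for i in range(n):
            ge[i] = ge[i] * decay_e + buf_e[slot, i]
            gi[i] = gi[i] * decay_i + buf_i[slot, i]
            buf_e[slot, i] = 0.0
            buf_i[slot, i] = 0.0

            cur = ge[i] - gi[i] + idc[i]
            vv = v[i]
            uu = u[i]
            dv1 = 0.04 * vv * vv + 5.0 * vv + 140.0 - uu + cur
            du1 = a[i] * (b[i] * vv - uu)
            vm = vv + 0.5 * dt * dv1
            um = uu + 0.5 * dt * du1
            dv2 = 0.04 * vm * vm + 5.0 * vm + 140.0 - um + cur
            du2 = a[i] * (b[i] * vm - um)
            vn = vv + dt * dv2
            un = uu + dt * du2

            if not (np.isfinite(vn) and np.isfinite(un)):
                return n_spikes, n_deliv, -(t * n + i) - 1

            if vn > 30.0:
                v_rec[i, t] = 30.0
                v[i] = c[i]
                u[i] = un + d[i]
                if n_spikes < cap:
                    spike_neuron[n_spikes] = i
                    spike_step[n_spikes] = t
                n_spikes += 1
                for k2 in range(eptr[i], eptr[i + 1]):
                    slot2 = (t + edelay[k2]) % ring_size
                    if einh[k2]:
                        buf_i[slot2, epost[k2]] += ew[k2]
                    else:
                        buf_e[slot2, epost[k2]] += ew[k2]
                    if t + edelay[k2] < n_steps:
                        n_deliv += 1
            else:
                v_rec[i, t] = vn
                v[i] = vn
                u[i] = un

    return n_spikes, n_deliv, 0
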