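"""Izhikevich point neurons and exponential current-based synapses.

The dynamical unit of the network is the two-variable Izhikevich model

    dv/dt = 0.04 v^2 + 5 v + 140 - u + I_psc + I_dc
    du/dt = a (b v - u)
    if v > 30:  v <- c,  u <- u + d

with ``v`` the membrane potential (mV), ``u`` a recovery variable, and the
total post-synaptic current ``I_psc = g_e - g_i`` assembled from exponentially
decaying current accumulators.  Each synaptic arrival of weight ``w`` (nA)
adds ``w`` to the relevant accumulator, which then decays as
``exp(-t / tau_syn)`` — the exact solution of the single-exponential synapse
between events, so decay is applied once per time step before injection.

Integration uses an explicit-midpoint (2nd order Runge-Kutta) step with the
synaptic current held constant over the step.  The spike test is applied
after the full step; on spike steps the recorded potential is clamped at the
30 mV threshold while the state itself is reset to ``c``.

Three tonic-mode parameterizations are shipped (see ``data/izhikevich_tonic.yaml``):
regular spiking (RS) for thalamo-cortical relay (TCR) and reticular (TRN)
cells, fast spiking (FS) for interneurons (IN).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import yaml

SPIKE_THRESHOLD_MV = 30.0


class IntegrationBlowupError(RuntimeError):
    """Raised when a neuron's state becomes non-finite during integration."""


@dataclass(frozen=True)
class IzhikevichParams:
    """Parameters of one Izhikevich neuron (or of a homogeneous population).

    ``a`` sets the recovery time scale, ``b`` the recovery/voltage coupling,
    ``c`` the post-spike reset potential (mV) and ``d`` the post-spike
    recovery increment.  ``v_init``/``u_init`` are the initial conditions and
    ``i_dc`` a constant bias current (nA).  Units follow the original
    Izhikevich convention: v in mV, currents in nA, a/b/c/d unitless.
    """

    a: float
    b: float
    c: float
    d: float
    v_init: float
    u_init: float
    i_dc: float = 0.0

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"a must be positive, got {self.a}")
        if not self.c < SPIKE_THRESHOLD_MV:
            raise ValueError(
                f"reset potential c={self.c} must lie below the spike "
                f"threshold ({SPIKE_THRESHOLD_MV} mV)"
            )

    def with_bias(self, i_dc: float) -> "IzhikevichParams":
        return replace(self, i_dc=i_dc)


@dataclass(frozen=True)
class SynapseKinetics:
    """Decay time constants (ms) of the excitatory/inhibitory accumulators."""

    tau_e: float = 2.0
    tau_i: float = 6.0

    def __post_init__(self) -> None:
        if not (self.tau_e > 0 and self.tau_i > 0):
            raise ValueError("synaptic time constants must be positive")


@dataclass
class NeuronState:
    """Evolving state of one neuron or a vector of neurons.

    ``g_e`` and ``g_i`` store the magnitudes of the excitatory and inhibitory
    current accumulators (both >= 0); the inhibitory sign is applied when the
    total current is assembled.
    """

    v: np.ndarray
    u: np.ndarray
    g_e: np.ndarray
    g_i: np.ndarray

    @classmethod
    def from_params(cls, params: IzhikevichParams, n: int = 1) -> "NeuronState":
        return cls(
            v=np.full(n, params.v_init, dtype=float),
            u=np.full(n, params.u_init, dtype=float),
            g_e=np.zeros(n, dtype=float),
            g_i=np.zeros(n, dtype=float),
        )

    def copy(self) -> "NeuronState":
        return NeuronState(self.v.copy(), self.u.copy(), self.g_e.copy(), self.g_i.copy())


def izhikevich_rhs(v, u, a, b, i_total):
    """Right-hand side of the membrane/recovery ODE pair."""
    dv = 0.04 * v * v + 5.0 * v + 140.0 - u + i_total
    du = a * (b * v - u)
    return dv, du


def step_neuron(
    state: NeuronState,
    params: IzhikevichParams,
    dt: float,
    *,
    t_ms: float | None = None,
):
    """Advance the membrane equations by one explicit-midpoint step.

    The synaptic current ``g_e - g_i`` plus bias is held constant over the
    step.  Returns ``(state, spiked)`` where ``spiked`` is a boolean array;
    ``state.v`` holds the post-reset potential.  Accumulators are untouched
    (see :func:`decay_and_inject`).

    Raises
    ------
    IntegrationBlowupError
        If any neuron's state becomes non-finite after the step.
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    v, u = state.v, state.u
    i_total = state.g_e - state.g_i + params.i_dc

    with np.errstate(over="ignore", invalid="ignore"):  # blowup handled below
        dv1, du1 = izhikevich_rhs(v, u, params.a, params.b, i_total)
        vm = v + 0.5 * dt * dv1
        um = u + 0.5 * dt * du1
        dv2, du2 = izhikevich_rhs(vm, um, params.a, params.b, i_total)
        v_new = v + dt * dv2
        u_new = u + dt * du2

    bad = ~(np.isfinite(v_new) & np.isfinite(u_new))
    if np.any(bad):
        idx = int(np.flatnonzero(bad)[0])
        when = f" at t={t_ms:g} ms" if t_ms is not None else ""
        raise IntegrationBlowupError(
            f"non-finite state for neuron index {idx}{when} "
            f"(v={v_new[idx]}, u={u_new[idx]})"
        )

    spiked = v_new > SPIKE_THRESHOLD_MV
    v_new = np.where(spiked, params.c, v_new)
    u_new = np.where(spiked, u_new + params.d, u_new)
    state.v, state.u = v_new, u_new
    return state, spiked


def decay_and_inject(
    state: NeuronState,
    kinetics: SynapseKinetics,
    dt: float,
    arrivals_e=0.0,
    arrivals_i=0.0,
) -> NeuronState:
    """Decay both accumulators over ``dt`` and add this step's arrivals.

    Exact single-exponential decay between events; superposition over
    multiple afferents is a plain sum of weights.  Arrival totals are
    magnitudes and must be non-negative.
    """
    arrivals_e = np.asarray(arrivals_e, dtype=float)
    arrivals_i = np.asarray(arrivals_i, dtype=float)
    if np.any(arrivals_e < 0) or np.any(arrivals_i < 0):
        raise ValueError("arrival totals are magnitudes and must be >= 0")
    state.g_e = state.g_e * np.exp(-dt / kinetics.tau_e) + arrivals_e
    state.g_i = state.g_i * np.exp(-dt / kinetics.tau_i) + arrivals_i
    return state


def _load_presets() -> dict:
    text = resources.files("lgnsim.data").joinpath("izhikevich_tonic.yaml").read_text()
    raw = yaml.safe_load(text)
    return {
        name: IzhikevichParams(
            a=row["a"], b=row["b"], c=row["c"], d=row["d"],
            v_init=row["v_init"], u_init=row["u_init"],
        )
        for name, row in raw.items()
    }


def tonic_presets() -> dict:
    """Tonic-mode presets for the TCR (RS), IN (FS) and TRN (RS) populations."""
    return _load_presets()


def simulate_single(
    params: IzhikevichParams,
    duration: float,
    dt: float = 0.1,
    i_dc: float | None = None,
):
    """Integrate one unconnected neuron under constant bias.

    Returns ``(times_ms, v_trace, spike_times_ms)`` with the recorded trace
    clamped at the spike threshold on spike steps.
    """
    p = params if i_dc is None else params.with_bias(i_dc)
    n_steps = int(round(duration / dt))
    state = NeuronState.from_params(p, 1)
    v_trace = np.empty(n_steps)
    spikes = []
    for k in range(n_steps):
        state, spiked = step_neuron(state, p, dt, t_ms=k * dt)
        if spiked[0]:
            v_trace[k] = SPIKE_THRESHOLD_MV
            spikes.append((k + 1) * dt)
        else:
            v_trace[k] = state.v[0]
    times = (np.arange(n_steps) + 1) * dt
    return times, v_trace, np.asarray(spikes)


def tonic_demo(
    params_by_population: dict | None = None,
    i_dc: float = 5.0,
    duration: float = 1000.0,
    dt: float = 0.1,
    n_per_population: int = 5,
) -> dict:
    """Spike rasters of unconnected populations under constant bias current.

    With no connectivity and no synaptic input every neuron in a population
    integrates the same equations from the same initial conditions, so all
    rasters within a population are identical — the homogeneity demo.

    Returns a dict ``{population: list of spike-time arrays (ms)}``.
    """
    if params_by_population is None:
        params_by_population = tonic_presets()
    rasters: dict = {}
    for name, params in params_by_population.items():
        _, _, spikes = simulate_single(params, duration, dt, i_dc=i_dc)
        rasters[name] = [spikes.copy() for _ in range(n_per_population)]
    return rasters
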