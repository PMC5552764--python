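"""Time-stepped simulation: single trials, multi-trial averaging, persistence.

A trial integrates the realized network for ``duration`` ms at resolution
``dt`` (defaults 6000 ms / 0.1 ms) with delayed spike delivery, recording
every neuron's membrane potential at every step (clamped at the 30 mV
threshold on spike steps).  The multi-trial protocol mirrors an SSVEP study:
each trial uses its own seed (governing, by default, both the wiring
realization and any stochastic stimulus), the per-population neuron-mean
series of each trial are averaged across trials, and the TCR average is
designated the *model output* — the local-field-potential-like quantity
the spectral analysis consumes.  For multi-node networks the output is the
mean of the per-node TCR averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._core import simulate_core
from .network import Network, NetworkConfig, build_lgn, build_multi_node
from .neurons import IntegrationBlowupError
from .stimulus import SpikeEventSet, StimulusSpec


class SpikeBufferOverflowError(RuntimeError):
    pass


@dataclass
class TrialResult:
    """Raw recordings of one trial.

    ``v`` maps population name to an (n_neurons, n_steps) membrane matrix in
    mV; ``spikes`` maps population name to a :class:`SpikeEventSet` whose
    channel indices are local neuron indices.
    """

    dt: float
    duration: float
    seed: int | None
    v: dict[str, np.ndarray]
    spikes: dict[str, SpikeEventSet]
    n_deliveries: int = 0

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    def population_mean(self, name: str) -> np.ndarray:
        """Across-neuron mean membrane series of one population."""
        return self.v[name].mean(axis=0)

    def save_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["dt"] = self.dt
            f.attrs["duration"] = self.duration
            f.attrs["seed"] = -1 if self.seed is None else self.seed
            f.attrs["n_deliveries"] = self.n_deliveries
            for name, mat in self.v.items():
                g = f.create_group(name)
                g.create_dataset("v", data=mat, compression="gzip")
                ev = self.spikes[name]
                g.create_dataset("spike_times", data=ev.times)
                g.create_dataset("spike_neurons", data=ev.channels)
                g.attrs["n_neurons"] = ev.n_channels

    @classmethod
    def load_hdf5(cls, path) -> "TrialResult":
        import h5py

        with h5py.File(path, "r") as f:
            seed = int(f.attrs["seed"])
            out = cls(
                dt=float(f.attrs["dt"]), duration=float(f.attrs["duration"]),
                seed=None if seed == -1 else seed,
                v={}, spikes={}, n_deliveries=int(f.attrs["n_deliveries"]),
            )
            for name, g in f.items():
                out.v[name] = g["v"][...]
                out.spikes[name] = SpikeEventSet(
                    int(g.attrs["n_neurons"]), g["spike_times"][...],
                    g["spike_neurons"][...],
                )
        return out


@dataclass
class AveragedTrace:
    """Across-trial average of per-population neuron-mean membrane series."""

    dt: float
    duration: float
    n_trials: int
    mean: dict[str, np.ndarray]
    per_trial: dict[str, np.ndarray] = field(default_factory=dict)
    node_count: int = 1
    base_seed: int | None = None

    @property
    def fs_hz(self) -> float:
        return 1000.0 / self.dt

    def times_ms(self) -> np.ndarray:
        n = int(round(self.duration / self.dt))
        return (np.arange(n) + 1) * self.dt

    def output_to_csv(self, path) -> None:
        """Model-output series as flat CSV (time_ms, value)."""
        series = model_output(self)
        t = self.times_ms()
        with open(path, "w") as fh:
            fh.write("time_ms,v_mean_mV\n")
            for ti, vi in zip(t, series):
                fh.write(f"{ti:.4f},{vi:.9g}\n")


def _csr_by_key(keys: np.ndarray, n_keys: int, *cols):
    order = np.argsort(keys, kind="stable")
    counts = np.bincount(keys, minlength=n_keys)
    ptr = np.zeros(n_keys + 1, dtype=np.int64)
    np.cumsum(counts, out=ptr[1:])
    return ptr, [np.ascontiguousarray(c[order]) for c in cols]


def run_trial(
    network: Network,
    stimulus: SpikeEventSet | None = None,
    duration: float = 6000.0,
    dt: float | None = None,
    seed: int | None = None,
) -> TrialResult:
    """Integrate one trial of a realized network.

    ``dt`` must match the resolution the network's delays were realized at
    (default: the network's own).  ``stimulus`` events are delivered through
    the RET->TCR / RET->IN edges; events at or after ``duration`` are
    ignored.  Raises :class:`IntegrationBlowupError` naming the neuron and
    time if the state diverges.
    """
    if dt is None:
        dt = network.dt
    if abs(dt - network.dt) > 1e-12:
        raise ValueError(
            f"dt={dt} differs from the resolution the network was realized at "
            f"({network.dt}); rebuild the network"
        )
    n_steps = int(round(duration / dt))
    n = network.n_neurons

    a, b, c, d, idc, v0, u0 = network.neuron_param_arrays()
    v = v0.copy(); u = u0.copy()
    ge = np.zeros(n); gi = np.zeros(n)
    kin = network.config.kinetics
    decay_e = float(np.exp(-dt / kin.tau_e))
    decay_i = float(np.exp(-dt / kin.tau_i))

    epre, epost, ew, edelay, einh = network.neuron_edge_arrays()
    if edelay.size and edelay.min() < 1:
        raise ValueError("all projection delays must be >= dt")
    eptr, (epost, ew, edelay, einh) = _csr_by_key(epre, n, epost, ew, edelay, einh)

    schan, spost, sw, sdelay = network.stimulus_edge_arrays()
    n_chan = max(network.n_stim_channels, 1)
    sptr, (spost, sw, sdelay) = _csr_by_key(schan, n_chan, spost, sw, sdelay)

    if stimulus is not None:
        if stimulus.n_channels != network.n_stim_channels:
            raise ValueError(
                f"stimulus has {stimulus.n_channels} channels, network expects "
                f"{network.n_stim_channels}"
            )
        ev = stimulus.on_events()
        steps = np.round(ev.times / dt).astype(np.int64)
        keep = (steps >= 0) & (steps < n_steps)
        stim_step = steps[keep]
        stim_chan = ev.channels[keep]
        order = np.argsort(stim_step, kind="stable")
        stim_step = np.ascontiguousarray(stim_step[order])
        stim_chan = np.ascontiguousarray(stim_chan[order])
    else:
        stim_step = np.zeros(0, dtype=np.int64)
        stim_chan = np.zeros(0, dtype=np.int64)

    max_delay = 1
    if edelay.size:
        max_delay = max(max_delay, int(edelay.max()))
    if sdelay.size:
        max_delay = max(max_delay, int(sdelay.max()))
    ring_size = max_delay + 1

    v_rec = np.empty((n, n_steps))
    cap = max(n * max(int(duration), 1), 1024)
    spike_neuron = np.empty(cap, dtype=np.int64)
    spike_step = np.empty(cap, dtype=np.int64)

    n_spikes, n_deliv, err = simulate_core(
        n_steps, float(dt), a, b, c, d, idc, v, u, ge, gi,
        decay_e, decay_i,
        eptr, epost.astype(np.int64), ew, edelay.astype(np.int64),
        einh.astype(np.bool_),
        stim_step, stim_chan,
        sptr, spost.astype(np.int64), sw, sdelay.astype(np.int64),
        ring_size, v_rec, spike_neuron, spike_step,
    )
    if err < 0:
        code = -err - 1
        t_idx, i_idx = divmod(code, n)
        raise IntegrationBlowupError(
            f"non-finite state for neuron {i_idx} at t={(t_idx + 1) * dt:g} ms"
        )
    if n_spikes > cap:
        raise SpikeBufferOverflowError(
            f"{n_spikes} spikes exceed the recording buffer ({cap}); "
            "the network is firing implausibly fast"
        )

    result = TrialResult(dt=dt, duration=duration, seed=seed, v={}, spikes={},
                         n_deliveries=int(n_deliv))
    sn = spike_neuron[:n_spikes]
    st = (spike_step[:n_spikes] + 1) * dt  # spike registered at end of step
    for pop in network.populations.values():
        sel = slice(pop.start, pop.start + pop.size)
        result.v[pop.name] = v_rec[sel]
        m = (sn >= pop.start) & (sn < pop.start + pop.size)
        result.spikes[pop.name] = SpikeEventSet(pop.size, st[m], sn[m] - pop.start)
    return result


def _build(config: NetworkConfig, seed: int, dt: float) -> Network:
    if config.node_count > 1:
        return build_multi_node(config, n_nodes=config.node_count, seed=seed, dt=dt)
    return build_lgn(config, seed=seed, dt=dt)


def run_trials(
    config: NetworkConfig,
    stimulus_spec: StimulusSpec | SpikeEventSet | None,
    n_trials: int = 10,
    base_seed: int = 0,
    duration: float = 6000.0,
    dt: float = 0.1,
    redraw_wiring: bool = True,
) -> AveragedTrace:
    """Run the multi-trial protocol and average.

    Trial k uses seed ``base_seed + k``.  By default the seed governs both
    the wiring realization and any stochastic stimulus (``redraw_wiring=False``
    freezes the wiring at ``base_seed`` and re-draws only the stimulus).  A
    fixed :class:`SpikeEventSet` (e.g. an emulated-retina recording) may be
    passed instead of a stimulus spec and is then identical across trials.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    mean_acc: dict[str, np.ndarray] = {}
    per_trial: dict[str, list[np.ndarray]] = {}
    network = None
    for k in range(n_trials):
        trial_seed = base_seed + k
        if network is None or redraw_wiring:
            network = _build(config, seed=trial_seed if redraw_wiring else base_seed,
                             dt=dt)
        if stimulus_spec is None:
            stim = None
        elif isinstance(stimulus_spec, SpikeEventSet):
            stim = stimulus_spec
        else:
            stim = stimulus_spec.realize(duration, seed=trial_seed)
        trial = run_trial(network, stim, duration=duration, dt=dt, seed=trial_seed)
        for name in trial.v:
            series = trial.population_mean(name)
            per_trial.setdefault(name, []).append(series)
            if name in mean_acc:
                mean_acc[name] += series
            else:
                mean_acc[name] = series.copy()
    mean = {name: acc / n_trials for name, acc in mean_acc.items()}
    return AveragedTrace(
        dt=dt, duration=duration, n_trials=n_trials, mean=mean,
        per_trial={name: np.vstack(rows) for name, rows in per_trial.items()},
        node_count=config.node_count, base_seed=base_seed,
    )


def model_output(avg: AveragedTrace) -> np.ndarray:
    """The model output: the (across-node mean of the) TCR averaged series."""
    tcr = [name for name in avg.mean if name.startswith("TCR")]
    if not tcr:
        raise ValueError("no TCR population present in this trace")
    return np.mean([avg.mean[name] for name in sorted(tcr)], axis=0)
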