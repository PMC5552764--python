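"""Input spike trains and the event-camera (DVS) retina emulator.

The network is driven through its 144 retinal channels by one of three
sources:

* synthetic **periodic** trains — every channel fires simultaneously at the
  drive frequency (10-50 Hz in the standard sweep), emulating the
  near-synchronous first-spike volley a flashing LED evokes across pixels;
* synthetic **Poisson** trains — independent homogeneous Poisson processes
  per channel, the aperiodic control;
* the **DVS emulator** — a model of a dynamic-vision-sensor pixel array
  watching a flashing LED.  Each pixel log-converts its photocurrent,
  ``V_log = K log(I_ph)``, and a differencing stage tracks
  ``dV_diff = A dV_log`` since the last reset; crossing the ON threshold
  emits a positive event and self-resets, crossing the OFF threshold emits a
  negative event.  ON events per illumination edge of contrast C therefore
  number about ``floor(A*K*ln(C) / (V_t_plus - V_ref))``.

A first-spike filter reduces the raw ON-event stream to each pixel's
earliest event after every LED OFF->ON transition, mirroring the
ON-center/first-spike reduction applied to the recorded retina data.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field

import numpy as np

ON, OFF = 1, -1


@dataclass
class SpikeEventSet:
    """Timestamped events on indexed channels, sorted by time (stable).

    ``polarity`` is optional (+1 ON / -1 OFF) and used only by DVS output.
    """

    n_channels: int
    times: np.ndarray
    channels: np.ndarray
    polarity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.channels = np.asarray(self.channels, dtype=np.int64)
        if self.polarity is not None:
            self.polarity = np.asarray(self.polarity, dtype=np.int8)
        if self.times.shape != self.channels.shape:
            raise ValueError("times and channels must have equal length")
        if self.times.size and (
            self.channels.min() < 0 or self.channels.max() >= self.n_channels
        ):
            raise ValueError("channel index out of range")
        order = np.argsort(self.times, kind="stable")
        self.times = self.times[order]
        self.channels = self.channels[order]
        if self.polarity is not None:
            self.polarity = self.polarity[order]

    def __len__(self) -> int:
        return self.times.size

    def select(self, mask: np.ndarray) -> "SpikeEventSet":
        pol = None if self.polarity is None else self.polarity[mask]
        return SpikeEventSet(self.n_channels, self.times[mask], self.channels[mask], pol)

    def on_events(self) -> "SpikeEventSet":
        """Keep positive-polarity events only (ON-center assumption)."""
        if self.polarity is None:
            return self
        return self.select(self.polarity == ON)

    def shifted(self, delta_ms: float) -> "SpikeEventSet":
        return SpikeEventSet(
            self.n_channels, self.times + delta_ms, self.channels.copy(),
            None if self.polarity is None else self.polarity.copy(),
        )

    # -- text / binary I/O --------------------------------------------------

    def to_text(self, path) -> None:
        """Two/three-column tab-separated text: channel, time_ms[, polarity]."""
        with open(path, "w") as fh:
            fh.write(f"# n_channels={self.n_channels}\n")
            if self.polarity is None:
                fh.write("channel\ttime_ms\n")
                for c, t in zip(self.channels, self.times):
                    fh.write(f"{c}\t{t:.6g}\n")
            else:
                fh.write("channel\ttime_ms\tpolarity\n")
                for c, t, p in zip(self.channels, self.times, self.polarity):
                    fh.write(f"{c}\t{t:.6g}\t{p:+d}\n")

    @classmethod
    def from_text(cls, path) -> "SpikeEventSet":
        n_channels = None
        chans, times, pols = [], [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    if "n_channels=" in line:
                        n_channels = int(line.split("n_channels=")[1])
                    continue
                if line.startswith("channel"):
                    continue
                parts = line.split("\t")
                chans.append(int(parts[0]))
                times.append(float(parts[1]))
                if len(parts) > 2:
                    pols.append(int(parts[2]))
        if n_channels is None:
            n_channels = (max(chans) + 1) if chans else 1
        pol = np.asarray(pols, dtype=np.int8) if pols else None
        return cls(n_channels, np.asarray(times), np.asarray(chans, dtype=np.int64), pol)

    def to_aer(self, path, n_cols: int) -> None:
        """AER-style binary record: per event uint16 x, y, int8 polarity, uint32 t_us."""
        pol = self.polarity if self.polarity is not None else np.ones(len(self), np.int8)
        with open(path, "wb") as fh:
            fh.write(struct.pack("<2sHI", b"AE", n_cols, len(self)))
            for c, t, p in zip(self.channels, self.times, pol):
                y, x = divmod(int(c), n_cols)
                fh.write(struct.pack("<HHbI", x, y, int(p), int(round(t * 1000.0))))

    @classmethod
    def from_aer(cls, path, n_channels: int | None = None) -> "SpikeEventSet":
        with open(path, "rb") as fh:
            magic, n_cols, n_ev = struct.unpack("<2sHI", fh.read(8))
            if magic != b"AE":
                raise ValueError(f"{path}: not an AER-style event file")
            rec = struct.Struct("<HHbI")
            chans = np.empty(n_ev, dtype=np.int64)
            times = np.empty(n_ev, dtype=float)
            pols = np.empty(n_ev, dtype=np.int8)
            for i in range(n_ev):
                x, y, p, t_us = rec.unpack(fh.read(rec.size))
                chans[i] = y * n_cols + x
                times[i] = t_us / 1000.0
                pols[i] = p
        if n_channels is None:
            n_channels = int(chans.max()) + 1 if n_ev else 1
        return cls(n_channels, times, chans, pols)


def periodic_train(
    freq: float,
    duration: float,
    n_channels: int = 144,
    jitter_ms: float = 0.0,
    seed: int | None = None,
) -> SpikeEventSet:
    """Coincident periodic trains: spikes at k*(1000/freq) ms on every channel.

    The spike at t=0 is included.  ``jitter_ms`` adds optional per-channel,
    per-event uniform jitter (seeded; default 0, i.e. perfectly coincident).
    """
    if not freq > 0:
        raise ValueError("freq must be positive")
    if not duration > 0:
        raise ValueError("duration must be positive")
    period = 1000.0 / freq
    base = np.arange(0.0, duration, period)
    if freq * duration / 1000.0 < 1.0:
        warnings.warn("less than one full period fits in the duration")
    times = np.tile(base, n_channels)
    chans = np.repeat(np.arange(n_channels, dtype=np.int64), base.size)
    if jitter_ms > 0:
        rng = np.random.default_rng(seed)
        times = times + rng.uniform(0.0, jitter_ms, size=times.size)
        keep = times < duration
        times, chans = times[keep], chans[keep]
    return SpikeEventSet(n_channels, times, chans)


def poisson_trains(
    rate: float,
    duration: float,
    n_channels: int = 144,
    seed: int | None = None,
) -> SpikeEventSet:
    """Independent homogeneous Poisson trains, one per channel."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    rng = np.random.default_rng(seed)
    if rate == 0:
        return SpikeEventSet(n_channels, np.zeros(0), np.zeros(0, dtype=np.int64))
    counts = rng.poisson(rate * duration / 1000.0, size=n_channels)
    chans = np.repeat(np.arange(n_channels, dtype=np.int64), counts)
    times = rng.uniform(0.0, duration, size=int(counts.sum()))
    return SpikeEventSet(n_channels, times, chans)


@dataclass
class IlluminationSignal:
    """Sampled illumination (arbitrary positive units) plus its ON edges."""

    times: np.ndarray
    values: np.ndarray
    on_transitions: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values <= 0):
            raise ValueError("illumination must stay positive (dark-level floor)")


def led_square_wave(
    freq: float,
    duration: float,
    level_on: float = 2.0,
    level_off: float = 1.0,
    duty: float = 0.5,
    fs_khz: float = 10.0,
) -> IlluminationSignal:
    """Square-wave LED drive sampled at ``fs_khz`` kHz.

    Contrast is ``level_on / level_off``.  Each period starts dark so that
    every OFF->ON transition is a real illumination step; the transition
    times are recorded for the first-spike filter.
    """
    if not level_on > level_off > 0:
        raise ValueError("require level_on > level_off > 0 (flashing, positive floor)")
    if not (0 < duty < 1):
        raise ValueError("duty must lie in (0, 1)")
    dt = 1.0 / fs_khz
    t = np.arange(0.0, duration, dt)
    period = 1000.0 / freq
    phase = np.mod(t, period)
    off_span = (1.0 - duty) * period
    values = np.where(phase >= off_span, level_on, level_off)
    transitions = np.arange(off_span, duration, period)
    return IlluminationSignal(t, values, transitions)


def sinusoidal_illumination(
    freq: float,
    duration: float,
    mean: float = 1.5,
    amplitude: float = 0.5,
    fs_khz: float = 10.0,
) -> IlluminationSignal:
    """Sinusoidal illumination (for pixel-behavior demos)."""
    if not mean > amplitude >= 0:
        raise ValueError("require mean > amplitude >= 0 so illumination stays positive")
    dt = 1.0 / fs_khz
    t = np.arange(0.0, duration, dt)
    values = mean + amplitude * np.sin(2 * np.pi * freq * t / 1000.0)
    rising_starts = np.arange(0.0, duration, 1000.0 / freq)
    return IlluminationSignal(t, values, rising_starts)


@dataclass(frozen=True)
class DVSPixelParams:
    """Pixel-front-end constants of the DVS model.

    Defaults give floor(A*K*ln 2 / (V_t_plus - V_ref)) = 4 ON events per
    contrast-2 edge.  All values are configurable; the thresholds must
    bracket the reset reference.
    """

    K: float = 1.0
    A: float = 10.0
    V_ref: float = 0.0
    V_t_plus: float = 1.5
    V_t_minus: float = -1.5

    def __post_init__(self) -> None:
        if not (self.V_t_minus < self.V_ref < self.V_t_plus):
            raise ValueError("thresholds must satisfy V_t_minus < V_ref < V_t_plus")


def dvs_simulate(
    signal: IlluminationSignal,
    params: DVSPixelParams | None = None,
    grid: tuple[int, int] = (12, 12),
    noise_seed: int | None = None,
    threshold_jitter: float = 0.0,
) -> SpikeEventSet:
    """Emulate a DVS pixel array watching ``signal`` (same light on all pixels).

    Per pixel, ``V_diff`` tracks ``A*K * d(log I_ph)`` since the last reset;
    an upward crossing of ``V_t_plus`` emits an ON event and self-resets to
    ``V_ref``, a downward crossing of ``V_t_minus`` emits an OFF event and
    resets.  ``threshold_jitter`` (relative sigma, seeded) perturbs each
    pixel's thresholds to emulate fabrication mismatch; with zero jitter all
    pixels behave identically.
    """
    if params is None:
        params = DVSPixelParams()
    rows, cols = grid
    if rows < 1 or cols < 1:
        raise ValueError("grid must be at least 1x1")
    n_pix = rows * cols

    vtp = np.full(n_pix, params.V_t_plus - params.V_ref)
    vtm = np.full(n_pix, params.V_t_minus - params.V_ref)
    if threshold_jitter > 0:
        rng = np.random.default_rng(noise_seed)
        vtp *= 1.0 + threshold_jitter * rng.standard_normal(n_pix)
        vtm *= 1.0 + threshold_jitter * rng.standard_normal(n_pix)
        vtp = np.maximum(vtp, 1e-6)
        vtm = np.minimum(vtm, -1e-6)

    v_log = params.K * np.log(signal.values)
    dv = params.A * np.diff(v_log, prepend=v_log[0])

    v_diff = np.zeros(n_pix)  # relative to V_ref
    times, chans, pols = [], [], []
    for i, t in enumerate(signal.times):
        v_diff += dv[i]
        n_on = np.floor_divide(v_diff, vtp).astype(np.int64)
        n_on = np.maximum(n_on, 0)
        n_off = np.floor_divide(v_diff, vtm).astype(np.int64)  # positive when v_diff<vtm
        n_off = np.maximum(n_off, 0)
        for counts, pol, thr in ((n_on, ON, vtp), (n_off, OFF, vtm)):
            hit = np.nonzero(counts)[0]
            for px in hit:
                k = int(counts[px])
                times.extend([t] * k)
                chans.extend([px] * k)
                pols.extend([pol] * k)
                v_diff[px] -= k * thr[px]
    return SpikeEventSet(
        n_pix, np.asarray(times), np.asarray(chans, dtype=np.int64),
        np.asarray(pols, dtype=np.int8) if times else np.zeros(0, np.int8),
    )


def first_spike_filter(
    events: SpikeEventSet, transitions
) -> SpikeEventSet:
    """Keep each channel's earliest ON event in every OFF->ON transition window.

    ``transitions`` are the LED OFF->ON times (ms), sorted ascending; window
    k spans [transitions[k], transitions[k+1]) (the last window is open-ended).
    OFF events must have been discarded upstream (:meth:`SpikeEventSet.on_events`).
    """
    transitions = np.asarray(transitions, dtype=float)
    if np.any(np.diff(transitions) < 0):
        raise ValueError("transition times must be sorted ascending")
    if events.polarity is not None and np.any(events.polarity != ON):
        raise ValueError("first_spike_filter expects ON events only; filter upstream")
    if len(events) == 0 or transitions.size == 0:
        return events.select(np.zeros(len(events), dtype=bool))
    window = np.searchsorted(transitions, events.times, side="right") - 1
    valid = window >= 0
    keep = np.zeros(len(events), dtype=bool)
    seen: set[tuple[int, int]] = set()
    for i in np.nonzero(valid)[0]:  # events are time-sorted, so first wins
        key = (int(events.channels[i]), int(window[i]))
        if key not in seen:
            seen.add(key)
            keep[i] = True
    return events.select(keep)


class StimulusSpec:
    """A reproducible stimulus recipe: ``realize(duration, seed)`` -> events."""

    def realize(self, duration: float, seed=None) -> SpikeEventSet:
        raise NotImplementedError


@dataclass(frozen=True)
class PeriodicStimulus(StimulusSpec):
    freq: float
    n_channels: int = 144
    jitter_ms: float = 0.0

    def realize(self, duration: float, seed=None) -> SpikeEventSet:
        jseed = None if seed is None else [int(seed), 104729]
        return periodic_train(self.freq, duration, self.n_channels,
                              jitter_ms=self.jitter_ms, seed=jseed)


@dataclass(frozen=True)
class PoissonStimulus(StimulusSpec):
    rate: float
    n_channels: int = 144

    def realize(self, duration: float, seed=None) -> SpikeEventSet:
        pseed = None if seed is None else [int(seed), 104729]
        return poisson_trains(self.rate, duration, self.n_channels, seed=pseed)


@dataclass(frozen=True)
class RetinaStimulus(StimulusSpec):
    """Emulated-retina drive: flashing LED -> DVS -> first-spike filter."""

    freq: float
    grid: tuple[int, int] = (12, 12)
    level_on: float = 2.0
    level_off: float = 1.0
    threshold_jitter: float = 0.02

    def realize(self, duration: float, seed=None) -> SpikeEventSet:
        nseed = None if seed is None else [int(seed), 99991]
        return dvs_led_stimulus(
            self.freq, duration, grid=self.grid, level_on=self.level_on,
            level_off=self.level_off, noise_seed=nseed,
            threshold_jitter=self.threshold_jitter,
        )


def dvs_led_stimulus(
    freq: float,
    duration: float = 1000.0,
    grid: tuple[int, int] = (12, 12),
    params: DVSPixelParams | None = None,
    level_on: float = 2.0,
    level_off: float = 1.0,
    noise_seed: int | None = None,
    threshold_jitter: float = 0.02,
) -> SpikeEventSet:
    """Full emulated-retina pipeline: LED -> DVS -> ON events -> first-spike filter."""
    sig = led_square_wave(freq, duration, level_on=level_on, level_off=level_off)
    raw = dvs_simulate(sig, params, grid=grid, noise_seed=noise_seed,
                       threshold_jitter=threshold_jitter)
    return first_spike_filter(raw.on_events(), sig.on_transitions)
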