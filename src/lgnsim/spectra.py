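"""SSVEP-style spectral analysis of the model output.

The processing chain mirrors standard evoked-potential practice: a 5 s epoch
(0.5-5.5 s, discarding the onset transient) of the averaged membrane series
is extracted and de-meaned, down-sampled from the simulation rate (10 kHz at
dt = 0.1 ms) to 1 kHz, band-passed 1-100 Hz with an order-10 Butterworth
filter (zero-phase, second-order sections), and its power spectral density
estimated with a Welch periodogram (Hann window, 1 s segments, 50% overlap,
4x zero-padded transform, so the frequency resolution is 0.25 Hz).

On top of the PSD sit the readouts: the peak frequency in a band
(entrainment), a harmonic/subharmonic profile (power at k*f0 and at
(2k-1)*f0/2 compared against the local spectral background), and the sweep
image stacking one PSD column per input frequency — the picture in which
entrainment appears as a diagonal ridge and feed-forward-inhibition
suppression as half-integer side ridges in the gamma band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .engine import model_output, run_trials
from .network import NetworkConfig
from .stimulus import PeriodicStimulus, PoissonStimulus, StimulusSpec


@dataclass
class PowerSpectrum:
    """A one-sided PSD with its frequency axis and provenance."""

    frequencies: np.ndarray
    power: np.ndarray
    resolution: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequency axis must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power density must be non-negative")

    def band(self, lo: float, hi: float):
        m = (self.frequencies >= lo) & (self.frequencies <= hi)
        return self.frequencies[m], self.power[m]

    def power_at(self, f0: float, tol: float = 1.0) -> float:
        """Maximum power density within ``±tol`` Hz of ``f0``."""
        m = np.abs(self.frequencies - f0) <= tol
        return float(self.power[m].max()) if m.any() else 0.0

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("frequency_hz,power\n")
            for f, p in zip(self.frequencies, self.power):
                fh.write(f"{f:.6g},{p:.9g}\n")


def preprocess(
    series: np.ndarray,
    fs_in: float = 10000.0,
    epoch: tuple[float, float] = (500.0, 5500.0),
    fs_out: float = 1000.0,
    band: tuple[float, float] = (1.0, 100.0),
    order: int = 10,
    antialias: bool = False,
) -> np.ndarray:
    """Epoch, de-mean, down-sample and band-pass one output series.

    ``epoch`` is in ms relative to series start.  Down-sampling is plain
    stride decimation by ``fs_in / fs_out`` (an anti-alias pre-filter can be
    switched on); the band-pass is a zero-phase order-``order`` Butterworth
    realized as second-order sections.
    """
    series = np.asarray(series, dtype=float)
    i0 = int(round(epoch[0] * fs_in / 1000.0))
    i1 = int(round(epoch[1] * fs_in / 1000.0))
    if i0 < 0 or i1 > series.size or i1 <= i0:
        raise ValueError(
            f"epoch {epoch} ms lies outside the series extent "
            f"({series.size / fs_in * 1000:g} ms)"
        )
    x = series[i0:i1]
    x = x - x.mean()
    stride_f = fs_in / fs_out
    stride = int(round(stride_f))
    if abs(stride_f - stride) > 1e-9:
        raise ValueError(f"fs_in={fs_in} must be an integer multiple of fs_out={fs_out}")
    if stride > 1:
        if antialias:
            x = sps.decimate(x, stride, ftype="fir", zero_phase=True)
        else:
            x = x[::stride]
    sos = sps.butter(order, band, btype="bandpass", fs=fs_out, output="sos")
    if not np.all(np.isfinite(sos)):
        raise RuntimeError("Butterworth SOS design produced non-finite coefficients")
    return sps.sosfiltfilt(sos, x)


def welch_psd(
    series: np.ndarray,
    fs: float = 1000.0,
    seg_len: int = 1000,
    overlap: float = 0.5,
    pad_factor: int = 4,
    window: str = "hann",
    provenance: dict | None = None,
) -> PowerSpectrum:
    """Welch PSD with ``pad_factor``-times zero-padded segments.

    Frequency resolution is ``fs / (pad_factor * seg_len)`` (0.25 Hz at the
    defaults).
    """
    series = np.asarray(series, dtype=float)
    if seg_len > series.size:
        raise ValueError(f"seg_len={seg_len} exceeds series length {series.size}")
    if not (0.0 <= overlap < 1.0):
        raise ValueError("overlap must lie in [0, 1)")
    nfft = int(pad_factor) * int(seg_len)
    freqs, pxx = sps.welch(
        series, fs=fs, window=window, nperseg=seg_len,
        noverlap=int(round(overlap * seg_len)), nfft=nfft,
        detrend="constant", scaling="density",
    )
    return PowerSpectrum(
        frequencies=freqs[1:], power=pxx[1:], resolution=fs / nfft,
        provenance=provenance or {},
    )


def peak_frequency(
    psd: PowerSpectrum, search_band: tuple[float, float] = (1.0, 100.0)
) -> float:
    """Frequency of maximal power within the band; ties go to the lower bin."""
    freqs, power = psd.band(*search_band)
    if freqs.size == 0:
        raise ValueError(f"band {search_band} contains no PSD bins")
    return float(freqs[int(np.argmax(power))])


@dataclass
class HarmonicComponent:
    nominal_hz: float
    power: float
    background: float
    present: bool


@dataclass
class HarmonicProfile:
    """Harmonic (k*f0) and subharmonic ((2k-1)*f0/2) content of one PSD.

    A component is flagged present when the maximum power within ``±tol`` of
    its nominal frequency (i) reaches ``prominence_factor`` times the local
    background (median power in a ±5 Hz annulus excluding the core) and
    (ii) clears a visibility floor of ``rel_floor`` times the strongest power
    in the analysis band.  The floor encodes "visible on a log-power sweep
    image": a component orders of magnitude below the dominant peak rises
    above the local noise floor numerically but would not register as a
    spectral ridge.
    """

    f0: float
    harmonics: list[HarmonicComponent]
    subharmonics: list[HarmonicComponent]

    @property
    def half_f_present(self) -> bool:
        return self.subharmonics[0].present

    def any_subharmonic(self) -> bool:
        return any(c.present for c in self.subharmonics)

    def table(self) -> str:
        rows = ["kind\tnominal_hz\tpower\tbackground\tpresent"]
        for kind, comps in (("harmonic", self.harmonics), ("subharmonic", self.subharmonics)):
            for c in comps:
                rows.append(
                    f"{kind}\t{c.nominal_hz:g}\t{c.power:.6g}\t{c.background:.6g}\t{c.present}"
                )
        return "\n".join(rows)


def _component(psd: PowerSpectrum, fc: float, tol: float, annulus: float,
               prominence_factor: float, floor: float) -> HarmonicComponent:
    f, p = psd.frequencies, psd.power
    if fc > f[-1] + tol or fc < f[0] - tol:
        return HarmonicComponent(fc, 0.0, 0.0, False)
    core = np.abs(f - fc) <= tol
    ring = (np.abs(f - fc) <= annulus) & ~core
    power = float(p[core].max()) if core.any() else 0.0
    background = float(np.median(p[ring])) if ring.any() else 0.0
    present = bool(
        core.any() and power >= prominence_factor * background > 0.0
        and power >= floor
    )
    return HarmonicComponent(fc, power, background, present)


def harmonic_profile(
    psd: PowerSpectrum,
    f0: float,
    tol: float = 1.0,
    prominence_factor: float = 3.0,
    rel_floor: float = 0.01,
    n_harmonics: int = 5,
    n_subharmonics: int = 4,
    annulus: float = 5.0,
    band: tuple[float, float] = (1.0, 100.0),
) -> HarmonicProfile:
    """Assess harmonics k*f0 (k=1..5) and subharmonics (2k-1)*f0/2 (k=1..4).

    ``rel_floor`` sets the visibility floor relative to the strongest power
    in ``band`` (0.01 = within 20 dB of the dominant component).
    """
    if not f0 > 0:
        raise ValueError("f0 must be positive")
    _, band_power = psd.band(*band)
    floor = rel_floor * float(band_power.max()) if band_power.size else 0.0
    harmonics = [
        _component(psd, k * f0, tol, annulus, prominence_factor, floor)
        for k in range(1, n_harmonics + 1)
    ]
    subharmonics = [
        _component(psd, (2 * k - 1) * f0 / 2.0, tol, annulus, prominence_factor, floor)
        for k in range(1, n_subharmonics + 1)
    ]
    return HarmonicProfile(f0=f0, harmonics=harmonics, subharmonics=subharmonics)


@dataclass
class SweepImage:
    """PSD columns of the model output across a sweep of input frequencies."""

    input_freqs: np.ndarray
    output_freqs: np.ndarray
    power: np.ndarray  # (n_output_freqs, n_input_freqs)
    provenance: dict = field(default_factory=dict)

    def column(self, freq: float) -> PowerSpectrum:
        j = int(np.argmin(np.abs(self.input_freqs - freq)))
        df = float(np.diff(self.output_freqs).min())
        return PowerSpectrum(self.output_freqs, self.power[:, j], df)

    def peak_per_column(self, band=(1.0, 100.0)) -> np.ndarray:
        return np.array([
            peak_frequency(self.column(f), band) for f in self.input_freqs
        ])

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("output_hz," + ",".join(f"{f:g}" for f in self.input_freqs) + "\n")
            for i, fo in enumerate(self.output_freqs):
                row = ",".join(f"{p:.6g}" for p in self.power[i])
                fh.write(f"{fo:.6g},{row}\n")


def analyze_output(
    avg,
    band: tuple[float, float] = (1.0, 100.0),
    **welch_kwargs,
) -> PowerSpectrum:
    """Model output -> preprocess -> Welch PSD, at the standard settings."""
    series = model_output(avg)
    fs_in = avg.fs_hz
    x = preprocess(series, fs_in=fs_in, band=band)
    return welch_psd(x, provenance={"n_trials": avg.n_trials,
                                    "node_count": avg.node_count,
                                    "base_seed": avg.base_seed})


def sweep(
    config: NetworkConfig,
    freqs: Sequence[float] = tuple(range(10, 51)),
    n_trials: int = 10,
    stimulus_kind: str = "periodic",
    base_seed: int = 0,
    duration: float = 6000.0,
    dt: float = 0.1,
    n_channels: int = 144,
    out_band: tuple[float, float] = (1.0, 100.0),
) -> SweepImage:
    """Run the full input-frequency sweep and stack PSD columns.

    ``stimulus_kind`` selects periodic trains or Poisson trains whose rate
    equals the nominal frequency.  One multi-trial run, preprocessing pass
    and Welch estimate per input frequency.
    """
    freqs = np.asarray(list(freqs), dtype=float)
    columns = []
    out_f = None
    for f in freqs:
        spec: StimulusSpec
        if stimulus_kind == "periodic":
            spec = PeriodicStimulus(freq=f, n_channels=n_channels)
        elif stimulus_kind == "poisson":
            spec = PoissonStimulus(rate=f, n_channels=n_channels)
        else:
            raise ValueError(f"unknown stimulus kind {stimulus_kind!r}")
        avg = run_trials(config, spec, n_trials=n_trials, base_seed=base_seed,
                         duration=duration, dt=dt)
        psd = analyze_output(avg)
        fsel, psel = psd.band(*out_band)
        if out_f is None:
            out_f = fsel
        columns.append(psel)
    return SweepImage(
        input_freqs=freqs, output_freqs=out_f, power=np.column_stack(columns),
        provenance={
            "stimulus_kind": stimulus_kind, "n_trials": n_trials,
            "base_seed": base_seed, "variant": config.variant,
            "duration_ms": duration, "dt_ms": dt,
        },
    )


def plot_sweep(image: SweepImage, path=None, log_power: bool = True):
    """Render a sweep image (log power by default); returns the figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    z = image.power
    if log_power:
        z = np.log10(np.maximum(z, z[z > 0].min() if (z > 0).any() else 1e-30))
    fig, ax = plt.subplots(figsize=(7, 5))
    mesh = ax.pcolormesh(image.input_freqs, image.output_freqs, z, shading="nearest")
    fig.colorbar(mesh, ax=ax, label="log10 power" if log_power else "power")
    ax.set_xlabel("input frequency (Hz)")
    ax.set_ylabel("output frequency (Hz)")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
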