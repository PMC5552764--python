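"""Experiment recipes: the figure-style protocols packaged as one call each.

Each recipe builds its networks, generates stimuli, runs the multi-trial
protocol, analyzes the output and writes artifacts (traces, PSD/sweep CSVs,
rendered figures, harmonic tables) plus a machine-readable ``summary.json``
and the resolved configuration snapshot into its output directory.

``scale="full"`` reproduces the desk-scale protocols (41-frequency sweeps,
10 trials); ``scale="ci"`` reduces sweeps to 5 representative frequencies
and 3 trials so a recipe finishes in minutes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .config import LoadedConfig, load_config
from .engine import model_output, run_trials
from .network import apply_in_suppression
from .neurons import tonic_demo
from .spectra import (analyze_output, harmonic_profile, peak_frequency,
                      plot_sweep, sweep)
from .stimulus import (PeriodicStimulus, RetinaStimulus, dvs_led_stimulus,
                       periodic_train, poisson_trains)

RECIPE_NAMES = ("tonic_demo", "sweep_periodic", "sweep_poisson",
                "in_suppression", "retina_compare", "multi_node")


@dataclass
class ExperimentRecipe:
    name: str
    out_dir: str | Path = "lgnsim_out"
    base_seed: int = 0
    scale: str = "full"
    config_path: str | None = None
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in RECIPE_NAMES:
            raise ValueError(f"unknown recipe {self.name!r}; choose from {RECIPE_NAMES}")
        if self.scale not in ("full", "ci"):
            raise ValueError("scale must be 'full' or 'ci'")


def _sweep_freqs(scale: str) -> list[int]:
    return list(range(10, 51)) if scale == "full" else [10, 20, 30, 40, 50]


def _gamma_freqs(scale: str) -> list[int]:
    return list(range(36, 51)) if scale == "full" else [36, 40, 44, 48, 50]


def _n_trials(scale: str, cfg: LoadedConfig) -> int:
    return cfg.run.n_trials if scale == "full" else min(cfg.run.n_trials, 3)


def run_recipe(recipe: ExperimentRecipe) -> dict:
    """Execute a named recipe end-to-end; returns the summary dict."""
    out = Path(recipe.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = load_config(recipe.config_path, overrides=recipe.overrides or None)
    cfg.write_snapshot(out / "config_snapshot.json")
    handler = {
        "tonic_demo": _recipe_tonic_demo,
        "sweep_periodic": _recipe_sweep,
        "sweep_poisson": _recipe_sweep,
        "in_suppression": _recipe_in_suppression,
        "retina_compare": _recipe_retina_compare,
        "multi_node": _recipe_multi_node,
    }[recipe.name]
    try:
        summary = handler(recipe, cfg, out)
    except Exception as exc:
        raise RuntimeError(f"recipe {recipe.name!r} failed: {exc}") from exc
    summary["recipe"] = recipe.name
    summary["base_seed"] = recipe.base_seed
    summary["scale"] = recipe.scale
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary


def _recipe_tonic_demo(recipe, cfg, out: Path) -> dict:
    duration = 1000.0
    rates = {}
    for i_dc in (3.0, 5.0, 7.0):
        rasters = tonic_demo(i_dc=i_dc, duration=duration, dt=cfg.run.dt_ms)
        rates[i_dc] = {}
        for pop, trains in rasters.items():
            rates[i_dc][pop] = len(trains[0]) / (duration / 1000.0)
            with open(out / f"tonic_{pop}_idc{i_dc:g}.txt", "w") as fh:
                fh.write("# spike times (ms), one line per neuron\n")
                for train in trains:
                    fh.write("\t".join(f"{t:g}" for t in train) + "\n")
    return {"firing_rate_hz": {f"{k:g}": v for k, v in rates.items()}}


def _recipe_sweep(recipe, cfg, out: Path) -> dict:
    kind = "periodic" if recipe.name == "sweep_periodic" else "poisson"
    freqs = _sweep_freqs(recipe.scale)
    image = sweep(
        cfg.network, freqs=freqs, n_trials=_n_trials(recipe.scale, cfg),
        stimulus_kind=kind, base_seed=recipe.base_seed,
        duration=cfg.run.duration_ms, dt=cfg.run.dt_ms,
    )
    image.to_csv(out / f"sweep_{kind}.csv")
    plot_sweep(image, out / f"sweep_{kind}.png")
    peaks = image.peak_per_column()
    second = [
        harmonic_profile(image.column(f), f0=f).harmonics[1].present for f in freqs
    ]
    return {
        "stimulus_kind": kind,
        "input_freqs_hz": freqs,
        "peak_hz": peaks.tolist(),
        "second_harmonic_present": second,
    }


def _recipe_in_suppression(recipe, cfg, out: Path) -> dict:
    freqs = _gamma_freqs(recipe.scale)
    n_trials = _n_trials(recipe.scale, cfg)
    summary = {"input_freqs_hz": freqs}
    for label, net in (("base", cfg.network),
                       ("in_suppressed", apply_in_suppression(cfg.network))):
        image = sweep(net, freqs=freqs, n_trials=n_trials, stimulus_kind="periodic",
                      base_seed=recipe.base_seed, duration=cfg.run.duration_ms,
                      dt=cfg.run.dt_ms)
        image.to_csv(out / f"sweep_gamma_{label}.csv")
        flags = [harmonic_profile(image.column(f), f0=f).half_f_present for f in freqs]
        summary[label] = {"half_f_present": flags, "count": int(sum(flags))}
    return summary


def _recipe_retina_compare(recipe, cfg, out: Path) -> dict:
    n_trials = _n_trials(recipe.scale, cfg)
    summary = {"cases": []}
    variants = (("base", cfg.network), ("in_suppressed", apply_in_suppression(cfg.network)))
    for freq in (10, 20, 40):
        stim = RetinaStimulus(freq=freq)
        for label, net in variants:
            avg = run_trials(net, stim, n_trials=n_trials, base_seed=recipe.base_seed,
                             duration=cfg.run.duration_ms, dt=cfg.run.dt_ms)
            psd = analyze_output(avg)
            psd.to_csv(out / f"retina_{freq}hz_{label}_psd.csv")
            avg.output_to_csv(out / f"retina_{freq}hz_{label}_trace.csv")
            prof = harmonic_profile(psd, f0=freq)
            summary["cases"].append({
                "input_hz": freq, "variant": label,
                "peak_hz": peak_frequency(psd),
                "half_f_present": prof.half_f_present,
                "second_harmonic_present": prof.harmonics[1].present,
            })
    return summary


def _recipe_multi_node(recipe, cfg, out: Path) -> dict:
    from dataclasses import replace

    n_trials = _n_trials(recipe.scale, cfg)
    freq = 10.0
    stim = PeriodicStimulus(freq=freq)
    summary = {"input_hz": freq, "node_count": 3}
    for label, net in (("base", cfg.network),
                       ("in_suppressed", apply_in_suppression(cfg.network))):
        net3 = replace(net, node_count=3)
        avg = run_trials(net3, stim, n_trials=n_trials, base_seed=recipe.base_seed,
                         duration=cfg.run.duration_ms, dt=cfg.run.dt_ms)
        psd = analyze_output(avg)
        psd.to_csv(out / f"multinode_{label}_psd.csv")
        p_f0 = psd.power_at(freq)
        p_2f0 = psd.power_at(2 * freq)
        summary[label] = {
            "peak_hz": peak_frequency(psd),
            "power_f0": p_f0, "power_2f0": p_2f0,
            "f0_to_2f0_ratio": p_f0 / p_2f0 if p_2f0 > 0 else float("inf"),
        }
    return summary


def generate_fixtures(out_dir, seed: int = 0) -> list[Path]:
    """Write small reproducible input files: DVS event streams for a
    10/20/40 Hz flashing LED (12x12 pixels, 1 s), synthetic spike-train
    files, and a tiny two-neuron network config for unit tests.

    All outputs are text (tab-separated event streams, YAML); regeneration
    from the same seed is bit-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for freq in (10, 20, 40):
        ev = dvs_led_stimulus(freq, duration=1000.0, noise_seed=[seed, freq],
                              threshold_jitter=0.02)
        p = out / f"dvs_led_{freq}hz_12x12_synthetic.txt"
        ev.to_text(p)
        written.append(p)
    p = out / "periodic_20hz_144ch.txt"
    periodic_train(20.0, 1000.0, 144).to_text(p)
    written.append(p)
    p = out / "poisson_30hz_144ch.txt"
    poisson_trains(30.0, 1000.0, 144, seed=[seed, 30]).to_text(p)
    written.append(p)
    p = out / "tiny_network.yaml"
    with open(p, "w") as fh:
        fh.write(
            "# minimal network for unit tests: one TCR, one IN, two RET channels\n"
            "populations:\n"
            "  TCR: {size: 1}\n"
            "  IN: {size: 1}\n"
            "  TRN: {size: 1}\n"
            "  RET: {size: 2}\n"
            "projections:\n"
            "  RET->TCR: {p_conn: 1.0}\n"
            "  RET->IN: {p_conn: 1.0}\n"
            "run: {duration_ms: 500, n_trials: 2}\n"
        )
    written.append(p)
    return written
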