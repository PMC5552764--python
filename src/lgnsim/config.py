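"""Structured-text (YAML) configuration loading with full validation.

A run file overrides the shipped defaults; an empty file reproduces the base
model exactly.  Recognized top-level keys::

    variant: base | in_suppressed
    node_count: <int>
    populations: {TCR: {size: ..}, IN: {..}, TRN: {..}, RET: {size: ..}}
    projections: {"IN->TCR": {p_conn: .., w_syn: .., d_conn: ..}, ...}
    kinetics:   {tau_e: .., tau_i: ..}
    run:        {duration_ms: .., dt_ms: .., n_trials: .., base_seed: ..}
    analysis:   {epoch_ms: [..,..], fs_out: .., band: [..,..], order: ..,
                 seg_len: .., overlap: .., pad_factor: ..}

Errors name the offending field path.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import yaml

from .network import NetworkConfig, PopulationSpec, apply_in_suppression
from .neurons import SynapseKinetics


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RunSettings:
    duration_ms: float = 6000.0
    dt_ms: float = 0.1
    n_trials: int = 10
    base_seed: int = 0


@dataclass(frozen=True)
class AnalysisSettings:
    epoch_ms: tuple[float, float] = (500.0, 5500.0)
    fs_out: float = 1000.0
    band: tuple[float, float] = (1.0, 100.0)
    order: int = 10
    seg_len: int = 1000
    overlap: float = 0.5
    pad_factor: int = 4


@dataclass
class LoadedConfig:
    network: NetworkConfig
    run: RunSettings = field(default_factory=RunSettings)
    analysis: AnalysisSettings = field(default_factory=AnalysisSettings)

    def snapshot(self) -> dict:
        """JSON-serializable resolved-configuration snapshot."""
        net = {
            "variant": self.network.variant,
            "node_count": self.network.node_count,
            "populations": {
                role: {"size": spec.size} for role, spec in self.network.populations.items()
            },
            "projections": {
                f"{pre}->{post}": {
                    "p_conn": s.p_conn, "w_syn": s.w_syn,
                    "d_conn": s.d_conn, "sign": s.sign,
                }
                for (pre, post), s in sorted(self.network.projections.items())
            },
            "kinetics": {"tau_e": self.network.kinetics.tau_e,
                         "tau_i": self.network.kinetics.tau_i},
        }
        return {"network": net, "run": asdict(self.run), "analysis": asdict(self.analysis)}

    def write_snapshot(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.snapshot(), fh, indent=2)


def _require_keys(mapping: dict, allowed: set, path: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")


def _num(mapping: dict, key: str, path: str, lo=None, hi=None, lo_open=False):
    val = mapping[key]
    if not isinstance(val, (int, float)) or isinstance(val, bool):
        raise ConfigError(f"{path}.{key}: expected a number, got {val!r}")
    if lo is not None and (val <= lo if lo_open else val < lo):
        raise ConfigError(f"{path}.{key}: value {val} below allowed range")
    if hi is not None and val > hi:
        raise ConfigError(f"{path}.{key}: value {val} above allowed range")
    return val


def load_config(path=None, overrides: dict | None = None) -> LoadedConfig:
    """Merge a YAML override file (or dict) onto the shipped defaults."""
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
    if overrides:
        raw = {**raw, **overrides}

    _require_keys(raw, {"variant", "node_count", "populations", "projections",
                        "kinetics", "run", "analysis"}, "config")

    net = NetworkConfig.base()

    for role, row in (raw.get("populations") or {}).items():
        if role not in net.populations:
            raise ConfigError(f"config.populations.{role}: unknown population")
        _require_keys(row, {"size"}, f"config.populations.{role}")
        size = int(_num(row, "size", f"config.populations.{role}", lo=1))
        spec = net.populations[role]
        net.populations[role] = PopulationSpec(role=role, size=size, params=spec.params)

    for key, row in (raw.get("projections") or {}).items():
        try:
            pre, post = (s.strip() for s in key.split("->"))
        except ValueError:
            raise ConfigError(f"config.projections.{key}: malformed pathway key") from None
        if (pre, post) not in net.projections:
            raise ConfigError(f"config.projections.{key}: unknown pathway")
        _require_keys(row, {"p_conn", "w_syn", "d_conn"}, f"config.projections.{key}")
        changes = {}
        if "p_conn" in row:
            changes["p_conn"] = _num(row, "p_conn", f"config.projections.{key}",
                                     lo=0, hi=1, lo_open=True)
        if "w_syn" in row:
            changes["w_syn"] = _num(row, "w_syn", f"config.projections.{key}", lo=0,
                                    lo_open=True)
        if "d_conn" in row:
            changes["d_conn"] = _num(row, "d_conn", f"config.projections.{key}", lo=0,
                                     lo_open=True)
        try:
            net = net.replace_projection(pre, post, **changes)
        except ValueError as exc:
            raise ConfigError(f"config.projections.{key}: {exc}") from None

    if "kinetics" in raw:
        _require_keys(raw["kinetics"], {"tau_e", "tau_i"}, "config.kinetics")
        kin = dict(tau_e=net.kinetics.tau_e, tau_i=net.kinetics.tau_i)
        for k in raw["kinetics"]:
            kin[k] = _num(raw["kinetics"], k, "config.kinetics", lo=0, lo_open=True)
        net = replace(net, kinetics=SynapseKinetics(**kin))

    variant = raw.get("variant", "base")
    if variant not in ("base", "in_suppressed"):
        raise ConfigError(f"config.variant: must be 'base' or 'in_suppressed', got {variant!r}")
    if variant == "in_suppressed":
        net = apply_in_suppression(net)

    if "node_count" in raw:
        nc = int(_num(raw, "node_count", "config", lo=1))
        net = replace(net, node_count=nc)

    run = RunSettings()
    if "run" in raw:
        _require_keys(raw["run"], {"duration_ms", "dt_ms", "n_trials", "base_seed"},
                      "config.run")
        run = replace(run, **{
            k: (_num(raw["run"], k, "config.run", lo=0, lo_open=(k != "base_seed")))
            for k in raw["run"]
        })
        run = replace(run, n_trials=int(run.n_trials), base_seed=int(run.base_seed))

    analysis = AnalysisSettings()
    if "analysis" in raw:
        allowed = {"epoch_ms", "fs_out", "band", "order", "seg_len", "overlap",
                   "pad_factor"}
        _require_keys(raw["analysis"], allowed, "config.analysis")
        vals = dict(raw["analysis"])
        for k in ("epoch_ms", "band"):
            if k in vals:
                pair = vals[k]
                if not (isinstance(pair, (list, tuple)) and len(pair) == 2):
                    raise ConfigError(f"config.analysis.{k}: expected [lo, hi]")
                vals[k] = (float(pair[0]), float(pair[1]))
        analysis = replace(analysis, **vals)

    net.validate()
    return LoadedConfig(network=net, run=run, analysis=analysis)
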