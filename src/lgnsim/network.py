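"""Populations, probabilistic projections and network builders.

The basic building block is a 140-neuron model of the lateral geniculate
nucleus: 80 thalamo-cortical relay cells (TCR), 20 interneurons (IN) and 40
reticular-nucleus cells (TRN), in the 8:2:4 ratio, plus a 144-channel retinal
spike source (RET, one channel per pixel of a 12x12 sensor crop).  Seven
pathways connect them: RET excites TCR and IN; IN inhibits TCR (feed-forward
inhibition) and itself; TCR excites TRN; TRN inhibits TCR (feedback
inhibition) and itself.  There is no TCR->IN pathway and no cortical
feedback.

Connectivity is probabilistic: every ordered (pre, post) pair is wired
independently with the pathway's ``p_conn`` (Bernoulli, fixed-probability
connector semantics), autapses excluded within a population.  The
``in_suppressed`` variant weakens feed-forward inhibition (IN->TCR p=0.07,
w=1 nA) and hands the full 30.9% inhibitory budget to feedback (TRN->TCR
p=0.309), leaving everything else untouched.

A multi-node network tiles ``n`` copies of the block; between every ordered
pair of distinct nodes the TCR->TRN, TRN->TCR and TRN->TRN pathways are
replicated with their intra-node attributes (interneurons stay local).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml

from .neurons import IzhikevichParams, SynapseKinetics, tonic_presets

ROLES = ("TCR", "IN", "TRN", "RET")
EXCITATORY, INHIBITORY = "excitatory", "inhibitory"

#: Inter-node pathway rule: (pre_role, post_role) pairs replicated between
#: every ordered pair of distinct nodes, with intra-node attributes.
INTER_NODE_PATHWAYS = (("TCR", "TRN"), ("TRN", "TCR"), ("TRN", "TRN"))


@dataclass(frozen=True)
class PopulationSpec:
    role: str
    size: int
    params: IzhikevichParams | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown population role {self.role!r}")
        if self.size < 1:
            raise ValueError(f"population size must be >= 1, got {self.size}")
        if self.role != "RET" and self.params is None:
            raise ValueError(f"population {self.role} requires neuron parameters")


@dataclass(frozen=True)
class ProjectionSpec:
    """One pathway: probability, weight (nA), delay (ms) and sign."""

    pre: str
    post: str
    p_conn: float
    w_syn: float
    d_conn: float
    sign: str

    def __post_init__(self) -> None:
        if not (0.0 < self.p_conn <= 1.0):
            raise ValueError(
                f"{self.pre}->{self.post}: p_conn must lie in (0, 1], got {self.p_conn}"
            )
        if not self.w_syn > 0:
            raise ValueError(f"{self.pre}->{self.post}: w_syn must be positive")
        if not self.d_conn > 0:
            raise ValueError(f"{self.pre}->{self.post}: d_conn must be positive")
        if self.sign not in (EXCITATORY, INHIBITORY):
            raise ValueError(f"{self.pre}->{self.post}: unknown sign {self.sign!r}")


@dataclass
class EdgeList:
    """Realized sparse connections of one projection.

    ``delay_steps`` is ``round(d_conn / dt)`` and is always >= 1.
    """

    pre_index: np.ndarray
    post_index: np.ndarray
    weight: np.ndarray
    delay_steps: np.ndarray
    sign: str

    def __len__(self) -> int:
        return self.pre_index.size

    def to_tsv(self, path, dt: float = 0.1) -> None:
        """Write edges as tab-separated text (pre, post, weight, delay_ms, sign)."""
        with open(path, "w") as fh:
            fh.write("pre\tpost\tweight_nA\tdelay_ms\tsign\n")
            for p, q, w, ds in zip(
                self.pre_index, self.post_index, self.weight, self.delay_steps
            ):
                fh.write(f"{p}\t{q}\t{w:g}\t{ds * dt:g}\t{self.sign}\n")


def _default_tables():
    text = resources.files("lgnsim.data").joinpath("network_defaults.yaml").read_text()
    return yaml.safe_load(text)


def _parse_pathway_key(key: str):
    try:
        pre, post = key.split("->")
    except ValueError:
        raise ValueError(f"malformed pathway key {key!r}; expected 'PRE->POST'") from None
    return pre.strip(), post.strip()


@dataclass
class NetworkConfig:
    """Sizes, pathways, synapse kinetics and variant tag of a network build."""

    populations: dict[str, PopulationSpec]
    projections: dict[tuple[str, str], ProjectionSpec]
    kinetics: SynapseKinetics = field(default_factory=SynapseKinetics)
    variant: str = "base"
    node_count: int = 1

    @classmethod
    def base(cls) -> "NetworkConfig":
        """The base (feed-forward-inhibition dominant) configuration."""
        tables = _default_tables()
        presets = tonic_presets()
        pops = {}
        for role, row in tables["populations"].items():
            params = presets[row["preset"]] if "preset" in row else None
            pops[role] = PopulationSpec(role=role, size=row["size"], params=params)
        projs = {}
        for key, row in tables["projections"].items():
            pre, post = _parse_pathway_key(key)
            projs[(pre, post)] = ProjectionSpec(
                pre=pre, post=post, p_conn=row["p_conn"], w_syn=row["w_syn"],
                d_conn=row["d_conn"], sign=row["sign"],
            )
        kin = SynapseKinetics(**tables["kinetics"])
        return cls(populations=pops, projections=projs, kinetics=kin)

    def validate(self) -> None:
        allowed = set(_default_tables()["projections"])
        for (pre, post), spec in self.projections.items():
            if f"{pre}->{post}" not in allowed:
                raise ValueError(
                    f"unknown pathway {pre}->{post}: the LGN block has no such "
                    f"projection (in particular there is no TCR->IN feed)"
                )
            if pre not in self.populations or post not in self.populations:
                raise ValueError(f"pathway {pre}->{post} references unknown population")
            if spec.pre != pre or spec.post != post:
                raise ValueError(f"projection key {pre}->{post} disagrees with its spec")

    def replace_projection(self, pre: str, post: str, **changes) -> "NetworkConfig":
        projs = dict(self.projections)
        projs[(pre, post)] = replace(projs[(pre, post)], **changes)
        return replace(self, projections=projs)


def apply_in_suppression(config: NetworkConfig) -> NetworkConfig:
    """Switch to the feedback-dominant variant.

    Sets IN->TCR to (p=0.07, w=1 nA) and TRN->TCR to p=0.309; delays, signs
    and all other pathways are untouched.  Idempotent: applying to an already
    suppressed config warns and returns it unchanged.
    """
    if config.variant == "in_suppressed":
        warnings.warn("configuration is already IN-suppressed; no change applied")
        return config
    overrides = _default_tables()["in_suppressed_overrides"]
    out = config
    for key, row in overrides.items():
        pre, post = _parse_pathway_key(key)
        out = out.replace_projection(pre, post, **row)
    return replace(out, variant="in_suppressed")


def realize_projection(
    spec: ProjectionSpec,
    n_pre: int,
    n_post: int,
    rng_seed,
    dt: float = 0.1,
    same_population: bool = False,
) -> EdgeList:
    """Draw one Bernoulli realization of a projection.

    Every ordered (pre, post) pair is included independently with probability
    ``p_conn``; the diagonal is excluded when pre and post are the same
    population.  Deterministic given the seed.
    """
    if n_pre < 1 or n_post < 1:
        raise ValueError("population sizes must be >= 1")
    rng = np.random.default_rng(rng_seed)
    mask = rng.random((n_pre, n_post)) < spec.p_conn
    if same_population:
        np.fill_diagonal(mask, False)
    pre_idx, post_idx = np.nonzero(mask)
    delay_steps = max(1, int(round(spec.d_conn / dt)))
    n = pre_idx.size
    return EdgeList(
        pre_index=pre_idx.astype(np.int64),
        post_index=post_idx.astype(np.int64),
        weight=np.full(n, float(spec.w_syn)),
        delay_steps=np.full(n, delay_steps, dtype=np.int64),
        sign=spec.sign,
    )


@dataclass(frozen=True)
class Population:
    """A placed population: global index range [start, start+size)."""

    name: str
    role: str
    node: int
    start: int
    size: int
    params: IzhikevichParams | None


class Network:
    """A realized network: placed populations plus drawn edge lists.

    Neuron populations (TCR/IN/TRN per node) occupy a single global index
    space; RET channels live in their own per-node channel space and drive
    the network through the RET->TCR and RET->IN edges.  The external
    stimulus has one logical channel per RET channel index and is broadcast
    to the RET copy of every node.
    """

    def __init__(self, config: NetworkConfig, seed: int, dt: float = 0.1):
        config.validate()
        self.config = config
        self.seed = int(seed)
        self.dt = float(dt)
        self.node_count = config.node_count
        self.populations: dict[str, Population] = {}
        self.edges: dict[tuple[str, str], EdgeList] = {}

        offset = 0
        for node in range(self.node_count):
            for role in ("TCR", "IN", "TRN"):
                spec = config.populations[role]
                name = self._pop_name(role, node)
                self.populations[name] = Population(
                    name=name, role=role, node=node, start=offset,
                    size=spec.size, params=spec.params,
                )
                offset += spec.size
        self.n_neurons = offset
        self.n_stim_channels = config.populations["RET"].size

        self._realize()

    def _pop_name(self, role: str, node: int) -> str:
        return role if self.node_count == 1 else f"{role}{node + 1}"

    @staticmethod
    def _pathway_seed(base_seed: int, node_pre: int, node_post: int, tag: int):
        # Stable derivation so node 0 of a multi-node build draws the same
        # intra-node wiring as a single-node build with the same seed.
        return [int(base_seed), node_pre, node_post, tag]

    def _realize(self) -> None:
        cfg = self.config
        pathway_tags = {key: i for i, key in enumerate(sorted(cfg.projections))}
        # intra-node projections
        for node in range(self.node_count):
            for (pre, post), spec in sorted(cfg.projections.items()):
                n_pre = cfg.populations[pre].size
                n_post = cfg.populations[post].size
                el = realize_projection(
                    spec, n_pre, n_post,
                    self._pathway_seed(self.seed, node, node, pathway_tags[(pre, post)]),
                    dt=self.dt, same_population=(pre == post),
                )
                pre_name = self._pop_name(pre, node)
                post_name = self._pop_name(post, node)
                self.edges[(pre_name, post_name)] = el
        # inter-node projections
        tag0 = len(pathway_tags)
        for i in range(self.node_count):
            for j in range(self.node_count):
                if i == j:
                    continue
                for k, (pre, post) in enumerate(INTER_NODE_PATHWAYS):
                    spec = cfg.projections[(pre, post)]
                    el = realize_projection(
                        spec, cfg.populations[pre].size, cfg.populations[post].size,
                        self._pathway_seed(self.seed, i, j, tag0 + k),
                        dt=self.dt, same_population=False,
                    )
                    self.edges[(self._pop_name(pre, i), self._pop_name(post, j))] = el

    # -- flattened views used by the engine ---------------------------------

    def population_names(self) -> list[str]:
        return list(self.populations)

    def neuron_edge_arrays(self):
        """Concatenated neuron->neuron edges in global indices."""
        pre, post, w, dly, inh = [], [], [], [], []
        for (pre_name, post_name), el in self.edges.items():
            if pre_name.startswith("RET"):
                continue
            p_pre = self.populations[pre_name]
            p_post = self.populations[post_name]
            pre.append(el.pre_index + p_pre.start)
            post.append(el.post_index + p_post.start)
            w.append(el.weight)
            dly.append(el.delay_steps)
            inh.append(np.full(len(el), el.sign == INHIBITORY, dtype=bool))
        if not pre:
            z = np.zeros(0, dtype=np.int64)
            return z, z, np.zeros(0), z, np.zeros(0, dtype=bool)
        return (
            np.concatenate(pre), np.concatenate(post), np.concatenate(w),
            np.concatenate(dly), np.concatenate(inh),
        )

    def stimulus_edge_arrays(self):
        """Concatenated stimulus edges: (channel, post_global, weight, delay_steps).

        Channel indices are RET channel indices (shared across nodes); all
        stimulus pathways are excitatory.
        """
        chan, post, w, dly = [], [], [], []
        for (pre_name, post_name), el in self.edges.items():
            if not pre_name.startswith("RET"):
                continue
            p_post = self.populations[post_name]
            chan.append(el.pre_index)
            post.append(el.post_index + p_post.start)
            w.append(el.weight)
            dly.append(el.delay_steps)
        if not chan:
            z = np.zeros(0, dtype=np.int64)
            return z, z, np.zeros(0), z
        return (
            np.concatenate(chan), np.concatenate(post),
            np.concatenate(w), np.concatenate(dly),
        )

    def neuron_param_arrays(self):
        """Per-neuron a, b, c, d, i_dc, v0, u0 arrays in global order."""
        n = self.n_neurons
        a = np.empty(n); b = np.empty(n); c = np.empty(n); d = np.empty(n)
        idc = np.empty(n); v0 = np.empty(n); u0 = np.empty(n)
        for pop in self.populations.values():
            s = slice(pop.start, pop.start + pop.size)
            p = pop.params
            a[s], b[s], c[s], d[s] = p.a, p.b, p.c, p.d
            idc[s], v0[s], u0[s] = p.i_dc, p.v_init, p.u_init
        return a, b, c, d, idc, v0, u0


def build_lgn(config: NetworkConfig | None = None, seed: int = 0, dt: float = 0.1) -> Network:
    """Build (and realize) the single-node 140-neuron LGN block.

    Neuron populations use the tonic presets with zero bias current: once the
    network is wired, all drive comes from the retinal stimulus.
    """
    if config is None:
        config = NetworkConfig.base()
    if config.node_count != 1:
        config = replace(config, node_count=1)
    return Network(config, seed=seed, dt=dt)


def build_multi_node(
    config: NetworkConfig | None = None,
    n_nodes: int = 3,
    seed: int = 0,
    dt: float = 0.1,
) -> Network:
    """Build the scaled architecture: ``n_nodes`` LGN blocks, fully coupled.

    Between every ordered pair of distinct nodes, TCR->TRN (excitatory),
    TRN->TCR and TRN->TRN (inhibitory) are replicated with intra-node
    attributes; interneurons make no inter-node synapses.  Nodes are treated
    as equidistant, so inter-node delays equal intra-node delays.
    """
    if n_nodes < 2:
        raise ValueError("a multi-node build requires n_nodes >= 2")
    if config is None:
        config = NetworkConfig.base()
    config = replace(config, node_count=n_nodes)
    return Network(config, seed=seed, dt=dt)
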