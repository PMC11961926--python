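"""Construction of the four-group excitatory/inhibitory network.

Builds heterogeneous networks (neuron and synapse parameters drawn from
truncated Gaussians around biology-informed means) and homogeneous control
networks (uniform draws around shared means, no cell-type distinction), with
block-structured Bernoulli connectivity: within-group excitatory coupling is
stronger than between-group coupling, and cross-group inhibition is the
competition mechanism that limits how many groups can stay active at once.

Connection probabilities and weight means are shipped as documented stand-ins
(the in-vivo tables they emulate are configuration, not code) and are fully
replaceable through :class:`NetworkConfig`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import (
    DendriteNonlinearity,
    NeuronParams,
    SpineCounts,
    SynapseParams,
    effective_synapse_counts,
)

__all__ = ["Connectivity", "NetworkConfig", "Network", "build_network",
           "scale_connections", "write_network", "read_network", "networks_equal"]

# named RNG streams so sweeps can share a network realization
_STREAM_CONNECTIVITY = 101
_STREAM_HETEROGENEITY = 202

_BLOCKS = ("EE", "IE", "EI", "II")  # pre-post order: "IE" = I -> E


@dataclass(frozen=True)
class Connectivity:
    """Block connection probabilities and weight means.

    Naming is pre->post: ``ie`` is inhibitory-to-excitatory. Within-group E-E
    coupling must exceed between-group coupling (the selectivity structure);
    cross-group I->E is denser than within-group I->E, with a net cross-group
    inhibitory drive (p x w) slightly above the within-group one, so that
    active groups suppress the others (the capacity-limiting competition).
    """

    p_ee_within: float = 0.35
    p_ee_between: float = 0.10
    p_ei_within: float = 0.40
    p_ei_between: float = 0.10
    p_ie_within: float = 0.25
    p_ie_between: float = 0.45
    p_ii_within: float = 0.30
    p_ii_between: float = 0.20
    w_ee_within: float = 1.0
    w_ee_between: float = 0.25
    w_ei_within: float = 1.0
    w_ei_between: float = 0.25
    w_ie_within: float = 0.8
    w_ie_between: float = 0.5
    w_ii_within: float = 1.0
    w_ii_between: float = 0.8

    def __post_init__(self):
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name.startswith("p_") and not 0.0 <= v <= 1.0:
                raise ValueError(f"{f.name} must lie in [0, 1]")
            if f.name.startswith("w_") and v < 0:
                raise ValueError(f"{f.name} must be non-negative")
        if self.w_ee_within <= self.w_ee_between:
            raise ValueError("within-group E-E weight must exceed between-group")

    def prob(self, pre_type: str, post_type: str, same_group: bool) -> float:
        return getattr(self, f"p_{pre_type.lower()}{post_type.lower()}_{'within' if same_group else 'between'}")

    def weight(self, pre_type: str, post_type: str, same_group: bool) -> float:
        return getattr(self, f"w_{pre_type.lower()}{post_type.lower()}_{'within' if same_group else 'between'}")


# parameters that heterogeneity / homogeneous uniform draws may perturb
# (strictly positive quantities only; potentials stay at their means so the
# reset<=threshold invariant and the V=V_L zero-current property hold exactly)
_HET_NEURON_FIELDS = ("C_m", "g_L")
_HET_SYNAPSE_FIELDS = ("g_AMPA_ext", "g_AMPA_rec", "g_NMDA_rec", "g_GABA",
                       "tau_AMPA", "tau_NMDA", "tau_GABA")


@dataclass(frozen=True)
class NetworkConfig:
    """Everything needed to realize a network.

    ``mode`` selects the parameter-assignment scheme: ``heterogeneous`` draws
    each perturbable parameter from a truncated Gaussian with coefficient of
    variation ``heterogeneity[field]`` (falling back to ``default_cv``);
    ``homogeneous`` draws uniformly within ``+-uniform_band`` around the
    excitatory means for every neuron, with no cell-type distinction.
    """

    n_groups: int = 4
    n_exc_per_group: int = 80
    n_inh_per_group: int = 20
    connectivity: Connectivity = field(default_factory=Connectivity)
    exc_neuron: NeuronParams = field(default_factory=lambda: NeuronParams(
        C_m=200.0, g_L=10.0, V_L=-70.0, V_th=-50.0, V_reset=-60.0, t_ref=2.0,
        is_excitatory=True))
    inh_neuron: NeuronParams = field(default_factory=lambda: NeuronParams(
        C_m=100.0, g_L=8.0, V_L=-70.0, V_th=-50.0, V_reset=-58.0, t_ref=1.0,
        is_excitatory=False))
    synapse: SynapseParams = field(default_factory=SynapseParams)
    inh_synapse: SynapseParams | None = field(
        default_factory=lambda: SynapseParams(g_AMPA_rec=0.008))
    spine_counts: SpineCounts = field(default_factory=SpineCounts)
    dendrite: DendriteNonlinearity = field(default_factory=DendriteNonlinearity)
    I_bg_exc: float = 120.0  # constant background current to E somata, pA
    I_bg_inh: float = 70.0  # constant background current to I somata, pA
    mode: str = "heterogeneous"
    default_cv: float = 0.25
    heterogeneity: dict = field(default_factory=dict)  # field name -> cv
    weight_cv: float = 0.25
    uniform_band: float = 0.20

    def __post_init__(self):
        if self.mode not in ("heterogeneous", "homogeneous"):
            raise ValueError("mode must be 'heterogeneous' or 'homogeneous'")
        if min(self.n_groups, self.n_exc_per_group) < 1 or self.n_inh_per_group < 0:
            raise ValueError("impossible group shape")

    @property
    def n_neurons(self) -> int:
        return self.n_groups * (self.n_exc_per_group + self.n_inh_per_group)


@dataclass(frozen=True)
class Network:
    """A realized network: labels, weights and per-neuron parameters.

    ``W`` is (post x pre); a zero entry means no synapse. Columns of an
    excitatory neuron feed AMPA/NMDA gating only, columns of an inhibitory
    neuron GABA only (Dale's principle, enforced by construction — the
    receptor a presynaptic neuron drives is determined by ``is_exc``).
    """

    group_of: np.ndarray  # (n,) int
    is_exc: np.ndarray  # (n,) bool
    W: np.ndarray  # (n, n) float, post x pre
    neuron_params: NeuronParams  # array-valued
    syn_params: SynapseParams  # array-valued, per neuron
    mu_NMDA: np.ndarray  # (n,) receptor multipliers per postsynaptic neuron
    mu_AMPA: np.ndarray
    mu_GABA: np.ndarray
    I_bg: np.ndarray  # (n,) pA
    spine_counts: SpineCounts
    dendrite: DendriteNonlinearity
    mode: str
    seed: int
    applied_condition: str | None = None

    @property
    def n_neurons(self) -> int:
        return self.group_of.size

    @property
    def n_groups(self) -> int:
        return int(self.group_of.max()) + 1


def _truncated_gaussian(rng, mean, cv, size):
    """Gaussian(mean, cv*mean) truncated below at 5% of the mean (resampled)."""
    mean = float(mean)
    if mean == 0.0 or cv == 0.0:
        return np.full(size, mean)
    sd = abs(mean) * cv
    out = rng.normal(mean, sd, size)
    floor = 0.05 * abs(mean)
    bad = out < floor
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out < floor
    return out


def _draw_params(cfg: NetworkConfig, is_exc: np.ndarray, rng) -> tuple[NeuronParams, SynapseParams]:
    n = is_exc.size

    def per_neuron(field_name, exc_val, inh_val, perturb):
        base = np.where(is_exc, float(exc_val), float(inh_val))
        if not perturb:
            return base
        if cfg.mode == "homogeneous":
            # no type distinction: shared excitatory mean, uniform band
            m = float(exc_val)
            return rng.uniform(m * (1 - cfg.uniform_band), m * (1 + cfg.uniform_band), n)
        cv = cfg.heterogeneity.get(field_name, cfg.default_cv)
        out = np.empty(n)
        for mask, mean in ((is_exc, exc_val), (~is_exc, inh_val)):
            out[mask] = _truncated_gaussian(rng, mean, cv, int(mask.sum()))
        return out

    nkw = {}
    for f in dataclasses.fields(NeuronParams):
        if f.name == "is_excitatory":
            continue
        nkw[f.name] = per_neuron(f.name, getattr(cfg.exc_neuron, f.name),
                                 getattr(cfg.inh_neuron, f.name),
                                 f.name in _HET_NEURON_FIELDS)
    np_arrays = NeuronParams(is_excitatory=is_exc.copy(), **nkw)

    inh_syn = cfg.inh_synapse if cfg.inh_synapse is not None else cfg.synapse
    skw = {}
    for f in dataclasses.fields(SynapseParams):
        skw[f.name] = per_neuron(f.name, getattr(cfg.synapse, f.name),
                                 getattr(inh_syn, f.name),
                                 f.name in _HET_SYNAPSE_FIELDS)
    sp_arrays = SynapseParams(**skw)
    return np_arrays, sp_arrays


def build_network(cfg: NetworkConfig, seed: int = 0) -> Network:
    """Realize a network from a configuration, deterministically per seed.

    Uses separate named RNG streams for connectivity and parameter
    heterogeneity so that the same seed yields the same wiring even if the
    heterogeneity scheme changes.
    """
    conn_rng = np.random.default_rng([seed, _STREAM_CONNECTIVITY])
    het_rng = np.random.default_rng([seed, _STREAM_HETEROGENEITY])

    n_per = cfg.n_exc_per_group + cfg.n_inh_per_group
    n = cfg.n_neurons
    group_of = np.repeat(np.arange(cfg.n_groups), n_per)
    within = np.arange(n) % n_per
    is_exc = within < cfg.n_exc_per_group

    same = group_of[:, None] == group_of[None, :]
    pre_e = is_exc[None, :]
    post_e = is_exc[:, None]
    c = cfg.connectivity
    P = np.empty((n, n))
    Wm = np.empty((n, n))
    for pre_t, pre_mask in (("e", pre_e), ("i", ~pre_e)):
        for post_t, post_mask in (("e", post_e), ("i", ~post_e)):
            for sg, sg_mask in ((True, same), (False, ~same)):
                m = pre_mask & post_mask & sg_mask
                P[m] = c.prob(pre_t, post_t, sg)
                Wm[m] = c.weight(pre_t, post_t, sg)

    mask = conn_rng.random((n, n)) < P
    np.fill_diagonal(mask, False)
    if cfg.mode == "homogeneous":
        W = np.where(mask, Wm * conn_rng.uniform(1 - cfg.uniform_band,
                                                 1 + cfg.uniform_band, (n, n)), 0.0)
    else:
        jitter = np.clip(conn_rng.normal(1.0, cfg.weight_cv, (n, n)), 0.05, None)
        W = np.where(mask, Wm * jitter, 0.0)

    neuron_params, syn_params = _draw_params(cfg, is_exc, het_rng)
    mu = effective_synapse_counts(cfg.spine_counts)
    mu_NMDA = np.where(is_exc, mu.mu_e_NMDA, mu.mu_i_NMDA).astype(float)
    mu_AMPA = np.where(is_exc, mu.mu_e_AMPA, mu.mu_i_AMPA).astype(float)
    mu_GABA = np.where(is_exc, mu.mu_e_GABA, mu.mu_i_GABA).astype(float)
    I_bg = np.where(is_exc, cfg.I_bg_exc, cfg.I_bg_inh).astype(float)

    return Network(
        group_of=group_of, is_exc=is_exc, W=W,
        neuron_params=neuron_params, syn_params=syn_params,
        mu_NMDA=mu_NMDA, mu_AMPA=mu_AMPA, mu_GABA=mu_GABA,
        I_bg=I_bg, spine_counts=cfg.spine_counts, dendrite=cfg.dendrite,
        mode=cfg.mode, seed=seed,
    )


def _block_mask(net: Network, which: str) -> np.ndarray:
    """Boolean mask of within-group entries of the named pre->post block."""
    if which not in _BLOCKS:
        raise ValueError(f"unknown block {which!r}; expected one of {_BLOCKS}")
    pre_t, post_t = which[0], which[1]
    pre_mask = net.is_exc[None, :] if pre_t == "E" else ~net.is_exc[None, :]
    post_mask = net.is_exc[:, None] if post_t == "E" else ~net.is_exc[:, None]
    same = net.group_of[:, None] == net.group_of[None, :]
    return pre_mask & post_mask & same


def scale_connections(net: Network, which: str, factor: float) -> Network:
    """Multiply within-group weights of one connection block by ``factor``.

    ``which`` is pre->post: "EE", "IE", "EI" or "II". Only within-group
    entries change; all other weights are untouched. Composable: scaling by
    a then b equals scaling by a*b.
    """
    if factor < 0:
        raise ValueError("factor must be non-negative")
    m = _block_mask(net, which)
    W = net.W.copy()
    W[m] *= factor
    return replace(net, W=W)


# ---------------------------------------------------------------------------
# serialization: neuron table + edge list, exact round trip
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.17g"


def write_network(net: Network, directory: str | Path) -> None:
    """Write a network as text: neurons.tsv, edges.tsv and meta.json."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)

    cols = {"neuron": np.arange(net.n_neurons),
            "group": net.group_of, "is_exc": net.is_exc.astype(int)}
    for f in dataclasses.fields(NeuronParams):
        if f.name == "is_excitatory":
            continue
        cols[f"np_{f.name}"] = np.broadcast_to(
            np.asarray(getattr(net.neuron_params, f.name), dtype=float), (net.n_neurons,))
    for f in dataclasses.fields(SynapseParams):
        cols[f"sp_{f.name}"] = np.broadcast_to(
            np.asarray(getattr(net.syn_params, f.name), dtype=float), (net.n_neurons,))
    for name in ("mu_NMDA", "mu_AMPA", "mu_GABA", "I_bg"):
        cols[name] = getattr(net, name)
    pd.DataFrame(cols).to_csv(d / "neurons.tsv", sep="\t", index=False,
                              float_format=_FLOAT_FMT)

    post, pre = np.nonzero(net.W)
    pd.DataFrame({"pre": pre, "post": post, "weight": net.W[post, pre],
                  "type": np.where(net.is_exc[pre], "E", "I")}).to_csv(
        d / "edges.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)

    meta = {
        "spine_counts": dataclasses.asdict(net.spine_counts),
        "dendrite": dataclasses.asdict(net.dendrite),
        "mode": net.mode, "seed": net.seed,
        "applied_condition": net.applied_condition,
        "n_neurons": net.n_neurons,
    }
    (d / "meta.json").write_text(json.dumps(meta, indent=1))


def read_network(directory: str | Path) -> Network:
    """Read a network written by :func:`write_network` (exact round trip)."""
    d = Path(directory)
    meta = json.loads((d / "meta.json").read_text())
    neurons = pd.read_csv(d / "neurons.tsv", sep="\t", float_precision="round_trip")
    edges = pd.read_csv(d / "edges.tsv", sep="\t", float_precision="round_trip")
    n = meta["n_neurons"]

    is_exc = neurons["is_exc"].to_numpy().astype(bool)
    nkw = {f.name: neurons[f"np_{f.name}"].to_numpy()
           for f in dataclasses.fields(NeuronParams) if f.name != "is_excitatory"}
    skw = {f.name: neurons[f"sp_{f.name}"].to_numpy()
           for f in dataclasses.fields(SynapseParams)}
    W = np.zeros((n, n))
    W[edges["post"].to_numpy(), edges["pre"].to_numpy()] = edges["weight"].to_numpy()

    return Network(
        group_of=neurons["group"].to_numpy(),
        is_exc=is_exc, W=W,
        neuron_params=NeuronParams(is_excitatory=is_exc, **nkw),
        syn_params=SynapseParams(**skw),
        mu_NMDA=neurons["mu_NMDA"].to_numpy(),
        mu_AMPA=neurons["mu_AMPA"].to_numpy(),
        mu_GABA=neurons["mu_GABA"].to_numpy(),
        I_bg=neurons["I_bg"].to_numpy(),
        spine_counts=SpineCounts(**meta["spine_counts"]),
        dendrite=DendriteNonlinearity(**meta["dendrite"]),
        mode=meta["mode"], seed=meta["seed"],
        applied_condition=meta["applied_condition"],
    )


def networks_equal(a: Network, b: Network) -> bool:
    """Bitwise equality of labels, weights and per-neuron parameters."""
    if not (np.array_equal(a.group_of, b.group_of)
            and np.array_equal(a.is_exc, b.is_exc)
            and np.array_equal(a.W, b.W)):
        return False
    for f in dataclasses.fields(NeuronParams):
        if not np.array_equal(np.asarray(getattr(a.neuron_params, f.name)),
                              np.asarray(getattr(b.neuron_params, f.name))):
            return False
    for f in dataclasses.fields(SynapseParams):
        if not np.array_equal(np.asarray(getattr(a.syn_params, f.name)),
                              np.asarray(getattr(b.syn_params, f.name))):
            return False
    for name in ("mu_NMDA", "mu_AMPA", "mu_GABA", "I_bg"):
        if not np.array_equal(getattr(a, name), getattr(b, name)):
            return False
    return a.spine_counts == b.spine_counts and a.dendrite == b.dendrite
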