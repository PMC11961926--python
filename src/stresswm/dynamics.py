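"""Equations of motion for the two-compartment integrate-and-fire network.

This module holds the pure dynamical primitives: the leaky integrate-and-fire
membrane update, AMPA/NMDA/GABA synaptic currents, the dendrite-to-soma
transfer nonlinearity, the mapping from dendritic-spine counts to effective
synapse counts, and short-term synaptic plasticity (facilitation via the
utilization variable ``u``, depression via the resource variable ``x``).

All functions are written for numpy broadcasting: every field of the state
and parameter dataclasses may be a scalar or a per-neuron array, so the same
code serves both single-synapse unit tests and the vectorized simulation
engine.

Sign convention
---------------
Every current function returns the conductance form ``g * (V - V_rev) * drive``
with a common reversal potential equal to the resting potential, so all
synaptic currents vanish identically at ``V = V_rev``. Excitatory and
inhibitory currents therefore come out with the same sign; the simulation
engine feeds GABA into the total-current sum with a negative sign (a single
signed-sum adapter) so that excitatory drive depolarizes the membrane and
inhibition hyperpolarizes it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SimulationError",
    "NeuronParams",
    "NeuronState",
    "SynapseParams",
    "SynapseState",
    "SpineCounts",
    "EffectiveSynapseCounts",
    "DendriteNonlinearity",
    "StressScaling",
    "CurrentComponents",
    "effective_synapse_counts",
    "stp_step",
    "nmda_current",
    "ampa_current_ext",
    "ampa_current_rec",
    "gaba_current",
    "dendrite_to_soma",
    "total_current",
    "membrane_step",
]


class SimulationError(RuntimeError):
    """Raised when the integration produces a non-finite membrane state."""


def _all(x) -> bool:
    return bool(np.all(x))


@dataclass(frozen=True)
class NeuronParams:
    """Integrate-and-fire membrane parameters.

    The membrane obeys ``C_m dV/dt = -g_L (V - V_L) + I_drive`` with a hard
    threshold ``V_th``, reset ``V_reset`` and absolute refractory period
    ``t_ref``. The subthreshold equation does not itself fix the spiking
    mechanism, so threshold/reset/refractory values are configuration with
    conventional cortical defaults.
    """

    C_m: float | np.ndarray = 200.0  # membrane capacitance, pF
    g_L: float | np.ndarray = 10.0  # leak conductance, nS
    V_L: float | np.ndarray = -70.0  # resting / reversal potential, mV
    V_th: float | np.ndarray = -50.0  # spike threshold, mV
    V_reset: float | np.ndarray = -60.0  # post-spike reset, mV
    t_ref: float | np.ndarray = 2.0  # absolute refractory period, ms
    is_excitatory: bool | np.ndarray = True

    def __post_init__(self):
        if not _all(np.asarray(self.C_m) > 0):
            raise ValueError("C_m must be positive")
        if not _all(np.asarray(self.g_L) > 0):
            raise ValueError("g_L must be positive")
        if not _all(np.asarray(self.V_reset) <= np.asarray(self.V_th)):
            raise ValueError("V_reset must not exceed V_th")
        if not _all(np.asarray(self.t_ref) >= 0):
            raise ValueError("t_ref must be non-negative")


@dataclass(frozen=True)
class NeuronState:
    """Per-neuron membrane state (somatic and dendritic compartment)."""

    V_soma: float | np.ndarray = -70.0  # mV
    V_dend: float | np.ndarray = -70.0  # mV
    refractory_until: float | np.ndarray = -np.inf  # absolute time, ms
    spiked: bool | np.ndarray = False


@dataclass(frozen=True)
class SynapseParams:
    """Receptor conductances, kinetics and short-term-plasticity constants.

    ``gamma_mg``/``beta_mg`` parametrize the NMDA magnesium-block voltage
    dependence ``1 / (1 + gamma_mg * exp(-beta_mg * V))`` (values for 1 mM
    extracellular Mg2+). ``gamma_AMPA``/``gamma_NMDA``/``gamma_I`` are the
    fractional channel strengths (gating-increment factors) that the stress
    sweeps vary. ``U``, ``tau_u``, ``tau_x`` are the facilitation/depression
    constants of the short-term plasticity model.
    """

    g_AMPA_ext: float | np.ndarray = 1.3  # nS
    g_AMPA_rec: float | np.ndarray = 0.03  # nS
    g_NMDA_rec: float | np.ndarray = 0.20  # nS
    g_GABA: float | np.ndarray = 0.50  # nS
    gamma_mg: float | np.ndarray = 0.2801  # [Mg]/3.57 at 1 mM
    beta_mg: float | np.ndarray = 0.062  # 1/mV
    tau_AMPA: float | np.ndarray = 2.0  # ms
    tau_NMDA: float | np.ndarray = 100.0  # ms
    tau_GABA: float | np.ndarray = 5.0  # ms
    gamma_AMPA: float | np.ndarray = 1.0
    gamma_NMDA: float | np.ndarray = 1.0
    gamma_I: float | np.ndarray = 1.0
    U: float | np.ndarray = 0.15  # baseline utilization
    tau_u: float | np.ndarray = 1500.0  # facilitation time constant, ms
    tau_x: float | np.ndarray = 2.0  # depression recovery time constant, ms

    def __post_init__(self):
        for name in ("tau_AMPA", "tau_NMDA", "tau_GABA", "tau_u", "tau_x"):
            if not _all(np.asarray(getattr(self, name)) > 0):
                raise ValueError(f"{name} must be positive")
        U = np.asarray(self.U)
        if not (_all(U > 0) and _all(U <= 1)):
            raise ValueError("U must lie in (0, 1]")


def default_synapse_state(p: SynapseParams, n: int | None = None) -> "SynapseState":
    """Resting synapse state: closed channels, u at baseline U, full resources."""
    if n is None:
        return SynapseState(u=np.asarray(p.U).item() if np.ndim(p.U) == 0 else np.array(p.U))
    z = np.zeros(n)
    return SynapseState(
        s_AMPA=z.copy(), s_NMDA=z.copy(), s_GABA=z.copy(),
        u=np.broadcast_to(np.asarray(p.U, dtype=float), (n,)).copy(),
        x=np.ones(n),
    )


@dataclass(frozen=True)
class SynapseState:
    """Per-presynaptic-neuron gating fractions and STP variables."""

    s_AMPA: float | np.ndarray = 0.0
    s_NMDA: float | np.ndarray = 0.0
    s_GABA: float | np.ndarray = 0.0
    u: float | np.ndarray = 0.15  # utilization (facilitation)
    x: float | np.ndarray = 1.0  # available resources (depression)


@dataclass(frozen=True)
class SpineCounts:
    """Mean dendritic-spine counts and inhibitory input fractions by cell class.

    ``EXN`` is the average spine count of excitatory neurons; ``BP``/``MP`` of
    bipolar and multipolar interneurons. The ``*_IN`` fields are the estimated
    inhibitory input fractions i/(i+e) on the dendrites of each class. ``fac``
    is the fractional loss of excitatory spines under chronic stress (0.16 in
    chronic stress, 0 otherwise). The count defaults are documented stand-ins
    for anatomical measurements; they are configuration, not constants.
    """

    EXN: float = 100.0
    BP: float = 40.0
    MP: float = 60.0
    EXN_IN: float = 0.2
    BP_IN: float = 0.35
    MP_IN: float = 0.25
    fac: float = 0.0

    def __post_init__(self):
        if min(self.EXN, self.BP, self.MP) < 0:
            raise ValueError("spine counts must be non-negative")
        for name in ("EXN_IN", "BP_IN", "MP_IN", "fac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class EffectiveSynapseCounts:
    """Per-neuron receptor multipliers derived from spine counts."""

    mu_e_NMDA: float
    mu_e_AMPA: float
    mu_e_GABA: float
    mu_i_NMDA: float
    mu_i_AMPA: float
    mu_i_GABA: float


@dataclass(frozen=True)
class DendriteNonlinearity:
    """Shape constants of the saturating dendrite-to-soma current transfer.

    ``I_soma = c1 * tanh((I_exc + c3*I_inh + c4) / (c5 * exp(-I_inh/c6))) + c2``

    c1 sets the gain (output bounded in [c2-|c1|, c2+|c1|]), c2 the offset,
    c3 how dendritic inhibition shifts the transfer, c4 the inflection point,
    c5 the input scale and c6 how inhibition rescales that input scale.
    Units: inputs in pA, output in pA.
    """

    c1: float = 60.0
    c2: float = 0.0
    c3: float = -0.5
    c4: float = -40.0
    c5: float = 250.0
    c6: float = 500.0

    def __post_init__(self):
        if self.c5 <= 0 or self.c6 <= 0:
            raise ValueError("c5 and c6 must be positive")


@dataclass(frozen=True)
class StressScaling:
    """Multiplicative stress transforms applied to the dynamics.

    ``beta_NMDA``/``beta_AMPA`` are the acute-stress current multipliers
    (stressed EPSC / control EPSC). ``gamma_I_scale`` rescales the GABA
    gating increment under chronic stress. The ``*_scale`` factors rescale
    within-group connection blocks. The control condition is the identity:
    all factors 1.
    """

    beta_NMDA: float = 1.0
    beta_AMPA: float = 1.0
    gamma_I_scale: float = 1.0
    ee_scale: float = 1.0
    ie_scale: float = 1.0
    ei_scale: float = 1.0
    ii_scale: float = 1.0

    def __post_init__(self):
        for name in ("beta_NMDA", "beta_AMPA", "gamma_I_scale",
                     "ee_scale", "ie_scale", "ei_scale", "ii_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def is_identity(self) -> bool:
        return all(
            getattr(self, name) == 1.0
            for name in ("beta_NMDA", "beta_AMPA", "gamma_I_scale",
                         "ee_scale", "ie_scale", "ei_scale", "ii_scale")
        )


@dataclass(frozen=True)
class CurrentComponents:
    """The six components of the total somatic current, signed for Eq-of-motion.

    ``gaba`` must already carry the hyperpolarizing (negative) sign; the other
    components are depolarizing-positive.
    """

    nmda_rec: float | np.ndarray = 0.0
    ampa_ext: float | np.ndarray = 0.0
    ampa_rec: float | np.ndarray = 0.0
    gaba: float | np.ndarray = 0.0
    soma_dend: float | np.ndarray = 0.0
    background: float | np.ndarray = 0.0


# ---------------------------------------------------------------------------
# spine counts -> effective synapse counts
# ---------------------------------------------------------------------------

def effective_synapse_counts(sc: SpineCounts) -> EffectiveSynapseCounts:
    """Map spine counts to per-neuron receptor multipliers.

    Chronic stress enters through ``sc.fac``: the excitatory spine count is
    reduced to ``EXN * (1 - fac)`` before splitting into receptor classes, so
    every EXN-derived multiplier scales by exactly ``(1 - fac)``. Spines carry
    predominantly excitatory synapses, hence the ``(1 - *_IN)`` excitatory
    fraction is halved between NMDA and AMPA receptor pools; the inhibitory
    fraction feeds the GABA pool.
    """
    exn = sc.EXN * (1.0 - sc.fac)
    mu_e_glut = exn * (1.0 - sc.EXN_IN) * 0.5
    mu_i = sc.BP * (1.0 - sc.BP_IN) * 0.5 + sc.MP * (1.0 - sc.MP_IN) * 0.5
    return EffectiveSynapseCounts(
        mu_e_NMDA=mu_e_glut,
        mu_e_AMPA=mu_e_glut,
        mu_e_GABA=exn * sc.EXN_IN,
        mu_i_NMDA=mu_i,
        mu_i_AMPA=mu_i,
        mu_i_GABA=mu_i,
    )


# ---------------------------------------------------------------------------
# short-term plasticity
# ---------------------------------------------------------------------------

def stp_step(
    state: SynapseState,
    spiked: bool | np.ndarray,
    p: SynapseParams,
    dt: float,
    is_inhibitory: bool | np.ndarray = False,
) -> SynapseState:
    """Advance gating fractions and STP variables by one time step.

    Between spikes every variable relaxes exponentially (exact exponential
    update, not Euler): the gating fractions decay to zero with their receptor
    time constants, ``u`` relaxes to ``U`` with ``tau_u`` and ``x`` to 1 with
    ``tau_x``. A presynaptic spike at the end of the step triggers the jump
    updates; the utilization jump is applied first and its post-jump value is
    used in the gating and resource increments:

        u  <- u + U (1 - u)
        s_AMPA <- s_AMPA + x u gamma_AMPA
        s_NMDA <- s_NMDA + x u (1 - s_NMDA) gamma_NMDA
        x  <- x - u x

    Inhibitory presynaptic spikes increment only the GABA gating, by
    ``gamma_I`` with no u/x dependence.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    spk = np.asarray(spiked, dtype=bool)
    inh = np.asarray(is_inhibitory, dtype=bool)

    s_A = np.asarray(state.s_AMPA, dtype=float) * np.exp(-dt / np.asarray(p.tau_AMPA))
    s_N = np.asarray(state.s_NMDA, dtype=float) * np.exp(-dt / np.asarray(p.tau_NMDA))
    s_G = np.asarray(state.s_GABA, dtype=float) * np.exp(-dt / np.asarray(p.tau_GABA))
    U = np.asarray(p.U, dtype=float)
    u = U + (np.asarray(state.u, dtype=float) - U) * np.exp(-dt / np.asarray(p.tau_u))
    x = 1.0 + (np.asarray(state.x, dtype=float) - 1.0) * np.exp(-dt / np.asarray(p.tau_x))

    exc_spk = spk & ~inh
    u_post = np.where(exc_spk, u + U * (1.0 - u), u)
    s_A = np.where(exc_spk, s_A + x * u_post * np.asarray(p.gamma_AMPA), s_A)
    s_N = np.where(exc_spk, s_N + x * u_post * (1.0 - s_N) * np.asarray(p.gamma_NMDA), s_N)
    x = np.where(exc_spk, x - u_post * x, x)
    s_G = np.where(spk & inh, s_G + np.asarray(p.gamma_I), s_G)

    if np.ndim(spiked) == 0 and np.ndim(state.u) == 0:
        return SynapseState(
            s_AMPA=float(s_A), s_NMDA=float(s_N), s_GABA=float(s_G),
            u=float(u_post), x=float(x),
        )
    return SynapseState(s_AMPA=s_A, s_NMDA=s_N, s_GABA=s_G, u=u_post, x=x)


# ---------------------------------------------------------------------------
# synaptic currents
# ---------------------------------------------------------------------------

def _weighted_drive(w: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Sum of weighted presynaptic gatings; matmul for a 2-D weight matrix."""
    w = np.asarray(w, dtype=float)
    s = np.asarray(s, dtype=float)
    if w.ndim == 2:
        if w.shape[1] != s.shape[-1]:
            raise ValueError("weight/gating length mismatch")
        return w @ s
    if w.shape != s.shape:
        raise ValueError("weight/gating length mismatch")
    return np.sum(w * s, axis=-1)


def nmda_current(V, s, w, u, mu, p: SynapseParams, beta_NMDA: float = 1.0,
                 V_rev: float | np.ndarray = -70.0):
    """Recurrent NMDA current with magnesium-block voltage dependence.

    ``beta_NMDA * mu * g_NMDA * (V - V_rev) / (1 + gamma_mg exp(-beta_mg V))
    * sum_j w_j s_j u_j``. ``w`` may be a per-synapse vector or a full
    (post x pre) weight matrix for vectorized evaluation.
    """
    s = np.asarray(s, dtype=float)
    u = np.asarray(u, dtype=float)
    if s.shape != u.shape:
        raise ValueError("gating/utilization length mismatch")
    drive = _weighted_drive(w, s * u)
    block = 1.0 / (1.0 + np.asarray(p.gamma_mg) * np.exp(-np.asarray(p.beta_mg) * np.asarray(V)))
    return beta_NMDA * np.asarray(mu) * np.asarray(p.g_NMDA_rec) * (np.asarray(V) - V_rev) * block * drive


def ampa_current_ext(V, s_ext, p: SynapseParams, V_rev: float | np.ndarray = -70.0):
    """External AMPA current: ``g_AMPA_ext (V - V_rev) sum_j s_j``."""
    s = np.asarray(s_ext, dtype=float)
    drive = np.sum(s, axis=-1) if s.ndim >= 1 else s
    return np.asarray(p.g_AMPA_ext) * (np.asarray(V) - V_rev) * drive


def ampa_current_rec(V, s, w, u, mu, p: SynapseParams, beta_AMPA: float = 1.0,
                     V_rev: float | np.ndarray = -70.0):
    """Recurrent AMPA current: ``beta mu g (V - V_rev) sum_j w_j s_j u_j``."""
    s = np.asarray(s, dtype=float)
    u = np.asarray(u, dtype=float)
    if s.shape != u.shape:
        raise ValueError("gating/utilization length mismatch")
    drive = _weighted_drive(w, s * u)
    return beta_AMPA * np.asarray(mu) * np.asarray(p.g_AMPA_rec) * (np.asarray(V) - V_rev) * drive


def gaba_current(V, s, mu, p: SynapseParams, w=None, V_rev: float | np.ndarray = -70.0):
    """GABA current: ``mu g_GABA (V - V_rev) sum_j s_j`` (unit weights by
    default; a weight vector/matrix may be supplied so connection-block
    rescaling reaches the inhibitory currents)."""
    s = np.asarray(s, dtype=float)
    if w is None:
        w = np.ones_like(s)
    drive = _weighted_drive(w, s)
    return np.asarray(mu) * np.asarray(p.g_GABA) * (np.asarray(V) - V_rev) * drive


def dendrite_to_soma(I_dend_exc, I_dend_inh, nl: DendriteNonlinearity):
    """Saturating transfer of dendritic current to the soma.

    ``I_dend_exc`` is the summed excitatory dendritic current (NMDA +
    external AMPA + recurrent AMPA + background), ``I_dend_inh`` the GABA
    current magnitude. The output is bounded in ``[c2 - |c1|, c2 + |c1|]``.
    """
    exc = np.asarray(I_dend_exc, dtype=float)
    inh = np.asarray(I_dend_inh, dtype=float)
    arg = (exc + nl.c3 * inh + nl.c4) / (nl.c5 * np.exp(-inh / nl.c6))
    return nl.c1 * np.tanh(arg) + nl.c2


def total_current(components: CurrentComponents, scaling: StressScaling | None = None):
    """Total somatic drive: the acute-stress-weighted sum of all components.

    ``beta_NMDA I_NMDA + I_AMPA,ext + beta_AMPA I_AMPA,rec + I_GABA +
    I_soma,dend + I_bg``; the GABA component is stored signed (negative for
    hyperpolarizing inhibition), so the control scaling returns the plain sum.
    """
    if scaling is None:
        scaling = StressScaling()
    return (
        scaling.beta_NMDA * np.asarray(components.nmda_rec)
        + np.asarray(components.ampa_ext)
        + scaling.beta_AMPA * np.asarray(components.ampa_rec)
        + np.asarray(components.gaba)
        + np.asarray(components.soma_dend)
        + np.asarray(components.background)
    )


# ---------------------------------------------------------------------------
# membrane update
# ---------------------------------------------------------------------------

def membrane_step(
    state: NeuronState,
    I_total,
    p: NeuronParams,
    dt: float,
    t: float = 0.0,
) -> NeuronState:
    """Forward-Euler membrane update with threshold, reset and refractoriness.

    ``I_total`` is the signed somatic drive (positive depolarizes). During the
    refractory period the somatic potential is clamped at ``V_reset``. Raises
    :class:`SimulationError` if the update produces a non-finite potential.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    V = np.asarray(state.V_soma, dtype=float)
    in_ref = t < np.asarray(state.refractory_until)
    dV = (dt / np.asarray(p.C_m)) * (
        -np.asarray(p.g_L) * (V - np.asarray(p.V_L)) + np.asarray(I_total)
    )
    V_new = np.where(in_ref, np.asarray(p.V_reset), V + dV)
    if not np.all(np.isfinite(V_new)):
        bad = np.atleast_1d(~np.isfinite(V_new)).nonzero()[0]
        raise SimulationError(
            f"non-finite membrane potential at t={t:.3f} ms "
            f"(neuron indices {bad[:5].tolist()})"
        )
    spiked = (V_new >= np.asarray(p.V_th)) & ~in_ref
    V_out = np.where(spiked, np.asarray(p.V_reset), V_new)
    ref_until = np.where(spiked, t + dt + np.asarray(p.t_ref), state.refractory_until)

    if np.ndim(state.V_soma) == 0 and np.ndim(I_total) == 0 and np.ndim(p.C_m) == 0:
        return NeuronState(
            V_soma=float(V_out), V_dend=state.V_dend,
            refractory_until=float(ref_until), spiked=bool(spiked),
        )
    return NeuronState(V_soma=V_out, V_dend=state.V_dend,
                       refractory_until=ref_until, spiked=spiked)
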