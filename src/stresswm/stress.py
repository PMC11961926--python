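"""Stress conditions: named transforms of the network and sweep grids.

Acute stress is purely dynamical — recurrent NMDA and AMPA currents are
multiplied by the ratio of stressed to control EPSC amplitudes measured in
prefrontal pyramidal neurons (forced swim: NMDAR-EPSC 425/197 pA, AMPAR-EPSC
98.8/58.6 pA). Chronic stress is structural — a 16% loss of excitatory
dendritic spines shrinks every excitatory-neuron effective synapse count,
optionally combined with a rescaled GABA gating increment and within-group
connection-block rescaling.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .dynamics import StressScaling, effective_synapse_counts
from .network import Network, scale_connections

__all__ = ["StressCondition", "SweepGrid", "acute_scaling_from_epsc",
           "apply_condition", "condition_preset", "CONDITION_NAMES",
           "SWIM_BETA_NMDA", "SWIM_BETA_AMPA", "CHRONIC_FAC"]

# EPSC amplitudes measured in prefrontal pyramidal neurons, forced-swim vs control (pA)
SWIM_NMDA_CONTROL, SWIM_NMDA_STRESS = 197.0, 425.0
SWIM_AMPA_CONTROL, SWIM_AMPA_STRESS = 58.6, 98.8
SWIM_BETA_NMDA = SWIM_NMDA_STRESS / SWIM_NMDA_CONTROL
SWIM_BETA_AMPA = SWIM_AMPA_STRESS / SWIM_AMPA_CONTROL
CHRONIC_FAC = 0.16  # fractional apical spine loss under chronic restraint

CONDITION_NAMES = ("control", "acute_swim", "acute_restraint", "acute_platform",
                   "acute_ketamine", "chronic")


def acute_scaling_from_epsc(control_pA: float, stress_pA: float) -> float:
    """Acute current multiplier: stressed EPSC amplitude / control amplitude."""
    if control_pA <= 0:
        raise ValueError("control EPSC amplitude must be positive")
    return stress_pA / control_pA


@dataclass(frozen=True)
class StressCondition:
    """A named stress condition: current scaling plus spine-loss fraction."""

    name: str = "control"
    scaling: StressScaling = field(default_factory=StressScaling)
    fac: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.fac <= 1.0:
            raise ValueError("fac must lie in [0, 1]")
        if self.name == "control" and not (self.scaling.is_identity and self.fac == 0.0):
            raise ValueError("control condition requires identity scaling and fac=0")


def condition_preset(name: str, **overrides) -> StressCondition:
    """Shipped condition presets.

    ``acute_swim`` carries the measured swim-stress EPSC ratios. The restraint
    and platform presets accept their own EPSC-derived betas via overrides
    (their EPSC amplitudes are not among this package's defaults) and
    fall back to the swim values. ``acute_ketamine`` models ketamine on the
    chronic-stress background as an NMDA fractional-strength increase.
    """
    if name == "control":
        base = StressCondition("control")
    elif name == "acute_swim":
        base = StressCondition("acute_swim", StressScaling(
            beta_NMDA=SWIM_BETA_NMDA, beta_AMPA=SWIM_BETA_AMPA))
    elif name in ("acute_restraint", "acute_platform"):
        base = StressCondition(name, StressScaling(
            beta_NMDA=SWIM_BETA_NMDA, beta_AMPA=SWIM_BETA_AMPA))
    elif name == "acute_ketamine":
        base = StressCondition("acute_ketamine", StressScaling(beta_NMDA=1.5),
                               fac=CHRONIC_FAC)
    elif name == "chronic":
        base = StressCondition("chronic", StressScaling(), fac=CHRONIC_FAC)
    else:
        raise ValueError(f"unknown stress condition {name!r}")
    if overrides:
        scaling_kw = {k: v for k, v in overrides.items()
                      if k in {f.name for f in dataclasses.fields(StressScaling)}}
        other = {k: v for k, v in overrides.items() if k not in scaling_kw}
        base = replace(base, scaling=replace(base.scaling, **scaling_kw), **other)
    return base


def apply_condition(net: Network, cond: StressCondition) -> Network:
    """Apply the structural part of a stress condition to a network.

    Control is the identity (the same object is returned). Acute conditions
    change nothing structurally — their beta factors act at the total-current
    sum inside the engine. Chronic (and the ketamine preset) recompute the
    effective synapse counts with the spine-loss fraction, rescale the GABA
    gating increment by ``gamma_I_scale``, and rescale any within-group
    connection blocks whose scale factor differs from 1.

    The returned network records the applied condition; reapplying a
    structural condition to an already-transformed network is an error
    (block scaling would compound).
    """
    if cond.name not in CONDITION_NAMES and cond.name != "sweep":
        raise ValueError(f"unknown stress condition {cond.name!r}")
    s = cond.scaling
    structural = (cond.fac != 0.0 or s.gamma_I_scale != 1.0
                  or any(getattr(s, f) != 1.0
                         for f in ("ee_scale", "ie_scale", "ei_scale", "ii_scale")))
    if not structural:
        # control or purely dynamical (acute beta factors act in the engine)
        return net

    if net.applied_condition is not None:
        raise ValueError(
            f"network already carries condition {net.applied_condition!r}")

    sc = replace(net.spine_counts, fac=cond.fac)
    mu = effective_synapse_counts(sc)
    out = replace(
        net,
        mu_NMDA=np.where(net.is_exc, mu.mu_e_NMDA, mu.mu_i_NMDA).astype(float),
        mu_AMPA=np.where(net.is_exc, mu.mu_e_AMPA, mu.mu_i_AMPA).astype(float),
        mu_GABA=np.where(net.is_exc, mu.mu_e_GABA, mu.mu_i_GABA).astype(float),
        spine_counts=sc,
        applied_condition=cond.name,
    )
    if cond.scaling.gamma_I_scale != 1.0:
        sp = replace(out.syn_params, gamma_I=np.asarray(out.syn_params.gamma_I)
                     * cond.scaling.gamma_I_scale)
        out = replace(out, syn_params=sp)
    for block, factor in (("EE", cond.scaling.ee_scale), ("IE", cond.scaling.ie_scale),
                          ("EI", cond.scaling.ei_scale), ("II", cond.scaling.ii_scale)):
        if factor != 1.0:
            out = scale_connections(out, block, factor)
    return out


@dataclass(frozen=True)
class SweepGrid:
    """A cartesian sweep over named axes with seeded replicates.

    Axis names: ``gamma_AMPA``, ``gamma_NMDA`` (gating-increment multipliers),
    ``gamma_I`` (GABA increment multiplier), ``beta_NMDA``/``beta_AMPA``
    (acute current multipliers), ``ee_scale``/``ie_scale``/``ei_scale``/
    ``ii_scale`` (within-group block multipliers), ``fac`` (spine loss).
    """

    axes: dict = field(default_factory=dict)  # name -> list of values
    replicates: int = 3

    _VALID = ("gamma_AMPA", "gamma_NMDA", "gamma_I", "beta_NMDA", "beta_AMPA",
              "ee_scale", "ie_scale", "ei_scale", "ii_scale", "fac")

    def __post_init__(self):
        if not self.axes or any(len(v) == 0 for v in self.axes.values()):
            raise ValueError("sweep grid needs at least one non-empty axis")
        for name in self.axes:
            if name not in self._VALID:
                raise ValueError(f"unknown sweep axis {name!r}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def n_points(self) -> int:
        n = 1
        for v in self.axes.values():
            n *= len(v)
        return n

    def points(self):
        """Iterate over grid points as dicts axis -> value."""
        names = list(self.axes)
        for combo in itertools.product(*(self.axes[n] for n in names)):
            yield dict(zip(names, combo))
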