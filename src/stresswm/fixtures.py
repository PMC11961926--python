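"""Synthetic rasters and count sequences with known ground truth.

Two generators make the analysis layer testable without running the
simulator: Poisson rasters in which a chosen subset of groups sustains
delay-period firing (ground-truth capacity = size of that subset), and
doubly-stochastic Poisson count matrices whose latent rate follows an AR(1)
process with a known autocorrelation timescale (ground truth for the
intrinsic-timescale estimator).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import Raster
from .protocol import StimulusProtocol

__all__ = ["FixtureSpec", "make_capacity_raster", "make_ar1_counts"]


@dataclass(frozen=True)
class FixtureSpec:
    """Specification of a capacity-raster fixture.

    All groups fire at ``rate_memory`` during the memory epoch; from delay
    onward only ``sustained_groups`` keep firing at ``rate_sustained`` while
    the rest drop to ``rate_silent``. ``rate_baseline`` is the fixation-epoch
    rate of every neuron.
    """

    n_groups: int = 4
    n_exc_per_group: int = 40
    n_inh_per_group: int = 10
    sustained_groups: tuple = ()
    rate_sustained: float = 40.0  # Hz, delay firing of sustained groups
    rate_memory: float = 30.0  # Hz, all groups during the memory epoch
    rate_baseline: float = 3.0  # Hz, fixation
    rate_silent: float = 1.0  # Hz, non-sustained groups after the stimulus
    seed: int = 0

    def __post_init__(self):
        if any(g < 0 or g >= self.n_groups for g in self.sustained_groups):
            raise ValueError("sustained_groups must be a subset of the groups")
        for name in ("rate_sustained", "rate_memory", "rate_baseline", "rate_silent"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def make_capacity_raster(spec: FixtureSpec,
                         proto: StimulusProtocol | None = None) -> Raster:
    """Poisson raster with a known number of sustained groups.

    Every neuron of a sustained group (excitatory and inhibitory — in the
    network model both keep firing in a winning group) emits Poisson spikes
    at ``rate_sustained`` through delay, cue and post epochs; other groups
    fall to ``rate_silent`` after the memory epoch.
    """
    proto = proto or StimulusProtocol()
    rng = np.random.default_rng([spec.seed, 505])
    n_per = spec.n_exc_per_group + spec.n_inh_per_group
    n = spec.n_groups * n_per
    group_of = np.repeat(np.arange(spec.n_groups), n_per)
    is_exc = (np.arange(n) % n_per) < spec.n_exc_per_group
    sustained = np.isin(group_of, np.asarray(spec.sustained_groups, dtype=int))

    t0, t1, t2, t3 = proto.boundaries
    segments = [(0.0, t0, lambda s: spec.rate_baseline),
                (t0, t1, lambda s: spec.rate_memory),
                (t1, proto.t_total,
                 lambda s: spec.rate_sustained if s else spec.rate_silent)]

    times_all: list[np.ndarray] = []
    ids_all: list[np.ndarray] = []
    for i in range(n):
        for lo, hi, rate_fn in segments:
            rate = rate_fn(sustained[i])
            dur = hi - lo
            if rate <= 0 or dur <= 0:
                continue
            k = rng.poisson(rate * dur / 1000.0)
            if k:
                times_all.append(lo + rng.random(k) * dur)
                ids_all.append(np.full(k, i, dtype=int))
    times = np.concatenate(times_all) if times_all else np.empty(0)
    ids = np.concatenate(ids_all) if ids_all else np.empty(0, dtype=int)
    order = np.argsort(times, kind="stable")
    return Raster(times=times[order], ids=ids[order], n_neurons=n,
                  group_of=group_of, is_exc=is_exc, t_span=proto.t_total)


def make_ar1_counts(
    tau_latent: float,
    span: float = 5000.0,
    bin: float = 50.0,
    seed: int = 0,
    n_units: int = 50,
    rate: float = 20.0,
    sigma_log: float = 0.5,
) -> np.ndarray:
    """Doubly-stochastic Poisson counts with a latent AR(1) rate.

    Each unit has an independent latent log-rate following a stationary AR(1)
    process with lag-one correlation ``exp(-bin/tau_latent)`` (so the latent
    autocorrelation is ``exp(-lag/tau_latent)``); the rate is
    ``rate * exp(z - sigma^2/2)`` — the AR(1) lives on the log-rate to keep
    rates positive — and counts are Poisson given the rate. Returns an
    integer matrix (units x windows), deterministic per seed.
    """
    if tau_latent <= 0:
        raise ValueError("tau_latent must be positive")
    if bin <= 0 or span <= 0:
        raise ValueError("bin and span must be positive")
    rng = np.random.default_rng([seed, 606])
    n_bins = int(round(span / bin))
    phi = np.exp(-bin / tau_latent)
    z = np.empty((n_units, n_bins))
    z[:, 0] = rng.normal(0.0, sigma_log, n_units)
    innov_sd = sigma_log * np.sqrt(1.0 - phi ** 2)
    for t in range(1, n_bins):
        z[:, t] = phi * z[:, t - 1] + rng.normal(0.0, innov_sd, n_units)
    rates = rate * np.exp(z - sigma_log ** 2 / 2.0)
    return rng.poisson(rates * bin / 1000.0)
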