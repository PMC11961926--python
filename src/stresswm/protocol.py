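"""The short-term recall paradigm and Poisson input generation.

The task is a fixation period, a long memory stimulus, a delay, and a brief
cue stimulus probing what the network retained. External input is delivered
as independent homogeneous Poisson spike trains through external AMPA
receptors: all excitatory neurons receive the memory and cue stimuli
simultaneously, and every neuron receives an ongoing background rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["StimulusProtocol", "InputSpikes", "epoch_of", "generate_poisson_input"]

EPOCHS = ("fixation", "memory", "delay", "cue", "post")


@dataclass(frozen=True)
class StimulusProtocol:
    """Epoch durations (ms) and Poisson rates (Hz) of the recall paradigm.

    Rates are per-target aggregate input rates (the summed rate of the
    external afferent pool converging on one neuron). ``rate_cue`` defaults
    to the memory rate — the two stimuli differ in duration, not intensity.
    ``ramp`` optionally ramps the memory-epoch rate linearly from
    ``rate_memory`` to ``ramp_final_factor * rate_memory`` across the epoch
    (the default is a constant rate).
    """

    t_fixation: float = 1000.0
    t_memory: float = 400.0
    t_delay: float = 1000.0
    t_cue: float = 5.0
    t_post: float = 600.0  # post-cue recording; anchors the cue-phase timescale
    rate_memory: float = 2600.0
    rate_cue: float | None = None
    rate_background: float = 1600.0
    ramp: str = "constant"  # "constant" | "linear"
    ramp_final_factor: float = 1.0

    def __post_init__(self):
        for name in ("t_fixation", "t_memory", "t_delay", "t_cue", "t_post"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("rate_memory", "rate_background"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.rate_cue is not None and self.rate_cue < 0:
            raise ValueError("rate_cue must be non-negative")
        if self.ramp not in ("constant", "linear"):
            raise ValueError("ramp must be 'constant' or 'linear'")

    @property
    def cue_rate(self) -> float:
        return self.rate_memory if self.rate_cue is None else self.rate_cue

    @property
    def boundaries(self) -> tuple[float, float, float, float]:
        """Epoch start times after fixation: (memory, delay, cue, post)."""
        t0 = self.t_fixation
        t1 = t0 + self.t_memory
        t2 = t1 + self.t_delay
        t3 = t2 + self.t_cue
        return (t0, t1, t2, t3)

    @property
    def t_total(self) -> float:
        return self.boundaries[3] + self.t_post

    def delay_window(self, width: float) -> tuple[float, float]:
        """The last ``width`` ms of the delay epoch."""
        _, t1, t2, _ = self.boundaries
        return (max(t1, t2 - width), t2)

    def stimulus_rate_at(self, t: float) -> float:
        """Extra stimulus rate delivered to excitatory neurons at time t."""
        ep = epoch_of(t, self)
        if ep == "memory":
            if self.ramp == "linear" and self.t_memory > 0:
                frac = (t - self.t_fixation) / self.t_memory
                return self.rate_memory * (1 + frac * (self.ramp_final_factor - 1))
            return self.rate_memory
        if ep == "cue":
            return self.cue_rate
        return 0.0


def epoch_of(t: float, proto: StimulusProtocol) -> str:
    """Map a time (ms) to its epoch label; boundaries are half-open [start, end)."""
    if t < 0:
        raise ValueError("t must be non-negative")
    t0, t1, t2, t3 = proto.boundaries
    if t < t0:
        return "fixation"
    if t < t1:
        return "memory"
    if t < t2:
        return "delay"
    if t < t3:
        return "cue"
    return "post"


@dataclass(frozen=True)
class InputSpikes:
    """External spike-time lists, one sorted array (ms) per target neuron."""

    times: tuple  # tuple of np.ndarray, one per target

    @property
    def n_targets(self) -> int:
        return len(self.times)

    def counts(self) -> np.ndarray:
        return np.array([t.size for t in self.times])


def generate_poisson_input(
    proto: StimulusProtocol,
    n_targets: int,
    seed: int = 0,
    excitatory_targets: np.ndarray | None = None,
) -> InputSpikes:
    """Independent homogeneous Poisson trains per target, deterministic per seed.

    Each target receives the background rate over the whole span; targets
    flagged excitatory (all, by default) additionally receive the memory- and
    cue-epoch stimulus rates. A linear ramp is realized by thinning a
    dominating homogeneous train.
    """
    rng = np.random.default_rng([seed, 303])
    if excitatory_targets is None:
        excitatory_targets = np.ones(n_targets, dtype=bool)
    t0, t1, t2, t3 = proto.boundaries
    span = proto.t_total

    spikes: list[np.ndarray] = []
    for i in range(n_targets):
        parts = [_hpp(rng, proto.rate_background, 0.0, span)]
        if excitatory_targets[i]:
            if proto.ramp == "linear" and proto.t_memory > 0:
                peak = proto.rate_memory * max(1.0, proto.ramp_final_factor)
                cand = _hpp(rng, peak, t0, t1)
                if cand.size:
                    accept = rng.random(cand.size) < np.array(
                        [proto.stimulus_rate_at(t) for t in cand]) / peak
                    cand = cand[accept]
                parts.append(cand)
            else:
                parts.append(_hpp(rng, proto.rate_memory, t0, t1))
            parts.append(_hpp(rng, proto.cue_rate, t2, t3))
        spikes.append(np.sort(np.concatenate(parts)))
    return InputSpikes(times=tuple(spikes))


def _hpp(rng, rate_hz: float, t_start: float, t_end: float) -> np.ndarray:
    """Homogeneous Poisson process on [t_start, t_end) in ms, rate in Hz."""
    dur = t_end - t_start
    if rate_hz <= 0 or dur <= 0:
        return np.empty(0)
    n = rng.poisson(rate_hz * dur / 1000.0)
    return t_start + rng.random(n) * dur
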