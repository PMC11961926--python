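"""Simulation loop: dynamics + network + protocol -> spike raster + currents.

The engine advances the whole population in lock step with a fixed time step
(forward Euler for the membrane, exact exponential updates for gating/STP
between spikes), a one-step synaptic delay, per-step Poisson external input,
and passive recording of spikes and population-mean receptor currents.
Everything is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import SimulationError
from .network import Network, build_network
from .protocol import StimulusProtocol
from .stress import StressCondition, SweepGrid, apply_condition

__all__ = ["Raster", "SimulationResult", "run_simulation", "run_sweep",
           "write_raster", "read_raster", "write_traces", "read_traces"]

log = logging.getLogger("stresswm")

_STREAM_SIM = 404

RECEPTORS = ("AMPA", "AMPA_ext", "NMDA", "GABA")


@dataclass(frozen=True)
class Raster:
    """Spike events plus the labels needed to interpret them."""

    times: np.ndarray  # spike times, ms
    ids: np.ndarray  # neuron ids
    n_neurons: int
    group_of: np.ndarray
    is_exc: np.ndarray
    t_span: float  # ms

    def __post_init__(self):
        if self.times.size and (self.times.min() < 0 or self.times.max() > self.t_span):
            raise ValueError("spike times outside the simulated span")


@dataclass(frozen=True)
class SimulationResult:
    """Raster, per-population mean current traces and run metadata."""

    times: np.ndarray
    ids: np.ndarray
    n_neurons: int
    group_of: np.ndarray
    is_exc: np.ndarray
    t_span: float
    currents: pd.DataFrame  # tidy: time, population, receptor, value
    protocol: StimulusProtocol
    condition: StressCondition
    dt: float
    seed: int
    config_hash: str = ""

    @property
    def raster(self) -> Raster:
        return Raster(self.times, self.ids, self.n_neurons,
                      self.group_of, self.is_exc, self.t_span)


def run_simulation(
    net: Network,
    proto: StimulusProtocol,
    cond: StressCondition | None = None,
    dt: float = 0.05,
    seed: int = 0,
    record_stride: float = 1.0,
    config_hash: str = "",
) -> SimulationResult:
    """Run the recall protocol on a network under a stress condition.

    Per step: draw external Poisson input and update the external AMPA
    gating; update recurrent gating/STP from the previous step's spikes
    (one-step synaptic delay); evaluate all receptor currents and the
    dendrite-to-soma transfer; sum them with the condition's acute beta
    factors (GABA entering with hyperpolarizing sign); and advance the
    membranes. ``net`` is the base network — the structural part of ``cond``
    is applied here.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    cond = cond or StressCondition("control")
    net = apply_condition(net, cond)

    n = net.n_neurons
    rng = np.random.default_rng([seed, _STREAM_SIM])
    npar = net.neuron_params
    sp = net.syn_params

    def bc(v):
        return np.ascontiguousarray(np.broadcast_to(np.asarray(v, dtype=float), (n,)))

    V_L, C_m, g_L = bc(npar.V_L), bc(npar.C_m), bc(npar.g_L)
    V_th, V_reset, t_ref = bc(npar.V_th), bc(npar.V_reset), bc(npar.t_ref)
    g_ext = bc(sp.g_AMPA_ext)
    gamma_mg, beta_mg = bc(sp.gamma_mg), bc(sp.beta_mg)
    # per-presynaptic decay factors and increments (exact exponential updates)
    dec_ext = np.exp(-dt / bc(sp.tau_AMPA))
    dec_A, dec_N = np.exp(-dt / bc(sp.tau_AMPA)), np.exp(-dt / bc(sp.tau_NMDA))
    dec_G = np.exp(-dt / bc(sp.tau_GABA))
    dec_u, dec_x = np.exp(-dt / bc(sp.tau_u)), np.exp(-dt / bc(sp.tau_x))
    U, gam_A, gam_N, gam_I = bc(sp.U), bc(sp.gamma_AMPA), bc(sp.gamma_NMDA), bc(sp.gamma_I)
    # per-postsynaptic conductance scales (receptor multiplier folded in)
    gmu_N = net.mu_NMDA * bc(sp.g_NMDA_rec)
    gmu_A = net.mu_AMPA * bc(sp.g_AMPA_rec)
    gmu_G = net.mu_GABA * bc(sp.g_GABA)
    I_bg = net.I_bg
    nl = net.dendrite
    bN, bA = cond.scaling.beta_NMDA, cond.scaling.beta_AMPA
    dtC = dt / C_m
    is_exc = net.is_exc
    is_inh = ~is_exc
    W = np.ascontiguousarray(net.W)

    n_steps = int(round(proto.t_total / dt))
    stim_lam = np.array([proto.stimulus_rate_at(i * dt) for i in range(n_steps)])
    stim_lam *= dt / 1000.0
    lam_bg = np.full(n, proto.rate_background * dt / 1000.0)

    V = V_L.copy()
    V_dend = V_L.copy()
    ref_until = np.full(n, -np.inf)
    spiked = np.zeros(n, dtype=bool)
    s_A = np.zeros(n)
    s_N = np.zeros(n)
    s_G = np.zeros(n)
    u = U.copy()
    x = np.ones(n)
    s_ext = np.zeros(n)
    S = np.empty((n, 3))  # gemm input: columns s_N*u, s_A*u, s_G

    # population recording: rows of M average over one (type, group) cell
    n_groups = net.n_groups
    pops = [f"{t}{g}" for t in ("E", "I") for g in range(n_groups)]
    M = np.zeros((len(pops), n))
    for k, p in enumerate(pops):
        mask = (net.group_of == int(p[1:])) & (is_exc if p[0] == "E" else is_inh)
        if mask.any():
            M[k, mask] = 1.0 / mask.sum()
    Mt = M.T.copy()
    stride_steps = max(1, int(round(record_stride / dt)))
    n_rec = (n_steps + stride_steps - 1) // stride_steps
    rec = np.zeros((len(RECEPTORS), len(pops), n_rec))
    rec_times = np.zeros(n_rec)

    spike_t: list[np.ndarray] = []
    spike_i: list[np.ndarray] = []
    r = 0
    for step in range(n_steps):
        t = step * dt
        # external Poisson input -> aggregated external AMPA gating
        lam = lam_bg if stim_lam[step] == 0.0 else lam_bg + stim_lam[step] * is_exc
        s_ext = s_ext * dec_ext + rng.poisson(lam)

        # recurrent gating / STP from last step's spikes (one-step delay);
        # exact exponential relaxation, then jump updates (u before x, s and
        # x increments using the post-jump utilization)
        s_A *= dec_A
        s_N *= dec_N
        s_G *= dec_G
        u = U + (u - U) * dec_u
        x = 1.0 + (x - 1.0) * dec_x
        if spiked.any():
            e = np.nonzero(spiked & is_exc)[0]
            if e.size:
                ue = u[e] + U[e] * (1.0 - u[e])
                u[e] = ue
                s_A[e] += x[e] * ue * gam_A[e]
                s_N[e] += x[e] * ue * (1.0 - s_N[e]) * gam_N[e]
                x[e] *= 1.0 - ue
            i = np.nonzero(spiked & is_inh)[0]
            if i.size:
                s_G[i] += gam_I[i]

        # receptor currents (common reversal at rest: all vanish at V = V_L)
        S[:, 0] = s_N * u
        S[:, 1] = s_A * u
        S[:, 2] = s_G
        D = W @ S
        dv = V - V_L
        mg_block = 1.0 / (1.0 + gamma_mg * np.exp(-beta_mg * V))
        I_N = gmu_N * dv * mg_block * D[:, 0]
        I_A_rec = gmu_A * dv * D[:, 1]
        I_A_ext = g_ext * dv * s_ext
        I_G = gmu_G * dv * D[:, 2]

        I_dend_exc = I_N + I_A_ext + I_A_rec + I_bg
        arg = (I_dend_exc + nl.c3 * I_G + nl.c4) / (nl.c5 * np.exp(-I_G / nl.c6))
        I_sd = nl.c1 * np.tanh(arg) + nl.c2
        # signed-sum adapter: GABA hyperpolarizes, acute betas scale glutamate
        I_tot = bN * I_N + I_A_ext + bA * I_A_rec - I_G + I_sd + I_bg

        # forward-Euler membrane update with threshold/reset/refractoriness
        in_ref = t < ref_until
        V = np.where(in_ref, V_reset, V + dtC * (-g_L * dv + I_tot))
        spiked = (V >= V_th) & ~in_ref
        if spiked.any():
            ids = np.nonzero(spiked)[0]
            V[ids] = V_reset[ids]
            ref_until[ids] = t + dt + t_ref[ids]
            spike_t.append(np.full(ids.size, t))
            spike_i.append(ids)
        V_dend += dtC * (-g_L * (V_dend - V_L) + I_dend_exc - I_G)

        if step % stride_steps == 0:
            rec[0, :, r] = I_A_rec @ Mt
            rec[1, :, r] = I_A_ext @ Mt
            rec[2, :, r] = I_N @ Mt
            rec[3, :, r] = I_G @ Mt
            rec_times[r] = t
            r += 1
            if not np.all(np.isfinite(V)):
                bad = np.nonzero(~np.isfinite(V))[0]
                raise SimulationError(
                    f"non-finite membrane potential at step {step} "
                    f"(t={t:.3f} ms, neurons {bad[:5].tolist()})")

    times = np.concatenate(spike_t) if spike_t else np.empty(0)
    ids = np.concatenate(spike_i).astype(int) if spike_i else np.empty(0, dtype=int)

    frames = []
    for ri, rname in enumerate(RECEPTORS):
        for k, p in enumerate(pops):
            frames.append(pd.DataFrame({
                "time": rec_times[:r], "population": p, "receptor": rname,
                "value": rec[ri, k, :r]}))
    currents = pd.concat(frames, ignore_index=True)

    return SimulationResult(
        times=times, ids=ids, n_neurons=n, group_of=net.group_of,
        is_exc=is_exc, t_span=proto.t_total, currents=currents,
        protocol=proto, condition=cond, dt=dt, seed=seed,
        config_hash=config_hash,
    )


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------

def _apply_sweep_point(net: Network, cond: StressCondition, point: dict
                       ) -> tuple[Network, StressCondition]:
    """Overlay one grid point on the base network/condition."""
    sp = net.syn_params
    skw = {}
    if "gamma_AMPA" in point:
        skw["gamma_AMPA"] = np.asarray(sp.gamma_AMPA) * point["gamma_AMPA"]
    if "gamma_NMDA" in point:
        skw["gamma_NMDA"] = np.asarray(sp.gamma_NMDA) * point["gamma_NMDA"]
    if skw:
        net = replace(net, syn_params=replace(sp, **skw))

    sc_kw = {}
    for axis, fieldname in (("gamma_I", "gamma_I_scale"), ("beta_NMDA", "beta_NMDA"),
                            ("beta_AMPA", "beta_AMPA"), ("ee_scale", "ee_scale"),
                            ("ie_scale", "ie_scale"), ("ei_scale", "ei_scale"),
                            ("ii_scale", "ii_scale")):
        if axis in point:
            sc_kw[fieldname] = getattr(cond.scaling, fieldname) * point[axis]
    fac = point.get("fac", cond.fac)
    scaling = replace(cond.scaling, **sc_kw) if sc_kw else cond.scaling
    name = cond.name
    if name == "control" and (not scaling.is_identity or fac != 0.0):
        name = "sweep"
    return net, StressCondition(name=name, scaling=scaling, fac=fac)


def run_sweep(cfg, grid: SweepGrid | None = None, out_path: str | Path | None = None,
              compute_timescales: bool = True) -> pd.DataFrame:
    """Run the protocol at every grid point x replicate; tidy result table.

    The network realization is shared across grid points (isolating the swept
    factor); replicates differ only in the simulation seed. Rows completed in
    an existing ``out_path`` table are skipped (resumable); per-row failures
    are recorded in the ``error`` column and the sweep continues.
    """
    from . import analysis  # deferred: analysis imports this module's Raster
    from .config import RunConfig, config_hash  # deferred: plumbing only

    if not isinstance(cfg, RunConfig):
        raise TypeError("cfg must be a RunConfig")
    grid = grid or cfg.sweep
    if grid is None:
        raise ValueError("no sweep grid configured")
    chash = config_hash(cfg)
    base_net = build_network(cfg.network, seed=cfg.seed)

    done: set[tuple[int, int]] = set()
    rows: list[dict] = []
    if out_path is not None and Path(out_path).exists():
        prev = pd.read_csv(out_path)
        rows = prev.to_dict("records")
        done = {(int(r["point"]), int(r["replicate"])) for r in rows}
        log.info("resuming sweep: %d rows already done", len(done))

    for pi, point in enumerate(grid.points()):
        for rep in range(grid.replicates):
            if (pi, rep) in done:
                continue
            run_seed = int(np.random.SeedSequence([cfg.seed, pi, rep])
                           .generate_state(1)[0] % (2 ** 31))
            row: dict = {"point": pi, "replicate": rep, "seed": run_seed,
                         "config_hash": chash, **point, "error": ""}
            try:
                net, cond = _apply_sweep_point(base_net, cfg.condition, point)
                res = run_simulation(net, cfg.protocol, cond, dt=cfg.dt,
                                     seed=run_seed, record_stride=cfg.record_stride,
                                     config_hash=chash)
                row["capacity"] = analysis.working_memory_capacity(
                    res, res.group_of, res.is_exc, cfg.protocol, cfg.capacity_criterion)
                for rname, col in (("AMPA", "mean_I_AMPA_E"), ("NMDA", "mean_I_NMDA_E"),
                                   ("GABA", "mean_I_GABA_E")):
                    tr = analysis.mean_current_traces(res, "E", rname)
                    row[col] = float(np.mean(tr.value))
                tr = analysis.mean_current_traces(res, "I", "GABA")
                row["mean_I_GABA_I"] = float(np.mean(tr.value))
                if compute_timescales:
                    fits = analysis.epoch_timescales(res)
                    for (epoch, popt), fit in fits.items():
                        row[f"tau_{popt}_{epoch}"] = fit.tau if fit.converged else np.nan
            except Exception as e:  # noqa: BLE001 - row-level fault isolation
                row["error"] = f"{type(e).__name__}: {e}"
                log.warning("sweep point %d rep %d failed: %s", pi, rep, e)
            rows.append(row)
            if out_path is not None:
                pd.DataFrame(rows).to_csv(out_path, index=False)
        log.info("sweep point %d/%d done", pi + 1, grid.n_points)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# raster / trace files (plain text, documented round trip)
# ---------------------------------------------------------------------------

def write_raster(raster, path: str | Path, **meta) -> None:
    """Write spike events as text: '# key=value' header, then 'time_ms neuron_id'."""
    p = Path(path)
    lines = [f"# n_neurons={raster.n_neurons}",
             f"# t_span={float(raster.t_span)!r}",
             "# groups=" + ",".join(str(int(g)) for g in raster.group_of),
             "# is_exc=" + "".join("1" if e else "0" for e in raster.is_exc)]
    for k, v in meta.items():
        lines.append(f"# {k}={v}")
    lines.append("time_ms neuron_id")
    for t, i in zip(raster.times, raster.ids):
        lines.append(f"{float(t)!r} {int(i)}")
    p.write_text("\n".join(lines) + "\n")


def read_raster(path: str | Path) -> Raster:
    """Read a raster file written by :func:`write_raster`."""
    meta: dict[str, str] = {}
    times: list[float] = []
    ids: list[int] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                k, _, v = line[1:].strip().partition("=")
                meta[k.strip()] = v
            elif line[0].isdigit() or line[0] in "-.":
                a, b = line.split()
                times.append(float(a))
                ids.append(int(b))
    n = int(meta["n_neurons"])
    groups = (np.array([int(x) for x in meta["groups"].split(",")])
              if meta.get("groups") else np.zeros(n, dtype=int))
    is_exc = (np.array([c == "1" for c in meta["is_exc"]])
              if meta.get("is_exc") else np.ones(n, dtype=bool))
    return Raster(times=np.array(times), ids=np.array(ids, dtype=int),
                  n_neurons=n, group_of=groups, is_exc=is_exc,
                  t_span=float(meta["t_span"]))


def write_traces(currents: pd.DataFrame, path: str | Path) -> None:
    """Write the tidy current-trace table as CSV."""
    currents.to_csv(path, index=False, float_format="%.17g")


def read_traces(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
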