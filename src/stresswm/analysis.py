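"""Measurement layer: working-memory capacity, intrinsic timescales,
mean current traces and sweep correlations.

Capacity counts the selective groups whose excitatory population keeps
firing through the late delay. The intrinsic timescale is the decay constant
of the spike-count autocorrelation function: spike trains are binned into a
count matrix, the Pearson correlation between count-matrix columns lagged by
delta is computed across units and averaged over column pairs, and an
exponential decay ``rho(lag) = a (exp(-lag/tau) + b)`` is fitted by damped
nonlinear least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["CapacityCriterion", "TimescaleFit", "working_memory_capacity",
           "spike_count_matrix", "autocorrelation_timescale",
           "fit_exponential_decay", "epoch_timescales", "sweep_correlation",
           "mean_current_traces", "CurrentTrace"]


@dataclass(frozen=True)
class CapacityCriterion:
    """Operational definition of 'a group sustains its memory'.

    A group counts toward capacity if at least ``fraction_active`` of its
    excitatory neurons fire at ``rate_threshold`` Hz or more during the last
    ``window`` ms of the delay epoch. These thresholds are configuration;
    every reported capacity should record the criterion used.
    """

    window: float = 200.0  # ms, portion of the delay examined
    rate_threshold: float = 10.0  # Hz
    fraction_active: float = 0.5

    def __post_init__(self):
        if self.window <= 0:
            raise ValueError("window must be positive")
        if self.rate_threshold < 0:
            raise ValueError("rate_threshold must be non-negative")
        if not 0.0 < self.fraction_active <= 1.0:
            raise ValueError("fraction_active must lie in (0, 1]")


def _raster_arrays(raster) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(raster, "times"):
        return np.asarray(raster.times), np.asarray(raster.ids)
    times, ids = raster
    return np.asarray(times), np.asarray(ids)


def working_memory_capacity(
    raster,
    group_of: np.ndarray,
    is_exc: np.ndarray,
    proto,
    crit: CapacityCriterion | None = None,
) -> int:
    """Number of groups whose excitatory population sustains delay firing.

    ``raster`` is a :class:`~stresswm.engine.Raster`/``SimulationResult`` or a
    ``(times, ids)`` pair. Bounded above by the number of structural groups.
    """
    crit = crit or CapacityCriterion()
    times, ids = _raster_arrays(raster)
    group_of = np.asarray(group_of)
    is_exc = np.asarray(is_exc, dtype=bool)
    t_lo, t_hi = proto.delay_window(crit.window)
    width = t_hi - t_lo
    if width <= 0:
        raise ValueError("capacity window does not overlap the delay epoch")

    in_win = (times >= t_lo) & (times < t_hi)
    counts = np.bincount(ids[in_win], minlength=group_of.size)
    rates = counts / width * 1000.0  # Hz

    capacity = 0
    for g in np.unique(group_of):
        e_mask = (group_of == g) & is_exc
        if not e_mask.any():
            raise ValueError(f"group {g} has no excitatory neurons")
        frac = np.mean(rates[e_mask] >= crit.rate_threshold)
        if frac >= crit.fraction_active:
            capacity += 1
    return capacity


def spike_count_matrix(
    raster,
    bin: float = 50.0,
    span: float = 5000.0,
    t_start: float = 0.0,
    unit_ids: np.ndarray | None = None,
    n_units: int | None = None,
) -> np.ndarray:
    """Integer spike counts, one row per unit and one column per time window.

    Windows tile ``[t_start, t_start + span)`` in steps of ``bin`` (``bin``
    must divide ``span``). ``unit_ids`` restricts (and orders) the rows.
    """
    if bin <= 0 or span <= 0:
        raise ValueError("bin and span must be positive")
    n_bins = span / bin
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("bin must divide span")
    n_bins = int(round(n_bins))

    times, ids = _raster_arrays(raster)
    if n_units is None:
        n_units = getattr(raster, "n_neurons", int(ids.max()) + 1 if ids.size else 0)
    if unit_ids is None:
        unit_ids = np.arange(n_units)
    unit_ids = np.asarray(unit_ids)

    sel = (times >= t_start) & (times < t_start + span)
    t_sel, i_sel = times[sel], ids[sel]
    cols = ((t_sel - t_start) // bin).astype(int)
    full = np.zeros((n_units, n_bins), dtype=int)
    np.add.at(full, (i_sel, cols), 1)
    return full[unit_ids]


@dataclass(frozen=True)
class TimescaleFit:
    """Result of the exponential fit to the lagged autocorrelation."""

    tau: float  # ms
    amplitude: float
    offset: float
    lags: np.ndarray  # ms
    rho: np.ndarray  # mean lagged correlation at each lag
    residual_norm: float
    converged: bool
    n_units_used: int = 0


def _lagged_correlations(counts: np.ndarray, max_lag: int, scheme: str) -> np.ndarray:
    """Mean Pearson correlation at lags 1..max_lag.

    ``columns`` (default downstream): correlate pairs of count-matrix columns
    lagged by delta across units, then average over all pairs at that lag;
    units that never fire carry no signal and are dropped first.
    ``per_unit``: correlate each unit's count sequence against itself shifted
    by the lag, then average over units with defined correlations.
    Lags with no defined correlation come back as NaN.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim == 1:
        counts = counts[None, :]
    if scheme == "columns":
        counts = counts[counts.std(axis=1) > 0]
    n_units, n_bins = counts.shape
    out = np.full(max_lag, np.nan)
    for lag in range(1, max_lag + 1):
        if n_bins - lag < 3:
            break
        if scheme == "per_unit":
            a = counts[:, :-lag]
            b = counts[:, lag:]
            am = a - a.mean(axis=1, keepdims=True)
            bm = b - b.mean(axis=1, keepdims=True)
            num = (am * bm).sum(axis=1)
            den = np.sqrt((am ** 2).sum(axis=1) * (bm ** 2).sum(axis=1))
            ok = den > 0
            if ok.any():
                out[lag - 1] = np.mean(num[ok] / den[ok])
        elif scheme == "columns":
            if n_units < 3:
                continue
            a = counts[:, :-lag]
            b = counts[:, lag:]
            am = a - a.mean(axis=0)
            bm = b - b.mean(axis=0)
            num = (am * bm).sum(axis=0)
            den = np.sqrt((am ** 2).sum(axis=0) * (bm ** 2).sum(axis=0))
            ok = den > 0
            if ok.any():
                out[lag - 1] = float(np.mean(num[ok] / den[ok]))
        else:
            raise ValueError("scheme must be 'per_unit' or 'columns'")
    return out


def fit_exponential_decay(lags: np.ndarray, rho: np.ndarray, bin: float = 50.0
                          ) -> TimescaleFit:
    """Fit ``rho(lag) = a (exp(-lag/tau) + b)`` by nonlinear least squares.

    Initialization a=1, b=0, tau=2 bins; tau is bounded positive. A fit is
    reported non-converged — never clamped — when the timescale is
    unidentifiable: amplitude collapsed below 1e-3, the fitted curve decays
    by less than 1e-3 across the observed lag range (a flat plateau carries
    no timescale information), or tau extrapolates beyond five times the
    longest observed lag.
    """
    lags = np.asarray(lags, dtype=float)
    rho = np.asarray(rho, dtype=float)
    ok = np.isfinite(rho)
    lags_f, rho_f = lags[ok], rho[ok]
    nan_fit = TimescaleFit(tau=np.nan, amplitude=np.nan, offset=np.nan,
                           lags=lags, rho=rho, residual_norm=np.nan,
                           converged=False)
    if lags_f.size < 3:
        return nan_fit

    def resid(p):
        a, b, tau = p
        return a * (np.exp(-lags_f / tau) + b) - rho_f

    try:
        res = optimize.least_squares(
            resid, x0=[1.0, 0.0, 2.0 * bin],
            bounds=([-np.inf, -np.inf, 1e-6], [np.inf, np.inf, np.inf]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14)
    except Exception:
        return nan_fit
    a, b, tau = res.x
    decay_span = abs(a) * abs(np.exp(-lags_f.min() / tau)
                              - np.exp(-lags_f.max() / tau))
    converged = (bool(res.success) and abs(a) >= 1e-3 and np.isfinite(tau)
                 and decay_span >= 1e-3 and tau <= 5.0 * lags_f.max())
    return TimescaleFit(tau=float(tau), amplitude=float(a), offset=float(b),
                        lags=lags, rho=rho,
                        residual_norm=float(np.linalg.norm(res.fun)),
                        converged=converged)


def autocorrelation_timescale(
    counts: np.ndarray,
    max_lag_windows: int = 20,
    bin: float = 50.0,
    scheme: str = "columns",
) -> TimescaleFit:
    """Intrinsic timescale of a spike-count matrix (units x windows).

    Computes the mean lagged Pearson correlation (per-unit pooling by
    default) at lags 1..``max_lag_windows`` windows and fits the exponential
    decay. Zero-variance counts yield a flagged non-converged fit, not an
    exception.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim == 1:
        counts = counts[None, :]
    n_bins = counts.shape[1]
    max_lag = min(max_lag_windows, n_bins - 3)
    if max_lag < 3:
        raise ValueError("need at least 3 usable lags")
    rho = _lagged_correlations(counts, max_lag, scheme)
    lags = np.arange(1, max_lag + 1) * bin
    fit = fit_exponential_decay(lags, rho, bin=bin)
    n_used = int(np.sum(counts.std(axis=1) > 0))
    return TimescaleFit(**{**fit.__dict__, "n_units_used": n_used})


def epoch_timescales(
    result,
    epochs: tuple[str, ...] = ("memory", "cue"),
    bin: float = 50.0,
    span: float = 5000.0,
    max_lag_windows: int = 20,
    scheme: str = "columns",
    sustained_only: bool = False,
    crit: CapacityCriterion | None = None,
) -> dict:
    """Timescale fits anchored at epoch starts, per E and I population.

    For each requested epoch the count matrix starts at that epoch's onset
    and extends ``span`` ms (clipped to the recording). By default all units
    of each population are pooled; ``sustained_only`` restricts to groups
    that meet the capacity criterion. Returns ``{(epoch, 'E'|'I'): fit}``.
    """
    proto = result.protocol
    starts = dict(zip(("memory", "delay", "cue", "post"), proto.boundaries))
    starts["fixation"] = 0.0
    group_of = np.asarray(result.group_of)
    is_exc = np.asarray(result.is_exc, dtype=bool)

    keep = np.ones(group_of.size, dtype=bool)
    if sustained_only:
        crit = crit or CapacityCriterion()
        times, ids = _raster_arrays(result)
        t_lo, t_hi = proto.delay_window(crit.window)
        counts = np.bincount(ids[(times >= t_lo) & (times < t_hi)],
                             minlength=group_of.size)
        rates = counts / (t_hi - t_lo) * 1000.0
        keep = np.zeros(group_of.size, dtype=bool)
        for g in np.unique(group_of):
            e = (group_of == g) & is_exc
            if np.mean(rates[e] >= crit.rate_threshold) >= crit.fraction_active:
                keep |= group_of == g

    out = {}
    for epoch in epochs:
        if epoch not in starts:
            raise ValueError(f"unknown epoch {epoch!r}")
        t0 = starts[epoch]
        avail = result.t_span - t0
        eff_span = min(span, np.floor(avail / bin) * bin)
        if eff_span / bin < 6:
            raise ValueError(f"epoch {epoch!r} too short for at least 3 lags")
        for pop, mask in (("E", is_exc & keep), ("I", ~is_exc & keep)):
            counts = spike_count_matrix(result, bin=bin, span=eff_span,
                                        t_start=t0,
                                        unit_ids=np.nonzero(mask)[0])
            out[(epoch, pop)] = autocorrelation_timescale(
                counts, max_lag_windows=max_lag_windows, bin=bin, scheme=scheme)
    return out


def sweep_correlation(table: pd.DataFrame, axis: str, outcome: str = "capacity"
                      ) -> tuple[float, float]:
    """Pearson r and two-sided p between a swept axis and an outcome.

    Replicates enter as individual observations. A constant outcome has no
    defined correlation and is reported as ``(nan, nan)``.
    """
    df = table.dropna(subset=[axis, outcome])
    if len(df) < 3:
        raise ValueError("need at least 3 grid points")
    x = df[axis].to_numpy(dtype=float)
    y = df[outcome].to_numpy(dtype=float)
    if np.std(y) == 0 or np.std(x) == 0:
        return (np.nan, np.nan)
    r, p = stats.pearsonr(x, y)
    return (float(r), float(p))


@dataclass(frozen=True)
class CurrentTrace:
    time: np.ndarray
    value: np.ndarray


def mean_current_traces(result, population: str, receptor: str) -> CurrentTrace:
    """Mean receptor current trace over a population.

    ``population`` is a recorded population label (e.g. ``"E0"``) or a type
    (``"E"``/``"I"``), in which case the per-group traces are averaged
    (groups are equally sized, so this is the population mean).
    """
    df = result.currents if hasattr(result, "currents") else result
    if receptor not in set(df["receptor"]):
        raise ValueError(f"receptor {receptor!r} not recorded")
    sub = df[df["receptor"] == receptor]
    if population in set(sub["population"]):
        sel = sub[sub["population"] == population]
        g = sel.groupby("time", sort=True)["value"].mean()
    elif population in ("E", "I"):
        sel = sub[sub["population"].str.startswith(population)]
        if sel.empty:
            raise ValueError(f"population {population!r} not recorded")
        g = sel.groupby("time", sort=True)["value"].mean()
    else:
        raise ValueError(f"population {population!r} not recorded")
    return CurrentTrace(time=g.index.to_numpy(), value=g.to_numpy())
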