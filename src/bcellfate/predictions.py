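"""Downstream quantities derived from a fitted model.

Three analyses: (1) the source-resolved influx decomposition — how much of
the CAR+ MZB pool is replenished each day by activation of CAR- MZB cells
versus differentiation of FoB (or GCB) cells, as percent of pool size per
day, with a cumulative-share variant; (2) Pearson correlations between ln
counts of B-cell subsets across mice, with week-bin metadata; (3) a
theoretical transplantation experiment — the CAR+ MZB trajectory that a
transferred donor FoB (branched route) or GCB (linear route) pool would
generate, which discriminates the two topologies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.integrate import cumulative_trapezoid

from .dynamics import _exp_step_chain, eval_sigmoid_rate, rate_functions, rhs
from .errors import ConfigurationError, DomainError, InsufficientDataError
from .params import ModelSpec, RateParameters
from .sources import SourceTrajectoryPair


@dataclass(frozen=True)
class InfluxDecomposition:
    """Per-time influx contributions (percent of CAR+ MZB pool per day) with
    95% credible bands, summarised over posterior draws."""

    summary: pd.DataFrame       # time, pct_carneg_*, pct_fob_*, cum_share_carneg_*
    budget_residual_max: float  # worst relative imbalance of the dM/dt budget
    n_draws: int


def _draw_fluxes(spec: ModelSpec, params: RateParameters,
                 sources: SourceTrajectoryPair, times: np.ndarray,
                 M: np.ndarray, G: np.ndarray):
    """Influx terms (cells/day) of the M-equation for one parameter draw."""
    alpha, beta, delta, mu = rate_functions(spec, params)
    carneg = beta(times) * sources.mzb_carneg.evaluate(times)
    if spec.topology == "branched":
        fob = mu(times) * sources.fob.evaluate(times)
    elif spec.topology == "linear":
        fob = mu(times) * G
    else:
        fob = np.zeros_like(times)
    return carneg, fob


def influx_decomposition(fit, times, max_draws: int = 200) -> InfluxDecomposition:
    """Decompose the daily influx into the CAR+ MZB pool by source.

    ``fit`` is a fitted :class:`~bcellfate.inference.BCellFateModel`.  For
    each retained posterior draw the control-group M trajectory is solved and
    the two influx terms beta(t)*Mneg(t) and mu(t)*F(t) (branched; mu(t)*G(t)
    for the linear route) are expressed as percent of M per day.  The
    cumulative variant reports the CAR- MZB-activation share of all influx
    accumulated since t0 (defined at t0 by its instantaneous limit).  The
    algebraic budget dM/dt = influxes - lambda*M is checked on every draw.
    """
    lp = fit.logprob_
    spec = fit.spec_
    sources = fit.sources_
    times = np.asarray(times, dtype=float)
    lo_s, hi_s = sources.mzb_carneg.support
    if times.min() < lo_s or times.max() > hi_s:
        warnings.warn("requested times extend beyond the fitted source support; "
                      "driver pools are clamped to boundary values")

    theta_all = np.log(np.stack([fit.posterior_[n].reshape(-1) for n in lp.names],
                                axis=1))
    step = max(len(theta_all) // max_draws, 1)
    sel = theta_all[::step]

    pct_carneg = np.empty((len(sel), len(times)))
    pct_fob = np.empty_like(pct_carneg)
    cum_share = np.empty_like(pct_carneg)
    worst = 0.0
    for i, th in enumerate(sel):
        params = lp.to_rate_params(th)
        G_grid, M_grid, _ = lp._trajectory_arrays(th)
        M = np.interp(times, lp.grid, M_grid)
        G = np.interp(times, lp.grid, G_grid)
        carneg, fob = _draw_fluxes(spec, params, sources, times, M, G)
        pct_carneg[i] = 100.0 * carneg / M
        pct_fob[i] = 100.0 * fob / M

        # budget closure: dM/dt from the model right-hand side vs the sum of
        # the decomposition's own terms
        dMdt_model = np.array([rhs(spec, params, sources, float(t), (g, m, 0.0))[1]
                               for t, g, m in zip(times, G, M)])
        dMdt_terms = (carneg + fob) - params.lambda_ctrl * M
        scale = np.maximum(np.abs(dMdt_model), 1e-12)
        worst = max(worst, float(np.max(np.abs(dMdt_model - dMdt_terms) / scale)))

        total = carneg + fob
        cum_carneg = cumulative_trapezoid(carneg, times, initial=0.0)
        cum_total = cumulative_trapezoid(total, times, initial=0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            share = np.where(cum_total > 0, cum_carneg / np.maximum(cum_total, 1e-300),
                             carneg / np.maximum(total, 1e-300))
        cum_share[i] = 100.0 * share

    def bands(arr, prefix):
        lo, med, hi = np.quantile(arr, [0.025, 0.5, 0.975], axis=0)
        return {f"{prefix}_mean": arr.mean(axis=0), f"{prefix}_median": med,
                f"{prefix}_lo": lo, f"{prefix}_hi": hi}

    cols = {"time": times}
    cols.update(bands(pct_carneg, "pct_carneg"))
    cols.update(bands(pct_fob, "pct_fob"))
    cols.update(bands(cum_share, "cum_share_carneg"))
    return InfluxDecomposition(summary=pd.DataFrame(cols),
                               budget_residual_max=worst, n_draws=len(sel))


def ln_count_correlations(data, pairs) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlations of natural-log counts between subset pairs.

    Pairs observations from the same mouse.  Returns a summary table
    (pop_a, pop_b, n, r, p_value) and the paired per-mouse table with a
    week bin (weeks 1-4) for plotting.
    """
    frame = data.to_frame() if hasattr(data, "to_frame") else data
    summaries, paired_parts = [], []
    for pop_a, pop_b in pairs:
        a = frame[frame["population"] == pop_a][["mouse_id", "group", "day", "count"]]
        b = frame[frame["population"] == pop_b][["mouse_id", "count"]]
        merged = a.merge(b, on="mouse_id", suffixes=("_a", "_b"))
        merged = merged[(merged["count_a"] > 0) & (merged["count_b"] > 0)]
        if len(merged) < 3:
            raise InsufficientDataError(
                f"fewer than 3 complete pairs for ({pop_a}, {pop_b})")
        ln_a = np.log(merged["count_a"].to_numpy(dtype=float))
        ln_b = np.log(merged["count_b"].to_numpy(dtype=float))
        if np.ptp(ln_a) == 0 or np.ptp(ln_b) == 0:
            raise DomainError("cannot correlate a constant series")
        r, p = stats.pearsonr(ln_a, ln_b)
        summaries.append({"pop_a": pop_a, "pop_b": pop_b, "n": len(merged),
                          "r": float(r), "p_value": float(p)})
        week = np.clip(np.ceil(merged["day"].to_numpy(dtype=float) / 7.0), 1, 4)
        paired_parts.append(pd.DataFrame({
            "pop_a": pop_a, "pop_b": pop_b, "mouse_id": merged["mouse_id"],
            "group": merged["group"], "day": merged["day"],
            "week_bin": week.astype(int), "ln_count_a": ln_a, "ln_count_b": ln_b}))
    return pd.DataFrame(summaries), pd.concat(paired_parts, ignore_index=True)


def simulate_transplant(params: RateParameters, donor: str, times,
                        donor_pool0: float = None, donor_decay: float = 0.0,
                        spec: ModelSpec = None, dt: float = 0.01) -> pd.DataFrame:
    """Donor-derived CAR+ MZB trajectory after a theoretical transfer.

    ``donor="FoB"`` routes the donor pool through the branched pathway
    (dM = mu(t) * P(t) - lambda * M); ``donor="GCB"`` through the linear one.
    The donor pool decays exponentially, P(t) = P0 * exp(-donor_decay *
    (t - t0)); recipient-derived influx is excluded by construction, so the
    trajectory isolates what each topology predicts the transfer would yield.
    """
    if donor not in ("FoB", "GCB"):
        raise ConfigurationError(f"donor must be 'FoB' or 'GCB', got {donor!r}")
    if donor_pool0 is None:
        raise ConfigurationError("donor pool initial size must be supplied")
    if donor_pool0 < 0 or donor_decay < 0:
        raise DomainError("donor pool size and decay rate must be >= 0")
    if spec is None:
        topo = "branched" if donor == "FoB" else "linear"
        spec = ModelSpec(topology=topo, influx_time_varying=True)

    times = np.asarray(times, dtype=float)
    t0 = params.t0
    if times[0] < t0 - 1e-12:
        raise DomainError("times must start at or after t0")
    n_steps = max(int(np.ceil((times[-1] - t0) / dt - 1e-9)), 1)
    grid = t0 + dt * np.arange(n_steps + 1)
    mid = grid[:-1] + 0.5 * dt

    pool_mid = donor_pool0 * np.exp(-donor_decay * (mid - t0))
    if spec.mu_time_varying:
        mu_mid = eval_sigmoid_rate(params.mu, params.nu3, mid, t0)
    else:
        mu_mid = np.full(mid.shape, params.mu)
    forcing = mu_mid * pool_mid
    lam = np.full(mid.shape, params.lambda_ctrl)
    M = _exp_step_chain(lam, np.asarray(forcing, dtype=float), 0.0,
                        np.full(mid.shape, dt))
    return pd.DataFrame({"time": times, "donor": donor,
                         "pathway": spec.topology,
                         "donor_derived_MZB": np.interp(times, grid, M)})
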