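"""Bayesian fitting of the compartment models to cross-sectional cohorts.

Each candidate model is fitted simultaneously to the CAR+ GCB and CAR+ MZB
time-courses of both genotype groups.  The observation model is log-normal:
ln counts are Normal around the ln model trajectory, with one noise scale
sigma per observed (group, population) series.  The GCB trajectory is shared
between groups; the N2KO CAR+ MZB trajectory uses the knockout loss rate
lambda' and no FoB/GCB influx (mu = 0).

Positive parameters (rates, pool sizes, sigmas, sigmoid shapes) are sampled
on the natural-log scale.  Priors are weakly informative: log-normal on
rates, log-normal on initial pools centred on early-day group geometric
means, half-Normal(0, 0.1 day^-2) on the sigmoid shape nu, half-Normal(0, 1)
on each sigma.  Sampling uses an affine-invariant ensemble sampler
initialised near the posterior mode (found by quasi-Newton optimisation),
with the ensemble walkers treated as chains for split-R-hat and effective
sample size.  Per-observation pointwise log-likelihoods are recomputed for
the retained draws, ready for PSIS-LOO model comparison.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .data import CohortDataset
from .dynamics import Trajectory, _grid_from_arrays, eval_sigmoid_rate, solve
from .errors import ConfigurationError, DomainError, InsufficientDataError
from .params import ModelSpec, RateParameters
from .sources import SourceTrajectoryPair

logger = logging.getLogger(__name__)

_LN2PI = float(np.log(2.0 * np.pi))
_THETA_BOUND = 25.0  # |ln parameter| beyond this is rejected outright


def clonal_half_life(net_loss_rate):
    """Time for a clonal lineage to halve: ln(2) / net loss rate (days).

    Accepts scalars or arrays (for per-draw uncertainty propagation); every
    rate must be strictly positive.
    """
    rate = np.asarray(net_loss_rate, dtype=float)
    if np.any(rate <= 0) or not np.all(np.isfinite(rate)):
        raise DomainError("net loss rate must be positive and finite")
    out = np.log(2.0) / rate
    return float(out) if np.ndim(net_loss_rate) == 0 else out


@dataclass(frozen=True)
class PriorSpec:
    """Prior for one positive parameter, evaluated in theta = ln(x) space.

    ``lognormal``: Normal(theta | loc, scale).
    ``halfnormal``: half-Normal(x | scale) with the log-Jacobian ``+theta``.
    """

    dist: str
    loc: float = 0.0
    scale: float = 1.0

    def logpdf_theta(self, theta: float) -> float:
        if self.dist == "lognormal":
            z = (theta - self.loc) / self.scale
            return -0.5 * z * z - np.log(self.scale) - 0.5 * _LN2PI
        if self.dist == "halfnormal":
            x = np.exp(theta)
            return (np.log(2.0) - np.log(self.scale) - 0.5 * _LN2PI
                    - 0.5 * (x / self.scale) ** 2 + theta)
        raise ConfigurationError(f"unknown prior dist {self.dist!r}")

    def initial_theta(self) -> float:
        if self.dist == "lognormal":
            return self.loc
        return float(np.log(self.scale * 0.5))


_RATE_PRIORS = {
    "alpha0": PriorSpec("lognormal", np.log(3e-3), 2.0),
    "beta0": PriorSpec("lognormal", np.log(5e-3), 2.0),
    "delta0": PriorSpec("lognormal", np.log(0.3), 1.5),
    "mu": PriorSpec("lognormal", np.log(1e-3), 2.0),
    "lambda_ctrl": PriorSpec("lognormal", np.log(0.3), 1.5),
    "lambda_n2ko": PriorSpec("lognormal", np.log(0.3), 1.5),
    "nu1": PriorSpec("halfnormal", scale=0.1),
    "nu2": PriorSpec("halfnormal", scale=0.1),
    "nu3": PriorSpec("halfnormal", scale=0.1),
}

_POOL_SERIES = {"G0": ("control", "GCB_CARpos"),
                "M0": ("control", "MZB_CARpos"),
                "M0_n2": ("n2ko", "MZB_CARpos")}


def default_priors(spec: ModelSpec, data: CohortDataset,
                   shared_nu: bool = True) -> dict[str, PriorSpec]:
    """Weakly-informative priors for every free parameter of ``spec`` given
    the cohort (initial pools centred on earliest-day geometric means)."""
    priors: dict[str, PriorSpec] = {}
    for name in spec.free_parameter_names():
        if name in ("G0", "M0", "M0_n2"):
            group, pop = _POOL_SERIES[name]
            obs = data.observations(group, pop)
            # groups are indistinguishable up to the day-4 anchor, so when a
            # group has no day-4 data (the N2KO design starts at day 7) the
            # prior centres on the other group's day-4 geometric mean
            # Groups are indistinguishable up to the day-4 anchor, so when a
            # group lacks day-4 data (the N2KO design starts at day 7) the
            # prior centre transfers from the other group's day-4 geometric
            # mean.  That transferred anchor is a genuine external datum for
            # the pool, so it gets the tight width implied by the anchor's
            # ln-scale standard error (plus a group-difference allowance);
            # pools whose own day-4 counts already enter the likelihood get a
            # weak prior instead, to avoid counting those mice twice.
            transferred = obs.empty or obs["day"].min() > 4.0
            if transferred:
                obs = data.observations("control", pop)
            if obs.empty:
                center, width = np.log(1e4), 2.0
            else:
                first_day = obs["day"].min()
                counts = obs.loc[obs["day"] == first_day, "count"].to_numpy()
                counts = np.maximum(counts, 1.0)
                center = float(np.mean(np.log(counts)))
                width = 0.5 if transferred else 1.0
            priors[name] = PriorSpec("lognormal", center, width)
        else:
            priors[name] = PriorSpec(_RATE_PRIORS[name].dist,
                                     _RATE_PRIORS[name].loc,
                                     _RATE_PRIORS[name].scale)
    if spec.influx_time_varying and not shared_nu:
        priors["nu2"] = _RATE_PRIORS["nu2"]
    return priors


# ---------------------------------------------------------------------------
# observation table
# ---------------------------------------------------------------------------

#: (group, population) series entering the likelihood; the driver pools
#: (FoB_total, MZB_CARneg) are handled by the sources module instead.
FITTED_SERIES = (("control", "GCB_CARpos"), ("control", "MZB_CARpos"),
                 ("n2ko", "GCB_CARpos"), ("n2ko", "MZB_CARpos"))


def _prepare_observations(data: CohortDataset) -> pd.DataFrame:
    """Flatten fitted series into one table with ln counts, replacing zero
    counts by half the smallest positive count of that population."""
    parts = []
    for group, pop in FITTED_SERIES:
        obs = data.observations(group, pop)
        if obs.empty:
            continue
        obs = obs.assign(series=f"{group}:{pop}")
        parts.append(obs)
    if not parts:
        raise InsufficientDataError("cohort contains no CAR+ GCB/MZB observations")
    table = pd.concat(parts, ignore_index=True)
    for pop in table["population"].unique():
        mask = (table["population"] == pop) & (table["count"] == 0)
        if mask.any():
            positive = table.loc[(table["population"] == pop) & (table["count"] > 0),
                                 "count"]
            if positive.empty:
                raise DomainError(f"all {pop} counts are zero")
            repl = 0.5 * positive.min()
            logger.warning("replacing %d zero %s counts by %g", mask.sum(), pop, repl)
            table.loc[mask, "count"] = repl
    table["ln_count"] = np.log(table["count"].to_numpy(dtype=float))
    return table


def _pointwise_normal(resid: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    return -0.5 * (resid / sigma) ** 2 - np.log(sigma) - 0.5 * _LN2PI


def _series_predictions(traj: Trajectory, table: pd.DataFrame) -> np.ndarray:
    """Model prediction for every observation row, interpolated on traj.times."""
    pred = np.empty(len(table))
    for series, curve in (("control:GCB_CARpos", traj.G),
                          ("n2ko:GCB_CARpos", traj.G),
                          ("control:MZB_CARpos", traj.M),
                          ("n2ko:MZB_CARpos", traj.M_n2)):
        mask = (table["series"] == series).to_numpy()
        if mask.any():
            pred[mask] = np.interp(table.loc[mask, "day"].to_numpy(dtype=float),
                                   traj.times, curve)
    return pred


def log_likelihood(spec: ModelSpec, params: RateParameters,
                   sources: SourceTrajectoryPair, data: CohortDataset,
                   sigma) -> tuple[float, np.ndarray, pd.DataFrame]:
    """Log-normal observation log-likelihood of a cohort under one model.

    ``sigma`` is a scalar, a ``{population: sd}`` or ``{(group, population):
    sd}`` mapping of ln-count noise scales.  Returns the total, the
    per-observation pointwise values, and the observation index table (order:
    group, population, day, mouse id) for LOO bookkeeping.
    """
    table = _prepare_observations(data)
    days = np.unique(table["day"].to_numpy(dtype=float))
    traj = solve(spec, params, sources, days, method="lsoda")
    pred = _series_predictions(traj, table)
    if np.any(pred <= 0):
        warnings.warn("model predicts non-positive counts; likelihood is -inf")
        return -np.inf, np.full(len(table), -np.inf), table

    sig = np.empty(len(table))
    for i, row in enumerate(table.itertuples()):
        if np.isscalar(sigma):
            sig[i] = sigma
        elif (row.group, row.population) in sigma:
            sig[i] = sigma[(row.group, row.population)]
        else:
            sig[i] = sigma[row.population]
    pointwise = _pointwise_normal(table["ln_count"].to_numpy() - np.log(pred), sig)
    return float(pointwise.sum()), pointwise, table


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

class _LogProb:
    """Fast posterior density: pre-grids the sources and observation indices
    so each call costs one exponential-integrator solve."""

    def __init__(self, spec, priors, table, sources, t0, dt, shared_nu):
        self.spec = spec
        self.t0 = t0
        self.dt = dt
        self.shared_nu = shared_nu
        self.rate_names = list(spec.free_parameter_names())
        if spec.influx_time_varying and not shared_nu:
            self.rate_names.append("nu2")
        self.series = sorted(table["series"].unique())
        self.sigma_names = [f"sigma_{s.replace(':', '_')}" for s in self.series]
        self.names = self.rate_names + self.sigma_names
        self.priors = [priors[n] if n in priors else PriorSpec("halfnormal", scale=1.0)
                       for n in self.names]

        t_end = float(table["day"].max())
        n_steps = max(int(np.ceil((t_end - t0) / dt - 1e-9)), 1)
        self.grid = t0 + dt * np.arange(n_steps + 1)
        self.mid = self.grid[:-1] + 0.5 * dt
        self.F_mid = sources.fob.evaluate(self.mid)
        self.Mneg_mid = sources.mzb_carneg.evaluate(self.mid)

        self.obs_idx = np.rint((table["day"].to_numpy(dtype=float) - t0) / dt
                               ).astype(np.int64)
        self.obs_idx = np.clip(self.obs_idx, 0, n_steps)
        self.ln_counts = table["ln_count"].to_numpy(dtype=float)
        self.curve_sel = np.zeros(len(table), dtype=np.int64)  # 0=G 1=M 2=Mn2
        series_arr = table["series"].to_numpy()
        self.curve_sel[series_arr == "control:MZB_CARpos"] = 1
        self.curve_sel[series_arr == "n2ko:MZB_CARpos"] = 2
        self.sigma_sel = np.searchsorted(np.array(self.series),
                                         series_arr).astype(np.int64)
        self.ndim = len(self.names)

    def to_rate_params(self, theta: np.ndarray) -> RateParameters:
        values = dict(zip(self.names, np.exp(theta)))
        fields = {k: v for k, v in values.items() if not k.startswith("sigma_")}
        if "nu3" in fields and self.shared_nu:
            fields["nu2"] = fields["nu3"]
        return RateParameters(t0=self.t0, **fields)

    def sigmas(self, theta: np.ndarray) -> dict:
        values = np.exp(theta[len(self.rate_names):])
        out = {}
        for s, v in zip(self.series, values):
            group, pop = s.split(":")
            out[(group, pop)] = float(v)
        return out

    def _trajectory_arrays(self, theta):
        p = self.to_rate_params(theta)
        mid, t0 = self.mid, self.t0
        spec = self.spec
        if spec.influx_time_varying:
            alpha_mid = eval_sigmoid_rate(p.alpha0, p.nu2, mid, t0)
            beta_mid = eval_sigmoid_rate(p.beta0, p.nu3, mid, t0)
        else:
            alpha_mid = np.full(mid.shape, p.alpha0)
            beta_mid = np.full(mid.shape, p.beta0)
        if spec.loss_time_varying:
            delta_mid = eval_sigmoid_rate(p.delta0, p.nu1, mid, t0)
        else:
            delta_mid = np.full(mid.shape, p.delta0)
        if not spec.uses_mu:
            mu_mid = np.zeros(mid.shape)
        elif spec.mu_time_varying:
            mu_mid = eval_sigmoid_rate(p.mu, p.nu3, mid, t0)
        else:
            mu_mid = np.full(mid.shape, p.mu)
        _, G, M, M_n2 = _grid_from_arrays(spec, p, self.grid, self.dt, alpha_mid,
                                          beta_mid, delta_mid, mu_mid,
                                          self.F_mid, self.Mneg_mid)
        return G, M, M_n2

    def pointwise(self, theta: np.ndarray) -> np.ndarray:
        G, M, M_n2 = self._trajectory_arrays(theta)
        curves = (G, M, M_n2)
        pred = np.empty(len(self.obs_idx))
        for c in range(3):
            mask = self.curve_sel == c
            if mask.any():
                pred[mask] = curves[c][self.obs_idx[mask]]
        if np.any(pred <= 0) or not np.all(np.isfinite(pred)):
            return np.full(len(self.obs_idx), -np.inf)
        sig = np.exp(theta[len(self.rate_names):])[self.sigma_sel]
        return _pointwise_normal(self.ln_counts - np.log(pred), sig)

    def log_prior(self, theta: np.ndarray) -> float:
        return float(sum(p.logpdf_theta(t) for p, t in zip(self.priors, theta)))

    def __call__(self, theta: np.ndarray) -> float:
        if np.any(np.abs(theta) > _THETA_BOUND) or not np.all(np.isfinite(theta)):
            return -np.inf
        pw = self.pointwise(theta)
        if not np.all(np.isfinite(pw)):
            return -np.inf
        return pw.sum() + self.log_prior(theta)

    def initial_theta(self) -> np.ndarray:
        return np.array([p.initial_theta() for p in self.priors])


class BCellFateModel(BaseEstimator):
    """Bayesian fit of one compartment model to a cross-sectional cohort.

    Parameters
    ----------
    model : str or ModelSpec
        Family member to fit, e.g. ``"branched_tvi"`` (branched topology with
        time-varying influx, the reference model), ``"null_neutral"``, ...
    draws, tune : int
        Post-burn-in and burn-in ensemble steps.
    walkers : int
        Ensemble size (>= 2x the free-parameter count).
    seed : int
        Controls initialisation and sampling; same seed, same posterior.
    dt : float
        Step (days) of the exponential-integrator grid used in the likelihood.
    shared_nu : bool
        Tie the alpha(t) and beta(t) sigmoid shapes to a single nu (default,
        as in the reference model); set False to free them separately.
    priors : dict[str, PriorSpec], optional
        Overrides for individual parameters.
    map_init : bool
        Start the ensemble in a small ball around the posterior mode.
    target_posterior_draws : int
        Retained draws are thinned to roughly this many total samples.

    Attributes (after ``fit``)
    --------------------------
    posterior_ : dict[str, ndarray]
        Natural-scale draws, shape (chains, draws-per-chain), including the
        derived ``half_life_ctrl``, ``half_life_n2ko`` and (time-varying
        influx) ``influx_halving_time``.
    summary_ : DataFrame
        parameter, median, ci_low, ci_high (95% equal-tailed), rhat, ess.
    idata_ : arviz.InferenceData
        Posterior plus pointwise log-likelihood, ready for PSIS-LOO.
    map_params_ : RateParameters at the posterior mode.
    converged_ : bool (all split-R-hat < 1.01).
    """

    def __init__(self, model="branched_tvi", draws=1500, tune=1500, walkers=None,
                 seed=0, dt=0.05, shared_nu=True, priors=None, map_init=True,
                 target_posterior_draws=2000):
        self.model = model
        self.draws = draws
        self.tune = tune
        self.walkers = walkers
        self.seed = seed
        self.dt = dt
        self.shared_nu = shared_nu
        self.priors = priors
        self.map_init = map_init
        self.target_posterior_draws = target_posterior_draws

    # -- helpers ----------------------------------------------------------
    @property
    def spec_(self) -> ModelSpec:
        return (self.model if isinstance(self.model, ModelSpec)
                else ModelSpec.from_name(self.model))

    def fit(self, data: CohortDataset, sources: SourceTrajectoryPair = None):
        """Fit to a cohort.  ``sources`` defaults to curves fitted from the
        cohort's own FoB_total / MZB_CARneg records."""
        if sources is None:
            from .sources import fit_sources_from_cohort
            sources = fit_sources_from_cohort(data)
        spec = self.spec_
        table = _prepare_observations(data)
        priors = default_priors(spec, data, shared_nu=self.shared_nu)
        if self.priors:
            priors.update(self.priors)
        lp = _LogProb(spec, priors, table, sources, t0=4.0, dt=self.dt,
                      shared_nu=self.shared_nu)
        self.logprob_ = lp
        self.sources_ = sources
        self.observations_ = table
        ndim = lp.ndim
        nwalkers = self.walkers or max(2 * ndim + 4, 24)
        if nwalkers < 2 * ndim:
            raise ConfigurationError("walkers must be >= 2x free parameters")

        rng = np.random.RandomState(self.seed % (2**31))
        theta0 = lp.initial_theta()
        if self.map_init:
            theta0 = self._find_map(lp, theta0)
        self.map_theta_ = theta0
        self.map_params_ = lp.to_rate_params(theta0)

        # Laplace preconditioner: sample in a space whitened by the Hessian
        # at the mode, which removes the strong linear ridges (e.g. mu~lambda
        # from the quasi-steady influx/loss balance) from the walkers' view.
        L = self._laplace_cholesky(lp, theta0)
        logp_white = lambda phi: lp(theta0 + L @ phi)
        moves = [(emcee.moves.DEMove(), 0.6),
                 (emcee.moves.DEMove(gamma0=1.0), 0.2),
                 (emcee.moves.DESnookerMove(), 0.2)]

        p0 = rng.standard_normal((nwalkers, ndim))
        sampler = emcee.EnsembleSampler(nwalkers, ndim, logp_white, moves=moves)
        sampler.random_state = rng.get_state()
        sampler.run_mcmc(p0, self.tune + self.draws, progress=False,
                         skip_initial_state_check=True)

        total = self.draws * nwalkers
        thin = max(int(np.ceil(total / max(self.target_posterior_draws, 1))), 1)
        phi_chain = sampler.get_chain(discard=self.tune, thin=thin)
        chain = np.einsum("ij,swj->swi", L, phi_chain) + theta0  # (n, walkers, ndim)
        self.acceptance_fraction_ = float(np.mean(sampler.acceptance_fraction))
        self._finalize(lp, chain)
        return self

    @staticmethod
    def _laplace_cholesky(lp: _LogProb, theta0: np.ndarray,
                          eps: float = 1e-4) -> np.ndarray:
        """Cholesky factor of the (regularised) inverse Hessian of -log p."""
        n = len(theta0)

        def nlp(theta):
            v = lp(theta)
            return 1e12 + float(np.sum(theta**2)) if not np.isfinite(v) else -v

        H = np.empty((n, n))
        f0 = nlp(theta0)
        shifts = eps * np.eye(n)
        f_i = np.array([nlp(theta0 + shifts[i]) for i in range(n)])
        for i in range(n):
            for j in range(i, n):
                fij = nlp(theta0 + shifts[i] + shifts[j])
                H[i, j] = H[j, i] = (fij - f_i[i] - f_i[j] + f0) / eps**2
        w, V = np.linalg.eigh((H + H.T) / 2.0)
        w = np.clip(w, 1e-4, None)  # floor flat/negative directions
        cov = V @ np.diag(1.0 / w) @ V.T
        return np.linalg.cholesky(cov)

    def _find_map(self, lp: _LogProb, theta0: np.ndarray) -> np.ndarray:
        def nlp(theta):
            v = lp(theta)
            if not np.isfinite(v):
                return 1e12 + float(np.sum(theta**2))
            return -v

        best = minimize(nlp, theta0, method="Nelder-Mead",
                        options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-8})
        refined = minimize(nlp, best.x, method="L-BFGS-B",
                           options={"maxiter": 500})
        return refined.x if refined.fun <= best.fun else best.x

    def _finalize(self, lp: _LogProb, chain: np.ndarray):
        n_kept, nwalkers, ndim = chain.shape
        # (chain, draw, dim) layout for arviz
        theta = np.transpose(chain, (1, 0, 2))
        posterior = {}
        for j, name in enumerate(lp.names):
            posterior[name] = np.exp(theta[:, :, j])
        if "lambda_ctrl" in posterior:
            posterior["half_life_ctrl"] = clonal_half_life(posterior["lambda_ctrl"])
        if "lambda_n2ko" in posterior:
            posterior["half_life_n2ko"] = clonal_half_life(posterior["lambda_n2ko"])
        if "nu3" in posterior:
            posterior["influx_halving_time"] = np.sqrt(np.log(3.0) / posterior["nu3"])

        flat = theta.reshape(-1, ndim)
        pw = np.empty((flat.shape[0], len(lp.ln_counts)))
        for i in range(flat.shape[0]):
            pw[i] = lp.pointwise(flat[i])
        loglik = pw.reshape(nwalkers, n_kept, -1)

        self.idata_ = az.from_dict(
            posterior=posterior,
            log_likelihood={"obs": loglik},
            coords={"obs_id": np.arange(loglik.shape[-1])},
            dims={"obs": ["obs_id"]},
        )
        self.posterior_ = posterior
        self.loglik_matrix_ = pw  # (total draws, observations)

        rows = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for name, draws2d in posterior.items():
                flat_d = draws2d.reshape(-1)
                lo, hi = np.quantile(flat_d, [0.025, 0.975])
                rhat = float(az.rhat(az.convert_to_dataset({name: draws2d}))[name])
                ess = float(az.ess(az.convert_to_dataset({name: draws2d}))[name])
                rows.append({"parameter": name, "median": float(np.median(flat_d)),
                             "ci_low": float(lo), "ci_high": float(hi),
                             "rhat": rhat, "ess": ess})
        self.summary_ = pd.DataFrame(rows)
        free = self.summary_["parameter"].isin(lp.names)
        self.converged_ = bool((self.summary_.loc[free, "rhat"] < 1.01).all())
        if not self.converged_:
            warnings.warn(
                f"model {self.spec_.name}: split-R-hat >= 1.01 for some "
                "parameters; treat the posterior with caution")

    # -- post-fit API ------------------------------------------------------
    def params_at(self, flat_index: int) -> RateParameters:
        """RateParameters for one retained posterior draw."""
        lp = self.logprob_
        theta = np.log(np.stack([self.posterior_[n].reshape(-1)
                                 for n in lp.names], axis=1))
        return lp.to_rate_params(theta[flat_index])

    def draws_frame(self) -> pd.DataFrame:
        return pd.DataFrame({k: v.reshape(-1) for k, v in self.posterior_.items()})

    def predict(self, times, group: str = "control",
                population: str = "MZB_CARpos") -> np.ndarray:
        """Posterior-median trajectory of one observed series."""
        env = self.trajectory_envelope(times, group, population)
        return env["median"].to_numpy()

    def trajectory_envelope(self, times, group="control", population="MZB_CARpos",
                            max_draws: int = 400) -> pd.DataFrame:
        """Median and 95% credible band of the fitted trajectory over time."""
        times = np.asarray(times, dtype=float)
        lp = self.logprob_
        theta_all = np.log(np.stack([self.posterior_[n].reshape(-1)
                                     for n in lp.names], axis=1))
        step = max(len(theta_all) // max_draws, 1)
        sel = theta_all[::step]
        curves = np.empty((len(sel), len(times)))
        which = {"GCB_CARpos": 0, "MZB_CARpos": 1}[population]
        if group == "n2ko" and population == "MZB_CARpos":
            which = 2
        for i, th in enumerate(sel):
            G, M, M_n2 = lp._trajectory_arrays(th)
            curves[i] = np.interp(times, lp.grid, (G, M, M_n2)[which])
        lo, med, hi = np.quantile(curves, [0.025, 0.5, 0.975], axis=0)
        return pd.DataFrame({"time": times, "median": med, "mean": curves.mean(axis=0),
                             "ci_low": lo, "ci_high": hi})

    def loo(self):
        """PSIS-LOO expected log predictive density for this fit."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return az.loo(self.idata_, pointwise=True)


def fit(spec, data, sources=None, priors=None, seed=0, draws=600, tune=600,
        **kwargs) -> BCellFateModel:
    """Functional wrapper over :class:`BCellFateModel`."""
    est = BCellFateModel(model=spec, priors=priors, seed=seed, draws=draws,
                         tune=tune, **kwargs)
    return est.fit(data, sources=sources)
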