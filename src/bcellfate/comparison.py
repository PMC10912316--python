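"""Model ranking by PSIS-LOO cross-validation and percentage weights.

Every fitted family member carries a draws x observations matrix of pointwise
log-likelihoods.  Leave-one-out expected log predictive density (elpd) is
estimated by Pareto-smoothed importance sampling; models fitted to the same
observations are then combined into percentage weights, by default with
pseudo-BMA+ (Bayesian-bootstrap-regularised elpd weights) and optionally by
stacking of predictive distributions.  Observations whose Pareto shape k
exceeds 0.7 are flagged as unreliable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .errors import ConfigurationError, DomainError

PARETO_K_THRESHOLD = 0.7


@dataclass(frozen=True)
class LooResult:
    elpd: float
    se: float
    pareto_k: np.ndarray
    pointwise: np.ndarray

    @property
    def flagged(self) -> np.ndarray:
        """Indices of observations with Pareto k above the 0.7 threshold."""
        return np.flatnonzero(self.pareto_k > PARETO_K_THRESHOLD)


def loo_elpd(pointwise_loglik, reff: float = 1.0) -> LooResult:
    """PSIS-LOO elpd from a (draws x observations) log-likelihood matrix.

    With too few draws for a Pareto tail fit, the smoothing is a no-op and the
    estimate reduces to raw importance sampling (the harmonic-mean identity
    ``elpd_i = log S - logsumexp(-loglik_i)``).
    """
    mat = np.asarray(pointwise_loglik, dtype=float)
    if mat.ndim != 2:
        raise DomainError("pointwise log-likelihood matrix must be draws x observations")
    bad = np.flatnonzero(~np.all(np.isfinite(mat), axis=0))
    if len(bad):
        raise DomainError(f"non-finite log-likelihood column(s) at observation(s) "
                          f"{bad.tolist()}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        log_weights, pareto_k = az.psislw(-mat.T, reff=reff)  # (obs, draws)
    pointwise = logsumexp(mat.T + np.asarray(log_weights), axis=1)
    elpd = float(pointwise.sum())
    n = mat.shape[1]
    se = float(np.sqrt(n * np.var(pointwise)))
    return LooResult(elpd=elpd, se=se, pareto_k=np.asarray(pareto_k),
                     pointwise=pointwise)


@dataclass(frozen=True)
class ComparisonTable:
    """Ranked LOO comparison of models fitted to the same observations."""

    table: pd.DataFrame  # index: model name; elpd_loo, se, weight_pct, rank, ...
    method: str
    subset: bool = False  # True for a restricted (e.g. one-on-one) comparison

    @property
    def best(self) -> str:
        return str(self.table.index[0])

    def weight(self, name: str) -> float:
        return float(self.table.loc[name, "weight_pct"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="model")

    def layout_grid(self) -> pd.DataFrame:
        """Weights as a topology x variant grid (percent)."""
        rows = {}
        for name in self.table.index:
            topo, _, variant = str(name).partition("_")
            rows.setdefault(topo, {})[variant] = self.table.loc[name, "weight_pct"]
        return pd.DataFrame(rows).T


def model_weights(fits: dict, method: str = "pseudo_bma_plus",
                  seed: int = 0, subset: bool = False) -> ComparisonTable:
    """Percentage LOO weights for >= 2 fitted models on identical data.

    ``fits`` maps model name to a fitted :class:`~bcellfate.inference.
    BCellFateModel` (or any object with an ``idata_`` carrying matching
    pointwise log-likelihoods).  ``method`` is ``"pseudo_bma_plus"`` (default;
    Bayesian bootstrap with fixed ``seed``) or ``"stacking"``.
    """
    if len(fits) < 2:
        raise ConfigurationError("need at least two fitted models to compare")
    idatas = {}
    n_obs = None
    for name, fit in fits.items():
        idata = fit.idata_ if hasattr(fit, "idata_") else fit
        m = idata.log_likelihood["obs"].shape[-1]
        if n_obs is None:
            n_obs = m
        elif m != n_obs:
            raise ConfigurationError(
                f"model {name!r} has {m} observations, others have {n_obs}; "
                "LOO weights require identical observation sets")
        idatas[name] = idata

    az_method = {"pseudo_bma_plus": "BB-pseudo-BMA", "stacking": "stacking"}.get(method)
    if az_method is None:
        raise ConfigurationError(f"unknown weight method {method!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cmp = az.compare(idatas, ic="loo", method=az_method, seed=seed % (2**31))

    table = pd.DataFrame({
        "elpd_loo": cmp["elpd_loo"],
        "se": cmp["se"],
        "weight_pct": 100.0 * cmp["weight"],
        "rank": cmp["rank"],
        "pareto_k_max": [
            float(np.max(az.loo(idatas[m], pointwise=True).pareto_k))
            for m in cmp.index
        ],
    })
    table = table.sort_values("rank")
    return ComparisonTable(table=table, method=method, subset=subset)


def one_on_one(fits: dict, a: str, b: str, method: str = "pseudo_bma_plus",
               seed: int = 0) -> ComparisonTable:
    """Pairwise re-normalised comparison of two family members."""
    return model_weights({a: fits[a], b: fits[b]}, method=method, seed=seed,
                         subset=True)
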