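"""Smooth empirical descriptions of the driver populations.

The dynamical models treat two pools as exogenous forcing terms: total
follicular B cells ``F(t)`` and CAR- marginal-zone B cells ``Mneg(t)``.  Both
are near-homeostatic pools that may shift transiently after immunization, so
we describe them with a four-parameter log-scale Gaussian bump,

    log N(t) = c0 + c1 * exp(-c2 * (t - c3)**2),

fitted by least squares on log counts (multiplicative inter-mouse noise).  A
natural cubic smoothing spline on log counts is available as an alternative
form.  Fitted curves are clamped to their boundary values outside the observed
day range, keeping every evaluator positive and continuous on the whole real
line.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import DomainError, InsufficientDataError

SourceKind = Literal["FoB", "CARneg_MZB"]


@dataclass(frozen=True)
class SourceTrajectory:
    """A positive, continuous map from day to population size, with clamped
    extrapolation outside ``support``."""

    kind: str
    support: tuple[float, float]
    form: str
    fit_params: tuple[float, ...]
    _log_evaluator: Callable[[np.ndarray], np.ndarray] = field(repr=False, compare=False, default=None)
    residual_sd: float = float("nan")

    def __call__(self, t):
        return self.evaluate(t)

    def evaluate(self, t):
        """Population size (cells) at time ``t`` (days); scalar in, scalar out."""
        t_arr = np.asarray(t, dtype=float)
        clamped = np.clip(t_arr, self.support[0], self.support[1])
        out = np.exp(self._log_evaluator(clamped))
        return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "support": list(self.support),
            "form": self.form,
            "fit_params": list(self.fit_params),
            "residual_sd": self.residual_sd,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SourceTrajectory":
        if d["form"] != "log_gaussian_bump":
            raise DomainError(f"cannot rebuild form {d['form']!r} from parameters alone")
        return log_gaussian_bump(d["kind"], *d["fit_params"],
                                 support=tuple(d["support"]),
                                 residual_sd=d.get("residual_sd", float("nan")))


@dataclass(frozen=True)
class SourceTrajectoryPair:
    """The two exogenous drivers needed by the ODE right-hand sides."""

    fob: SourceTrajectory
    mzb_carneg: SourceTrajectory


def log_gaussian_bump(kind: str, c0: float, c1: float, c2: float, c3: float,
                      support: tuple[float, float] = (0.0, 40.0),
                      residual_sd: float = float("nan")) -> SourceTrajectory:
    """Construct a source directly from log-bump coefficients."""
    params = (float(c0), float(c1), float(c2), float(c3))

    def log_eval(t, _p=params):
        return _p[0] + _p[1] * np.exp(-_p[2] * (t - _p[3]) ** 2)

    return SourceTrajectory(kind=kind, support=tuple(support), form="log_gaussian_bump",
                            fit_params=params, _log_evaluator=log_eval,
                            residual_sd=residual_sd)


def constant_source(kind: str, size: float,
                    support: tuple[float, float] = (0.0, 40.0)) -> SourceTrajectory:
    """A flat pool of ``size`` cells (log-bump with zero amplitude)."""
    if size <= 0:
        raise DomainError("pool size must be positive")
    return log_gaussian_bump(kind, np.log(size), 0.0, 0.0, 0.0, support=support)


class SourceCurve(BaseEstimator, RegressorMixin):
    """Least-squares fit of a driver-pool trajectory on log counts.

    Parameters
    ----------
    kind : str
        Which pool this curve describes (``"FoB"`` or ``"CARneg_MZB"``);
        metadata only.
    form : {"log_gaussian_bump", "spline"}
        Parametric family.  The default four-parameter bump captures both flat
        pools and transient post-immunization excursions; the spline is a
        natural cubic spline through per-day geometric means.

    Attributes
    ----------
    trajectory_ : SourceTrajectory
        The fitted evaluator.
    coef_ : ndarray
        Fitted coefficients (bump form only).
    residual_sd_ : float
        Standard deviation of log-count residuals.
    """

    def __init__(self, kind: str = "FoB", form: str = "log_gaussian_bump"):
        self.kind = kind
        self.form = form

    def fit(self, X, y):
        """Fit to observation days ``X`` (n,) or (n,1) and counts ``y`` (cells)."""
        days = np.asarray(X, dtype=float).reshape(-1)
        counts = np.asarray(y, dtype=float).reshape(-1)
        if days.shape != counts.shape:
            raise DomainError("days and counts must have equal length")
        if np.any(counts <= 0) or not np.all(np.isfinite(counts)):
            raise DomainError("counts must be positive and finite")
        if len(np.unique(days)) < 3:
            raise InsufficientDataError(
                f"need observations on >= 3 distinct days, got {len(np.unique(days))}"
            )
        logc = np.log(counts)
        support = (float(days.min()), float(days.max()))

        if self.form == "log_gaussian_bump":
            self.trajectory_ = self._fit_bump(days, logc, support)
            self.coef_ = np.asarray(self.trajectory_.fit_params)
        elif self.form == "spline":
            self.trajectory_ = self._fit_spline(days, logc, support)
        else:
            raise DomainError(f"unknown form {self.form!r}")
        self.residual_sd_ = float(
            np.std(logc - np.log(self.trajectory_.evaluate(days)), ddof=0)
        )
        object.__setattr__(self.trajectory_, "residual_sd", self.residual_sd_)
        return self

    def _fit_bump(self, days, logc, support) -> SourceTrajectory:
        def resid(p):
            c0, c1, c2, c3 = p
            return c0 + c1 * np.exp(-c2 * (days - c3) ** 2) - logc

        # Start from a flat pool with a bump at the most deviant day.  The
        # bump inverse-width c2 is capped so the excursion cannot be narrower
        # than the sampling resolution (the curve describes a smooth trend,
        # not an interpolant of per-day noise).
        c0_init = float(np.median(logc))
        idx = int(np.argmax(np.abs(logc - c0_init)))
        x0 = np.array([c0_init, logc[idx] - c0_init, 0.02, days[idx]])
        lo = [-np.inf, -3.0, 0.0, support[0] - 5.0]
        hi = [np.inf, 3.0, 0.08, support[1] + 5.0]
        best = None
        for x_start in (x0, np.array([c0_init, 0.0, 0.02, np.mean(support)])):
            sol = least_squares(resid, x_start, bounds=(lo, hi), xtol=1e-14,
                                ftol=1e-14, gtol=1e-14)
            if best is None or sol.cost < best.cost - 1e-15:
                best = sol
        return log_gaussian_bump(self.kind, *best.x, support=support)

    def _fit_spline(self, days, logc, support) -> SourceTrajectory:
        uniq = np.unique(days)
        means = np.array([logc[days == d].mean() for d in uniq])
        spline = CubicSpline(uniq, means, bc_type="natural")
        return SourceTrajectory(kind=self.kind, support=support, form="spline",
                                fit_params=tuple(means), _log_evaluator=spline)

    def predict(self, X):
        days = np.asarray(X, dtype=float).reshape(-1)
        return self.trajectory_.evaluate(days)


def fit_source(kind: str, observations, form: str = "log_gaussian_bump") -> SourceTrajectory:
    """Fit one driver pool from ``(day, count)`` pairs; see :class:`SourceCurve`."""
    obs = np.asarray(observations, dtype=float)
    curve = SourceCurve(kind=kind, form=form).fit(obs[:, 0], obs[:, 1])
    return curve.trajectory_


def fit_sources_from_cohort(cohort, form: str = "log_gaussian_bump") -> SourceTrajectoryPair:
    """Fit both drivers from a cohort table (groups pooled).

    ``cohort`` is anything with a ``to_frame()`` returning the tidy schema, or
    a DataFrame with columns day/population/count.
    """
    frame = cohort.to_frame() if hasattr(cohort, "to_frame") else cohort
    out = {}
    for kind, population in (("FoB", "FoB_total"), ("CARneg_MZB", "MZB_CARneg")):
        sub = frame[frame["population"] == population]
        if sub.empty:
            raise InsufficientDataError(f"cohort has no {population} observations")
        out[kind] = fit_source(kind, sub[["day", "count"]].to_numpy(), form=form)
    return SourceTrajectoryPair(fob=out["FoB"], mzb_carneg=out["CARneg_MZB"])


def save_sources(pair: SourceTrajectoryPair, path) -> None:
    with open(path, "w") as fh:
        json.dump({"fob": pair.fob.to_dict(), "mzb_carneg": pair.mzb_carneg.to_dict()},
                  fh, indent=2)


def load_sources(path) -> SourceTrajectoryPair:
    with open(path) as fh:
        d = json.load(fh)
    return SourceTrajectoryPair(fob=SourceTrajectory.from_dict(d["fob"]),
                                mzb_carneg=SourceTrajectory.from_dict(d["mzb_carneg"]))
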