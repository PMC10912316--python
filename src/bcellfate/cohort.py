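"""Synthetic cross-sectional immunization cohorts.

The generator reproduces the statistical structure the inference assumes: a
ground-truth model from the family is solved for the CAR+ GCB / CAR+ MZB
trajectories, the driver pools follow smooth log-Gaussian-bump curves, and
each mouse's counts are drawn log-normally around the day's true value
(multiplicative inter-mouse variability).  Each mouse is observed at exactly
one day and contributes one record per population, matching the study design:
control mice at days 4-30, Notch2-knockout mice at days 7, 9 and 14.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .data import CohortDataset, cohort_from_records
from .dynamics import solve
from .errors import ConfigurationError, IntegrationError
from .params import ModelSpec, RateParameters
from .sources import SourceTrajectoryPair, log_gaussian_bump

#: Per-day mouse numbers of the emulated design (control days 4-30, N2KO days
#: 7-14).  48 control + 18 knockout mice.
CONTROL_DESIGN = {4: 3, 7: 9, 9: 3, 14: 15, 17: 3, 22: 5, 26: 4, 30: 6}
N2KO_DESIGN = {7: 7, 9: 5, 14: 6}

#: Multiplicative (ln-scale) inter-mouse noise per population.  The activated
#: CAR+ compartments are the noisiest; the homeostatic driver pools are
#: tighter.
DEFAULT_SIGMA = {
    "GCB_CARpos": 0.5,
    "MZB_CARpos": 0.5,
    "MZB_CARneg": 0.25,
    "FoB_total": 0.2,
}


def default_truth_sources() -> SourceTrajectoryPair:
    """Ground-truth driver pools: ~1.5e7 FoB cells with a mild transient
    expansion peaking mid-response (day ~14, with the GC), ~1e6 CAR- MZB
    cells with a mild dip around day 12 as activation converts them."""
    fob = log_gaussian_bump("FoB", np.log(1.5e7), 0.15, 0.02, 14.0, support=(0.0, 40.0))
    mzb = log_gaussian_bump("CARneg_MZB", np.log(1.0e6), -0.20, 0.03, 12.0,
                            support=(0.0, 40.0))
    return SourceTrajectoryPair(fob=fob, mzb_carneg=mzb)


def reference_truth() -> tuple[ModelSpec, RateParameters]:
    """The reference ground truth: branched topology with time-varying influx.

    Rates use the study-scale values — FoB->MZB differentiation mu = 1/1430
    per day, per-capita CAR- activation scale beta0 = 1/150 per day, CAR+ MZB
    net loss 0.49 (control) and 0.94 (Notch2-KO) per day — with the shared
    influx shape nu chosen so the sigmoid influx rate halves (relative to its
    day-4 value) 14.2 days after the anchor, i.e. nu = ln 3 / 14.2**2.
    """
    spec = ModelSpec(topology="branched", influx_time_varying=True)
    nu = np.log(3.0) / 14.2**2
    params = RateParameters(
        alpha0=5.0e-3,
        beta0=1.0 / 150.0,
        delta0=0.25,
        mu=1.0 / 1430.0,
        lambda_ctrl=0.49,
        lambda_n2ko=0.94,
        t0=4.0,
        G0=1.0e4,
        M0=2.5e4,
        # groups are indistinguishable up to the day-4 anchor, so the N2KO
        # CAR+ MZB pool starts at the control value and diverges only through
        # its faster loss and missing FoB influx
        M0_n2=2.5e4,
    ).with_shared_nu(nu)
    return spec, params


def influx_halving_time(nu: float) -> float:
    """Days after t0 at which a sigmoid influx rate falls to half its value at
    t0 (where it equals scale/2): solves exp(nu*dt^2) = 3."""
    if not nu > 0:
        raise ConfigurationError("halving time defined only for nu > 0")
    return float(np.sqrt(np.log(3.0) / nu))


@dataclass(frozen=True)
class CohortDesign:
    """Sampling design plus ground truth for one synthetic cohort."""

    seed: int
    control_days: dict = field(default_factory=lambda: dict(CONTROL_DESIGN))
    n2ko_days: dict = field(default_factory=lambda: dict(N2KO_DESIGN))
    sigma: dict = field(default_factory=lambda: dict(DEFAULT_SIGMA))
    spec: ModelSpec = None
    params: RateParameters = None
    sources: SourceTrajectoryPair = None
    include_n2ko_gcb: bool = True

    def __post_init__(self):
        if self.seed is None:
            raise ConfigurationError("CohortDesign requires an explicit seed")
        for design in (self.control_days, self.n2ko_days):
            if any(n < 1 for n in design.values()):
                raise ConfigurationError("per-day mouse count must be >= 1")
        if any(s < 0 for s in self.sigma.values()):
            raise ConfigurationError("noise sigma must be >= 0")
        if self.spec is None or self.params is None:
            spec, params = reference_truth()
            object.__setattr__(self, "spec", self.spec or spec)
            object.__setattr__(self, "params", self.params or params)
        if self.sources is None:
            object.__setattr__(self, "sources", default_truth_sources())


def generate(design: CohortDesign) -> tuple[CohortDataset, dict]:
    """Draw one synthetic cohort; returns the dataset and a ground-truth record.

    Counts are sampled as ``exp(Normal(ln truth(day), sigma_pop))``.  The
    CAR+ GCB trajectory is shared between groups (its dynamics do not depend
    on Notch2 status); the N2KO CAR+ MZB trajectory uses lambda' and mu = 0.
    Fully reproducible from ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    days = sorted(set(design.control_days) | set(design.n2ko_days))
    try:
        traj = solve(design.spec, design.params, design.sources, np.asarray(days, float),
                     method="lsoda")
    except IntegrationError:
        raise
    truth_at_day = {
        d: {"GCB_CARpos": traj.G[i], "MZB_CARpos": traj.M[i],
            "MZB_CARpos_n2": traj.M_n2[i],
            "MZB_CARneg": design.sources.mzb_carneg.evaluate(d),
            "FoB_total": design.sources.fob.evaluate(d)}
        for i, d in enumerate(days)
    }

    records = []

    def add_mouse(mouse_id, group, day, pops):
        for pop, true_value in pops:
            sigma = design.sigma[pop]
            noise = rng.normal(0.0, sigma) if sigma > 0 else 0.0
            records.append((mouse_id, group, day, pop,
                            float(np.exp(np.log(max(true_value, 1e-300)) + noise))))

    idx = 0
    for day, n in sorted(design.control_days.items()):
        tv = truth_at_day[day]
        for _ in range(n):
            idx += 1
            add_mouse(f"ctrl_{idx:03d}", "control", day,
                      [("GCB_CARpos", tv["GCB_CARpos"]),
                       ("MZB_CARpos", tv["MZB_CARpos"]),
                       ("MZB_CARneg", tv["MZB_CARneg"]),
                       ("FoB_total", tv["FoB_total"])])
    idx = 0
    for day, n in sorted(design.n2ko_days.items()):
        tv = truth_at_day[day]
        for _ in range(n):
            idx += 1
            pops = [("MZB_CARpos", tv["MZB_CARpos_n2"]),
                    ("MZB_CARneg", tv["MZB_CARneg"]),
                    ("FoB_total", tv["FoB_total"])]
            if design.include_n2ko_gcb:
                pops.insert(0, ("GCB_CARpos", tv["GCB_CARpos"]))
            add_mouse(f"n2ko_{idx:03d}", "n2ko", day, pops)

    truth = {
        "seed": design.seed,
        "spec": asdict(design.spec),
        "params": asdict(design.params),
        "sigma": dict(design.sigma),
        "sources": {"fob": design.sources.fob.to_dict(),
                    "mzb_carneg": design.sources.mzb_carneg.to_dict()},
        "trajectory_at_days": {str(d): {k: float(v) for k, v in tv.items()}
                               for d, tv in truth_at_day.items()},
    }
    return cohort_from_records(records), truth


def save_ground_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2)
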