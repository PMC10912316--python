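"""Model topologies, rate-variant flags and rate-parameter containers.

The compartment models describe two activated B-cell populations after a
T-dependent immunization: CAR+ germinal-center B cells (GCB, ``G``) and CAR+
marginal-zone B cells (MZB, ``M``; ``M_n2`` in Notch2-knockout mice).  Three
topologies differ only in the source feeding the CAR+ MZB pool:

- ``branched``: activated follicular B (FoB) cells differentiate directly into
  CAR+ MZB cells (per-capita rate ``mu`` acting on the FoB pool);
- ``linear``: GCB cells differentiate into CAR+ MZB cells (``mu`` acting on G);
- ``null``: CAR+ MZB cells arise only from activation of pre-existing CAR- MZB
  cells (``mu`` plays no role).

Each topology can be combined with one rate-time-dependence variant: neutral
(all rates constant), time-varying influx (``alpha`` and ``beta`` decay as a
shared sigmoid of time since the anchor day), or time-varying GCB loss
(``delta`` decays instead).  A tenth family member adds time dependence to
``mu`` on top of the branched time-varying-influx model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

from .errors import ConfigurationError, DomainError

Topology = Literal["branched", "linear", "null"]

#: Default anchor day: cell counts are indistinguishable between groups up to
#: day 4 post-immunization, so all models start there.
T0_DEFAULT = 4.0


@dataclass(frozen=True)
class RateParameters:
    """Scalar rates, sigmoid shape parameters and initial pool sizes.

    All rates are per day; pool sizes are absolute cell numbers at the anchor
    time ``t0`` (day 4 by default).  ``nu1``/``nu2``/``nu3`` (day^-2) shape the
    sigmoid time dependence of the GCB loss rate, the FoB->GCB recruitment rate
    and the CAR- -> CAR+ MZB activation rate respectively; a time-varying
    ``mu`` reuses ``nu3``.

    ``lambda_ctrl`` and ``lambda_n2ko`` are the net loss rates of CAR+ MZB
    cells in control and Notch2-knockout mice (``lambda`` and ``lambda'``).
    """

    alpha0: float = 0.0          # FoB -> GCB recruitment scale (day^-1)
    beta0: float = 0.0           # CAR- -> CAR+ MZB activation scale (day^-1, per capita)
    delta0: float = 0.0          # GCB net-loss scale (day^-1)
    mu: float = 0.0              # differentiation rate into CAR+ MZB (day^-1)
    lambda_ctrl: float = 0.0     # CAR+ MZB net loss, control (day^-1)
    lambda_n2ko: float = 0.0     # CAR+ MZB net loss, N2KO (day^-1)
    nu1: float = 0.0             # shape of delta(t) (day^-2)
    nu2: float = 0.0             # shape of alpha(t) (day^-2)
    nu3: float = 0.0             # shape of beta(t) (and mu(t)) (day^-2)
    t0: float = T0_DEFAULT       # anchor time (days post-immunization)
    G0: float = 0.0              # CAR+ GCB pool at t0 (cells)
    M0: float = 0.0              # CAR+ MZB pool at t0, control (cells)
    M0_n2: float = 0.0           # CAR+ MZB pool at t0, N2KO (cells)

    def __post_init__(self):
        for name in ("alpha0", "beta0", "delta0", "mu", "lambda_ctrl",
                     "lambda_n2ko", "nu1", "nu2", "nu3", "G0", "M0", "M0_n2"):
            value = getattr(self, name)
            if not value >= 0.0:
                raise DomainError(f"RateParameters.{name} must be >= 0, got {value!r}")

    def with_shared_nu(self, nu: float) -> "RateParameters":
        """Return a copy with a single shared sigmoid shape for all rates."""
        return replace(self, nu1=nu, nu2=nu, nu3=nu)


@dataclass(frozen=True)
class ModelSpec:
    """One member of the model family: a topology plus rate-variant flags.

    At most one of ``influx_time_varying`` and ``loss_time_varying`` may be
    set (the family treats them as alternatives), and ``mu_time_varying``
    requires the branched or linear topology with time-varying influx.
    """

    topology: Topology
    influx_time_varying: bool = False
    loss_time_varying: bool = False
    mu_time_varying: bool = False

    def __post_init__(self):
        if self.topology not in ("branched", "linear", "null"):
            raise ConfigurationError(f"unknown topology {self.topology!r}")
        if self.influx_time_varying and self.loss_time_varying:
            raise ConfigurationError(
                "influx_time_varying and loss_time_varying are mutually exclusive"
            )
        if self.mu_time_varying:
            if self.topology == "null":
                raise ConfigurationError("null topology has no mu; mu_time_varying invalid")
            if not self.influx_time_varying:
                raise ConfigurationError(
                    "mu_time_varying is defined as an extension of the "
                    "time-varying-influx model"
                )

    @property
    def uses_mu(self) -> bool:
        return self.topology != "null"

    @property
    def name(self) -> str:
        if self.mu_time_varying:
            variant = "tvi_mut"
        elif self.influx_time_varying:
            variant = "tvi"
        elif self.loss_time_varying:
            variant = "tvloss"
        else:
            variant = "neutral"
        return f"{self.topology}_{variant}"

    @classmethod
    def from_name(cls, name: str) -> "ModelSpec":
        topology, _, variant = name.partition("_")
        flags = {
            "neutral": {},
            "tvi": {"influx_time_varying": True},
            "tvloss": {"loss_time_varying": True},
            "tvi_mut": {"influx_time_varying": True, "mu_time_varying": True},
        }
        if variant not in flags:
            raise ConfigurationError(f"unknown model name {name!r}")
        return cls(topology=topology, **flags[variant])  # type: ignore[arg-type]

    def free_parameter_names(self) -> list[str]:
        """Names of the RateParameters fields this spec actually uses."""
        names = ["alpha0", "beta0", "delta0", "lambda_ctrl", "lambda_n2ko",
                 "G0", "M0", "M0_n2"]
        if self.uses_mu:
            names.insert(3, "mu")
        if self.influx_time_varying:
            names.append("nu3")  # shared influx shape (nu2 tied to nu3 by default)
        if self.loss_time_varying:
            names.append("nu1")
        return names


def enumerate_model_family() -> list[ModelSpec]:
    """The ten candidate models: 3 topologies x 3 variants, plus branched
    time-varying influx with time-varying ``mu``."""
    family = []
    for topology in ("branched", "linear", "null"):
        for flags in ({}, {"influx_time_varying": True}, {"loss_time_varying": True}):
            family.append(ModelSpec(topology=topology, **flags))  # type: ignore[arg-type]
    family.append(ModelSpec(topology="branched", influx_time_varying=True,
                            mu_time_varying=True))
    return family
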