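"""Tidy per-mouse cohort container shared by the whole pipeline.

The design is cross-sectional: each mouse is sacrificed at a single day
post-immunization and contributes at most one count per population.  Groups
are ``control`` (functional Notch2) and ``n2ko`` (activation-induced Notch2
deletion); populations are CAR+ germinal-center B cells, CAR+ and CAR-
marginal-zone B cells, and the total follicular-B pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CohortParseError

GROUPS = ("control", "n2ko")
POPULATIONS = ("GCB_CARpos", "MZB_CARpos", "MZB_CARneg", "FoB_total")
COLUMNS = ("mouse_id", "group", "day", "population", "count")


@dataclass(frozen=True)
class CohortDataset:
    """Validated tidy table of per-mouse counts."""

    frame: pd.DataFrame

    def __post_init__(self):
        f = self.frame
        missing = [c for c in COLUMNS if c not in f.columns]
        if missing:
            raise CohortParseError(f"missing columns: {missing}", column=missing[0])
        for i, g in enumerate(f["group"]):
            if g not in GROUPS:
                raise CohortParseError(
                    f"unknown group {g!r} (expected one of {GROUPS}) at row {i + 1}",
                    row=i + 1, column="group")
        for i, p in enumerate(f["population"]):
            if p not in POPULATIONS:
                raise CohortParseError(
                    f"unknown population {p!r} (expected one of {POPULATIONS}) "
                    f"at row {i + 1}", row=i + 1, column="population")
        counts = pd.to_numeric(f["count"], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(counts) | (counts < 0))
        if len(bad):
            raise CohortParseError(
                f"count must be a non-negative number at row {bad[0] + 1}",
                row=int(bad[0]) + 1, column="count")
        days = pd.to_numeric(f["day"], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(days) | (days < 0))
        if len(bad):
            raise CohortParseError(
                f"day must be a non-negative number at row {bad[0] + 1}",
                row=int(bad[0]) + 1, column="day")
        dup = f.duplicated(subset=["mouse_id", "population"])
        if dup.any():
            i = int(np.flatnonzero(dup.to_numpy())[0])
            raise CohortParseError(
                f"duplicate (mouse_id, population) pair at row {i + 1}",
                row=i + 1, column="mouse_id")
        # cross-sectional design: one sampling day per mouse
        per_mouse = f.groupby("mouse_id")["day"].nunique()
        multi = per_mouse[per_mouse > 1]
        if len(multi):
            raise CohortParseError(
                f"mouse {multi.index[0]!r} appears at more than one day "
                "(design is cross-sectional)")

    def to_frame(self) -> pd.DataFrame:
        return self.frame.copy()

    @property
    def records(self):
        return list(self.frame.itertuples(index=False, name="CohortRecord"))

    def __len__(self) -> int:
        return len(self.frame)

    def n_mice(self, group: str | None = None) -> int:
        f = self.frame if group is None else self.frame[self.frame["group"] == group]
        return f["mouse_id"].nunique()

    def observations(self, group: str, population: str) -> pd.DataFrame:
        """Sub-table for one group/population, sorted by day then mouse id."""
        f = self.frame
        sub = f[(f["group"] == group) & (f["population"] == population)]
        return sub.sort_values(["day", "mouse_id"]).reset_index(drop=True)

    def subset(self, populations) -> "CohortDataset":
        return CohortDataset(
            self.frame[self.frame["population"].isin(populations)].reset_index(drop=True))


def cohort_from_records(records) -> CohortDataset:
    return CohortDataset(pd.DataFrame(records, columns=list(COLUMNS)))
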