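"""Cohort CSV readers/writers and the pipeline configuration object.

The single data format is a long (tidy) CSV with header
``mouse_id,group,day,population,count``: integer days post-immunization,
absolute cell counts, groups ``control``/``n2ko``, populations
``GCB_CARpos``/``MZB_CARpos``/``MZB_CARneg``/``FoB_total``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from .data import COLUMNS, CohortDataset
from .errors import CohortParseError


def read_cohort(path) -> CohortDataset:
    """Read and validate a cohort CSV; schema errors name the offending row."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cohort file not found: {path}")
    try:
        frame = pd.read_csv(path, dtype={"mouse_id": str, "group": str,
                                         "population": str})
    except Exception as exc:  # malformed CSV
        raise CohortParseError(f"could not parse {path}: {exc}") from exc
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise CohortParseError(f"{path}: missing column(s) {missing}",
                               column=missing[0])
    return CohortDataset(frame[list(COLUMNS)])


def write_cohort(data: CohortDataset, path) -> None:
    data.to_frame().to_csv(path, index=False)


class PipelineConfig(BaseModel):
    """Everything needed to re-run the pipeline end to end."""

    cohort_csv: str
    output_dir: str
    seed: int
    models: list[str] = Field(default_factory=lambda: ["branched_tvi"])
    draws: int = 600
    tune: int = 600
    walkers: int | None = None
    dt: float = 0.05
    shared_nu: bool = True
    source_form: str = "log_gaussian_bump"
    comparison_method: str = "pseudo_bma_plus"
    prediction_times: list[float] = Field(
        default_factory=lambda: [float(t) for t in range(4, 31)])
    correlation_pairs: list[list[str]] = Field(
        default_factory=lambda: [["GCB_CARpos", "MZB_CARpos"]])

    @field_validator("seed")
    @classmethod
    def _seed_required(cls, v):
        if v is None:
            raise ValueError("seed is required")
        return v

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
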