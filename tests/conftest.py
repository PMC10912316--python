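import warnings

import numpy as np
import pytest

import bcellfate as bf

# arviz emits refactor FutureWarnings on import/use; they are not ours
warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture(scope="session")
def study_truth():
    """Reference ground truth: branched time-varying-influx model at
    study-scale rates."""
    return bf.reference_truth()


@pytest.fixture(scope="session")
def truth_sources():
    return bf.default_truth_sources()


@pytest.fixture(scope="session")
def constant_sources():
    """Flat driver pools: make forced-linear dynamics exactly solvable."""
    return bf.SourceTrajectoryPair(
        fob=bf.constant_source("FoB", 1.0e7),
        mzb_carneg=bf.constant_source("CARneg_MZB", 1.0e6),
    )


@pytest.fixture(scope="session")
def cohort():
    """One default-design synthetic cohort (48 control + 18 N2KO mice)."""
    data, truth = bf.generate(bf.CohortDesign(seed=11))
    return data, truth


@pytest.fixture(scope="session")
def smoke_fit(cohort, truth_sources):
    """One reduced-draw fit of the generating model, shared across tests."""
    data, _ = cohort
    est = bf.BCellFateModel(model="branched_tvi", seed=7, draws=400, tune=400)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(data, sources=truth_sources)
    return est
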