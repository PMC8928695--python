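"""Shared fixtures: phantom cohorts and pipeline reports built once."""
from __future__ import annotations

import numpy as np
import pytest

from sinusmrac.phantom import PhantomSpec, generate_cohort, generate_subject
from sinusmrac.volume_io import TissueProbabilitySet, VolumeGrid
from sinusmrac.workflow import RunConfig, run_pipeline


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    return PhantomSpec()


@pytest.fixture(scope="session")
def subject0(default_spec):
    return generate_subject(default_spec, 0)


@pytest.fixture(scope="session")
def cohort10(default_spec):
    return generate_cohort(default_spec, 10)


@pytest.fixture(scope="session")
def run_config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def reports(cohort10, run_config):
    """Pipeline reports for all three sinus methods on the shared cohort."""
    return {
        method: run_pipeline(cohort10, method, run_config)
        for method in ("bulk", "cuboid", "template")
    }


def one_hot_probmaps(class_grid: np.ndarray, spacing=(2.0, 2.0, 2.0)) -> TissueProbabilitySet:
    """Build one-hot probability maps from a class-name array.

    ``class_grid`` holds strings out of grey/white/csf/soft/bone/air.
    """
    maps = {}
    for name in TissueProbabilitySet.CLASS_NAMES:
        maps[name] = VolumeGrid((class_grid == name).astype(float), spacing)
    return TissueProbabilitySet(**maps)
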