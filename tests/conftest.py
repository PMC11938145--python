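import numpy as np
import pytest

from agrocycle import synthetic
from agrocycle.optimize import ConstraintBounds
from agrocycle.pipeline import hydro_scenario_for, representative_precip
from agrocycle.straw import load_scenario_weights


@pytest.fixture(scope="session")
def study_config():
    return synthetic.StudyConfig(seed=42)


@pytest.fixture(scope="session")
def bundle(study_config):
    return synthetic.generate_parameters(study_config)


@pytest.fixture(scope="session")
def design(study_config):
    return synthetic.generate_design(study_config)


@pytest.fixture(scope="session")
def scenario_weights():
    return load_scenario_weights()


@pytest.fixture(scope="session")
def precip_cfg():
    return {"mean_mm": 553.2, "cv": 0.25, "cs": 0.5}


def make_toy(seed, n_crops=1, n_stages=2):
    """Small instance for optimizer tests: bundle, bounds, hydro scenario."""
    cfg = synthetic.StudyConfig(seed=seed, n_crops=n_crops, n_stages=n_stages)
    b = synthetic.generate_parameters(cfg)
    reps, _ = representative_precip({"mean_mm": 553.2, "cv": 0.25, "cs": 0.5})
    hydro = hydro_scenario_for(b, "normal", reps["normal"])
    bounds = ConstraintBounds(
        w_min=np.full(n_crops, 5.0),
        w_max=np.full(n_crops, 150.0),
        n_min=np.array([0.4 * c.recommended_n for c in b.crops]),
        n_max=np.array([1.6 * c.recommended_n for c in b.crops]),
    )
    return b, bounds, hydro


@pytest.fixture
def toy():
    return make_toy(seed=7)
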