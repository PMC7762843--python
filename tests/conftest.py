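import numpy as np
import pytest

from megdecode.datamodel import ConditionDesign, PipelineConfig
from megdecode.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config() -> PipelineConfig:
    return PipelineConfig(rng_seed=7, n_permutations=300)


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete two-region dataset (no injected effects)."""
    cfg = SimConfig(n_subjects=3, regions=["visual", "ctrl"], n_vertices=20,
                    n_trials=60, rng_seed=7)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def face_design() -> ConditionDesign:
    return ConditionDesign.default("face")
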