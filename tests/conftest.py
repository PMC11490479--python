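import numpy as np
import pytest

from cpmix import ModelParams, ScenarioConfig, ScheduleConfig
from cpmix.types import Experiment


@pytest.fixture
def params() -> ModelParams:
    return ModelParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def toy_config() -> ScenarioConfig:
    """22x12 interior, 2 cells per type, the standard tiny scenario."""
    return ScenarioConfig(
        width=22, height=12, n_per_type=2, a0=60, barrier_width=2,
        experiment=Experiment.MIXING,
        schedule=ScheduleConfig(relax_mcs=20, polarize_mcs=30,
                                total_mcs=120, sample_every=10),
        seed=7,
    )
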