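import numpy as np
import pytest

from combindex import (
    AgentSpec,
    DoseResponseDataset,
    InteractionSpec,
    MedianEffectModel,
    PlateConfig,
    predict_fa,
)


def noise_free_dataset(dm: float, m: float, multipliers=(0.125, 0.25, 0.5, 1, 2, 4),
                       agent="agent", experiment="exp1") -> DoseResponseDataset:
    """Exact observations from a known median-effect model."""
    model = MedianEffectModel(dm=dm, m=m)
    doses = np.asarray(multipliers, dtype=float) * dm
    return DoseResponseDataset.from_arrays(agent, experiment, doses,
                                           predict_fa(model, doses))


@pytest.fixture
def simple_model() -> MedianEffectModel:
    return MedianEffectModel(dm=1.0, m=1.0)


@pytest.fixture
def two_agent_panel():
    return [AgentSpec("A", true_dm=10.0, true_m=1.5),
            AgentSpec("B", true_dm=20.0, true_m=2.0)]


@pytest.fixture
def noise_free_plate() -> PlateConfig:
    return PlateConfig(n_experiments=2, replicates_per_dose=3,
                       noise_sd=0.0, control_wells=4, seed=11)


@pytest.fixture
def synergy_pair():
    return [InteractionSpec("A", "B", ci_star=0.5)]
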