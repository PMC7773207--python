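import numpy as np
import pytest
from hypothesis import settings

from zahnreihe.model import ModelParams
from zahnreihe.records import (
    load_canine_annotations,
    load_galesaurus_observations,
    load_galesaurus_table,
)

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def galesaurus_records():
    return load_galesaurus_table()


@pytest.fixture(scope="session")
def galesaurus_observations():
    return load_galesaurus_observations()


@pytest.fixture(scope="session")
def canine_flags():
    return load_canine_annotations()


def random_model_params(rng: np.random.Generator) -> ModelParams:
    """Randomized but valid simulator parameters for property runs."""
    waves_per_cycle = int(rng.integers(2, 5))
    return ModelParams(
        wave_spacing_k=int(rng.integers(2, 5)),
        waves_per_cycle=waves_per_cycle,
        adult_waves_per_cycle=int(rng.integers(1, waves_per_cycle + 1)),
        wave_interval_stages=int(rng.integers(1, 3)),
        within_wave_lag_stages=int(rng.integers(0, 3)),
        wave_direction=str(rng.choice(["back_to_front", "front_to_back"])),
        generations_at_mesial_locus=int(rng.integers(2, 4)),
        initial_locus_count=int(rng.integers(2, 7)),
        first_wave_stage=int(rng.integers(1, 4)),
    )
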