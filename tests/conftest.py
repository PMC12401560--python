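import numpy as np
import pytest

from fastball.simulate import GroupSpec, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20250919)


@pytest.fixture
def quiet_config():
    """Noise-free, artifact-free simulation config (pure tones)."""
    return SimulationConfig(
        noise_pink_uv=0.0,
        noise_white_uv=0.0,
        artifact_rate_per_min=0.0,
        seed=7,
    )


def two_group_config(d: float, n_per_group: int, sd: float = 0.3, seed: int = 0) -> SimulationConfig:
    """Config with two groups separated by a standardized difference d."""
    return SimulationConfig(
        groups={
            "A": GroupSpec(n_per_group, 1.0, sd),
            "B": GroupSpec(n_per_group, 1.0 - d * sd, sd),
        },
        seed=seed,
    )
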