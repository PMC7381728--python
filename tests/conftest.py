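import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def clean_scenario():
    """Noiseless default monitoring scenario (flashes at 300/630 s)."""
    from sonoperf import default_scenario

    cfg = default_scenario(noise_scale=0.0)
    cfg.noise.model = "none"
    return cfg


@pytest.fixture
def short_scenario():
    """Small, fast scenario: one flash at 30 s on a 100 s acquisition."""
    from sonoperf import NoiseSpec, Region, ScenarioConfig

    return ScenarioConfig(
        n_frames=400,
        frame_shape=(16, 16),
        frame_rate=4.0,
        regions=[
            Region("treated", A=10.0, beta=0.1, y0=0.5,
                   geometry={"shape": "disk", "center": (8, 5), "radius": 3}),
            Region("control", A=8.0, beta=0.1, y0=0.5,
                   geometry={"shape": "disk", "center": (8, 12), "radius": 2}),
        ],
        infusion_tau=5.0,
        flash_times=(30.0,),
        recirculation_delay=5.0,
        noise=NoiseSpec(model="none", scale=0.0),
        seed=0,
    )
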