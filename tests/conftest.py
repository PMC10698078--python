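import dataclasses

import pytest

from mycotrace import SimulationConfig, generate_study


@pytest.fixture(scope="session")
def study():
    """Default synthetic study (stated study conditions), fixed seed."""
    return generate_study(seed=7)


@pytest.fixture(scope="session")
def noise_free_config():
    """All stochastic spreads switched off: the deterministic skeleton."""
    return SimulationConfig(
        noise_sd_13c=0.0, noise_sd_15n=0.0,
        lateral_noise_sd_13c=0.0, lateral_noise_sd_15n=0.0,
        control_delta_sd=0.0, compartment_noise_frac=0.0,
        cn_jitter_sd=0.0,
    )


@pytest.fixture(scope="session")
def noise_free_study(noise_free_config):
    return generate_study(noise_free_config, seed=11)


@pytest.fixture()
def tweak():
    """Helper to derive a config variant from another config."""
    def _tweak(cfg, **kw):
        return dataclasses.replace(cfg, **kw)
    return _tweak
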