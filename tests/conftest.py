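import dataclasses

import pytest

from wristpaee.config import GeneratorConfig


def noise_free(config: GeneratorConfig | None = None, **overrides) -> GeneratorConfig:
    """Generator configuration with every error source switched off."""
    base = config or GeneratorConfig()
    return dataclasses.replace(
        base, criterion_noise_sd_log=0.0, person_offset_sd_log=0.0,
        sex_calibration_factor=(1.0, 1.0), trunk_person_sd_log=0.0,
        trunk_noise_sd_log=0.0, wrist_noise_sd_mg=0.0,
        wrist_person_offset_sd_mg=0.0, nonwear_rate=0.0, **overrides)


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """A fast 30-person, 2-day cohort used across unit tests."""
    return dataclasses.replace(GeneratorConfig(), n_participants=30, days=2, seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    from wristpaee.synthetic import generate_dataset
    return generate_dataset(small_config, with_latent=True)
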