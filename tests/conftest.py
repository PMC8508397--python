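"""Shared fixtures: station configs and seeded synthetic campaigns."""

from dataclasses import replace

import pytest

from uvidose import MORONI, SyntheticConfig, generate_campaign


@pytest.fixture(scope="session")
def station():
    return MORONI


@pytest.fixture(scope="session")
def clear_config():
    """A cloud-free, noise-free configuration (austral-summer start)."""
    cfg = SyntheticConfig(seed=11, n_days=3, start_date="2020-01-10", sensor_noise_sd=0.0)
    return replace(
        cfg,
        cloud=replace(
            cfg.cloud,
            ar1_sd=0.0,
            anchors=((0, 0.0), (1439, 0.0)),
            wet_multiplier=1.0,
            dry_multiplier=1.0,
        ),
    )


@pytest.fixture(scope="session")
def clear_bundle(clear_config):
    return generate_campaign(clear_config)


@pytest.fixture(scope="session")
def regime_config():
    """90 days of well-separated cloud regimes (clear cf < 0.1, cloudy cf > 0.5)."""
    return SyntheticConfig(seed=12, n_days=90, start_date="2020-01-01")


@pytest.fixture(scope="session")
def regime_bundle(regime_config):
    return generate_campaign(regime_config, regime=True)
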