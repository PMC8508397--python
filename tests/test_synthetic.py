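"""Determinism and physical consistency of the synthetic-station simulator."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from uvidose import (
    SyntheticConfig,
    generate_campaign,
    generate_cloud_day,
    generate_estimates,
    generate_hike,
    generate_regime_cloud_day,
    generate_uvi_day,
)
from uvidose.filtering import CLEAR
from uvidose.synthetic import cloud_baseline


def _quiet_cloud(cfg, **over):
    return replace(cfg, cloud=replace(cfg.cloud, **over))


def test_zero_noise_cloud_day_equals_baseline(station):
    cfg = _quiet_cloud(SyntheticConfig(seed=1), ar1_sd=0.0)
    cf, _ = generate_cloud_day(cfg, "2020-01-05", np.random.default_rng(1))
    assert np.allclose(cf["cf_total"].to_numpy(), cloud_baseline(cfg, "2020-01-05"))


def test_same_seed_reproduces_identical_series():
    cfg = SyntheticConfig(seed=42, n_days=2)
    a = generate_campaign(cfg)
    b = generate_campaign(cfg)
    pd.testing.assert_series_equal(a.uvi, b.uvi)
    pd.testing.assert_frame_equal(a.cf, b.cf)
    pd.testing.assert_series_equal(a.labels, b.labels)


def test_cloud_fraction_components_consistent():
    cfg = SyntheticConfig(seed=2, n_days=5)
    truth = generate_campaign(cfg)
    cf = truth.cf
    assert ((cf >= 0) & (cf <= 1)).all().all()
    total = cf["cf_thick"] + cf["cf_thin"]
    assert (total <= cf["cf_total"] + 0.05).all()


def test_many_day_mean_diurnal_cf_reproduces_baseline():
    """Law of large numbers: the per-minute mean converges to the baseline."""
    cfg = _quiet_cloud(
        SyntheticConfig(seed=3, n_days=300, start_date="2020-01-01"),
        ar1_sd=0.02,
        ar1_phi=0.9,
        wet_multiplier=1.0,
        dry_multiplier=1.0,
    )
    truth = generate_campaign(cfg)
    local_minute = (
        (truth.cf.index + pd.Timedelta(hours=3)).hour * 60
        + (truth.cf.index + pd.Timedelta(hours=3)).minute
    )
    mean_by_minute = truth.cf["cf_total"].groupby(local_minute).mean()
    baseline = cloud_baseline(cfg, "2020-01-01")
    assert np.abs(mean_by_minute.to_numpy() - baseline).max() <= 0.02


def test_overcast_day_attenuates_by_the_configured_fraction(station):
    cfg = replace(
        _quiet_cloud(SyntheticConfig(seed=4), ar1_sd=0.0, anchors=((0, 1.0), (1439, 1.0)),
                     wet_multiplier=1.0, dry_multiplier=1.0),
        sensor_noise_sd=0.0,
    )
    cf, _ = generate_cloud_day(cfg, "2020-01-05", np.random.default_rng(4))
    uvi, _, ref = generate_uvi_day(cfg, "2020-01-05", cf, np.random.default_rng(4))
    # cmf = 1 - 0.75 * 1**2 = 0.25: a 75 % reduction everywhere
    assert np.allclose(uvi.to_numpy(), ref.uvi_cs.to_numpy() * 0.25)


def test_clear_noiseless_day_equals_clear_sky_truth(clear_bundle):
    assert np.allclose(clear_bundle.uvi.to_numpy(), clear_bundle.uvi_cs.to_numpy())


def test_allsky_uvi_bounded_by_enhanced_clear_sky():
    cfg = SyntheticConfig(seed=5, n_days=10)
    truth = generate_campaign(cfg)
    assert (truth.uvi >= 0).all()
    assert (truth.uvi <= truth.uvi_cs * cfg.cmf.enhancement_max + 1e-12).all()


def test_regime_day_separation():
    cfg = SyntheticConfig(seed=6)
    cf, labels = generate_regime_cloud_day(cfg, "2020-01-05", np.random.default_rng(6))
    clear = labels.to_numpy() == CLEAR
    assert (cf["cf_total"].to_numpy()[clear] < 0.1).all()
    assert (cf["cf_total"].to_numpy()[~clear] > 0.5).all()


def test_labels_follow_cloud_threshold():
    cfg = SyntheticConfig(seed=7, n_days=3)
    truth = generate_campaign(cfg)
    expected_clear = truth.cf["cf_total"].to_numpy() < cfg.cloud.label_threshold
    assert ((truth.labels.to_numpy() == CLEAR) == expected_clear).all()


def test_hike_flat_profile_matches_station_subsampling(clear_config):
    cfg = replace(clear_config, station=replace(clear_config.station, altitude_km=0.0))
    profile = [("2020-01-10 04:00+00:00", 0.0), ("2020-01-10 12:00+00:00", 0.0)]
    hike = generate_hike(cfg, profile, seed=9)
    truth = generate_campaign(replace(cfg, n_days=1))
    # same seed stream is not shared, but with zero cloud and zero noise the
    # all-sky day is the deterministic clear-sky profile in both cases
    expected = truth.uvi.reindex(hike.index, method="nearest")
    assert np.allclose(hike.to_numpy(), expected.to_numpy())


def test_hike_altitude_ratio_is_the_linear_factor(clear_config):
    cfg = replace(clear_config, station=replace(clear_config.station, altitude_km=0.0))
    lo = generate_hike(cfg, [("2020-01-10 04:00+00:00", 0.0), ("2020-01-10 12:00+00:00", 0.0)], seed=9)
    hi = generate_hike(cfg, [("2020-01-10 04:00+00:00", 2.36), ("2020-01-10 12:00+00:00", 2.36)], seed=9)
    daylight = lo > 1.0
    ratio = hi[daylight] / lo[daylight]
    assert np.allclose(ratio.to_numpy(), 1.0 + 0.06 * 2.36)


def test_hike_reproducible_under_seed(clear_config):
    profile = [("2020-01-10 04:00+00:00", 0.39), ("2020-01-10 09:00+00:00", 2.36)]
    a = generate_hike(clear_config, profile, seed=9)
    b = generate_hike(clear_config, profile, seed=9)
    pd.testing.assert_series_equal(a, b)


def test_unbiased_noiseless_estimates_reproduce_truth(clear_bundle, clear_config):
    est = generate_estimates(
        clear_bundle, clear_config, "SAT", seed=1, bias=1.0, noise_sd=0.0,
        mode="satellite", smooth_cloudy_only=True,
    )
    truth_at = clear_bundle.uvi.reindex(
        pd.DatetimeIndex(est["timestamp"]), method="nearest"
    )
    # clear minutes are unsmoothed point samples of the truth
    assert np.allclose(est["uvi"].to_numpy(), truth_at.to_numpy(), atol=1e-9)
    assert len(est) == clear_config.n_days


def test_estimate_coordinates_stay_within_jitter(clear_bundle, clear_config):
    from uvidose import haversine_km

    est = generate_estimates(clear_bundle, clear_config, "SAT", seed=2, mode="model")
    d = haversine_km(
        est["latitude"].to_numpy(), est["longitude"].to_numpy(),
        clear_config.station.latitude, clear_config.station.longitude,
    )
    assert (d <= 8.0 + 1e-6).all()
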