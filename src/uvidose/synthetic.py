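"""Synthetic station simulator with known ground truth.

Generates minute-resolution cloud-fraction and UV-index series that mimic a
tropical island monitoring station, plus hike campaigns and satellite/model
estimate streams, so the whole pipeline (filtering, doses, colocation,
climatology) is testable without any downloads.

The simulator is deterministic under a fixed integer seed: multi-day runs
derive one child generator per day from a ``numpy.random.SeedSequence`` so
that day k of a campaign does not depend on how many days precede it being
regenerated.

Two cloud regimes are available:

* the default *diurnal* process — baseline diurnal cycle + AR(1) noise,
  emulating the observed station climatology (morning dip, late-afternoon
  maximum, constant thin deck);
* a *two-regime* process — alternating blocks of unambiguously clear
  (cf < 0.1) and unambiguously cloudy (cf > 0.5) sky, useful for validating
  the sky filters against a known separation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clearsky import (
    DEFAULT_PARAMS,
    ClearSkyReference,
    daily_clearsky_profile,
)
from .config import MORONI, SyntheticConfig
from .exceptions import InvalidInputError
from .filtering import CLEAR, CLOUDY
from .solar import solar_position


@dataclass(frozen=True)
class TruthBundle:
    """Everything the simulator knows: series plus per-minute ground truth.

    Attributes
    ----------
    uvi : pandas.Series
        All-sky UVI (what the radiometer would record).
    uvi_cs : pandas.Series
        Clear-sky truth at the same minutes.
    cf : pandas.DataFrame
        Cloud fractions (``cf_total``, ``cf_thick``, ``cf_thin``).
    labels : pandas.Series
        True sky label per minute ("clear"/"cloudy").
    toc : pandas.Series
        Total ozone column (DU) per simulated date.
    references : dict
        date -> ClearSkyReference used for each day.
    """

    uvi: pd.Series
    uvi_cs: pd.Series
    cf: pd.DataFrame
    labels: pd.Series
    toc: pd.Series
    references: dict


def daily_toc(config: SyntheticConfig, date) -> float:
    """Seasonal-sinusoid total ozone column for a calendar date (DU)."""
    doy = pd.Timestamp(date).dayofyear
    phase = 2.0 * np.pi * (doy - config.toc.peak_doy) / 365.25
    return float(config.toc.mean_du + config.toc.amplitude_du * np.cos(phase))


def _day_minutes(config: SyntheticConfig, date) -> pd.DatetimeIndex:
    start = pd.Timestamp(date).normalize().tz_localize("UTC") - pd.Timedelta(
        hours=config.station.utc_offset
    )
    return pd.date_range(start, periods=1440, freq="min")


def cloud_baseline(config: SyntheticConfig, date) -> np.ndarray:
    """Deterministic diurnal cf_total baseline for a date (1440 values)."""
    cm = config.cloud
    minute = np.arange(1440, dtype=float)
    xs = [a[0] for a in cm.anchors]
    ys = [a[1] for a in cm.anchors]
    base = np.interp(minute, xs, ys)
    month = pd.Timestamp(date).month
    mult = cm.wet_multiplier if month in cm.wet_months else cm.dry_multiplier
    return base * mult


def generate_cloud_day(
    config: SyntheticConfig, date, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.Series]:
    """One day of cloud fractions from the diurnal baseline + AR(1) noise.

    Returns the cloud DataFrame and the true per-minute sky labels
    (clear iff cf_total < the configured label threshold).
    """
    cm = config.cloud
    minutes = _day_minutes(config, date)
    base = cloud_baseline(config, date)

    noise = np.zeros(1440)
    if cm.ar1_sd > 0:
        stationary_sd = cm.ar1_sd / np.sqrt(max(1.0 - cm.ar1_phi**2, 1e-12))
        noise[0] = rng.normal(0.0, stationary_sd)
        eps = rng.normal(0.0, cm.ar1_sd, size=1439)
        for t in range(1, 1440):
            noise[t] = cm.ar1_phi * noise[t - 1] + eps[t - 1]

    cf_total = np.clip(base + noise, 0.0, 1.0)
    local_minute = np.arange(1440)
    cf_thin = np.where(local_minute >= cm.thin_start_minute, cm.thin_cf, 0.0)
    cf_thin = np.minimum(cf_thin, cf_total)
    cf_thick = np.maximum(cf_total - cf_thin, 0.0)

    cf = pd.DataFrame(
        {"cf_total": cf_total, "cf_thick": cf_thick, "cf_thin": cf_thin}, index=minutes
    )
    labels = pd.Series(
        np.where(cf_total < cm.label_threshold, CLEAR, CLOUDY), index=minutes, name="label"
    )
    return cf, labels


def generate_regime_cloud_day(
    config: SyntheticConfig,
    date,
    rng: np.random.Generator,
    p_clear: float = 0.5,
    block_minutes: int = 120,
    clear_cf_max: float = 0.1,
    cloudy_cf_min: float = 0.5,
) -> tuple[pd.DataFrame, pd.Series]:
    """One day of well-separated cloud regimes in persistent blocks.

    Each ``block_minutes`` block is clear with probability ``p_clear``;
    clear minutes draw cf_total uniformly below ``clear_cf_max``, cloudy
    minutes uniformly above ``cloudy_cf_min``.
    """
    cm = config.cloud
    minutes = _day_minutes(config, date)
    n_blocks = int(np.ceil(1440 / block_minutes))
    block_clear = rng.random(n_blocks) < p_clear
    is_clear = np.repeat(block_clear, block_minutes)[:1440]

    cf_total = np.where(
        is_clear,
        rng.uniform(0.0, clear_cf_max, size=1440),
        rng.uniform(cloudy_cf_min, 1.0, size=1440),
    )
    local_minute = np.arange(1440)
    cf_thin = np.where(local_minute >= cm.thin_start_minute, cm.thin_cf, 0.0)
    cf_thin = np.minimum(cf_thin, cf_total)
    cf_thick = np.maximum(cf_total - cf_thin, 0.0)

    cf = pd.DataFrame(
        {"cf_total": cf_total, "cf_thick": cf_thick, "cf_thin": cf_thin}, index=minutes
    )
    labels = pd.Series(np.where(is_clear, CLEAR, CLOUDY), index=minutes, name="label")
    return cf, labels


def generate_uvi_day(
    config: SyntheticConfig,
    date,
    cloud: pd.DataFrame,
    rng: np.random.Generator,
    reference: ClearSkyReference | None = None,
) -> tuple[pd.Series, pd.Series, ClearSkyReference]:
    """All-sky UVI for one day: clear-sky profile x CMF x sensor noise.

    The CMF is 1 - a * cf**b for attenuated minutes; on broken-cloud minutes
    it is redrawn in (1, enhancement_max] with the configured probability.
    Output is clipped to [0, uvi_cs * enhancement_max].
    """
    mm = config.cmf
    if reference is None:
        reference = daily_clearsky_profile(config.station, date, daily_toc(config, date))
    uvi_cs = reference.uvi_cs
    cf = cloud["cf_total"].reindex(uvi_cs.index)
    if cf.isna().any():
        raise InvalidInputError("cloud series does not cover the clear-sky profile")

    cf_arr = cf.to_numpy()
    cmf = 1.0 - mm.attenuation * np.power(cf_arr, mm.exponent)

    broken = (cf_arr > mm.broken_low) & (cf_arr < mm.broken_high)
    enh_draw = rng.random(1440) < mm.enhancement_prob
    enh_values = rng.uniform(1.0, mm.enhancement_max, size=1440)
    enhance = broken & enh_draw
    cmf = np.where(enhance, np.nextafter(enh_values, 2.0), cmf)

    noise = 1.0 + rng.normal(0.0, config.sensor_noise_sd, size=1440)
    uvi = np.clip(
        uvi_cs.to_numpy() * cmf * noise, 0.0, uvi_cs.to_numpy() * mm.enhancement_max
    )
    return pd.Series(uvi, index=uvi_cs.index, name="uvi"), cf, reference


def generate_campaign(
    config: SyntheticConfig,
    regime: bool = False,
    **regime_kwargs,
) -> TruthBundle:
    """Simulate ``config.n_days`` consecutive days with full ground truth.

    ``regime=True`` switches the cloud process to the two-regime generator
    (extra keyword arguments are forwarded to it).
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_days)
    dates = pd.date_range(config.start_date, periods=config.n_days, freq="D")

    uvi_parts, cs_parts, cf_parts, label_parts = [], [], [], []
    toc_map, ref_map = {}, {}
    for date, child in zip(dates, children):
        rng = np.random.default_rng(child)
        if regime:
            cf, labels = generate_regime_cloud_day(config, date, rng, **regime_kwargs)
        else:
            cf, labels = generate_cloud_day(config, date, rng)
        uvi, _, ref = generate_uvi_day(config, date, cf, rng)
        uvi_parts.append(uvi)
        cs_parts.append(ref.uvi_cs)
        cf_parts.append(cf)
        label_parts.append(labels)
        toc_map[date.date()] = ref.toc
        ref_map[date.date()] = ref

    return TruthBundle(
        uvi=pd.concat(uvi_parts),
        uvi_cs=pd.concat(cs_parts),
        cf=pd.concat(cf_parts),
        labels=pd.concat(label_parts),
        toc=pd.Series(toc_map, name="toc"),
        references=ref_map,
    )


def generate_hike(
    config: SyntheticConfig,
    altitude_profile: list[tuple],
    seed: int,
    step_min: int = 10,
) -> pd.Series:
    """UVI samples along an altitude profile, every ``step_min`` minutes.

    ``altitude_profile`` is a list of (timestamp, altitude_km) waypoints;
    altitude is interpolated linearly in time between them.  The station
    day's all-sky UVI is rescaled from the station altitude to the walker's
    altitude with the configured linear rate.
    """
    if len(altitude_profile) < 2:
        raise InvalidInputError("altitude profile needs at least two waypoints")
    times = pd.DatetimeIndex([pd.Timestamp(t) for t, _ in altitude_profile])
    if times.tz is None:
        times = times.tz_localize("UTC")
    alts = np.asarray([a for _, a in altitude_profile], dtype=float)
    if np.any(alts < 0):
        raise InvalidInputError("altitudes must be >= 0")

    date = (times[0] + pd.Timedelta(hours=config.station.utc_offset)).date()
    rng = np.random.default_rng(seed)
    cf, _ = generate_cloud_day(config, date, rng)
    uvi_station, _, ref = generate_uvi_day(config, date, cf, rng)

    sample_times = pd.date_range(times[0], times[-1], freq=f"{step_min}min")
    alt_at = np.interp(
        sample_times.asi8.astype(float), times.asi8.astype(float), alts
    )
    base = uvi_station.reindex(sample_times, method="nearest")
    rate = DEFAULT_PARAMS.altitude_rate
    station_factor = 1.0 + rate * config.station.altitude_km
    hike = base.to_numpy() / station_factor * (1.0 + rate * alt_at)
    return pd.Series(hike, index=sample_times, name="uvi")


def generate_estimates(
    truth: TruthBundle,
    config: SyntheticConfig,
    source: str,
    seed: int,
    bias: float | None = None,
    noise_sd: float | None = None,
    mode: str = "satellite",
    n_samples: int | None = None,
    smooth_cloudy_only: bool = False,
    satellite=None,
) -> pd.DataFrame:
    """Sample satellite-like or model-like UVI estimates from the truth.

    Modes
    -----
    ``satellite``
        One estimate per day at local solar noon + overpass offset.
    ``model``
        One estimate per day at each configured forecast hour (UTC).
    ``sampled``
        ``n_samples`` random daylight minutes across the campaign.

    The estimate is the truth smoothed over a +/- smooth_window/2 rolling
    mean (a surrogate for coarse-pixel spatial mismatch), multiplied by
    ``bias`` plus Gaussian noise; with ``smooth_cloudy_only`` the smoothing
    applies only where the true sky is cloudy, so clear-sky estimates remain
    faithful point samples.  Estimate coordinates are jittered uniformly
    within ``jitter_km`` of the station.
    """
    from .config import SatelliteModel
    from .solar import local_solar_noon

    sat = satellite if satellite is not None else SatelliteModel()
    bias = sat.bias if bias is None else bias
    noise_sd = sat.noise_sd if noise_sd is None else noise_sd

    rng = np.random.default_rng(seed)
    smoothed = truth.uvi.rolling(sat.smooth_window_min, center=True, min_periods=1).mean()
    if smooth_cloudy_only:
        is_clear = (truth.labels == CLEAR).to_numpy()
        smoothed = pd.Series(
            np.where(is_clear, truth.uvi.to_numpy(), smoothed.to_numpy()),
            index=truth.uvi.index,
        )

    dates = list(truth.toc.index)
    if mode == "satellite":
        instants = [
            _nearest_minute(truth.uvi.index,
                            local_solar_noon(config.station, d)
                            + pd.Timedelta(minutes=sat.overpass_offset_min))
            for d in dates
        ]
    elif mode == "model":
        instants = []
        for d in dates:
            for h in sat.forecast_hours_utc:
                t = pd.Timestamp(d).tz_localize("UTC") + pd.Timedelta(hours=h)
                if truth.uvi.index[0] <= t <= truth.uvi.index[-1]:
                    instants.append(_nearest_minute(truth.uvi.index, t))
    elif mode == "sampled":
        if not n_samples:
            raise InvalidInputError("mode='sampled' requires n_samples")
        daylight = truth.uvi.index[truth.uvi_cs.to_numpy() >= 1.0]
        if len(daylight) == 0:
            raise InvalidInputError("no daylight minutes to sample")
        pick = rng.choice(len(daylight), size=min(n_samples, len(daylight)), replace=False)
        instants = list(daylight[np.sort(pick)])
    else:
        raise InvalidInputError(f"unknown mode {mode!r}")

    instants = pd.DatetimeIndex(sorted(set(instants)))
    values = smoothed.reindex(instants, method="nearest").to_numpy()
    est_uvi = np.clip(values * bias + rng.normal(0.0, noise_sd, size=len(instants)), 0.0, None)

    # uniform jitter on a disc around the station
    theta = rng.uniform(0.0, 2.0 * np.pi, size=len(instants))
    radius = sat.jitter_km * np.sqrt(rng.uniform(0.0, 1.0, size=len(instants)))
    dlat = radius * np.cos(theta) / 111.195
    dlon = radius * np.sin(theta) / (
        111.195 * np.cos(np.radians(config.station.latitude))
    )

    sky = truth.labels.reindex(instants, method="nearest")
    return pd.DataFrame(
        {
            "timestamp": instants,
            "latitude": config.station.latitude + dlat,
            "longitude": config.station.longitude + dlon,
            "uvi": est_uvi,
            "source": source,
            "sky": np.where(sky.to_numpy() == CLEAR, "clear", "all"),
        }
    )


def _nearest_minute(index: pd.DatetimeIndex, t: pd.Timestamp) -> pd.Timestamp:
    pos = index.get_indexer([t], method="nearest")[0]
    return index[pos]


def _daylight_mask(config: SyntheticConfig, index: pd.DatetimeIndex) -> np.ndarray:
    """True where the sun is above the horizon at the station."""
    return solar_position(config.station, index)["sza"].to_numpy() < 90.0


DEFAULT_STATION = MORONI
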