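"""Configuration objects for the synthetic station simulator and pipelines.

The default configuration emulates a tropical island monitoring station on
the west coast of Ngazidja (Comoros): latitude ~11.7 S, near sea level,
civil time UTC+3, an austral wet season from November to April, and a marked
diurnal cloud cycle — about 0.55 total cloud fraction at dawn, a late-morning
minimum, and a maximum near 0.8 towards 17:00 local time, with a thin-cloud
deck of ~0.15 appearing from 08:00 onward.

Every stochastic generator call requires an explicit integer seed; nothing
draws from global random state.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

from .exceptions import ConfigError
from .solar import StationMeta

#: The default emulated station (west-coast Ngazidja, 12 m a.s.l., UTC+3).
MORONI = StationMeta(latitude=-11.708, longitude=43.247, altitude_km=0.012, utc_offset=3.0)


@dataclass(frozen=True)
class TocModel:
    """Seasonal sinusoid for the daily total ozone column (Dobson units).

    Tropical TOC varies little; the defaults (260 +/- 15 DU, peaking in
    austral spring) are plausible values for ~12 S, exposed as configuration
    rather than asserted as measurements.
    """

    mean_du: float = 260.0
    amplitude_du: float = 15.0
    peak_doy: int = 280


@dataclass(frozen=True)
class CloudModel:
    """Diurnal cloud-fraction baseline plus AR(1) noise and seasonal scaling.

    ``anchors`` are (local minute-of-day, cf_total) knots interpolated
    linearly; the AR(1) term adds minute-scale persistence.  Wet-season
    months (Nov-Apr) scale the baseline up, dry-season months down.  Thin
    cloud is a constant deck from ``thin_start_minute`` on; thick cloud is
    the remainder.  True sky labels are clear iff cf_total < label_threshold.
    """

    anchors: tuple = ((0, 0.55), (360, 0.55), (600, 0.45), (1020, 0.80), (1439, 0.60))
    ar1_phi: float = 0.95
    ar1_sd: float = 0.03
    wet_multiplier: float = 1.1
    dry_multiplier: float = 0.9
    wet_months: tuple = (11, 12, 1, 2, 3, 4)
    thin_cf: float = 0.15
    thin_start_minute: int = 480
    label_threshold: float = 0.2


@dataclass(frozen=True)
class CmfModel:
    """Cloud modification factor model: cmf = 1 - a * cf**b, plus enhancement.

    Attenuation can reach ~75-80 % under overcast skies; on broken-cloud
    minutes (cf in the open interval (broken_low, broken_high)) the factor is
    redrawn above 1 with probability ``enhancement_prob``, capped at
    ``enhancement_max`` (~20 % enhancement).
    """

    attenuation: float = 0.75
    exponent: float = 2.0
    enhancement_prob: float = 0.05
    enhancement_max: float = 1.2
    broken_low: float = 0.2
    broken_high: float = 0.7


@dataclass(frozen=True)
class SatelliteModel:
    """Overpass/forecast sampling of the truth with bias, noise and jitter."""

    bias: float = 1.05
    noise_sd: float = 0.25
    overpass_offset_min: float = 60.0
    forecast_hours_utc: tuple = (3, 6, 9, 12)
    jitter_km: float = 8.0
    smooth_window_min: int = 31


@dataclass(frozen=True)
class SyntheticConfig:
    """Full study configuration for the synthetic station simulator."""

    seed: int
    station: StationMeta = MORONI
    start_date: str = "2020-01-01"
    n_days: int = 90
    toc: TocModel = field(default_factory=TocModel)
    cloud: CloudModel = field(default_factory=CloudModel)
    cmf: CmfModel = field(default_factory=CmfModel)
    sensor_noise_sd: float = 0.02


_NESTED = {
    "station": StationMeta,
    "toc": TocModel,
    "cloud": CloudModel,
    "cmf": CmfModel,
}


def _build(cls, data: dict[str, Any], context: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown key(s) in {context}: {', '.join(sorted(unknown))}")
    kwargs = {}
    for key, value in data.items():
        if key in _NESTED and isinstance(value, dict):
            kwargs[key] = _build(_NESTED[key], value, f"{context}.{key}")
        elif isinstance(value, list):
            kwargs[key] = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def load_config(path) -> SyntheticConfig:
    """Load a simulator configuration from YAML.

    Unknown keys are rejected by name; a ``seed`` is mandatory so that every
    simulation is reproducible by construction.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    if "seed" not in data:
        raise ConfigError("configuration must provide an integer 'seed'")
    return _build(SyntheticConfig, data, "config")


def dump_config(config: SyntheticConfig, path) -> None:
    """Serialise a configuration to YAML (round-trips through load_config)."""
    def _clean(obj):
        if dataclasses.is_dataclass(obj):
            return {k: _clean(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, tuple):
            return [_clean(v) for v in obj]
        return obj

    with open(path, "w") as fh:
        yaml.safe_dump(_clean(config), fh, sort_keys=False)
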