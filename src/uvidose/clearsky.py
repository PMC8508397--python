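"""Analytic clear-sky UV index and cloud modification.

The clear-sky model is the well-known power law in the cosine of the solar
zenith angle and the total ozone column,

    UVI_cs = c * mu0**p * (TOC / 300 DU)**q,       c = 12.50, p = 2.42, q = -1.23,

which reproduces radiative-transfer results to within a few percent for
cloud- and aerosol-free skies at sea level.  Altitude is handled as a linear
percent-per-km brightening (default 6 %/km, the usual UV altitude-effect
range being 5-8 %/km).  Aerosol and surface-albedo effects are lumped into a
single constant multiplicative factor.  All coefficients live in
:class:`ClearSkyParams` so a station operator can recalibrate them.

Cloud effects enter as a multiplicative cloud modification factor (CMF):
values below 1 are attenuation (overcast skies can remove ~80 % of the UV),
values slightly above 1 (up to ~1.2) are broken-cloud enhancement.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError
from .solar import StationMeta, solar_position

REFERENCE_TOC_DU = 300.0


@dataclass(frozen=True)
class ClearSkyParams:
    """Coefficients of the clear-sky power law and its modifiers.

    Attributes
    ----------
    coefficient : float
        Overhead-sun UVI at 300 DU and sea level.
    sza_exponent : float
        Exponent on mu0 = cos(SZA).
    ozone_exponent : float
        Exponent on TOC/300 (negative: more ozone, less UV).
    altitude_rate : float
        Fractional UVI increase per km of altitude, in [0, 0.25].
    clear_factor : float
        Constant multiplicative factor absorbing aerosols and albedo.
    """

    coefficient: float = 12.50
    sza_exponent: float = 2.42
    ozone_exponent: float = -1.23
    altitude_rate: float = 0.06
    clear_factor: float = 1.0


DEFAULT_PARAMS = ClearSkyParams()


@dataclass(frozen=True)
class ClearSkyReference:
    """A one-day, one-minute-step clear-sky UVI profile.

    ``uvi_cs`` is indexed by UTC instants covering the station-local calendar
    day; it is zero whenever the sun is below the horizon and unimodal with
    its maximum at local solar noon.
    """

    date: pd.Timestamp
    uvi_cs: pd.Series
    toc: float
    altitude_km: float


def clearsky_uvi(sza, toc, params: ClearSkyParams = DEFAULT_PARAMS):
    """Clear-sky UVI from solar zenith angle (degrees) and TOC (DU).

    Accepts scalars or arrays; returns 0 for sza >= 90 (sun below horizon).

    Raises
    ------
    InvalidInputError
        If ``toc`` is not strictly positive or ``sza`` is outside [0, 180].
    """
    sza_arr = np.asarray(sza, dtype=float)
    toc_arr = np.asarray(toc, dtype=float)
    if np.any(toc_arr <= 0.0):
        raise InvalidInputError("total ozone column must be > 0 DU")
    if np.any((sza_arr < 0.0) | (sza_arr > 180.0)):
        raise InvalidInputError("sza must lie in [0, 180] degrees")
    mu0 = np.cos(np.radians(sza_arr))
    with np.errstate(invalid="ignore"):
        uvi = (
            params.coefficient
            * np.power(np.clip(mu0, 0.0, 1.0), params.sza_exponent)
            * np.power(toc_arr / REFERENCE_TOC_DU, params.ozone_exponent)
            * params.clear_factor
        )
    uvi = np.where(sza_arr < 90.0, uvi, 0.0)
    if np.ndim(sza) == 0 and np.ndim(toc) == 0:
        return float(uvi)
    return uvi


def altitude_adjust(uvi, altitude_km: float, rate: float = DEFAULT_PARAMS.altitude_rate):
    """Scale a sea-level UVI to altitude with a linear percent-per-km rate."""
    if altitude_km < 0.0:
        raise InvalidInputError("altitude_km must be >= 0")
    if not 0.0 <= rate <= 0.25:
        raise InvalidInputError("altitude rate must lie in [0, 0.25] per km")
    return uvi * (1.0 + rate * altitude_km)


def apply_cloud_modification(uvi_cs, cmf):
    """All-sky UVI = clear-sky UVI times a cloud modification factor.

    CMF < 1 is attenuation; CMF in (1, ~1.2] models broken-cloud enhancement.
    """
    if np.any(np.asarray(cmf, dtype=float) < 0.0):
        raise InvalidInputError("cloud modification factor must be >= 0")
    return uvi_cs * cmf


def daily_clearsky_profile(
    station: StationMeta,
    date,
    toc: float,
    params: ClearSkyParams = DEFAULT_PARAMS,
    altitude_km: float | None = None,
) -> ClearSkyReference:
    """1440-minute clear-sky UVI profile for a station-local calendar day.

    Parameters
    ----------
    station : StationMeta
    date : date-like
        Station-local calendar date the profile covers.
    toc : float
        Total ozone column in Dobson units for that day.
    altitude_km : float, optional
        Overrides the station altitude (used e.g. along a hiking profile).
    """
    day = pd.Timestamp(date).normalize()
    alt = station.altitude_km if altitude_km is None else altitude_km
    start = day.tz_localize("UTC") - pd.Timedelta(hours=station.utc_offset)
    minutes = pd.date_range(start, periods=1440, freq="min")
    pos = solar_position(station, minutes)
    uvi = clearsky_uvi(pos["sza"].to_numpy(), toc, params)
    uvi = altitude_adjust(uvi, alt, params.altitude_rate)
    series = pd.Series(uvi, index=minutes, name="uvi_cs")
    return ClearSkyReference(date=day, uvi_cs=series, toc=float(toc), altitude_km=float(alt))


def with_params(params: ClearSkyParams, **kwargs) -> ClearSkyParams:
    """Return a copy of ``params`` with selected fields replaced."""
    return replace(params, **kwargs)
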