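"""Aggregation: daily noon/overpass extraction, monthly climatology, diurnal cycles.

Monthly boxplot statistics use the Tukey convention: quartiles by linear
interpolation, outliers outside [q25 - 1.5*IQR, q75 + 1.5*IQR] (the fence
that corresponds to roughly +/-2.7 sigma for normally distributed data), and
whiskers at the most extreme non-outlier points.  Diurnal cycles are keyed on
station-local civil minute-of-day.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError
from .solar import StationMeta, local_solar_noon

MONTH_INDEX = pd.RangeIndex(1, 13, name="month")


def extract_noon(
    series: pd.Series, station: StationMeta, tolerance_min: float = 5.0
) -> pd.Series:
    """One value per local day: the sample nearest local solar noon.

    Days without a sample within ``tolerance_min`` of solar noon are missing.
    Returned series is indexed by local calendar date.
    """
    return extract_overpass(series, station, offset_min=0.0, tolerance_min=tolerance_min)


def extract_overpass(
    series: pd.Series,
    station: StationMeta,
    offset_min: float = 60.0,
    tolerance_min: float = 5.0,
) -> pd.Series:
    """One value per local day at solar noon + ``offset_min`` minutes.

    Models a polar-orbiter overpass, typically about one hour after local
    solar noon for an early-afternoon orbit.
    """
    if offset_min < 0:
        raise InvalidInputError("offset_min must be >= 0")
    local = series.index + pd.Timedelta(hours=station.utc_offset)
    tol = pd.Timedelta(minutes=tolerance_min)

    out = {}
    for day_key in np.unique(local.normalize()):
        day = pd.Timestamp(day_key)
        target = local_solar_noon(station, day) + pd.Timedelta(minutes=offset_min)
        pos = series.index.get_indexer([target], method="nearest")[0]
        if pos >= 0 and abs(series.index[pos] - target) <= tol:
            out[day.date()] = float(series.iloc[pos])
        else:
            out[day.date()] = np.nan
    return pd.Series(out, name=series.name).sort_index()


def monthly_climatology(daily_values: pd.Series) -> pd.DataFrame:
    """Boxplot-style monthly statistics of daily values across all years.

    Parameters
    ----------
    daily_values : pandas.Series
        Indexed by date (or datetime); NaNs ignored.

    Returns
    -------
    pandas.DataFrame
        Indexed by month 1..12 with columns ``mean, sd, median, q25, q75,
        whisker_low, whisker_high, n`` and an object column ``outliers``
        listing the flagged values.  Months without data have n = 0 and NaN
        statistics.
    """
    idx = pd.DatetimeIndex(daily_values.index)
    vals = pd.Series(daily_values.to_numpy(dtype=float), index=idx).dropna()

    rows = []
    for month in MONTH_INDEX:
        x = vals[vals.index.month == month].to_numpy()
        if x.size == 0:
            rows.append(
                dict(mean=np.nan, sd=np.nan, median=np.nan, q25=np.nan, q75=np.nan,
                     whisker_low=np.nan, whisker_high=np.nan, n=0, outliers=[])
            )
            continue
        q25, med, q75 = np.percentile(x, [25, 50, 75])
        iqr = q75 - q25
        lo_fence, hi_fence = q25 - 1.5 * iqr, q75 + 1.5 * iqr
        inside = x[(x >= lo_fence) & (x <= hi_fence)]
        outliers = x[(x < lo_fence) | (x > hi_fence)]
        rows.append(
            dict(
                mean=float(np.mean(x)),
                sd=float(np.std(x, ddof=1)) if x.size >= 2 else np.nan,
                median=float(med),
                q25=float(q25),
                q75=float(q75),
                whisker_low=float(inside.min()),
                whisker_high=float(inside.max()),
                n=int(x.size),
                outliers=sorted(float(v) for v in outliers),
            )
        )
    return pd.DataFrame(rows, index=MONTH_INDEX)


def diurnal_cycle(series: pd.Series, station: StationMeta | None = None) -> pd.DataFrame:
    """Mean, standard deviation and count per (local) minute-of-day.

    With ``station`` given, minutes are keyed on station-local civil time;
    otherwise on UTC.  The counts sum to the number of non-missing samples.
    """
    offset = 0.0 if station is None else station.utc_offset
    local = series.index + pd.Timedelta(hours=offset)
    minute_of_day = local.hour * 60 + local.minute
    vals = pd.Series(series.to_numpy(dtype=float), index=minute_of_day).dropna()
    grouped = vals.groupby(level=0)
    out = pd.DataFrame(
        {"mean": grouped.mean(), "sd": grouped.std(ddof=1), "count": grouped.size()}
    )
    out = out.reindex(pd.RangeIndex(0, 1440, name="minute_of_day"))
    out["count"] = out["count"].fillna(0).astype(int)
    return out
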