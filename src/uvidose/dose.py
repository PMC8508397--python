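"""Erythemal doses, cumulative daily doses, WHO categories, phototype exceedance.

Unit conventions (international standards, used throughout):

* 1 UVI corresponds to 0.025 W m-2 of erythemally weighted irradiance, i.e.
  erythemal irradiance = UVI / 40.
* 1 SED (standard erythemal dose) is 100 J m-2 of erythemally weighted
  radiant exposure.  A constant UVI of 20 over one minute therefore delivers
  20/40 * 60 / 100 = 0.30 SED.

Daily accumulation (CSED) is keyed on the *station-local* calendar day, so a
tropical station at UTC+3 resets its running dose at local midnight.

Phototype tolerance thresholds follow the Fitzpatrick skin-type scale
(I palest to VI darkest).  The default table is an explicit, configurable
choice on the minimal-erythemal-dose scale; reports always carry the table
used rather than assuming it silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError, NoDataError

#: W m-2 of erythemal irradiance per UVI unit.
WATTS_PER_UVI = 0.025
#: J m-2 per SED.
JOULES_PER_SED = 100.0

#: WHO exposure categories as half-open UVI bins [low, high).
WHO_BINS = (
    ("low", 0.0, 3.0),
    ("moderate", 3.0, 6.0),
    ("high", 6.0, 8.0),
    ("very_high", 8.0, 11.0),
    ("extreme", 11.0, np.inf),
)
WHO_LABELS = tuple(b[0] for b in WHO_BINS)


@dataclass(frozen=True)
class PhototypeThresholds:
    """Daily SED tolerance per Fitzpatrick phototype (I..VI, nondecreasing)."""

    thresholds: dict = field(
        default_factory=lambda: {
            "I": 2.0,
            "II": 2.5,
            "III": 3.0,
            "IV": 4.5,
            "V": 6.0,
            "VI": 10.0,
        }
    )

    def __post_init__(self) -> None:
        vals = list(self.thresholds.values())
        if any(v <= 0 for v in vals):
            raise InvalidInputError("phototype thresholds must be positive")
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise InvalidInputError("phototype thresholds must be nondecreasing I..VI")


def uvi_to_erythemal_irradiance(uvi):
    """Erythemally weighted irradiance (W m-2) from UVI: uvi / 40."""
    arr = np.asarray(uvi, dtype=float)
    if np.any(arr < 0):
        raise InvalidInputError("uvi must be >= 0")
    out = arr * WATTS_PER_UVI
    return float(out) if np.ndim(uvi) == 0 else out


def _local_index(index: pd.DatetimeIndex, utc_offset: float) -> pd.DatetimeIndex:
    return index + pd.Timedelta(hours=utc_offset)


def _regularize_day(day: pd.Series, gap_limit_min: int) -> tuple[pd.Series, bool]:
    """Fill a day's series onto a 1-min grid; interpolate short gaps.

    Gaps of at most ``gap_limit_min`` minutes are linearly interpolated;
    longer gaps contribute zero dose and mark the day partial.
    """
    grid = pd.date_range(day.index[0], day.index[-1], freq="min")
    s = day.reindex(grid)
    isna = s.isna()
    if not isna.any():
        return s, False
    run_id = (isna != isna.shift()).cumsum()
    run_len = isna.groupby(run_id).transform("sum")
    long_gap = isna & (run_len > gap_limit_min)
    filled = s.interpolate(method="time", limit_area="inside")
    filled[long_gap] = 0.0
    partial = bool(long_gap.any())
    return filled.fillna(0.0), partial


def sed_per_window(
    uvi: pd.Series,
    window_s: float = 60.0,
    utc_offset: float = 0.0,
    gap_limit_min: int = 10,
) -> pd.DataFrame:
    """Accumulate erythemal dose into fixed windows (default one minute).

    Each 1-min sample is treated as the mean irradiance over its minute and
    windows tile the station-local day starting at local midnight, so the
    daily total is invariant to the window size.  Days containing gaps longer
    than ``gap_limit_min`` are listed in ``result.attrs["partial_days"]``.

    Returns
    -------
    pandas.DataFrame
        Indexed by UTC window start, column ``sed``.
    """
    if uvi.empty:
        raise InvalidInputError("empty UVI series")
    if window_s <= 0:
        raise InvalidInputError("window_s must be > 0")
    if np.any(uvi.to_numpy() < 0):
        raise InvalidInputError("uvi must be >= 0")

    local = uvi.copy()
    local.index = _local_index(uvi.index, utc_offset)

    partial_days: list = []
    day_frames = []
    for day_key, day in local.groupby(local.index.normalize()):
        filled, partial = _regularize_day(day, gap_limit_min)
        if partial:
            partial_days.append(day_key.date())
        irr = filled.to_numpy() * WATTS_PER_UVI
        secs = (filled.index - day_key).total_seconds().to_numpy()
        win_start_s = np.floor(secs / window_s) * window_s
        sed = pd.Series(irr * 60.0 / JOULES_PER_SED).groupby(win_start_s).sum()
        starts = day_key + pd.to_timedelta(sed.index, unit="s")
        day_frames.append(pd.DataFrame({"sed": sed.to_numpy()}, index=starts))

    out = pd.concat(day_frames).sort_index()
    out.index = out.index - pd.Timedelta(hours=utc_offset)  # back to UTC
    out.index.name = "window_start"
    out.attrs["window_s"] = float(window_s)
    out.attrs["utc_offset"] = float(utc_offset)
    out.attrs["partial_days"] = partial_days
    return out


def cumulative_sed(doses: pd.DataFrame, utc_offset: float | None = None) -> pd.DataFrame:
    """Add a running cumulative-SED column that resets at local midnight."""
    if utc_offset is None:
        utc_offset = float(doses.attrs.get("utc_offset", 0.0))
    out = doses.copy()
    local_days = _local_index(out.index, utc_offset).normalize()
    out["csed"] = out["sed"].groupby(local_days).cumsum()
    out.attrs.update(doses.attrs)
    return out


def exceedance_time(doses: pd.DataFrame, thresholds: PhototypeThresholds) -> pd.DataFrame:
    """First instant each phototype's daily tolerance is crossed, per local day.

    Returns a DataFrame indexed by local calendar day with one column per
    phototype, holding the UTC window start of the first window whose
    cumulative SED reaches the threshold, or NaT if never crossed.  A
    threshold of zero crosses at the first window with nonzero dose.
    """
    if "csed" not in doses.columns:
        doses = cumulative_sed(doses)
    utc_offset = float(doses.attrs.get("utc_offset", 0.0))
    local_days = _local_index(doses.index, utc_offset).normalize()

    rows = {}
    for day_key, day in doses.groupby(local_days):
        row = {}
        for pt, thr in thresholds.thresholds.items():
            if thr <= 0:
                hit = day.index[day["sed"].to_numpy() > 0]
            else:
                hit = day.index[day["csed"].to_numpy() >= thr]
            row[pt] = hit[0] if len(hit) else pd.NaT
        rows[day_key.date()] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def who_category(uvi: float) -> str:
    """WHO exposure category of a UVI value (half-open bins, lower-inclusive)."""
    if uvi < 0:
        raise InvalidInputError("uvi must be >= 0")
    for label, lo, hi in WHO_BINS:
        if lo <= uvi < hi:
            return label
    raise AssertionError("unreachable: WHO bins partition [0, inf)")


def category_frequencies(values) -> pd.Series:
    """Proportion of UVI values in each WHO category; sums to 1."""
    arr = np.asarray(list(values), dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise NoDataError("no UVI values to categorise")
    if np.any(arr < 0):
        raise InvalidInputError("uvi must be >= 0")
    edges = [b[1] for b in WHO_BINS] + [np.inf]
    counts = np.histogram(arr, bins=edges)[0]
    return pd.Series(counts / arr.size, index=list(WHO_LABELS), name="frequency")
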