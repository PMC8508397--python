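"""Ground-vs-satellite/model colocation and comparison statistics.

Estimates (satellite overpasses, model forecast steps) are paired with ground
minutes under a space gate (great-circle distance to the station, default
10 km) and a time gate (default 60 s).  Several estimates surviving the gates
at the same ground minute are averaged into a single pair, matching how
coarse-pixel products are usually collapsed onto a point measurement.

Comparison statistics mirror the standard validation table: mean/median
relative difference RD = 100*(estimate - ground)/ground [%], mean/median
absolute difference AD = estimate - ground [UVI units], their spreads, the
Pearson correlation r and its square.  RD is undefined near zero ground UVI,
so pairs with ground below ``rd_floor`` (default 0.5 UVI) are excluded from
the RD statistics only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InvalidInputError
from .filtering import CLEAR
from .solar import StationMeta

EARTH_RADIUS_KM = 6371.0


def haversine_km(lat1, lon1, lat2, lon2, radius: float = EARTH_RADIUS_KM):
    """Great-circle distance in km between points given in degrees."""
    p1, l1, p2, l2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = np.sin((p2 - p1) / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin((l2 - l1) / 2.0) ** 2
    return 2.0 * radius * np.arcsin(np.sqrt(a))


@dataclass(frozen=True)
class ComparisonStats:
    """Paired ground-vs-estimate difference statistics."""

    mean_rd: float
    sd_rd: float
    median_rd: float
    mean_ad: float
    sd_ad: float
    median_ad: float
    r: float
    r2: float
    n: int
    n_rd: int

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "mean_rd_pct": self.mean_rd,
                "sd_rd_pct": self.sd_rd,
                "median_rd_pct": self.median_rd,
                "mean_ad_uvi": self.mean_ad,
                "sd_ad_uvi": self.sd_ad,
                "median_ad_uvi": self.median_ad,
                "r": self.r,
                "r2": self.r2,
                "n": self.n,
                "n_rd": self.n_rd,
            }
        )


def match(
    ground: pd.Series,
    estimates: pd.DataFrame,
    station: StationMeta,
    max_dist_km: float = 10.0,
    max_dt_s: float = 60.0,
) -> pd.DataFrame:
    """Pair ground UVI minutes with estimate points under space/time gates.

    Parameters
    ----------
    ground : pandas.Series
        UTC-indexed ground UVI.
    estimates : pandas.DataFrame
        Columns ``timestamp`` (or a DatetimeIndex), ``latitude``,
        ``longitude``, ``uvi``; extra columns are ignored.

    Returns
    -------
    pandas.DataFrame
        Indexed by matched ground timestamp with columns ``ground_uvi``,
        ``estimate_uvi`` (mean of surviving estimates), ``dt_s`` (largest
        absolute time offset among them) and ``distance_km`` (mean).
        Empty if nothing matches.
    """
    if max_dist_km <= 0 or max_dt_s <= 0:
        raise InvalidInputError("gates must be positive")
    est = estimates.copy()
    if "timestamp" in est.columns:
        est = est.set_index("timestamp")
    est = est.sort_index()
    if est.index.tz is None:
        est.index = est.index.tz_localize("UTC")

    dist = haversine_km(
        est["latitude"].to_numpy(), est["longitude"].to_numpy(),
        station.latitude, station.longitude,
    )
    est = est.assign(distance_km=dist).loc[dist <= max_dist_km]
    if est.empty:
        return _empty_pairs()

    ground_df = pd.DataFrame({"timestamp": ground.index, "ground_uvi": ground.to_numpy()})
    est_df = est.reset_index(names="timestamp")
    merged = pd.merge_asof(
        est_df.sort_values("timestamp"),
        ground_df,
        on="timestamp",
        direction="nearest",
        tolerance=pd.Timedelta(seconds=max_dt_s),
    ).dropna(subset=["ground_uvi"])
    if merged.empty:
        return _empty_pairs()

    # recover the matched ground instant to group coincident estimates
    g_idx = ground.index
    pos = g_idx.get_indexer(merged["timestamp"], method="nearest")
    merged["ground_time"] = g_idx[pos]
    merged["dt_s"] = (merged["timestamp"] - merged["ground_time"]).dt.total_seconds().abs()

    grouped = merged.groupby("ground_time").agg(
        ground_uvi=("ground_uvi", "first"),
        estimate_uvi=("uvi", "mean"),
        dt_s=("dt_s", "max"),
        distance_km=("distance_km", "mean"),
    )
    grouped.index.name = "timestamp"
    return grouped


def _empty_pairs() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["ground_uvi", "estimate_uvi", "dt_s", "distance_km"],
        index=pd.DatetimeIndex([], tz="UTC", name="timestamp"),
    )


def compare(pairs: pd.DataFrame, rd_floor: float = 0.5) -> ComparisonStats:
    """Comparison statistics over matched pairs.

    ``r`` and ``r2`` are reported as NaN when fewer than two pairs (or a
    degenerate ground series) make the correlation undefined.
    """
    if pairs.empty:
        raise InvalidInputError("no matched pairs to compare")
    g = pairs["ground_uvi"].to_numpy(dtype=float)
    e = pairs["estimate_uvi"].to_numpy(dtype=float)
    ad = e - g

    ok = g >= rd_floor
    rd = 100.0 * (e[ok] - g[ok]) / g[ok]

    if len(g) >= 2 and np.std(g) > 0 and np.std(e) > 0:
        r = float(stats.pearsonr(g, e).statistic)
    else:
        r = np.nan

    def _sd(x):
        return float(np.std(x, ddof=1)) if len(x) >= 2 else np.nan

    return ComparisonStats(
        mean_rd=float(np.mean(rd)) if rd.size else np.nan,
        sd_rd=_sd(rd),
        median_rd=float(np.median(rd)) if rd.size else np.nan,
        mean_ad=float(np.mean(ad)),
        sd_ad=_sd(ad),
        median_ad=float(np.median(ad)),
        r=r,
        r2=r * r if np.isfinite(r) else np.nan,
        n=int(len(g)),
        n_rd=int(rd.size),
    )


def stratify_by_sky(pairs: pd.DataFrame, mask: pd.Series) -> dict[str, pd.DataFrame]:
    """Split pairs into a clear-sky stratum and the all-sky set.

    The clear stratum keeps pairs whose ground minute is labelled ``clear``
    in ``mask``; the ``all`` stratum keeps every pair.
    """
    labels = mask.reindex(pairs.index)
    return {"clear": pairs.loc[(labels == CLEAR).to_numpy()], "all": pairs}
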