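"""Clear-sky / cloudy classification of UVI minutes.

Two independent methods are provided:

* the **automatic filter (AF)**: a minute is clear when the matched all-sky
  camera cloud fraction is below a threshold *and* the solar zenith angle is
  below a gate (default 45 deg);
* the **bell-shape filter (MF)**: an automated version of the manual
  inspection of daily UVI profiles against the analytic clear-sky bell curve.
  A sliding window (default one hour) is declared clear when at least
  ``min_frac`` of its minutes deviate from the clear-sky reference by no more
  than ``rel_tol`` in relative terms; every minute belonging to at least one
  clear window is labelled clear.

The cloud-fraction threshold of the automatic filter is chosen by maximising
the agreement between the two methods over a candidate grid, mirroring how a
station operator would calibrate the automatic filter against the manual one.

Sky masks are plain pandas Series of labels ``{"clear", "cloudy", "unknown"}``
indexed by UTC timestamp, with the method tag stored in ``.attrs["method"]``.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd

from .clearsky import ClearSkyReference
from .exceptions import InvalidInputError, NoDataError
from .solar import StationMeta, solar_position

CLEAR = "clear"
CLOUDY = "cloudy"
UNKNOWN = "unknown"
LABELS = (CLEAR, CLOUDY, UNKNOWN)

#: Nearest cloud-fraction sample must lie within this of the UVI minute.
DEFAULT_MATCH_TOLERANCE = pd.Timedelta(minutes=2)
#: Relative-deviation floor: below this clear-sky UVI a minute is "unknown".
DEFAULT_EPS_UVI = 0.5
#: Default candidate grid for the cloud-fraction threshold search.
DEFAULT_THRESHOLD_GRID = tuple(np.round(np.arange(0.05, 0.951, 0.05), 2))


def _new_mask(index: pd.DatetimeIndex, labels: np.ndarray, method: str) -> pd.Series:
    mask = pd.Series(labels, index=index, name="label")
    mask.attrs["method"] = method
    return mask


def cf_threshold_filter(
    uvi: pd.Series,
    cf: pd.DataFrame,
    station: StationMeta,
    cf_threshold: float = 0.3,
    sza_max: float = 45.0,
    match_tolerance: pd.Timedelta = DEFAULT_MATCH_TOLERANCE,
) -> pd.Series:
    """Automatic clear-sky filter from cloud fraction and an SZA gate.

    A UVI minute is *clear* iff the nearest cloud-fraction sample within
    ``match_tolerance`` has ``cf_total < cf_threshold`` and the solar zenith
    angle is below ``sza_max``.  Minutes with no cloud-fraction sample within
    tolerance are *unknown*; everything else is *cloudy*.
    """
    if uvi.empty:
        raise InvalidInputError("empty UVI series")
    if not 0.0 <= cf_threshold <= 1.0:
        raise InvalidInputError("cf_threshold must lie in [0, 1]")
    if not 0.0 < sza_max <= 90.0:
        raise InvalidInputError("sza_max must lie in (0, 90]")

    left = pd.DataFrame({"timestamp": uvi.index})
    right = pd.DataFrame({"timestamp": cf.index, "cf_total": cf["cf_total"].to_numpy()})
    matched = pd.merge_asof(
        left, right, on="timestamp", direction="nearest", tolerance=match_tolerance
    )["cf_total"].to_numpy()

    sza = solar_position(station, uvi.index)["sza"].to_numpy()
    labels = np.full(len(uvi), CLOUDY, dtype=object)
    labels[np.isnan(matched)] = UNKNOWN
    clear = (~np.isnan(matched)) & (matched < cf_threshold) & (sza < sza_max)
    labels[clear] = CLEAR
    return _new_mask(uvi.index, labels, "AF")


def _reference_series(reference) -> pd.Series:
    """Concatenate one or many daily clear-sky references into one series."""
    if isinstance(reference, ClearSkyReference):
        return reference.uvi_cs
    if isinstance(reference, Mapping):
        refs: Iterable[ClearSkyReference] = reference.values()
    else:
        refs = reference
    parts = [r.uvi_cs for r in refs]
    if not parts:
        raise InvalidInputError("no clear-sky reference supplied")
    return pd.concat(parts).sort_index()


def bell_shape_filter(
    uvi: pd.Series,
    reference,
    window: int = 60,
    rel_tol: float = 0.10,
    min_frac: float = 0.9,
    eps: float = DEFAULT_EPS_UVI,
) -> pd.Series:
    """Bell-shape clear-sky filter against an analytic reference profile.

    Parameters
    ----------
    uvi : pandas.Series
        Measured UVI, UTC-indexed at nominal 1-min cadence.
    reference : ClearSkyReference or mapping/sequence of them
        The clear-sky bell curve(s) covering the days of ``uvi``.
    window : int
        Sliding-window length in minutes (>= 10; default one hour).
    rel_tol : float
        Maximum tolerated relative deviation |uvi - uvi_cs| / uvi_cs.
    min_frac : float
        Fraction of in-tolerance minutes a window needs to count as clear,
        in (0.5, 1].
    eps : float
        Clear-sky UVI floor; minutes with uvi_cs < eps (twilight/night) are
        labelled *unknown* since relative deviation is meaningless there.
    """
    if window < 10:
        raise InvalidInputError("window must be >= 10 minutes")
    if rel_tol <= 0.0:
        raise InvalidInputError("rel_tol must be > 0")
    if not 0.5 < min_frac <= 1.0:
        raise InvalidInputError("min_frac must lie in (0.5, 1]")
    if uvi.empty:
        raise InvalidInputError("empty UVI series")

    cs = _reference_series(reference)
    if uvi.index.difference(cs.index).size:
        raise InvalidInputError("reference does not cover the UVI series dates")

    on_grid = uvi.reindex(cs.index)
    valid = cs.to_numpy() >= eps
    with np.errstate(invalid="ignore", divide="ignore"):
        rel_dev = np.abs(on_grid.to_numpy() - cs.to_numpy()) / np.maximum(cs.to_numpy(), eps)
    ok = valid & ~np.isnan(on_grid.to_numpy()) & (rel_dev <= rel_tol)

    # forward window sums: s[e] counts ok-minutes in the window ending at e
    ok_series = pd.Series(ok.astype(float), index=cs.index)
    win_sum = ok_series.rolling(window).sum()
    qualifies = (win_sum >= np.ceil(min_frac * window) - 1e-9).astype(float)
    # minute j is clear if any qualifying window ends in [j, j + window - 1]
    in_clear_window = (
        qualifies.iloc[::-1].rolling(window, min_periods=1).max().iloc[::-1].to_numpy() > 0.0
    )

    labels = np.full(len(cs), CLOUDY, dtype=object)
    labels[in_clear_window & valid] = CLEAR
    labels[~valid] = UNKNOWN
    mask = _new_mask(cs.index, labels, "MF")
    return mask.loc[uvi.index]


def agreement(a: pd.Series, b: pd.Series, restrict: pd.Series | None = None) -> float:
    """Fraction of comparable timestamps on which two sky masks coincide.

    Timestamps labelled *unknown* by either mask are excluded.  ``restrict``
    optionally limits the comparison further (e.g. to minutes inside the
    automatic filter's SZA gate, or to daylight minutes).

    Raises
    ------
    InvalidInputError
        If the masks share no timestamps.
    NoDataError
        If no comparable timestamp remains.
    """
    common = a.index.intersection(b.index)
    if common.empty:
        raise InvalidInputError("sky masks have disjoint timestamp bases")
    aa = a.loc[common]
    bb = b.loc[common]
    comparable = (aa != UNKNOWN) & (bb != UNKNOWN)
    if restrict is not None:
        comparable &= restrict.reindex(common, fill_value=False).astype(bool)
    n = int(comparable.sum())
    if n == 0:
        raise NoDataError("no comparable timestamps between the two masks")
    return float((aa[comparable] == bb[comparable]).mean())


def select_cf_threshold(
    uvi: pd.Series,
    cf: pd.DataFrame,
    reference,
    station: StationMeta,
    candidate_grid=DEFAULT_THRESHOLD_GRID,
    sza_max: float = 45.0,
    **bell_kwargs,
) -> tuple[float, float]:
    """Choose the cloud-fraction threshold that best matches the bell filter.

    Evaluates :func:`cf_threshold_filter` on every candidate threshold and
    returns ``(threshold, agreement)`` for the grid value maximising agreement
    with :func:`bell_shape_filter`; ties break toward the smaller threshold.
    Agreement is evaluated where the automatic filter applies, i.e. at minutes
    with SZA below ``sza_max`` (outside the gate the automatic method cannot
    call a minute clear by construction, so comparing there would only measure
    the gate, not the cloud threshold).
    """
    grid = sorted(float(g) for g in candidate_grid)
    if not grid:
        raise InvalidInputError("candidate grid must be nonempty")
    if any(g < 0.0 or g > 1.0 for g in grid):
        raise InvalidInputError("candidate thresholds must lie in [0, 1]")

    bell = bell_shape_filter(uvi, reference, **bell_kwargs)
    sza = solar_position(station, uvi.index)["sza"]
    in_gate = pd.Series(sza.to_numpy() < sza_max, index=uvi.index)

    best_thr = None
    best_score = -np.inf
    for thr in grid:
        af = cf_threshold_filter(uvi, cf, station, cf_threshold=thr, sza_max=sza_max)
        score = agreement(af, bell, restrict=in_gate)
        if score > best_score:  # strict: ties keep the smaller threshold
            best_thr, best_score = thr, score
    return best_thr, best_score
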