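"""Sky classification: threshold filter, bell-shape filter, agreement, selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uvidose import (
    CLEAR,
    CLOUDY,
    UNKNOWN,
    InvalidInputError,
    agreement,
    bell_shape_filter,
    cf_threshold_filter,
    daily_clearsky_profile,
    select_cf_threshold,
    solar_position,
)


@pytest.fixture(scope="module")
def day_reference(station):
    return daily_clearsky_profile(station, "2020-01-15", 260.0)


def _cf_frame(index, cf_total):
    cf_total = np.broadcast_to(np.asarray(cf_total, dtype=float), (len(index),)).copy()
    return pd.DataFrame(
        {"cf_total": cf_total, "cf_thick": cf_total, "cf_thin": np.zeros(len(index))},
        index=index,
    )


def test_zero_cloud_labels_all_gated_daylight_clear(station, day_reference):
    uvi = day_reference.uvi_cs.rename("uvi")
    cf = _cf_frame(uvi.index, 0.0)
    mask = cf_threshold_filter(uvi, cf, station, cf_threshold=0.3, sza_max=45.0)
    sza = solar_position(station, uvi.index)["sza"].to_numpy()
    assert (mask.to_numpy()[sza < 45.0] == CLEAR).all()
    assert (mask.to_numpy()[sza >= 45.0] == CLOUDY).all()


def test_overcast_yields_no_clear_labels(station, day_reference):
    uvi = day_reference.uvi_cs.rename("uvi")
    mask = cf_threshold_filter(uvi, _cf_frame(uvi.index, 1.0), station)
    assert not (mask == CLEAR).any()


def test_missing_cf_minutes_are_unknown(station, day_reference):
    uvi = day_reference.uvi_cs.rename("uvi")
    cf = _cf_frame(uvi.index, 0.0).iloc[:600]  # CF coverage stops mid-morning
    mask = cf_threshold_filter(uvi, cf, station)
    # beyond the 2-min matching tolerance everything is unknown
    assert (mask.iloc[603:] == UNKNOWN).all()


def test_step_cloud_day_matches_minutewise_oracle(station, day_reference):
    """CF steps 0 -> 0.5 at noon with threshold 0.3: clear only before noon."""
    uvi = day_reference.uvi_cs.rename("uvi")
    noon = uvi.idxmax()
    cf_vals = np.where(uvi.index < noon, 0.0, 0.5)
    cf = _cf_frame(uvi.index, cf_vals)
    mask = cf_threshold_filter(uvi, cf, station, cf_threshold=0.3, sza_max=45.0)

    sza = solar_position(station, uvi.index)["sza"].to_numpy()
    expected = np.where((cf_vals < 0.3) & (sza < 45.0), CLEAR, CLOUDY)
    assert (mask.to_numpy() == expected).all()


def test_empty_series_rejected(station, day_reference):
    empty = pd.Series(dtype=float, index=pd.DatetimeIndex([], tz="UTC"))
    with pytest.raises(InvalidInputError):
        cf_threshold_filter(empty, _cf_frame(day_reference.uvi_cs.index, 0.0), station)


def test_bell_filter_perfect_match_is_all_clear(day_reference):
    uvi = day_reference.uvi_cs.rename("uvi")
    mask = bell_shape_filter(uvi, day_reference)
    valid = day_reference.uvi_cs >= 0.5
    assert (mask[valid] == CLEAR).all()
    assert (mask[~valid] == UNKNOWN).all()


def test_bell_filter_heavy_attenuation_never_clear(day_reference):
    uvi = (day_reference.uvi_cs * 0.3).rename("uvi")
    mask = bell_shape_filter(uvi, day_reference, rel_tol=0.10)
    assert not (mask == CLEAR).any()


def test_bell_filter_recovers_clear_interval_with_high_jaccard(station, day_reference):
    """A day clear 09:00-11:00 local and attenuated elsewhere is recovered."""
    uvi = day_reference.uvi_cs.copy()
    local = uvi.index + pd.Timedelta(hours=station.utc_offset)
    truth_clear = (local.hour >= 9) & (local.hour < 11)
    uvi[~truth_clear] *= 0.4
    mask = bell_shape_filter(uvi.rename("uvi"), day_reference)

    found = (mask == CLEAR).to_numpy()
    valid = (day_reference.uvi_cs >= 0.5).to_numpy()
    truth = truth_clear & valid
    jaccard = (found & truth).sum() / (found | truth).sum()
    assert jaccard >= 0.8


def test_bell_filter_date_mismatch_rejected(station, day_reference):
    other = daily_clearsky_profile(station, "2020-02-20", 260.0)
    with pytest.raises(InvalidInputError):
        bell_shape_filter(day_reference.uvi_cs.rename("uvi"), other)


def _mask(index, labels):
    return pd.Series(labels, index=index, name="label")


def test_agreement_identical_and_complementary():
    idx = pd.date_range("2020-01-01", periods=10, freq="min", tz="UTC")
    a = _mask(idx, [CLEAR] * 5 + [CLOUDY] * 5)
    assert agreement(a, a) == 1.0
    b = _mask(idx, [CLOUDY] * 5 + [CLEAR] * 5)
    assert agreement(a, b) == 0.0


def test_agreement_counts_mismatches_excluding_unknown():
    idx = pd.date_range("2020-01-01", periods=110, freq="min", tz="UTC")
    a_labels = np.array([CLEAR] * 100 + [UNKNOWN] * 10, dtype=object)
    b_labels = a_labels.copy()
    b_labels[:3] = CLOUDY            # 3 of 100 comparable minutes differ
    b_labels[100:] = CLEAR           # unknown in a: excluded from the count
    assert agreement(_mask(idx, a_labels), _mask(idx, b_labels)) == pytest.approx(0.97)


def test_agreement_is_symmetric(regime_bundle, regime_config):
    uvi, cf = regime_bundle.uvi, regime_bundle.cf
    st_meta = regime_config.station
    day = slice("2020-01-02", "2020-01-04")
    a = cf_threshold_filter(uvi.loc[day], cf.loc[day], st_meta, cf_threshold=0.2)
    b = cf_threshold_filter(uvi.loc[day], cf.loc[day], st_meta, cf_threshold=0.6)
    assert agreement(a, b) == agreement(b, a)


def test_agreement_disjoint_bases_rejected():
    idx1 = pd.date_range("2020-01-01", periods=5, freq="min", tz="UTC")
    idx2 = pd.date_range("2020-06-01", periods=5, freq="min", tz="UTC")
    with pytest.raises(InvalidInputError):
        agreement(_mask(idx1, [CLEAR] * 5), _mask(idx2, [CLEAR] * 5))


def test_threshold_grid_of_one_returns_it(station, day_reference):
    uvi = day_reference.uvi_cs.rename("uvi")
    cf = _cf_frame(uvi.index, 0.0)
    thr, _ = select_cf_threshold(uvi, cf, day_reference, station, candidate_grid=[0.42])
    assert thr == 0.42


def test_all_clear_tie_breaks_to_smallest_threshold(station, day_reference):
    uvi = day_reference.uvi_cs.rename("uvi")
    cf = _cf_frame(uvi.index, 0.0)  # every threshold classifies identically
    thr, score = select_cf_threshold(
        uvi, cf, day_reference, station, candidate_grid=[0.1, 0.3, 0.5]
    )
    assert thr == 0.1
    assert score == 1.0


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    cf_vals=st.lists(st.floats(0.0, 1.0), min_size=30, max_size=30),
    thr=st.floats(0.05, 0.9),
    delta=st.floats(0.01, 0.1),
)
def test_raising_threshold_never_removes_clear_labels(cf_vals, thr, delta):
    """Monotone gate: the clear set grows with the CF threshold (set inclusion)."""
    from uvidose import MORONI

    idx = pd.date_range("2020-01-15 08:00", periods=30, freq="min", tz="UTC")
    uvi = pd.Series(5.0, index=idx, name="uvi")
    cf = _cf_frame(idx, cf_vals)
    lo = cf_threshold_filter(uvi, cf, MORONI, cf_threshold=thr)
    hi = cf_threshold_filter(uvi, cf, MORONI, cf_threshold=min(thr + delta, 1.0))
    assert ((lo == CLEAR) <= (hi == CLEAR)).all()
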