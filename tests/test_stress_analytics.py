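"""Water-stress markers: Tetens Psat, the two VPD forms, classifiers, summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from aerofog.stress_analytics import (
    DtlaStress,
    VpdStress,
    annotate_frame,
    classify_dtla,
    classify_vpd,
    dtla,
    saturation_vapor_pressure,
    summarize,
    vpd_kpa,
    vpd_pa,
)

# frozen from an independent evaluation of the Tetens form
PSAT_25 = 3.1677777175068473
PSAT_20 = 2.338281270927446


@pytest.mark.parametrize(
    "T,expected",
    [(0.0, 0.6108), (25.0, PSAT_25), (20.0, PSAT_20)],
)
def test_saturation_vapor_pressure_reference_points(T, expected):
    assert saturation_vapor_pressure(T) == pytest.approx(expected, rel=1e-9)


def test_psat_domain_and_monotonicity():
    with pytest.raises(ValueError):
        saturation_vapor_pressure(-240.0)
    ts = np.linspace(-30, 50, 200)
    ps = saturation_vapor_pressure(ts)
    assert np.all(ps > 0)
    assert np.all(np.diff(ps) > 0)


@pytest.mark.parametrize(
    "tc,ta,rh,expected",
    [
        (22.0, 22.0, 100.0, 0.0),
        (25.0, 25.0, 50.0, PSAT_25 - 0.5 * PSAT_25),
        (20.0, 25.0, 50.0, PSAT_20 - 0.5 * PSAT_25),
    ],
)
def test_vpd_kpa_reference_points(tc, ta, rh, expected):
    assert vpd_kpa(tc, ta, rh) == pytest.approx(expected, abs=1e-9)


def test_vpd_rejects_bad_humidity():
    with pytest.raises(ValueError):
        vpd_kpa(20.0, 25.0, 120.0)
    with pytest.raises(ValueError):
        vpd_pa(20.0, 25.0, -1.0)


def test_vpd_pa_matches_kpa_form_on_grid():
    """The e-based and base-10 forms agree within 0.2% (unit-adjusted)
    over the physiological grid; tight agreement since 17.27/ln10 ≈ 7.5006."""
    tc, ta, rh = np.meshgrid(
        np.arange(0.0, 41.0, 2.0), np.arange(0.0, 41.0, 2.0), np.arange(0.0, 101.0, 5.0)
    )
    k = vpd_kpa(tc, ta, rh)
    p = vpd_pa(tc, ta, rh) / 1000.0
    err = np.abs(p - k)
    assert np.all(err <= 0.002 * np.maximum(np.abs(k), 0.1))
    assert vpd_pa(25.0, 25.0, 50.0) == pytest.approx(1584.0, abs=1.0)
    assert vpd_pa(30.0, 30.0, 100.0) == 0.0


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    tc=st.floats(0, 40),
    ta=st.floats(0, 40),
    rh=st.floats(0, 99),
    drh=st.floats(0.5, 10),
)
def test_vpd_strictly_decreasing_in_humidity(tc, ta, rh, drh):
    hi = min(rh + drh, 100.0)
    assert vpd_kpa(tc, ta, hi) < vpd_kpa(tc, ta, rh)


def test_dtla_is_plain_difference():
    assert dtla(20.0, 25.0) == -5.0
    assert dtla(30.0, 25.0) == 5.0
    assert dtla(25.0, 25.0) == 0.0


@pytest.mark.parametrize(
    "d,expected",
    [
        (5.0, DtlaStress.STRESS),
        (4.0, DtlaStress.STRESS),
        (6.0, DtlaStress.STRESS),
        (-2.0, DtlaStress.NO_STRESS),
        (-4.0, DtlaStress.NO_STRESS),
        (-1.0, DtlaStress.NO_STRESS),
        (0.0, DtlaStress.INDETERMINATE),
        (3.99, DtlaStress.INDETERMINATE),
        (6.01, DtlaStress.INDETERMINATE),
        (-4.01, DtlaStress.INDETERMINATE),
    ],
)
def test_dtla_stress_bands(d, expected):
    assert classify_dtla(d) is expected


@pytest.mark.parametrize(
    "v,expected",
    [
        (1.5, VpdStress.HARMFUL),
        (1.0001, VpdStress.HARMFUL),
        (1.0, VpdStress.FAVORABLE),
        (0.7, VpdStress.FAVORABLE),
        (0.5, VpdStress.FAVORABLE),
        (0.49, VpdStress.INTERMEDIATE),
        (-0.2, VpdStress.INTERMEDIATE),
    ],
)
def test_vpd_stress_bands(v, expected):
    assert classify_vpd(v) is expected


class TestSummarize:
    def test_constant_series(self):
        idx = pd.date_range("2021-11-01", periods=5, freq="30s")
        s = summarize(pd.Series([3.0] * 5, index=idx), "x")
        assert s.minimum == s.maximum == s.mean == 3.0
        assert s.std == 0.0

    def test_sample_std_small_series(self):
        pairs = [
            (pd.Timestamp("2021-11-01 00:00"), 1.0),
            (pd.Timestamp("2021-11-01 00:01"), 2.0),
            (pd.Timestamp("2021-11-01 00:02"), 3.0),
            (pd.Timestamp("2021-11-01 00:03"), 4.0),
        ]
        s = summarize(pairs, "x")
        assert s.mean == 2.5
        assert s.std == pytest.approx(1.2909944487358056)
        assert s.time_of_min == pd.Timestamp("2021-11-01 00:00")
        assert s.time_of_max == pd.Timestamp("2021-11-01 00:03")

    def test_tie_breaks_to_earliest(self):
        idx = pd.DatetimeIndex(
            ["2021-11-01 01:00", "2021-11-01 02:00", "2021-11-01 03:00"]
        )
        s = summarize(pd.Series([7.0, 7.0, 1.0], index=idx), "x")
        assert s.time_of_max == idx[0]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize([])

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=500)
        idx = pd.date_range("2021-11-01", periods=500, freq="30s")
        s = summarize(pd.Series(values, index=idx), "x")
        # brute-force single pass
        mn, mx, total = math.inf, -math.inf, 0.0
        for v in values:
            mn, mx, total = min(mn, v), max(mx, v), total + v
        mean = total / len(values)
        var = sum((v - mean) ** 2 for v in values) / (len(values) - 1)
        assert (s.minimum, s.maximum) == (mn, mx)
        assert s.mean == pytest.approx(mean)
        assert s.std == pytest.approx(math.sqrt(var))


def test_annotate_frame_appends_markers_and_flags_negative():
    df = pd.DataFrame(
        {
            "timestamp": pd.date_range("2021-11-01", periods=3, freq="30s"),
            "Ta": [25.0, 25.0, 30.0],
            "Tc": [25.0, 21.5, 24.0],
            "RHa": [50.0, 95.0, 40.0],
            "RHc": [50.0, 95.0, 40.0],
        }
    )
    out = annotate_frame(df)
    assert {"Psat_c", "Psat_a", "VPD", "VPD_pa", "DTla", "stress_dtla", "stress_vpd"} <= set(out.columns)
    assert out.loc[0, "VPD"] == pytest.approx(0.5 * PSAT_25)
    # leaf much cooler than near-saturated air: negative VPD reported, flagged
    assert out.loc[1, "VPD"] < 0
    assert bool(out.loc[1, "vpd_negative"])
    assert out.loc[1, "stress_dtla"] == "no_stress"
    with pytest.raises(ValueError):
        annotate_frame(df.drop(columns=["Tc"]))
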