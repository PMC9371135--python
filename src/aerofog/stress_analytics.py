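"""Leaf-to-air water-stress markers.

Saturation vapor pressure follows the Tetens form (FAO-56 / Allen 1998):

    Psat(T) = 0.6108 * exp(17.27 T / (T + 237.3))   [kPa]

The leaf-to-air vapor pressure deficit uses the crop (leaf) temperature
for the saturation term and the air temperature with relative humidity
for the actual-vapor term:

    VPD = Psat(Tc) - (RH/100) * Psat(Ta)            [kPa]

An equivalent base-10 form (610.7 Pa prefactor, exponent coefficient
7.5 ≈ 17.27 / ln 10) is provided for cross-validation; the two agree to
better than 0.2 % over the physiological range. The crop-minus-air
temperature difference DT_la = Tc − Ta is the second stress marker:
arid/semi-arid literature flags water stress when the leaf runs 4–6 °C
hotter than the air and no stress when it runs 1–4 °C cooler. A VPD
above 1 kPa is potentially harmful (stomatal closure); 0.5–1 kPa is the
favorable window.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "saturation_vapor_pressure",
    "vpd_kpa",
    "vpd_pa",
    "dtla",
    "classify_dtla",
    "classify_vpd",
    "DtlaStress",
    "VpdStress",
    "SummaryStats",
    "summarize",
    "annotate_frame",
]

ArrayLike = Union[float, np.ndarray]

_T_MIN = -237.3  # Tetens pole


class DtlaStress(str, Enum):
    STRESS = "stress"
    NO_STRESS = "no_stress"
    INDETERMINATE = "indeterminate"


class VpdStress(str, Enum):
    HARMFUL = "harmful"
    FAVORABLE = "favorable"
    INTERMEDIATE = "intermediate"


def saturation_vapor_pressure(T: ArrayLike) -> ArrayLike:
    """Tetens saturation vapor pressure in kPa at temperature ``T`` (°C)."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= _T_MIN):
        raise ValueError(f"temperature must exceed {_T_MIN} °C")
    out = 0.6108 * np.exp(17.27 * T / (T + 237.3))
    return float(out) if out.ndim == 0 else out


def _check_rh(RH: np.ndarray) -> None:
    if np.any((RH < 0.0) | (RH > 100.0)):
        raise ValueError("relative humidity must lie in [0, 100]")


def vpd_kpa(Tc: ArrayLike, Ta: ArrayLike, RH: ArrayLike) -> ArrayLike:
    """Leaf-to-air VPD in kPa: Psat(Tc) − (RH/100)·Psat(Ta).

    May be negative when the leaf is much cooler than saturated air;
    such values are reported as computed, not clipped.
    """
    RH = np.asarray(RH, dtype=float)
    _check_rh(RH)
    out = saturation_vapor_pressure(Tc) - (RH / 100.0) * saturation_vapor_pressure(Ta)
    return float(out) if np.ndim(out) == 0 else out


def vpd_pa(Tc: ArrayLike, Ta: ArrayLike, RH: ArrayLike) -> ArrayLike:
    """Leaf-to-air VPD in Pa, base-10 exponential form.

    610.7·[10^(7.5 Tc/(Tc+237.3)) − (RH/100)·10^(7.5 Ta/(Ta+237.3))].
    Retained for validation against :func:`vpd_kpa`; the two forms agree
    within 0.2 % relative over the physiological grid.
    """
    Tc = np.asarray(Tc, dtype=float)
    Ta = np.asarray(Ta, dtype=float)
    RH = np.asarray(RH, dtype=float)
    _check_rh(RH)
    if np.any(Tc <= _T_MIN) or np.any(Ta <= _T_MIN):
        raise ValueError(f"temperature must exceed {_T_MIN} °C")
    out = 610.7 * (
        np.power(10.0, 7.5 * Tc / (Tc + 237.3))
        - (RH / 100.0) * np.power(10.0, 7.5 * Ta / (Ta + 237.3))
    )
    return float(out) if np.ndim(out) == 0 else out


def dtla(Tc: ArrayLike, Ta: ArrayLike) -> ArrayLike:
    """Crop-minus-air temperature difference DT_la = Tc − Ta (°C)."""
    out = np.asarray(Tc, dtype=float) - np.asarray(Ta, dtype=float)
    return float(out) if np.ndim(out) == 0 else out


def classify_dtla(d: float) -> DtlaStress:
    """Water-stress class from DT_la: stress in [+4, +6] °C, no stress in
    [−4, −1] °C, indeterminate elsewhere (the published bands do not
    cover the whole line)."""
    if 4.0 <= d <= 6.0:
        return DtlaStress.STRESS
    if -4.0 <= d <= -1.0:
        return DtlaStress.NO_STRESS
    return DtlaStress.INDETERMINATE


def classify_vpd(v: float) -> VpdStress:
    """VPD class: harmful strictly above 1 kPa, favorable in
    [0.5, 1] kPa, intermediate below 0.5 kPa."""
    if v > 1.0:
        return VpdStress.HARMFUL
    if v >= 0.5:
        return VpdStress.FAVORABLE
    return VpdStress.INTERMEDIATE


@dataclass(frozen=True)
class SummaryStats:
    """Series summary in the deployment-report layout: extrema, mean,
    sample standard deviation, and clock times of the extrema."""

    variable: str
    minimum: float
    maximum: float
    mean: float
    std: float
    time_of_max: pd.Timestamp
    time_of_min: pd.Timestamp


def summarize(
    series: Union[pd.Series, Sequence[tuple]],
    variable: str = "",
) -> SummaryStats:
    """Summarize a timestamped series.

    Accepts a pandas Series indexed by timestamps or a sequence of
    ``(timestamp, value)`` pairs. Std is the sample (n−1) standard
    deviation (0 for a single point); extremum-time ties break to the
    earliest timestamp.
    """
    if not isinstance(series, pd.Series):
        pairs = list(series)
        if not pairs:
            raise ValueError("series must be non-empty")
        series = pd.Series(
            [v for _, v in pairs], index=pd.DatetimeIndex([t for t, _ in pairs])
        )
    if series.empty:
        raise ValueError("series must be non-empty")
    values = series.to_numpy(dtype=float)
    std = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return SummaryStats(
        variable=variable,
        minimum=float(values.min()),
        maximum=float(values.max()),
        mean=float(values.mean()),
        std=std,
        time_of_max=series.index[int(np.argmax(values))],
        time_of_min=series.index[int(np.argmin(values))],
    )


def annotate_frame(df: pd.DataFrame, rh_source: str = "RHa") -> pd.DataFrame:
    """Batch entry point: append stress markers to a telemetry frame.

    ``df`` must carry columns Ta, RHa, Tc (RHc required only when
    ``rh_source='RHc'``). Appends Psat_c, Psat_a, VPD (kPa), VPD_pa,
    DTla, the two categorical labels, and a ``vpd_negative`` warning
    flag for physically awkward (leaf far cooler than air at high
    humidity) negative deficits.
    """
    if rh_source not in ("RHa", "RHc"):
        raise ValueError("rh_source must be 'RHa' or 'RHc'")
    required = {"Ta", "Tc", rh_source}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = df.copy()
    rh = out[rh_source].to_numpy(dtype=float)
    tc = out["Tc"].to_numpy(dtype=float)
    ta = out["Ta"].to_numpy(dtype=float)
    out["Psat_c"] = saturation_vapor_pressure(tc)
    out["Psat_a"] = saturation_vapor_pressure(ta)
    out["VPD"] = vpd_kpa(tc, ta, rh)
    out["VPD_pa"] = vpd_pa(tc, ta, rh)
    out["DTla"] = dtla(tc, ta)
    out["stress_dtla"] = [classify_dtla(d).value for d in out["DTla"]]
    out["stress_vpd"] = [classify_vpd(v).value for v in out["VPD"]]
    out["vpd_negative"] = out["VPD"] < 0.0
    return out
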