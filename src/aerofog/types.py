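"""Shared domain records for the monitoring stack.

These are the in-memory counterparts of one telemetry row: a climate
reading, a nutrient-tank reading, and the on/off state of the actuators
driven by the fog-layer services.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd


@dataclass(frozen=True)
class ClimateSample:
    """One timestamped climate reading.

    Attributes
    ----------
    t : pd.Timestamp
        Sample time (timezone-naive local clock time).
    Ta : float
        Ambient air temperature, °C.
    RHa : float
        Ambient relative humidity, % (0–100).
    Tc : float
        Crop (leaf) temperature, °C.
    RHc : float
        Relative humidity at the crop, % (0–100).
    Lum : float
        Ambient light intensity, lux (≥ 0).
    """

    t: pd.Timestamp
    Ta: float
    RHa: float
    Tc: float
    RHc: float
    Lum: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.RHa <= 100.0):
            raise ValueError(f"RHa out of [0, 100]: {self.RHa}")
        if not (0.0 <= self.RHc <= 100.0):
            raise ValueError(f"RHc out of [0, 100]: {self.RHc}")
        if self.Lum < 0.0:
            raise ValueError(f"Lum negative: {self.Lum}")


@dataclass(frozen=True)
class TankSample:
    """Nutrient-solution tank state at one instant.

    ``lost_l`` accumulates liquid that permanently left the two-tank
    system (plant uptake, evaporation, non-returned irrigation spray,
    overflow), so that ``L_sol + L_res + lost_l`` is conserved across
    actuator steps and conservation is directly testable.
    """

    t: pd.Timestamp
    T_sol: float
    L_sol: float
    T_res: float
    L_res: float
    lost_l: float = 0.0


@dataclass(frozen=True)
class ActuatorState:
    """On/off state of the pumps plus the camera-service status code.

    ``S_cam`` uses the pulse code of the image-acquisition service:
    3 = both cameras captured, 2 = upper-camera flaw, 1 = frontal-camera
    flaw, 0 = no capture / service down.
    """

    S_irr: bool = False
    S_res: bool = False
    S_mix: bool = False
    S_cam: int = 0

    def __post_init__(self) -> None:
        if self.S_cam not in (0, 1, 2, 3):
            raise ValueError(f"S_cam must be in {{0,1,2,3}}, got {self.S_cam}")


# Ordering of the eight environmental-channel sensors. Bit k of the
# sensor-health register corresponds to ENV_FIELDS[k]; the ambient
# temperature is measured twice (two independent thermometers on the
# rig), hence the _htu/_mlx pair.
ENV_FIELDS: tuple[str, ...] = (
    "Ta_htu",
    "Ta_mlx",
    "Tc",
    "RHa",
    "RHc",
    "Lum",
    "T_res",
    "L_res",
)
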