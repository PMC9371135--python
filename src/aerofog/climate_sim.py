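"""Synthetic device layer for an aeroponic greenhouse.

Generates the telemetry the physical rig would produce: diurnal ambient
temperature / humidity / luminosity, a coupled crop (leaf) temperature,
nutrient-tank level and temperature dynamics under irrigation and
recirculation, injected sensor/service faults, and synthetic root
images with pixel-level ground truth.

The diurnal model is deliberately simple — clipped sinusoids with
configurable peak times — because the goal is a controllable stand-in
for the greenhouse, not an energy-balance model. Defaults follow the
observed operating ranges of the reference deployment (ambient
temperature 6.47–34.19 °C peaking at 12:52, humidity 5.87–97.43 %,
luminosity up to 9118 lux, leaf-minus-air temperature −4.63–0.24 °C,
tanks of 83.5 and 21.5 L, 160 L/h mixing pump, irrigation every 24 min
for 30 s).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, time
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .types import ActuatorState, ClimateSample, TankSample

__all__ = [
    "SimConfig",
    "FaultPlan",
    "RootImageTruth",
    "simulate",
    "simulate_full",
    "step_tanks",
    "synth_root_image",
    "climate_to_frame",
    "tanks_to_frame",
]

# Named noise streams. Each stream derives its generator from
# (root seed, stream index) so adding a stream never perturbs the others.
_STREAMS = {
    "Ta": 0,
    "RHa": 1,
    "dtla": 2,
    "RHc": 3,
    "Lum": 4,
    "T_sol": 5,
    "T_res": 6,
    "root_image": 7,
}


def _stream_rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[name]])


class SimConfig(BaseModel):
    """Simulation configuration: climate ranges, tank plumbing, schedules.

    Times of day are local clock times (timezone-naive). ``noise_sd``
    maps a variable name (Ta, RHa, dtla, RHc, Lum, T_sol, T_res) to the
    standard deviation of its additive Gaussian noise, in the variable's
    own units.
    """

    t_start: datetime = datetime(2021, 11, 1, 0, 0, 0)
    t_end: datetime = datetime(2021, 11, 2, 0, 0, 0)
    step_s: int = 30

    Ta_min: float = 6.47
    Ta_max: float = 34.19
    RHa_min: float = 5.87
    RHa_max: float = 97.43
    Lum_max: float = 9118.0
    peak_time_Ta: time = time(12, 52)
    peak_time_Lum: time = time(12, 23)
    day_start: time = time(6, 30)
    day_end: time = time(19, 30)
    dtla_min: float = -4.63
    dtla_max: float = 0.24

    noise_sd: dict[str, float] = Field(
        default_factory=lambda: {
            "Ta": 0.1,
            "RHa": 0.5,
            "dtla": 0.05,
            "RHc": 0.5,
            "Lum": 20.0,
            "T_sol": 0.05,
            "T_res": 0.05,
        }
    )

    main_tank_capacity_l: float = 83.5
    recirc_tank_capacity_l: float = 21.5
    initial_L_sol: float = 50.0
    initial_L_res: float = 0.0
    irrigation_flow_l_per_h: float = 6.0
    return_fraction: float = 0.9
    uptake_l_per_h: float = 0.0
    mix_pump_flow_l_per_h: float = 160.0
    tank_temp_tau_s: float = 3.0 * 3600.0

    # autonomous fog-service defaults used when no actuator log is given
    irrigation_period_min: float = 24.0
    irrigation_on_s: float = 30.0
    recirc_threshold_l: float = 16.0
    recirc_low_l: float = 0.5
    mix_time_s: float = 120.0
    camera_times: list[time] = Field(
        default_factory=lambda: [
            time(6, 0), time(7, 0), time(8, 0), time(11, 0), time(12, 0),
            time(13, 0), time(17, 30), time(18, 30), time(19, 30),
        ]
    )

    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        if self.step_s <= 0:
            raise ValueError("step_s must be positive")
        if not self.Ta_min < self.Ta_max:
            raise ValueError("require Ta_min < Ta_max")
        if not (0.0 <= self.RHa_min < self.RHa_max <= 100.0):
            raise ValueError("require 0 <= RHa_min < RHa_max <= 100")
        if not (0.0 <= self.return_fraction <= 1.0):
            raise ValueError("return_fraction must lie in [0, 1]")
        if self.main_tank_capacity_l <= 0 or self.recirc_tank_capacity_l <= 0:
            raise ValueError("tank capacities must be positive")
        if self.dtla_min > self.dtla_max:
            raise ValueError("require dtla_min <= dtla_max")
        if self.t_end <= self.t_start:
            raise ValueError("require t_start < t_end")
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ValueError("noise_sd values must be non-negative")
        return self

    def sd(self, name: str) -> float:
        return float(self.noise_sd.get(name, 0.0))


ServiceName = Literal["irrigation", "recirculation", "camera", "sensor"]
CameraName = Literal["frontal", "upper"]


class FaultPlan(BaseModel):
    """Injected outages: per-sensor, per-service and per-camera windows."""

    sensor_faults: list[tuple[int, datetime, datetime]] = Field(default_factory=list)
    service_faults: list[tuple[ServiceName, datetime, datetime]] = Field(default_factory=list)
    camera_faults: list[tuple[CameraName, datetime, datetime]] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check(self) -> "FaultPlan":
        for idx, t_on, t_off in self.sensor_faults:
            if not (0 <= idx <= 7):
                raise ValueError(f"sensor index out of [0, 7]: {idx}")
            if not t_on < t_off:
                raise ValueError("fault window requires t_on < t_off")
        for _, t_on, t_off in list(self.service_faults) + list(self.camera_faults):
            if not t_on < t_off:
                raise ValueError("fault window requires t_on < t_off")
        return self

    def sensor_ok(self, index: int, t: pd.Timestamp) -> bool:
        return not any(
            i == index and t_on <= t < t_off for i, t_on, t_off in self.sensor_faults
        )

    def sensor_flags(self, t: pd.Timestamp) -> list[bool]:
        return [self.sensor_ok(k, t) for k in range(8)]

    def service_ok(self, name: str, t: pd.Timestamp) -> bool:
        return not any(
            s == name and t_on <= t < t_off for s, t_on, t_off in self.service_faults
        )

    def camera_ok(self, name: str, t: pd.Timestamp) -> bool:
        return not any(
            c == name and t_on <= t < t_off for c, t_on, t_off in self.camera_faults
        )


@dataclass(frozen=True)
class RootImageTruth:
    """A rendered root image plus its ground-truth root mask."""

    image: np.ndarray  # H x W x 3 uint8
    truth_mask: np.ndarray  # H x W bool
    root_fraction: float

    def __post_init__(self) -> None:
        if self.image.shape[:2] != self.truth_mask.shape:
            raise ValueError("truth_mask dimensions must equal image dimensions")


def _hours_of_day(times: pd.DatetimeIndex) -> np.ndarray:
    ns = times - times.normalize()
    return ns.total_seconds().to_numpy() / 3600.0


def _time_to_hours(t: time) -> float:
    return t.hour + t.minute / 60.0 + t.second / 3600.0


def _diurnal_cos(h: np.ndarray, peak_h: float, lo: float, hi: float) -> np.ndarray:
    """Cosine with 24 h period attaining ``hi`` at ``peak_h`` and ``lo`` 12 h away."""
    mid = 0.5 * (lo + hi)
    amp = 0.5 * (hi - lo)
    return mid + amp * np.cos(2.0 * np.pi * (h - peak_h) / 24.0)


def _lum_curve(h: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """Raised-cosine daylight bump: 0 outside [day_start, day_end],
    Lum_max at peak_time_Lum."""
    start = _time_to_hours(cfg.day_start)
    end = _time_to_hours(cfg.day_end)
    peak = _time_to_hours(cfg.peak_time_Lum)
    lum = np.zeros_like(h)
    rising = (h >= start) & (h <= peak)
    falling = (h > peak) & (h <= end)
    if peak > start:
        lum[rising] = cfg.Lum_max * 0.5 * (1 - np.cos(np.pi * (h[rising] - start) / (peak - start)))
    if end > peak:
        lum[falling] = cfg.Lum_max * 0.5 * (1 + np.cos(np.pi * (h[falling] - peak) / (end - peak)))
    return lum


def step_tanks(
    state: TankSample,
    actuators: ActuatorState,
    dt_s: float,
    config: SimConfig,
) -> TankSample:
    """Advance the two-tank nutrient system by ``dt_s`` seconds.

    Irrigation sprays from the main tank; ``return_fraction`` of the
    sprayed volume drains back into the recirculation tank and the rest
    (mist deposited on the crop, drift) is counted as lost. The
    recirculation pump moves liquid back to the main tank at the mixing
    pump's flow rate. Plant uptake / evaporation is a constant
    configurable drain. Levels are clipped to tank capacities; anything
    that cannot fit is accounted in ``lost_l`` so that
    ``L_sol + L_res + lost_l`` is exactly conserved.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    dt_h = dt_s / 3600.0
    l_sol, l_res, lost = state.L_sol, state.L_res, state.lost_l

    if actuators.S_irr:
        sprayed = min(l_sol, config.irrigation_flow_l_per_h * dt_h)
        l_sol -= sprayed
        returned = config.return_fraction * sprayed
        fits = min(returned, config.recirc_tank_capacity_l - l_res)
        l_res += fits
        lost += sprayed - fits

    if actuators.S_res:
        moved = min(
            l_res,
            config.mix_pump_flow_l_per_h * dt_h,
            config.main_tank_capacity_l - l_sol,
        )
        l_res -= moved
        l_sol += moved

    if config.uptake_l_per_h > 0.0:
        uptake = min(l_sol, config.uptake_l_per_h * dt_h)
        l_sol -= uptake
        lost += uptake

    return TankSample(
        t=pd.Timestamp(state.t) + pd.Timedelta(seconds=dt_s),
        T_sol=state.T_sol,
        L_sol=l_sol,
        T_res=state.T_res,
        L_res=l_res,
        lost_l=lost,
    )


def _autonomous_actuator(
    t: pd.Timestamp,
    tank: TankSample,
    cfg: SimConfig,
    faults: FaultPlan,
    ctl: dict,
) -> ActuatorState:
    """Default fog-service behaviour when no actuator log is supplied."""
    secs = (t - t.normalize()).total_seconds()
    period_s = cfg.irrigation_period_min * 60.0
    irr = (secs % period_s) < cfg.irrigation_on_s
    if not faults.service_ok("irrigation", t):
        irr = False

    # recirculation hysteresis: on above threshold, off at the low setpoint
    res = ctl.get("res_on", False)
    if res:
        res = tank.L_res > cfg.recirc_low_l
    else:
        res = tank.L_res > cfg.recirc_threshold_l
    if not faults.service_ok("recirculation", t):
        res = False
    # mixing pump runs for mix_time_s after a recirculation transfer ends
    if ctl.get("res_on", False) and not res:
        ctl["mix_until"] = t + pd.Timedelta(seconds=cfg.mix_time_s)
    ctl["res_on"] = res
    mix = t < ctl.get("mix_until", pd.Timestamp.min)

    cam = 0
    if faults.service_ok("camera", t):
        tod = t.time()
        step = pd.Timedelta(seconds=cfg.step_s)
        for ct in cfg.camera_times:
            ct_ts = t.normalize() + pd.Timedelta(hours=ct.hour, minutes=ct.minute, seconds=ct.second)
            if ct_ts <= t < ct_ts + step:
                frontal = faults.camera_ok("frontal", t)
                upper = faults.camera_ok("upper", t)
                cam = 3 if frontal and upper else (2 if frontal else (1 if upper else 0))
                break
    return ActuatorState(S_irr=bool(irr), S_res=bool(res), S_mix=bool(mix), S_cam=cam)


def simulate_full(
    config: SimConfig,
    faults: Optional[FaultPlan] = None,
    actuator_log: Optional[Sequence[ActuatorState]] = None,
) -> tuple[list[ClimateSample], list[TankSample], list[ActuatorState]]:
    """Run the device-layer simulation, returning climate, tank and
    actuator streams at ``step_s`` cadence over ``[t_start, t_end)``.

    Identical (config, faults, actuator_log) produce bit-identical
    output. When ``actuator_log`` is None the built-in autonomous
    services (periodic irrigation, 16 L recirculation hysteresis,
    scheduled cameras) drive the actuators.
    """
    faults = faults or FaultPlan()
    times = pd.date_range(
        config.t_start, config.t_end, freq=f"{config.step_s}s", inclusive="left"
    )
    n = len(times)
    if actuator_log is not None and len(actuator_log) not in (0, n):
        raise ValueError(
            f"actuator_log must cover the simulation window ({n} steps) or be empty"
        )
    if actuator_log is not None and len(actuator_log) == 0:
        actuator_log = None

    h = _hours_of_day(times)
    ta_clean = _diurnal_cos(h, _time_to_hours(config.peak_time_Ta), config.Ta_min, config.Ta_max)
    ta = ta_clean + _stream_rng(config.seed, "Ta").normal(0.0, config.sd("Ta"), n)
    ta = np.clip(ta, config.Ta_min, config.Ta_max)

    # humidity anti-correlated with the clean temperature curve
    u = (ta_clean - config.Ta_min) / (config.Ta_max - config.Ta_min)
    rha = config.RHa_max - u * (config.RHa_max - config.RHa_min)
    rha = rha + _stream_rng(config.seed, "RHa").normal(0.0, config.sd("RHa"), n)
    rha = np.clip(rha, config.RHa_min, config.RHa_max)

    # leaf-air coupling: most negative near midday (transpirative cooling)
    d = _diurnal_cos(h, 0.0, config.dtla_min, config.dtla_max)
    d = d + _stream_rng(config.seed, "dtla").normal(0.0, config.sd("dtla"), n)
    d = np.clip(d, config.dtla_min, config.dtla_max)
    tc = ta + d

    rhc = rha + _stream_rng(config.seed, "RHc").normal(0.0, config.sd("RHc"), n)
    rhc = np.clip(rhc, config.RHa_min, config.RHa_max)

    lum = _lum_curve(h, config)
    lum_noise = _stream_rng(config.seed, "Lum").normal(0.0, config.sd("Lum"), n)
    lum = np.where(lum > 0.0, np.clip(lum + lum_noise, 0.0, config.Lum_max), 0.0)

    climate = [
        ClimateSample(t=times[i], Ta=float(ta[i]), RHa=float(rha[i]),
                      Tc=float(tc[i]), RHc=float(rhc[i]), Lum=float(lum[i]))
        for i in range(n)
    ]

    sol_noise = _stream_rng(config.seed, "T_sol").normal(0.0, config.sd("T_sol"), n)
    res_noise = _stream_rng(config.seed, "T_res").normal(0.0, config.sd("T_res"), n)
    alpha = config.step_s / config.tank_temp_tau_s

    tanks: list[TankSample] = []
    actuators: list[ActuatorState] = []
    ctl: dict = {}
    tank = TankSample(
        t=times[0], T_sol=float(ta[0]), L_sol=config.initial_L_sol,
        T_res=float(ta[0]), L_res=config.initial_L_res,
    )
    for i, t in enumerate(times):
        act = actuator_log[i] if actuator_log is not None else _autonomous_actuator(
            t, tank, config, faults, ctl
        )
        # tank temperatures relax toward ambient with a slow first-order lag
        t_sol = tank.T_sol + alpha * (float(ta[i]) - tank.T_sol) + float(sol_noise[i])
        t_res = tank.T_res + alpha * (float(ta[i]) - tank.T_res) + float(res_noise[i])
        tank = TankSample(t=t, T_sol=t_sol, L_sol=tank.L_sol,
                          T_res=t_res, L_res=tank.L_res, lost_l=tank.lost_l)
        tanks.append(tank)
        actuators.append(act)
        tank = step_tanks(tank, act, config.step_s, config)

    return climate, tanks, actuators


def simulate(
    config: SimConfig,
    faults: Optional[FaultPlan] = None,
    actuator_log: Optional[Sequence[ActuatorState]] = None,
) -> tuple[list[ClimateSample], list[TankSample]]:
    """Spec'd entry point: climate and tank streams only."""
    climate, tanks, _ = simulate_full(config, faults, actuator_log)
    return climate, tanks


def climate_to_frame(samples: Sequence[ClimateSample]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "timestamp": [s.t for s in samples],
            "Ta": [s.Ta for s in samples],
            "RHa": [s.RHa for s in samples],
            "Tc": [s.Tc for s in samples],
            "RHc": [s.RHc for s in samples],
            "Lum": [s.Lum for s in samples],
        }
    )


def tanks_to_frame(samples: Sequence[TankSample]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "timestamp": [s.t for s in samples],
            "T_sol": [s.T_sol for s in samples],
            "L_sol": [s.L_sol for s in samples],
            "T_res": [s.T_res for s in samples],
            "L_res": [s.L_res for s in samples],
        }
    )


def synth_root_image(
    h: int,
    w: int,
    root_fraction: float,
    background_hue: float = 90.0,
    seed: int = 0,
) -> RootImageTruth:
    """Render a synthetic root image: dark reddish root strands hanging
    over a bright greenish background, with a pixel ground-truth mask.

    ``background_hue`` is on the 0–179 hue scale used by the
    segmentation pipeline; it should sit inside the background band
    (35, 140) for the image to be cleanly separable. Root strands are
    rendered with hues near red (outside the band) and mid-high value,
    as they appear under the root-chamber illumination.
    """
    from skimage.color import hsv2rgb

    if not (0.0 <= root_fraction < 1.0):
        raise ValueError("root_fraction must lie in [0, 1)")
    if h < 16 or w < 16:
        raise ValueError("image must be at least 16x16")

    rng = np.random.default_rng([int(seed), _STREAMS["root_image"]])
    mask = np.zeros((h, w), dtype=bool)
    target = int(round(root_fraction * h * w))

    # strands are 3 px wide and drift slowly so they survive a 2x2
    # morphological opening nearly intact (clean-separation fixture)
    guard = 0
    while mask.sum() < target and guard < 10_000:
        guard += 1
        remaining = target - int(mask.sum())
        length = int(min(0.8 * h, max(8, remaining // 3)))
        x = int(rng.integers(0, w - 3))
        y0 = int(rng.integers(0, max(1, h // 4)))
        for j, y in enumerate(range(y0, min(h, y0 + length))):
            if j % 3 == 2:
                x = int(np.clip(x + rng.integers(-1, 2), 0, w - 3))
            mask[y, x : x + 3] = True
            if mask.sum() >= target:
                break

    hsv = np.empty((h, w, 3), dtype=float)
    bg_h = np.clip(background_hue + rng.normal(0.0, 2.0, (h, w)), 36.0, 139.0)
    hsv[..., 0] = bg_h / 180.0
    hsv[..., 1] = np.clip(rng.normal(0.55, 0.05, (h, w)), 0.3, 0.8)
    hsv[..., 2] = np.clip(rng.normal(0.80, 0.04, (h, w)), 0.6, 1.0)

    root_h = np.clip(rng.normal(8.0, 3.0, (h, w)), 0.0, 30.0) / 180.0
    root_s = np.clip(rng.normal(0.75, 0.05, (h, w)), 0.5, 1.0)
    root_v = np.clip(rng.normal(0.55, 0.05, (h, w)), 0.45, 0.75)
    hsv[..., 0] = np.where(mask, root_h, hsv[..., 0])
    hsv[..., 1] = np.where(mask, root_s, hsv[..., 1])
    hsv[..., 2] = np.where(mask, root_v, hsv[..., 2])

    image = (hsv2rgb(hsv) * 255.0).round().astype(np.uint8)
    return RootImageTruth(
        image=image, truth_mask=mask, root_fraction=float(mask.sum()) / (h * w)
    )
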