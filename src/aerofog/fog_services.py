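"""Fog-layer microservices.

The fog layer sits between the (simulated) greenhouse devices and the
channel store: it schedules irrigation, recirculates the nutrient
solution when the return tank fills past 16 L, triggers the two crop
cameras on a user schedule, polls the eight environmental sensors every
30 s into one packed channel write, folds per-sensor read success into
a one-byte health register, detects failures from pulse absence and
stuck-at-zero health bits, and raises alert events for new failures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, datetime, time
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import pandas as pd

from .channel_store import ENVIRONMENTAL, ChannelWrite
from .types import ENV_FIELDS, ClimateSample, TankSample

__all__ = [
    "MICROSERVICES",
    "IrrigationWindow",
    "IrrigationConfig",
    "CameraSchedule",
    "HealthRegister",
    "FailureReport",
    "AlertEvent",
    "Expectations",
    "plan_irrigation",
    "reservoir_service",
    "camera_service",
    "sensor_service_poll",
    "encode_health",
    "decode_health",
    "detect_failures",
    "AlertService",
    "JsonlTransport",
]

MICROSERVICES = ("irrigation", "recirculation", "camera", "sensor", "control", "alert")


def _hours(t: time) -> float:
    return t.hour + t.minute / 60.0 + t.second / 3600.0


@dataclass(frozen=True)
class IrrigationWindow:
    """A time-of-day window with its own period and on-time. A window
    whose end precedes its start wraps past midnight."""

    start: time
    end: time
    frequency_min: float
    on_time_s: float

    def __post_init__(self) -> None:
        if not (0.0 < self.on_time_s < self.frequency_min * 60.0):
            raise ValueError(
                "require 0 < on_time_s < frequency_min*60 "
                f"(got on_time_s={self.on_time_s}, frequency_min={self.frequency_min})"
            )


@dataclass(frozen=True)
class IrrigationConfig:
    """Base sprinkler cadence, with optional day/night overrides."""

    frequency_min: float = 24.0
    on_time_s: float = 30.0
    day_window: Optional[IrrigationWindow] = None
    night_window: Optional[IrrigationWindow] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.on_time_s < self.frequency_min * 60.0):
            raise ValueError("require 0 < on_time_s < frequency_min*60")


def plan_irrigation(
    config: IrrigationConfig, day: Union[date, datetime, pd.Timestamp]
) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Sprinkler (on, off) events for one calendar day.

    Events are anchored at each window's start (first activation at
    offset zero) and repeat every ``frequency_min`` minutes while the
    activation start lies inside the window. Without overrides a single
    full-day window applies, giving floor(1440/f) activations when f
    divides 1440.
    """
    midnight = pd.Timestamp(day).normalize()

    segments: list[tuple[float, float, float, float]] = []  # start_h, end_h, freq, on_s
    if config.day_window is None and config.night_window is None:
        segments.append((0.0, 24.0, config.frequency_min, config.on_time_s))
    else:
        for win in (config.day_window, config.night_window):
            if win is None:
                continue
            s, e = _hours(win.start), _hours(win.end)
            if e > s:
                segments.append((s, e, win.frequency_min, win.on_time_s))
            else:  # wraps midnight: split, each part anchored at its own start
                segments.append((s, 24.0, win.frequency_min, win.on_time_s))
                if e > 0.0:
                    segments.append((0.0, e, win.frequency_min, win.on_time_s))

    events: list[tuple[pd.Timestamp, pd.Timestamp]] = []
    for start_h, end_h, freq_min, on_s in segments:
        k = 0
        while True:
            t_h = start_h + k * freq_min / 60.0
            if t_h >= end_h - 1e-9:
                break
            t_on = midnight + pd.Timedelta(hours=t_h)
            events.append((t_on, t_on + pd.Timedelta(seconds=on_s)))
            k += 1
    events.sort()
    for (a_on, a_off), (b_on, _) in zip(events, events[1:]):
        if b_on < a_off:
            raise ValueError(f"overlapping irrigation events at {b_on}")
    return events


def reservoir_service(
    level_l: float,
    pump_on: bool,
    threshold_l: float = 16.0,
    low_setpoint_l: float = 0.5,
) -> bool:
    """Recirculation transfer-pump command with hysteresis.

    The pump switches on when the recirculation-tank level is strictly
    above ``threshold_l`` (16 L) and, once running, stays on until the
    level drops to ``low_setpoint_l``; the mixing pump is then run by
    the caller for its configured mix time.
    """
    if level_l < 0.0:
        raise ValueError("level_l must be non-negative")
    if pump_on:
        return level_l > low_setpoint_l
    return level_l > threshold_l


@dataclass(frozen=True)
class CameraSchedule:
    """Ordered capture times-of-day for the frontal and upper cameras."""

    capture_times: tuple[time, ...] = (
        time(6, 0), time(7, 0), time(8, 0), time(11, 0), time(12, 0),
        time(13, 0), time(17, 30), time(18, 30), time(19, 30),
    )

    def __post_init__(self) -> None:
        hs = [_hours(t) for t in self.capture_times]
        if any(b <= a for a, b in zip(hs, hs[1:])):
            raise ValueError("capture_times must be strictly increasing")

    def times_on(self, day: Union[date, pd.Timestamp]) -> list[pd.Timestamp]:
        midnight = pd.Timestamp(day).normalize()
        return [midnight + pd.Timedelta(hours=_hours(t)) for t in self.capture_times]


def camera_service(
    schedule: CameraSchedule,
    t: pd.Timestamp,
    camera_health: Optional[dict[str, bool]] = None,
    tick_s: float = 30.0,
) -> tuple[list[str], Optional[int]]:
    """Attempt scheduled captures at tick ``t``.

    On a scheduled tick (``t`` within ``tick_s`` after a capture time)
    returns the list of cameras that captured and the status pulse:
    3 = both cameras ok, 2 = upper-camera flaw, 1 = frontal-camera flaw,
    0 = neither captured (indistinguishable from a downed service).
    Off-schedule ticks return ``([], None)`` — no pulse.
    """
    camera_health = camera_health or {"frontal": True, "upper": True}
    t = pd.Timestamp(t)
    scheduled = any(
        ct <= t < ct + pd.Timedelta(seconds=tick_s) for ct in schedule.times_on(t)
    )
    if not scheduled:
        return [], None
    frontal = bool(camera_health.get("frontal", True))
    upper = bool(camera_health.get("upper", True))
    captures = [name for name, ok in (("frontal", frontal), ("upper", upper)) if ok]
    if frontal and upper:
        return captures, 3
    if frontal:  # upper flawed
        return captures, 2
    if upper:  # frontal flawed
        return captures, 1
    return captures, 0


@dataclass(frozen=True)
class HealthRegister:
    """One byte of per-sensor read-success flags; bit k is sensor k of
    the environmental channel (0 = Ta_htu ... 7 = L_res)."""

    value: int
    bits: tuple[bool, ...]

    def __post_init__(self) -> None:
        if not (0 <= self.value <= 255):
            raise ValueError(f"register value out of [0, 255]: {self.value}")
        if len(self.bits) != 8:
            raise ValueError("register needs exactly 8 bits")


def encode_health(flags: Sequence[bool]) -> HealthRegister:
    """Fold eight per-sensor success flags into the 0–255 register
    (bit k = flag k, LSB first)."""
    if len(flags) != 8:
        raise ValueError("exactly 8 sensor flags required")
    value = sum(1 << k for k, ok in enumerate(flags) if ok)
    return HealthRegister(value=value, bits=tuple(bool(f) for f in flags))


def decode_health(value: int) -> tuple[bool, ...]:
    if not (0 <= value <= 255):
        raise ValueError(f"register value out of [0, 255]: {value}")
    return tuple(bool(value >> k & 1) for k in range(8))


def sensor_service_poll(
    climate: ClimateSample,
    tank: TankSample,
    sensor_health: Sequence[bool],
) -> tuple[ChannelWrite, HealthRegister]:
    """Pack one polling cycle into a single environmental-channel write.

    The eight fields follow the environmental channel ordering (the
    ambient temperature is read by two independent thermometers). A
    failed sensor contributes a missing value (None, serialized as an
    empty CSV cell / JSON null — never 0) and a 0 bit in the register.
    """
    if len(sensor_health) != 8:
        raise ValueError("exactly 8 sensor-health flags required")
    readings = {
        "Ta_htu": climate.Ta,
        "Ta_mlx": climate.Ta,
        "Tc": climate.Tc,
        "RHa": climate.RHa,
        "RHc": climate.RHc,
        "Lum": climate.Lum,
        "T_res": tank.T_res,
        "L_res": tank.L_res,
    }
    values = {
        f: (readings[f] if ok else None)
        for f, ok in zip(ENV_FIELDS, sensor_health)
    }
    register = encode_health(list(sensor_health))
    return ChannelWrite(channel=ENVIRONMENTAL, t=climate.t, values=values), register


@dataclass(frozen=True)
class FailureReport:
    service_failures: tuple[tuple[str, tuple[pd.Timestamp, pd.Timestamp]], ...] = ()
    sensor_failures: tuple[tuple[int, float], ...] = ()
    camera_failures: tuple[tuple[str, tuple[pd.Timestamp, pd.Timestamp]], ...] = ()

    @property
    def empty(self) -> bool:
        return not (self.service_failures or self.sensor_failures or self.camera_failures)


@dataclass(frozen=True)
class Expectations:
    """Expected cadence per service over an analysis window."""

    window: tuple[pd.Timestamp, pd.Timestamp]
    periods_s: dict[str, float] = field(default_factory=dict)
    camera_schedule: Optional[CameraSchedule] = None


PulseSeries = dict[str, list[tuple[pd.Timestamp, float]]]


def _gap_failures(
    times: list[pd.Timestamp],
    window: tuple[pd.Timestamp, pd.Timestamp],
    max_gap_s: float,
) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    lo, hi = window
    edges = [lo] + sorted(times) + [hi]
    return [
        (a, b)
        for a, b in zip(edges, edges[1:])
        if (b - a).total_seconds() > max_gap_s
    ]


def detect_failures(
    pulse_series: PulseSeries,
    register_series: Sequence[tuple[pd.Timestamp, int]],
    expectations: Expectations,
    miss_factor: float = 2.0,
    theta: float = 0.5,
    stagnation_min: int = 2,
) -> FailureReport:
    """Recover fault windows from the recorded pulses and registers.

    A service fails over any gap between consecutive pulses (or a window
    edge) longer than ``miss_factor`` times its expected period. Sensor
    k is flagged when its health bit is 0 in at least ``theta`` of the
    register samples. A camera flaw is reported when the camera status
    stagnates at 2 (upper) or 1 (frontal) for ``stagnation_min``
    consecutive scheduled captures.
    """
    service_failures: list[tuple[str, tuple[pd.Timestamp, pd.Timestamp]]] = []
    camera_failures: list[tuple[str, tuple[pd.Timestamp, pd.Timestamp]]] = []

    for service, pulses in pulse_series.items():
        if service == "camera":
            if expectations.camera_schedule is None:
                raise ValueError("camera pulses present but no camera schedule expected")
            sched = expectations.camera_schedule
            lo, hi = expectations.window
            expected: list[pd.Timestamp] = []
            day = lo.normalize()
            while day < hi:
                expected.extend(t for t in sched.times_on(day) if lo <= t < hi)
                day += pd.Timedelta(days=1)
            gaps = [e - s for s, e in zip(expected, expected[1:])]
            slack = min(gaps).total_seconds() / 2 if gaps else 1800.0
            pulse_times = [t for t, v in pulses if v > 0]
            missed = [
                e
                for e in expected
                if not any(abs((t - e).total_seconds()) <= slack for t in pulse_times)
            ]
            # runs of >= miss_factor consecutive missed captures
            run: list[pd.Timestamp] = []
            for e in expected:
                if e in missed:
                    run.append(e)
                else:
                    if len(run) >= miss_factor:
                        service_failures.append(("camera", (run[0], run[-1])))
                    run = []
            if len(run) >= miss_factor:
                service_failures.append(("camera", (run[0], run[-1])))
            # stagnation at a flaw code
            flaw_runs: dict[int, list[pd.Timestamp]] = {1: [], 2: []}
            for t, v in sorted(pulses):
                for code, cam in ((2, "upper"), (1, "frontal")):
                    if v == code:
                        flaw_runs[code].append(t)
                    else:
                        if len(flaw_runs[code]) >= stagnation_min:
                            camera_failures.append(
                                (cam, (flaw_runs[code][0], flaw_runs[code][-1]))
                            )
                        flaw_runs[code] = []
            for code, cam in ((2, "upper"), (1, "frontal")):
                if len(flaw_runs[code]) >= stagnation_min:
                    camera_failures.append(
                        (cam, (flaw_runs[code][0], flaw_runs[code][-1]))
                    )
        else:
            if service not in expectations.periods_s:
                raise ValueError(f"no expected cadence for service '{service}'")
            period = expectations.periods_s[service]
            times = [t for t, v in pulses if v > 0]
            for gap in _gap_failures(times, expectations.window, miss_factor * period):
                service_failures.append((service, gap))

    sensor_failures: list[tuple[int, float]] = []
    if register_series:
        n = len(register_series)
        for k in range(8):
            zeros = sum(1 for _, v in register_series if not (v >> k & 1))
            frac = zeros / n
            if frac >= theta:
                sensor_failures.append((k, frac))

    return FailureReport(
        service_failures=tuple(service_failures),
        sensor_failures=tuple(sensor_failures),
        camera_failures=tuple(camera_failures),
    )


@dataclass(frozen=True)
class AlertEvent:
    t: pd.Timestamp
    service: str
    message: str
    delivered_via: str

    def __post_init__(self) -> None:
        if self.service not in MICROSERVICES:
            raise ValueError(f"unknown microservice '{self.service}'")


class JsonlTransport:
    """Default alert sink: structured JSON-lines log."""

    name = "jsonl"

    def __init__(self, path: Union[str, Path]):
        self.path = Path(path)

    def send(self, event: AlertEvent) -> None:
        with open(self.path, "a") as fh:
            fh.write(
                json.dumps(
                    {
                        "t": pd.Timestamp(event.t).isoformat(),
                        "service": event.service,
                        "message": event.message,
                    }
                )
                + "\n"
            )


class _MemoryTransport:
    name = "memory"

    def __init__(self) -> None:
        self.sent: list[AlertEvent] = []

    def send(self, event: AlertEvent) -> None:
        self.sent.append(event)


class AlertService:
    """Turns failure reports into alert events, once per distinct failure.

    Repeated identical reports do not produce duplicate alerts. If the
    transport raises, the event is queued and retried on the next
    notification; the error is recorded in ``errors``.
    """

    def __init__(self, transport=None):
        self.transport = transport if transport is not None else _MemoryTransport()
        self._seen: set = set()
        self._pending: list[AlertEvent] = []
        self.errors: list[str] = []
        self.delivered: list[AlertEvent] = []

    def _failure_keys(self, report: FailureReport):
        for service, (a, b) in report.service_failures:
            yield ("service", service, a, b), service, f"{service} service: no pulses in [{a}, {b}]"
        for k, frac in report.sensor_failures:
            yield ("sensor", k), "sensor", f"sensor {k} bit stuck at 0 ({frac:.0%} of samples)"
        for cam, (a, b) in report.camera_failures:
            yield ("camera_flaw", cam, a, b), "camera", f"{cam} camera flaw between {a} and {b}"

    def notify(
        self, report: FailureReport, t: Optional[pd.Timestamp] = None
    ) -> list[AlertEvent]:
        """Emit one AlertEvent per newly seen failure; returns the new events."""
        t = pd.Timestamp(t) if t is not None else pd.Timestamp.now()
        via = getattr(self.transport, "name", "custom")
        new: list[AlertEvent] = []
        for key, service, message in self._failure_keys(report):
            if key in self._seen:
                continue
            self._seen.add(key)
            new.append(AlertEvent(t=t, service=service, message=message, delivered_via=via))
        for event in self._pending + new:
            try:
                self.transport.send(event)
                self.delivered.append(event)
                if event in self._pending:
                    self._pending.remove(event)
            except Exception as exc:  # queue and retry next time
                if event not in self._pending:
                    self._pending.append(event)
                self.errors.append(f"{event.service}: {exc}")
        return new
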