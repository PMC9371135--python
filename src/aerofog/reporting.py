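"""Report suite and end-to-end pipeline.

The application layer exposes twelve reports, each defined by the set
of monitored variables it displays (the deployment's variable→report
matrix): ambient and crop climate, crop-minus-air temperature
difference, luminosity, solution and reservoir state, camera
inspection, VPD, nutrient-solution and crop parameters, and two
request-accounting views. Reports are emitted as CSV tables; plots are
optional renderings, never the data of record.

``run_pipeline`` wires the whole stack together: device-layer
simulation → fog services → channel store → stress analytics → failure
detection/alerts → root-image enhancement → the report suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import channel_store as cs
from . import climate_sim, fog_services, root_imaging, stress_analytics
from .channel_store import ChannelStore, ChannelWrite, QuotaPolicy, WriteResult
from .climate_sim import FaultPlan, SimConfig
from .types import ENV_FIELDS

__all__ = [
    "REPORT_KINDS",
    "TABLE_VARIABLES",
    "ReportSpec",
    "Report",
    "ManualRecord",
    "generate_report",
    "record_manual",
    "run_pipeline",
]

# Variable -> report matrix of the deployment. The two request reports
# are counter views over all channels rather than variable columns.
TABLE_VARIABLES: dict[str, tuple[str, ...]] = {
    "ambient": ("T_a", "RH_a"),
    "crop": ("T_c", "RH_c"),
    "difference_temperature": ("T_a", "T_c"),
    "luminosity": ("Lum",),
    "solution": ("T_sol", "T_res"),
    "reservoir": ("L_res", "S_irr", "S_res"),
    "inspection": ("S_cam",),
    "vpd": ("T_a", "RH_c"),
    "solution_parameters": ("pH", "EC", "HNO_3", "A_sol", "B_sol"),
    "crop_parameters": ("Fw", "L_l", "W_l"),
}
REPORT_KINDS = tuple(TABLE_VARIABLES) + ("requests_per_hour", "requests_per_channel")

# where each monitored variable lives in the default deployment
_VARIABLE_SOURCE: dict[str, tuple[str, str]] = {
    "T_a": (cs.ENVIRONMENTAL, "Ta_htu"),
    "RH_a": (cs.ENVIRONMENTAL, "RHa"),
    "T_c": (cs.ENVIRONMENTAL, "Tc"),
    "RH_c": (cs.ENVIRONMENTAL, "RHc"),
    "Lum": (cs.ENVIRONMENTAL, "Lum"),
    "T_sol": (cs.SERVICES, "T_sol"),
    "L_sol": (cs.SERVICES, "L_sol"),
    "T_res": (cs.ENVIRONMENTAL, "T_res"),
    "L_res": (cs.ENVIRONMENTAL, "L_res"),
    "S_irr": (cs.SERVICES, "S_irr"),
    "S_res": (cs.SERVICES, "S_res"),
    "S_cam": (cs.SERVICES, "S_cam"),
    "pH": (cs.MANUAL, "pH"),
    "EC": (cs.MANUAL, "EC"),
    "Fw": (cs.MANUAL, "Fw"),
    "L_l": (cs.MANUAL, "L_l"),
    "W_l": (cs.MANUAL, "W_l"),
    "HNO_3": (cs.CONTROL, "HNO3"),
    "A_sol": (cs.CONTROL, "A_sol"),
    "B_sol": (cs.CONTROL, "B_sol"),
}


@dataclass(frozen=True)
class ReportSpec:
    """Which report to build and over which window (default: the last
    three days of stored data)."""

    kind: str
    window: Optional[tuple[pd.Timestamp, pd.Timestamp]] = None

    def __post_init__(self) -> None:
        if self.kind not in REPORT_KINDS:
            raise ValueError(
                f"unknown report kind '{self.kind}'; expected one of {REPORT_KINDS}"
            )


@dataclass(frozen=True)
class Report:
    kind: str
    table: pd.DataFrame
    missing: tuple[str, ...] = ()


def _latest_timestamp(store: ChannelStore) -> Optional[pd.Timestamp]:
    stamps = [
        store.frame(name)["timestamp"].max()
        for name in store.channel_names
        if store.accepted_count(name)
    ]
    stamps = [t for t in stamps if pd.notna(t)]
    return max(stamps) if stamps else None


def _resolve_window(
    spec: ReportSpec, store: ChannelStore
) -> Optional[tuple[pd.Timestamp, pd.Timestamp]]:
    if spec.window is not None:
        return (pd.Timestamp(spec.window[0]), pd.Timestamp(spec.window[1]))
    latest = _latest_timestamp(store)
    if latest is None:
        return None
    return (latest - pd.Timedelta(days=3), latest + pd.Timedelta(seconds=1))


def generate_report(
    spec: ReportSpec,
    store: ChannelStore,
    plot_path: Optional[Union[str, Path]] = None,
) -> Report:
    """Assemble one report table from the channel store.

    Variable reports carry exactly the variables of the deployment
    matrix for that kind (the VPD report additionally includes the
    computed VPD series; the temperature-difference report adds DT_la
    and its stress class). A variable with no stored data appears as an
    entry in ``missing`` and an all-NaN column, never a silent omission.
    """
    window = _resolve_window(spec, store)

    if spec.kind == "requests_per_hour":
        per_hour, _ = store.request_counters(window)
        table = pd.DataFrame(
            {"hour": list(per_hour), "requests": list(per_hour.values())}
        ).sort_values("hour", ignore_index=True)
        return Report(kind=spec.kind, table=table)
    if spec.kind == "requests_per_channel":
        _, per_channel = store.request_counters(window)
        table = pd.DataFrame(
            {"channel": list(per_channel), "requests": list(per_channel.values())}
        )
        return Report(kind=spec.kind, table=table)

    variables = TABLE_VARIABLES[spec.kind]
    columns: dict[str, pd.Series] = {}
    missing: list[str] = []
    for var in variables:
        channel, fld = _VARIABLE_SOURCE[var]
        frame = store.frame(channel, window)
        series = pd.Series(
            frame[fld].to_numpy(dtype=float) if len(frame) else [],
            index=pd.DatetimeIndex(frame["timestamp"] if len(frame) else []),
            name=var,
        )
        if series.dropna().empty:
            missing.append(var)
        columns[var] = series

    table = pd.concat(columns.values(), axis=1) if columns else pd.DataFrame()
    table.index.name = "timestamp"
    table = table.reset_index()

    if spec.kind == "vpd":
        env = store.frame(cs.ENVIRONMENTAL, window)
        if len(env):
            vpd = stress_analytics.vpd_kpa(
                env["Tc"].to_numpy(dtype=float),
                env["Ta_htu"].to_numpy(dtype=float),
                np.clip(env["RHa"].to_numpy(dtype=float), 0.0, 100.0),
            )
            vpd_series = pd.Series(vpd, index=pd.DatetimeIndex(env["timestamp"]))
            table = table.set_index("timestamp")
            table["VPD"] = vpd_series
            table = table.reset_index()
        else:
            table["VPD"] = pd.Series(dtype=float)
            missing.append("VPD")
    elif spec.kind == "difference_temperature":
        dt = table["T_c"] - table["T_a"]
        table["DT_la"] = dt
        table["stress_dtla"] = [
            stress_analytics.classify_dtla(d).value if pd.notna(d) else "missing"
            for d in dt
        ]

    if plot_path is not None:
        _render_plot(spec.kind, table, plot_path)
    return Report(kind=spec.kind, table=table, missing=tuple(missing))


def _render_plot(kind: str, table: pd.DataFrame, path: Union[str, Path]) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    numeric = table.select_dtypes("number")
    x = table["timestamp"] if "timestamp" in table else numeric.index
    for col in numeric.columns:
        ax.plot(x, numeric[col], label=col, lw=0.8)
    ax.set_title(kind)
    if len(numeric.columns):
        ax.legend(loc="best", fontsize=8)
    fig.autofmt_xdate()
    fig.savefig(path, dpi=100)
    plt.close(fig)


class ManualRecord(BaseModel):
    """A manual measurement round: crop and solution readings plus any
    readjustment dosing (mL of stock per liter of solution)."""

    t: pd.Timestamp
    Ta: Optional[float] = None
    RHa: Optional[float] = Field(default=None, ge=0.0, le=100.0)
    Tc: Optional[float] = None
    pH: Optional[float] = Field(default=None, gt=0.0, lt=14.0)
    EC: Optional[float] = Field(default=None, ge=0.0)
    Fw: Optional[float] = Field(default=None, ge=0.0)
    L_l: Optional[float] = Field(default=None, ge=0.0)
    W_l: Optional[float] = Field(default=None, ge=0.0)
    HNO3: Optional[float] = Field(default=None, ge=0.0)
    A_sol: Optional[float] = Field(default=None, ge=0.0)
    B_sol: Optional[float] = Field(default=None, ge=0.0)

    model_config = {"arbitrary_types_allowed": True}


def record_manual(
    rec: ManualRecord,
    store: ChannelStore,
    policy: QuotaPolicy = QuotaPolicy(),
) -> WriteResult:
    """Append a manual record to the manual-measurements channel (and
    any readjust dosing to the control channel), subject to the store's
    quota policy."""
    manual_values = {
        "Ta_man": rec.Ta,
        "RHa_man": rec.RHa,
        "Tc_man": rec.Tc,
        "pH": rec.pH,
        "EC": rec.EC,
        "Fw": rec.Fw,
        "L_l": rec.L_l,
        "W_l": rec.W_l,
    }
    result = store.write(
        ChannelWrite(channel=cs.MANUAL, t=rec.t, values=manual_values), policy
    )
    dosing = {"HNO3": rec.HNO3, "A_sol": rec.A_sol, "B_sol": rec.B_sol}
    if result.accepted and any(v is not None for v in dosing.values()):
        store.write(ChannelWrite(channel=cs.CONTROL, t=rec.t, values=dosing), policy)
    return result


def run_pipeline(
    config: SimConfig,
    days: int = 1,
    seed: Optional[int] = None,
    out_dir: Union[str, Path] = "aerofog_run",
    faults: Optional[FaultPlan] = None,
) -> Path:
    """Simulate ``days`` of greenhouse operation end to end and write
    all artifacts (telemetry CSVs, channel exports, stress markers,
    failure report, alert log, enhanced root images, the twelve
    reports) under ``out_dir``. Deterministic for a given seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    updates: dict = {"t_end": config.t_start + pd.Timedelta(days=days)}
    if seed is not None:
        updates["seed"] = int(seed)
    cfg = config.model_copy(update=updates)
    faults = faults or FaultPlan()

    climate, tanks, actuators = climate_sim.simulate_full(cfg, faults)
    climate_sim.climate_to_frame(climate).to_csv(out / "climate.csv", index=False)
    climate_sim.tanks_to_frame(tanks).to_csv(out / "tanks.csv", index=False)

    store = cs.default_deployment()
    policy = QuotaPolicy()
    registers: list[tuple[pd.Timestamp, int]] = []
    for sample, tank, act in zip(climate, tanks, actuators):
        sensor_ok = faults.sensor_flags(sample.t)
        if faults.service_ok("sensor", sample.t):
            w, register = fog_services.sensor_service_poll(sample, tank, sensor_ok)
            store.write(w, policy)
            registers.append((sample.t, register.value))
            reg_value: Optional[float] = float(register.value)
        else:
            reg_value = None
        store.write(
            ChannelWrite(
                channel=cs.SERVICES,
                t=sample.t,
                values={
                    "T_sol": tank.T_sol,
                    "L_sol": tank.L_sol,
                    "S_irr": float(act.S_irr),
                    "S_res": float(act.S_res),
                    "S_mix": float(act.S_mix),
                    "S_cam": float(act.S_cam),
                    "health_register": reg_value,
                },
            ),
            policy,
        )

    # stress analytics over the recorded environmental channel
    env = store.frame(cs.ENVIRONMENTAL)
    env_named = env.rename(columns={"Ta_htu": "Ta"})
    stress = stress_analytics.annotate_frame(
        env_named[["timestamp", "Ta", "Tc", "RHa", "RHc"]].dropna()
    )
    stress.to_csv(out / "stress_markers.csv", index=False)

    # failure detection from the services channel pulses
    svc = store.frame(cs.SERVICES)
    tstamps = pd.DatetimeIndex(svc["timestamp"])
    pulse_series: fog_services.PulseSeries = {
        "irrigation": [
            (t, v) for t, v in zip(tstamps, svc["S_irr"]) if v and v > 0
        ],
        "sensor": [
            (t, 1.0) for t, v in zip(tstamps, svc["health_register"]) if pd.notna(v)
        ],
        "camera": [(t, float(v)) for t, v in zip(tstamps, svc["S_cam"]) if v and v > 0],
    }
    expectations = fog_services.Expectations(
        window=(pd.Timestamp(cfg.t_start), pd.Timestamp(cfg.t_end)),
        periods_s={
            "irrigation": cfg.irrigation_period_min * 60.0,
            "sensor": float(cfg.step_s),
        },
        camera_schedule=fog_services.CameraSchedule(tuple(cfg.camera_times)),
    )
    report = fog_services.detect_failures(pulse_series, registers, expectations)
    with open(out / "failure_report.json", "w") as fh:
        json.dump(
            {
                "service_failures": [
                    [s, [str(a), str(b)]] for s, (a, b) in report.service_failures
                ],
                "sensor_failures": [[k, f] for k, f in report.sensor_failures],
                "camera_failures": [
                    [c, [str(a), str(b)]] for c, (a, b) in report.camera_failures
                ],
            },
            fh,
            indent=2,
        )
    alerts = fog_services.AlertService(
        transport=fog_services.JsonlTransport(out / "alerts.jsonl")
    )
    (out / "alerts.jsonl").write_text("")
    alerts.notify(report, t=pd.Timestamp(cfg.t_end))

    # synthetic root inspection image and its enhancement
    truth = climate_sim.synth_root_image(256, 256, 0.15, seed=cfg.seed)
    result = root_imaging.enhance_root(truth.image)
    _save_png(truth.image, out / "root_rgb.png")
    _save_png(
        (truth.truth_mask * 255).astype(np.uint8), out / "root_truth_mask.png"
    )
    _save_png((result.root_mask * 255).astype(np.uint8), out / "root_mask.png")
    _save_png(result.rgb_enhanced, out / "root_rgb_enhanced.png")
    _save_png(result.hsv_enhanced_rgb, out / "root_hsv_enhanced.png")

    for name in store.channel_names:
        store.export_csv(name, out / f"channel_{name}.csv")

    reports_dir = out / "reports"
    reports_dir.mkdir(exist_ok=True)
    for kind in REPORT_KINDS:
        rep = generate_report(ReportSpec(kind=kind), store)
        rep.table.to_csv(reports_dir / f"{kind}.csv", index=False)

    svc_frame = store.frame(cs.SERVICES)
    cam = svc_frame["S_cam"].fillna(0)
    summary = {
        "environmental_writes": store.accepted_count(cs.ENVIRONMENTAL),
        "total_writes": store.accepted_count(),
        "captures_frontal": int(((cam == 3) | (cam == 2)).sum()),
        "captures_upper": int(((cam == 3) | (cam == 1)).sum()),
        "root_mask_dice": root_imaging.dice_score(result.root_mask, truth.truth_mask),
        "failures_detected": not report.empty,
    }
    for var in ("Ta", "RHa", "Tc", "RHc", "Lum"):
        series = pd.Series(
            env_named[var].to_numpy(dtype=float),
            index=pd.DatetimeIndex(env_named["timestamp"]),
        ).dropna()
        if series.empty:  # sensor dead for the whole window
            summary[var] = None
            continue
        s = stress_analytics.summarize(series, variable=var)
        summary[var] = {
            "min": s.minimum, "max": s.maximum, "mean": s.mean, "std": s.std,
            "time_max": str(s.time_of_max.time()), "time_min": str(s.time_of_min.time()),
        }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return out


def _save_png(array: np.ndarray, path: Union[str, Path]) -> None:
    from PIL import Image

    Image.fromarray(array).save(path)
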