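"""Fog-layer services: schedulers, hysteresis, health register, failure detection."""

from datetime import date, time

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from aerofog.channel_store import ENVIRONMENTAL
from aerofog.fog_services import (
    AlertService,
    CameraSchedule,
    Expectations,
    FailureReport,
    IrrigationConfig,
    IrrigationWindow,
    camera_service,
    decode_health,
    detect_failures,
    encode_health,
    plan_irrigation,
    reservoir_service,
    sensor_service_poll,
)
from aerofog.types import ClimateSample, TankSample

DAY = date(2021, 11, 1)


class TestIrrigationPlanning:
    def test_paper_cadence_gives_60_activations(self):
        events = plan_irrigation(IrrigationConfig(frequency_min=24, on_time_s=30), DAY)
        assert len(events) == 60
        assert events[0][0] == pd.Timestamp("2021-11-01 00:00:00")
        assert (events[0][1] - events[0][0]).total_seconds() == 30

    def test_daily_frequency_gives_single_activation(self):
        events = plan_irrigation(IrrigationConfig(frequency_min=1440, on_time_s=30), DAY)
        assert len(events) == 1

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(freq=st.integers(min_value=10, max_value=720))
    def test_count_matches_minute_by_minute_oracle(self, freq):
        events = plan_irrigation(IrrigationConfig(frequency_min=freq, on_time_s=30), DAY)
        # brute-force: walk every minute of the day, fire on schedule
        expected = sum(1 for minute in range(1440) if minute % freq == 0)
        assert len(events) == expected

    def test_day_night_overrides(self):
        cfg = IrrigationConfig(
            day_window=IrrigationWindow(time(6, 0), time(18, 0), 24, 30),
            night_window=IrrigationWindow(time(18, 0), time(6, 0), 60, 20),
        )
        events = plan_irrigation(cfg, DAY)
        day_events = [e for e in events if time(6) <= e[0].time() < time(18)]
        night_events = [e for e in events if not (time(6) <= e[0].time() < time(18))]
        assert len(day_events) == 30  # 12 h / 24 min
        assert len(night_events) == 12  # 6 h + 6 h at hourly cadence
        assert all((off - on).total_seconds() == 20 for on, off in night_events)

    def test_overlapping_config_rejected(self):
        with pytest.raises(ValueError):
            IrrigationConfig(frequency_min=1, on_time_s=60)


class TestReservoirService:
    def test_threshold_is_strict_at_16(self):
        assert reservoir_service(15.9, pump_on=False) is False
        assert reservoir_service(16.0, pump_on=False) is False
        assert reservoir_service(16.1, pump_on=False) is True

    def test_hysteresis_keeps_pump_running(self):
        assert reservoir_service(10.0, pump_on=True) is True
        assert reservoir_service(0.4, pump_on=True) is False

    def test_negative_level_rejected(self):
        with pytest.raises(ValueError):
            reservoir_service(-1.0, pump_on=False)


class TestCameraService:
    schedule = CameraSchedule()

    def test_paper_schedule_has_nine_times(self):
        assert len(self.schedule.capture_times) == 9

    def test_status_codes(self):
        t = pd.Timestamp("2021-11-01 06:00:00")
        captures, status = camera_service(self.schedule, t)
        assert status == 3 and set(captures) == {"frontal", "upper"}
        _, status = camera_service(self.schedule, t, {"frontal": True, "upper": False})
        assert status == 2
        _, status = camera_service(self.schedule, t, {"frontal": False, "upper": True})
        assert status == 1
        captures, status = camera_service(self.schedule, t, {"frontal": False, "upper": False})
        assert status == 0 and captures == []

    def test_off_schedule_emits_no_pulse(self):
        captures, status = camera_service(self.schedule, pd.Timestamp("2021-11-01 06:05:00"))
        assert captures == [] and status is None

    def test_unordered_schedule_rejected(self):
        with pytest.raises(ValueError):
            CameraSchedule((time(7), time(6)))


class TestHealthRegister:
    def test_all_success_is_255_all_fail_is_0(self):
        assert encode_health([True] * 8).value == 255
        assert encode_health([False] * 8).value == 0

    def test_single_sensor_powers_of_two(self):
        for k in range(8):
            flags = [i == k for i in range(8)]
            assert encode_health(flags).value == 2**k

    def test_bijection_over_all_256_values(self):
        seen = set()
        for value in range(256):
            flags = decode_health(value)
            assert encode_health(flags).value == value
            seen.add(flags)
        assert len(seen) == 256

    def test_range_checks(self):
        with pytest.raises(ValueError):
            decode_health(256)
        with pytest.raises(ValueError):
            encode_health([True] * 7)


def _sample(t="2021-11-01 08:00:00"):
    climate = ClimateSample(
        t=pd.Timestamp(t), Ta=20.0, RHa=50.0, Tc=18.5, RHc=55.0, Lum=3000.0
    )
    tank = TankSample(
        t=pd.Timestamp(t), T_sol=18.0, L_sol=45.0, T_res=17.5, L_res=3.2
    )
    return climate, tank


def test_sensor_poll_packs_eight_fields_and_register():
    climate, tank = _sample()
    write, register = sensor_service_poll(climate, tank, [True] * 8)
    assert write.channel == ENVIRONMENTAL
    assert len(write.values) == 8
    assert register.value == 255
    assert write.values["L_res"] == 3.2
    # failed sensors yield missing values (never zero) and a zero bit
    flags = [True, True, False, True, True, True, True, False]
    write, register = sensor_service_poll(climate, tank, flags)
    assert write.values["Tc"] is None and write.values["L_res"] is None
    assert register.value == 255 - 2**2 - 2**7


WINDOW = (pd.Timestamp("2021-11-01"), pd.Timestamp("2021-11-02"))


def _healthy_pulses():
    irr = [
        (t, 1.0)
        for t in pd.date_range(WINDOW[0], WINDOW[1], freq="24min", inclusive="left")
    ]
    sensor = [
        (t, 1.0)
        for t in pd.date_range(WINDOW[0], WINDOW[1], freq="30s", inclusive="left")
    ]
    cam = [(t, 3.0) for t in CameraSchedule().times_on(WINDOW[0])]
    return {"irrigation": irr, "sensor": sensor, "camera": cam}


def _expectations():
    return Expectations(
        window=WINDOW,
        periods_s={"irrigation": 24 * 60.0, "sensor": 30.0},
        camera_schedule=CameraSchedule(),
    )


class TestDetectFailures:
    def test_healthy_day_yields_empty_report(self):
        registers = [(t, 255) for t, _ in _healthy_pulses()["sensor"]]
        report = detect_failures(_healthy_pulses(), registers, _expectations())
        assert report.empty

    def test_stuck_sensor_bit_recovered_exactly(self):
        registers = [(t, 255 - 2**3) for t, _ in _healthy_pulses()["sensor"]]
        report = detect_failures(_healthy_pulses(), registers, _expectations())
        assert report.sensor_failures == ((3, 1.0),)
        assert not report.service_failures and not report.camera_failures

    def test_missing_irrigation_pulses_flagged(self):
        pulses = _healthy_pulses()
        gap_start = pd.Timestamp("2021-11-01 10:00")
        gap_end = pd.Timestamp("2021-11-01 12:00")  # 3 missing periods
        pulses["irrigation"] = [
            (t, v) for t, v in pulses["irrigation"] if not (gap_start <= t < gap_end)
        ]
        registers = [(t, 255) for t, _ in pulses["sensor"]]
        report = detect_failures(pulses, registers, _expectations())
        services = [s for s, _ in report.service_failures]
        assert services == ["irrigation"]
        (start, end) = report.service_failures[0][1]
        assert start <= gap_start and end >= gap_end - pd.Timedelta(minutes=24)

    def test_camera_flaw_stagnation(self):
        pulses = _healthy_pulses()
        pulses["camera"] = [
            (t, 2.0 if i >= 5 else 3.0) for i, (t, _) in enumerate(pulses["camera"])
        ]
        registers = [(t, 255) for t, _ in pulses["sensor"]]
        report = detect_failures(pulses, registers, _expectations())
        assert [c for c, _ in report.camera_failures] == ["upper"]
        assert not report.service_failures

    def test_injected_faults_recall_and_precision(self):
        """Every injected fault is recovered and nothing else is flagged."""
        pulses = _healthy_pulses()
        # camera service outage: drop the three midday captures
        pulses["camera"] = [
            (t, v) for t, v in pulses["camera"] if not (11 <= t.hour <= 13)
        ]
        # sensor 6 dead for 60% of the day
        registers = [
            (t, 255 - 2**6 if i < 0.6 * 2880 else 255)
            for i, (t, _) in enumerate(pulses["sensor"])
        ]
        report = detect_failures(pulses, registers, _expectations())
        assert [s for s, _ in report.service_failures] == ["camera"]
        assert [k for k, _ in report.sensor_failures] == [6]
        assert report.sensor_failures[0][1] == pytest.approx(0.6, abs=1e-3)
        assert not report.camera_failures

    def test_missing_expectation_is_an_error(self):
        with pytest.raises(ValueError):
            detect_failures(
                {"irrigation": []}, [], Expectations(window=WINDOW, periods_s={})
            )


class TestAlertService:
    def report(self):
        return FailureReport(
            service_failures=(("irrigation", (WINDOW[0], WINDOW[1])),),
            sensor_failures=((3, 1.0),),
        )

    def test_one_event_per_new_failure(self):
        svc = AlertService()
        events = svc.notify(self.report(), t=WINDOW[1])
        assert len(events) == 2
        assert {e.service for e in events} == {"irrigation", "sensor"}

    def test_idempotent_across_repeated_reports(self):
        svc = AlertService()
        svc.notify(self.report(), t=WINDOW[1])
        again = svc.notify(self.report(), t=WINDOW[1])
        assert again == []
        assert len(svc.delivered) == 2

    def test_empty_report_no_events(self):
        svc = AlertService()
        assert svc.notify(FailureReport(), t=WINDOW[1]) == []

    def test_transport_failure_queues_and_retries(self):
        class Flaky:
            name = "flaky"

            def __init__(self):
                self.calls = 0
                self.sent = []

            def send(self, event):
                self.calls += 1
                if self.calls == 1:
                    raise ConnectionError("down")
                self.sent.append(event)

        transport = Flaky()
        svc = AlertService(transport=transport)
        svc.notify(
            FailureReport(sensor_failures=((1, 1.0),)), t=WINDOW[1]
        )
        assert svc.errors and not transport.sent
        svc.notify(FailureReport(), t=WINDOW[1])  # retry happens here
        assert len(transport.sent) == 1
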