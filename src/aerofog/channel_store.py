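"""Local emulation of the cloud-layer time-series channels.

Mirrors the free-tier contract of the hosted service the deployment
used: at most four channels of up to eight numeric fields each, a
minimum update interval of 15 s per channel, and a pooled daily quota
of 8200 accepted messages across all channels (day boundary at local
midnight). Rejected writes are logged and never partially applied.

Storage is an in-memory index with an optional append-only JSON-lines
file per channel (one object per accepted write:
``{"t": "<ISO-8601>", "values": {field: number-or-null}}``).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .types import ENV_FIELDS

__all__ = [
    "MAX_FIELDS",
    "ChannelSchema",
    "ChannelWrite",
    "QuotaPolicy",
    "WriteResult",
    "ChannelStore",
    "SchemaError",
    "ConflictError",
    "NotFoundError",
    "CsvParseError",
    "default_deployment",
    "used_field_count",
    "ENVIRONMENTAL",
    "SERVICES",
    "MANUAL",
    "CONTROL",
]

MAX_FIELDS = 8

ENVIRONMENTAL = "environmental"
SERVICES = "services"
MANUAL = "manual"
CONTROL = "control"


class SchemaError(ValueError):
    pass


class ConflictError(ValueError):
    pass


class NotFoundError(KeyError):
    pass


class CsvParseError(ValueError):
    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass(frozen=True)
class ChannelSchema:
    """A named channel with an ordered list of 1–8 unique field names."""

    name: str
    fields: tuple[str, ...]

    def __post_init__(self) -> None:
        if not (1 <= len(self.fields) <= MAX_FIELDS):
            raise SchemaError(
                f"channel '{self.name}' must declare 1-{MAX_FIELDS} fields, "
                f"got {len(self.fields)}"
            )
        if len(set(self.fields)) != len(self.fields):
            raise SchemaError(f"channel '{self.name}' has duplicate field names")


@dataclass(frozen=True)
class ChannelWrite:
    """One timestamped row: per-field numbers; missing values allowed
    (serialized as null / empty cell, never as 0)."""

    channel: str
    t: pd.Timestamp
    values: dict[str, Optional[float]]


@dataclass(frozen=True)
class QuotaPolicy:
    min_interval_s: float = 15.0
    daily_quota: int = 8200

    def __post_init__(self) -> None:
        if self.min_interval_s <= 0:
            raise ValueError("min_interval_s must be positive")
        if self.daily_quota <= 0:
            raise ValueError("daily_quota must be positive")


@dataclass(frozen=True)
class WriteResult:
    accepted: bool
    reason: Optional[str] = None  # "rate" | "quota" when rejected


@dataclass
class _Channel:
    schema: ChannelSchema
    rows: list[tuple[pd.Timestamp, dict[str, Optional[float]]]] = field(default_factory=list)
    last_accepted: Optional[pd.Timestamp] = None


class ChannelStore:
    """Registry of channels with rate-limit and pooled-quota accounting."""

    def __init__(self, persist_dir: Optional[Union[str, Path]] = None):
        self._channels: dict[str, _Channel] = {}
        self._accepted_per_day: dict = {}
        self._rejections: list[tuple[str, pd.Timestamp, str]] = []
        self._persist_dir = Path(persist_dir) if persist_dir is not None else None
        if self._persist_dir is not None:
            self._persist_dir.mkdir(parents=True, exist_ok=True)

    # -- registry ----------------------------------------------------

    def create_channel(self, schema: ChannelSchema) -> str:
        if schema.name in self._channels:
            raise ConflictError(f"channel '{schema.name}' already exists")
        self._channels[schema.name] = _Channel(schema=schema)
        return schema.name

    @property
    def channel_names(self) -> list[str]:
        return list(self._channels)

    def schema(self, channel: str) -> ChannelSchema:
        return self._get(channel).schema

    @property
    def field_slots(self) -> int:
        """Total field slots across channels (8 per channel)."""
        return MAX_FIELDS * len(self._channels)

    def _get(self, channel: str) -> _Channel:
        try:
            return self._channels[channel]
        except KeyError:
            raise NotFoundError(f"unknown channel '{channel}'") from None

    # -- writes ------------------------------------------------------

    def write(self, w: ChannelWrite, policy: QuotaPolicy = QuotaPolicy()) -> WriteResult:
        ch = self._get(w.channel)
        unknown = set(w.values) - set(ch.schema.fields)
        if unknown:
            raise SchemaError(
                f"values for unknown fields on '{w.channel}': {sorted(unknown)}"
            )
        t = pd.Timestamp(w.t)
        if ch.last_accepted is not None and (
            (t - ch.last_accepted).total_seconds() < policy.min_interval_s
        ):
            self._rejections.append((w.channel, t, "rate"))
            return WriteResult(False, "rate")
        day = t.date()
        if self._accepted_per_day.get(day, 0) >= policy.daily_quota:
            self._rejections.append((w.channel, t, "quota"))
            return WriteResult(False, "quota")
        values = {f: (None if w.values.get(f) is None else float(w.values[f]))
                  for f in ch.schema.fields if f in w.values}
        ch.rows.append((t, values))
        ch.last_accepted = t
        self._accepted_per_day[day] = self._accepted_per_day.get(day, 0) + 1
        if self._persist_dir is not None:
            line = json.dumps({"t": t.isoformat(), "values": values})
            with open(self._persist_dir / f"{w.channel}.jsonl", "a") as fh:
                fh.write(line + "\n")
        return WriteResult(True)

    @property
    def rejections(self) -> list[tuple[str, pd.Timestamp, str]]:
        return list(self._rejections)

    def accepted_count(self, channel: Optional[str] = None) -> int:
        if channel is not None:
            return len(self._get(channel).rows)
        return sum(len(ch.rows) for ch in self._channels.values())

    # -- queries -----------------------------------------------------

    def frame(
        self,
        channel: str,
        window: Optional[tuple[pd.Timestamp, pd.Timestamp]] = None,
    ) -> pd.DataFrame:
        """Accepted writes as a DataFrame with a ``timestamp`` column and
        one column per schema field (NaN for missing)."""
        ch = self._get(channel)
        rows = ch.rows
        if window is not None:
            lo, hi = pd.Timestamp(window[0]), pd.Timestamp(window[1])
            rows = [(t, v) for t, v in rows if lo <= t < hi]
        data = {"timestamp": [t for t, _ in rows]}
        for f in ch.schema.fields:
            data[f] = [v.get(f, None) for _, v in rows]
        df = pd.DataFrame(data)
        if df.empty:
            df = pd.DataFrame(columns=["timestamp", *ch.schema.fields])
        return df

    def request_counters(
        self,
        window: Optional[tuple[pd.Timestamp, pd.Timestamp]] = None,
    ) -> tuple[dict[pd.Timestamp, int], dict[str, int]]:
        """Accepted-write counts per clock hour and per channel.

        Both views sum to the total number of accepted writes in the
        window.
        """
        per_hour: dict[pd.Timestamp, int] = {}
        per_channel: dict[str, int] = {name: 0 for name in self._channels}
        for name, ch in self._channels.items():
            for t, _ in ch.rows:
                if window is not None and not (window[0] <= t < window[1]):
                    continue
                hour = t.floor("h")
                per_hour[hour] = per_hour.get(hour, 0) + 1
                per_channel[name] += 1
        return per_hour, per_channel

    # -- CSV round trip ----------------------------------------------

    def export_csv(
        self,
        channel: str,
        path: Union[str, Path],
        window: Optional[tuple[pd.Timestamp, pd.Timestamp]] = None,
    ) -> int:
        """Write a channel window to CSV (header row, ISO-8601 timestamps,
        shortest-round-trip decimal floats, empty cell for missing).
        Returns the number of rows written."""
        ch = self._get(channel)
        rows = ch.rows
        if window is not None:
            lo, hi = pd.Timestamp(window[0]), pd.Timestamp(window[1])
            rows = [(t, v) for t, v in rows if lo <= t < hi]
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["timestamp", *ch.schema.fields])
            for t, values in rows:
                writer.writerow(
                    [t.isoformat()]
                    + [
                        "" if values.get(f) is None else repr(values[f])
                        for f in ch.schema.fields
                    ]
                )
        return len(rows)

    def import_csv(self, channel: str, path: Union[str, Path]) -> int:
        """Append rows from a CSV produced by :meth:`export_csv`,
        bypassing rate/quota policy (bulk restore). Malformed cells
        raise :class:`CsvParseError` naming the offending line; nothing
        is applied on error."""
        ch = self._get(channel)
        staged: list[tuple[pd.Timestamp, dict[str, Optional[float]]]] = []
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            try:
                header = next(reader)
            except StopIteration:
                raise CsvParseError("empty file", 1) from None
            expected = ["timestamp", *ch.schema.fields]
            if header != expected:
                raise CsvParseError(f"header mismatch, expected {expected}", 1)
            for lineno, row in enumerate(reader, start=2):
                if len(row) != len(expected):
                    raise CsvParseError(
                        f"expected {len(expected)} cells, got {len(row)}", lineno
                    )
                try:
                    t = pd.Timestamp(row[0])
                except ValueError:
                    raise CsvParseError(f"bad timestamp {row[0]!r}", lineno) from None
                values: dict[str, Optional[float]] = {}
                for f, cell in zip(ch.schema.fields, row[1:]):
                    if cell == "":
                        values[f] = None
                        continue
                    try:
                        x = float(cell)
                    except ValueError:
                        raise CsvParseError(
                            f"non-numeric cell {cell!r} in field '{f}'", lineno
                        ) from None
                    if math.isnan(x):
                        values[f] = None
                    else:
                        values[f] = x
                staged.append((t, values))
        ch.rows.extend(staged)
        for t, _ in staged:
            day = t.date()
            self._accepted_per_day[day] = self._accepted_per_day.get(day, 0) + 1
        if staged:
            last = max(t for t, _ in staged)
            if ch.last_accepted is None or last > ch.last_accepted:
                ch.last_accepted = last
        return len(staged)


# Default four-channel deployment. Every channel declares its full
# eight slots; "reserved_*" names are the unused slots (27 of 32 used).
_SERVICES_FIELDS = (
    "T_sol", "L_sol", "S_irr", "S_res", "S_mix", "S_cam",
    "health_register", "reserved_s1",
)
_MANUAL_FIELDS = ("Ta_man", "RHa_man", "Tc_man", "pH", "EC", "Fw", "L_l", "W_l")
_CONTROL_FIELDS = (
    "command_word", "HNO3", "A_sol", "B_sol",
    "reserved_c1", "reserved_c2", "reserved_c3", "reserved_c4",
)


def default_deployment(persist_dir: Optional[Union[str, Path]] = None) -> ChannelStore:
    """The four channels of the reference deployment: environmental
    telemetry, service status, manual measurements, and the control
    channel carrying command words."""
    store = ChannelStore(persist_dir=persist_dir)
    store.create_channel(ChannelSchema(ENVIRONMENTAL, ENV_FIELDS))
    store.create_channel(ChannelSchema(SERVICES, _SERVICES_FIELDS))
    store.create_channel(ChannelSchema(MANUAL, _MANUAL_FIELDS))
    store.create_channel(ChannelSchema(CONTROL, _CONTROL_FIELDS))
    return store


def used_field_count(store: ChannelStore) -> int:
    """Fields actually allocated (non-reserved) across the deployment."""
    return sum(
        1
        for name in store.channel_names
        for f in store.schema(name).fields
        if not f.startswith("reserved_")
    )
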