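"""Readers and writers for event logs, deliveries, and configuration documents.

Event logs and delivery logs are JSON Lines (UTF-8, one record per line);
configuration (patient config, goals timeline, templates, push schedules) is
YAML. A flattened CSV export of logs is provided for analytics interchange.
"""

from __future__ import annotations

import datetime as dt
import json
from pathlib import Path
from typing import IO, Iterable, Union

import pandas as pd
import yaml

from .errors import ParseError, SchemaError
from .models import (
    DeliveredIntervention,
    EntryRecord,
    GoalsTimeline,
    InterventionTemplate,
    PatientConfig,
    validate_entry,
)
from .scheduler import PushSchedule

Source = Union[str, Path, IO[str]]

__all__ = [
    "read_event_log",
    "write_event_log",
    "read_deliveries",
    "write_deliveries",
    "entries_to_frame",
    "load_patient_config",
    "dump_patient_config",
    "load_templates",
    "dump_templates",
    "load_goals_timeline",
    "dump_goals_timeline",
    "load_push_schedules",
    "dump_push_schedules",
]


def _open_for(source: Source, mode: str):
    if isinstance(source, (str, Path)):
        return open(source, mode, encoding="utf-8"), True
    return source, False


def read_event_log(source: Source) -> list[EntryRecord]:
    """Read a JSON-lines event log, validating every record.

    Returns records sorted by timestamp (stable for ties). Duplicate entry ids
    raise :class:`~skillnudge.errors.SchemaError`; a malformed line raises
    :class:`~skillnudge.errors.ParseError` carrying its 1-based line number.
    """
    fh, owned = _open_for(source, "r")
    try:
        records: list[EntryRecord] = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                raw = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"malformed JSON ({exc.msg})", line=lineno) from exc
            try:
                rec = validate_entry(raw)
            except SchemaError as exc:
                raise ParseError(str(exc), line=lineno) from exc
            if rec.entry_id in seen:
                raise SchemaError(f"duplicate entry_id {rec.entry_id!r}")
            seen.add(rec.entry_id)
            records.append(rec)
    finally:
        if owned:
            fh.close()
    records.sort(key=lambda r: r.timestamp)
    return records


def _write_jsonl(models: Iterable, dest: Source) -> None:
    fh, owned = _open_for(dest, "w")
    try:
        for m in models:
            fh.write(
                json.dumps(m.model_dump(mode="json", exclude_none=True)) + "\n"
            )
    finally:
        if owned:
            fh.close()


def write_event_log(records: Iterable[EntryRecord], dest: Source) -> None:
    """Write records as JSON lines. ``read_event_log`` round-trips exactly."""
    _write_jsonl(records, dest)


def read_deliveries(source: Source) -> list[DeliveredIntervention]:
    fh, owned = _open_for(source, "r")
    try:
        out = []
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                out.append(DeliveredIntervention.model_validate(json.loads(line)))
            except json.JSONDecodeError as exc:
                raise ParseError(f"malformed JSON ({exc.msg})", line=lineno) from exc
    finally:
        if owned:
            fh.close()
    out.sort(key=lambda d: d.timestamp)
    return out


def write_deliveries(deliveries: Iterable[DeliveredIntervention], dest: Source) -> None:
    _write_jsonl(deliveries, dest)


def entries_to_frame(records: Iterable[EntryRecord]) -> pd.DataFrame:
    """Flatten an event log into a tidy DataFrame (one row per entry).

    Set-valued behaviors become a sorted '|'-joined string; suitable for CSV
    export and for the analytics module's pandas pipelines.
    """
    rows = []
    for r in records:
        d = r.model_dump(mode="json")
        d["behaviors"] = "|".join(d["behaviors"])
        d["foods"] = "|".join(d["foods"])
        rows.append(d)
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame["timestamp"] = pd.to_datetime(frame["timestamp"])
    return frame


# -- YAML configuration documents -------------------------------------------


def _load_yaml(source: Source):
    fh, owned = _open_for(source, "r")
    try:
        return yaml.safe_load(fh)
    finally:
        if owned:
            fh.close()


def _dump_yaml(payload, dest: Source) -> None:
    fh, owned = _open_for(dest, "w")
    try:
        yaml.safe_dump(payload, fh, sort_keys=False, default_flow_style=False)
    finally:
        if owned:
            fh.close()


def load_patient_config(source: Source) -> PatientConfig:
    raw = _load_yaml(source)
    if "waking_window" in raw:
        raw["waking_window"] = tuple(
            dt.time.fromisoformat(t) if isinstance(t, str) else t
            for t in raw["waking_window"]
        )
    return PatientConfig.model_validate(raw)


def dump_patient_config(config: PatientConfig, dest: Source) -> None:
    payload = config.model_dump(mode="json")
    payload["waking_window"] = [t.isoformat() for t in config.waking_window]
    _dump_yaml(payload, dest)


def load_templates(source: Source) -> dict[str, InterventionTemplate]:
    raw = _load_yaml(source) or []
    templates = [InterventionTemplate.model_validate(t) for t in raw]
    return {t.template_id: t for t in templates}


def dump_templates(templates: dict[str, InterventionTemplate], dest: Source) -> None:
    _dump_yaml([t.model_dump(mode="json") for t in templates.values()], dest)


def load_goals_timeline(source: Source) -> GoalsTimeline:
    return GoalsTimeline.model_validate({"segments": _load_yaml(source) or []})


def dump_goals_timeline(timeline: GoalsTimeline, dest: Source) -> None:
    _dump_yaml(
        [s.model_dump(mode="json", exclude_none=True) for s in timeline.segments],
        dest,
    )


def load_push_schedules(source: Source) -> list[PushSchedule]:
    raw = _load_yaml(source) or []
    return [PushSchedule.model_validate(p) for p in raw]


def dump_push_schedules(schedules: list[PushSchedule], dest: Source) -> None:
    _dump_yaml([p.model_dump(mode="json", exclude_none=True) for p in schedules], dest)
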