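"""Raw interface event logs: the record type and JSONL/CSV round-trip I/O.

An :class:`InterfaceEvent` is one timestamped interaction with the task
interface.  Event types mirror the panels of the task: variable adjustments
and trial runs (Experimentation Panel), answer-element edits (Question
Panel), record deletion (Data Panel), and the task start/end markers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

__all__ = [
    "EVENT_TYPES",
    "InterfaceEvent",
    "write_jsonl",
    "read_jsonl",
    "write_csv",
    "read_csv",
    "group_by_student",
]

EVENT_TYPES = (
    "start_task",
    "adjust_gate",
    "adjust_diameter",
    "run_trial",
    "edit_answer",
    "delete_record",
    "end_task",
)


@dataclass(frozen=True)
class InterfaceEvent:
    """One raw log record.

    ``payload`` is event-specific: ``adjust_gate`` carries ``gate``;
    ``adjust_diameter`` carries ``diameter``; ``run_trial`` carries the
    settings and the resulting ``rpm``; ``edit_answer`` carries ``element``
    (gate/diameter/speed) and ``value``; ``delete_record`` carries the
    ``index`` of the removed data row.
    """

    student_id: str
    t: float
    event: str
    payload: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.event not in EVENT_TYPES:
            raise ValueError(f"unknown event type: {self.event!r}")


def write_jsonl(events: Iterable[InterfaceEvent], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ev in events:
            fh.write(
                json.dumps(
                    {"student_id": ev.student_id, "t": ev.t, "event": ev.event, "payload": ev.payload},
                    sort_keys=True,
                )
                + "\n"
            )


def read_jsonl(path: str | Path) -> list[InterfaceEvent]:
    events = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            events.append(
                InterfaceEvent(
                    student_id=str(rec["student_id"]),
                    t=float(rec["t"]),
                    event=rec["event"],
                    payload=rec.get("payload", {}),
                )
            )
    return events


_PAYLOAD_COLUMNS = ("gate", "diameter", "rpm", "element", "value", "index")


def write_csv(events: Iterable[InterfaceEvent], path: str | Path) -> None:
    """CSV alternative with the payload flattened into fixed columns."""
    rows = []
    for ev in events:
        row = {"student_id": ev.student_id, "t": ev.t, "event": ev.event}
        for col in _PAYLOAD_COLUMNS:
            row[col] = ev.payload.get(col, "")
        rows.append(row)
    pd.DataFrame(rows, columns=["student_id", "t", "event", *_PAYLOAD_COLUMNS]).to_csv(
        path, index=False
    )


def read_csv(path: str | Path) -> list[InterfaceEvent]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    events = []
    for _, row in df.iterrows():
        payload = {}
        for col in _PAYLOAD_COLUMNS:
            raw = row.get(col, "")
            if raw == "":
                continue
            if col in ("diameter", "index"):
                payload[col] = int(float(raw))
            elif col == "rpm":
                payload[col] = float(raw)
            elif col == "value":
                try:
                    payload[col] = json.loads(raw)
                except (ValueError, TypeError):
                    payload[col] = raw
            else:
                payload[col] = raw
        events.append(
            InterfaceEvent(
                student_id=str(row["student_id"]),
                t=float(row["t"]),
                event=row["event"],
                payload=payload,
            )
        )
    return events


def group_by_student(events: Iterable[InterfaceEvent]) -> Iterator[tuple[str, list[InterfaceEvent]]]:
    """Yield (student_id, chronologically ordered events) per student.

    Students are yielded in order of first appearance; within a student the
    events are sorted by timestamp (stable, so ties keep log order).
    """
    by_student: dict[str, list[InterfaceEvent]] = {}
    for ev in events:
        by_student.setdefault(ev.student_id, []).append(ev)
    for sid, evs in by_student.items():
        yield sid, sorted(evs, key=lambda e: e.t)
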