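"""Two-level behavior coding of raw interface event logs.

Raw events are recoded into a closed alphabet of eight micro-level behavior
codes, which aggregate many-to-one into six macro-level inquiry phases:

===============  ==============
micro code       macro category
===============  ==============
Start Task       START
Adjust Gate      DESIGN
Adjust Diameter  DESIGN
Run Trial        CONDUCT
Initial Answer   ANSWER
Revise Answer    ANSWER
Remove Record    MANAGE
End Task         END
===============  ==============

Answer-element edits are grouped into *episodes*: a maximal run of
consecutive ``edit_answer`` events collapses to one code.  The first
episode per student is Initial Answer; every later episode is Revise
Answer.  The result is a pair of parallel time-ordered sequences per
student plus timing metadata.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import cohen_kappa_score

from .events import InterfaceEvent
from .task_model import AnswerTriple, DiameterLevel, GateLevel

__all__ = [
    "MicroCode",
    "MacroCode",
    "MICRO_ORDER",
    "MACRO_ORDER",
    "MICRO_TO_MACRO",
    "CodedSequence",
    "CodingError",
    "code_log",
    "code_cohort",
    "extract_final_answer",
    "cohens_kappa",
    "sequence_stats",
    "sequences_to_frame",
]


class MicroCode(str, enum.Enum):
    START_TASK = "Start Task"
    ADJUST_GATE = "Adjust Gate"
    ADJUST_DIAMETER = "Adjust Diameter"
    RUN_TRIAL = "Run Trial"
    INITIAL_ANSWER = "Initial Answer"
    REVISE_ANSWER = "Revise Answer"
    REMOVE_RECORD = "Remove Record"
    END_TASK = "End Task"


class MacroCode(str, enum.Enum):
    START = "START"
    DESIGN = "DESIGN"
    CONDUCT = "CONDUCT"
    ANSWER = "ANSWER"
    MANAGE = "MANAGE"
    END = "END"


#: Canonical ordering of the eight-code micro alphabet.
MICRO_ORDER: tuple[MicroCode, ...] = (
    MicroCode.START_TASK,
    MicroCode.ADJUST_GATE,
    MicroCode.ADJUST_DIAMETER,
    MicroCode.RUN_TRIAL,
    MicroCode.INITIAL_ANSWER,
    MicroCode.REVISE_ANSWER,
    MicroCode.REMOVE_RECORD,
    MicroCode.END_TASK,
)

#: Canonical ordering of the six-category macro alphabet.
MACRO_ORDER: tuple[MacroCode, ...] = (
    MacroCode.START,
    MacroCode.DESIGN,
    MacroCode.CONDUCT,
    MacroCode.ANSWER,
    MacroCode.MANAGE,
    MacroCode.END,
)

MICRO_TO_MACRO: dict[MicroCode, MacroCode] = {
    MicroCode.START_TASK: MacroCode.START,
    MicroCode.ADJUST_GATE: MacroCode.DESIGN,
    MicroCode.ADJUST_DIAMETER: MacroCode.DESIGN,
    MicroCode.RUN_TRIAL: MacroCode.CONDUCT,
    MicroCode.INITIAL_ANSWER: MacroCode.ANSWER,
    MicroCode.REVISE_ANSWER: MacroCode.ANSWER,
    MicroCode.REMOVE_RECORD: MacroCode.MANAGE,
    MicroCode.END_TASK: MacroCode.END,
}

_EVENT_TO_MICRO = {
    "start_task": MicroCode.START_TASK,
    "adjust_gate": MicroCode.ADJUST_GATE,
    "adjust_diameter": MicroCode.ADJUST_DIAMETER,
    "run_trial": MicroCode.RUN_TRIAL,
    "delete_record": MicroCode.REMOVE_RECORD,
    "end_task": MicroCode.END_TASK,
}


class CodingError(ValueError):
    """The event stream violates the task grammar; carries the position."""

    def __init__(self, message: str, position: int | None = None):
        if position is not None:
            message = f"{message} (event position {position})"
        super().__init__(message)
        self.position = position


@dataclass(frozen=True)
class CodedSequence:
    """A student's parallel micro/macro behavior sequences plus timing."""

    student_id: str
    micro: tuple[MicroCode, ...]
    macro: tuple[MacroCode, ...]
    completion_time: float
    #: per-code timestamp of the first raw event mapped to that code
    times: tuple[float, ...]

    @property
    def sequence_length(self) -> int:
        return len(self.micro)


def code_log(events: Sequence[InterfaceEvent]) -> CodedSequence:
    """Recode one student's chronologically ordered raw events.

    Raises :class:`CodingError` when the stream violates the grammar:
    missing/duplicated start or end markers, events outside the
    start..end span, or timestamps that go backwards.
    """
    if not events:
        raise CodingError("empty event stream")
    sid = events[0].student_id
    for i, ev in enumerate(events):
        if ev.student_id != sid:
            raise CodingError("events from more than one student", i)
        if i and ev.t < events[i - 1].t:
            raise CodingError("timestamps decrease", i)
    if events[0].event != "start_task":
        raise CodingError("first event must be start_task", 0)
    if events[-1].event != "end_task":
        raise CodingError("last event must be end_task", len(events) - 1)
    for i, ev in enumerate(events):
        if ev.event == "start_task" and i != 0:
            raise CodingError("duplicate start_task", i)
        if ev.event == "end_task" and i != len(events) - 1:
            raise CodingError("event after end_task" if i < len(events) - 1 else "", i)

    micro: list[MicroCode] = []
    times: list[float] = []
    seen_answer = False
    in_episode = False
    for ev in events:
        if ev.event == "edit_answer":
            if in_episode:
                continue  # same episode: collapse
            micro.append(MicroCode.REVISE_ANSWER if seen_answer else MicroCode.INITIAL_ANSWER)
            times.append(ev.t)
            seen_answer = True
            in_episode = True
        else:
            in_episode = False
            micro.append(_EVENT_TO_MICRO[ev.event])
            times.append(ev.t)
    macro = [MICRO_TO_MACRO[m] for m in micro]
    completion = events[-1].t - events[0].t
    if completion <= 0:
        raise CodingError("non-positive completion time")
    return CodedSequence(
        student_id=sid,
        micro=tuple(micro),
        macro=tuple(macro),
        completion_time=completion,
        times=tuple(times),
    )


def code_cohort(per_student: Iterable[tuple[str, Sequence[InterfaceEvent]]]) -> list[CodedSequence]:
    return [code_log(evs) for _, evs in per_student]


def extract_final_answer(events: Sequence[InterfaceEvent]) -> AnswerTriple:
    """The last value written to each answer element before end of task."""
    values: dict[str, object] = {}
    for ev in events:
        if ev.event == "edit_answer":
            values[ev.payload["element"]] = ev.payload["value"]
    gate = GateLevel(values["gate"]) if "gate" in values else None
    diameter = DiameterLevel(int(values["diameter"])) if "diameter" in values else None
    speed = float(values["speed"]) if "speed" in values else None
    return AnswerTriple(gate=gate, diameter=diameter, speed=speed)


def cohens_kappa(codes_a: Sequence, codes_b: Sequence) -> tuple[float, float]:
    """Cohen's κ and raw percent agreement between two aligned codings.

    Returns ``(kappa, percent_agreement)`` with agreement on a 0–100 scale.
    """
    if len(codes_a) != len(codes_b):
        raise ValueError("codings must have equal length")
    if len(codes_a) < 2:
        raise ValueError("need at least 2 paired codes")
    a = [getattr(c, "value", c) for c in codes_a]
    b = [getattr(c, "value", c) for c in codes_b]
    agreement = 100.0 * float(np.mean([x == y for x, y in zip(a, b)]))
    if a == b:
        return 1.0, agreement  # identical codings: κ exactly 1 by convention
    kappa = float(cohen_kappa_score(a, b))
    return kappa, agreement


def sequences_to_frame(coded: Iterable[CodedSequence]) -> pd.DataFrame:
    """Long-format frame: one row per (student, position)."""
    rows = []
    for seq in coded:
        for pos, (mi, ma, t) in enumerate(zip(seq.micro, seq.macro, seq.times)):
            rows.append(
                {
                    "student_id": seq.student_id,
                    "position": pos,
                    "micro": mi.value,
                    "macro": ma.value,
                    "t": t,
                }
            )
    return pd.DataFrame(rows, columns=["student_id", "position", "micro", "macro", "t"])


def sequence_stats(
    coded: Iterable[CodedSequence],
    groups: Mapping[str, str] | None = None,
) -> dict:
    """Per-student and groupwise completion-time / sequence-length summaries.

    When ``groups`` maps student ids to exactly two group labels, Welch's
    t-test (unequal variances, Satterthwaite df) compares the groups on
    both metrics.  Groups without the n ≥ 2 needed for a test produce a
    notice instead of a test row.
    """
    per_student = pd.DataFrame(
        [
            {
                "student_id": s.student_id,
                "completion_time": s.completion_time,
                "sequence_length": s.sequence_length,
            }
            for s in coded
        ]
    )
    if per_student.empty:
        raise ValueError("no coded sequences supplied")
    out: dict = {"per_student": per_student}
    if groups is None:
        out["summary"] = per_student[["completion_time", "sequence_length"]].agg(["mean", "std", "count"])
        return out
    per_student = per_student.assign(group=per_student["student_id"].map(groups))
    out["per_student"] = per_student
    out["summary"] = per_student.groupby("group")[["completion_time", "sequence_length"]].agg(
        ["mean", "std", "count"]
    )
    labels = sorted(per_student["group"].dropna().unique())
    tests = []
    notices = []
    if len(labels) == 2:
        for metric in ("completion_time", "sequence_length"):
            x = per_student.loc[per_student["group"] == labels[0], metric].to_numpy(float)
            y = per_student.loc[per_student["group"] == labels[1], metric].to_numpy(float)
            if len(x) < 2 or len(y) < 2 or (np.var(x) == 0 and np.var(y) == 0):
                notices.append(f"{metric}: test skipped (insufficient data or zero variance)")
                continue
            res = stats.ttest_ind(x, y, equal_var=False)
            tests.append(
                {
                    "metric": metric,
                    "group_a": labels[0],
                    "group_b": labels[1],
                    "t": float(res.statistic),
                    "df": float(res.df),
                    "p": float(res.pvalue),
                }
            )
    else:
        notices.append("Welch test requires exactly two groups")
    out["welch"] = pd.DataFrame(tests, columns=["metric", "group_a", "group_b", "t", "df", "p"])
    out["notices"] = notices
    return out
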