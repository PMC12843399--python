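"""Hydroelectric Power Plant task environment.

The task asks a student to find the operating condition of a water-wheel
generator that maximizes rotation speed (rpm) while staying below a safety
limit.  Two factors are manipulated: gate position (Low/Medium/High) and
inlet diameter (40/80/120 cm).  The simulation itself is a deterministic
lookup into a 3x3 outcome table; the science of the task lives in the
structure of that table (monotone in both factors, with the global maximum
above the safety limit so the constrained optimum is an interior trade-off).

A final answer is a triple (gate, diameter, speed) and is scored
dichotomously: 1 only if it names the unique constrained optimum cell and
its exact rpm, 0 otherwise.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "GateLevel",
    "DiameterLevel",
    "OutcomeTable",
    "AnswerTriple",
    "IncompleteAnswerError",
    "TableValidationResult",
    "rotation_speed",
    "score_answer",
    "validate_table",
    "default_table",
    "load_table",
    "save_table",
]


class GateLevel(str, enum.Enum):
    """Gate position, ordered Low < Medium < High."""

    LOW = "Low"
    MEDIUM = "Medium"
    HIGH = "High"

    @property
    def rank(self) -> int:
        return _GATE_ORDER.index(self)


class DiameterLevel(int, enum.Enum):
    """Inlet diameter in centimetres, ordered 40 < 80 < 120."""

    D40 = 40
    D80 = 80
    D120 = 120

    @property
    def rank(self) -> int:
        return _DIAM_ORDER.index(self)


_GATE_ORDER = [GateLevel.LOW, GateLevel.MEDIUM, GateLevel.HIGH]
_DIAM_ORDER = [DiameterLevel.D40, DiameterLevel.D80, DiameterLevel.D120]

#: Default rpm for every (gate, diameter) cell.  Three cells are fixed by the
#: task narrative (Medium/120 = 309 optimum, High/120 = 438 over the limit,
#: High/80 = 292 next-best safe); the rest are chosen to be strictly monotone
#: in both factors with every non-optimal safe cell below 309.
DEFAULT_RPM: dict[tuple[GateLevel, DiameterLevel], float] = {
    (GateLevel.LOW, DiameterLevel.D40): 76,
    (GateLevel.LOW, DiameterLevel.D80): 124,
    (GateLevel.LOW, DiameterLevel.D120): 208,
    (GateLevel.MEDIUM, DiameterLevel.D40): 118,
    (GateLevel.MEDIUM, DiameterLevel.D80): 196,
    (GateLevel.MEDIUM, DiameterLevel.D120): 309,
    (GateLevel.HIGH, DiameterLevel.D40): 163,
    (GateLevel.HIGH, DiameterLevel.D80): 292,
    (GateLevel.HIGH, DiameterLevel.D120): 438,
}

DEFAULT_SAFETY_LIMIT = 400.0


class IncompleteAnswerError(ValueError):
    """Raised when a final answer with blank elements is submitted.

    Models the interface prompt that forces students to fill all three
    answer elements before the task can end.
    """


@dataclass(frozen=True)
class AnswerTriple:
    """A submitted final answer: gate position, inlet diameter, rpm.

    Any element may be ``None`` (left blank); the answer is *complete* iff
    all three are filled.
    """

    gate: GateLevel | None = None
    diameter: DiameterLevel | None = None
    speed: float | None = None

    @property
    def complete(self) -> bool:
        return self.gate is not None and self.diameter is not None and self.speed is not None


@dataclass(frozen=True)
class TableValidationResult:
    valid: bool
    errors: tuple[str, ...] = ()


@dataclass(frozen=True)
class OutcomeTable:
    """The 3x3 rpm outcome table plus the safety limit."""

    rpm: Mapping[tuple[GateLevel, DiameterLevel], float] = field(
        default_factory=lambda: dict(DEFAULT_RPM)
    )
    safety_limit: float = DEFAULT_SAFETY_LIMIT

    def __post_init__(self) -> None:
        missing = [
            (g.value, d.value) for g in _GATE_ORDER for d in _DIAM_ORDER if (g, d) not in self.rpm
        ]
        if missing:
            raise ValueError(f"outcome table is missing cells: {missing}")

    def safe_cells(self) -> list[tuple[GateLevel, DiameterLevel]]:
        return [
            (g, d)
            for g in _GATE_ORDER
            for d in _DIAM_ORDER
            if self.rpm[(g, d)] < self.safety_limit
        ]

    def optimum(self) -> tuple[GateLevel, DiameterLevel]:
        """The unique safe cell with maximal rpm (the correct answer)."""
        safe = self.safe_cells()
        if not safe:
            raise ValueError("no cell is below the safety limit")
        best = max(safe, key=lambda cell: self.rpm[cell])
        ties = [c for c in safe if self.rpm[c] == self.rpm[best]]
        if len(ties) > 1:
            raise ValueError("non-unique optimum: safe maximum is tied")
        return best


def default_table() -> OutcomeTable:
    return OutcomeTable()


def rotation_speed(table: OutcomeTable, gate: GateLevel, diameter: DiameterLevel) -> float:
    """Deterministic rpm returned by the simulator for one trial."""
    gate = GateLevel(gate)
    diameter = DiameterLevel(diameter)
    return table.rpm[(gate, diameter)]


def score_answer(table: OutcomeTable, answer: AnswerTriple) -> int:
    """Dichotomous correctness: 1 iff the answer names the unique optimum.

    All three elements must be correct — the optimum's gate, its diameter,
    and the exact rpm of that cell.  Incomplete answers are rejected (the
    interface would not let them through).
    """
    if not answer.complete:
        raise IncompleteAnswerError("all three answer elements must be filled")
    opt = table.optimum()
    correct = (
        answer.gate == opt[0]
        and answer.diameter == opt[1]
        and float(answer.speed) == float(table.rpm[opt])
    )
    return int(correct)


def validate_table(table: OutcomeTable) -> TableValidationResult:
    """Check the structural requirements of a task outcome table.

    A valid table has (a) a unique constrained optimum and (b) rpm strictly
    increasing along both the gate and the diameter orderings — the two
    qualitative priors the task states to students.
    """
    errors: list[str] = []
    for cell, value in table.rpm.items():
        if value <= 0:
            errors.append(f"non-positive rpm at {cell[0].value}/{cell[1].value}")
    try:
        table.optimum()
    except ValueError as exc:
        errors.append(str(exc))
    for d in _DIAM_ORDER:
        for lo, hi in zip(_GATE_ORDER[:-1], _GATE_ORDER[1:]):
            if table.rpm[(lo, d)] >= table.rpm[(hi, d)]:
                errors.append(
                    f"monotonicity violated in gate at diameter {d.value}: "
                    f"rpm({lo.value}) >= rpm({hi.value})"
                )
    for g in _GATE_ORDER:
        for lo, hi in zip(_DIAM_ORDER[:-1], _DIAM_ORDER[1:]):
            if table.rpm[(g, lo)] >= table.rpm[(g, hi)]:
                errors.append(
                    f"monotonicity violated in diameter at gate {g.value}: "
                    f"rpm({lo.value}) >= rpm({hi.value})"
                )
    return TableValidationResult(valid=not errors, errors=tuple(errors))


def _table_to_dict(table: OutcomeTable) -> dict:
    return {
        "safety_limit": table.safety_limit,
        "rpm": {g.value: {str(d.value): table.rpm[(g, d)] for d in _DIAM_ORDER} for g in _GATE_ORDER},
    }


def _table_from_dict(data: dict) -> OutcomeTable:
    rpm = {
        (GateLevel(g), DiameterLevel(int(d))): float(v)
        for g, row in data["rpm"].items()
        for d, v in row.items()
    }
    return OutcomeTable(rpm=rpm, safety_limit=float(data.get("safety_limit", DEFAULT_SAFETY_LIMIT)))


def save_table(table: OutcomeTable, path: str | Path) -> None:
    """Write a task config as YAML (or JSON if the suffix is .json)."""
    path = Path(path)
    data = _table_to_dict(table)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))


def load_table(path: str | Path) -> OutcomeTable:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return _table_from_dict(data)
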