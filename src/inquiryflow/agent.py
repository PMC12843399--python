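"""Agent-based generation of synthetic interface event logs.

Each agent is a stationary first-order Markov chain over the eight
micro-level behavior codes.  A behavioral profile supplies the transition
matrix, per-behavior log-normal dwell-time parameters, and an answer
policy (the probability that the final submitted triple is the task
optimum).  Four built-in profiles emulate the qualitative signatures of
the 2x2 performance subgroups: effective profiles cycle iteratively
between variable adjustment and trial running before committing to an
answer, ineffective profiles answer early and explore little, and within
each effectiveness level the inefficient profile is slower and longer.

The raw chain is constrained on the fly to honor the task grammar:

* ``Remove Record`` is masked while the Data Panel is empty;
* answer codes are positional — a proposed Initial Answer when an answer
  already exists is emitted as Revise Answer (and vice versa), and two
  answer episodes never abut (they would merge under coding);
* a proposed ``End Task`` before any answer forces an answer episode
  first, mirroring the interface prompt that blocks incomplete
  submissions.

Built-in profiles whose structure makes these repairs unreachable (the
chain answers at the first step and only then exposes revision/end mass)
generate logs whose coded transition frequencies converge to the profile
matrix, which is what makes ground-truth parameter recovery testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coding import MICRO_ORDER, MicroCode
from .events import InterfaceEvent
from .task_model import (
    DiameterLevel,
    GateLevel,
    OutcomeTable,
    rotation_speed,
)

__all__ = [
    "CODE_ORDER",
    "BehaviorProfile",
    "CohortSpec",
    "GenerationError",
    "builtin_profiles",
    "generate_cohort",
]

#: Canonical ordering of the micro-behavior alphabet for matrix layouts.
CODE_ORDER: tuple[MicroCode, ...] = MICRO_ORDER
_IDX = {c: i for i, c in enumerate(CODE_ORDER)}
_ANSWER_CODES = (MicroCode.INITIAL_ANSWER, MicroCode.REVISE_ANSWER)


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class BehaviorProfile:
    """Parameterization of one agent population.

    ``transition_matrix`` maps source code -> {target code: probability};
    rows must be stochastic, Start Task must have no incoming mass, and
    End Task is absorbing.  ``dwell_time`` maps each code to log-normal
    ``(mu, sigma)`` parameters of the pause (seconds) following an event
    of that code.
    """

    name: str
    transition_matrix: Mapping[MicroCode, Mapping[MicroCode, float]]
    dwell_time: Mapping[MicroCode, tuple[float, float]]
    answer_policy: float
    max_steps: int = 500
    #: optional log-normal ``(mu, sigma)`` of the student's total completion
    #: time.  When set, the sampled per-event dwells are rescaled so their
    #: sum equals the student-level draw: dwell parameters then act as
    #: relative pace weights.  This separates *how long* a student takes
    #: (a student-level trait with realistic, unimodal-per-profile spread)
    #: from *how many* steps they take (the chain's geometric-tailed path
    #: length), so mixed cohorts show the bimodal completion times the
    #: efficiency profiling stage is designed to resolve.
    total_time: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        for src, row in self.transition_matrix.items():
            total = sum(row.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"profile {self.name!r}: row {src.value!r} sums to {total}")
            if any(p < 0 for p in row.values()):
                raise ValueError(f"profile {self.name!r}: negative probability in row {src.value!r}")
            if row.get(MicroCode.START_TASK, 0.0) > 0:
                raise ValueError(f"profile {self.name!r}: Start Task must have no incoming mass")
        if self.transition_matrix.get(MicroCode.END_TASK):
            raise ValueError(f"profile {self.name!r}: End Task must be absorbing")
        if MicroCode.START_TASK not in self.transition_matrix:
            raise ValueError(f"profile {self.name!r}: missing Start Task row")
        if not 0.0 <= self.answer_policy <= 1.0:
            raise ValueError("answer_policy must be a probability")
        for code, (mu, sigma) in self.dwell_time.items():
            if sigma <= 0:
                raise ValueError(f"profile {self.name!r}: non-positive dwell sigma for {code.value!r}")
        if self.max_steps < 1:
            raise ValueError("max_steps must be positive")
        if self.total_time is not None and self.total_time[1] <= 0:
            raise ValueError("total_time sigma must be positive")

    def matrix_array(self) -> np.ndarray:
        """The transition matrix as an 8x8 array in :data:`CODE_ORDER`."""
        arr = np.zeros((len(CODE_ORDER), len(CODE_ORDER)))
        for src, row in self.transition_matrix.items():
            for tgt, p in row.items():
                arr[_IDX[src], _IDX[tgt]] = p
        return arr


@dataclass(frozen=True)
class CohortSpec:
    profiles: Sequence[tuple[BehaviorProfile, int]]
    seed: int = 0
    id_prefix: str = "s"

    def __post_init__(self) -> None:
        if any(count < 1 for _, count in self.profiles):
            raise ValueError("profile counts must be >= 1")
        if sum(count for _, count in self.profiles) < 2:
            raise ValueError("a cohort needs at least 2 students")


def _dwell(mu_sigma: tuple[float, float], rng: np.random.Generator) -> float:
    mu, sigma = mu_sigma
    return float(rng.lognormal(mean=mu, sigma=sigma))


def _sample_micro_path(profile: BehaviorProfile, rng: np.random.Generator) -> list[MicroCode]:
    """Sample one grammar-valid micro-code path from Start Task to End Task."""
    matrix = {src: dict(row) for src, row in profile.transition_matrix.items()}
    path = [MicroCode.START_TASK]
    records = 0
    answered = False
    while path[-1] != MicroCode.END_TASK:
        if len(path) > profile.max_steps:
            raise GenerationError(
                f"profile {profile.name!r} did not reach End Task within {profile.max_steps} steps"
            )
        row = matrix.get(path[-1])
        if not row:
            raise GenerationError(f"profile {profile.name!r}: no outgoing mass from {path[-1].value!r}")
        probs = dict(row)
        if records == 0:
            probs.pop(MicroCode.REMOVE_RECORD, None)
        if path[-1] in _ANSWER_CODES:
            # abutting answer episodes would merge under coding
            for code in _ANSWER_CODES:
                probs.pop(code, None)
        total = sum(probs.values())
        if total <= 0:
            raise GenerationError(
                f"profile {profile.name!r}: all transitions from {path[-1].value!r} "
                "are contextually invalid"
            )
        codes = list(probs)
        nxt = codes[rng.choice(len(codes), p=np.array([probs[c] for c in codes]) / total)]
        if nxt == MicroCode.INITIAL_ANSWER and answered:
            nxt = MicroCode.REVISE_ANSWER
        elif nxt == MicroCode.REVISE_ANSWER and not answered:
            nxt = MicroCode.INITIAL_ANSWER
        if nxt == MicroCode.END_TASK and not answered:
            # interface prompt: cannot end with a blank answer
            path.append(MicroCode.INITIAL_ANSWER)
            answered = True
        if nxt == MicroCode.RUN_TRIAL:
            records += 1
        elif nxt == MicroCode.REMOVE_RECORD:
            records -= 1
        elif nxt in _ANSWER_CODES:
            answered = True
        path.append(nxt)
    return path


def _choose_final_triple(
    profile: BehaviorProfile, table: OutcomeTable, rng: np.random.Generator
) -> tuple[GateLevel, DiameterLevel, float]:
    opt = table.optimum()
    if rng.random() < profile.answer_policy:
        gate, diam = opt
    else:
        alternatives = [c for c in table.safe_cells() if c != opt]
        gate, diam = alternatives[rng.choice(len(alternatives))]
    return gate, diam, table.rpm[(gate, diam)]


def _materialize_events(
    student_id: str,
    path: Sequence[MicroCode],
    profile: BehaviorProfile,
    table: OutcomeTable,
    rng: np.random.Generator,
) -> list[InterfaceEvent]:
    """Turn a micro-code path into a raw event log with faithful payloads."""
    gates = list(GateLevel)
    diams = list(DiameterLevel)
    gate, diam = GateLevel.LOW, DiameterLevel.D40  # interface default setting
    records: list[int] = []
    next_record_id = 0
    final = _choose_final_triple(profile, table, rng)
    episode_positions = [i for i, c in enumerate(path) if c in _ANSWER_CODES]
    last_episode = episode_positions[-1] if episode_positions else None

    staged: list[tuple[str, dict, MicroCode]] = []

    def emit(event: str, payload: dict, code: MicroCode) -> None:
        staged.append((event, payload, code))

    for i, code in enumerate(path):
        if code == MicroCode.START_TASK:
            emit("start_task", {}, code)
        elif code == MicroCode.ADJUST_GATE:
            gate = [g for g in gates if g != gate][rng.choice(2)]
            emit("adjust_gate", {"gate": gate.value}, code)
        elif code == MicroCode.ADJUST_DIAMETER:
            diam = [d for d in diams if d != diam][rng.choice(2)]
            emit("adjust_diameter", {"diameter": diam.value}, code)
        elif code == MicroCode.RUN_TRIAL:
            rpm = rotation_speed(table, gate, diam)
            records.append(next_record_id)
            next_record_id += 1
            emit("run_trial", {"gate": gate.value, "diameter": diam.value, "rpm": rpm}, code)
        elif code == MicroCode.REMOVE_RECORD:
            idx = int(rng.choice(len(records)))
            records.pop(idx)
            emit("delete_record", {"index": idx}, code)
        elif code in _ANSWER_CODES:
            if i == last_episode:
                triple = final
            else:
                # an interim guess: current settings and the rpm they yield
                triple = (gate, diam, table.rpm[(gate, diam)])
            if code == MicroCode.INITIAL_ANSWER or i == last_episode:
                elements = ["gate", "diameter", "speed"]
            else:
                n_edit = int(rng.choice(3)) + 1
                elements = list(np.array(["gate", "diameter", "speed"])[
                    np.sort(rng.choice(3, size=n_edit, replace=False))
                ])
            values = {"gate": triple[0].value, "diameter": triple[1].value, "speed": triple[2]}
            for el in elements:
                emit("edit_answer", {"element": el, "value": values[el]}, code)
        elif code == MicroCode.END_TASK:
            emit("end_task", {}, code)

    # timestamps: cumulative sums of sampled dwell times.  With a
    # total_time model the dwells are rescaled so the last event lands at
    # the student-level completion-time draw.
    dwells = np.array([_dwell(profile.dwell_time[code], rng) for _, _, code in staged[:-1]])
    if profile.total_time is not None and len(dwells):
        mu, sigma = profile.total_time
        total = float(rng.lognormal(mean=mu, sigma=sigma))
        dwells *= total / dwells.sum()
    times = np.concatenate([[0.0], np.cumsum(dwells)])
    return [
        InterfaceEvent(student_id=student_id, t=round(float(t), 3), event=event, payload=payload)
        for t, (event, payload, _) in zip(times, staged)
    ]


def generate_cohort(
    spec: CohortSpec, table: OutcomeTable | None = None
) -> tuple[list[InterfaceEvent], pd.DataFrame]:
    """Generate one well-formed event log per student plus ground truth.

    Returns ``(events, labels)`` where ``labels`` has one row per student
    with the generating profile name and whether the submitted final
    answer was the task optimum.  Identical spec + seed gives identical
    output.  Per-student RNG streams are spawned from the cohort seed, so
    a student's log depends only on the seed and their index.
    """
    if table is None:
        table = OutcomeTable()
    total = sum(count for _, count in spec.profiles)
    streams = np.random.SeedSequence(spec.seed).spawn(total)
    width = max(4, len(str(total)))
    events: list[InterfaceEvent] = []
    labels = []
    student = 0
    opt = table.optimum()
    for profile, count in spec.profiles:
        for _ in range(count):
            sid = f"{spec.id_prefix}{student:0{width}d}"
            rng = np.random.default_rng(streams[student])
            path = _sample_micro_path(profile, rng)
            log = _materialize_events(sid, path, profile, table, rng)
            events.extend(log)
            final_edits = {
                ev.payload["element"]: ev.payload["value"] for ev in log if ev.event == "edit_answer"
            }
            correct = (
                final_edits.get("gate") == opt[0].value
                and final_edits.get("diameter") == opt[1].value
                and float(final_edits.get("speed", np.nan)) == table.rpm[opt]
            )
            labels.append({"student_id": sid, "profile": profile.name, "answer_correct": bool(correct)})
            student += 1
    return events, pd.DataFrame(labels)


def _row(**kwargs: float) -> dict[MicroCode, float]:
    return {MicroCode(k): v for k, v in kwargs.items()}


_M = {
    "ST": MicroCode.START_TASK,
    "AG": MicroCode.ADJUST_GATE,
    "AD": MicroCode.ADJUST_DIAMETER,
    "RT": MicroCode.RUN_TRIAL,
    "IA": MicroCode.INITIAL_ANSWER,
    "RA": MicroCode.REVISE_ANSWER,
    "RR": MicroCode.REMOVE_RECORD,
    "ET": MicroCode.END_TASK,
}


def _matrix(rows: dict[str, dict[str, float]]) -> dict[MicroCode, dict[MicroCode, float]]:
    return {_M[src]: {_M[t]: p for t, p in row.items()} for src, row in rows.items()}


def _dwells(default: tuple[float, float], **overrides: tuple[float, float]) -> dict:
    d = {code: default for code in CODE_ORDER}
    for key, val in overrides.items():
        d[_M[key]] = val
    return d


def builtin_profiles() -> dict[str, BehaviorProfile]:
    """The four preset profiles of the 2x2 effectiveness x efficiency design.

    Qualitative signatures: effective profiles submit the optimum with
    high probability and cycle adjust -> run iteratively; the
    ineffective-efficient profile opens with an immediate answer and stays
    short; inefficient profiles have slower dwell times (and, for the
    effective one, markedly longer sequences).  Mean completion times are
    ordered efficient < inefficient within each effectiveness level.
    """
    pace = _dwells((0.0, 0.5), IA=(-0.8, 0.5), RA=(-0.8, 0.5), RT=(0.4, 0.5))
    eff_eff = BehaviorProfile(
        name="effective_efficient",
        transition_matrix=_matrix(
            {
                "ST": {"IA": 1.0},
                "IA": {"AG": 0.80, "AD": 0.12, "RT": 0.08},
                "AG": {"RT": 0.92, "AD": 0.08},
                "AD": {"RT": 0.95, "AG": 0.05},
                "RT": {"AD": 0.35, "AG": 0.13, "RT": 0.04, "RA": 0.40, "RR": 0.08},
                "RA": {"ET": 0.65, "RT": 0.22, "AG": 0.13},
                "RR": {"RT": 0.60, "AG": 0.20, "AD": 0.20},
            }
        ),
        dwell_time=pace,
        answer_policy=0.97,
        total_time=(4.3397, 0.3313),
    )
    eff_ineff = BehaviorProfile(
        name="effective_inefficient",
        transition_matrix=_matrix(
            {
                "ST": {"RT": 0.35, "IA": 0.35, "AG": 0.20, "AD": 0.10},
                "IA": {"RT": 0.40, "AD": 0.35, "AG": 0.25},
                "AG": {"RT": 0.85, "AD": 0.15},
                "AD": {"RT": 0.90, "AG": 0.10},
                "RT": {"AD": 0.30, "AG": 0.12, "RT": 0.06, "RA": 0.32, "RR": 0.20},
                "RA": {"ET": 0.50, "RT": 0.27, "AG": 0.11, "AD": 0.12},
                "RR": {"AG": 0.36, "RT": 0.34, "AD": 0.30},
            }
        ),
        dwell_time=pace,
        answer_policy=0.95,
        total_time=(5.2556, 0.2288),
    )
    ineff_eff = BehaviorProfile(
        name="ineffective_efficient",
        transition_matrix=_matrix(
            {
                "ST": {"IA": 0.80, "AG": 0.12, "AD": 0.08},
                "IA": {"AG": 0.34, "RT": 0.30, "AD": 0.16, "ET": 0.20},
                "AG": {"RT": 0.80, "AD": 0.20},
                "AD": {"RT": 0.90, "AG": 0.10},
                "RT": {"RA": 0.36, "RT": 0.14, "AG": 0.13, "AD": 0.15, "RR": 0.05, "ET": 0.17},
                "RA": {"ET": 0.66, "RT": 0.24, "AG": 0.10},
                "RR": {"RT": 0.44, "RA": 0.30, "AG": 0.26},
            }
        ),
        dwell_time=pace,
        answer_policy=0.02,
        total_time=(4.0790, 0.3150),
    )
    ineff_ineff = BehaviorProfile(
        name="ineffective_inefficient",
        transition_matrix=_matrix(
            {
                "ST": {"IA": 0.41, "AG": 0.36, "RT": 0.13, "AD": 0.10},
                "IA": {"RT": 0.35, "AG": 0.26, "AD": 0.22, "ET": 0.17},
                "AG": {"RT": 0.75, "AD": 0.25},
                "AD": {"RT": 0.85, "AG": 0.15},
                "RT": {"AD": 0.30, "AG": 0.13, "RT": 0.08, "RA": 0.23, "RR": 0.08, "ET": 0.18},
                "RA": {"ET": 0.62, "RT": 0.20, "AD": 0.09, "AG": 0.09},
                "RR": {"RA": 0.40, "AD": 0.30, "RT": 0.30},
            }
        ),
        dwell_time=pace,
        answer_policy=0.02,
        total_time=(4.9284, 0.2897),
    )
    return {p.name: p for p in (eff_eff, eff_ineff, ineff_eff, ineff_ineff)}
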