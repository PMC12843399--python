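"""Shared fixtures: the default task table and small simulated cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from inquiryflow import agent, coding
from inquiryflow.events import group_by_student
from inquiryflow.task_model import OutcomeTable


@pytest.fixture(scope="session")
def table() -> OutcomeTable:
    return OutcomeTable()


@pytest.fixture(scope="session")
def presets() -> dict[str, agent.BehaviorProfile]:
    return agent.builtin_profiles()


@pytest.fixture(scope="session")
def demo_cohort(presets, table):
    """A small mixed cohort (60 students, seed 0) with ground-truth labels."""
    spec = agent.CohortSpec(
        profiles=[
            (presets["effective_efficient"], 20),
            (presets["effective_inefficient"], 6),
            (presets["ineffective_efficient"], 26),
            (presets["ineffective_inefficient"], 8),
        ],
        seed=0,
    )
    events, labels = agent.generate_cohort(spec, table)
    return events, labels


@pytest.fixture(scope="session")
def demo_coded(demo_cohort):
    events, _ = demo_cohort
    per_student = list(group_by_student(events))
    return coding.code_cohort(per_student), per_student


def sample_chain(matrix: dict, rng: np.random.Generator, max_steps: int = 500):
    """Plain Markov-chain walk Start Task -> End Task (test-local oracle).

    Used to generate micro sequences directly from a known matrix without
    the agent layer's grammar handling.
    """
    from inquiryflow.coding import MicroCode

    path = [MicroCode.START_TASK]
    while path[-1] != MicroCode.END_TASK:
        if len(path) > max_steps:
            raise RuntimeError("chain did not absorb")
        row = matrix[path[-1]]
        codes = list(row)
        probs = np.array([row[c] for c in codes], dtype=float)
        path.append(codes[rng.choice(len(codes), p=probs / probs.sum())])
    return path
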