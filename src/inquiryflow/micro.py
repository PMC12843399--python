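"""Micro-level dynamics: behavioral entropy and first-order process models.

**Entropy.**  Each student's behavior repertoire is summarized as Shannon
entropy of the relative frequencies of the eight micro codes,
H = -sum_i p_i log2 p_i, normalized by log2(8) = 3 to lie in [0, 1].
Subgroup means carry percentile bootstrap CIs and a two-way ANOVA
(effectiveness x efficiency, Type II sums of squares) with partial eta
squared quantifies group differences.

**Process models.**  Transitions between consecutive micro behaviors are
counted per subgroup (End Task is never a source and Start Task never a
target — structural zeros from the task grammar), normalized to
conditional probabilities P(t|s) = count(s,t) / sum_t' count(s,t'), and
shrunk toward a global prior with a hierarchical Dirichlet–multinomial
posterior mean: a per-row concentration alpha (default 0.5) splits total
prior mass proportionally to the global row, mildly regularizing sparse
rows while leaving well-populated rows nearly untouched.  Uncertainty is
quantified by resampling students with replacement; efficiency contrasts
are *delta probability maps* (Efficient minus Inefficient) whose cells
are flagged significant when the 95% bootstrap interval excludes zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .coding import MICRO_ORDER, MicroCode

__all__ = [
    "SOURCES",
    "TARGETS",
    "TransitionMatrix",
    "DeltaMap",
    "normalized_entropy",
    "entropy_group_comparison",
    "count_transitions",
    "estimate_transitions",
    "bootstrap_deltas",
    "build_process_graph",
    "graph_to_dot",
    "graph_from_dot",
    "graph_to_json",
    "graph_from_json",
]

#: Row (source) states: every micro code except the absorbing End Task.
SOURCES: tuple[MicroCode, ...] = tuple(c for c in MICRO_ORDER if c != MicroCode.END_TASK)
#: Column (target) states: every micro code except Start Task.
TARGETS: tuple[MicroCode, ...] = tuple(c for c in MICRO_ORDER if c != MicroCode.START_TASK)
_SRC_IDX = {c: i for i, c in enumerate(SOURCES)}
_TGT_IDX = {c: i for i, c in enumerate(TARGETS)}


def normalized_entropy(micro: Sequence[MicroCode]) -> tuple[float, float]:
    """Shannon entropy (bits) and its normalized form for one sequence.

    Frequencies are taken over the fixed eight-code alphabet with the
    0 * log 0 = 0 convention; the normalizer is log2(8) = 3 bits.
    """
    if len(micro) == 0:
        raise ValueError("entropy undefined for an empty sequence")
    counts = np.zeros(len(MICRO_ORDER))
    idx = {c: i for i, c in enumerate(MICRO_ORDER)}
    for code in micro:
        counts[idx[MicroCode(code)]] += 1
    p = counts / counts.sum()
    nz = p[p > 0]
    h = float(-(nz * np.log2(nz)).sum())
    return h, h / np.log2(len(MICRO_ORDER))


def entropy_group_comparison(
    values: Sequence[float],
    effectiveness: Sequence[str],
    efficiency: Sequence[str],
    B: int = 2000,
    seed: int = 0,
) -> dict:
    """Subgroup bootstrap CIs plus a two-way ANOVA on normalized entropy.

    Bootstrap resamples students within each 2x2 subgroup (percentile 95%
    CI of the mean, ``B`` resamples).  The ANOVA models effectiveness,
    efficiency and their interaction with Type II sums of squares;
    partial eta squared is SS_effect / (SS_effect + SS_error).  With an
    empty cell the ANOVA is refused but means are still reported.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = pd.DataFrame(
        {
            "entropy": np.asarray(values, float),
            "effectiveness": list(effectiveness),
            "efficiency": list(efficiency),
        }
    )
    rng = np.random.default_rng(seed)
    summary_rows = []
    for (eff, effi), cell in df.groupby(["effectiveness", "efficiency"], sort=True):
        x = cell["entropy"].to_numpy()
        boot_means = np.array(
            [x[rng.integers(0, len(x), len(x))].mean() for _ in range(B)]
        )
        lo, hi = np.percentile(boot_means, [2.5, 97.5])
        summary_rows.append(
            {
                "effectiveness": eff,
                "efficiency": effi,
                "n": len(x),
                "mean": float(x.mean()),
                "ci_low": float(lo),
                "ci_high": float(hi),
            }
        )
    out: dict = {"subgroups": pd.DataFrame(summary_rows)}
    cells = df.groupby(["effectiveness", "efficiency"]).size()
    if len(cells) < 4 or cells.min() < 2:
        out["anova"] = None
        out["notice"] = "ANOVA refused: empty or singleton 2x2 cell"
        return out
    model = smf.ols("entropy ~ C(effectiveness) * C(efficiency)", data=df).fit()
    table = anova_lm(model, typ=2)
    ss_error = table.loc["Residual", "sum_sq"]
    table["partial_eta_sq"] = table["sum_sq"] / (table["sum_sq"] + ss_error)
    table.loc["Residual", "partial_eta_sq"] = np.nan
    out["anova"] = table
    return out


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic first-order model over the micro behaviors.

    ``probs`` has one row per source in :data:`SOURCES` and one column
    per target in :data:`TARGETS`.  Rows with no observed transitions and
    no prior are undefined (NaN) and listed in ``undefined_rows``.
    """

    counts: np.ndarray
    probs: np.ndarray
    smoothed: bool = False
    alpha: float = 0.0
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    undefined_rows: tuple[MicroCode, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.probs,
            index=[c.value for c in SOURCES],
            columns=[c.value for c in TARGETS],
        )

    def prob(self, src: MicroCode, tgt: MicroCode) -> float:
        return float(self.probs[_SRC_IDX[src], _TGT_IDX[tgt]])


def count_transitions(sequences: Sequence[Sequence[MicroCode]]) -> np.ndarray:
    """Aggregate consecutive-pair counts; a length-L sequence adds L-1."""
    counts = np.zeros((len(SOURCES), len(TARGETS)))
    for seq in sequences:
        codes = [MicroCode(c) for c in seq]
        for s, t in zip(codes[:-1], codes[1:]):
            counts[_SRC_IDX[s], _TGT_IDX[t]] += 1
    return counts


def _probs_from_counts(
    counts: np.ndarray, prior: "TransitionMatrix | None", alpha: float
) -> np.ndarray:
    """Row-normalize counts, shrinking toward the prior where available."""
    row_sums = counts.sum(axis=1)
    probs = np.full_like(counts, np.nan, dtype=float)
    for i in range(counts.shape[0]):
        prior_row = None if prior is None else prior.probs[i]
        if prior_row is None or np.all(np.isnan(prior_row)) or alpha == 0:
            if row_sums[i] > 0:
                probs[i] = counts[i] / row_sums[i]
        else:
            probs[i] = (counts[i] + alpha * prior_row) / (row_sums[i] + alpha)
    return probs


def estimate_transitions(
    sequences: Sequence[Sequence[MicroCode]],
    prior: TransitionMatrix | None = None,
    alpha: float = 0.5,
) -> TransitionMatrix:
    """Estimate P(t|s), optionally shrunk toward a global prior.

    Without a prior, rows are the maximum-likelihood frequencies.  With a
    prior, each row is the Dirichlet–multinomial posterior mean
    ``(count(s,t) + alpha * prior(t|s)) / (sum_t' count(s,t') + alpha)``,
    i.e. total pseudo-mass ``alpha`` split along the prior row.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    if not sequences:
        raise ValueError("no sequences supplied")
    counts = count_transitions(sequences)
    probs = _probs_from_counts(counts, prior, alpha)
    undefined = [src for i, src in enumerate(SOURCES) if np.all(np.isnan(probs[i]))]
    return TransitionMatrix(
        counts=counts,
        probs=probs,
        smoothed=prior is not None and alpha > 0,
        alpha=alpha if prior is not None else 0.0,
        undefined_rows=tuple(undefined),
    )


@dataclass(frozen=True)
class DeltaMap:
    """Per-cell difference between two subgroup transition matrices."""

    delta: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    significant: np.ndarray  # CI excludes 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.delta, index=[c.value for c in SOURCES], columns=[c.value for c in TARGETS]
        )


def bootstrap_deltas(
    sequences_a: Sequence[Sequence[MicroCode]],
    sequences_b: Sequence[Sequence[MicroCode]],
    prior: TransitionMatrix,
    alpha: float = 0.5,
    B: int = 1000,
    seed: int = 0,
) -> tuple[DeltaMap, TransitionMatrix, TransitionMatrix]:
    """Bootstrap the A-minus-B transition-probability differences.

    Students are resampled with replacement independently within each
    subgroup; the global prior is held fixed across resamples so the
    intervals reflect subgroup sampling variability only.  Returns the
    delta map and the two point-estimate matrices annotated with
    per-cell percentile CIs.
    """
    if len(sequences_a) < 2 or len(sequences_b) < 2:
        raise ValueError("each subgroup needs at least 2 sequences")
    rng = np.random.default_rng(seed)
    point_a = estimate_transitions(sequences_a, prior=prior, alpha=alpha)
    point_b = estimate_transitions(sequences_b, prior=prior, alpha=alpha)
    # per-student count matrices once; a resample is then just a sum
    stud_a = np.stack([count_transitions([s]) for s in sequences_a])
    stud_b = np.stack([count_transitions([s]) for s in sequences_b])
    boots_a = np.empty((B, len(SOURCES), len(TARGETS)))
    boots_b = np.empty_like(boots_a)
    for b in range(B):
        counts_a = stud_a[rng.integers(0, len(stud_a), len(stud_a))].sum(axis=0)
        counts_b = stud_b[rng.integers(0, len(stud_b), len(stud_b))].sum(axis=0)
        boots_a[b] = _probs_from_counts(counts_a, prior, alpha)
        boots_b[b] = _probs_from_counts(counts_b, prior, alpha)
    deltas = boots_a - boots_b
    with warnings.catch_warnings():
        # rows that are structurally undefined (no data, no prior) are
        # all-NaN across resamples; their CIs are NaN by design
        warnings.filterwarnings("ignore", message="All-NaN slice", category=RuntimeWarning)
        lo, hi = np.nanpercentile(deltas, [2.5, 97.5], axis=0)
        a_lo, a_hi = np.nanpercentile(boots_a, [2.5, 97.5], axis=0)
        b_lo, b_hi = np.nanpercentile(boots_b, [2.5, 97.5], axis=0)
    delta_point = point_a.probs - point_b.probs
    significant = (lo > 0) | (hi < 0)
    significant &= ~np.isnan(delta_point)
    mat_a = TransitionMatrix(
        counts=point_a.counts, probs=point_a.probs, smoothed=point_a.smoothed,
        alpha=point_a.alpha, ci_low=a_lo, ci_high=a_hi, undefined_rows=point_a.undefined_rows,
    )
    mat_b = TransitionMatrix(
        counts=point_b.counts, probs=point_b.probs, smoothed=point_b.smoothed,
        alpha=point_b.alpha, ci_low=b_lo, ci_high=b_hi, undefined_rows=point_b.undefined_rows,
    )
    return DeltaMap(delta=delta_point, ci_low=lo, ci_high=hi, significant=significant), mat_a, mat_b


def build_process_graph(
    matrix: TransitionMatrix,
    threshold: float = 0.30,
    comparison: DeltaMap | None = None,
) -> nx.DiGraph:
    """Directed process model keeping only edges with Pr >= threshold.

    Nodes are the behavior codes; edge weights are transition
    probabilities.  With a ``comparison`` delta map, significant cells
    color the edge green (more prominent in subgroup A) or red (more
    prominent in subgroup B).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    graph = nx.DiGraph()
    for code in MICRO_ORDER:
        graph.add_node(code.value)
    for i, src in enumerate(SOURCES):
        for j, tgt in enumerate(TARGETS):
            p = matrix.probs[i, j]
            if np.isnan(p) or p < threshold:
                continue
            attrs = {"weight": round(float(p), 4)}
            if comparison is not None and comparison.significant[i, j]:
                attrs["color"] = "green" if comparison.delta[i, j] > 0 else "red"
            graph.add_edge(src.value, tgt.value, **attrs)
    return graph


def graph_to_dot(graph: nx.DiGraph) -> str:
    lines = ["digraph process {"]
    for node in sorted(graph.nodes):
        lines.append(f'  "{node}";')
    for src, tgt, data in sorted(graph.edges(data=True)):
        attrs = [f'label="{data["weight"]:.2f}"', f'weight="{data["weight"]}"']
        if "color" in data:
            attrs.append(f'color="{data["color"]}"')
        lines.append(f'  "{src}" -> "{tgt}" [{", ".join(attrs)}];')
    lines.append("}")
    return "\n".join(lines)


def graph_from_dot(text: str) -> nx.DiGraph:
    """Parse the DOT dialect written by :func:`graph_to_dot`."""
    import re

    graph = nx.DiGraph()
    for line in text.splitlines():
        line = line.strip().rstrip(";")
        edge = re.match(r'"(.+)" -> "(.+)" \[(.*)\]', line)
        if edge:
            src, tgt, attr_text = edge.groups()
            attrs = dict(re.findall(r'(\w+)="([^"]*)"', attr_text))
            data = {"weight": float(attrs["weight"])}
            if "color" in attrs:
                data["color"] = attrs["color"]
            graph.add_edge(src, tgt, **data)
            continue
        node = re.match(r'"(.+)"$', line)
        if node:
            graph.add_node(node.group(1))
    return graph


def graph_to_json(graph: nx.DiGraph) -> dict:
    return {
        "nodes": sorted(graph.nodes),
        "edges": [
            {"source": s, "target": t, **d} for s, t, d in sorted(graph.edges(data=True))
        ],
    }


def graph_from_json(data: dict) -> nx.DiGraph:
    graph = nx.DiGraph()
    graph.add_nodes_from(data["nodes"])
    for edge in data["edges"]:
        attrs = {k: v for k, v in edge.items() if k not in ("source", "target")}
        graph.add_edge(edge["source"], edge["target"], **attrs)
    return graph
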