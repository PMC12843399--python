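"""Macro-level analytics: behavior rates, state distributions, pattern mining.

Three complementary views of the six-category macro sequences:

* **Rate comparison** — per-behavior Poisson GLMs with a log link, a group
  indicator, and log sequence length as exposure offset, so counts are
  modeled as rates per step.  Wald CIs use HC3 sandwich standard errors
  and p-values are Benjamini–Hochberg adjusted across behaviors.
* **State distributions** — the cross-sectional distribution of macro
  states at each sequence position, with short sequences padded by a
  BLANK filler state (the classic sequence-distribution plot).
* **Frequent subsequence mining** — SPADE-style enumeration of
  order-preserving, gap-tolerant subsequences of length 2..max_len whose
  support (share of a group's students containing the pattern, counted at
  most once per student) reaches the threshold in at least one group,
  with Wilson score CIs, two-proportion z tests and BH adjustment.

The six-state alphabet and the short maximum length make exhaustive
level-wise enumeration with anti-monotone pruning sufficient; no ID-list
machinery is needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

from .coding import MACRO_ORDER, MacroCode

__all__ = [
    "BLANK",
    "rate_comparison",
    "state_distribution",
    "plot_state_distribution",
    "contains_subsequence",
    "mine_patterns",
    "compare_pattern_support",
]

BLANK = "BLANK"


def _counts_frame(
    sequences: Sequence[Sequence[MacroCode]], groups: Sequence[str]
) -> pd.DataFrame:
    rows = []
    for seq, grp in zip(sequences, groups):
        counts = {code.value: 0 for code in MACRO_ORDER}
        for code in seq:
            counts[MacroCode(code).value] += 1
        rows.append({"group": grp, "length": len(seq), **counts})
    return pd.DataFrame(rows)


def rate_comparison(
    sequences: Sequence[Sequence[MacroCode]],
    groups: Sequence[str],
    reference: str | None = None,
    alpha_fdr: float = 0.05,
) -> pd.DataFrame:
    """Offset Poisson GLM of per-student behavior counts on group.

    ``reference`` names the baseline group (default: lexicographically
    first); IRRs are exposure-adjusted rates of the other group relative
    to it.  Behaviors with zero count variance (START, END by
    construction) or absent everywhere are skipped; a behavior absent in
    exactly one group is fitted but flagged, since its IRR sits on the
    boundary.
    """
    if len(sequences) != len(groups):
        raise ValueError("sequences and groups must align")
    frame = _counts_frame(sequences, groups)
    labels = sorted(frame["group"].unique())
    if len(labels) != 2:
        raise ValueError("rate comparison requires exactly two groups")
    if reference is None:
        reference = labels[0]
    other = [g for g in labels if g != reference][0]
    if frame.groupby("group").size().min() < 2:
        raise ValueError("each group needs at least 2 students")
    indicator = (frame["group"] == other).astype(float)
    offset = np.log(frame["length"].to_numpy(float))
    results = []
    for code in MACRO_ORDER:
        counts = frame[code.value].to_numpy(float)
        if counts.sum() == 0:
            results.append({"behavior": code.value, "skipped": "absent in both groups"})
            continue
        if np.var(counts) == 0:
            results.append({"behavior": code.value, "skipped": "zero variance in counts"})
            continue
        warning = ""
        if frame.groupby("group")[code.value].sum().min() == 0:
            warning = "separation: behavior absent in one group; IRR is a boundary estimate"
        X = sm.add_constant(indicator.to_numpy())
        fit = sm.GLM(counts, X, family=sm.families.Poisson(), offset=offset).fit(cov_type="HC3")
        coef, se = fit.params[1], fit.bse[1]
        lo, hi = fit.conf_int()[1]
        results.append(
            {
                "behavior": code.value,
                "IRR": float(np.exp(coef)),
                "ci_low": float(np.exp(lo)),
                "ci_high": float(np.exp(hi)),
                "p_raw": float(fit.pvalues[1]),
                "warning": warning,
                "skipped": "",
            }
        )
    out = pd.DataFrame(results)
    tested = out["skipped"] == "" if "skipped" in out else pd.Series(True, index=out.index)
    if tested.any():
        adj = multipletests(out.loc[tested, "p_raw"], alpha=alpha_fdr, method="fdr_bh")[1]
        out.loc[tested, "p_fdr"] = adj
    out.attrs["reference"] = reference
    out.attrs["comparison"] = other
    return out


def state_distribution(sequences: Sequence[Sequence[MacroCode]]) -> pd.DataFrame:
    """Per-position state proportions over the 6 macro states + BLANK.

    Sequences are right-padded with BLANK to the cohort maximum length;
    every column of the result sums to 1.
    """
    if not sequences:
        raise ValueError("no sequences supplied")
    max_len = max(len(s) for s in sequences)
    states = [code.value for code in MACRO_ORDER] + [BLANK]
    matrix = np.zeros((len(states), max_len))
    index = {s: i for i, s in enumerate(states)}
    for seq in sequences:
        for pos in range(max_len):
            state = MacroCode(seq[pos]).value if pos < len(seq) else BLANK
            matrix[index[state], pos] += 1
    matrix /= len(sequences)
    return pd.DataFrame(matrix, index=states, columns=[f"pos{p + 1}" for p in range(max_len)])


_STATE_COLORS = {
    "START": "#9e9e9e",
    "DESIGN": "#4878cf",
    "CONDUCT": "#6acc65",
    "ANSWER": "#d65f5f",
    "MANAGE": "#b47cc7",
    "END": "#555555",
    BLANK: "#eeeeee",
}


def plot_state_distribution(dist: pd.DataFrame, ax=None, title: str | None = None):
    """Stacked-area rendering of a state-distribution matrix."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    positions = np.arange(1, dist.shape[1] + 1)
    colors = [_STATE_COLORS.get(s, "#000000") for s in dist.index]
    ax.stackplot(positions, dist.to_numpy(), labels=list(dist.index), colors=colors)
    ax.set_xlim(1, positions[-1])
    ax.set_ylim(0, 1)
    ax.set_xlabel("sequence position")
    ax.set_ylabel("proportion of students")
    if title:
        ax.set_title(title)
    ax.legend(loc="upper right", fontsize=8)
    return ax


def contains_subsequence(sequence: Sequence, pattern: Sequence) -> bool:
    """Order-preserving containment with unlimited gaps (greedy scan)."""
    it = iter(sequence)
    return all(any(x == p for x in it) for p in pattern)


def _support_counts(
    pattern: tuple, sequences_by_group: Mapping[str, Sequence[Sequence]]
) -> dict[str, int]:
    return {
        grp: sum(contains_subsequence(seq, pattern) for seq in seqs)
        for grp, seqs in sequences_by_group.items()
    }


def mine_patterns(
    sequences_by_group: Mapping[str, Sequence[Sequence[MacroCode]]],
    min_support: float = 0.30,
    max_len: int = 4,
    alpha_fdr: float = 0.05,
) -> pd.DataFrame:
    """Mine frequent macro subsequences and test group differences.

    Candidates are subsequences (length 2..max_len, gaps allowed) whose
    support reaches ``min_support`` in at least one group; anti-monotone
    pruning extends only patterns that are themselves frequent somewhere.
    Each candidate gets per-group supports with Wilson 95% CIs, a pooled
    two-proportion z test, and BH-adjusted p over the whole candidate
    set; ``retained`` marks the support rule plus ``p_fdr < alpha_fdr``.
    """
    if not 0 < min_support <= 1:
        raise ValueError("min_support must be in (0, 1]; 0 is refused")
    if max_len < 2:
        raise ValueError("max_len must be >= 2")
    groups = list(sequences_by_group)
    if len(groups) != 2:
        raise ValueError("pattern mining compares exactly two groups")
    sizes = {g: len(sequences_by_group[g]) for g in groups}
    if min(sizes.values()) == 0:
        raise ValueError("both groups need at least one sequence")
    normalized = {
        g: [tuple(MacroCode(c).value for c in seq) for seq in seqs]
        for g, seqs in sequences_by_group.items()
    }
    alphabet = [code.value for code in MACRO_ORDER]

    def frequent(pattern: tuple) -> tuple[bool, dict[str, int]]:
        counts = _support_counts(pattern, normalized)
        ok = any(counts[g] / sizes[g] >= min_support for g in groups)
        return ok, counts

    frontier = [(c,) for c in alphabet if frequent((c,))[0]]
    candidates: list[tuple[tuple, dict[str, int]]] = []
    for _ in range(2, max_len + 1):
        next_frontier = []
        for pattern in frontier:
            for symbol in alphabet:
                extended = pattern + (symbol,)
                ok, counts = frequent(extended)
                if ok:
                    next_frontier.append(extended)
                    candidates.append((extended, counts))
        frontier = next_frontier
        if not frontier:
            break

    rows = []
    for pattern, counts in candidates:
        stats_ab = compare_pattern_support(
            counts[groups[0]], sizes[groups[0]], counts[groups[1]], sizes[groups[1]]
        )
        row = {"pattern": "<" + ", ".join(pattern) + ">", "length": len(pattern)}
        for g in groups:
            support = counts[g] / sizes[g]
            lo, hi = _wilson(counts[g], sizes[g])
            row[f"count_{g}"] = counts[g]
            row[f"support_{g}"] = support
            row[f"wilson_low_{g}"] = float(lo)
            row[f"wilson_high_{g}"] = float(hi)
        row["z"] = stats_ab["z"]
        row["p_raw"] = stats_ab["p"]
        rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["p_fdr"] = multipletests(out["p_raw"], alpha=alpha_fdr, method="fdr_bh")[1]
    out["retained"] = out["p_fdr"] < alpha_fdr
    out.attrs["groups"] = groups
    out.attrs["min_support"] = min_support
    return out


def _wilson(count: int, n: int) -> tuple[float, float]:
    """Wilson 95% score interval, clamped to bracket the point estimate.

    The analytic interval always contains count/n; clamping removes the
    ~1e-17 floating-point spill statsmodels can produce at the boundaries.
    """
    lo, hi = proportion_confint(count, n, alpha=0.05, method="wilson")
    p = count / n
    return float(min(max(0.0, lo), p)), float(max(min(1.0, hi), p))


def compare_pattern_support(count_a: int, n_a: int, count_b: int, n_b: int) -> dict:
    """Supports, Wilson 95% CIs, and the pooled two-proportion z test."""
    for count, n in ((count_a, n_a), (count_b, n_b)):
        if n < 1:
            raise ValueError("group size must be >= 1")
        if not 0 <= count <= n:
            raise ValueError("count must lie in [0, n]")
    p_a, p_b = count_a / n_a, count_b / n_b
    wilson_a = _wilson(count_a, n_a)
    wilson_b = _wilson(count_b, n_b)
    pooled = (count_a + count_b) / (n_a + n_b)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n_a + 1 / n_b))
    if se == 0:
        z, p = 0.0, 1.0
    else:
        z = (p_a - p_b) / se
        p = 2 * stats.norm.sf(abs(z))
    return {
        "support_a": p_a,
        "support_b": p_b,
        "wilson_a": (float(wilson_a[0]), float(wilson_a[1])),
        "wilson_b": (float(wilson_b[0]), float(wilson_b[1])),
        "z": float(z),
        "p": float(p),
    }
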