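"""Performance subgrouping: effectiveness x latent efficiency profiles.

Students are crossed on two performance dimensions.  *Effectiveness* is
dichotomous task correctness (did the final answer name the unique
constrained optimum).  *Efficiency* is a latent profile obtained by
fitting univariate Gaussian mixtures to task completion time (seconds)
within each effectiveness group: models with K = 1..K_max components are
fitted by EM and the minimum-BIC model selected; students are assigned to
the component with the largest posterior responsibility, and the
smaller-mean ("faster") component is labeled Efficient.

The behavioral plausibility of the split is checked with PDR — the
proportion of Adjust Diameter -> Run Trial transitions in a student's
micro sequence — via a regression of PDR on standardized log completion
time and task correctness, plus quantile-based sensitivity splits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.mixture import GaussianMixture

from .coding import CodedSequence, MicroCode
from .task_model import AnswerTriple, OutcomeTable, score_answer

__all__ = [
    "GMMFit",
    "EfficiencyResult",
    "classify_effectiveness",
    "fit_efficiency_profiles",
    "compute_pdr",
    "pdr_regression",
    "sensitivity_split",
    "assign_subgroups",
]

EFFECTIVE = "Effective"
INEFFECTIVE = "Ineffective"
EFFICIENT = "Efficient"
INEFFICIENT = "Inefficient"


@dataclass(frozen=True)
class GMMFit:
    """One fitted univariate mixture, components ordered by mean."""

    K: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    log_likelihood: float
    bic: float
    aic: float
    posteriors: np.ndarray  # (n_students, K), rows sum to 1

    @property
    def mean_max_posterior(self) -> float:
        return float(self.posteriors.max(axis=1).mean())

    @property
    def n_parameters(self) -> int:
        return 3 * self.K - 1


@dataclass(frozen=True)
class EfficiencyResult:
    fits: dict[int, GMMFit]
    selected_K: int
    labels: tuple[str, ...]       # Efficient / Inefficient per student
    components: np.ndarray        # max-posterior component index per student
    posteriors: np.ndarray        # max posterior per student

    @property
    def selected(self) -> GMMFit:
        return self.fits[self.selected_K]

    def selection_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"K": k, "logL": f.log_likelihood, "AIC": f.aic, "BIC": f.bic}
                for k, f in sorted(self.fits.items())
            ]
        )


def classify_effectiveness(
    answers: Mapping[str, AnswerTriple], table: OutcomeTable | None = None
) -> dict[str, str]:
    """Effective iff the student's final answer scores 1."""
    if table is None:
        table = OutcomeTable()
    return {
        sid: EFFECTIVE if score_answer(table, ans) == 1 else INEFFECTIVE
        for sid, ans in answers.items()
    }


def _fit_one_gmm(
    x: np.ndarray,
    K: int,
    seed: int,
    reg_covar: float,
    previous: "GMMFit | None" = None,
) -> GMMFit:
    """EM fit for one K, best of quantile-based and nested initialization.

    Nesting the (K-1)-component solution (plus a small extra component at
    the upper tail) keeps the fitted log-likelihood non-decreasing in K.
    """
    n = len(x)
    var = float(np.var(x))
    quantiles = (np.arange(K) + 0.5) / K
    inits = [
        (
            np.quantile(x, quantiles).reshape(-1, 1),
            np.full(K, 1.0 / K),
            np.full((K, 1, 1), 1.0 / var),
        )
    ]
    if previous is not None:
        eps = 0.02
        means = np.append(previous.means, np.quantile(x, 0.98)).reshape(-1, 1)
        weights = np.append(previous.weights * (1 - eps), eps)
        precisions = 1.0 / np.append(previous.sds**2, var).reshape(-1, 1, 1)
        inits.append((means, weights / weights.sum(), precisions))

    last_error: Exception | None = None
    rng = np.random.default_rng(seed)
    best: GMMFit | None = None
    for base_means, base_weights, base_precisions in inits:
        for attempt in range(4):
            init = base_means
            if attempt:  # bounded retries with jittered means
                init = base_means + rng.normal(scale=np.sqrt(var) / 10, size=(K, 1))
            try:
                gm = GaussianMixture(
                    n_components=K,
                    covariance_type="full",
                    reg_covar=reg_covar,
                    means_init=init,
                    weights_init=base_weights,
                    precisions_init=base_precisions,
                    max_iter=500,
                    random_state=seed,
                )
                gm.fit(x.reshape(-1, 1))
                if not gm.converged_ and gm.n_iter_ >= 500:
                    raise RuntimeError("EM did not converge")
                order = np.argsort(gm.means_.ravel())
                post = gm.predict_proba(x.reshape(-1, 1))[:, order]
                fit = GMMFit(
                    K=K,
                    weights=gm.weights_[order],
                    means=gm.means_.ravel()[order],
                    sds=np.sqrt(gm.covariances_.reshape(K)[order]),
                    log_likelihood=float(gm.score(x.reshape(-1, 1)) * n),
                    bic=float(gm.bic(x.reshape(-1, 1))),
                    aic=float(gm.aic(x.reshape(-1, 1))),
                    posteriors=post,
                )
                if best is None or fit.log_likelihood > best.log_likelihood:
                    best = fit
                break
            except Exception as exc:  # degenerate EM: retry with jitter
                last_error = exc
    if best is None:
        raise RuntimeError(f"EM failed for K={K} after retries: {last_error}")
    return best


def fit_efficiency_profiles(
    times: Sequence[float], K_max: int = 4, seed: int = 0
) -> EfficiencyResult:
    """Fit GMMs with K = 1..K_max to completion times; select by min BIC.

    Times enter in raw seconds.  The regularization floor scales with the
    sample variance, so relabeling the time unit (seconds vs minutes)
    leaves assignments unchanged.
    """
    x = np.asarray(times, dtype=float)
    if np.any(x <= 0):
        raise ValueError("completion times must be positive")
    if len(x) <= K_max:
        raise ValueError(f"need more than K_max={K_max} observations")
    if np.var(x) == 0:
        raise ValueError("degenerate input: all completion times identical")
    reg_covar = 1e-6 * float(np.var(x))
    fits: dict[int, GMMFit] = {}
    previous = None
    for K in range(1, K_max + 1):
        fits[K] = _fit_one_gmm(x, K, seed, reg_covar, previous=previous)
        previous = fits[K]
    selected_K = min(fits, key=lambda k: fits[k].bic)
    best = fits[selected_K]
    components = best.posteriors.argmax(axis=1)
    max_post = best.posteriors.max(axis=1)
    # the smallest-mean ("fastest") component is the Efficient profile
    labels = tuple(EFFICIENT if c == 0 else INEFFICIENT for c in components)
    return EfficiencyResult(
        fits=fits,
        selected_K=selected_K,
        labels=labels,
        components=components,
        posteriors=max_post,
    )


def compute_pdr(micro: Sequence[MicroCode]) -> float:
    """Share of consecutive pairs that are Adjust Diameter -> Run Trial."""
    if len(micro) < 2:
        raise ValueError("PDR undefined for sequences shorter than 2")
    pairs = list(zip(micro[:-1], micro[1:]))
    hits = sum(
        1 for a, b in pairs if a == MicroCode.ADJUST_DIAMETER and b == MicroCode.RUN_TRIAL
    )
    return hits / len(pairs)


def pdr_regression(
    pdr: Sequence[float], times: Sequence[float], correctness: Sequence[int]
) -> dict:
    """OLS of PDR on z-scored log completion time and a correctness flag."""
    pdr = np.asarray(pdr, float)
    times = np.asarray(times, float)
    correctness = np.asarray(correctness, float)
    if len(pdr) < 10:
        raise ValueError("need at least 10 students")
    log_t = np.log(times)
    if np.std(log_t) == 0 or np.std(correctness) == 0:
        raise ValueError("constant predictor")
    z_log_t = (log_t - log_t.mean()) / log_t.std(ddof=0)
    X = sm.add_constant(np.column_stack([z_log_t, correctness]))
    fit = sm.OLS(pdr, X).fit()
    return {
        "slope_log_time": float(fit.params[1]),
        "p_log_time": float(fit.pvalues[1]),
        "coef_correct": float(fit.params[2]),
        "p_correct": float(fit.pvalues[2]),
        "r_squared": float(fit.rsquared),
        "model": fit,
    }


def sensitivity_split(times: Sequence[float], method: str = "median") -> list[str]:
    """Quantile-based alternative efficiency labels.

    ``median`` labels the faster half Efficient; ``tertile`` labels the
    fastest third Efficient and the slowest third Inefficient, with the
    middle third labeled ``Middle``.  Values tied with the cut point are
    deterministically assigned to the faster side.
    """
    x = np.asarray(times, float)
    if len(x) < 3:
        raise ValueError("need at least 3 students per group")
    if method == "median":
        cut = np.quantile(x, 0.5)
        return [EFFICIENT if v <= cut else INEFFICIENT for v in x]
    if method == "tertile":
        lo, hi = np.quantile(x, [1 / 3, 2 / 3])
        out = []
        for v in x:
            if v <= lo:
                out.append(EFFICIENT)
            elif v <= hi:
                out.append("Middle")
            else:
                out.append(INEFFICIENT)
        return out
    raise ValueError(f"unknown split method: {method!r}")


def assign_subgroups(
    coded: Sequence[CodedSequence],
    answers: Mapping[str, AnswerTriple],
    table: OutcomeTable | None = None,
    K_max: int = 4,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, EfficiencyResult]]:
    """Full 2x2 assignment: effectiveness, then GMM efficiency per group.

    Returns the assignment table (student_id, effectiveness, efficiency,
    posterior, pdr) and the per-effectiveness-group efficiency fits.
    """
    if table is None:
        table = OutcomeTable()
    effectiveness = classify_effectiveness(answers, table)
    rows = []
    fits: dict[str, EfficiencyResult] = {}
    by_group: dict[str, list[CodedSequence]] = {}
    for seq in coded:
        by_group.setdefault(effectiveness[seq.student_id], []).append(seq)
    for group, seqs in sorted(by_group.items()):
        times = [s.completion_time for s in seqs]
        result = fit_efficiency_profiles(times, K_max=K_max, seed=seed)
        fits[group] = result
        for seq, label, post in zip(seqs, result.labels, result.posteriors):
            rows.append(
                {
                    "student_id": seq.student_id,
                    "effectiveness": group,
                    "efficiency": label,
                    "posterior": float(post),
                    "pdr": compute_pdr(seq.micro),
                }
            )
    frame = pd.DataFrame(rows).sort_values("student_id").reset_index(drop=True)
    return frame, fits
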