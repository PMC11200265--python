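"""Ranking, early-recognition and significance machinery for screen evaluation.

Conventions, pinned because every one of them has competing dialects:

* ``pr_auc`` is average precision (mean of precision at the rank of each
  active; no trapezoidal interpolation). Ranking is by descending score with
  ties broken by stable input order.
* ``delta_pr_auc`` subtracts the random-guess baseline, i.e. the prevalence
  of actives in the evaluated set, so 0 means "no better than random".
* ``roc_auc`` uses the Mann-Whitney identity with ties counted 1/2.
* ``bedroc`` is the Boltzmann-enhanced discrimination of ROC of Truchon &
  Bayly: an exponentially rank-weighted enrichment in [0, 1], alpha = 20 by
  default (weight concentrated on roughly the top 1/alpha of the ranking).
* Nonparametric tests switch from exact enumeration to the normal
  approximation above n = 12 paired differences / per-group observations.
* Aggregation follows the replicate protocol: average over replicates within
  each task first, then mean and SD across tasks ("mean of means").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    DegenerateInputError,
    DegenerateLabelError,
    DegenerateScreenError,
    ProtocolError,
)

DEFAULT_BEDROC_ALPHA = 20.0
EXACT_TEST_MAX_N = 12


@dataclass(frozen=True)
class TaskResult:
    """Metrics of one task in one replicate."""

    task_id: str
    replicate: int
    pr_auc: float
    delta_pr_auc: float
    roc_auc: float


@dataclass(frozen=True)
class RankedScreen:
    """A scored screen: per-compound scores and 0/1 activity labels."""

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        scores = np.asarray(self.scores, dtype=np.float64)
        labels = np.asarray(self.labels, dtype=np.int64)
        if scores.shape != labels.shape or scores.ndim != 1:
            raise ValueError("scores and labels must be equal-length 1-D arrays")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "labels", labels)

    @property
    def N(self) -> int:
        return self.labels.size

    @property
    def n_actives(self) -> int:
        return int(self.labels.sum())

    @property
    def Ra(self) -> float:
        return self.n_actives / self.N


def _check_two_classes(labels: np.ndarray) -> None:
    if np.unique(labels).size < 2:
        raise DegenerateLabelError("labels contain a single class")


def _descending_order(scores: np.ndarray) -> np.ndarray:
    # stable: ties keep input order
    return np.argsort(-np.asarray(scores, dtype=np.float64), kind="stable")


def pr_auc(labels, scores) -> float:
    """Average precision of the descending-score ranking (stable ties)."""
    labels = np.asarray(labels, dtype=np.int64)
    scores = np.asarray(scores, dtype=np.float64)
    _check_two_classes(labels)
    ranked = labels[_descending_order(scores)]
    hits = np.cumsum(ranked)
    ranks = np.arange(1, labels.size + 1)
    precision_at_rank = hits / ranks
    return float(precision_at_rank[ranked == 1].sum() / ranked.sum())


def delta_pr_auc(labels, scores) -> float:
    """Average precision minus the active prevalence (random baseline)."""
    labels = np.asarray(labels, dtype=np.int64)
    return pr_auc(labels, scores) - float(labels.mean())


def roc_auc(labels, scores) -> float:
    """P(random active outranks random inactive), ties counted 1/2."""
    labels = np.asarray(labels, dtype=np.int64)
    scores = np.asarray(scores, dtype=np.float64)
    _check_two_classes(labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = stats.rankdata(scores)  # midranks for ties
    rank_sum_pos = ranks[labels == 1].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def bedroc(screen: RankedScreen, alpha: float = DEFAULT_BEDROC_ALPHA) -> float:
    """Boltzmann-enhanced discrimination of ROC (early recognition, in [0,1]).

    Exponentially weights the rank of each active by exp(-alpha * rank / N)
    and normalizes via the closed-form robust-initial-enhancement scaling so
    a perfect ranking scores exactly 1 and the worst ranking approaches 0.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    N, n = screen.N, screen.n_actives
    if n == 0 or n == N:
        raise DegenerateScreenError(
            f"screen needs both actives and inactives (n={n}, N={N})"
        )
    order = _descending_order(screen.scores)
    ranks = np.flatnonzero(screen.labels[order] == 1) + 1  # 1-based
    Ra = n / N
    s = np.exp(-alpha * ranks / N).sum()
    rie = s / (n * (1.0 / N) * (1.0 - np.exp(-alpha)) / (np.exp(alpha / N) - 1.0))
    factor = Ra * np.sinh(alpha / 2.0) / (
        np.cosh(alpha / 2.0) - np.cosh(alpha / 2.0 - alpha * Ra)
    )
    return float(rie * factor + 1.0 / (1.0 - np.exp(alpha * (1.0 - Ra))))


def recall_curve(labels, scores) -> np.ndarray:
    """Step curve (fraction screened, fraction of actives retrieved).

    Returns an (N+1) x 2 array starting at (0, 0) and ending at (1, 1);
    monotone non-decreasing in both coordinates.
    """
    labels = np.asarray(labels, dtype=np.int64)
    scores = np.asarray(scores, dtype=np.float64)
    n = int(labels.sum())
    if n == 0:
        raise DegenerateScreenError("no actives in the screen")
    ranked = labels[_descending_order(scores)]
    frac_screened = np.arange(0, labels.size + 1) / labels.size
    recall = np.concatenate([[0.0], np.cumsum(ranked) / n])
    return np.column_stack([frac_screened, recall])


# ---------------------------------------------------------------------------
# Significance tests and multiple-testing correction
# ---------------------------------------------------------------------------

def _clean_pair(x, y):
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    return x, y


def wilcoxon_signed_rank(x, y=None) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples (or differences).

    Exact null enumeration for n <= 12 nonzero differences, normal
    approximation above; zero differences are dropped (Wilcoxon's rule).
    """
    x = np.asarray(x, dtype=np.float64)
    d = x if y is None else x - np.asarray(y, dtype=np.float64)
    if d.size < 3:
        raise DegenerateInputError(f"need >= 3 pairs, got {d.size}")
    n_nonzero = int(np.count_nonzero(d))
    method = "exact" if n_nonzero <= EXACT_TEST_MAX_N else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                         method=method, correction=False)
    return float(res.statistic), float(res.pvalue)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration when both groups have <= 12 observations and the pooled
    sample is tie-free; otherwise the tie-corrected normal approximation.
    """
    x, y = _clean_pair(x, y)
    if x.size < 2 or y.size < 2:
        raise DegenerateInputError("need >= 2 observations per group")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = max(x.size, y.size) <= EXACT_TEST_MAX_N and not has_ties
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=False,
    )
    return float(res.statistic), float(res.pvalue)


def welch_t(x, y) -> tuple[float, float]:
    """Two-sided Welch t-test (unequal variances)."""
    x, y = _clean_pair(x, y)
    if x.size < 2 or y.size < 2:
        raise DegenerateInputError("need >= 2 observations per group")
    if np.var(x) == 0 and np.var(y) == 0:
        raise DegenerateInputError("both groups have zero variance")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def pearson(x, y) -> tuple[float, float]:
    """Pearson correlation with its two-sided p-value."""
    x, y = _clean_pair(x, y)
    if x.size < 3:
        raise DegenerateInputError(f"need >= 3 observations, got {x.size}")
    if np.var(x) == 0 or np.var(y) == 0:
        raise DegenerateInputError("zero-variance input to pearson")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    pvals = np.asarray(pvals, dtype=np.float64)
    if pvals.size == 0:
        return pvals.copy()
    if ((pvals < 0) | (pvals > 1)).any() or not np.isfinite(pvals).all():
        raise ValueError("p-values must lie in [0, 1]")
    return np.asarray(stats.false_discovery_control(pvals, method="bh"))


# ---------------------------------------------------------------------------
# Replicate/task aggregation
# ---------------------------------------------------------------------------

def aggregate_tasks(
    results: Sequence[TaskResult],
) -> dict[str, tuple[float, float]]:
    """Mean-of-means aggregation: replicates within task, then across tasks.

    Returns ``{metric: (mean_of_task_means, sd_of_task_means)}`` for pr_auc,
    delta_pr_auc and roc_auc. SD is the population SD across task means
    (a single task therefore reports SD 0). Every task must carry the same
    number of replicates.
    """
    if not results:
        raise ProtocolError("no task results to aggregate")
    df = pd.DataFrame(
        {
            "task_id": [r.task_id for r in results],
            "replicate": [r.replicate for r in results],
            "pr_auc": [r.pr_auc for r in results],
            "delta_pr_auc": [r.delta_pr_auc for r in results],
            "roc_auc": [r.roc_auc for r in results],
        }
    )
    counts = df.groupby("task_id")["replicate"].count()
    if counts.nunique() > 1:
        raise ProtocolError(
            f"ragged replicate counts per task: {counts.to_dict()}"
        )
    task_means = df.groupby("task_id")[["pr_auc", "delta_pr_auc", "roc_auc"]].mean()
    return {
        metric: (float(task_means[metric].mean()), float(task_means[metric].std(ddof=0)))
        for metric in ("pr_auc", "delta_pr_auc", "roc_auc")
    }
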