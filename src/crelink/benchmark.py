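"""CRISPRi benchmarking statistics: precision-recall curve, AUPRC,
percentile bootstrap confidence intervals, the fixed-recall operating
point, and score-vs-effect-size Spearman correlation.

AUPRC is computed by step-wise summation sum_i (R_i - R_{i-1}) * P_i over
descending score thresholds (the average-precision convention; no
interpolation, no monotone precision envelope). Tied scores collapse to a
single threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "PRCurve",
    "BenchmarkResult",
    "pr_auprc",
    "bootstrap_ci",
    "threshold_at_recall",
    "score_effect_spearman",
    "evaluate",
]

logger = logging.getLogger(__name__)

N_BOOTSTRAP = 10_000
RECALL_TARGET = 0.70


@dataclass
class PRCurve:
    thresholds: np.ndarray  # descending unique score values
    precision: np.ndarray
    recall: np.ndarray
    auprc: float


@dataclass
class BenchmarkResult:
    auprc: float
    ci: tuple[float, float]
    threshold_at_recall: float
    precision_at_threshold: float
    n_pos: int
    n_neg: int
    n_boot: int
    seed: int
    recall_target: float = RECALL_TARGET
    spearman_rho: float | None = None
    metadata: dict = field(default_factory=dict)


def _check_binary(labels: np.ndarray) -> None:
    u = np.unique(labels)
    if not (len(u) == 2 and set(u) <= {0, 1}):
        raise ValueError("labels must contain both classes (0 and 1)")


def pr_auprc(scores, labels) -> PRCurve:
    """Precision-recall curve over unique thresholds and its step-wise area."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_binary(labels)
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # collapse ties: evaluate at the last row of each tied block
    distinct = np.nonzero(np.diff(s))[0]
    idx = np.r_[distinct, len(s) - 1]
    tp = np.cumsum(y)[idx].astype(float)
    fp = np.cumsum(1 - y)[idx].astype(float)
    n_pos = labels.sum()
    precision = tp / (tp + fp)
    recall = tp / n_pos
    dr = np.diff(np.r_[0.0, recall])
    auprc = float(np.sum(dr * precision))
    return PRCurve(thresholds=s[idx], precision=precision, recall=recall, auprc=auprc)


def bootstrap_ci(
    scores,
    labels,
    n_boot: int = N_BOOTSTRAP,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI on AUPRC over resampled labeled pairs.

    Pairs are resampled with replacement; replicates that draw a single
    class are redrawn (count logged). Bit-reproducible for a fixed seed.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_binary(labels)
    rng = np.random.default_rng(seed)
    n = len(scores)
    reps = np.empty(n_boot)
    redraws = 0
    for i in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            yb = labels[idx]
            if 0 < yb.sum() < n:
                break
            redraws += 1
        reps[i] = pr_auprc(scores[idx], yb).auprc
    if redraws:
        logger.info("redrew %d single-class bootstrap replicates", redraws)
    low, high = np.percentile(reps, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(low), float(high)


def threshold_at_recall(scores, labels, target_recall: float = RECALL_TARGET):
    """Largest threshold t with recall(score > t) >= target, and the
    precision achieved there.

    Binary calls use strict ``score > t``. The returned t sits just below
    the m-th highest positive score (m = ceil(target * n_pos)), the
    supremum of thresholds meeting the target.
    """
    if not (0 < target_recall <= 1):
        raise ValueError("target_recall must be in (0, 1]")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_binary(labels)
    pos = np.sort(scores[labels == 1])[::-1]
    m = int(np.ceil(target_recall * len(pos)))
    t = float(np.nextafter(pos[m - 1], -np.inf))
    called = scores > t
    tp = int(np.sum(called & (labels == 1)))
    fp = int(np.sum(called & (labels == 0)))
    return t, tp / (tp + fp)


def score_effect_spearman(scores, effects) -> float:
    """Spearman rank correlation between predictor scores and measured
    CRISPRi effect sizes (percent expression change), average-rank ties."""
    scores = np.asarray(scores, dtype=float)
    effects = np.asarray(effects, dtype=float)
    if len(scores) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(scores) == 0 or np.ptp(effects) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho, _ = stats.spearmanr(scores, effects)
    return float(rho)


def evaluate(
    scores,
    labels,
    effects=None,
    n_boot: int = N_BOOTSTRAP,
    target_recall: float = RECALL_TARGET,
    seed: int = 0,
) -> BenchmarkResult:
    """Full benchmark: AUPRC + bootstrap CI + fixed-recall operating point
    (+ Spearman against effect sizes when provided)."""
    labels = np.asarray(labels, dtype=int)
    curve = pr_auprc(scores, labels)
    ci = bootstrap_ci(scores, labels, n_boot=n_boot, seed=seed)
    if not (ci[0] <= curve.auprc <= ci[1]):
        logger.warning("AUPRC %.4f outside bootstrap CI %s", curve.auprc, ci)
    thr, prec = threshold_at_recall(scores, labels, target_recall)
    rho = None
    if effects is not None:
        rho = score_effect_spearman(scores, effects)
    return BenchmarkResult(
        auprc=curve.auprc,
        ci=ci,
        threshold_at_recall=thr,
        precision_at_threshold=prec,
        n_pos=int(labels.sum()),
        n_neg=int(len(labels) - labels.sum()),
        n_boot=n_boot,
        seed=seed,
        recall_target=target_recall,
        spearman_rho=rho,
        metadata={"bootstrap": "full-list resample, single-class replicates redrawn"},
    )
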