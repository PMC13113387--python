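"""Discrimination and clinical-utility metrics.

Implements the empirical (Mann–Whitney) AUC with the tie-aware kernel
phi(X, Y) = 1 if X > Y, 0.5 if X = Y, 0 otherwise; its DeLong
placement-component variance and normal-approximation confidence
interval; Youden-J threshold selection from out-of-fold predictions;
bootstrap confidence intervals for accuracy / recall / F1; and
decision-curve net benefit

    NB(p_t) = TP/N - (FP/N) * p_t / (1 - p_t)

compared against the treat-all and treat-none strategies.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "ScorePair",
    "RocSummary",
    "DecisionCurve",
    "empirical_auc",
    "delong_interval",
    "youden_threshold",
    "classification_metrics",
    "net_benefit",
    "decision_curve",
]

log = logging.getLogger(__name__)


@dataclass
class ScorePair:
    """Prediction scores split by true class: X (positives), Y (negatives)."""

    pos: np.ndarray
    neg: np.ndarray

    def __post_init__(self):
        self.pos = np.asarray(self.pos, dtype=float)
        self.neg = np.asarray(self.neg, dtype=float)
        if self.pos.size < 1 or self.neg.size < 1:
            raise ValueError("both classes must be non-empty")
        if not (np.isfinite(self.pos).all() and np.isfinite(self.neg).all()):
            raise ValueError("scores must be finite")

    @classmethod
    def from_labels(cls, scores, labels) -> "ScorePair":
        scores = np.asarray(scores, dtype=float)
        labels = np.asarray(labels).astype(int)
        return cls(pos=scores[labels == 1], neg=scores[labels == 0])

    @property
    def m(self) -> int:
        return self.pos.size

    @property
    def n(self) -> int:
        return self.neg.size


@dataclass
class RocSummary:
    auc: float
    variance: float
    ci: tuple
    level: float
    threshold_j: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None


@dataclass
class DecisionCurve:
    thresholds: np.ndarray
    net_benefit: dict = field(default_factory=dict)  # model name -> NB array
    treat_all: np.ndarray | None = None
    treat_none: np.ndarray | None = None
    prevalence: float | None = None


def _placements(pair: ScorePair) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample placement values V10_i = mean_j phi(X_i, Y_j) and
    V01_j = mean_i phi(X_i, Y_j), computed via sorted-array counting."""
    xs, ys = pair.pos, pair.neg
    sy = np.sort(ys)
    lo = np.searchsorted(sy, xs, side="left")
    hi = np.searchsorted(sy, xs, side="right")
    v10 = (lo + 0.5 * (hi - lo)) / pair.n
    sx = np.sort(xs)
    lo = np.searchsorted(sx, ys, side="right")
    hi = np.searchsorted(sx, ys, side="left")
    # phi(X, Y) summed over X: count(X > y) + 0.5 * count(X == y)
    v01 = ((pair.m - lo) + 0.5 * (lo - hi)) / pair.m
    return v10, v01


def empirical_auc(pair: ScorePair) -> float:
    """Mean of phi(X_i, Y_j) over all m*n pairs; ties count 0.5."""
    v10, _ = _placements(pair)
    return float(v10.mean())


def delong_interval(pair: ScorePair, level: float = 0.95) -> RocSummary:
    """DeLong structural-components variance and normal CI for the AUC.

    Var(AUC) = s10/m + s01/n with s10, s01 the sample variances of the
    placement values.  The interval is clipped to [0, 1]; a degenerate
    zero variance collapses the CI to a point with a warning.
    """
    if pair.m < 2 or pair.n < 2:
        raise ValueError("need m, n >= 2 for a finite variance estimate")
    v10, v01 = _placements(pair)
    auc = float(v10.mean())
    var = float(v10.var(ddof=1) / pair.m + v01.var(ddof=1) / pair.n)
    if var <= 0:
        warnings.warn("degenerate DeLong variance; CI collapses to a point")
        ci = (max(0.0, min(1.0, auc)),) * 2
        return RocSummary(auc=auc, variance=0.0, ci=ci, level=level)
    z = sps.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    return RocSummary(auc=auc, variance=var, ci=ci, level=level)


def youden_threshold(scores, labels) -> float:
    """Threshold (among unique observed scores) maximizing J = sens + spec - 1.

    The classification rule is ``score >= threshold``; among ties the
    smallest qualifying threshold is returned.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    cand = np.unique(scores)
    # sens(t) = mean(pos >= t); spec(t) = mean(neg < t), vectorized by sorting
    sp = np.sort(pos)
    sn = np.sort(neg)
    sens = 1.0 - np.searchsorted(sp, cand, side="left") / pos.size
    spec = np.searchsorted(sn, cand, side="left") / neg.size
    j = sens + spec - 1.0
    # smallest threshold attaining the maximum, with a float-noise margin
    # so that mathematically tied J values compare as ties
    best = int(np.flatnonzero(j >= j.max() - 1e-9)[0])
    return float(cand[best])


def _point_metrics(scores, labels, threshold):
    calls = np.asarray(scores, dtype=float) >= threshold
    labels = np.asarray(labels).astype(bool)
    tp = int(np.sum(calls & labels))
    fp = int(np.sum(calls & ~labels))
    fn = int(np.sum(~calls & labels))
    tn = int(np.sum(~calls & ~labels))
    acc = (tp + tn) / len(labels)
    recall = tp / (tp + fn) if tp + fn else float("nan")
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * recall / (prec + recall) if (prec + recall) else 0.0
    return {"tp": tp, "fp": fp, "fn": fn, "tn": tn,
            "accuracy": acc, "recall": recall, "f1": f1}


def classification_metrics(
    scores, labels, threshold: float, n_boot: int = 2000, seed: int = 0
) -> dict:
    """Accuracy / recall / F1 with percentile-bootstrap CIs.

    Patients are resampled with replacement; a replicate without any
    positive subject leaves recall undefined and is redrawn (logged).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n = len(labels)
    point = _point_metrics(scores, labels, threshold)
    rng = np.random.default_rng(seed)
    reps = {"accuracy": [], "recall": [], "f1": []}
    redrawn = 0
    for _ in range(n_boot):
        while True:
            idx = rng.integers(0, n, n)
            if labels[idx].sum() > 0:
                break
            redrawn += 1
        m = _point_metrics(scores[idx], labels[idx], threshold)
        for k in reps:
            reps[k].append(m[k])
    if redrawn:
        log.info("redrew %d bootstrap replicates lacking positive subjects", redrawn)
    out = dict(point)
    out["threshold"] = float(threshold)
    out["n_boot"] = n_boot
    for k, vals in reps.items():
        lo, hi = np.percentile(vals, [2.5, 97.5])
        out[f"{k}_ci"] = (float(lo), float(hi))
    return out


def net_benefit(scores, labels, p_t: float) -> float:
    """Net benefit of calling positive at probability threshold ``p_t``."""
    if not 0 <= p_t < 1:
        raise ValueError("p_t must lie in [0, 1)")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n = len(labels)
    calls = scores >= p_t
    tp = float(np.sum(calls & (labels == 1)))
    fp = float(np.sum(calls & (labels == 0)))
    return tp / n - (fp / n) * p_t / (1.0 - p_t)


def decision_curve(models: dict, labels, grid=None) -> DecisionCurve:
    """Net benefit over a threshold grid for each named score set, plus
    the treat-all and treat-none reference strategies."""
    labels = np.asarray(labels).astype(int)
    if grid is None:
        grid = np.round(np.arange(0.0, 0.61, 0.01), 10)
    grid = np.asarray(grid, dtype=float)
    if np.any((grid < 0) | (grid >= 1)):
        raise ValueError("grid thresholds must lie in [0, 1)")
    prev = float(labels.mean())
    nb = {
        name: np.array([net_benefit(s, labels, t) for t in grid])
        for name, s in models.items()
    }
    treat_all = prev - (1 - prev) * grid / (1 - grid)
    return DecisionCurve(
        thresholds=grid,
        net_benefit=nb,
        treat_all=treat_all,
        treat_none=np.zeros_like(grid),
        prevalence=prev,
    )
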