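"""Sequential score-cutoff reduction of a risk equation.

Terms whose integer presentation score (round(w * scale), the same scale
used in the printed score tables) falls below a cut-off are pruned;
scanning a grid of cut-offs while tracking out-of-fold validation AUC
locates the most compact equation that preserves discrimination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .encoding import BinaryDesign
from .engine import _fit_logistic
from .evaluation import ScorePair, empirical_auc
from .model import RiskEquation

__all__ = ["ReductionTrace", "apply_cutoff", "reduction_trace", "select_cutoff"]


@dataclass
class ReductionTrace:
    cutoffs: list           # ordered cut-off values
    sizes: list             # surviving |S| per cut-off
    aucs: list              # validation AUC per cut-off
    equations: list         # surviving RiskEquation per cut-off

    def __post_init__(self):
        order = np.argsort(self.cutoffs)
        sizes = np.asarray(self.sizes)[order]
        if np.any(np.diff(sizes) > 0):
            raise ValueError("surviving count must be non-increasing in cut-off")


def apply_cutoff(
    eq: RiskEquation,
    cutoff: float,
    refit: bool = True,
    design: BinaryDesign | None = None,
    scale: float = 100.0,
    ridge: float = 1e-4,
) -> RiskEquation:
    """Keep terms with presentation score round(w * scale) >= cutoff.

    With ``refit`` set, weights and bias are refit on the training rows
    of ``design`` over the surviving set; otherwise the parent's weights
    are carried over unchanged.  An empty surviving set yields a
    bias-only equation (with a warning).
    """
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    keep = [i for i, (_, w) in enumerate(eq.terms) if round(w * scale) >= cutoff]
    if not keep:
        warnings.warn("cut-off removed every term; returning bias-only equation")
    sub = eq.subset(keep)
    sub.provenance = dict(eq.provenance, cutoff=float(cutoff), scale=float(scale))
    if refit:
        if design is None:
            raise ValueError("refit requires a design")
        names = [c.name for c in sub.conditions]
        mask = design.train_mask
        X = design.X.loc[:, names].to_numpy(dtype=float)[mask]
        w, b, _ = _fit_logistic(X, design.y[mask], ridge)
        sub.terms = [(c, float(wi)) for (c, _), wi in zip(sub.terms, w)]
        sub.bias = b
    return sub


def _validation_auc(eq: RiskEquation, design: BinaryDesign, refit: bool, ridge: float):
    """Cross-validated AUC on the training portion.

    With refitting, weights are refit per CV fold and the fold-wise
    out-of-fold AUCs are averaged (fold-wise, not pooled, so that
    fold-specific intercepts cannot scramble the cross-fold ranking of
    a coarse-grained score).  Without refitting the fixed equation is
    scored once on all training rows.
    """
    mask = design.train_mask
    names = [c.name for c in eq.conditions]
    X = design.X.loc[:, names].to_numpy(dtype=float)[mask]
    y = design.y[mask]
    if not refit or design.fold is None:
        r = X @ eq.weights + eq.bias
        return empirical_auc(ScorePair.from_labels(r, y))
    fold = np.asarray(design.fold)[mask]
    aucs = []
    for f in sorted(set(fold)):
        tr = fold != f
        w, b, _ = _fit_logistic(X[tr], y[tr], ridge)
        r = X[~tr] @ w + b
        aucs.append(empirical_auc(ScorePair.from_labels(r, y[~tr])))
    return float(np.mean(aucs))


def reduction_trace(
    eq: RiskEquation,
    design: BinaryDesign,
    cutoffs,
    scale: float = 100.0,
    refit: bool = True,
    ridge: float = 1e-4,
) -> ReductionTrace:
    """One trace row per cut-off: surviving size and validation AUC.

    Validation predictions are out-of-fold over the training CV folds
    (the held-out test split is never touched).
    """
    cutoffs = list(cutoffs)
    sizes, aucs, eqs = [], [], []
    for c in sorted(cutoffs):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sub = apply_cutoff(eq, c, refit=refit, design=design, scale=scale, ridge=ridge)
        if len(sub) == 0:
            auc = 0.5  # constant score: every pair ties
        else:
            auc = _validation_auc(sub, design, refit, ridge)
        sizes.append(len(sub))
        aucs.append(float(auc))
        eqs.append(sub)
    return ReductionTrace(cutoffs=sorted(cutoffs), sizes=sizes, aucs=aucs, equations=eqs)


def select_cutoff(trace: ReductionTrace) -> tuple[float, float]:
    """Cut-off maximizing validation AUC; ties break toward the larger
    cut-off (the smaller model).  Returns (cutoff, auc)."""
    if not trace.cutoffs:
        raise ValueError("empty trace")
    best_c, best_a = None, -np.inf
    for c, a in zip(trace.cutoffs, trace.aucs):
        if a > best_a or (a == best_a and (best_c is None or c > best_c)):
            best_c, best_a = c, a
    return float(best_c), float(best_a)
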