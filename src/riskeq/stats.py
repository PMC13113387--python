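"""Univariate screening: two-sample t-tests and chi-square tests.

The Welch (unequal-variance) t-test is computable either from raw data
or from printed group summaries (mean, SD, n per group), so published
baseline tables can be re-checked without patient-level data.
Categorical variables are screened with the Pearson chi-square test
(continuity correction optional).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .encoding import CleanTable

__all__ = [
    "GroupSummary",
    "Contingency2x2",
    "welch_t_from_summary",
    "welch_t",
    "chi2_2x2",
    "screen",
]


@dataclass(frozen=True)
class GroupSummary:
    """Per-group mean, standard deviation and size for two groups."""

    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int

    def __post_init__(self):
        if self.sd1 < 0 or self.sd2 < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("each group needs n >= 2")

    @classmethod
    def from_raw(cls, x1, x2) -> "GroupSummary":
        x1 = np.asarray(x1, dtype=float)
        x2 = np.asarray(x2, dtype=float)
        return cls(
            mean1=float(x1.mean()), sd1=float(x1.std(ddof=1)), n1=len(x1),
            mean2=float(x2.mean()), sd2=float(x2.std(ddof=1)), n2=len(x2),
        )


@dataclass(frozen=True)
class Contingency2x2:
    """2x2 counts; rows are outcome groups, columns are categories."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be >= 0")

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def welch_t_from_summary(s: GroupSummary) -> tuple[float, float, float]:
    """Welch t statistic, Welch–Satterthwaite df and two-sided p from
    group summaries.  Two identical degenerate groups give t=0, p=1."""
    se1 = s.sd1**2 / s.n1
    se2 = s.sd2**2 / s.n2
    se = se1 + se2
    if se == 0:
        df = s.n1 + s.n2 - 2
        if s.mean1 == s.mean2:
            return 0.0, float(df), 1.0
        return float("inf"), float(df), 0.0
    t = (s.mean1 - s.mean2) / np.sqrt(se)
    df = se**2 / (se1**2 / (s.n1 - 1) + se2**2 / (s.n2 - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def welch_t(x1, x2) -> tuple[float, float, float]:
    """Welch t-test from raw samples (equivalent to the summary form)."""
    return welch_t_from_summary(GroupSummary.from_raw(x1, x2))


def chi2_2x2(table, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, 1 df, optional Yates correction.

    A zero row or column margin is an error.
    """
    if isinstance(table, Contingency2x2):
        tab = table.table
    else:
        tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(tab < 0):
        raise ValueError("counts must be >= 0")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise ValueError("a margin of the 2x2 table is zero")
    res = sps.chi2_contingency(tab, correction=yates)
    return float(res.statistic), float(res.pvalue)


def screen(clean: CleanTable, schemas: dict | None = None, alpha: float = 0.05) -> pd.DataFrame:
    """Per-variable univariate screening against the binary outcome.

    Continuous variables get a Welch t-test between outcome groups;
    categorical (ordinal / nominal / binary) variables get a Pearson
    chi-square test on the outcome x category contingency table.
    Returns one row per variable with the statistic, p-value and a
    significance flag at ``alpha``.
    """
    df = clean.data
    y = clean.y
    rows = []
    for col in df.columns:
        if col == clean.outcome:
            continue
        sch = (schemas or {}).get(col)
        kind = sch.kind if sch is not None else None
        ser = df[col]
        if kind is None:
            if pd.api.types.is_numeric_dtype(ser) and ser.nunique() > 4:
                kind = "continuous"
            else:
                kind = "nominal"
        if kind == "continuous":
            g1 = ser[y == 1].to_numpy(dtype=float)
            g0 = ser[y == 0].to_numpy(dtype=float)
            t, _, p = welch_t(g1, g0)
            rows.append({"variable": col, "test": "welch_t", "statistic": t, "p": p})
        else:
            tab = pd.crosstab(y, ser)
            if tab.shape[1] < 2 or (tab.sum(axis=0) == 0).any():
                rows.append({"variable": col, "test": "chi2", "statistic": float("nan"), "p": 1.0})
            else:
                res = sps.chi2_contingency(tab.to_numpy(), correction=False)
                rows.append({"variable": col, "test": "chi2",
                             "statistic": float(res.statistic), "p": float(res.pvalue)})
    out = pd.DataFrame(rows)
    out["significant"] = out["p"] < alpha
    return out
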