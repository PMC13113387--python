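"""Core domain objects: threshold conditions and additive risk equations.

A risk equation is an additive model over binary clinical conditions,

    R = sum_{j in S} w_j x_j + b,        y_hat = sigmoid(R),

where each x_j indicates whether a threshold rule such as ``BUN >= 23.6``
or ``CRRT == True`` is satisfied.  Conditions are evaluable on any clean
(fully imputed, numerically coded) patient table; the equation itself can
also be applied directly to a pre-computed 0/1 design matrix whose columns
are keyed by condition name.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = ["Condition", "RiskEquation", "sigmoid"]

# relations a condition may carry
GE = "ge"          # value >= bound
LT = "lt"          # value < bound
EQ = "eq"          # value == bound (category / boolean)
INTERVAL = "interval"  # bound_a <= value < bound_b


def sigmoid(r):
    """Numerically stable logistic function sigma(r) = 1 / (1 + exp(-r))."""
    r = np.asarray(r, dtype=float)
    out = np.empty_like(r)
    pos = r >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-r[pos]))
    er = np.exp(r[~pos])
    out[~pos] = er / (1.0 + er)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class Condition:
    """One binary threshold/category rule on a single variable.

    Parameters
    ----------
    variable
        Column name in the clean table.
    relation
        One of ``"ge"``, ``"lt"``, ``"eq"``, ``"interval"``.
    bounds
        One value for ge/lt/eq, two (a, b) for the half-open interval
        ``[a, b)``.  For ordinal variables bounds are integer class codes.
    display
        Optional rendered bound text (e.g. the class label ``"PosGray"``
        for an ordinal code) used when formatting the rule.
    """

    variable: str
    relation: str
    bounds: tuple
    display: tuple | None = None

    def __post_init__(self):
        if self.relation not in (GE, LT, EQ, INTERVAL):
            raise ValueError(f"unknown relation {self.relation!r}")
        if self.relation == INTERVAL:
            if len(self.bounds) != 2:
                raise ValueError("interval condition needs two bounds")
            a, b = self.bounds
            if not a < b:
                raise ValueError(f"interval bounds must satisfy a < b, got {a!r}, {b!r}")
        elif len(self.bounds) != 1:
            raise ValueError(f"{self.relation} condition needs exactly one bound")

    # -- evaluation ---------------------------------------------------
    def evaluate(self, data) -> np.ndarray:
        """Evaluate the rule on a clean table (DataFrame) or row mapping.

        Returns an int array of exactly 0/1 values.
        """
        if isinstance(data, pd.DataFrame):
            if self.variable not in data.columns:
                raise KeyError(f"variable {self.variable!r} not present in table")
            col = data[self.variable]
        elif isinstance(data, Mapping):
            if self.variable not in data:
                raise KeyError(f"variable {self.variable!r} not present in row")
            col = data[self.variable]
        else:
            col = data
        if self.relation == EQ:
            bound = self.bounds[0]
            if isinstance(bound, bool):
                res = np.asarray(col).astype(bool) == bound
            else:
                res = np.asarray(col) == bound
        else:
            vals = np.asarray(col, dtype=float)
            if self.relation == GE:
                res = vals >= self.bounds[0]
            elif self.relation == LT:
                res = vals < self.bounds[0]
            else:  # INTERVAL, left-closed right-open
                a, b = self.bounds
                res = (vals >= a) & (vals < b)
        res = np.asarray(res)
        if res.ndim == 0:
            return int(res)
        return res.astype(np.int8)

    # -- rendering ----------------------------------------------------
    def _fmt_bound(self, i: int) -> str:
        if self.display is not None:
            return str(self.display[i])
        b = self.bounds[i]
        if isinstance(b, bool):
            return str(b)
        if isinstance(b, (int, float, np.floating, np.integer)):
            return f"{float(b):g}"
        return str(b)

    def range_text(self) -> str:
        """Rule text in score-table style: ``>=12.0``, ``<PosGray``,
        ``==True``, ``>=4.0 and <12.0``."""
        if self.relation == GE:
            return f"≥{self._fmt_bound(0)}"
        if self.relation == LT:
            return f"<{self._fmt_bound(0)}"
        if self.relation == EQ:
            return f"=={self._fmt_bound(0)}"
        return f"≥{self._fmt_bound(0)} and <{self._fmt_bound(1)}"

    @property
    def name(self) -> str:
        return f"{self.variable} {self.range_text()}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name

    # -- (de)serialization --------------------------------------------
    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "relation": self.relation,
            "bounds": list(self.bounds),
            "display": list(self.display) if self.display is not None else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Condition":
        disp = d.get("display")
        return cls(
            variable=d["variable"],
            relation=d["relation"],
            bounds=tuple(d["bounds"]),
            display=tuple(disp) if disp is not None else None,
        )


@dataclass
class RiskEquation:
    """Additive risk model ``R = sum w_j x_j + b`` over binary conditions."""

    terms: list  # list[(Condition, float)]
    bias: float
    provenance: dict = field(default_factory=dict)

    @property
    def conditions(self) -> list:
        return [c for c, _ in self.terms]

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, w in self.terms], dtype=float)

    def __len__(self) -> int:
        return len(self.terms)

    # -- scoring ------------------------------------------------------
    def risk_score(self, row) -> np.ndarray | float:
        """Exact weighted sum plus bias on a 0/1 feature source.

        ``row`` may be a DataFrame/mapping keyed by condition name (a
        design matrix) or a clean table on which conditions are evaluated
        directly (columns keyed by raw variable names).
        """
        if isinstance(row, pd.DataFrame):
            keys = row.columns
            total = np.full(len(row), float(self.bias))
        elif isinstance(row, Mapping):
            keys = row
            total = float(self.bias)
        else:
            raise TypeError("row must be a DataFrame or mapping")
        for cond, w in self.terms:
            if cond.name in keys:
                x = np.asarray(row[cond.name], dtype=float)
            elif cond.variable in keys:
                x = np.asarray(cond.evaluate(row), dtype=float)
            else:
                raise KeyError(f"no value supplied for condition {cond.name!r}")
            if not np.all(np.isin(x, (0.0, 1.0))):
                raise ValueError(f"non-binary value for condition {cond.name!r}")
            total = total + w * x
        return total

    def predict_prob(self, row):
        """Predicted probability sigma(R); strictly increasing in R."""
        return sigmoid(self.risk_score(row))

    # -- manipulation -------------------------------------------------
    def subset(self, keep: Iterable[int]) -> "RiskEquation":
        keep = list(keep)
        return RiskEquation(
            terms=[self.terms[i] for i in keep],
            bias=self.bias,
            provenance=dict(self.provenance),
        )

    # -- (de)serialization --------------------------------------------
    def to_dict(self) -> dict:
        return {
            "terms": [dict(c.to_dict(), weight=float(w)) for c, w in self.terms],
            "bias": float(self.bias),
            "metadata": self.provenance,
        }

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_dict(cls, d: dict) -> "RiskEquation":
        terms = [
            (Condition.from_dict(t), float(t["weight"])) for t in d["terms"]
        ]
        return cls(terms=terms, bias=float(d["bias"]), provenance=d.get("metadata", {}))

    @classmethod
    def from_json(cls, src) -> "RiskEquation":
        if hasattr(src, "read"):
            d = json.load(src)
        else:
            try:
                d = json.loads(src)
            except (ValueError, TypeError):
                with open(src) as fh:
                    d = json.load(fh)
        return cls.from_dict(d)
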