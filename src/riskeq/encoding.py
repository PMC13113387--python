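"""EHR-style cohort preprocessing and reference-range binarization.

Turns a raw patient table — continuous labs, 4-level serology strings,
clipped numeric strings (``">12.0"``), categorical status variables,
missing cells — into (i) a clean, fully imputed numeric table and (ii) a
patient x condition 0/1 design matrix, where each condition is a clinical
threshold rule derived from reference ranges (e.g. ``Na <136``,
``BUN >=23.6``) or a category indicator (``CRRT ==True``).

Pipeline order: :func:`decode_table` (lexical normalization) ->
:func:`filter_variables` (variance / missingness) -> :func:`impute`
(Shapiro–Wilk guided) -> :func:`binarize` -> :func:`stratified_partition`.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps
from sklearn.model_selection import StratifiedKFold

from .model import EQ, GE, INTERVAL, LT, Condition

__all__ = [
    "VariableSchema",
    "CleanTable",
    "BinaryDesign",
    "SEROLOGY_ORDER",
    "parse_clipped",
    "encode_serology",
    "decode_table",
    "filter_variables",
    "impute",
    "conditions_for",
    "binarize",
    "stratified_partition",
    "zscore",
    "load_schemas",
    "save_schemas",
]

#: canonical 4-level serology ordering, weakest to strongest signal
SEROLOGY_ORDER = ("Negative", "NegGray", "PosGray", "Positive")


@dataclass(frozen=True)
class VariableSchema:
    """Declared type and clinical reference information for one variable.

    ``kind`` is one of ``continuous``, ``ordinal``, ``nominal``,
    ``binary`` or ``serology`` (the latter expands to a continuous titer
    column plus a 4-level ordinal class column during decoding).
    ``reference_range`` is the clinical normal range (lower, upper) in the
    variable's own units; ``extra_cuts`` are additional thresholds.
    """

    name: str
    kind: str
    reference_range: tuple | None = None
    extra_cuts: tuple = ()
    ordinal_order: tuple | None = None
    missing_indicator: bool = False

    def __post_init__(self):
        if self.kind not in ("continuous", "ordinal", "nominal", "binary", "serology"):
            raise ValueError(f"unknown variable kind {self.kind!r}")
        if self.reference_range is not None:
            lo, hi = self.reference_range
            if not lo < hi:
                raise ValueError(f"{self.name}: reference range must have lower < upper")
        if list(self.extra_cuts) != sorted(set(self.extra_cuts)):
            raise ValueError(f"{self.name}: extra_cuts must be strictly increasing")
        if self.ordinal_order is not None and len(set(self.ordinal_order)) < 2:
            raise ValueError(f"{self.name}: ordinal order needs >=2 distinct labels")

    @property
    def cuts(self) -> tuple:
        vals = set(self.extra_cuts)
        if self.reference_range is not None:
            vals.update(self.reference_range)
        return tuple(sorted(vals))


@dataclass
class CleanTable:
    """Fully imputed table: no missing cells, ordinals as integer codes."""

    data: pd.DataFrame
    outcome: str
    imputation: dict = field(default_factory=dict)  # variable -> method used
    indicator_columns: list = field(default_factory=list)

    def __post_init__(self):
        if self.data.isna().any().any():
            bad = self.data.columns[self.data.isna().any()].tolist()
            raise ValueError(f"clean table still has missing cells in {bad}")

    @property
    def y(self) -> np.ndarray:
        return self.data[self.outcome].to_numpy().astype(int)


@dataclass
class BinaryDesign:
    """Patients x conditions 0/1 matrix with outcome and split labels."""

    X: pd.DataFrame                 # 0/1 entries, columns = condition names
    conditions: list                # parallel to X's columns
    y: np.ndarray                   # 0/1 outcome
    split: np.ndarray | None = None  # "train"/"test" per row
    fold: np.ndarray | None = None   # 1..k on train rows, 0 elsewhere

    def __post_init__(self):
        vals = self.X.to_numpy()
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("design entries must be 0/1")
        self.y = np.asarray(self.y).astype(int)
        if len(self.y) != len(self.X):
            raise ValueError("outcome length mismatch")

    @property
    def n_conditions(self) -> int:
        return self.X.shape[1]

    @property
    def train_mask(self) -> np.ndarray:
        if self.split is None:
            return np.ones(len(self.X), dtype=bool)
        return np.asarray(self.split) == "train"

    @property
    def test_mask(self) -> np.ndarray:
        if self.split is None:
            return np.zeros(len(self.X), dtype=bool)
        return np.asarray(self.split) == "test"

    def matrix(self, mask=None) -> np.ndarray:
        M = self.X.to_numpy(dtype=np.float64)
        return M if mask is None else M[mask]

    def save(self, path: str) -> None:
        """Write the design as CSV plus a JSON sidecar with the conditions."""
        df = self.X.copy()
        df["__outcome__"] = self.y
        if self.split is not None:
            df["__split__"] = self.split
        if self.fold is not None:
            df["__fold__"] = self.fold
        df.to_csv(path, index=False)
        import json

        with open(str(path) + ".conditions.json", "w") as fh:
            json.dump([c.to_dict() for c in self.conditions], fh, indent=1)

    @classmethod
    def load(cls, path: str) -> "BinaryDesign":
        import json

        df = pd.read_csv(path)
        y = df.pop("__outcome__").to_numpy()
        split = df.pop("__split__").to_numpy() if "__split__" in df.columns else None
        fold = df.pop("__fold__").to_numpy() if "__fold__" in df.columns else None
        with open(str(path) + ".conditions.json") as fh:
            conds = [Condition.from_dict(d) for d in json.load(fh)]
        return cls(X=df, conditions=conds, y=y, split=split, fold=fold)


# ----------------------------------------------------------------------
# lexical decoding
# ----------------------------------------------------------------------

_CLIPPED_RE = re.compile(r"^\s*([<>])\s*([^<>]+?)\s*$")

_SEROLOGY_COUNTED = re.compile(
    r"^\s*(Positive|Gray\s+Positive|Gray\s+Negative|Negative)\s*\(\s*([-+0-9.eE]+)\s*\)\s*$",
    re.IGNORECASE,
)
_SEROLOGY_PLAIN = {
    "positive": "Positive",
    "positive gray": "PosGray",
    "gray positive": "PosGray",
    "negative gray": "NegGray",
    "gray negative": "NegGray",
    "negative": "Negative",
    "nd": "Negative",
}
_COUNTED_CLASS = {
    "positive": "Positive",
    "gray positive": "PosGray",
    "gray negative": "NegGray",
    "negative": "Negative",
}


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    if isinstance(value, str) and value.strip() in ("", "NaN", "nan"):
        return True
    return False


def parse_clipped(value):
    """Strip a clipped-value inequality: ``">12.0"`` -> 12.0, ``"<0.5"`` -> 0.5.

    Plain numbers (or numeric strings) pass through unchanged; anything
    else raises ``ValueError`` naming the offending cell.
    """
    if _is_missing(value):
        return float("nan")
    if isinstance(value, (int, float, np.integer, np.floating)):
        return float(value)
    s = str(value)
    m = _CLIPPED_RE.match(s)
    payload = m.group(2) if m else s
    try:
        return float(payload)
    except ValueError:
        raise ValueError(f"cannot parse numeric cell {value!r}") from None


def encode_serology(value):
    """Map one serology cell to ``(numeric, ordinal_class)``.

    Counted positives (``"Positive (32)"``, ``"Gray Positive (8)"``) keep
    their titer; counted negatives and ``"ND"`` map to 0.  Count-free
    labels keep the 4-level class, with the titer of count-free positives
    left missing for downstream imputation.  Missing stays missing.
    """
    if _is_missing(value):
        return float("nan"), None
    s = str(value).strip()
    m = _SEROLOGY_COUNTED.match(s)
    if m:
        label = re.sub(r"\s+", " ", m.group(1).lower())
        cls = _COUNTED_CLASS[label]
        n = float(m.group(2))
        numeric = n if cls in ("Positive", "PosGray") else 0.0
        return numeric, cls
    key = re.sub(r"\s+", " ", s.lower())
    if key in _SEROLOGY_PLAIN:
        cls = _SEROLOGY_PLAIN[key]
        numeric = 0.0 if cls in ("Negative", "NegGray") else float("nan")
        return numeric, cls
    raise ValueError(
        f"unrecognized serology value {value!r}; allowed forms: 'Positive (n)', "
        "'Gray Positive (n)', 'Gray Negative (n)', 'Negative (n)', 'ND', "
        "'Positive', 'Positive Gray', 'Negative Gray', 'Negative'"
    )


def decode_table(df: pd.DataFrame, schemas: dict) -> tuple[pd.DataFrame, dict]:
    """Normalize lexical forms column-wise.

    Continuous columns get clipped strings parsed to numbers; serology
    columns are expanded into a numeric titer column (same name) plus a
    ``"<name> class"`` ordinal column coded 0..3 on
    Negative < NegGray < PosGray < Positive; ordinal columns with a
    declared order are mapped to integer codes.  Returns the decoded
    table and an updated schema dict covering the derived columns.
    """
    out = {}
    new_schemas = dict(schemas)
    for col in df.columns:
        sch = schemas.get(col)
        if sch is None or sch.kind in ("nominal", "binary"):
            out[col] = df[col]
            continue
        if sch.kind == "continuous":
            out[col] = df[col].map(parse_clipped).astype(float)
        elif sch.kind == "ordinal":
            order = list(sch.ordinal_order)
            codes = df[col].map(
                lambda v: float("nan") if _is_missing(v) else float(order.index(v))
            )
            out[col] = codes.astype(float)
        elif sch.kind == "serology":
            pairs = df[col].map(encode_serology)
            numeric = pairs.map(lambda p: p[0]).astype(float)
            order = list(SEROLOGY_ORDER)
            cls = pairs.map(
                lambda p: float("nan") if p[1] is None else float(order.index(p[1]))
            )
            out[col] = numeric
            cls_name = f"{col} class"
            out[cls_name] = cls.astype(float)
            new_schemas[col] = replace(sch, kind="continuous", ordinal_order=None)
            new_schemas[cls_name] = VariableSchema(
                name=cls_name, kind="ordinal", ordinal_order=SEROLOGY_ORDER
            )
    return pd.DataFrame(out, index=df.index), new_schemas


# ----------------------------------------------------------------------
# variance / missingness filter
# ----------------------------------------------------------------------

def filter_variables(
    df: pd.DataFrame,
    outcome: str,
    variance_floor: float = 0.0,
    missing_cap: float = 0.5,
) -> tuple[pd.DataFrame, dict]:
    """Drop near-constant and mostly-missing columns.

    A numeric column is dropped when its variance over non-missing
    entries is <= ``variance_floor``; any column is dropped when its
    missing fraction exceeds ``missing_cap``.  The outcome column is
    never dropped.  Returns the filtered table and a removal report.
    """
    if not 0 < missing_cap <= 1:
        raise ValueError("missing_cap must be in (0, 1]")
    if outcome not in df.columns:
        raise ValueError(f"outcome column {outcome!r} not present")
    removed = {}
    keep = []
    for col in df.columns:
        if col == outcome:
            keep.append(col)
            continue
        ser = df[col]
        miss = ser.map(_is_missing)
        frac = float(miss.mean())
        if frac > missing_cap:
            removed[col] = {"reason": "missingness", "missing_fraction": frac}
            continue
        obs = ser[~miss]
        if pd.api.types.is_numeric_dtype(obs.infer_objects()):
            var = float(pd.to_numeric(obs).var(ddof=1)) if len(obs) > 1 else 0.0
            if not var > variance_floor:
                removed[col] = {"reason": "variance", "variance": var}
                continue
        else:
            if obs.nunique() <= 1:
                removed[col] = {"reason": "variance", "variance": 0.0}
                continue
        keep.append(col)
    report = {
        "removed": removed,
        "kept": [c for c in keep if c != outcome],
        "missing_cap": missing_cap,
        "variance_floor": variance_floor,
    }
    return df[keep].copy(), report


# ----------------------------------------------------------------------
# imputation
# ----------------------------------------------------------------------

def impute(
    df: pd.DataFrame,
    schemas: dict,
    outcome: str,
    normality_alpha: float = 0.05,
) -> CleanTable:
    """Fill missing cells, choosing mean vs median by a Shapiro–Wilk test.

    Continuous columns whose non-missing sample is consistent with
    normality (p >= ``normality_alpha``) are mean-imputed, otherwise
    median-imputed; categorical/ordinal/binary columns get the mode.
    Variables whose schema sets ``missing_indicator`` (stable
    patient-specific measures like height and weight) are mean-imputed
    and gain a 0/1 ``"<name> missing"`` indicator column.
    """
    if not 0 < normality_alpha < 1:
        raise ValueError("normality_alpha must be in (0, 1)")
    out = {}
    record = {}
    indicators = []
    for col in df.columns:
        ser = df[col]
        if col == outcome:
            out[col] = ser
            continue
        miss = ser.map(_is_missing)
        if miss.all():
            raise ValueError(f"column {col!r} is entirely missing; filter it first")
        sch = schemas.get(col)
        kind = sch.kind if sch is not None else ("continuous" if pd.api.types.is_numeric_dtype(ser) else "nominal")
        if kind == "continuous":
            vals = pd.to_numeric(ser[~miss])
            if sch is not None and sch.missing_indicator:
                fill, method = float(vals.mean()), "mean+indicator"
                ind = f"{col} missing"
                out[ind] = miss.astype(int)
                indicators.append(ind)
            else:
                uniq = vals.nunique()
                if len(vals) >= 3 and uniq > 1:
                    p = float(sps.shapiro(vals.to_numpy()).pvalue)
                else:
                    p = 1.0
                if p >= normality_alpha:
                    fill, method = float(vals.mean()), "mean"
                else:
                    fill, method = float(vals.median()), "median"
            filled = pd.to_numeric(ser.where(~miss)).astype(float).fillna(fill)
        else:
            vals = ser[~miss]
            mode = vals.mode().sort_values().iloc[0]
            fill, method = mode, "mode"
            filled = ser.copy()
            filled[miss] = fill
            if kind in ("ordinal", "binary"):
                filled = pd.to_numeric(filled)
        out[col] = filled
        record[col] = method
    clean = pd.DataFrame(out, index=df.index)
    return CleanTable(data=clean, outcome=outcome, imputation=record, indicator_columns=indicators)


# ----------------------------------------------------------------------
# binarization
# ----------------------------------------------------------------------

def conditions_for(schema: VariableSchema) -> list[Condition]:
    """Conditions emitted for one variable.

    Continuous with only a reference range (lower, upper): the two
    out-of-range flags ``< lower`` and ``>= upper``.  Continuous with
    extra cuts: the full left-closed partition ``< c0``,
    ``[c_i, c_{i+1})`` per consecutive pair, ``>= c_last``.  Ordinal: for
    every class above the lowest, the cumulative pair ``>= class`` and
    ``< class``.  Nominal: one dummy per level (requires ordinal_order
    listing the levels).  Binary: ``== True``.
    """
    name = schema.name
    if schema.kind == "continuous":
        cuts = schema.cuts
        if not cuts:
            raise ValueError(f"{name}: continuous schema needs a reference range or cuts")
        if len(cuts) == 2 and not schema.extra_cuts:
            lo, hi = cuts
            return [
                Condition(name, LT, (float(lo),)),
                Condition(name, GE, (float(hi),)),
            ]
        conds = [Condition(name, LT, (float(cuts[0]),))]
        for a, b in zip(cuts[:-1], cuts[1:]):
            conds.append(Condition(name, INTERVAL, (float(a), float(b))))
        conds.append(Condition(name, GE, (float(cuts[-1]),)))
        return conds
    if schema.kind == "ordinal":
        order = schema.ordinal_order
        if order is None:
            raise ValueError(f"{name}: ordinal schema needs an order")
        conds = []
        for code in range(1, len(order)):
            label = order[code]
            conds.append(Condition(name, GE, (float(code),), display=(label,)))
            conds.append(Condition(name, LT, (float(code),), display=(label,)))
        return conds
    if schema.kind == "nominal":
        if schema.ordinal_order is None:
            raise ValueError(f"{name}: nominal schema needs its level list in ordinal_order")
        return [Condition(name, EQ, (lev,)) for lev in schema.ordinal_order]
    if schema.kind == "binary":
        return [Condition(name, EQ, (True,))]
    raise ValueError(f"{name}: cannot binarize kind {schema.kind!r}")


def binarize(clean: CleanTable, schemas: dict) -> BinaryDesign:
    """Evaluate every schema-derived condition on the clean table."""
    conds: list[Condition] = []
    for col in clean.data.columns:
        if col == clean.outcome:
            continue
        sch = schemas.get(col)
        if sch is None:
            if col in clean.indicator_columns or set(np.unique(clean.data[col])) <= {0, 1}:
                sch = VariableSchema(name=col, kind="binary")
            else:
                raise ValueError(f"no schema for non-binary column {col!r}")
        conds.extend(conditions_for(sch))
    if not conds:
        raise ValueError("no conditions generated")
    cols = {}
    for c in conds:
        cols[c.name] = c.evaluate(clean.data)
    X = pd.DataFrame(cols, index=clean.data.index)
    return BinaryDesign(X=X, conditions=conds, y=clean.y)


# ----------------------------------------------------------------------
# splitting
# ----------------------------------------------------------------------

def stratified_partition(
    design: BinaryDesign,
    test_fraction: float = 0.2,
    k_folds: int = 5,
    seed: int = 0,
) -> BinaryDesign:
    """Stratified train/test split plus stratified CV folds on the train part.

    The test allocation preserves the outcome ratio within +-1 subject:
    the positive test count is the nearest integer to m * test_fraction
    (ties toward more positives in test), the negative count the nearest
    integer rounding the other way.  Deterministic given ``seed``.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    y = design.y
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("need exactly two outcome classes")
    if counts.min() < k_folds:
        raise ValueError(f"a class has fewer than k_folds={k_folds} members")
    rng = np.random.default_rng(seed)
    split = np.full(len(y), "train", dtype=object)
    for cls in classes:
        idx = np.flatnonzero(y == cls)
        m = len(idx)
        raw = m * test_fraction
        if cls == 1:
            n_test = int(math.floor(raw + 0.5))   # ties -> more positives in test
        else:
            n_test = int(math.ceil(raw - 0.5))    # ties -> fewer negatives in test
        perm = rng.permutation(idx)
        split[perm[:n_test]] = "test"
    fold = np.zeros(len(y), dtype=int)
    train_idx = np.flatnonzero(split == "train")
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=int(seed) % (2**32))
    for f, (_, val) in enumerate(skf.split(train_idx.reshape(-1, 1), y[train_idx]), start=1):
        fold[train_idx[val]] = f
    return BinaryDesign(
        X=design.X, conditions=design.conditions, y=design.y, split=split, fold=fold
    )


# ----------------------------------------------------------------------
# utilities
# ----------------------------------------------------------------------

def zscore(df: pd.DataFrame, columns=None) -> pd.DataFrame:
    """z-score standardization utility (used by linear baselines, not by
    the symbolic-regression path, which works on binarized inputs)."""
    out = df.copy()
    for col in columns if columns is not None else df.select_dtypes("number").columns:
        v = out[col].astype(float)
        sd = v.std(ddof=0)
        out[col] = (v - v.mean()) / (sd if sd > 0 else 1.0)
    return out


def encode_cohort(
    df: pd.DataFrame,
    schemas: dict,
    outcome: str,
    variance_floor: float = 0.0,
    missing_cap: float = 0.5,
    normality_alpha: float = 0.05,
) -> tuple[CleanTable, BinaryDesign, dict]:
    """Full raw-to-design pipeline: decode, filter, impute, binarize."""
    decoded, schemas2 = decode_table(df, schemas)
    filtered, report = filter_variables(decoded, outcome, variance_floor, missing_cap)
    clean = impute(filtered, schemas2, outcome, normality_alpha)
    design = binarize(clean, schemas2)
    report["imputation"] = clean.imputation
    return clean, design, report


def load_schemas(path) -> dict:
    """Read a YAML reference-range config: one block per variable with
    keys kind / lower / upper / cuts / order / missing_indicator."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    schemas = {}
    for name, spec in raw.items():
        spec = spec or {}
        rng = None
        if "lower" in spec or "upper" in spec:
            rng = (spec["lower"], spec["upper"])
        schemas[name] = VariableSchema(
            name=name,
            kind=spec.get("kind", "continuous"),
            reference_range=rng,
            extra_cuts=tuple(spec.get("cuts", ())),
            ordinal_order=tuple(spec["order"]) if "order" in spec else None,
            missing_indicator=bool(spec.get("missing_indicator", False)),
        )
    return schemas


def save_schemas(schemas: dict, path) -> None:
    raw = {}
    for name, sch in schemas.items():
        spec = {"kind": sch.kind}
        if sch.reference_range is not None:
            spec["lower"], spec["upper"] = [float(v) for v in sch.reference_range]
        if sch.extra_cuts:
            spec["cuts"] = [float(c) for c in sch.extra_cuts]
        if sch.ordinal_order is not None:
            spec["order"] = list(sch.ordinal_order)
        if sch.missing_indicator:
            spec["missing_indicator"] = True
        raw[name] = spec
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False, allow_unicode=True)
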