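"""Raw-table decoding, filtering, imputation, binarization and splitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import riskeq as rq
from riskeq.encoding import VariableSchema, conditions_for, decode_table


# -- lexical decoding --------------------------------------------------

@pytest.mark.parametrize("raw,expected", [
    (">12.0", 12.0),
    ("<0.5", 0.5),
    ("7.2", 7.2),
    (7.2, 7.2),
    (" > 3 ", 3.0),
])
def test_parse_clipped_strips_inequalities(raw, expected):
    assert rq.parse_clipped(raw) == expected


def test_parse_clipped_rejects_garbage():
    with pytest.raises(ValueError, match="abc"):
        rq.parse_clipped(">abc")


@settings(max_examples=50, derandomize=True)
@given(st.floats(allow_nan=False, allow_infinity=False, width=32))
def test_parse_clipped_passthrough_is_identity(x):
    assert rq.parse_clipped(x) == float(x)
    assert rq.parse_clipped(f">{x}") == float(x)


@pytest.mark.parametrize("raw,numeric,cls", [
    ("Positive (32)", 32.0, "Positive"),
    ("Gray Positive (8)", 8.0, "PosGray"),
    ("Gray Negative (2)", 0.0, "NegGray"),
    ("Negative (0)", 0.0, "Negative"),
    ("ND", 0.0, "Negative"),
    ("Negative Gray", 0.0, "NegGray"),
    ("Positive Gray", None, "PosGray"),   # count-free positive: titer unknown
    ("Negative", 0.0, "Negative"),
])
def test_encode_serology_mapping(raw, numeric, cls):
    num, c = rq.encode_serology(raw)
    assert c == cls
    if numeric is None:
        assert np.isnan(num)
    else:
        assert num == numeric


def test_encode_serology_missing_stays_missing():
    num, c = rq.encode_serology(float("nan"))
    assert np.isnan(num) and c is None


def test_encode_serology_rejects_unknown_label():
    with pytest.raises(ValueError, match="Gray Positive"):
        rq.encode_serology("Weird (3)")


def test_decode_table_expands_serology():
    schemas = {"CMV": VariableSchema("CMV", "serology", extra_cuts=(10.0,))}
    df = pd.DataFrame({"CMV": ["Positive (20)", "ND", "Negative Gray", np.nan]})
    out, schemas2 = decode_table(df, schemas)
    assert list(out["CMV"])[:3] == [20.0, 0.0, 0.0]
    assert list(out["CMV class"])[:3] == [3.0, 0.0, 1.0]
    assert np.isnan(out["CMV class"].iloc[3])
    assert schemas2["CMV"].kind == "continuous"
    assert schemas2["CMV class"].ordinal_order == rq.SEROLOGY_ORDER


# -- filtering ---------------------------------------------------------

def test_filter_drops_constants_and_high_missingness():
    n = 100
    df = pd.DataFrame({
        "const": [3.0] * n,
        "mostly_missing": [np.nan] * 60 + list(range(40)),
        "fine": list(np.linspace(0, 1, n)),
        "slightly_missing": [np.nan] * 3 + list(range(n - 3)),
        "y": [0, 1] * (n // 2),
    })
    out, report = rq.filter_variables(df, outcome="y", missing_cap=0.5)
    assert set(out.columns) == {"fine", "slightly_missing", "y"}
    assert report["removed"]["const"]["reason"] == "variance"
    assert report["removed"]["mostly_missing"]["reason"] == "missingness"


def test_filter_never_drops_outcome():
    df = pd.DataFrame({"y": [1] * 10, "x": range(10)})
    out, _ = rq.filter_variables(df, outcome="y")
    assert "y" in out.columns  # constant outcome survives


def test_filter_preserves_row_count(small_cohort):
    cfg, raw, _ = small_cohort
    out, _ = rq.filter_variables(raw, outcome="BSI")
    assert len(out) == len(raw)


# -- imputation --------------------------------------------------------

def _schemas(**kinds):
    return {k: VariableSchema(k, v) for k, v in kinds.items()}


def test_impute_mean_for_normal_median_for_skewed():
    rng = np.random.default_rng(0)
    normal = rng.normal(10, 1, 200)
    skewed = rng.lognormal(0, 1.5, 200)
    df = pd.DataFrame({"normal": normal, "skewed": skewed, "y": [0, 1] * 100})
    df.loc[0:9, "normal"] = np.nan
    df.loc[0:9, "skewed"] = np.nan
    clean = rq.impute(df, _schemas(normal="continuous", skewed="continuous"), "y")
    assert clean.imputation == {"normal": "mean", "skewed": "median"}
    assert clean.data.loc[5, "normal"] == pytest.approx(df["normal"].mean())
    assert clean.data.loc[5, "skewed"] == pytest.approx(df["skewed"].median())


def test_impute_adds_indicator_for_flagged_variables():
    df = pd.DataFrame({"Height": [160.0, np.nan, 170.0, 175.0], "y": [0, 1, 0, 1]})
    schemas = {"Height": VariableSchema("Height", "continuous",
                                        reference_range=(150, 180),
                                        missing_indicator=True)}
    clean = rq.impute(df, schemas, "y")
    assert clean.indicator_columns == ["Height missing"]
    assert list(clean.data["Height missing"]) == [0, 1, 0, 0]
    assert clean.imputation["Height"] == "mean+indicator"


def test_impute_leaves_observed_cells_bit_identical():
    rng = np.random.default_rng(1)
    vals = rng.normal(0, 1, 50)
    df = pd.DataFrame({"x": vals.copy(), "y": [0, 1] * 25})
    df.loc[3, "x"] = np.nan
    clean = rq.impute(df, _schemas(x="continuous"), "y")
    keep = [i for i in range(50) if i != 3]
    assert (clean.data.loc[keep, "x"].to_numpy() == vals[keep]).all()
    assert not clean.data.isna().any().any()


def test_impute_rejects_all_missing_column():
    df = pd.DataFrame({"x": [np.nan, np.nan], "y": [0, 1]})
    with pytest.raises(ValueError, match="entirely missing"):
        rq.impute(df, _schemas(x="continuous"), "y")


# -- binarization ------------------------------------------------------

def test_reference_range_conditions():
    sch = VariableSchema("Na", "continuous", reference_range=(136.0, 146.0))
    conds = conditions_for(sch)
    assert [c.range_text() for c in conds] == ["<136", "≥146"]
    # in-range value leaves both flags at 0
    row = pd.DataFrame({"Na": [140.0]})
    assert [int(c.evaluate(row)[0]) for c in conds] == [0, 0]


def test_extra_cuts_emit_partition():
    sch = VariableSchema("RBC transfusion", "continuous", extra_cuts=(4.0, 12.0))
    conds = conditions_for(sch)
    assert [c.range_text() for c in conds] == ["<4", "≥4 and <12", "≥12"]
    row = pd.DataFrame({"RBC transfusion": [6.0]})
    assert [int(c.evaluate(row)[0]) for c in conds] == [0, 1, 0]


def test_threshold_condition_fires_at_bound():
    cond = rq.Condition("BUN_adm", "ge", (23.6,))
    assert cond.evaluate(pd.DataFrame({"BUN_adm": [25.0, 23.6, 23.5]})).tolist() == [1, 1, 0]
    assert cond.name == "BUN_adm ≥23.6"


def test_ordinal_conditions_render_class_labels():
    sch = VariableSchema("Ab class", "ordinal", ordinal_order=rq.SEROLOGY_ORDER)
    names = [c.range_text() for c in conditions_for(sch)]
    assert "<PosGray" in names and "≥NegGray" in names and "<Positive" in names
    lt_posgray = [c for c in conditions_for(sch) if c.range_text() == "<PosGray"][0]
    assert lt_posgray.evaluate(pd.DataFrame({"Ab class": [0.0, 1.0, 2.0, 3.0]})).tolist() == [1, 1, 0, 0]


def test_binarize_round_trip_reproduces_matrix(small_cohort):
    cfg, raw, _ = small_cohort
    from riskeq.simulate import schemas_for
    clean, design, _ = rq.encode_cohort(raw, schemas_for(cfg.variables), "BSI")
    assert len(design.X) == len(raw)
    for cond in design.conditions[::7]:
        np.testing.assert_array_equal(
            design.X[cond.name].to_numpy(), cond.evaluate(clean.data))
    assert set(np.unique(design.X.to_numpy())) <= {0, 1}


def test_partition_conditions_are_mutually_exclusive(small_cohort):
    cfg, raw, _ = small_cohort
    from riskeq.simulate import schemas_for
    clean, design, _ = rq.encode_cohort(raw, schemas_for(cfg.variables), "BSI")
    cols = [c.name for c in design.conditions if c.variable == "RBC transfusion"]
    assert (design.X[cols].sum(axis=1) <= 1).all()


def test_binarize_requires_schema_for_nonbinary():
    clean = rq.CleanTable(
        data=pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [0, 1, 0]}), outcome="y")
    with pytest.raises(ValueError, match="no schema"):
        rq.binarize(clean, {})


# -- splitting ---------------------------------------------------------

def test_partition_preserves_class_ratio(small_design):
    _, design, _ = small_design
    y = design.y
    te = design.test_mask
    expected = round(y.sum() * 0.2)
    assert abs(int(y[te].sum()) - expected) <= 1
    assert abs(te.sum() - round(len(y) * 0.2)) <= 1


def test_partition_is_deterministic(small_design):
    _, design, _ = small_design
    again = rq.stratified_partition(design, 0.2, 5, seed=11)
    np.testing.assert_array_equal(design.split, again.split)
    np.testing.assert_array_equal(design.fold, again.fold)


def test_partition_fold_sizes_balanced(small_design):
    _, design, _ = small_design
    fold = np.asarray(design.fold)[design.train_mask]
    sizes = [int((fold == f).sum()) for f in sorted(set(fold))]
    assert len(sizes) == 5
    assert max(sizes) - min(sizes) <= 1


def test_partition_rejects_tiny_class():
    X = pd.DataFrame({"c ==True": [0, 1] * 5})
    design = rq.BinaryDesign(
        X=X, conditions=[rq.Condition("c", "eq", (True,))],
        y=np.array([1, 0, 0, 0, 0, 0, 0, 0, 0, 0]))
    with pytest.raises(ValueError, match="fewer than"):
        rq.stratified_partition(design, 0.2, k_folds=5, seed=0)


def test_design_csv_round_trip(tmp_path, small_design):
    _, design, _ = small_design
    path = tmp_path / "design.csv"
    design.save(path)
    loaded = rq.BinaryDesign.load(path)
    pd.testing.assert_frame_equal(loaded.X, design.X.reset_index(drop=True),
                                  check_dtype=False)
    np.testing.assert_array_equal(loaded.y, design.y)
    assert [c.name for c in loaded.conditions] == [c.name for c in design.conditions]
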