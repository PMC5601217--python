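"""Clinical table encoding, transforms, rare-factor filtering, cohort summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import neocca as nc


def make_table(n=10, seed=0, missing=False):
    g = np.random.default_rng(seed)
    df = pd.DataFrame({
        "age": g.uniform(25, 40, n),
        "days": g.exponential(5, n),
        "male": (g.uniform(size=n) < 0.5).astype(float),
    })
    if missing:
        df.loc[df.index[2], "age"] = np.nan
        df.loc[df.index[4], "male"] = np.nan
    return nc.ClinicalTable(data=df, kinds={"age": "continuous", "days": "continuous",
                                            "male": "binary"})


def test_encode_standardizes_and_centers():
    df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [0.0, 1.0, 1.0]})
    t = nc.ClinicalTable(data=df, kinds={"a": "continuous", "b": "binary"})
    X = nc.encode(t)
    assert np.allclose(X.values[:, 0], np.array([-1.0, 0.0, 1.0]))  # sd of {1,2,3} is 1
    assert X.values[:, 1] == pytest.approx([-2 / 3, 1 / 3, 1 / 3])  # centered, not scaled
    Xs = nc.encode(t, scale_binary=True)
    assert Xs.values[:, 1].std(ddof=1) == pytest.approx(1.0)


def test_encode_imputes_and_counts():
    t = make_table(n=20, missing=True)
    X = nc.encode(t)
    assert not np.isnan(X.values).any()
    assert X.imputed["age"] == 1 and X.imputed["male"] == 1 and X.imputed["days"] == 0
    # mean imputation: the imputed raw value equals the observed mean
    obs_mean = t.data["age"].dropna().mean()
    assert X.raw["age"].iloc[2] == pytest.approx(obs_mean)
    # mode imputation for the binary column
    assert X.raw["male"].iloc[4] in (0.0, 1.0)


def test_encode_rejects_constant_naming_variable():
    df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 1.0, 1.0]})
    t = nc.ClinicalTable(data=df, kinds={"a": "continuous", "b": "binary"})
    with pytest.raises(ValueError, match="'b'"):
        nc.encode(t)


def test_encode_idempotent_on_encoded_data():
    t = make_table(n=30)
    X = nc.encode(t)
    t2 = nc.ClinicalTable(data=X.to_frame(),
                          kinds={n: "continuous" for n in X.names})
    X2 = nc.encode(t2)
    # re-encoding already standardized continuous data changes nothing;
    # the binary column was centered, so z-scoring it only rescales
    assert np.allclose(X2.values[:, :2], X.values[:, :2], atol=1e-12)


def test_transforms_arithmetic_and_guards():
    df = pd.DataFrame({"a": [-8.0, 0.0, 8.0], "b": [-1.0, 0.0, 1.0]})
    t = nc.ClinicalTable(data=df, kinds={"a": "continuous", "b": "continuous"})
    X = nc.encode(t)
    Xt = nc.transform_skewed(X, {"a": "cbrt"})
    assert np.allclose(Xt.raw["a"], [-2.0, 0.0, 2.0])
    assert Xt.transforms["a"] == "cbrt" and Xt.transforms["b"] == "none"
    Xsq = nc.transform_skewed(X, {"b": "square"})
    assert np.allclose(sorted(Xsq.raw["b"]), [0.0, 1.0, 1.0])
    with pytest.raises(ValueError, match="'a'"):
        nc.transform_skewed(X, {"a": "sqrt"})  # negative values
    with pytest.raises(ValueError, match="unknown transform"):
        nc.transform_skewed(X, {"a": "log"})


def test_cbrt_reduces_lognormal_skewness():
    g = np.random.default_rng(5)
    vals = np.exp(g.standard_normal(500))
    df = pd.DataFrame({"x": vals, "y": g.standard_normal(500)})
    t = nc.ClinicalTable(data=df, kinds={"x": "continuous", "y": "continuous"})
    X = nc.encode(t)
    Xt = nc.transform_skewed(X, {"x": "cbrt"})
    assert abs(stats.skew(Xt.raw["x"])) < abs(stats.skew(vals))


def test_filter_rare_thresholds():
    n = 449
    g = np.random.default_rng(0)
    df = pd.DataFrame({
        "rare": np.r_[np.ones(6), np.zeros(n - 6)],        # 1.34% positive
        "common": np.r_[np.ones(226), np.zeros(n - 226)],  # 50.33% positive
        "cont": g.standard_normal(n),
    })
    t = nc.ClinicalTable(data=df, kinds={"rare": "binary", "common": "binary",
                                         "cont": "continuous"})
    kept, dropped = nc.filter_rare(t, 0.10)
    assert dropped == ["rare"]
    assert set(kept.names) == {"common", "cont"}
    same, none_dropped = nc.filter_rare(t, 0.0)
    assert none_dropped == [] and same.names == t.names


@given(thr1=st.floats(0.0, 0.5), thr2=st.floats(0.0, 0.5))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_filter_rare_monotone(thr1, thr2):
    """Raising the threshold never re-admits a dropped variable."""
    lo, hi = sorted((thr1, thr2))
    g = np.random.default_rng(1)
    df = pd.DataFrame({f"b{i}": (g.uniform(size=60) < prev).astype(float)
                       for i, prev in enumerate((0.05, 0.2, 0.4, 0.6))})
    t = nc.ClinicalTable(data=df, kinds={c: "binary" for c in df.columns})
    _, dropped_lo = nc.filter_rare(t, lo)
    _, dropped_hi = nc.filter_rare(t, hi)
    assert set(dropped_lo) <= set(dropped_hi)


def test_summarize_percentages_match_counts():
    n = 449
    df = pd.DataFrame({
        "male": np.r_[np.ones(226), np.zeros(n - 226)],
        "motion": np.r_[np.ones(143), np.zeros(n - 143)],
        "none": np.zeros(n),
        "ga": np.linspace(23.5, 32.9, n),
    })
    t = nc.ClinicalTable(data=df, kinds={"male": "binary", "motion": "binary",
                                         "none": "binary", "ga": "continuous"})
    s = nc.summarize(t).to_frame().set_index("variable")
    assert s.loc["male", "percent"] == 50.33
    assert round(s.loc["motion", "percent"], 1) == 31.8
    assert s.loc["none", "percent"] == 0.00
    assert s.loc["ga", "center"] == pytest.approx(np.median(df["ga"]))
    assert (s.loc["ga", "low"], s.loc["ga", "high"]) == (23.5, 32.9)
    # percentages recompute exactly from the stored count and denominator
    for _, row in s[s["kind"] == "binary"].iterrows():
        assert row["percent"] == round(100 * row["count"] / row["denominator"], 2)


def test_summarize_mean_flag_and_missing_denominator():
    df = pd.DataFrame({"tpn": [0.0, 4.0, np.nan, 8.0], "x": [0.0, 1.0, 1.0, 0.0]})
    t = nc.ClinicalTable(data=df, kinds={"tpn": "continuous", "x": "binary"},
                         summary_stat={"tpn": "mean"})
    s = nc.summarize(t).to_frame().set_index("variable")
    assert s.loc["tpn", "center"] == pytest.approx(4.0)
    assert s.loc["tpn", "n_missing"] == 1 and s.loc["tpn", "denominator"] == 3


def test_drop_subjects_consistency():
    t = make_table(n=449)
    ids = t.data.index[:37]
    t2 = nc.drop_subjects(t, ids)
    assert t2.n_subjects == 412
    with pytest.raises(KeyError):
        nc.drop_subjects(t, [99999])
    with pytest.raises(ValueError, match="every subject"):
        nc.drop_subjects(t, t.data.index)
    same = nc.drop_subjects(t, [])
    assert same.n_subjects == t.n_subjects


def test_binary_values_validated():
    df = pd.DataFrame({"a": [0.0, 1.0, 2.0], "b": [0.0, 1.0, 0.0]})
    with pytest.raises(ValueError, match="'a'"):
        nc.ClinicalTable(data=df, kinds={"a": "binary", "b": "binary"})
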