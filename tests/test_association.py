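import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lipidprs.association import (ModelSpec, bin_contrast, fit_linear,
                                  fit_logistic, linear_table)
from lipidprs.scoring import bin_score


def _table_cohort(a, b, c, d):
    """2x2 layout: exposed cases a, exposed controls b, unexposed cases c,
    unexposed controls d."""
    exposure = [1] * (a + b) + [0] * (c + d)
    outcome = [1] * a + [0] * b + [1] * c + [0] * d
    return pd.DataFrame({"x": exposure, "y": outcome}, dtype=float)


def test_logistic_matches_crossproduct_on_reference_table():
    cohort = _table_cohort(20, 80, 10, 90)
    res = fit_logistic(cohort, ModelSpec("y", "x", family="logistic"))
    assert res.estimate == pytest.approx((20 * 90) / (80 * 10), rel=1e-5)
    assert res.ci95[0] < res.estimate < res.ci95[1]


@given(st.tuples(*[st.integers(3, 60)] * 4))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_logistic_or_equals_crossproduct_ratio_property(cells):
    a, b, c, d = cells
    res = fit_logistic(_table_cohort(a, b, c, d),
                       ModelSpec("y", "x", family="logistic"))
    assert res.estimate == pytest.approx((a * d) / (b * c), rel=1e-4)


def test_linear_r2_equals_squared_pearson_single_predictor():
    rng = np.random.default_rng(0)
    x = rng.normal(size=200)
    y = 0.4 * x + rng.normal(size=200)
    cohort = pd.DataFrame({"x": x, "y": y})
    res = fit_linear(cohort, ModelSpec("y", "x"))
    assert res.r_squared == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2, abs=1e-10)


def test_linear_noiseless_and_constant_outcomes():
    prs = pd.Series(np.arange(50, dtype=float))
    exact = pd.DataFrame({"prs": prs, "y": 2 * prs})
    res = fit_linear(exact, ModelSpec("y", "prs"))
    assert res.estimate == pytest.approx(2.0)
    assert res.r_squared == pytest.approx(1.0)
    const = pd.DataFrame({"prs": prs, "y": np.ones(50)})
    res0 = fit_linear(const, ModelSpec("y", "prs"))
    assert res0.estimate == 0.0 and res0.r_squared == 0.0


def test_adding_covariates_never_decreases_full_r2():
    rng = np.random.default_rng(1)
    n = 300
    df = pd.DataFrame({
        "prs": rng.integers(0, 11, n).astype(float),
        "age": rng.normal(50, 10, n), "bmi": rng.normal(27, 5, n),
    })
    df["y"] = 0.1 * df["prs"] + 0.02 * df["age"] + rng.normal(0, 1, n)
    base = fit_linear(df, ModelSpec("y", "prs"))
    more = fit_linear(df, ModelSpec("y", "prs", ("age",)))
    most = fit_linear(df, ModelSpec("y", "prs", ("age", "bmi")))
    assert base.r_squared_full <= more.r_squared_full + 1e-12
    assert more.r_squared_full <= most.r_squared_full + 1e-12


def test_population_filter_excludes_cad_and_lipid_lowering():
    rng = np.random.default_rng(2)
    n = 200
    df = pd.DataFrame({
        "prs": rng.integers(0, 11, n).astype(float),
        "y": rng.normal(3, 1, n),
        "cad": [1.0] * 50 + [0.0] * 150,
        "on_lipid_lowering": [0.0] * 150 + [1.0] * 50,
    })
    res = fit_linear(df, ModelSpec("y", "prs", exclude_cad_and_lipid_lowering=True))
    assert res.n_used == 100


def test_logistic_null_simulation_covers_one():
    rng = np.random.default_rng(3)
    n = 2000
    df = pd.DataFrame({"prs": rng.integers(0, 11, n).astype(float),
                       "y": rng.binomial(1, 0.3, n).astype(float)})
    res = fit_logistic(df, ModelSpec("y", "prs", family="logistic"))
    assert res.ci95[0] < 1.0 < res.ci95[1]


def test_logistic_degenerate_inputs():
    df = pd.DataFrame({"x": [0.0, 1.0, 2.0], "y": [1.0, 1.0, 1.0]})
    with pytest.raises(ValueError, match="single class"):
        fit_logistic(df, ModelSpec("y", "x", family="logistic"))
    sep = pd.DataFrame({"x": np.r_[np.zeros(20), np.ones(20)],
                        "y": np.r_[np.zeros(20), np.ones(20)]})
    res = fit_logistic(sep, ModelSpec("y", "x", family="logistic"))
    assert res.separation and np.isnan(res.estimate)


def test_quartile_contrast_layout_and_null_calibration():
    rng = np.random.default_rng(4)
    n = 800
    df = pd.DataFrame({"prs": rng.binomial(10, 0.4, n).astype(float),
                       "y": rng.binomial(1, 0.3, n).astype(float)})
    bins = bin_score(df["prs"], 4)
    results = bin_contrast(df, bins, "y", contrast="each_vs_first")
    assert len(results) == 3  # Q2, Q3, Q4 against Q1
    covered = sum(r.ci95[0] <= 1.0 <= r.ci95[1] for r in results)
    assert covered >= 2  # null: CIs should generally cover OR = 1


def test_tertile_contrast_detects_strong_effect():
    rng = np.random.default_rng(5)
    n = 900
    prs = rng.binomial(10, 0.4, n).astype(float)
    p = 1 / (1 + np.exp(-(-2 + 0.6 * (prs - prs.mean()))))
    df = pd.DataFrame({"prs": prs, "y": rng.binomial(1, p).astype(float)})
    bins = bin_score(df["prs"], 3)
    (res,) = bin_contrast(df, bins, "y")
    assert res.estimate > 1.0
    assert res.p_value < 0.05


def test_linear_table_layout(cohort_table):
    from lipidprs.pipeline import linear_models
    table = linear_table(linear_models(cohort_table))
    assert len(table) == 3
    assert {"beta_unadj", "explained_pct_unadj", "beta_adj",
            "explained_pct_adj"} <= set(table.columns)
    assert (table["explained_pct_adj"] >= table["explained_pct_unadj"] - 1e-9).all()
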