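import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lipidprs.lipids import (FriedewaldInvalid, PlanellaConstants, THRESHOLDS,
                             absolute_change_at_mean, categorize,
                             categorize_frame, derive_ldl_frame, friedewald_ldl,
                             mgdl_to_mmol, mmol_to_mgdl,
                             percent_change_per_allele, planella_ldl)


def test_friedewald_reference_values():
    assert friedewald_ldl(4.92, 1.36, 1.11) == pytest.approx(4.92 - 1.36 - 1.11 / 2.2)
    assert friedewald_ldl(4.0, 1.0, 0.0) == pytest.approx(3.0)
    with pytest.raises(FriedewaldInvalid):
        friedewald_ldl(5.0, 1.0, 4.0)
    with pytest.raises(ValueError):
        friedewald_ldl(-1.0, 1.0, 1.0)


@given(tc=st.floats(2, 10), hdl=st.floats(0.5, 3), tg=st.floats(0, 3.89))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_friedewald_monotonicity(tc, hdl, tg):
    base = friedewald_ldl(tc, hdl, tg)
    assert friedewald_ldl(tc + 0.5, hdl, tg) > base
    assert friedewald_ldl(tc, hdl + 0.2, tg) < base
    if tg + 0.1 < 3.9:
        assert friedewald_ldl(tc, hdl, tg + 0.1) < base


def test_planella_linear_strategy():
    assert planella_ldl(2.5, PlanellaConstants(slope=1.0, intercept=0.0)) == 2.5
    # default constants keep physiologic apoB in the physiologic LDL range
    assert 1.0 < planella_ldl(1.2) < 10.0
    assert np.isnan(planella_ldl(float("nan")))
    with pytest.raises(ValueError):
        planella_ldl(-0.1)


def test_ldl_derivation_frame_branches_and_provenance():
    pheno = pd.DataFrame({
        "tc": [4.92, 5.5, 6.0, 5.0],
        "hdl": [1.36, 1.2, 1.1, 1.3],
        "tg": [1.11, 4.2, 4.5, 1.0],
        "apob": [np.nan, 1.3, np.nan, np.nan],
        "ldl": [np.nan, np.nan, np.nan, 3.3],
    }, index=pd.Index(list("ABCD")))
    ldl, method = derive_ldl_frame(pheno)
    assert method.tolist() == ["friedewald", "planella", "missing", "measured"]
    assert ldl["A"] == pytest.approx(4.92 - 1.36 - 1.11 / 2.2)
    assert ldl["B"] == pytest.approx(2.70 * 1.3 - 0.30)
    assert np.isnan(ldl["C"])  # high TG without apoB stays missing
    assert ldl["D"] == 3.3


def test_unit_conversion_round_trip_and_analytes():
    for x in (0.0, 1.36, 4.92):
        assert mgdl_to_mmol(mmol_to_mgdl(x, "cholesterol"), "cholesterol") == pytest.approx(x)
        assert mgdl_to_mmol(mmol_to_mgdl(x, "triglyceride"), "triglyceride") == pytest.approx(x)
    with pytest.raises(ValueError):
        mmol_to_mgdl(1.0, "glucose")


def test_thresholds_pair_with_printed_mgdl_values():
    """Each guideline mg/dL cut converts back to its mmol/L partner at the
    partner's printed precision (the mmol/L values are rounded to 1–2
    decimals, e.g. 100 mg/dL → 2.586 → printed 2.6)."""
    printed = {"ldl_gt_2_6": 100, "ldl_gt_3_0": 116, "hdl_lt_1_03": 40,
               "hdl_gt_1_55": 60, "tg_gt_1_69": 150, "tg_gt_2_26": 200}
    for name, (lipid, _, cut) in THRESHOLDS.items():
        analyte = "triglyceride" if lipid == "tg" else "cholesterol"
        ndigits = len(str(cut).split(".")[1])
        assert round(mgdl_to_mmol(printed[name], analyte), ndigits) == cut


def test_log_scale_effect_interpretation():
    assert percent_change_per_allele(0.0) == 0.0
    assert percent_change_per_allele(-0.021) == pytest.approx(-2.078, abs=0.001)
    assert absolute_change_at_mean(0.018, 1.11) == pytest.approx(
        1.11 * (math.exp(0.018) - 1))
    with pytest.raises(ValueError):
        absolute_change_at_mean(0.01, 0.0)


def test_categorize_strict_inequalities_and_consistency():
    flags = categorize(ldl=3.0, hdl=1.6, tg=1.8)
    assert flags["ldl_gt_3_0"] is False  # strict ">" at the boundary
    assert flags["ldl_gt_2_6"] is True
    assert flags["hdl_gt_1_55"] is True and flags["hdl_lt_1_03"] is False
    assert flags["tg_gt_1_69"] is True and flags["tg_gt_2_26"] is False
    missing = categorize(hdl=1.0)
    assert missing["ldl_gt_2_6"] is None and missing["hdl_lt_1_03"] is True


@given(hdl=st.floats(0.2, 3.0))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_low_and_high_hdl_flags_never_both_true(hdl):
    flags = categorize(hdl=hdl)
    assert not (flags["hdl_lt_1_03"] and flags["hdl_gt_1_55"])


def test_categorize_frame_matches_scalar_path():
    pheno = pd.DataFrame({"ldl": [2.7, np.nan], "hdl": [1.0, 1.6],
                          "tg": [2.5, 1.0]}, index=pd.Index(["A", "B"]))
    frame = categorize_frame(pheno)
    assert frame.loc["A", "ldl_gt_2_6"] == True  # noqa: E712
    assert pd.isna(frame.loc["B", "ldl_gt_2_6"])
    assert frame.loc["B", "hdl_gt_1_55"] == True  # noqa: E712
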