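"""Classification rules: BMI categories, metabolic criteria, covariates."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metatrans import (
    IncompleteRecordError,
    UnderweightError,
    classify_checkups,
    classify_metabolic,
    classify_phenotype,
    classify_weight,
    count_metabolic_criteria,
    dichotomize_covariates,
)
from metatrans.phenotyping import convert_mgdl


@pytest.mark.parametrize(
    "bmi,expected",
    [
        (21.48, 0),  # a typical normal-weight median
        (23.999, 0),
        (24.0, 1),  # closed lower boundary of overweight
        (27.999, 1),
        (28.0, 2),  # closed lower boundary of obesity
        (35.0, 2),
        (18.5, 0),  # eligibility lower bound is included
    ],
)
def test_weight_categories(bmi, expected):
    assert classify_weight(bmi) == expected


def test_weight_rejects_underweight_and_nonfinite():
    with pytest.raises(UnderweightError):
        classify_weight(18.4)
    with pytest.raises(ValueError):
        classify_weight(float("nan"))


@given(a=st.floats(18.5, 60), b=st.floats(18.5, 60))
@settings(derandomize=True, max_examples=200, deadline=None)
def test_weight_monotone(a, b):
    if a <= b:
        assert classify_weight(a) <= classify_weight(b)


_HEALTHY_MALE = dict(sex="male", sbp=114, dbp=69, fpg=5.18, tg=0.80, hdl=1.41)


@pytest.mark.parametrize(
    "kwargs,expected",
    [
        # two criteria met (TG and low HDL for a female)
        (dict(sex="female", sbp=118, dbp=76, fpg=5.2, tg=1.90, hdl=1.01), 1),
        # all medians below every threshold
        (_HEALTHY_MALE, 0),
        # exactly one criterion met -> still healthy
        (dict(sex="male", sbp=135, dbp=80, fpg=5.0, tg=1.0, hdl=1.2), 0),
        # medication counts as criterion 1; FPG boundary is closed
        (
            dict(
                sex="female",
                sbp=110,
                dbp=70,
                fpg=5.6,
                tg=1.0,
                hdl=1.5,
                on_antihypertensive=True,
            ),
            1,
        ),
    ],
)
def test_metabolic_classification(kwargs, expected):
    assert classify_metabolic(**kwargs) == expected


@pytest.mark.parametrize(
    "field,at,above_meets",
    [
        ("sbp", 130.0, True),  # >= closed
        ("dbp", 85.0, True),
        ("fpg", 5.6, True),
        ("tg", 1.7, True),
    ],
)
def test_metabolic_threshold_sides(field, at, above_meets):
    base = dict(_HEALTHY_MALE)
    base[field] = at
    assert count_metabolic_criteria(**base) == 1  # boundary meets the criterion
    base[field] = at - 1e-9
    assert count_metabolic_criteria(**base) == 0


def test_hdl_strictly_less():
    assert count_metabolic_criteria(**{**_HEALTHY_MALE, "hdl": 1.0}) == 0
    assert count_metabolic_criteria(**{**_HEALTHY_MALE, "hdl": 0.999}) == 1
    f = dict(_HEALTHY_MALE, sex="female")
    assert count_metabolic_criteria(**{**f, "hdl": 1.3}) == 0
    assert count_metabolic_criteria(**{**f, "hdl": 1.299}) == 1


def test_absent_pg2h_not_missing_but_can_be_required():
    assert classify_metabolic(**_HEALTHY_MALE, pg2h=None) == 0
    assert count_metabolic_criteria(**_HEALTHY_MALE, pg2h=8.0) == 1
    with pytest.raises(IncompleteRecordError):
        count_metabolic_criteria(**_HEALTHY_MALE, pg2h=None, require_pg2h=True)


def test_missing_field_signals_incomplete():
    bad = dict(_HEALTHY_MALE, tg=float("nan"))
    with pytest.raises(IncompleteRecordError):
        classify_metabolic(**bad)


@given(
    sbp=st.floats(90, 180),
    dbp=st.floats(50, 110),
    fpg=st.floats(4, 8),
    tg=st.floats(0.3, 4),
    hdl=st.floats(0.5, 2.5),
    flip=st.integers(0, 3),
)
@settings(derandomize=True, max_examples=200, deadline=None)
def test_metabolic_monotone_in_criteria(sbp, dbp, fpg, tg, hdl, flip):
    """Forcing one more criterion true never flips unhealthy -> healthy."""
    base = dict(sex="male", sbp=sbp, dbp=dbp, fpg=fpg, tg=tg, hdl=hdl)
    before = classify_metabolic(**base)
    forced = dict(base)
    forced[["sbp", "fpg", "tg", "hdl"][flip]] = [200.0, 9.0, 5.0, 0.2][flip]
    assert classify_metabolic(**forced) >= before


@pytest.mark.parametrize(
    "levels,label,index",
    [
        ((0, 0), "MHNW", 1),
        ((1, 0), "MHOW", 2),
        ((2, 0), "MHO", 3),
        ((0, 1), "MUNW", 4),
        ((1, 1), "MUOW", 5),
        ((2, 1), "MUO", 6),
    ],
)
def test_phenotype_bijection(levels, label, index):
    state = classify_phenotype(*levels)
    assert (state.label, state.index) == (label, index)
    assert (state.weight_level, state.metabolic_level) == levels


def test_covariate_boundaries_belong_to_reference_group():
    v = dichotomize_covariates(sex="male", age=45, alt=40, ast=40, scr=133, ua=420)
    assert v.as_array().tolist() == [0, 0, 0, 0, 0, 0]
    v = dichotomize_covariates(sex="female", age=46, alt=41, ast=30, scr=90, ua=361)
    assert (v.female, v.middle_aged, v.alt_elevated, v.ua_elevated) == (1, 1, 1, 1)
    assert (v.ast_elevated, v.scr_elevated) == (0, 0)
    # sex-specific SCr cut-off: 107 is elevated for a female, normal for a male
    assert dichotomize_covariates(sex="female", age=30, alt=20, ast=20, scr=107, ua=300).scr_elevated == 1
    assert dichotomize_covariates(sex="male", age=30, alt=20, ast=20, scr=107, ua=300).scr_elevated == 0


def _frame(rows):
    cols = ["subject_id", "visit_time", "sex", "age", "bmi", "sbp", "dbp",
            "fpg", "tg", "hdl", "alt", "ast", "scr", "ua"]
    return pd.DataFrame(rows, columns=cols)


def test_dataframe_classification_matches_scalar_rules():
    df = _frame(
        [
            (1, 0.0, "male", 30, 21.0, 114, 69, 5.18, 0.8, 1.41, 15, 19, 59, 266),
            (1, 1.0, "male", 31, 24.5, 135, 86, 5.7, 1.8, 0.9, 45, 41, 140, 430),
            (2, 0.0, "female", 50, 29.0, 132, 88, 5.9, 2.0, 1.1, 20, 20, 108, 370),
        ]
    )
    out = classify_checkups(df)
    assert out["state"].tolist() == [1, 5, 6]
    assert out["phenotype"].tolist() == ["MHNW", "MUOW", "MUO"]
    assert out.loc[1, ["alt_elevated", "ast_elevated", "scr_elevated", "ua_elevated"]].tolist() == [1, 1, 1, 1]
    assert out.loc[2, ["female", "middle_aged", "scr_elevated", "ua_elevated"]].tolist() == [1, 1, 1, 1]


def test_dataframe_underweight_raises_or_drops():
    df = _frame([(1, 0.0, "male", 30, 18.2, 114, 69, 5.18, 0.8, 1.41, 15, 19, 59, 266)])
    with pytest.raises(UnderweightError):
        classify_checkups(df)
    assert len(classify_checkups(df, on_underweight="drop")) == 0


def test_mgdl_conversion_roundtrip():
    df = pd.DataFrame({"fpg": [100.0], "tg": [150.0], "hdl": [40.0], "scr": [1.0]})
    out = convert_mgdl(df)
    assert math.isclose(out["fpg"][0], 5.551, abs_tol=0.001)
    assert math.isclose(out["tg"][0], 1.6936, abs_tol=0.001)
    assert math.isclose(out["hdl"][0], 1.0344, abs_tol=0.001)
    assert math.isclose(out["scr"][0], 88.42, abs_tol=0.001)
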