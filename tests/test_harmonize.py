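"""Derived variables: BMI, Friedewald LDL, adjustments, outliers, diseases."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spousesim import (
    activity_threshold,
    apply_treatment_adjustment,
    classify_diseases,
    compute_bmi,
    derive_all,
    flag_outliers,
    friedewald_ldl,
    generate_cohort,
    recode_education,
)
from spousesim.config import MedicationModel, TreatmentAdjustmentPolicy
from spousesim.harmonize import HarmonizationError

from conftest import make_cohort, make_participants, minimal_config, null_trait


@pytest.mark.parametrize(
    "weight,height,expected",
    [(80, 200, 20.0), (66.5, 166.7, 23.93), (54.1, 154.4, 22.70)],
)
def test_bmi(weight, height, expected):
    assert compute_bmi(weight, height) == pytest.approx(expected, abs=0.01)


def test_bmi_rejects_nonpositive():
    with pytest.raises(HarmonizationError):
        compute_bmi(0, 170)
    with pytest.raises(HarmonizationError):
        compute_bmi(70, -1)


@pytest.mark.parametrize(
    "tc,hdl,tg,expected",
    [(200, 50, 100, 130.0), (180, 60, 0, 120.0)],
)
def test_friedewald(tc, hdl, tg, expected):
    assert friedewald_ldl(tc, hdl, tg) == expected


def test_friedewald_invalid_above_tg_limit():
    assert math.isnan(friedewald_ldl(200, 50, 400))
    with pytest.raises(HarmonizationError):
        friedewald_ldl(-1, 50, 100)


def test_treatment_adjustment_constants():
    df = make_participants(
        [
            dict(id="a", sex="male", age=60, sbp=130.0, tc=160.0, on_antihypertensive=True,
                 on_lipid_lowering=True),
            dict(id="b", sex="male", age=60, sbp=130.0, tc=160.0),
        ]
    )
    adj = apply_treatment_adjustment(df)
    assert adj.loc[0, "sbp_adj"] == 145.0
    assert adj.loc[0, "dbp_adj"] != adj.loc[0, "dbp_adj"]  # missing stays missing
    assert adj.loc[0, "tc_adj"] == pytest.approx(200.0)
    assert adj.loc[1, "sbp_adj"] == 130.0
    assert adj.loc[1, "tc_adj"] == 160.0


def test_back_adjustment_inverts_generator_attenuation():
    """The generator stores treatment-attenuated measurements; the
    back-adjustment recovers the pre-treatment values exactly."""
    cfg = minimal_config(
        n_pairs=500,
        traits={
            "sbp": null_trait(mean_m=150.0, mean_f=145.0, sd_m=16.0, sd_f=17.0),
            "dbp": null_trait(mean_m=88.0, mean_f=85.0, sd_m=10.0, sd_f=10.0),
            "tc": null_trait(mean_m=210.0, mean_f=215.0, sd_m=30.0, sd_f=33.0),
            "ldl": null_trait(mean_m=140.0, mean_f=140.0, sd_m=30.0, sd_f=30.0),
        },
        medications={
            "antihypertensive": MedicationModel(triggers={"sbp": 140.0, "dbp": 90.0}, prob=0.7),
            "lipid_lowering": MedicationModel(triggers={"ldl": 140.0}, prob=0.6),
        },
    )
    cohort = generate_cohort(cfg, seed=9)
    part = cohort.participants
    treated = part["on_antihypertensive"].fillna(False).astype(bool)
    assert treated.any() and part["on_lipid_lowering"].fillna(False).astype(bool).any()
    adj = apply_treatment_adjustment(part)
    # attenuation was sbp-15 / ldl*0.7, so adding/dividing back restores the
    # draw; untreated rows pass through untouched
    assert np.allclose(adj.loc[treated, "sbp_adj"], part.loc[treated, "sbp"] + 15.0)
    lip = part["on_lipid_lowering"].fillna(False).astype(bool)
    assert np.allclose(adj.loc[lip, "ldl_adj"], part.loc[lip, "ldl"] / 0.7)
    assert np.allclose(adj.loc[~treated, "sbp_adj"], part.loc[~treated, "sbp"])


def test_flag_outliers_cases():
    assert flag_outliers([1, 1, 1, 1, 1], k=5).all()
    rng = np.random.default_rng(0)
    vals = np.concatenate([rng.standard_normal(1000), [8.0]])
    include = flag_outliers(vals, k=5)
    # independent recomputation of the single-pass rule
    mean, sd = vals.mean(), vals.std(ddof=1)
    assert abs(8.0 - mean) > 5 * sd
    assert not include[-1]
    assert include[:-1].all()
    with pytest.raises(HarmonizationError):
        flag_outliers([1.0], k=5)
    # missing values never included, never used for mean/SD
    inc = flag_outliers([1.0, np.nan, 2.0, 3.0], k=5)
    assert list(inc) == [True, False, True, True]


@settings(derandomize=True, max_examples=30)
@given(st.lists(st.floats(min_value=-100, max_value=100), min_size=2, max_size=25))
def test_outlier_rule_spares_bounded_samples(values):
    """No point in a sample of <=25 bounded values can exceed mean±5·SD."""
    if np.std(values, ddof=1) == 0:
        assert flag_outliers(values, k=5).all()
    else:
        assert flag_outliers(values, k=5).all()


def _disease_row(**kwargs):
    base = dict(id="x", sex="male", age=60)
    base.update(kwargs)
    return make_participants([base])


def test_mets_requires_waist_criterion():
    df = _disease_row(waist=84.0, sbp=160.0, dbp=80.0, hba1c=7.0, tg=300.0, hdl=30.0)
    flags = classify_diseases(df)
    assert flags.loc[0, "metabolic_syndrome"] == False  # noqa: E712


def test_mets_two_of_three():
    df = _disease_row(waist=90.0, sbp=135.0, dbp=80.0, hba1c=6.1, tg=100.0, hdl=60.0)
    flags = classify_diseases(df)
    assert flags.loc[0, "metabolic_syndrome"] == True  # noqa: E712


def test_hypertension_strict_thresholds():
    df = _disease_row(sbp=139.0, dbp=89.0)
    assert classify_diseases(df).loc[0, "hypertension"] == False  # noqa: E712
    df = _disease_row(sbp=140.0, dbp=60.0)
    assert classify_diseases(df).loc[0, "hypertension"] == True  # noqa: E712
    df = _disease_row(sbp=120.0, dbp=70.0, on_antihypertensive=True)
    assert classify_diseases(df).loc[0, "hypertension"] == True  # noqa: E712


def test_disease_flags_missing_when_undecidable():
    flags = classify_diseases(_disease_row(sbp=130.0))  # dbp unknown, could be >=90
    assert pd.isna(flags.loc[0, "hypertension"])
    flags = classify_diseases(_disease_row(sbp=150.0))  # decided by sbp alone
    assert flags.loc[0, "hypertension"] == True  # noqa: E712
    assert pd.isna(classify_diseases(_disease_row()).loc[0, "diabetes"])


@settings(derandomize=True, max_examples=40)
@given(
    sbp=st.floats(min_value=80, max_value=139),
    bump=st.floats(min_value=0, max_value=120),
)
def test_hypertension_monotone_in_sbp(sbp, bump):
    lo = classify_diseases(_disease_row(sbp=sbp, dbp=70.0)).loc[0, "hypertension"]
    hi = classify_diseases(_disease_row(sbp=sbp + bump, dbp=70.0)).loc[0, "hypertension"]
    assert not (lo == True and hi == False)  # noqa: E712


@pytest.mark.parametrize(
    "values,p,expected",
    [(list(range(1, 11)), 80, 8.2), ([5, 5, 5, 5], 37, 5.0), ([3, 1, 2], 0, 1.0)],
)
def test_activity_threshold(values, p, expected):
    assert activity_threshold(values, p) == pytest.approx(expected)


def test_activity_threshold_needs_data():
    with pytest.raises(HarmonizationError):
        activity_threshold([], 80)


@pytest.mark.parametrize(
    "raw,expected",
    [
        ("elementary or junior high school", "low"),
        ("high school", "medium"),
        ("vocational school", "medium"),
        ("college or technical college", "high"),
        ("university", "high"),
        ("graduate school", "high"),
        ("other", None),
        (None, None),
    ],
)
def test_recode_education(raw, expected):
    assert recode_education(raw) == expected


def test_recode_education_unknown():
    with pytest.raises(HarmonizationError):
        recode_education("kindergarten")


def test_derive_all_single_couple(tiny_couples):
    derived = derive_all(tiny_couples)
    assert derived["bmi"].notna().all()
    assert derived["log_tg"].notna().all()
    assert derived["hypertension"].notna().all()
    assert (derived["hba1c_analysis_eligible"]).all()
    m1 = derived.set_index("id").loc["M1"]
    assert m1["bmi"] == pytest.approx(70 / 1.70**2)
    assert m1["education"] == "medium"


def test_derive_all_log_tg_domain():
    cohort = make_cohort(
        [dict(id="M1", sex="male", age=60, tg=0.0), dict(id="F1", sex="female", age=58, tg=100.0)],
        [("M1", "F1")],
    )
    derived = derive_all(cohort).set_index("id")
    assert math.isnan(derived.loc["M1", "log_tg"])
    assert derived.loc["F1", "log_tg"] == pytest.approx(2.0)


def test_hba1c_eligibility_excludes_treated():
    cohort = make_cohort(
        [
            dict(id="M1", sex="male", age=60, hba1c=7.0, on_glucose_lowering=True),
            dict(id="F1", sex="female", age=58, hba1c=5.5),
        ],
        [("M1", "F1")],
    )
    derived = derive_all(cohort).set_index("id")
    assert not derived.loc["M1", "hba1c_analysis_eligible"]
    assert derived.loc["F1", "hba1c_analysis_eligible"]


def test_derive_all_idempotent():
    cfg = minimal_config(n_pairs=120, missing_rates={"sbp": 0.1})
    cohort = generate_cohort(cfg, seed=4)
    once = derive_all(cohort)
    from spousesim import PairedCohort

    twice = derive_all(PairedCohort(once, cohort.pairs))
    pd.testing.assert_frame_equal(once, twice[once.columns])


def test_friedewald_fills_missing_ldl_in_derive():
    cohort = make_cohort(
        [
            dict(id="M1", sex="male", age=60, tc=200.0, hdl=50.0, tg=100.0),
            dict(id="F1", sex="female", age=58, tc=200.0, hdl=50.0, tg=450.0),
        ],
        [("M1", "F1")],
    )
    derived = derive_all(cohort).set_index("id")
    assert derived.loc["M1", "ldl"] == pytest.approx(130.0)
    assert math.isnan(derived.loc["F1", "ldl"])  # TG beyond Friedewald validity


def test_outlier_screening_blanks_derived_value_only():
    rows = [dict(id=f"M{i}", sex="male", age=60, sbp=120.0 + i) for i in range(30)]
    rows[0]["sbp"] = 5000.0
    rows += [dict(id=f"F{i}", sex="female", age=58, sbp=118.0 + i) for i in range(30)]
    cohort = make_cohort([dict(r) for r in rows], [(f"M{i}", f"F{i}") for i in range(30)])
    derived = derive_all(cohort).set_index("id")
    assert math.isnan(derived.loc["M0", "sbp_adj"])
    assert derived.loc["M0", "sbp"] == 5000.0  # raw measurement untouched
    assert derived.loc["M1", "sbp_adj"] == 121.0
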