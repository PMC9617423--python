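"""Derivation of analysis variables from raw participant records.

Covers BMI, Friedewald LDL, treatment back-adjustment of blood pressure and
lipids, log10 triglycerides, ±k·SD outlier exclusion per variable per sex,
disease classification (hypertension, type 2 diabetes, metabolic syndrome by
the Japanese criteria), lifestyle recodes and the education recode.

Disease flags are evaluated on raw measured values; the treatment
back-adjustment exists only to restore the population ranking of treated
individuals for the correlation analyses.
"""
from __future__ import annotations

import math
from typing import Iterable

import numpy as np
import pandas as pd

from .cohort import PairedCohort
from .config import DiseaseCriteria, TreatmentAdjustmentPolicy

__all__ = [
    "HarmonizationError",
    "compute_bmi",
    "friedewald_ldl",
    "apply_treatment_adjustment",
    "flag_outliers",
    "classify_diseases",
    "activity_threshold",
    "recode_education",
    "derive_all",
    "FRIEDEWALD_TG_LIMIT",
    "OUTLIER_VARIABLES",
]


class HarmonizationError(ValueError):
    pass


#: Friedewald estimation is unreliable at high triglycerides (mg/dL).
FRIEDEWALD_TG_LIMIT = 400.0

#: Analysis variables subject to the ±k·SD exclusion, per sex.
OUTLIER_VARIABLES = [
    "weight", "height", "waist", "bmi", "sbp_adj", "dbp_adj",
    "hba1c", "tc_adj", "log_tg", "hdl", "ldl_adj", "met_hours",
]

_EDUCATION_MAP = {
    "elementary or junior high school": "low",
    "high school": "medium",
    "vocational school": "medium",
    "college or technical college": "high",
    "university": "high",
    "graduate school": "high",
    "other": None,
}


def compute_bmi(weight: float, height: float) -> float:
    """Body-mass index: weight (kg) over squared height (m)."""
    if not (weight > 0 and height > 0):
        raise HarmonizationError(f"non-positive weight/height: {weight}, {height}")
    return weight / (height / 100.0) ** 2


def friedewald_ldl(tc: float, hdl: float, tg: float) -> float:
    """LDL cholesterol (mg/dL) by the Friedewald equation, NaN above the TG limit."""
    if tc < 0 or hdl < 0 or tg < 0:
        raise HarmonizationError("negative lipid input")
    if tg >= FRIEDEWALD_TG_LIMIT:
        return float("nan")
    return tc - hdl - tg / 5.0


def apply_treatment_adjustment(
    df: pd.DataFrame, policy: TreatmentAdjustmentPolicy | None = None
) -> pd.DataFrame:
    """Back-adjusted BP and lipid columns for treated individuals.

    Returns a frame with sbp_adj, dbp_adj, tc_adj, ldl_adj: for people on
    antihypertensive medication the additive effects are added back to
    SBP/DBP; for people on lipid-lowering medication TC and LDL are divided
    by the expected proportional reduction.  Missing inputs stay missing.
    """
    policy = policy or TreatmentAdjustmentPolicy()
    out = pd.DataFrame(index=df.index)
    bp = df["on_antihypertensive"].fillna(False).astype(bool).to_numpy()
    lip = df["on_lipid_lowering"].fillna(False).astype(bool).to_numpy()
    out["sbp_adj"] = np.where(bp, df["sbp"] + policy.sbp_add, df["sbp"])
    out["dbp_adj"] = np.where(bp, df["dbp"] + policy.dbp_add, df["dbp"])
    out["tc_adj"] = np.where(lip, df["tc"] / policy.tc_divisor, df["tc"])
    out["ldl_adj"] = np.where(lip, df["ldl"] / policy.ldl_divisor, df["ldl"])
    return out


def flag_outliers(values: Iterable[float], k: float = 5.0) -> np.ndarray:
    """Inclusion mask: False where |x − mean| > k·SD or x is missing.

    Mean and SD are computed once over the non-missing values (single pass,
    no re-iteration after exclusion).
    """
    if k <= 0:
        raise HarmonizationError("k must be positive")
    x = np.asarray(values, dtype=float)
    ok = ~np.isnan(x)
    if ok.sum() < 2:
        raise HarmonizationError("need at least 2 non-missing values for outlier screening")
    mean = x[ok].mean()
    sd = x[ok].std(ddof=1)
    include = ok & (np.abs(x - mean) <= k * sd)
    return include


def classify_diseases(
    df: pd.DataFrame, criteria: DiseaseCriteria | None = None
) -> pd.DataFrame:
    """Hypertension, type 2 diabetes and metabolic-syndrome flags.

    Uses raw measured SBP/DBP/HbA1c (not back-adjusted values).  A flag is
    missing whenever a component required to decide it is missing.
    Metabolic syndrome requires the sex-specific waist criterion plus at
    least two of: elevated BP (or BP medication), hyperglycaemia (or glucose
    medication), high TG / low HDL (or lipid medication).
    """
    c = criteria or DiseaseCriteria()
    out = pd.DataFrame(index=df.index)

    def _num(col):
        return pd.to_numeric(df[col], errors="coerce")

    def _med(col):
        return df[col].astype("boolean")

    sbp, dbp, hba1c = _num("sbp"), _num("dbp"), _num("hba1c")
    tg, hdl, waist = _num("tg"), _num("hdl"), _num("waist")
    bp_med, glu_med, lip_med = _med("on_antihypertensive"), _med("on_glucose_lowering"), _med("on_lipid_lowering")

    def _cmp(series: pd.Series, op: str, thr) -> pd.arrays.BooleanArray:
        # comparison with NA propagation (NaN comparisons are unknown, not False)
        arr = pd.array(series.ge(thr) if op == "ge" else series.lt(thr), dtype="boolean")
        arr[series.isna().to_numpy()] = pd.NA
        return arr

    # Kleene logic: a flag is missing exactly when the missing components
    # could change its truth value
    htn = _cmp(sbp, "ge", c.htn_sbp) | _cmp(dbp, "ge", c.htn_dbp) | bp_med.array
    out["hypertension"] = htn
    out["diabetes"] = _cmp(hba1c, "ge", c.dm_hba1c) | glu_med.array

    waist_thr = pd.Series(np.where(df["sex"] == "male", c.mets_waist_m, c.mets_waist_f), index=df.index)
    waist_crit = pd.array(waist.ge(waist_thr), dtype="boolean")
    waist_crit[waist.isna().to_numpy()] = pd.NA

    bp_crit = _cmp(sbp, "ge", c.mets_sbp) | _cmp(dbp, "ge", c.mets_dbp) | bp_med.array
    glu_crit = _cmp(hba1c, "ge", c.mets_hba1c) | glu_med.array
    lip_crit = _cmp(tg, "ge", c.mets_tg) | _cmp(hdl, "lt", c.mets_hdl) | lip_med.array

    crit_list = [bp_crit, glu_crit, lip_crit]
    known_true = sum(c.fillna(False).to_numpy(dtype=int) for c in crit_list)
    unknown = sum(c.isna().astype(int) for c in crit_list)
    two_plus = pd.array(known_true >= 2, dtype="boolean")
    two_plus[(known_true < 2) & (known_true + unknown >= 2)] = pd.NA

    out["metabolic_syndrome"] = waist_crit & two_plus
    return out


def activity_threshold(men_met_values: Iterable[float], percentile: float = 80.0) -> float:
    """Physical-activity cut-off: a percentile of the men's MET·hours/day.

    Linear interpolation between order statistics; the same cut-off is
    applied to both sexes downstream (active iff met_hours >= threshold).
    """
    x = np.asarray(list(men_met_values), dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 2:
        raise HarmonizationError("need at least 2 non-missing male MET values")
    if not 0 <= percentile <= 100:
        raise HarmonizationError("percentile must be in [0, 100]")
    return float(np.percentile(x, percentile, method="linear"))


def recode_education(raw: str | None) -> str | None:
    """Collapse the seven questionnaire categories to low/medium/high.

    'other' is treated as missing.
    """
    if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw is pd.NA:
        return None
    if raw not in _EDUCATION_MAP:
        raise HarmonizationError(f"unknown education category: {raw!r}")
    return _EDUCATION_MAP[raw]


def derive_all(
    cohort: PairedCohort,
    criteria: DiseaseCriteria | None = None,
    policy: TreatmentAdjustmentPolicy | None = None,
) -> pd.DataFrame:
    """Full derived table: one row per participant with all analysis columns.

    Recomputes everything from the raw columns (idempotent by construction).
    Outlier screening (±outlier_sd SD, per variable per sex) blanks the
    derived analysis value, never the raw measurement.  HbA1c analyses later
    exclude anyone on glucose-lowering medication via
    ``hba1c_analysis_eligible``.
    """
    c = criteria or DiseaseCriteria()
    policy = policy or TreatmentAdjustmentPolicy()
    df = cohort.participants.copy()

    hw = df["height"].notna() & df["weight"].notna() & (df["height"] > 0) & (df["weight"] > 0)
    df["bmi"] = np.where(hw, df["weight"] / (df["height"] / 100.0) ** 2, np.nan)

    # fill LDL via Friedewald where missing but components are present
    need_ldl = df["ldl"].isna() & df["tc"].notna() & df["hdl"].notna() & df["tg"].notna()
    valid_tg = df["tg"] < FRIEDEWALD_TG_LIMIT
    df.loc[need_ldl & valid_tg, "ldl"] = (
        df.loc[need_ldl & valid_tg, "tc"]
        - df.loc[need_ldl & valid_tg, "hdl"]
        - df.loc[need_ldl & valid_tg, "tg"] / 5.0
    )

    df[["sbp_adj", "dbp_adj", "tc_adj", "ldl_adj"]] = apply_treatment_adjustment(df, policy)
    df["log_tg"] = np.where(df["tg"] > 0, np.log10(df["tg"].where(df["tg"] > 0)), np.nan)

    df[["hypertension", "diabetes", "metabolic_syndrome"]] = classify_diseases(df, c)

    df["current_smoker"] = pd.array(df["smoking"] == "current", dtype="boolean")
    df.loc[df["smoking"].isna(), "current_smoker"] = pd.NA
    df["current_drinker"] = pd.array(df["drinking"] == "current", dtype="boolean")
    df.loc[df["drinking"].isna(), "current_drinker"] = pd.NA

    men_met = df.loc[(df["sex"] == "male") & df["met_hours"].notna(), "met_hours"]
    if len(men_met) >= 2:
        thr = activity_threshold(men_met, c.activity_percentile)
        df["sufficiently_active"] = pd.array(df["met_hours"] >= thr, dtype="boolean")
        df.loc[df["met_hours"].isna(), "sufficiently_active"] = pd.NA
    else:
        df["sufficiently_active"] = pd.array([pd.NA] * len(df), dtype="boolean")

    df["education"] = [recode_education(v) for v in df["education_raw"]]
    df["hba1c_analysis_eligible"] = ~df["on_glucose_lowering"].fillna(False).astype(bool)

    # per-sex outlier screening of analysis columns
    for var in OUTLIER_VARIABLES:
        for sex in ("male", "female"):
            idx = df.index[df["sex"] == sex]
            vals = df.loc[idx, var].astype(float)
            if vals.notna().sum() < 2:
                continue
            include = flag_outliers(vals.to_numpy(), c.outlier_sd)
            df.loc[idx[~include & vals.notna().to_numpy()], var] = np.nan
    return df
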