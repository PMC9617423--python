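"""Descriptive cohort table with male-versus-female group tests.

Continuous variables are summarized as mean (SD) and compared by the
pooled-variance Student t test; triglycerides, being right-skewed, as
median [IQR] with the Mann–Whitney U test (normal approximation with tie
correction); categorical variables as n (%) with the Pearson chi-square
test without continuity correction.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["DescriptiveRow", "describe_cohort", "percent", "DescribeError"]


class DescribeError(ValueError):
    pass


def percent(count: int, denominator: int) -> float:
    """A percentage rounded to one decimal, as printed in descriptive tables."""
    if denominator <= 0:
        raise DescribeError("denominator must be positive")
    if count < 0 or count > denominator:
        raise DescribeError("count must be between 0 and the denominator")
    return round(100.0 * count / denominator, 1)


@dataclass
class DescriptiveRow:
    variable: str
    n_available: int
    male_summary: str
    female_summary: str
    test: str
    p_value: Optional[float]


_CONTINUOUS = [
    ("age", "Age, years"),
    ("weight", "Weight, kg"),
    ("height", "Height, cm"),
    ("waist", "Waist circumference, cm"),
    ("bmi", "Body mass index, kg/m2"),
    ("sbp", "SBP, mmHg"),
    ("dbp", "DBP, mmHg"),
    ("hba1c", "HbA1c, %"),
    ("tc", "Total cholesterol, mg/dL"),
    ("hdl", "HDL-C, mg/dL"),
    ("ldl", "LDL-C, mg/dL"),
]

_CATEGORICAL = [
    ("smoking", "Smoking status"),
    ("drinking", "Alcohol consumption status"),
    ("education", "Education level"),
    ("sufficiently_active", "Sufficient physical activity"),
    ("hypertension", "Hypertension"),
    ("diabetes", "Type 2 diabetes"),
    ("metabolic_syndrome", "Metabolic syndrome"),
]


def _paired_members(derived: pd.DataFrame, pairs: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    idx = derived.set_index("id")
    return idx.loc[pairs["male_id"]], idx.loc[pairs["female_id"]]


def describe_cohort(derived: pd.DataFrame, pairs: pd.DataFrame) -> list[DescriptiveRow]:
    """Descriptive rows for the paired participants of a derived cohort.

    ``n_available`` counts pairs where both members have the variable,
    mirroring per-row denominators in paired descriptive tables.
    """
    if len(pairs) == 0:
        raise DescribeError("empty cohort")
    males, females = _paired_members(derived, pairs)
    rows: list[DescriptiveRow] = []

    for col, label in _CONTINUOUS:
        m = males[col].astype(float).to_numpy()
        f = females[col].astype(float).to_numpy()
        both = ~(np.isnan(m) | np.isnan(f))
        m, f = m[both], f[both]
        if len(m) < 2:
            continue
        t, p = stats.ttest_ind(m, f, equal_var=True)
        rows.append(
            DescriptiveRow(label, int(both.sum()),
                           f"{m.mean():.1f} ({m.std(ddof=1):.1f})",
                           f"{f.mean():.1f} ({f.std(ddof=1):.1f})",
                           "student-t", float(p))
        )

    m = males["tg"].astype(float).to_numpy()
    f = females["tg"].astype(float).to_numpy()
    both = ~(np.isnan(m) | np.isnan(f))
    m, f = m[both], f[both]
    if len(m) >= 2:
        _, p = stats.mannwhitneyu(m, f, alternative="two-sided", method="asymptotic")
        rows.append(
            DescriptiveRow(
                "Triglycerides, mg/dL", int(both.sum()),
                f"{np.median(m):.0f} [{np.percentile(m, 25):.0f}-{np.percentile(m, 75):.0f}]",
                f"{np.median(f):.0f} [{np.percentile(f, 25):.0f}-{np.percentile(f, 75):.0f}]",
                "mann-whitney-u", float(p),
            )
        )

    for col, label in _CATEGORICAL:
        m = males[col]
        f = females[col]
        both = m.notna().to_numpy() & f.notna().to_numpy()
        m, f = m[both], f[both]
        if both.sum() == 0:
            continue
        levels = sorted(set(m.dropna().unique()) | set(f.dropna().unique()), key=str)
        if len(levels) < 2:
            continue
        table = np.array(
            [[(m == lev).sum() for lev in levels], [(f == lev).sum() for lev in levels]]
        )
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        n = int(both.sum())
        msum = "; ".join(f"{lev}: {cnt} ({percent(int(cnt), n)}%)" for lev, cnt in zip(levels, table[0]))
        fsum = "; ".join(f"{lev}: {cnt} ({percent(int(cnt), n)}%)" for lev, cnt in zip(levels, table[1]))
        rows.append(DescriptiveRow(label, n, msum, fsum, "chi-square", float(p)))
    return rows


def descriptive_frame(rows: list[DescriptiveRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variable": [r.variable for r in rows],
            "n_available": [r.n_available for r in rows],
            "male_summary": [r.male_summary for r in rows],
            "female_summary": [r.female_summary for r in rows],
            "test": [r.test for r in rows],
            "p_value": [r.p_value for r in rows],
        }
    )
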