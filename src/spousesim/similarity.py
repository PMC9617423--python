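"""Pairwise trait correlations between partners, simple and age-adjusted.

The simple estimate is the Pearson correlation of (male value, female value)
over pairs where both members have the variable.  The age-adjusted estimate
replaces each person's value with the residual from a sex-specific ordinary
least-squares regression of the value on age, fitted over exactly the
individuals entering that variable's analysis; correlating the residuals
removes similarity that is explained by the couple's age alignment alone.
Confidence intervals use the Fisher z transform with standard error
1/sqrt(n − 3).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "CorrelationResult",
    "SimilarityError",
    "fisher_ci",
    "pearson_with_ci",
    "age_residuals",
    "pair_correlation",
    "SpousalSimilarity",
    "SimilarityResults",
    "CONTINUOUS_VARIABLES",
]


class SimilarityError(ValueError):
    pass


#: analysis variable -> (derived column, transform tag)
CONTINUOUS_VARIABLES: dict[str, tuple[str, str]] = {
    "age": ("age", "none"),
    "weight": ("weight", "none"),
    "height": ("height", "none"),
    "waist": ("waist", "none"),
    "bmi": ("bmi", "none"),
    "sbp": ("sbp_adj", "none"),
    "dbp": ("dbp_adj", "none"),
    "hba1c": ("hba1c", "none"),
    "tc": ("tc_adj", "none"),
    "tg": ("log_tg", "log10"),
    "hdl": ("hdl", "none"),
    "ldl": ("ldl_adj", "none"),
}


@dataclass
class CorrelationResult:
    """Spousal correlation of one variable with Fisher-z confidence limits."""

    variable: str
    n_pairs: int
    r_simple: float
    ci_simple: tuple[float, float]
    r_adjusted: Optional[float] = None
    ci_adjusted: Optional[tuple[float, float]] = None
    transform: str = "none"


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a Pearson correlation.

    tanh(atanh(r) ± z_{1−α/2} / sqrt(n − 3)); degenerate (|r| = 1) inputs
    return the point itself.
    """
    if n < 4:
        raise SimilarityError(f"need at least 4 pairs for a CI (got {n})")
    if abs(r) >= 1.0:
        return (r, r)
    z = stats.norm.ppf(0.5 + level / 2.0)
    zr = np.arctanh(r)
    half = z / np.sqrt(n - 3)
    return (float(np.tanh(zr - half)), float(np.tanh(zr + half)))


def pearson_with_ci(x: Iterable[float], y: Iterable[float], level: float = 0.95) -> tuple[float, float, float]:
    """Pearson r over pairwise-complete entries, with its Fisher-z CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise SimilarityError("x and y must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        raise SimilarityError(f"need at least 4 complete pairs (got {n})")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise SimilarityError("zero variance: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    # collinear inputs can land a few ulps inside ±1; snap so the CI
    # degenerates to the point rather than exploding through atanh
    if abs(r) >= 1.0 - 1e-15:
        r = math.copysign(1.0, r)
    lo, hi = fisher_ci(r, n, level)
    return r, lo, hi


def age_residuals(values: Iterable[float], ages: Iterable[float]) -> np.ndarray:
    """OLS residuals of value on age (intercept + linear term).

    Called separately per sex.  Residuals sum to zero by construction.
    """
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if len(values) != len(ages):
        raise SimilarityError("values and ages must align")
    ok = ~(np.isnan(values) | np.isnan(ages))
    if ok.sum() < 3:
        raise SimilarityError("need at least 3 complete (value, age) pairs")
    if np.ptp(ages[ok]) == 0:
        raise SimilarityError("all ages identical: age coefficient unidentifiable")
    out = np.full(len(values), np.nan)
    X = sm.add_constant(ages[ok])
    out[ok] = sm.OLS(values[ok], X).fit().resid
    return out


def _pair_values(derived: pd.DataFrame, pairs: pd.DataFrame, variable: str) -> pd.DataFrame:
    if variable not in CONTINUOUS_VARIABLES:
        raise SimilarityError(f"unknown variable: {variable!r}")
    column, _ = CONTINUOUS_VARIABLES[variable]
    idx = derived.set_index("id")
    tab = pd.DataFrame(
        {
            "value_m": idx.loc[pairs["male_id"], column].to_numpy(dtype=float),
            "value_f": idx.loc[pairs["female_id"], column].to_numpy(dtype=float),
            "age_m": idx.loc[pairs["male_id"], "age"].to_numpy(dtype=float),
            "age_f": idx.loc[pairs["female_id"], "age"].to_numpy(dtype=float),
        }
    )
    if variable == "hba1c":
        elig_m = idx.loc[pairs["male_id"], "hba1c_analysis_eligible"].to_numpy(dtype=bool)
        elig_f = idx.loc[pairs["female_id"], "hba1c_analysis_eligible"].to_numpy(dtype=bool)
        tab = tab[elig_m & elig_f]
    return tab.dropna()


def pair_correlation(
    derived: pd.DataFrame,
    pairs: pd.DataFrame,
    variable: str,
    adjusted: bool = True,
    level: float = 0.95,
) -> CorrelationResult:
    """Spousal correlation for one variable on a derived cohort.

    Pairs are dropped when either member lacks the variable (and, for HbA1c,
    when either member is on glucose-lowering medication).  With
    ``adjusted=True`` the result additionally carries the age-residual
    correlation; age itself has no adjusted version.
    """
    tab = _pair_values(derived, pairs, variable)
    n = len(tab)
    if n < 4:
        raise SimilarityError(f"{variable}: only {n} usable pairs")
    r, lo, hi = pearson_with_ci(tab["value_m"], tab["value_f"], level)
    result = CorrelationResult(
        variable=variable,
        n_pairs=n,
        r_simple=r,
        ci_simple=(lo, hi),
        transform=CONTINUOUS_VARIABLES[variable][1],
    )
    if adjusted and variable != "age":
        res_m = age_residuals(tab["value_m"], tab["age_m"])
        res_f = age_residuals(tab["value_f"], tab["age_f"])
        ra, alo, ahi = pearson_with_ci(res_m, res_f, level)
        result.r_adjusted = ra
        result.ci_adjusted = (alo, ahi)
    return result


class SpousalSimilarity:
    """Model of partner similarity in continuous traits for one pairing.

    Parameters
    ----------
    derived : DataFrame
        Output of :func:`spousesim.harmonize.derive_all`.
    pairs : DataFrame
        Pair table (spouse or randomized origin).
    variables : sequence of str, optional
        Defaults to every variable in :data:`CONTINUOUS_VARIABLES`.
    level : float
        Confidence level for all intervals.
    errors : {'raise', 'skip'}
        With 'skip', variables with too little usable data are silently
        dropped from the results instead of raising.
    """

    def __init__(
        self,
        derived: pd.DataFrame,
        pairs: pd.DataFrame,
        variables: Optional[Iterable[str]] = None,
        level: float = 0.95,
        errors: str = "raise",
    ) -> None:
        self.derived = derived
        self.pairs = pairs
        self.variables = list(variables) if variables is not None else list(CONTINUOUS_VARIABLES)
        self.level = level
        self.errors = errors

    @classmethod
    def from_cohort(cls, cohort, criteria=None, policy=None, **kwargs) -> "SpousalSimilarity":
        from .harmonize import derive_all

        return cls(derive_all(cohort, criteria, policy), cohort.pairs, **kwargs)

    def fit(self) -> "SimilarityResults":
        results = []
        for v in self.variables:
            try:
                results.append(pair_correlation(self.derived, self.pairs, v, adjusted=True, level=self.level))
            except SimilarityError:
                if self.errors != "skip":
                    raise
        return SimilarityResults(results, self.level)


class SimilarityResults:
    """Fitted spousal-similarity correlations with a tabular summary."""

    def __init__(self, results: list[CorrelationResult], level: float) -> None:
        self.results = {r.variable: r for r in results}
        self.level = level

    @property
    def frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results.values():
            rows.append(
                {
                    "variable": r.variable,
                    "n_pairs": r.n_pairs,
                    "transform": r.transform,
                    "r_simple": r.r_simple,
                    "ci_simple_low": r.ci_simple[0],
                    "ci_simple_high": r.ci_simple[1],
                    "r_adjusted": r.r_adjusted,
                    "ci_adjusted_low": r.ci_adjusted[0] if r.ci_adjusted else None,
                    "ci_adjusted_high": r.ci_adjusted[1] if r.ci_adjusted else None,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"Spousal similarity: Pearson correlations with {self.level:.0%} Fisher-z CIs",
            f"{'variable':<10}{'n':>6}  {'simple r (CI)':<28}{'age-adjusted r (CI)':<28}",
        ]
        for r in self.results.values():
            simple = f"{r.r_simple:.3f} ({r.ci_simple[0]:.3f}, {r.ci_simple[1]:.3f})"
            if r.r_adjusted is not None:
                adj = f"{r.r_adjusted:.3f} ({r.ci_adjusted[0]:.3f}, {r.ci_adjusted[1]:.3f})"
            else:
                adj = "NA"
            lines.append(f"{r.variable:<10}{r.n_pairs:>6}  {simple:<28}{adj:<28}")
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)
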