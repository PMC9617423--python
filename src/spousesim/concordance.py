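"""Concordance odds ratios for binary traits between partners.

The male's status is regressed on his partner's status by logistic
regression; the exponentiated coefficient of the female status is the
concordance odds ratio (OR > 1: partners tend to share the trait).  The
age-adjusted model adds two pair-level covariates — the mean of the two
ages and the male−female age difference — which absorb similarity that is
driven purely by the age alignment of pairs.  Confidence intervals are Wald
intervals on the log-odds scale.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ConcordanceError",
    "ConcordanceResult",
    "two_by_two_or",
    "fit_concordance",
    "SpousalConcordance",
    "ConcordanceResults",
    "BINARY_OUTCOMES",
]


class ConcordanceError(ValueError):
    pass


#: binary outcomes (derived columns) eligible for concordance analysis
BINARY_OUTCOMES = [
    "current_smoker",
    "current_drinker",
    "sufficiently_active",
    "hypertension",
    "diabetes",
    "metabolic_syndrome",
]

_MIN_PAIRS = 10


@dataclass
class ConcordanceResult:
    """Crude and age-adjusted concordance ORs for one binary trait."""

    outcome: str
    n_pairs: int
    crude_or: float
    crude_ci: tuple[float, float]
    adjusted_or: float
    adjusted_ci: tuple[float, float]
    crude_p: float
    adjusted_p: float


def two_by_two_or(a: float, b: float, c: float, d: float, level: float = 0.95) -> tuple[float, float, float]:
    """Cross-product odds ratio of a 2×2 table with a Woolf CI.

    Cells: a = both exposed/outcome-positive ... d = both negative in the
    conventional layout; OR = ad/bc.  Zero cells raise (no automatic
    continuity correction is applied).
    """
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise ConcordanceError("negative cell count")
    if any(x == 0 for x in cells):
        raise ConcordanceError(
            "zero cell in 2x2 table; apply a continuity correction explicitly if desired"
        )
    or_ = (a * d) / (b * c)
    z = stats.norm.ppf(0.5 + level / 2.0)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return or_, math.exp(math.log(or_) - z * se), math.exp(math.log(or_) + z * se)


def _logit_or(y: np.ndarray, X: np.ndarray, outcome: str, level: float) -> tuple[float, tuple[float, float], float]:
    model = sm.Logit(y, X)
    try:
        # convergence and separation are checked explicitly below, so the
        # in-flight statsmodels warnings are redundant noise
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit(disp=0, maxiter=100)
    except Exception as exc:  # perfect separation raises inside statsmodels
        raise ConcordanceError(f"{outcome}: logistic fit failed ({exc})") from exc
    if not fit.mle_retvals.get("converged", False):
        raise ConcordanceError(f"{outcome}: logistic fit did not converge")
    beta = fit.params[1]
    se = fit.bse[1]
    if not np.isfinite(beta) or not np.isfinite(se) or se > 1e3:
        raise ConcordanceError(f"{outcome}: unstable estimate (possible separation)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return math.exp(beta), (math.exp(beta - z * se), math.exp(beta + z * se)), float(fit.pvalues[1])


def fit_concordance(
    derived: pd.DataFrame,
    pairs: pd.DataFrame,
    outcome: str,
    level: float = 0.95,
) -> ConcordanceResult:
    """Crude and age-adjusted concordance ORs for one outcome.

    Pairs with either member missing the outcome are dropped.  The crude
    model is male status ~ female status; the adjusted model adds the pair
    mean age and the male−female age difference.
    """
    if outcome not in BINARY_OUTCOMES:
        raise ConcordanceError(f"unknown outcome: {outcome!r}")
    idx = derived.set_index("id")
    y = idx.loc[pairs["male_id"], outcome].to_numpy()
    x = idx.loc[pairs["female_id"], outcome].to_numpy()
    age_m = idx.loc[pairs["male_id"], "age"].to_numpy(dtype=float)
    age_f = idx.loc[pairs["female_id"], "age"].to_numpy(dtype=float)
    ok = ~(pd.isna(y) | pd.isna(x) | np.isnan(age_m) | np.isnan(age_f))
    y = y[ok].astype(float)
    x = x[ok].astype(float)
    n = len(y)
    if n < _MIN_PAIRS:
        raise ConcordanceError(f"{outcome}: only {n} usable pairs")
    mean_age = (age_m[ok] + age_f[ok]) / 2.0
    age_diff = age_m[ok] - age_f[ok]

    X_crude = np.column_stack([np.ones(n), x])
    crude_or, crude_ci, crude_p = _logit_or(y, X_crude, outcome, level)
    X_adj = np.column_stack([np.ones(n), x, mean_age, age_diff])
    adj_or, adj_ci, adj_p = _logit_or(y, X_adj, outcome, level)
    return ConcordanceResult(
        outcome=outcome,
        n_pairs=n,
        crude_or=crude_or,
        crude_ci=crude_ci,
        adjusted_or=adj_or,
        adjusted_ci=adj_ci,
        crude_p=crude_p,
        adjusted_p=adj_p,
    )


def _stars(p: float) -> str:
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


class SpousalConcordance:
    """Model of partner concordance in binary traits for one pairing."""

    def __init__(
        self,
        derived: pd.DataFrame,
        pairs: pd.DataFrame,
        outcomes: Optional[Iterable[str]] = None,
        level: float = 0.95,
        errors: str = "raise",
    ) -> None:
        self.derived = derived
        self.pairs = pairs
        self.outcomes = list(outcomes) if outcomes is not None else list(BINARY_OUTCOMES)
        self.level = level
        self.errors = errors

    @classmethod
    def from_cohort(cls, cohort, criteria=None, policy=None, **kwargs) -> "SpousalConcordance":
        from .harmonize import derive_all

        return cls(derive_all(cohort, criteria, policy), cohort.pairs, **kwargs)

    def fit(self) -> "ConcordanceResults":
        results = []
        for o in self.outcomes:
            try:
                results.append(fit_concordance(self.derived, self.pairs, o, self.level))
            except ConcordanceError:
                if self.errors != "skip":
                    raise
        return ConcordanceResults(results, self.level)


class ConcordanceResults:
    """Fitted concordance ORs with a tabular summary."""

    def __init__(self, results: list[ConcordanceResult], level: float) -> None:
        self.results = {r.outcome: r for r in results}
        self.level = level

    @property
    def frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results.values():
            rows.append(
                {
                    "outcome": r.outcome,
                    "n_pairs": r.n_pairs,
                    "crude_or": r.crude_or,
                    "crude_ci_low": r.crude_ci[0],
                    "crude_ci_high": r.crude_ci[1],
                    "crude_sig": _stars(r.crude_p),
                    "adjusted_or": r.adjusted_or,
                    "adjusted_ci_low": r.adjusted_ci[0],
                    "adjusted_ci_high": r.adjusted_ci[1],
                    "adjusted_sig": _stars(r.adjusted_p),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"Partner concordance: logistic ORs with {self.level:.0%} Wald CIs",
            f"{'outcome':<20}{'n':>6}  {'crude OR (CI)':<30}{'age-adjusted OR (CI)':<30}",
        ]
        for r in self.results.values():
            crude = f"{r.crude_or:.2f} ({r.crude_ci[0]:.2f}-{r.crude_ci[1]:.2f}){_stars(r.crude_p)}"
            adj = f"{r.adjusted_or:.2f} ({r.adjusted_ci[0]:.2f}-{r.adjusted_ci[1]:.2f}){_stars(r.adjusted_p)}"
            lines.append(f"{r.outcome:<20}{r.n_pairs:>6}  {crude:<30}{adj:<30}")
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)
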