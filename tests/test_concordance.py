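"""Concordance ORs: 2x2 oracle equivalence, calibration, confounding."""
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spousesim import (
    derive_all,
    fit_concordance,
    generate_cohort,
    two_by_two_or,
    SpousalConcordance,
)
from spousesim.concordance import ConcordanceError
from spousesim.config import BinaryTraitModel

from conftest import make_cohort, minimal_config


def _binary_cohort(y_m, y_f, ages_m=None, ages_f=None):
    n = len(y_m)
    # deterministic age variation so the adjusted design is full rank
    ages_m = ages_m if ages_m is not None else 50 + (7 * np.arange(n)) % 15
    ages_f = ages_f if ages_f is not None else 48 + (5 * np.arange(n)) % 13
    rows, pairs = [], []
    for i in range(n):
        rows += [
            dict(id=f"M{i}", sex="male", age=int(ages_m[i]),
                 drinking="current" if y_m[i] else "never"),
            dict(id=f"F{i}", sex="female", age=int(ages_f[i]),
                 drinking="current" if y_f[i] else "never"),
        ]
        pairs.append((f"M{i}", f"F{i}"))
    return make_cohort(rows, pairs)


def test_two_by_two_examples():
    or_, lo, hi = two_by_two_or(30, 20, 20, 30)
    assert or_ == pytest.approx(2.25)
    se = math.sqrt(1 / 30 + 1 / 20 + 1 / 20 + 1 / 30)
    z = stats.norm.ppf(0.975)
    assert lo == pytest.approx(math.exp(math.log(2.25) - z * se), abs=1e-9)
    assert hi == pytest.approx(math.exp(math.log(2.25) + z * se), abs=1e-9)
    assert two_by_two_or(10, 10, 10, 10)[0] == 1.0


def test_two_by_two_zero_cell_errors():
    with pytest.raises(ConcordanceError, match="continuity"):
        two_by_two_or(0, 10, 10, 10)
    with pytest.raises(ConcordanceError):
        two_by_two_or(-1, 10, 10, 10)


def test_crude_logistic_equals_cross_product_oracle():
    """On 50 random 2x2 tables the crude logistic OR equals ad/bc to 1e-8."""
    rng = np.random.default_rng(17)
    checked = 0
    while checked < 50:
        a, b, c, d = rng.integers(5, 60, size=4)
        y_m = np.concatenate([np.ones(a + b), np.zeros(c + d)])
        y_f = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
        cohort = _binary_cohort(y_m, y_f)
        res = fit_concordance(derive_all(cohort), cohort.pairs, "current_drinker")
        assert res.crude_or == pytest.approx((a * d) / (b * c), abs=1e-8, rel=1e-8)
        checked += 1


def test_label_symmetry_of_crude_or():
    rng = np.random.default_rng(23)
    a, b, c, d = rng.integers(8, 40, size=4)
    y_m = np.concatenate([np.ones(a + b), np.zeros(c + d)])
    y_f = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
    forward = _binary_cohort(y_m, y_f)
    swapped = _binary_cohort(y_f, y_m)
    r1 = fit_concordance(derive_all(forward), forward.pairs, "current_drinker")
    r2 = fit_concordance(derive_all(swapped), swapped.pairs, "current_drinker")
    assert r1.crude_or == pytest.approx(r2.crude_or, rel=1e-8)


def test_null_couple_effect_ci_covers_one():
    cfg = minimal_config(n_pairs=2000)
    cohort = generate_cohort(cfg, seed=31)
    res = fit_concordance(derive_all(cohort), cohort.pairs, "current_drinker")
    assert res.crude_ci[0] <= 1.0 <= res.crude_ci[1]


def test_age_confounding_crude_versus_adjusted():
    """Prevalence rising with age in both sexes and no couple effect: the
    crude OR is inflated above 1 while the adjusted CI covers 1."""
    cfg = minimal_config(
        n_pairs=4000,
        binary_traits={
            "drinking_current": BinaryTraitModel(
                intercept_m=-6.5, age_slope_m=0.10,
                intercept_f=-6.5, age_slope_f=0.10,
                couple_log_or=0.0,
            )
        },
    )
    cohort = generate_cohort(cfg, seed=37)
    res = fit_concordance(derive_all(cohort), cohort.pairs, "current_drinker")
    assert res.crude_ci[0] > 1.0
    assert res.adjusted_ci[0] <= 1.0 <= res.adjusted_ci[1]


def test_power_monotone_in_couple_log_or():
    """Rejection frequency rises with the injected couple effect."""
    rates = []
    for log_or in (0.0, 0.3, 0.7):
        cfg = minimal_config(
            n_pairs=400,
            binary_traits={
                "drinking_current": BinaryTraitModel(
                    intercept_m=-0.4, intercept_f=-0.4, couple_log_or=log_or
                )
            },
        )
        rej = 0
        for seed in range(60):
            cohort = generate_cohort(cfg, seed=9000 + seed)
            res = fit_concordance(derive_all(cohort), cohort.pairs, "current_drinker")
            rej += not (res.adjusted_ci[0] <= 1.0 <= res.adjusted_ci[1])
        rates.append(rej / 60)
    assert rates[0] < rates[1] < rates[2]


def test_couple_log_or_recovered_by_adjusted_model():
    cfg = minimal_config(
        n_pairs=6000,
        binary_traits={
            "drinking_current": BinaryTraitModel(
                intercept_m=-3.5, age_slope_m=0.05,
                intercept_f=-3.5, age_slope_f=0.05,
                couple_log_or=0.8,
            )
        },
    )
    cohort = generate_cohort(cfg, seed=41)
    res = fit_concordance(derive_all(cohort), cohort.pairs, "current_drinker")
    assert res.adjusted_ci[0] <= math.exp(0.8) <= res.adjusted_ci[1]


def test_too_few_pairs_errors():
    y = np.array([1, 0, 1, 0])
    cohort = _binary_cohort(y, y)
    with pytest.raises(ConcordanceError, match="usable pairs"):
        fit_concordance(derive_all(cohort), cohort.pairs, "current_drinker")
    with pytest.raises(ConcordanceError, match="unknown outcome"):
        fit_concordance(derive_all(cohort), cohort.pairs, "left_handed")


def test_concordance_model_summary():
    cfg = minimal_config(n_pairs=800)
    cohort = generate_cohort(cfg, seed=51)
    results = SpousalConcordance.from_cohort(cohort, outcomes=["current_drinker"]).fit()
    frame = results.frame
    assert (frame["crude_or"] > 0).all()
    assert (frame["crude_ci_low"] <= frame["crude_or"]).all()
    assert (frame["crude_or"] <= frame["crude_ci_high"]).all()
    assert "current_drinker" in results.summary()
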