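import numpy as np
import pandas as pd
import pytest

from spousesim import PairedCohort, default_config
from spousesim.cohort import PARTICIPANT_COLUMNS
from spousesim.config import BinaryTraitModel, GeneratorConfig, TraitModel


def null_trait(**kwargs) -> TraitModel:
    """A trait with no couple effect and no age trend unless overridden."""
    base = dict(mean_m=100.0, mean_f=90.0, sd_m=10.0, sd_f=8.0,
                age_slope_m=0.0, age_slope_f=0.0, couple_corr=0.0)
    base.update(kwargs)
    return TraitModel(**base)


def minimal_config(n_pairs: int = 200, **overrides) -> GeneratorConfig:
    """A small, fast generator config with independent partners by default."""
    cfg = GeneratorConfig(
        n_pairs=n_pairs,
        age_mean_m=63.2,
        age_mean_f=60.4,
        age_sd_m=10.5,
        age_sd_f=10.2,
        age_corr=0.934,
        traits={"sbp": null_trait(mean_m=129.7, mean_f=125.9, sd_m=16.3, sd_f=17.7)},
        binary_traits={
            "drinking_current": BinaryTraitModel(intercept_m=-0.4, intercept_f=-0.4, couple_log_or=0.0)
        },
    )
    # re-validate so invalid overrides are rejected like any other config
    return GeneratorConfig.model_validate({**cfg.model_dump(), **overrides})


def nulled_default_config(n_pairs: int) -> GeneratorConfig:
    """The default config with couple effects, age slopes, medications and
    missingness all switched off (partners independent given nothing)."""
    cfg = default_config()
    traits = {
        name: t.model_copy(update={"couple_corr": 0.0, "age_slope_m": 0.0, "age_slope_f": 0.0})
        for name, t in cfg.traits.items()
    }
    binary = {
        name: b.model_copy(update={"couple_log_or": 0.0, "age_slope_m": 0.0, "age_slope_f": 0.0})
        for name, b in cfg.binary_traits.items()
    }
    return cfg.model_copy(
        update={"n_pairs": n_pairs, "traits": traits, "binary_traits": binary,
                "medications": {}, "missing_rates": {}}
    )


def make_participants(rows: list[dict]) -> pd.DataFrame:
    """Hand-built participants table; unspecified fields are missing."""
    df = pd.DataFrame(rows)
    for col in PARTICIPANT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    for col in ("on_antihypertensive", "on_glucose_lowering", "on_lipid_lowering"):
        df[col] = pd.array([bool(x) if pd.notna(x) else False for x in df[col]], dtype="boolean")
    return df[PARTICIPANT_COLUMNS]


def make_cohort(rows: list[dict], pairs: list[tuple[str, str]]) -> PairedCohort:
    return PairedCohort(
        make_participants(rows),
        pd.DataFrame({"male_id": [p[0] for p in pairs],
                      "female_id": [p[1] for p in pairs],
                      "origin": "spouse"}),
    )


@pytest.fixture
def tiny_couples() -> PairedCohort:
    """Three complete couples with wife ages 60, 60, 62."""
    rows = []
    for i, (age_m, age_f) in enumerate([(62, 60), (65, 60), (63, 62)], start=1):
        rows.append(dict(id=f"M{i}", sex="male", age=age_m, height=170.0, weight=70.0,
                         waist=86.0, sbp=130.0, dbp=80.0, hba1c=5.5, tc=200.0, tg=100.0,
                         hdl=55.0, ldl=120.0, smoking="never", drinking="current",
                         met_hours=3.0, education_raw="high school"))
        rows.append(dict(id=f"F{i}", sex="female", age=age_f, height=155.0, weight=52.0,
                         waist=80.0, sbp=120.0, dbp=75.0, hba1c=5.4, tc=210.0, tg=90.0,
                         hdl=65.0, ldl=125.0, smoking="never", drinking="never",
                         met_hours=2.0, education_raw="university"))
    return make_cohort(rows, [("M1", "F1"), ("M2", "F2"), ("M3", "F3")])
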