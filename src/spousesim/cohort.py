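"""Paired-cohort container and CSV round-trip.

A cohort is two tables: one row per participant, and a pair table linking
male and female ids.  Pairs carry an ``origin`` column distinguishing the
observed spouse pairing from an age-matched random re-pairing.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["PairedCohort", "PARTICIPANT_COLUMNS", "PAIR_COLUMNS", "CohortError"]


class CohortError(ValueError):
    """Raised on structural violations of the cohort schema."""


PARTICIPANT_COLUMNS = [
    "id",
    "sex",
    "age",
    "height",
    "weight",
    "waist",
    "sbp",
    "dbp",
    "hba1c",
    "tc",
    "tg",
    "hdl",
    "ldl",
    "smoking",
    "drinking",
    "met_hours",
    "education_raw",
    "on_antihypertensive",
    "on_glucose_lowering",
    "on_lipid_lowering",
]

PAIR_COLUMNS = ["male_id", "female_id", "origin"]

_NUMERIC = ["age", "height", "weight", "waist", "sbp", "dbp", "hba1c", "tc", "tg", "hdl", "ldl", "met_hours"]
_BOOLEAN = ["on_antihypertensive", "on_glucose_lowering", "on_lipid_lowering"]


@dataclass
class PairedCohort:
    """Participants plus a husband–wife pair list (spouse or randomized)."""

    participants: pd.DataFrame
    pairs: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=PAIR_COLUMNS))

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        missing_cols = [c for c in PARTICIPANT_COLUMNS if c not in self.participants.columns]
        if missing_cols:
            raise CohortError(f"participants table missing columns: {missing_cols}")
        if self.participants["id"].duplicated().any():
            dup = self.participants.loc[self.participants["id"].duplicated(), "id"].tolist()
            raise CohortError(f"duplicate participant ids: {dup[:5]}")
        ids = set(self.participants["id"])
        sex = self.participants.set_index("id")["sex"]
        for col, want in (("male_id", "male"), ("female_id", "female")):
            if col not in self.pairs.columns:
                raise CohortError(f"pairs table missing column {col!r}")
            unknown = set(self.pairs[col]) - ids
            if unknown:
                raise CohortError(f"{col} not in participants: {sorted(unknown)[:5]}")
            wrong = [i for i in self.pairs[col] if sex[i] != want]
            if wrong:
                raise CohortError(f"{col} refers to non-{want} records: {wrong[:5]}")
            if self.pairs[col].duplicated().any():
                raise CohortError(f"participant appears in more than one pair ({col})")

    # -- convenience --------------------------------------------------------
    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def participant(self, pid: str) -> pd.Series:
        return self.participants.set_index("id").loc[pid]

    def with_pairs(self, pairs: pd.DataFrame) -> "PairedCohort":
        return PairedCohort(self.participants, pairs.reset_index(drop=True))

    # -- CSV round-trip ------------------------------------------------------
    def write(self, outdir: str | Path, prefix: str = "") -> tuple[Path, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ppath = outdir / f"{prefix}participants.csv"
        qpath = outdir / f"{prefix}pairs.csv"
        self.participants.to_csv(ppath, index=False)
        self.pairs.to_csv(qpath, index=False)
        return ppath, qpath

    @classmethod
    def read(cls, participants_path: str | Path, pairs_path: str | Path) -> "PairedCohort":
        participants = pd.read_csv(participants_path, dtype={"id": str})
        for col in _BOOLEAN:
            participants[col] = participants[col].astype("boolean")
        for col in _NUMERIC:
            participants[col] = pd.to_numeric(participants[col])
        pairs = pd.read_csv(pairs_path, dtype=str)
        if "origin" not in pairs.columns:
            pairs["origin"] = "spouse"
        return cls(participants, pairs)


def empty_participants() -> pd.DataFrame:
    """An empty participants table with the full schema."""
    df = pd.DataFrame(columns=PARTICIPANT_COLUMNS)
    for col in _NUMERIC:
        df[col] = df[col].astype(float)
    for col in _BOOLEAN:
        df[col] = df[col].astype("boolean")
    return df
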