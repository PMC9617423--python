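"""Exact-age-matched random re-pairing.

The null construction: women are grouped into strata of identical integer
age and permuted within each stratum, so every man receives a partner of
exactly his original partner's age.  This destroys couple-specific structure
(assortment, cohabitation) while preserving the joint age distribution, and
hence the male–female age correlation, exactly.  A re-paired couple may by
chance coincide with an original spouse pair; no rejection is performed.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import PairedCohort

__all__ = ["AgeStratum", "build_strata", "exact_age_shuffle", "PairingError"]


class PairingError(ValueError):
    pass


@dataclass(frozen=True)
class AgeStratum:
    """Women of one exact integer age, in original pair-list order."""

    age: int
    member_ids: tuple[str, ...]


def build_strata(cohort: PairedCohort) -> list[AgeStratum]:
    """Group paired women by exact integer age, ascending.

    Every paired woman lands in exactly one stratum; order within a stratum
    follows the pair table.
    """
    if cohort.n_pairs == 0:
        return []
    ages = cohort.participants.set_index("id")["age"]
    female_ids = cohort.pairs["female_id"].tolist()
    female_ages = ages.loc[female_ids]
    bad = female_ages.index[female_ages.isna()].tolist()
    if bad:
        raise PairingError(f"paired women with missing age: {bad[:5]}")
    groups: dict[int, list[str]] = {}
    for fid, age in zip(female_ids, female_ages):
        groups.setdefault(int(age), []).append(fid)
    return [AgeStratum(age, tuple(groups[age])) for age in sorted(groups)]


def exact_age_shuffle(cohort: PairedCohort, seed: int | np.random.Generator) -> PairedCohort:
    """Random male–female pairs with the spousal age structure intact.

    Within each age stratum, wives are permuted uniformly at random
    (Fisher–Yates via the seeded generator) and reassigned to that stratum's
    husbands in original pair order.  Strata are processed in ascending age
    order so results are reproducible across platforms.  Returns a cohort
    with the same participants and a pair table with ``origin='randomized'``.
    """
    if (cohort.pairs["origin"] != "spouse").any():
        raise PairingError("exact_age_shuffle expects a spouse-origin pairing")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    strata = build_strata(cohort)

    new_partner: dict[str, str] = {}
    ages = cohort.participants.set_index("id")["age"]
    wife_age = {fid: int(ages[fid]) for fid in cohort.pairs["female_id"]}
    husbands_by_age: dict[int, list[str]] = {}
    for mid, fid in zip(cohort.pairs["male_id"], cohort.pairs["female_id"]):
        husbands_by_age.setdefault(wife_age[fid], []).append(mid)

    for stratum in strata:
        permuted = list(np.array(stratum.member_ids, dtype=object)[rng.permutation(len(stratum.member_ids))])
        for mid, fid in zip(husbands_by_age[stratum.age], permuted):
            new_partner[mid] = fid

    pairs = pd.DataFrame(
        {
            "male_id": cohort.pairs["male_id"],
            "female_id": [new_partner[m] for m in cohort.pairs["male_id"]],
            "origin": "randomized",
        }
    )
    return cohort.with_pairs(pairs)
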