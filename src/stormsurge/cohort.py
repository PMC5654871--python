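"""Analysis cohort construction and the out-of-state comparison pool.

The study cohort is the set of fee-for-service beneficiaries in the study
state who were continuously enrolled across both panel years; a seeded
simple random sample (the claims-file sampling fraction) is drawn from the
eligible set.  The comparison pool holds continuously-enrolled FFS
beneficiaries from states not affected by the storm: everywhere except the
study state and the fourteen affected states.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
import pandas as pd

from .claims_model import N_ENROLLMENT_MONTHS

#: States excluded from the comparison pool because the storm affected
#: them, in addition to the study state itself.
DEFAULT_AFFECTED_STATES = (
    "FL", "SC", "NC", "VA", "DC", "MD", "DE", "PA", "NY", "CT", "RI", "MA",
    "NH", "VT",
)


@dataclasses.dataclass(frozen=True)
class Cohort:
    """A drawn analysis cohort: member ids plus the fraction used."""

    members: frozenset
    sampling_fraction: float
    label: str = ""

    def __len__(self) -> int:
        return len(self.members)


def _continuously_enrolled(beneficiaries: pd.DataFrame) -> pd.Series:
    months = beneficiaries["enrolled_months"].astype(str)
    return months == "1" * N_ENROLLMENT_MONTHS


def filter_continuous_ffs(
    beneficiaries: pd.DataFrame, state: str = "NJ"
) -> pd.DataFrame:
    """Beneficiaries of ``state`` with FFS coverage and all 24 months enrolled.

    Idempotent: applying it to its own output returns the same rows.
    """
    if not len(beneficiaries):
        return beneficiaries.copy()
    keep = (
        _continuously_enrolled(beneficiaries)
        & beneficiaries["ffs_flag"].astype(bool)
        & (beneficiaries["state"] == state)
    )
    return beneficiaries.loc[keep].copy()


def draw_sample(
    eligible: pd.DataFrame | Iterable[str],
    fraction: float,
    seed: int,
    label: str = "",
) -> Cohort:
    """Seeded simple random sample without replacement of the eligible set.

    The sample size is ``round(fraction * n)`` with banker's rounding, so
    repeated draws over many fractions are unbiased in expectation.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction!r}")
    if isinstance(eligible, pd.DataFrame):
        ids = eligible["bene_id"].to_numpy(dtype=object)
    else:
        ids = np.asarray(sorted(eligible), dtype=object)
    ids = np.sort(ids)
    size = round(fraction * len(ids))
    rng = np.random.Generator(np.random.Philox(key=[int(seed) & (2**63 - 1), 99]))
    chosen = rng.choice(ids, size=size, replace=False) if size else ids[:0]
    return Cohort(
        members=frozenset(chosen), sampling_fraction=fraction, label=label
    )


def build_comparison_pool(
    beneficiaries: pd.DataFrame,
    excluded_states: Iterable[str] = DEFAULT_AFFECTED_STATES,
    study_state: str = "NJ",
) -> pd.DataFrame:
    """Continuous-FFS beneficiaries outside the study and affected states."""
    if not len(beneficiaries):
        return beneficiaries.copy()
    excluded = set(excluded_states) | {study_state}
    keep = (
        _continuously_enrolled(beneficiaries)
        & beneficiaries["ffs_flag"].astype(bool)
        & ~beneficiaries["state"].isin(excluded)
    )
    return beneficiaries.loc[keep].copy()
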