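"""Shared fixtures: small generated populations and random claim fixtures."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import stormsurge as ss
from stormsurge.claims_model import StudyWindows

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")


@pytest.fixture(scope="session")
def windows() -> StudyWindows:
    return StudyWindows()


@pytest.fixture(scope="session")
def sandy_bundle():
    """A mid-sized storm-scenario population shared across tests."""
    scenario = ss.get_preset("sandy_like", n_beneficiaries=20_000, seed=17)
    return scenario, ss.generate_bundle(scenario)


@pytest.fixture(scope="session")
def null_bundle():
    scenario = ss.get_preset("null", n_beneficiaries=6_000, seed=23)
    return scenario, ss.generate_bundle(scenario)


def random_claims(
    rng: np.random.Generator,
    n_benes: int = 40,
    max_claims_per_bene: int = 12,
) -> pd.DataFrame:
    """A random inpatient table exercising every transfer-detection path."""
    rows = []
    cid = 0
    base = pd.Timestamp("2012-01-01")
    sources = [
        "routine", "unknown", "transfer_hospital", "transfer_snf",
        "transfer_hospice",
    ]
    for b in range(n_benes):
        for _ in range(int(rng.integers(0, max_claims_per_bene + 1))):
            ftype = ["hospital", "snf", "hospice"][
                int(rng.choice([0, 0, 0, 1, 2]))
            ]
            admit = base + pd.Timedelta(days=int(rng.integers(0, 330)))
            stay = int(rng.integers(0, 20))
            rows.append(
                {
                    "claim_id": f"C{cid:05d}",
                    "bene_id": f"B{b:04d}",
                    "facility_id": f"F{int(rng.integers(0, 6)):02d}",
                    "facility_type": ftype,
                    "admit_date": admit,
                    "discharge_date": admit + pd.Timedelta(days=stay),
                    "drg_code": f"DRG{int(rng.integers(1, 6)):03d}",
                    "admission_source": sources[int(rng.integers(0, 5))]
                    if ftype == "hospital"
                    else "routine",
                    "through_ed": bool(rng.integers(0, 2)),
                    "discharge_disposition": "home",
                }
            )
            cid += 1
    return pd.DataFrame(
        rows,
        columns=[
            "claim_id", "bene_id", "facility_id", "facility_type",
            "admit_date", "discharge_date", "drg_code", "admission_source",
            "through_ed", "discharge_disposition",
        ],
    )
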