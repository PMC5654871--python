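"""Inter-facility transfer detection and ED-visit disposition linkage.

A hospital admission H counts as an inter-facility transfer from a source
stay S of the same beneficiary when either

* H's admission-source code names S's facility type
  (``transfer_hospital`` / ``transfer_snf`` / ``transfer_hospice``), or
* H's admission date falls inside S's stay interval
  (``S.admit_date <= H.admit_date <= S.discharge_date``, endpoints
  inclusive, so a same-day facility move counts),

with S at a *different* facility (same-facility readmissions are never
transfers).  Each admission links to at most one source: when several
candidates qualify, the one with the latest admission date wins, ties
broken by lexicographically smallest facility id.  When the admission
source code and the date-overlap rule disagree on the source type, the
explicit code wins and the disagreement is logged.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .claims_model import FACILITY_TYPES, TRANSFER_SOURCES, ClaimsError

logger = logging.getLogger(__name__)

TRANSFER_COLUMNS = (
    "bene_id",
    "source_type",
    "source_claim_id",
    "hospital_claim_id",
    "detection_rule",
)


class IntegrityError(ClaimsError):
    """A visit references a claim belonging to another beneficiary."""


def _empty_transfers() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in TRANSFER_COLUMNS})


def detect_transfers(inpatient: pd.DataFrame) -> pd.DataFrame:
    """Find transfer admissions among hospital claims.

    Returns one row per detected transfer with columns
    ``bene_id, source_type, source_claim_id, hospital_claim_id,
    detection_rule`` where ``detection_rule`` is ``source_code`` when the
    admission-source variable identified the transfer and ``date_overlap``
    when only the stay-interval rule did.  An admission whose source code
    names a transfer but with no matching source stay on file is still
    reported (with an empty ``source_claim_id``).
    """
    if not len(inpatient):
        return _empty_transfers()

    cols = [
        "claim_id", "bene_id", "facility_id", "facility_type", "admit_date",
        "discharge_date", "admission_source",
    ]
    claims = inpatient[cols]
    hospitals = claims[claims["facility_type"] == "hospital"]
    sources = claims[claims["facility_type"].isin(FACILITY_TYPES)]
    if not len(hospitals):
        return _empty_transfers()

    pairs = hospitals.merge(
        sources, on="bene_id", suffixes=("_h", "_s"), how="left"
    )
    pairs = pairs[
        (pairs["claim_id_h"] != pairs["claim_id_s"])
        & (pairs["facility_id_h"] != pairs["facility_id_s"])
    ]

    overlap = (pairs["admit_date_s"] <= pairs["admit_date_h"]) & (
        pairs["admit_date_h"] <= pairs["discharge_date_s"]
    )
    coded = pairs["admission_source_h"].isin(TRANSFER_SOURCES)
    coded_type = pairs["admission_source_h"].str.replace(
        "transfer_", "", regex=False
    )
    type_match = coded & (pairs["facility_type_s"] == coded_type)

    # candidate iff the source code names this stay's type, or dates overlap
    cand = pairs[type_match | overlap].copy()
    cand["type_agrees"] = (
        ~coded.loc[cand.index] | type_match.loc[cand.index]
    )

    # selection: code-matching candidates outrank overlap-only ones, then
    # latest source admission, then smallest facility id
    cand = cand.sort_values(
        ["claim_id_h", "type_agrees", "admit_date_s", "facility_id_s"],
        ascending=[True, False, False, True],
        kind="mergesort",
    )
    best = cand.groupby("claim_id_h", sort=False).head(1)

    disagreements = int((~best["type_agrees"]).sum())
    if disagreements:
        logger.warning(
            "detect_transfers: %d admission(s) whose source code disagrees "
            "with every overlapping stay's facility type; keeping the coded "
            "type",
            disagreements,
        )

    coded_h = hospitals["admission_source"].isin(TRANSFER_SOURCES)
    best_overlap = overlap.loc[best.index]
    out = pd.DataFrame(
        {
            "bene_id": best["bene_id"].to_numpy(dtype=object),
            "source_type": np.where(
                best["claim_id_h"]
                .map(hospitals.set_index("claim_id")["admission_source"])
                .isin(TRANSFER_SOURCES),
                best["claim_id_h"]
                .map(hospitals.set_index("claim_id")["admission_source"])
                .str.replace("transfer_", "", regex=False),
                best["facility_type_s"],
            ).astype(object),
            "source_claim_id": best["claim_id_s"].to_numpy(dtype=object),
            "hospital_claim_id": best["claim_id_h"].to_numpy(dtype=object),
            "detection_rule": np.where(
                best["claim_id_h"].isin(hospitals.loc[coded_h, "claim_id"]),
                "source_code",
                "date_overlap",
            ).astype(object),
        }
    )

    # coded transfers with no candidate stay at all
    matched = set(out["hospital_claim_id"])
    orphan = hospitals[coded_h & ~hospitals["claim_id"].isin(matched)]
    if len(orphan):
        out = pd.concat(
            [
                out,
                pd.DataFrame(
                    {
                        "bene_id": orphan["bene_id"].to_numpy(dtype=object),
                        "source_type": orphan["admission_source"]
                        .str.replace("transfer_", "", regex=False)
                        .to_numpy(dtype=object),
                        "source_claim_id": "",
                        "hospital_claim_id": orphan["claim_id"].to_numpy(
                            dtype=object
                        ),
                        "detection_rule": "source_code",
                    }
                ),
            ],
            ignore_index=True,
        )

    return (
        out.sort_values("hospital_claim_id", kind="mergesort")
        .reset_index(drop=True)[list(TRANSFER_COLUMNS)]
    )


def classify_ed_visits(
    ed_visits: pd.DataFrame, inpatient: pd.DataFrame
) -> pd.DataFrame:
    """Assign each ED visit its disposition from the inpatient table.

    A visit is ``admitted`` iff a same-beneficiary hospital claim flagged
    through-ED admits on the visit date (ties broken by smallest claim
    id); otherwise it is ``discharged``.  The returned frame always
    partitions: discharged + admitted = total visits.

    Raises :class:`IntegrityError` if an input visit's ``linked_claim_id``
    references a claim of a different beneficiary.
    """
    out = ed_visits.copy()
    if not len(out):
        return out

    if len(inpatient):
        claim_owner = inpatient.set_index("claim_id")["bene_id"]
        linked = out["linked_claim_id"].astype(str)
        has_link = linked != ""
        owners = linked[has_link].map(claim_owner)
        bad = owners.notna() & (owners != out.loc[has_link, "bene_id"])
        if bad.any():
            vid = out.loc[has_link].loc[bad, "visit_id"].iloc[0]
            raise IntegrityError(
                f"visit {vid!r} linked to a claim of another beneficiary"
            )

    through = inpatient[
        (inpatient["facility_type"] == "hospital")
        & inpatient["through_ed"].astype(bool)
    ] if len(inpatient) else inpatient
    if len(through):
        cand = (
            through[["bene_id", "admit_date", "claim_id"]]
            .sort_values("claim_id", kind="mergesort")
            .drop_duplicates(["bene_id", "admit_date"], keep="first")
        )
        merged = out.merge(
            cand,
            left_on=["bene_id", "visit_date"],
            right_on=["bene_id", "admit_date"],
            how="left",
        )
        admitted = merged["claim_id"].notna().to_numpy()
        out["disposition"] = np.where(admitted, "admitted", "discharged")
        out["linked_claim_id"] = np.where(
            admitted, merged["claim_id"].fillna(""), ""
        ).astype(object)
    else:
        out["disposition"] = "discharged"
        out["linked_claim_id"] = ""
    return out
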