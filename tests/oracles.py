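"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately re-derive results with naive all-pairs loops and plain
summation so they share no code with the implementations they check.
"""

from __future__ import annotations

import math

import pandas as pd

TRANSFER_SOURCES = {"transfer_hospital", "transfer_snf", "transfer_hospice"}


def brute_force_transfers(inpatient: pd.DataFrame) -> set[tuple]:
    """All-pairs transfer detection.

    Returns a set of (hospital_claim_id, source_claim_id, source_type,
    detection_rule) tuples under the same linkage policy as the package:
    candidate iff the admission-source code names the source stay's type
    or the admission date falls inside the source stay; code-matching
    candidates outrank overlap-only ones, then latest source admission,
    then smallest facility id; coded transfers with no candidate are
    reported with an empty source id.
    """
    records = inpatient.to_dict("records")
    by_bene: dict[str, list[dict]] = {}
    for c in records:
        by_bene.setdefault(c["bene_id"], []).append(c)

    events: set[tuple] = set()
    for h in records:
        if h["facility_type"] != "hospital":
            continue
        coded = h["admission_source"] in TRANSFER_SOURCES
        coded_type = (
            h["admission_source"].replace("transfer_", "") if coded else None
        )
        candidates = []
        for s in by_bene[h["bene_id"]]:
            if s["claim_id"] == h["claim_id"]:
                continue
            if s["facility_id"] == h["facility_id"]:
                continue
            if s["facility_type"] not in ("hospital", "snf", "hospice"):
                continue
            overlap = s["admit_date"] <= h["admit_date"] <= s["discharge_date"]
            type_match = coded and s["facility_type"] == coded_type
            if overlap or type_match:
                agrees = (not coded) or type_match
                candidates.append((agrees, s))
        rule = "source_code" if coded else "date_overlap"
        if candidates:
            best = sorted(
                candidates,
                key=lambda t: (
                    not t[0],                      # code-agreeing first
                    -t[1]["admit_date"].toordinal(),  # latest admission
                    t[1]["facility_id"],           # smallest facility id
                ),
            )[0]
            agrees, s = best
            source_type = coded_type if coded else s["facility_type"]
            events.add((h["claim_id"], s["claim_id"], source_type, rule))
        elif coded:
            events.add((h["claim_id"], "", coded_type, rule))
    return events


def transfer_frame_to_set(transfers: pd.DataFrame) -> set[tuple]:
    return {
        (r.hospital_claim_id, r.source_claim_id, r.source_type, r.detection_rule)
        for r in transfers.itertuples()
    }


def naive_mean_weight(claims: pd.DataFrame, weights: pd.DataFrame) -> float:
    lookup = dict(zip(weights["drg_code"], weights["weight"]))
    values = [lookup[c] for c in claims["drg_code"]]
    return math.fsum(values) / len(values)


def naive_mean_los(claims: pd.DataFrame) -> float:
    days = [
        (d - a).days
        for a, d in zip(claims["admit_date"], claims["discharge_date"])
    ]
    return math.fsum(days) / len(days)
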