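"""Case-mix index (CMI), length of stay, and DRG-matched comparison frames.

CMI is the arithmetic mean of the DRG service-intensity weights of a claim
population (valid weight range 0.1-30.0); a higher CMI means a more
resource-intensive mix of patients.  Length of stay is the calendar-day
difference between discharge and admission (a same-day stay is 0 days).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .claims_model import ClaimsError


class SeverityError(ClaimsError):
    """A claim references a DRG code absent from the weight table."""


@dataclasses.dataclass(frozen=True)
class SeveritySummary:
    n: int
    cmi: float | None
    alos: float | None


def claim_weights(claims: pd.DataFrame, weight_table: pd.DataFrame) -> pd.Series:
    """Per-claim DRG weights; raises naming any unmapped code."""
    if not len(claims):
        return pd.Series(dtype=float)
    lookup = weight_table.set_index("drg_code")["weight"]
    weights = claims["drg_code"].map(lookup)
    if weights.isna().any():
        code = claims.loc[weights.isna(), "drg_code"].iloc[0]
        raise SeverityError(f"drg_code {code!r} not in the weight table")
    return weights.astype(float)


def compute_cmi(
    claims: pd.DataFrame, weight_table: pd.DataFrame
) -> float | None:
    """Mean DRG weight of a claim subset; ``None`` for an empty subset."""
    if not len(claims):
        return None
    return float(claim_weights(claims, weight_table).mean())


def length_of_stay(claims: pd.DataFrame) -> pd.Series:
    """Whole-day stay lengths (discharge minus admission)."""
    if not len(claims):
        return pd.Series(dtype=float)
    los = (claims["discharge_date"] - claims["admit_date"]).dt.days
    return los.astype(float)


def compute_alos(claims: pd.DataFrame) -> float | None:
    """Mean length of stay in days; ``None`` for an empty subset."""
    if not len(claims):
        return None
    return float(length_of_stay(claims).mean())


def severity_summary(
    claims: pd.DataFrame, weight_table: pd.DataFrame
) -> SeveritySummary:
    return SeveritySummary(
        n=len(claims),
        cmi=compute_cmi(claims, weight_table),
        alos=compute_alos(claims),
    )


def drg_matched_frame(
    target: pd.DataFrame, reference: pd.DataFrame
) -> pd.DataFrame:
    """Stack target and reference claims restricted to shared DRG codes.

    Returns a frame with columns ``claim_id, bene_id, drg_code, los,
    label`` where ``label`` is ``"target"`` or ``"reference"`` and only
    DRG codes present in *both* inputs are retained (the DRG is kept as a
    matching stratum for stratified comparisons).  An empty intersection
    yields an empty frame, not an exception.
    """
    shared = set(target["drg_code"]) & set(reference["drg_code"]) if (
        len(target) and len(reference)
    ) else set()
    parts = []
    for df, label in ((target, "target"), (reference, "reference")):
        sub = df[df["drg_code"].isin(shared)] if len(df) else df
        if len(sub):
            parts.append(
                pd.DataFrame(
                    {
                        "claim_id": sub["claim_id"].to_numpy(dtype=object),
                        "bene_id": sub["bene_id"].to_numpy(dtype=object),
                        "drg_code": sub["drg_code"].to_numpy(dtype=object),
                        "los": length_of_stay(sub).to_numpy(),
                        "label": label,
                    }
                )
            )
    if not parts:
        return pd.DataFrame(
            {
                c: pd.Series(dtype=object)
                for c in ("claim_id", "bene_id", "drg_code", "los", "label")
            }
        )
    return pd.concat(parts, ignore_index=True)
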