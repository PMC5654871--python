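"""Pre-landfall comparisons: discharge proportions, transfer shares, case
mix, and length of stay.

Every estimator here contrasts the week before landfall in the storm year
against the weekday-aligned week of the prior year.  All p-values are
two-sided, the significance threshold throughout the package is 0.05, and
no multiple-testing correction is applied (each contrast is reported on
its own, as is conventional for a small set of pre-specified outcomes).

Denominator convention for "percent discharged" (documented prominently
because administrative sources rarely define it): the denominator is every
inpatient occupying a bed at any point during the target week (admitted on
or before the week's last day and discharged on or after its first day);
the numerator is those discharged within the week.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .claims_model import DateInterval, in_interval

logger = logging.getLogger(__name__)

SIGNIFICANCE_LEVEL = 0.05


class InsufficientDataError(ValueError):
    """An estimator was handed fewer observations than it needs."""


@dataclasses.dataclass
class EffectEstimate:
    """A single comparison's result.

    ``estimate`` is on the scale native to the design: a difference in
    proportions for ``chi_square``, an odds ratio for
    ``logistic_adjusted``, a mean difference for ``welch_t``, days for
    ``ols_drg_matched``, visits per beneficiary-week for ``dd``/``ddd_mcs``.
    ``status`` is ``"ok"`` unless the fit degenerated
    (``"non_convergence"``, ``"degenerate"``, ``"single_stratum"``).
    """

    design: str
    estimate: float | None
    se: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    p_value: float | None = None
    n: int = 0
    status: str = "ok"

    def significant(self, alpha: float = SIGNIFICANCE_LEVEL) -> bool | None:
        if self.p_value is None:
            return None
        return bool(self.p_value <= alpha)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def relative_change(baseline_pct: float, comparison_pct: float) -> float:
    """Percent relative change between two percentages, to one decimal.

    ``relative_change(51.8, 55.5) == 7.1``.
    """
    if baseline_pct <= 0:
        raise ValueError(
            f"baseline percentage must be > 0, got {baseline_pct!r}"
        )
    return round(100.0 * (comparison_pct - baseline_pct) / baseline_pct, 1)


def compare_proportions(
    events_a: int,
    total_a: int,
    events_b: int,
    total_b: int,
    continuity_correction: bool = False,
) -> tuple[EffectEstimate, float | None]:
    """Pearson chi-square contrast of two proportions (a = prior, b = study).

    Returns the effect (estimate = difference in proportions, b minus a)
    together with the percent relative change of the proportions.  The
    continuity correction is off by default (large-sample claims data);
    pass ``continuity_correction=True`` to enable Yates' correction.
    A degenerate 2x2 table (any zero margin) yields a flagged estimate
    with an absent p-value.
    """
    if total_a <= 0 or total_b <= 0:
        raise ValueError("totals must be > 0")
    if not (0 <= events_a <= total_a) or not (0 <= events_b <= total_b):
        raise ValueError("events must lie in [0, total]")
    pa, pb = events_a / total_a, events_b / total_b
    n = total_a + total_b
    se = float(
        np.sqrt(pa * (1 - pa) / total_a + pb * (1 - pb) / total_b)
    )
    table = np.array(
        [[events_a, total_a - events_a], [events_b, total_b - events_b]]
    )
    est = EffectEstimate(
        design="chi_square",
        estimate=pb - pa,
        se=se,
        ci_low=pb - pa - 1.959963984540054 * se,
        ci_high=pb - pa + 1.959963984540054 * se,
        n=n,
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        est.status = "degenerate"
        est.p_value = None
    else:
        chi2 = stats.chi2_contingency(table, correction=continuity_correction)
        est.p_value = float(chi2.pvalue)
    rel = relative_change(100.0 * pa, 100.0 * pb) if pa > 0 else None
    return est, rel


def adjusted_discharge_model(rows: pd.DataFrame) -> EffectEstimate:
    """Logistic regression of a binary outcome on the study-week indicator
    adjusted for age, sex, and race.

    ``rows`` needs columns ``outcome`` (bool/0-1), ``study_week``
    (bool/0-1), ``age`` (years, continuous), ``sex``, ``race``
    (categorical; the most frequent level is the reference).  The estimate
    is the odds ratio on the study-week indicator with a Wald CI.
    Complete separation or non-convergence yields a flagged estimate
    rather than an exception.
    """
    y = rows["outcome"].astype(float).to_numpy()
    if len(np.unique(y)) < 2:
        return EffectEstimate(
            design="logistic_adjusted",
            estimate=None,
            n=len(rows),
            status="non_convergence",
        )
    X = _design_matrix(rows, indicator="study_week")
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        converged = bool(fit.mle_retvals.get("converged", False))
        bse = np.asarray(fit.bse)
        if not converged or not np.isfinite(bse).all() or bse[1] > 50:
            raise ValueError("non-convergence")
    except Exception:
        return EffectEstimate(
            design="logistic_adjusted",
            estimate=None,
            n=len(rows),
            status="non_convergence",
        )
    beta, se = float(fit.params[1]), float(fit.bse[1])
    z = 1.959963984540054
    return EffectEstimate(
        design="logistic_adjusted",
        estimate=float(np.exp(beta)),
        se=se,
        ci_low=float(np.exp(beta - z * se)),
        ci_high=float(np.exp(beta + z * se)),
        p_value=float(fit.pvalues[1]),
        n=len(rows),
    )


def compare_cmi(weights_prior, weights_study) -> EffectEstimate:
    """Welch two-sample t contrast of DRG weights (study minus prior)."""
    a = np.asarray(weights_prior, dtype=float)
    b = np.asarray(weights_study, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError(
            f"compare_cmi needs n >= 2 in both arms, got {len(a)} and {len(b)}"
        )
    res = stats.ttest_ind(b, a, equal_var=False)
    ci = res.confidence_interval(0.95)
    diff = float(b.mean() - a.mean())
    se = float(np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b)))
    return EffectEstimate(
        design="welch_t",
        estimate=diff,
        se=se,
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        p_value=float(res.pvalue),
        n=len(a) + len(b),
    )


def alos_shift(matched: pd.DataFrame) -> EffectEstimate:
    """OLS shift in length of stay for the target week, within DRG strata.

    ``matched`` is the output of
    :func:`stormsurge.severity.drg_matched_frame`.  The model regresses
    length of stay on a target indicator plus DRG stratum indicators; the
    estimate is the indicator coefficient in days.  With a single stratum
    the fit falls back to the unstratified difference (logged and
    flagged).
    """
    if not len(matched):
        raise InsufficientDataError("alos_shift: empty matched frame")
    y = matched["los"].astype(float).to_numpy()
    target = (matched["label"] == "target").astype(float).to_numpy()
    strata = pd.get_dummies(matched["drg_code"], drop_first=True, dtype=float)
    single = strata.shape[1] == 0
    if single:
        logger.warning(
            "alos_shift: single DRG stratum; falling back to the "
            "unstratified difference"
        )
        X = np.column_stack([np.ones_like(y), target])
    else:
        X = np.column_stack([np.ones_like(y), target, strata.to_numpy()])
    fit = sm.OLS(y, X).fit()
    se = float(fit.bse[1])
    z = 1.959963984540054
    return EffectEstimate(
        design="ols_drg_matched",
        estimate=float(fit.params[1]),
        se=se,
        ci_low=float(fit.params[1] - z * se),
        ci_high=float(fit.params[1] + z * se),
        p_value=float(fit.pvalues[1]),
        n=len(matched),
        status="single_stratum" if single else "ok",
    )


def _design_matrix(rows: pd.DataFrame, indicator: str) -> np.ndarray:
    """Intercept, indicator, age, then sex/race dummies (most frequent
    level of each categorical as the reference)."""
    parts = [
        np.ones(len(rows)),
        rows[indicator].astype(float).to_numpy(),
        rows["age"].astype(float).to_numpy(),
    ]
    for col in ("sex", "race"):
        levels = rows[col].value_counts().index.tolist()
        for level in levels[1:]:
            parts.append((rows[col] == level).astype(float).to_numpy())
    return np.column_stack(parts)


# ---------------------------------------------------------------------------
# Window census helpers (discharge-denominator convention)
# ---------------------------------------------------------------------------


def window_census(claims: pd.DataFrame, interval: DateInterval) -> pd.DataFrame:
    """Claims occupying a bed at any point during the interval."""
    if not len(claims):
        return claims
    start, end = pd.Timestamp(interval[0]), pd.Timestamp(interval[1])
    keep = (claims["admit_date"] <= end) & (claims["discharge_date"] >= start)
    return claims.loc[keep]


def window_discharges(
    claims: pd.DataFrame, interval: DateInterval
) -> pd.DataFrame:
    """Claims discharged within the interval (inclusive endpoints)."""
    if not len(claims):
        return claims
    return claims.loc[in_interval(claims["discharge_date"], interval)]


def discharge_counts(
    claims: pd.DataFrame, interval: DateInterval
) -> tuple[int, int]:
    """(discharged within the week, census during the week)."""
    census = window_census(claims, interval)
    discharged = window_discharges(census, interval)
    return len(discharged), len(census)
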