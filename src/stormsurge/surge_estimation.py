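"""Post-landfall ED-surge estimation.

The design is a 2x2 difference-in-differences (DD): beneficiary-week ED
visit counts in the week before vs the week after landfall, in the storm
year vs the weekday-aligned weeks of the prior year.  The outcome enters a
linear model so the year x period interaction reads directly in visits per
beneficiary-week, and the percent surge divides the interaction by the
model-implied counterfactual post-week mean (the pre-storm-week mean plus
the prior year's post-minus-pre difference).  Standard errors are
heteroskedasticity-consistent (HC1).

Validation is a matched triple difference (DDD): a Monte Carlo loop
(default 1,000 iterations) matches each study-state beneficiary 1:1 with
replacement to a comparison-pool beneficiary in the same (5-year age band,
sex, race) cell and subtracts the matched pool's DD from the study state's
DD, removing any shock common to both regions in the storm year (seasonal
influenza and the like).  Without covariate adjustment the pooled
triple-interaction regression coefficient is algebraically identical to
that difference of DDs computed from cell means, which is how the Monte
Carlo loop evaluates it; the full regression route is available via
``triple_difference_regression`` / ``adjust=True``.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .claims_model import (
    StudyWindows,
    assign_quartile,
    assign_quartiles,  # noqa: F401  (re-exported convenience)
    in_interval,
)
from .prestorm_stats import EffectEstimate

logger = logging.getLogger(__name__)

PANEL_COLUMNS = (
    "bene_id", "year", "period", "ed_visits", "ed_discharges",
    "ed_admissions", "age", "sex", "race", "quartile",
)

OUTCOMES = ("ed_visits", "ed_discharges", "ed_admissions")

_Z95 = 1.959963984540054


class DesignError(ValueError):
    """The panel is missing a year x period cell the design requires."""


# ---------------------------------------------------------------------------
# Simple arithmetic operations
# ---------------------------------------------------------------------------


def extrapolate(sample_count: int, sampling_fraction: float) -> int:
    """Scale a sample count to the full population: round(count / fraction)."""
    if sampling_fraction <= 0 or sampling_fraction > 1:
        raise ValueError(
            f"sampling_fraction must be in (0, 1], got {sampling_fraction!r}"
        )
    return round(sample_count / sampling_fraction)


def disposition_split(
    discharged_increase: int, admitted_increase: int
) -> tuple[int, int]:
    """Percent of a surge discharged vs admitted, as whole percents."""
    if discharged_increase < 0 or admitted_increase < 0:
        raise ValueError("counts must be >= 0")
    total = discharged_increase + admitted_increase
    if total == 0:
        raise ValueError("disposition split undefined when both counts are 0")
    return (
        round(100.0 * discharged_increase / total),
        round(100.0 * admitted_increase / total),
    )


# ---------------------------------------------------------------------------
# Panel construction
# ---------------------------------------------------------------------------


def build_panel(
    members,
    beneficiaries: pd.DataFrame,
    ed_visits: pd.DataFrame,
    county_chi: pd.DataFrame | None = None,
    windows: StudyWindows | None = None,
) -> pd.DataFrame:
    """One row per beneficiary x year x period with ED utilization counts.

    ``members`` is an iterable of bene_ids (e.g. a cohort or pool).  Every
    member contributes exactly 4 rows; weeks without visits count zero,
    and visit counts always partition into discharges + admissions.
    Visits outside all four windows are ignored by design; the number
    ignored is recorded in ``panel.attrs["visits_outside_windows"]``.
    Age is the beneficiary's age at January 1 of each row's year.
    """
    windows = windows or StudyWindows()
    member_ids = pd.Index(sorted(set(members)), dtype=object, name="bene_id")
    demo = beneficiaries.set_index("bene_id").loc[member_ids]

    cells = list(windows.by_cell().items())
    visits = ed_visits[ed_visits["bene_id"].isin(member_ids)]
    labels = pd.Series("", index=visits.index, dtype=object)
    for (year, period), interval in cells:
        labels[in_interval(visits["visit_date"], interval)] = f"{year}|{period}"
    in_any = labels != ""
    outside = int((~in_any).sum())

    vis = visits[in_any].copy()
    vis["cell"] = labels[in_any]
    vis["admitted"] = (vis["disposition"] == "admitted").astype(int)
    counts = (
        vis.groupby(["bene_id", "cell"], sort=False)
        .agg(ed_visits=("visit_id", "size"), ed_admissions=("admitted", "sum"))
        .reset_index()
    )

    grid = pd.MultiIndex.from_product(
        [member_ids, [f"{y}|{p}" for (y, p), _ in cells]],
        names=["bene_id", "cell"],
    ).to_frame(index=False)
    panel = grid.merge(counts, on=["bene_id", "cell"], how="left").fillna(
        {"ed_visits": 0, "ed_admissions": 0}
    )
    panel[["year", "period"]] = panel["cell"].str.split("|", expand=True)
    panel["ed_visits"] = panel["ed_visits"].astype(int)
    panel["ed_admissions"] = panel["ed_admissions"].astype(int)
    panel["ed_discharges"] = panel["ed_visits"] - panel["ed_admissions"]

    study_year = windows.post_2012[0].year
    year_num = np.where(panel["year"] == "study", study_year, study_year - 1)
    panel["age"] = year_num - panel["bene_id"].map(demo["birth_year"]).to_numpy()
    panel["sex"] = panel["bene_id"].map(demo["sex"])
    panel["race"] = panel["bene_id"].map(demo["race"])
    if county_chi is not None and len(county_chi):
        county_q = county_chi.set_index("county_id")["quartile"]
        panel["quartile"] = panel["bene_id"].map(
            demo["county_id"].map(county_q)
        )
    else:
        panel["quartile"] = pd.NA

    panel = panel[list(PANEL_COLUMNS)]
    panel.attrs["visits_outside_windows"] = outside
    if outside:
        logger.info(
            "build_panel: %d visit(s) fell outside all study windows", outside
        )
    return panel


def _cell_means(panel: pd.DataFrame, outcome: str) -> dict[tuple[str, str], float]:
    means = panel.groupby(["year", "period"])[outcome].mean()
    out = {}
    for year in ("study", "prior"):
        for period in ("pre", "post"):
            if (year, period) not in means.index:
                raise DesignError(
                    f"panel has no rows for cell (year={year}, period={period})"
                )
            out[(year, period)] = float(means.loc[(year, period)])
    return out


def counterfactual_post_mean(
    panel: pd.DataFrame, outcome: str = "ed_visits"
) -> float:
    """Post-week mean expected absent the storm: study pre mean plus the
    prior year's post-minus-pre difference."""
    m = _cell_means(panel, outcome)
    return m[("study", "pre")] + m[("prior", "post")] - m[("prior", "pre")]


# ---------------------------------------------------------------------------
# Difference in differences
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class DDResult:
    """A DD fit: the interaction effect plus its percent-surge reading."""

    effect: EffectEstimate
    percent_surge: float
    percent_se: float
    counterfactual: float
    cell_means: dict

    def as_dict(self) -> dict:
        d = self.effect.as_dict()
        d.update(
            percent_surge=self.percent_surge,
            percent_se=self.percent_se,
            counterfactual=self.counterfactual,
        )
        return d


def dd_estimate(
    panel: pd.DataFrame, outcome: str = "ed_visits", adjust: bool = True
) -> DDResult:
    """Difference-in-differences regression on a beneficiary-week panel.

    Linear model of the outcome count on year, period, their interaction
    and (when ``adjust``) age, sex, and race, with HC1 robust standard
    errors.  The interaction coefficient is the surge in visits per
    beneficiary-week; ``percent_surge`` expresses it relative to the
    counterfactual post-week mean.
    """
    means = _cell_means(panel, outcome)
    y = panel[outcome].astype(float).to_numpy()
    study = (panel["year"] == "study").astype(float).to_numpy()
    post = (panel["period"] == "post").astype(float).to_numpy()
    parts = [np.ones_like(y), study, post, study * post]
    if adjust:
        parts.append(panel["age"].astype(float).to_numpy())
        for col in ("sex", "race"):
            levels = panel[col].value_counts().index.tolist()
            for level in levels[1:]:
                parts.append((panel[col] == level).astype(float).to_numpy())
    X = np.column_stack(parts)
    fit = sm.OLS(y, X).fit(cov_type="HC1")
    beta, se = float(fit.params[3]), float(fit.bse[3])
    cf = means[("study", "pre")] + means[("prior", "post")] - means[("prior", "pre")]
    if cf <= 0:
        raise DesignError(
            f"counterfactual post-week mean is non-positive ({cf:g}); "
            "percent surge undefined"
        )
    effect = EffectEstimate(
        design="dd",
        estimate=beta,
        se=se,
        ci_low=beta - _Z95 * se,
        ci_high=beta + _Z95 * se,
        p_value=float(fit.pvalues[3]),
        n=len(panel),
    )
    return DDResult(
        effect=effect,
        percent_surge=100.0 * beta / cf,
        percent_se=100.0 * se / cf,
        counterfactual=cf,
        cell_means={f"{y_}_{p}": v for (y_, p), v in means.items()},
    )


# ---------------------------------------------------------------------------
# Demographic matching and the Monte Carlo triple difference
# ---------------------------------------------------------------------------

AGE_BAND_YEARS = 5


def _age_band(age: np.ndarray, width: int = AGE_BAND_YEARS) -> np.ndarray:
    return (np.asarray(age, dtype=int) // width) * width


def _demo_cells(demo: pd.DataFrame, width: int) -> pd.Series:
    band = _age_band(demo["age"].to_numpy(), width)
    return pd.Series(
        [f"{b}|{s}|{r}" for b, s, r in zip(band, demo["sex"], demo["race"])],
        index=demo.index,
    )


class _Matcher:
    """Precomputed (age band, sex, race) cell structure for repeated draws."""

    def __init__(self, nj_demo: pd.DataFrame, pool_demo: pd.DataFrame):
        if not len(pool_demo):
            raise ValueError("comparison pool is empty")
        nj_cells = _demo_cells(nj_demo, AGE_BAND_YEARS).to_numpy()
        pool_cells = _demo_cells(pool_demo, AGE_BAND_YEARS).to_numpy()
        pool_pos: dict[str, np.ndarray] = {
            c: np.flatnonzero(pool_cells == c) for c in np.unique(pool_cells)
        }
        wide_nj = wide_pos = None
        self.groups: list[tuple[np.ndarray, np.ndarray]] = []
        self.n = len(nj_demo)
        for cell in np.unique(nj_cells):
            rows = np.flatnonzero(nj_cells == cell)
            pool_rows = pool_pos.get(cell)
            if pool_rows is None or not len(pool_rows):
                if wide_pos is None:
                    logger.warning(
                        "match_beneficiaries: empty pool cell %r; widening "
                        "to 10-year age bands", cell,
                    )
                    wide_nj = _demo_cells(nj_demo, 2 * AGE_BAND_YEARS).to_numpy()
                    wide_pool = _demo_cells(
                        pool_demo, 2 * AGE_BAND_YEARS
                    ).to_numpy()
                    wide_pos = {
                        c: np.flatnonzero(wide_pool == c)
                        for c in np.unique(wide_pool)
                    }
                pool_rows = wide_pos.get(
                    wide_nj[rows[0]], np.empty(0, dtype=np.int64)
                )
                if not len(pool_rows):
                    raise ValueError(
                        f"no comparison-pool member matches cell {cell!r} "
                        "even with 10-year age bands"
                    )
            self.groups.append((rows, pool_rows))

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        out = np.empty(self.n, dtype=np.int64)
        for rows, pool_rows in self.groups:
            out[rows] = pool_rows[rng.integers(0, len(pool_rows), size=len(rows))]
        return out


def match_beneficiaries(
    nj_demo: pd.DataFrame,
    pool_demo: pd.DataFrame,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Positions into ``pool_demo`` matching each study row 1:1 with
    replacement on (5-year age band, sex, race).

    Both frames need ``age``, ``sex`` and ``race`` columns (one row per
    beneficiary).  A study cell with no pool counterpart falls back to
    10-year age bands (with a warning); a cell empty even then raises.
    The matched sample's demographic cell counts equal the study counts
    by construction.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.Generator(np.random.Philox(key=[int(rng) & (2**63 - 1), 7]))
    return _Matcher(nj_demo, pool_demo).draw(rng)


@dataclasses.dataclass
class MCSResult:
    """Aggregate of the Monte Carlo matched triple-difference iterations.

    ``estimates`` are per-iteration DDD effects in visits per
    beneficiary-week; ``percents`` express each iteration relative to the
    storm-free counterfactual (study counterfactual plus the matched
    comparison's DD, so a shock common to both regions cancels from the
    numerator and denominator alike).  ``point`` is the mean of
    ``estimates`` (median available via ``use_median`` upstream);
    percentile CIs are absent when there are fewer than 2 usable
    iterations.
    """

    iterations: int
    estimates: np.ndarray
    percents: np.ndarray
    point: float
    ci_low: float | None
    ci_high: float | None
    percent_point: float
    percent_ci_low: float | None
    percent_ci_high: float | None
    seed: int
    n_missing: int = 0

    def sd(self) -> float:
        return float(np.std(self.estimates, ddof=1)) if len(self.estimates) > 1 else 0.0

    def percent_sd(self) -> float:
        return float(np.std(self.percents, ddof=1)) if len(self.percents) > 1 else 0.0


def member_dd(panel: pd.DataFrame, outcome: str = "ed_visits") -> pd.DataFrame:
    """Per-beneficiary DD contrasts plus demographics (one row each).

    The member-level DD is (post - pre) in the study year minus
    (post - pre) in the prior year; its mean over members equals the
    unadjusted panel DD interaction.
    """
    wide = panel.pivot_table(
        index="bene_id", columns=["year", "period"], values=outcome,
        aggfunc="sum", fill_value=0,
    )
    dd = (
        wide[("study", "post")] - wide[("study", "pre")]
        - wide[("prior", "post")] + wide[("prior", "pre")]
    )
    demo = (
        panel[panel["year"] == "study"]
        .drop_duplicates("bene_id")
        .set_index("bene_id")[["age", "sex", "race"]]
    )
    out = demo.loc[dd.index].copy()
    out["dd"] = dd.astype(float)
    return out.reset_index()


def triple_difference_regression(
    nj_panel: pd.DataFrame,
    comparison_panel: pd.DataFrame,
    adjust: bool = False,
) -> EffectEstimate:
    """Pooled OLS with the study-state x year x period triple interaction.

    Unadjusted, the triple-interaction coefficient equals the difference
    of the two groups' DD interactions exactly; this route exists for
    covariate adjustment and as a cross-check of the cell-mean fast path.
    """
    pooled = pd.concat(
        [nj_panel.assign(in_study=1.0), comparison_panel.assign(in_study=0.0)],
        ignore_index=True,
    )
    y = pooled["ed_visits"].astype(float).to_numpy()
    g = pooled["in_study"].to_numpy()
    s = (pooled["year"] == "study").astype(float).to_numpy()
    p = (pooled["period"] == "post").astype(float).to_numpy()
    parts = [np.ones_like(y), g, s, p, g * s, g * p, s * p, g * s * p]
    if adjust:
        parts.append(pooled["age"].astype(float).to_numpy())
        for col in ("sex", "race"):
            levels = pooled[col].value_counts().index.tolist()
            for level in levels[1:]:
                parts.append((pooled[col] == level).astype(float).to_numpy())
    X = np.column_stack(parts)
    fit = sm.OLS(y, X).fit(cov_type="HC1")
    beta, se = float(fit.params[7]), float(fit.bse[7])
    return EffectEstimate(
        design="ddd_mcs",
        estimate=beta,
        se=se,
        ci_low=beta - _Z95 * se,
        ci_high=beta + _Z95 * se,
        p_value=float(fit.pvalues[7]),
        n=len(pooled),
    )


def ddd_mcs(
    nj_panel: pd.DataFrame,
    pool_panel: pd.DataFrame,
    iterations: int = 1000,
    seed: int = 0,
    outcome: str = "ed_visits",
    use_median: bool = False,
) -> MCSResult:
    """Monte Carlo matched triple difference.

    Each iteration draws a fresh 1:1-with-replacement demographic match of
    the comparison pool to the study cohort and evaluates
    DDD = (study DD) - (matched comparison DD).  Deterministic given
    ``seed``.  Iterations whose matched DD is undefined are recorded as
    missing; the run continues while fewer than 5% are missing.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    nj = member_dd(nj_panel, outcome)
    pool = member_dd(pool_panel, outcome)
    nj_dd = float(nj["dd"].mean())
    cf = counterfactual_post_mean(nj_panel, outcome)

    rng = np.random.Generator(np.random.Philox(key=[int(seed) & (2**63 - 1), 11]))
    pool_dd = pool["dd"].to_numpy()
    matcher = _Matcher(nj, pool)
    estimates = np.empty(iterations)
    percents = np.empty(iterations)
    missing = 0
    for it in range(iterations):
        idx = matcher.draw(rng)
        comp_dd = float(pool_dd[idx].mean())
        denom = cf + comp_dd
        if not np.isfinite(comp_dd) or denom <= 0:
            estimates[it] = np.nan
            percents[it] = np.nan
            missing += 1
            if missing / iterations >= 0.05:
                raise RuntimeError(
                    "ddd_mcs: 5% or more iterations failed to produce an "
                    "estimate"
                )
            continue
        estimates[it] = nj_dd - comp_dd
        percents[it] = 100.0 * (nj_dd - comp_dd) / denom
    ok = np.isfinite(estimates)
    est, pct = estimates[ok], percents[ok]
    agg = np.median if use_median else np.mean
    if len(est) > 1:
        lo, hi = np.percentile(est, [2.5, 97.5])
        plo, phi = np.percentile(pct, [2.5, 97.5])
    else:
        lo = hi = plo = phi = None
    return MCSResult(
        iterations=iterations,
        estimates=est,
        percents=pct,
        point=float(agg(est)),
        ci_low=None if lo is None else float(lo),
        ci_high=None if hi is None else float(hi),
        percent_point=float(agg(pct)),
        percent_ci_low=None if plo is None else float(plo),
        percent_ci_high=None if phi is None else float(phi),
        seed=seed,
        n_missing=missing,
    )


# ---------------------------------------------------------------------------
# Quartile stratification
# ---------------------------------------------------------------------------


def stratify_by_quartile(
    panel: pd.DataFrame,
    outcomes=OUTCOMES,
    adjust: bool = False,
) -> pd.DataFrame:
    """Percent surge per CHI quartile and statewide, per disposition.

    Returns one row per (stratum, outcome) with the DD effect, percent
    surge and significance; an empty quartile is flagged absent rather
    than raising.
    """
    rows = []
    strata = [("statewide", panel)] + [
        (q, panel[panel["quartile"] == q]) for q in ("Q1", "Q2", "Q3", "Q4")
    ]
    for name, sub in strata:
        for outcome in outcomes:
            if not len(sub):
                rows.append(
                    {"stratum": name, "outcome": outcome, "status": "absent"}
                )
                continue
            try:
                res = dd_estimate(sub, outcome=outcome, adjust=adjust)
            except DesignError:
                rows.append(
                    {"stratum": name, "outcome": outcome, "status": "absent"}
                )
                continue
            rows.append(
                {
                    "stratum": name,
                    "outcome": outcome,
                    "status": "ok",
                    "effect": res.effect.estimate,
                    "se": res.effect.se,
                    "p_value": res.effect.p_value,
                    "percent_surge": res.percent_surge,
                    "percent_se": res.percent_se,
                    "n_members": sub["bene_id"].nunique(),
                }
            )
    return pd.DataFrame(rows)
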