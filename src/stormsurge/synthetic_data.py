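"""Synthetic claims generator with planted storm effects.

Restricted Medicare claims cannot be redistributed, so every downstream
stage of this package is exercised on populations drawn from a
:class:`Scenario`: a two-year (2011-2012) enrollment panel, weekly ED-visit
processes with sinusoidal seasonality, inpatient stays with
diagnosis-related-group (DRG) service-intensity weights, inter-facility
transfer events, and county assignment with Community Hardship Index (CHI)
scores binned into the published impact quartiles.

Planted effects (all switched off in the ``"null"`` preset):

* a pre-landfall-week multiplicative acceleration of the weekly hospital
  discharge probability,
* a pre-landfall-week surge in SNF-to-hospital transfer admissions, whose
  patients carry an upward-shifted log DRG weight,
* an additive shift (in days) to the length of stay of pre-landfall-week
  discharges,
* a post-landfall-week multiplicative ED-visit surge graded by CHI
  quartile, with the storm-attributable visits admitted at a lower rate
  than baseline visits,
* optionally a post-landfall-week shock shared by every state (the
  ``"confounded"`` preset), which biases a plain difference-in-differences
  estimate but is removed by the matched triple difference.

Determinism: all randomness flows through counter-based (Philox) streams
keyed by the scenario seed, with a fixed draw budget per record laid out
beneficiary-major.  Identical scenario + seed reproduces the output
byte-for-byte, and enlarging ``n_beneficiaries`` leaves the records of
existing beneficiaries unchanged.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .claims_model import (
    Bundle,
    DRG_WEIGHT_RANGE,
    QUARTILES,
    assign_quartiles,
)


class ScenarioError(ValueError):
    """Raised when a scenario's parameters are invalid."""


# ---------------------------------------------------------------------------
# Default county table
# ---------------------------------------------------------------------------

# (county_id, CHI score) grouped by impact quartile; population shares are
# proportional to the published per-quartile beneficiary counts
# 37,581 / 52,754 / 56,193 / 77,588 split equally among each quartile's
# counties.
_COUNTY_CHI = {
    "Q1": (
        ("salem", 20.0),
        ("camden", 25.0),
        ("cumberland", 30.0),
        ("gloucester", 35.0),
        ("burlington", 38.0),
    ),
    "Q2": (
        ("warren", 40.0),
        ("passaic", 41.0),
        ("mercer", 43.0),
        ("cape_may", 44.0),
        ("essex", 46.0),
        ("atlantic", 47.0),
    ),
    "Q3": (
        ("hudson", 48.0),
        ("bergen", 50.0),
        ("morris", 53.0),
        ("sussex", 56.0),
        ("hunterdon", 58.0),
    ),
    "Q4": (
        ("union", 60.0),
        ("middlesex", 65.0),
        ("somerset", 72.0),
        ("ocean", 80.0),
        ("monmouth", 90.0),
    ),
}
_QUARTILE_N = {"Q1": 37_581, "Q2": 52_754, "Q3": 56_193, "Q4": 77_588}
_TOTAL_N = sum(_QUARTILE_N.values())


def _default_county_table() -> tuple[tuple[str, float, float], ...]:
    rows = []
    for q, counties in _COUNTY_CHI.items():
        share_q = _QUARTILE_N[q] / _TOTAL_N
        for county_id, chi in counties:
            rows.append((county_id, chi, share_q / len(counties)))
    return tuple(rows)


DEFAULT_COUNTY_TABLE = _default_county_table()

# Weekly grid: 104 Monday-aligned weeks covering 2011-01-03 .. 2012-12-30,
# chosen so the four analysis windows coincide exactly with grid weeks.
WEEK0 = np.datetime64("2011-01-03")
N_WEEKS = 104
PRE_2011_WEEK, POST_2011_WEEK = 42, 43
PRE_2012_WEEK, POST_2012_WEEK = 94, 95

_MAX_STAY_WEEKS = 13  # stays are forced closed after this many weekly draws


# ---------------------------------------------------------------------------
# Scenario
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class Scenario:
    """Generator parameters; defaults describe a storm-free baseline.

    Rates are per beneficiary-week.  The baseline weekly ED-visit rate is
    a statistical-convenience default (it controls how much information a
    run of a given size carries about the planted effects), not an
    empirical Medicare rate; see ``docs/methods.md``.
    """

    n_beneficiaries: int = 10_000
    county_table: tuple = DEFAULT_COUNTY_TABLE
    comparison_share: float = 0.5
    comparison_states: tuple = (
        "OH", "IL", "MI", "IN", "WI", "MN", "MO", "TX", "CA", "WA",
    )
    state: str = "NJ"

    # demographics
    birth_year_range: tuple[int, int] = (1920, 1947)
    sex_female_prob: float = 0.55
    race_probs: tuple = (
        ("white", 0.80), ("black", 0.10), ("hispanic", 0.06), ("other", 0.04),
    )
    continuous_fraction: float = 0.9
    ffs_fraction: float = 0.95

    # baseline event processes
    baseline_ed_rate: float = 0.10
    admit_given_ed: float = 0.40
    surge_admit_given_ed: float = 0.20
    baseline_discharge_rate: float = 0.518
    seasonal_amplitude: float = 0.10
    seasonal_peak_doy: int = 15

    # planted storm effects
    surge_multipliers: tuple = (
        ("Q1", 1.0), ("Q2", 1.0), ("Q3", 1.0), ("Q4", 1.0),
    )
    confounder_multiplier: float = 1.0
    discharge_acceleration: float = 1.0
    snf_transfer_multiplier: float = 1.0
    snf_severity_shift: float = 0.0
    alos_shift_days: float = 0.0

    # transfer / severity structure
    snf_transfer_baseline: float = 0.09
    hospital_transfer_baseline: float = 0.03
    hospice_transfer_baseline: float = 0.01
    source_code_missing_prob: float = 0.30
    drg_weight_sigma: float = 0.50
    drg_weight_cmi: float = 1.40
    n_drg_codes: int = 40
    n_hospitals: int = 20
    n_snfs: int = 50
    n_hospices: int = 8
    discharge_disposition_probs: tuple = (
        ("home", 0.45), ("home_health", 0.20), ("snf", 0.20),
        ("hospice", 0.03), ("transfer_hospital", 0.02),
        ("expired", 0.05), ("other", 0.05),
    )

    seed: int = 0

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        """Raise :class:`ScenarioError` listing every offending field."""
        bad: list[str] = []
        if self.n_beneficiaries < 0:
            bad.append("n_beneficiaries must be >= 0")
        shares = [row[2] for row in self.county_table]
        if abs(sum(shares) - 1.0) > 1e-9:
            bad.append("county population shares must sum to 1 within 1e-9")
        if any(s < 0 for s in shares):
            bad.append("county population shares must be non-negative")
        for name in (
            "comparison_share", "sex_female_prob", "continuous_fraction",
            "ffs_fraction", "admit_given_ed", "surge_admit_given_ed",
            "baseline_discharge_rate", "snf_transfer_baseline",
            "hospital_transfer_baseline", "hospice_transfer_baseline",
            "source_code_missing_prob",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                bad.append(f"{name} must be in [0, 1], got {v!r}")
        if self.baseline_ed_rate < 0 or self.baseline_ed_rate > 1:
            bad.append("baseline_ed_rate must be in [0, 1]")
        if not (0.0 <= self.seasonal_amplitude < 1.0):
            bad.append("seasonal_amplitude must be in [0, 1)")
        for name in (
            "confounder_multiplier", "discharge_acceleration",
            "snf_transfer_multiplier",
        ):
            if getattr(self, name) <= 0:
                bad.append(f"{name} must be > 0")
        if abs(self.alos_shift_days) > 6.0 / 7.0:
            bad.append(
                "alos_shift_days magnitude must be <= 6/7 day (the shift "
                "is planted within a single discharge week)"
            )
        mults = dict(self.surge_multipliers)
        if set(mults) != set(QUARTILES):
            bad.append("surge_multipliers must cover Q1..Q4")
        elif any(m <= 0 for m in mults.values()):
            bad.append("surge multipliers must be > 0")
        if abs(sum(p for _, p in self.race_probs) - 1.0) > 1e-9:
            bad.append("race_probs must sum to 1")
        if self.n_drg_codes < 2:
            bad.append("n_drg_codes must be >= 2")
        if bad:
            raise ScenarioError("invalid scenario: " + "; ".join(bad))

    # -- derived structures ------------------------------------------------

    def surge_multiplier_map(self) -> dict[str, float]:
        return dict(self.surge_multipliers)

    def county_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            list(self.county_table), columns=["county_id", "chi_score", "share"]
        )
        df["quartile"] = assign_quartiles(df["chi_score"].to_numpy())
        return df

    def drg_weight_table(self) -> pd.DataFrame:
        """DRG codes with log-normal-quantile weights, clipped to range.

        The grid of log-weights is placed at equiprobable normal quantiles
        so that a claim drawing a latent log-normal severity and snapping
        to the nearest code has mean weight ~ ``drg_weight_cmi``.
        """
        k = self.n_drg_codes
        sigma = self.drg_weight_sigma
        mu = math.log(self.drg_weight_cmi) - sigma**2 / 2.0
        qs = (np.arange(k) + 0.5) / k
        logw = mu + sigma * stats.norm.ppf(qs)
        w = np.clip(np.exp(logw), *DRG_WEIGHT_RANGE)
        codes = [f"DRG{i + 1:03d}" for i in range(k)]
        return pd.DataFrame({"drg_code": codes, "weight": np.round(w, 4)})

    # -- planted-value helpers (exact expectations under the model) -------

    def quartile_shares(self) -> dict[str, float]:
        df = self.county_frame()
        return df.groupby("quartile")["share"].sum().to_dict()

    def planted_statewide_surge_multiplier(self) -> float:
        shares = self.quartile_shares()
        mults = self.surge_multiplier_map()
        return sum(shares.get(q, 0.0) * mults[q] for q in QUARTILES)

    def planted_surge_pct(
        self, quartile: str | None = None, outcome: str = "ed_visits"
    ) -> float:
        """Expected percent surge recovered by the DD estimator.

        ``outcome`` is one of ``ed_visits``, ``ed_discharges``,
        ``ed_admissions``.  Storm-attributable visits are admitted with
        probability ``surge_admit_given_ed`` instead of ``admit_given_ed``,
        so disposition-specific surges differ from the total.
        """
        if quartile is None:
            m = self.planted_statewide_surge_multiplier()
        else:
            m = self.surge_multiplier_map()[quartile]
        extra = m - 1.0
        if outcome == "ed_visits":
            return 100.0 * extra
        pa, ps = self.admit_given_ed, self.surge_admit_given_ed
        if extra < 0:  # rate deficits scale baseline visits uniformly
            ps = pa
        if outcome == "ed_admissions":
            return 100.0 * extra * ps / pa
        if outcome == "ed_discharges":
            return 100.0 * extra * (1.0 - ps) / (1.0 - pa)
        raise ValueError(f"unknown outcome {outcome!r}")

    def planted_relative_discharge_change_pct(self) -> float:
        return 100.0 * (self.discharge_acceleration - 1.0)

    def planted_discharge_odds_ratio(self) -> float:
        p = self.baseline_discharge_rate
        pa = min(p * self.discharge_acceleration, 0.99)
        return (pa / (1 - pa)) / (p / (1 - p))

    def planted_snf_transfer_change_pct(self) -> float:
        return 100.0 * (self.snf_transfer_multiplier - 1.0)

    def planted_snf_cmi_ratio(self) -> float:
        return math.exp(self.snf_severity_shift)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------


def preset_scenarios(n_beneficiaries: int = 10_000, seed: int = 0) -> dict:
    """Named scenario catalog.

    ``"null"``
        no storm effects at all; every estimator should find nothing.
    ``"sandy_like"``
        effects sized to the published point estimates: a 7.1% relative
        discharge increase, a 38.9% SNF-transfer increase with the
        1.40 -> 1.96 case-mix shift, a -0.3 day length-of-stay shift, and
        quartile ED-surge multipliers whose beneficiary-weighted statewide
        mean is +14.3% with +35.5% in the hardest-hit quartile.
    ``"confounded"``
        sandy_like plus a +25% post-landfall-week shock common to every
        state (a flu-like wave), used to demonstrate that the matched
        triple difference removes what plain DD cannot.
    """

    def base(**kw) -> Scenario:
        return Scenario(n_beneficiaries=n_beneficiaries, seed=seed, **kw)

    sandy_kw = dict(
        discharge_acceleration=1.071,
        alos_shift_days=-0.3,
        snf_transfer_multiplier=12.5 / 9.0,
        snf_severity_shift=math.log(1.96 / 1.40),
        surge_multipliers=(
            ("Q1", 0.97), ("Q2", 1.02), ("Q3", 1.0815), ("Q4", 1.355),
        ),
    )
    catalog = {
        "null": base(),
        "sandy_like": base(**sandy_kw),
        "confounded": base(confounder_multiplier=1.25, **sandy_kw),
    }
    return catalog


def get_preset(name: str, n_beneficiaries: int = 10_000, seed: int = 0) -> Scenario:
    catalog = preset_scenarios(n_beneficiaries=n_beneficiaries, seed=seed)
    try:
        return catalog[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(catalog)}"
        ) from None


# ---------------------------------------------------------------------------
# Random streams
# ---------------------------------------------------------------------------


def _stream(seed: int, label: int) -> np.random.Generator:
    """A counter-based stream; distinct labels are independent streams."""
    return np.random.Generator(np.random.Philox(key=[int(seed) & (2**63 - 1), label]))


def _seasonal_factors(scn: Scenario) -> np.ndarray:
    mid = WEEK0 + 7 * np.arange(N_WEEKS) + 3  # mid-week dates
    year_start = mid.astype("datetime64[Y]").astype("datetime64[D]")
    doy = (mid - year_start).astype(int) + 1
    phase = 2.0 * np.pi * (doy - scn.seasonal_peak_doy) / 365.25
    return 1.0 + scn.seasonal_amplitude * np.cos(phase)


# ---------------------------------------------------------------------------
# Population
# ---------------------------------------------------------------------------


def generate_population(scenario: Scenario) -> pd.DataFrame:
    """Draw the beneficiary table for a scenario.

    A ``comparison_share`` fraction of rows is assigned to non-affected
    comparison states (for the triple-difference pool); the rest live in
    the study state with county membership drawn from the scenario's
    county population shares.  Deterministic given the scenario seed.
    """
    scenario.validate()
    n = scenario.n_beneficiaries
    cols = [
        "bene_id", "birth_year", "sex", "race", "state", "county_id",
        "ffs_flag", "enrolled_months",
    ]
    if n == 0:
        return pd.DataFrame({c: pd.Series(dtype=object) for c in cols})

    u = _stream(scenario.seed, 0).random((n, 9))
    counties = scenario.county_frame()
    county_cut = np.cumsum(counties["share"].to_numpy())
    county_cut[-1] = 1.0

    is_comparison = u[:, 0] < scenario.comparison_share
    states = np.asarray(scenario.comparison_states, dtype=object)
    state = np.where(
        is_comparison,
        states[(u[:, 1] * len(states)).astype(int)],
        scenario.state,
    ).astype(object)
    county_idx = np.searchsorted(county_cut, u[:, 2], side="right")
    county_idx = np.minimum(county_idx, len(counties) - 1)
    county = counties["county_id"].to_numpy(dtype=object)[county_idx]
    county = np.where(
        is_comparison,
        np.char.add(state.astype(str), "_pool").astype(object),
        county,
    )

    y0, y1 = scenario.birth_year_range
    birth_year = y0 + (u[:, 3] * (y1 - y0 + 1)).astype(int)
    sex = np.where(u[:, 4] < scenario.sex_female_prob, "F", "M").astype(object)
    race_labels = np.asarray([r for r, _ in scenario.race_probs], dtype=object)
    race_cut = np.cumsum([p for _, p in scenario.race_probs])
    race_cut[-1] = 1.0
    race = race_labels[np.searchsorted(race_cut, u[:, 5], side="right")]

    continuous = u[:, 6] < scenario.continuous_fraction
    gap_month = (u[:, 7] * 24).astype(int)
    flags = np.full((n, 24), "1", dtype="U1")
    rows = np.nonzero(~continuous)[0]
    flags[rows, gap_month[rows]] = "0"
    enrolled = np.array(["".join(r) for r in flags], dtype=object)

    ffs = u[:, 8] < scenario.ffs_fraction
    bene_id = np.array([f"B{i:07d}" for i in range(n)], dtype=object)

    return pd.DataFrame(
        {
            "bene_id": bene_id,
            "birth_year": birth_year.astype(np.int64),
            "sex": sex,
            "race": race,
            "state": state,
            "county_id": county,
            "ffs_flag": ffs,
            "enrolled_months": enrolled,
        }
    )


# ---------------------------------------------------------------------------
# Claims
# ---------------------------------------------------------------------------


def _week_rate_matrix(
    scn: Scenario, is_nj: np.ndarray, quartile_mult: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-week baseline rate vector and post-storm-week column multiplier."""
    seasonal = _seasonal_factors(scn)
    base_week = scn.baseline_ed_rate * seasonal
    post_mult = np.where(is_nj, quartile_mult, 1.0) * scn.confounder_multiplier
    return base_week, post_mult


def generate_claims(
    beneficiaries: pd.DataFrame,
    scenario: Scenario,
    weight_table: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw ED visits and inpatient/transfer claims for a population.

    Returns ``(inpatient, ed_visits)`` tables.  At most one counted ED
    visit per beneficiary-week (the analysis unit is the beneficiary-week);
    each admission draws a DRG code by snapping a latent log-normal
    severity onto the weight-table grid, and a length of stay from weekly
    discharge draws whose probability is accelerated during the
    pre-landfall week for study-state stays.
    """
    scenario.validate()
    if weight_table is None:
        weight_table = scenario.drg_weight_table()
    n = len(beneficiaries)
    inp_cols = [
        "claim_id", "bene_id", "facility_id", "facility_type", "admit_date",
        "discharge_date", "drg_code", "admission_source", "through_ed",
        "discharge_disposition",
    ]
    ed_cols = ["visit_id", "bene_id", "visit_date", "disposition", "linked_claim_id"]
    if n == 0:
        return (
            pd.DataFrame({c: pd.Series(dtype=object) for c in inp_cols}),
            pd.DataFrame({c: pd.Series(dtype=object) for c in ed_cols}),
        )

    is_nj = (beneficiaries["state"] == scenario.state).to_numpy()
    counties = scenario.county_frame().set_index("county_id")
    qmap = scenario.surge_multiplier_map()
    county_mult = counties["quartile"].map(qmap)
    quartile_mult = (
        beneficiaries["county_id"].map(county_mult).fillna(1.0).to_numpy(float)
    )

    base_week, post_mult = _week_rate_matrix(scenario, is_nj, quartile_mult)

    # -- weekly visit occurrence (chunked; stream order is row-major) ------
    occ = _stream(scenario.seed, 1)
    vis_rows: list[np.ndarray] = []
    vis_weeks: list[np.ndarray] = []
    chunk = max(1, min(n, 65_536))
    for start in range(0, n, chunk):
        stop = min(n, start + chunk)
        u = occ.random((stop - start, N_WEEKS))
        p = np.broadcast_to(base_week, u.shape).copy()
        p[:, POST_2012_WEEK] = np.clip(
            p[:, POST_2012_WEEK] * post_mult[start:stop], 0.0, 0.95
        )
        r, w = np.nonzero(u < p)
        vis_rows.append(r + start)
        vis_weeks.append(w)
    row = np.concatenate(vis_rows)
    week = np.concatenate(vis_weeks)
    n_visits = len(row)

    # -- visit attributes --------------------------------------------------
    ua = _stream(scenario.seed, 2).random((n_visits, 3))
    visit_date = WEEK0 + 7 * week + (ua[:, 2] * 7).astype(int)

    nj_v = is_nj[row]
    mult_v = quartile_mult[row]
    is_post_storm = week == POST_2012_WEEK
    surge_frac = np.where(
        is_post_storm & nj_v & (mult_v > 1.0), 1.0 - 1.0 / np.maximum(mult_v, 1.0), 0.0
    )
    p_admit = np.where(
        ua[:, 1] < surge_frac, scenario.surge_admit_given_ed, scenario.admit_given_ed
    )
    admitted = ua[:, 0] < p_admit

    # -- stays -------------------------------------------------------------
    s_row = row[admitted]
    s_week = week[admitted]
    s_date = visit_date[admitted]
    n_stays = len(s_row)
    us = _stream(scenario.seed, 3).random((n_stays, 9 + _MAX_STAY_WEEKS))
    # column map: 0 severity, 1 source, 2 disposition, 3 discharge day,
    # 4 receiving facility, 5 source-claim gap, 6 LOS shift, 7 missing
    # source code, 8 source facility, 9.. weekly discharge draws
    nj_s = is_nj[s_row]
    pre_storm_adm = s_week == PRE_2012_WEEK

    # length of stay: weekly discharge draws, accelerated in the
    # pre-landfall calendar week for study-state stays
    cal_week = s_week[:, None] + np.arange(_MAX_STAY_WEEKS)[None, :]
    p_dis = np.full(cal_week.shape, scenario.baseline_discharge_rate)
    accel_cell = (cal_week == PRE_2012_WEEK) & nj_s[:, None]
    p_dis[accel_cell] = np.clip(
        scenario.baseline_discharge_rate * scenario.discharge_acceleration,
        0.0,
        0.99,
    )
    success = us[:, 9:] < p_dis
    any_succ = success.any(axis=1)
    k = np.where(any_succ, success.argmax(axis=1), _MAX_STAY_WEEKS - 1)
    discharge_date = WEEK0 + 7 * (s_week + k) + (us[:, 3] * 7).astype(int)
    discharge_date = np.maximum(discharge_date, s_date)

    # Additive length-of-stay shift for pre-landfall-week discharges.
    # Moves are confined to the window (a shifted discharge never crosses
    # the window boundary or its own admission date, so the census
    # discharge proportion is untouched); the move probability is scaled
    # by the realized movable fraction so the expected shift over all
    # window discharges is exact.
    shift = scenario.alos_shift_days
    if shift != 0.0:
        pre_lo = WEEK0 + 7 * PRE_2012_WEEK
        pre_hi = pre_lo + 6
        in_pre = (discharge_date >= pre_lo) & (discharge_date <= pre_hi) & nj_s
        if shift < 0:
            movable = in_pre & (discharge_date > pre_lo) & (discharge_date > s_date)
            step = np.timedelta64(-1, "D")
        else:
            movable = in_pre & (discharge_date < pre_hi)
            step = np.timedelta64(1, "D")
        n_pre, n_mov = int(in_pre.sum()), int(movable.sum())
        if n_mov:
            p_move = min(abs(shift) * n_pre / n_mov, 1.0)
            move = movable & (us[:, 6] < p_move)
            discharge_date = np.where(move, discharge_date + step, discharge_date)

    # admission source
    p_snf = np.where(
        pre_storm_adm & nj_s,
        scenario.snf_transfer_baseline * scenario.snf_transfer_multiplier,
        scenario.snf_transfer_baseline,
    )
    c1 = p_snf
    c2 = c1 + scenario.hospital_transfer_baseline
    c3 = c2 + scenario.hospice_transfer_baseline
    src_u = us[:, 1]
    source_type = np.select(
        [src_u < c1, src_u < c2, src_u < c3],
        ["snf", "hospital", "hospice"],
        default="",
    ).astype(object)
    is_transfer = source_type != ""
    code_missing = us[:, 7] < scenario.source_code_missing_prob
    admission_source = np.where(
        is_transfer,
        np.where(
            code_missing, "unknown", np.char.add("transfer_", source_type.astype(str))
        ),
        "routine",
    ).astype(object)

    # severity -> DRG code
    wt = weight_table.sort_values("weight").reset_index(drop=True)
    logw_grid = np.log(wt["weight"].to_numpy(float))
    mids = (logw_grid[1:] + logw_grid[:-1]) / 2.0
    sigma = scenario.drg_weight_sigma
    mu = math.log(scenario.drg_weight_cmi) - sigma**2 / 2.0
    z = stats.norm.ppf(np.clip(us[:, 0], 1e-12, 1 - 1e-12))
    sev = mu + sigma * z
    sev = np.where(
        (source_type == "snf") & pre_storm_adm & nj_s,
        sev + scenario.snf_severity_shift,
        sev,
    )
    code_idx = np.searchsorted(mids, sev)
    drg_code = wt["drg_code"].to_numpy(dtype=object)[code_idx]

    # discharge disposition
    disp_labels = np.asarray(
        [d for d, _ in scenario.discharge_disposition_probs], dtype=object
    )
    disp_cut = np.cumsum([p for _, p in scenario.discharge_disposition_probs])
    disp_cut[-1] = 1.0
    disposition = disp_labels[np.searchsorted(disp_cut, us[:, 2], side="right")]

    # facilities
    recv_fac = (us[:, 4] * scenario.n_hospitals).astype(int)
    facility_id = np.array([f"H{i + 1:03d}" for i in recv_fac], dtype=object)

    claim_id = np.array(
        [f"C{b:07d}W{w:03d}" for b, w in zip(s_row, s_week)], dtype=object
    )
    hosp = pd.DataFrame(
        {
            "claim_id": claim_id,
            "bene_id": beneficiaries["bene_id"].to_numpy(dtype=object)[s_row],
            "facility_id": facility_id,
            "facility_type": "hospital",
            "admit_date": pd.to_datetime(s_date),
            "discharge_date": pd.to_datetime(discharge_date),
            "drg_code": drg_code,
            "admission_source": admission_source,
            "through_ed": True,
            "discharge_disposition": disposition,
        }
    )

    # source-facility claims for transfer admissions (SNF / hospital /
    # hospice stay ending the day the receiving hospital admits)
    t = np.nonzero(is_transfer)[0]
    if len(t):
        st = source_type[t].astype(str)
        n_src = np.where(
            st == "snf",
            scenario.n_snfs,
            np.where(st == "hospital", scenario.n_hospitals, scenario.n_hospices),
        )
        src_idx = (us[t, 8] * (n_src - (st == "hospital"))).astype(int)
        # a hospital source must differ from the receiving hospital
        same = (st == "hospital") & (src_idx >= recv_fac[t])
        src_idx = src_idx + same.astype(int)
        prefix = np.where(st == "snf", "S", np.where(st == "hospital", "H", "X"))
        src_fac = np.array(
            [f"{p}{i + 1:03d}" for p, i in zip(prefix, src_idx)], dtype=object
        )
        gap = 3 + (us[t, 5] * 25).astype(int)
        src_admit = s_date[t] - gap.astype("timedelta64[D]")
        src = pd.DataFrame(
            {
                "claim_id": np.char.add(
                    "T", claim_id[t].astype(str)
                ).astype(object),
                "bene_id": hosp["bene_id"].to_numpy(dtype=object)[t],
                "facility_id": src_fac,
                "facility_type": np.where(st == "snf", "snf",
                                          np.where(st == "hospital", "hospital",
                                                   "hospice")).astype(object),
                "admit_date": pd.to_datetime(src_admit),
                "discharge_date": pd.to_datetime(s_date[t]),
                "drg_code": "",
                "admission_source": "routine",
                "through_ed": False,
                "discharge_disposition": "transfer_hospital",
            }
        )
        # hospital source claims need a DRG code to satisfy the schema
        src_hosp = src["facility_type"] == "hospital"
        src.loc[src_hosp, "drg_code"] = drg_code[t][src_hosp.to_numpy()]
        inpatient = pd.concat([hosp, src], ignore_index=True)
    else:
        inpatient = hosp

    visit_id = np.array(
        [f"V{b:07d}W{w:03d}" for b, w in zip(row, week)], dtype=object
    )
    linked = np.full(n_visits, "", dtype=object)
    linked[admitted] = claim_id
    ed_visits = pd.DataFrame(
        {
            "visit_id": visit_id,
            "bene_id": beneficiaries["bene_id"].to_numpy(dtype=object)[row],
            "visit_date": pd.to_datetime(visit_date),
            "disposition": np.where(admitted, "admitted", "discharged").astype(object),
            "linked_claim_id": linked,
        }
    )
    return inpatient, ed_visits


def generate_bundle(scenario: Scenario) -> Bundle:
    """Generate the full five-table population for a scenario."""
    beneficiaries = generate_population(scenario)
    weights = scenario.drg_weight_table()
    inpatient, ed_visits = generate_claims(beneficiaries, scenario, weights)
    county_chi = scenario.county_frame()[["county_id", "chi_score", "quartile"]]
    return Bundle(
        beneficiaries=beneficiaries,
        inpatient=inpatient,
        ed_visits=ed_visits,
        drg_weights=weights,
        county_chi=county_chi.reset_index(drop=True),
    )
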