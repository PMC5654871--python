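"""Core claim-table schemas, validation, and delimited-text I/O.

The package works on five plain-text tables that mimic (in deliberately
simplified form) the structure of CMS fee-for-service claims extracts:

``beneficiaries.csv``
    one row per beneficiary: demographics, state, county, a 24-month
    enrollment string covering Jan 2011 - Dec 2012, and a fee-for-service
    flag.
``inpatient.csv``
    one row per facility stay (hospital, skilled nursing facility, or
    hospice): admission/discharge dates, DRG code, admission source,
    through-ED flag, and discharge disposition.
``ed_visits.csv``
    one row per emergency department encounter with its disposition
    (discharged vs admitted) and, for admissions, the resulting inpatient
    claim id.
``drg_weights.csv``
    diagnosis-related-group service-intensity weights, each in
    [0.1, 30.0].
``county_chi.csv``
    county-level Community Hardship Index scores (1-100) with their
    impact quartile.

All dates are inclusive calendar dates in ISO-8601 form; there are no
timestamps anywhere.  Interval membership ``d in [a, b]`` always means
``a <= d <= b``.  The schema is documented column-by-column in
``docs/data_dictionary.md``; it is not a bit-faithful CMS RIF layout.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd


class ClaimsError(Exception):
    """Base class for errors raised by this package's table handling."""


class SchemaError(ClaimsError):
    """A file's header does not match the documented schema."""


class ValidationError(ClaimsError):
    """A record violates a type invariant."""


# ---------------------------------------------------------------------------
# Categorical vocabularies
# ---------------------------------------------------------------------------

SEXES = ("F", "M")
FACILITY_TYPES = ("hospital", "snf", "hospice")
ADMISSION_SOURCES = (
    "routine",
    "transfer_hospital",
    "transfer_snf",
    "transfer_hospice",
    "unknown",
)
TRANSFER_SOURCES = ("transfer_hospital", "transfer_snf", "transfer_hospice")
DISCHARGE_DISPOSITIONS = (
    "home",
    "home_health",
    "snf",
    "hospice",
    "transfer_hospital",
    "expired",
    "other",
)
ED_DISPOSITIONS = ("discharged", "admitted")
QUARTILES = ("Q1", "Q2", "Q3", "Q4")

#: Upper CHI score edge of Q1, Q2 and Q3.  Scores at an edge fall in the
#: lower quartile (gap closure downward at 39) and anything above the last
#: edge is Q4 (gap closure upward at 59); see :func:`assign_quartile`.
DEFAULT_QUARTILE_EDGES = (39.0, 47.0, 58.0)

CHI_SCORE_RANGE = (1.0, 100.0)
DRG_WEIGHT_RANGE = (0.1, 30.0)
N_ENROLLMENT_MONTHS = 24


def assign_quartile(chi_score: float, edges=DEFAULT_QUARTILE_EDGES) -> str:
    """Map a Community Hardship Index score to its impact quartile.

    The published bins are Q1 < 39, Q2 40-47, Q3 48-58, Q4 > 59, which
    leave integer scores 39 and 59 unassigned; 39 closes downward into Q1
    and 59 upward into Q4.  Non-integer scores are binned by the same
    inequalities (Q1: s <= 39; Q2: 39 < s <= 47; Q3: 47 < s <= 58;
    Q4: s > 58).
    """
    lo, hi = CHI_SCORE_RANGE
    if not (lo <= chi_score <= hi):
        raise ValueError(
            f"chi_score must be in [{lo:g}, {hi:g}], got {chi_score!r}"
        )
    idx = int(np.searchsorted(np.asarray(edges), chi_score, side="left"))
    return QUARTILES[idx]


def assign_quartiles(chi_scores, edges=DEFAULT_QUARTILE_EDGES) -> np.ndarray:
    """Vectorised :func:`assign_quartile` for an array of scores."""
    scores = np.asarray(chi_scores, dtype=float)
    lo, hi = CHI_SCORE_RANGE
    if scores.size and ((scores < lo) | (scores > hi)).any():
        bad = scores[(scores < lo) | (scores > hi)][0]
        raise ValueError(f"chi_score must be in [{lo:g}, {hi:g}], got {bad!r}")
    idx = np.searchsorted(np.asarray(edges), scores, side="left")
    return np.asarray(QUARTILES, dtype=object)[idx]


# ---------------------------------------------------------------------------
# Study windows
# ---------------------------------------------------------------------------

DateInterval = tuple[dt.date, dt.date]


def _interval(a: str, b: str) -> DateInterval:
    return (dt.date.fromisoformat(a), dt.date.fromisoformat(b))


@dataclasses.dataclass(frozen=True)
class StudyWindows:
    """The four one-week analysis windows around landfall.

    Each interval is an inclusive 7-day span.  The defaults are the study
    weeks: the week before landfall and the week after, in the storm year
    and aligned by weekday in the prior year.
    """

    pre_2012: DateInterval = _interval("2012-10-22", "2012-10-28")
    post_2012: DateInterval = _interval("2012-10-29", "2012-11-04")
    pre_2011: DateInterval = _interval("2011-10-24", "2011-10-30")
    post_2011: DateInterval = _interval("2011-10-31", "2011-11-06")

    def __post_init__(self) -> None:
        for name in ("pre_2012", "post_2012", "pre_2011", "post_2011"):
            start, end = getattr(self, name)
            if (end - start).days != 6:
                raise ValidationError(
                    f"window {name} must span exactly 7 calendar days "
                    f"inclusive, got {start}..{end}"
                )

    def by_cell(self) -> dict[tuple[str, str], DateInterval]:
        """Map (year, period) cells to intervals.

        ``year`` is ``"study"`` (storm year) or ``"prior"``; ``period`` is
        ``"pre"`` or ``"post"``.
        """
        return {
            ("study", "pre"): self.pre_2012,
            ("study", "post"): self.post_2012,
            ("prior", "pre"): self.pre_2011,
            ("prior", "post"): self.post_2011,
        }


def in_interval(dates: pd.Series, interval: DateInterval) -> pd.Series:
    """Inclusive membership of a datetime series in a date interval."""
    start, end = (pd.Timestamp(interval[0]), pd.Timestamp(interval[1]))
    return (dates >= start) & (dates <= end)


# ---------------------------------------------------------------------------
# Table schemas
# ---------------------------------------------------------------------------

TABLE_COLUMNS: dict[str, tuple[str, ...]] = {
    "beneficiaries": (
        "bene_id",
        "birth_year",
        "sex",
        "race",
        "state",
        "county_id",
        "ffs_flag",
        "enrolled_months",
    ),
    "inpatient": (
        "claim_id",
        "bene_id",
        "facility_id",
        "facility_type",
        "admit_date",
        "discharge_date",
        "drg_code",
        "admission_source",
        "through_ed",
        "discharge_disposition",
    ),
    "ed_visits": (
        "visit_id",
        "bene_id",
        "visit_date",
        "disposition",
        "linked_claim_id",
    ),
    "drg_weights": ("drg_code", "weight"),
    "county_chi": ("county_id", "chi_score", "quartile"),
}

TABLE_FILENAMES = {name: f"{name}.csv" for name in TABLE_COLUMNS}

_PRIMARY_KEYS = {
    "beneficiaries": "bene_id",
    "inpatient": "claim_id",
    "ed_visits": "visit_id",
    "drg_weights": "drg_code",
    "county_chi": "county_id",
}

_INT_COLUMNS = {"birth_year"}
_FLOAT_COLUMNS = {"weight", "chi_score"}
_BOOL_COLUMNS = {"ffs_flag", "through_ed"}
_DATE_COLUMNS = {"admit_date", "discharge_date", "visit_date"}
_OPTIONAL_COLUMNS = {"linked_claim_id", "drg_code"}


@dataclasses.dataclass
class Bundle:
    """An in-memory population: the five claim/reference tables."""

    beneficiaries: pd.DataFrame
    inpatient: pd.DataFrame
    ed_visits: pd.DataFrame
    drg_weights: pd.DataFrame
    county_chi: pd.DataFrame

    def tables(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in TABLE_COLUMNS}

    def copy(self) -> "Bundle":
        return Bundle(**{k: v.copy() for k, v in self.tables().items()})


def empty_bundle() -> Bundle:
    """A bundle with all five tables present but empty."""
    return Bundle(
        **{
            name: pd.DataFrame({c: pd.Series(dtype=object) for c in cols})
            for name, cols in TABLE_COLUMNS.items()
        }
    )


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------


def _parse_dates(raw: pd.Series, table: str, column: str) -> pd.Series:
    parsed = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() & (raw != "")
    if bad.any():
        row = int(bad.idxmax())
        raise ValidationError(
            f"{table}: unparseable date {raw[row]!r} in column {column!r} "
            f"at line {row + 2} (ISO-8601 YYYY-MM-DD required)"
        )
    return parsed


def _coerce(table: str, df: pd.DataFrame) -> pd.DataFrame:
    out = {}
    for col in TABLE_COLUMNS[table]:
        raw = df[col].astype(str) if len(df) else df[col]
        if col in _DATE_COLUMNS:
            out[col] = _parse_dates(raw, table, col)
        elif col in _INT_COLUMNS:
            out[col] = pd.to_numeric(raw, errors="raise").astype(np.int64)
        elif col in _FLOAT_COLUMNS:
            out[col] = pd.to_numeric(raw, errors="raise").astype(float)
        elif col in _BOOL_COLUMNS:
            vals = raw.isin(("1", "True", "true"))
            out[col] = vals.astype(bool)
        else:
            out[col] = raw.astype(object)
    return pd.DataFrame(out, columns=list(TABLE_COLUMNS[table]))


def read_table(path: str | Path, table: str) -> pd.DataFrame:
    """Read one typed table from a CSV file.

    Raises :class:`SchemaError` naming any missing column, and
    :class:`ValidationError` with a line number for unparseable dates.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{table}: file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in TABLE_COLUMNS[table] if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{table}: missing column(s) {missing} in {path} "
            f"(found {list(df.columns)})"
        )
    return _coerce(table, df)


def read_tables(paths: str | Path | Mapping[str, str | Path]) -> Bundle:
    """Read a full population bundle.

    ``paths`` is either a directory containing the five standard file
    names, or a mapping from table name to file path.
    """
    if isinstance(paths, (str, Path)):
        directory = Path(paths)
        paths = {
            name: directory / fname for name, fname in TABLE_FILENAMES.items()
        }
    tables = {name: read_table(paths[name], name) for name in TABLE_COLUMNS}
    return Bundle(**tables)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_bundle(bundle: Bundle) -> list[str]:
    """Check every type invariant; return a list of problem descriptions."""
    problems: list[str] = []
    ben, inp, ed = bundle.beneficiaries, bundle.inpatient, bundle.ed_visits
    wts, chi = bundle.drg_weights, bundle.county_chi

    for name, df in bundle.tables().items():
        key = _PRIMARY_KEYS[name]
        if len(df) and df[key].duplicated().any():
            dup = df.loc[df[key].duplicated(), key].iloc[0]
            problems.append(f"{name}: duplicate {key} {dup!r}")

    if len(ben):
        months = ben["enrolled_months"].astype(str)
        bad_len = months.str.len() != N_ENROLLMENT_MONTHS
        if bad_len.any():
            problems.append(
                f"beneficiaries: enrolled_months must have exactly "
                f"{N_ENROLLMENT_MONTHS} flags "
                f"(bene_id {ben.loc[bad_len, 'bene_id'].iloc[0]!r})"
            )
        bad_chr = ~months.str.fullmatch(r"[01]*").fillna(False)
        if bad_chr.any():
            problems.append(
                "beneficiaries: enrolled_months flags must be '0'/'1'"
            )
        bad_sex = ~ben["sex"].isin(SEXES)
        if bad_sex.any():
            problems.append(
                f"beneficiaries: unknown sex "
                f"{ben.loc[bad_sex, 'sex'].iloc[0]!r}"
            )

    if len(inp):
        bad = inp["admit_date"] > inp["discharge_date"]
        if bad.any():
            row = inp[bad].iloc[0]
            problems.append(
                f"inpatient: admit_date after discharge_date for claim "
                f"{row['claim_id']!r} ({row['admit_date'].date()} > "
                f"{row['discharge_date'].date()})"
            )
        hosp = inp["facility_type"] == "hospital"
        no_drg = hosp & (inp["drg_code"].astype(str) == "")
        if no_drg.any():
            problems.append(
                f"inpatient: drg_code missing for hospital claim "
                f"{inp.loc[no_drg, 'claim_id'].iloc[0]!r}"
            )
        bad_ft = ~inp["facility_type"].isin(FACILITY_TYPES)
        if bad_ft.any():
            problems.append(
                f"inpatient: unknown facility_type "
                f"{inp.loc[bad_ft, 'facility_type'].iloc[0]!r}"
            )
        bad_src = ~inp["admission_source"].isin(ADMISSION_SOURCES)
        if bad_src.any():
            problems.append(
                f"inpatient: unknown admission_source "
                f"{inp.loc[bad_src, 'admission_source'].iloc[0]!r}"
            )
        bad_dd = ~inp["discharge_disposition"].isin(DISCHARGE_DISPOSITIONS)
        if bad_dd.any():
            problems.append(
                f"inpatient: unknown discharge_disposition "
                f"{inp.loc[bad_dd, 'discharge_disposition'].iloc[0]!r}"
            )

    if len(ed):
        linked = ed["linked_claim_id"].astype(str) != ""
        admitted = ed["disposition"] == "admitted"
        bad = linked != admitted
        if bad.any():
            problems.append(
                f"ed_visits: disposition=admitted iff linked_claim_id "
                f"present violated (visit "
                f"{ed.loc[bad, 'visit_id'].iloc[0]!r})"
            )
        bad_disp = ~ed["disposition"].isin(ED_DISPOSITIONS)
        if bad_disp.any():
            problems.append(
                f"ed_visits: unknown disposition "
                f"{ed.loc[bad_disp, 'disposition'].iloc[0]!r}"
            )

    if len(wts):
        lo, hi = DRG_WEIGHT_RANGE
        bad = (wts["weight"] < lo) | (wts["weight"] > hi)
        if bad.any():
            problems.append(
                f"drg_weights: weight outside [{lo}, {hi}] for code "
                f"{wts.loc[bad, 'drg_code'].iloc[0]!r}"
            )

    if len(chi):
        expected = assign_quartiles(chi["chi_score"].to_numpy())
        bad = chi["quartile"].to_numpy(dtype=object) != expected
        if bad.any():
            problems.append(
                f"county_chi: quartile inconsistent with chi_score for "
                f"county {chi.loc[bad, 'county_id'].iloc[0]!r}"
            )

    return problems


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------


def write_tables(
    bundle: Bundle, directory: str | Path, validate: bool = True
) -> dict[str, Path]:
    """Write the five tables as CSV with deterministic row/column order.

    Rows are sorted by primary id, dates are ISO-8601, booleans are 0/1.
    Refuses to write (raising :class:`ValidationError`) if any invariant
    fails, unless ``validate=False``.
    """
    if validate:
        problems = validate_bundle(bundle)
        if problems:
            raise ValidationError(
                "refusing to write invalid bundle:\n- " + "\n- ".join(problems)
            )
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, df in bundle.tables().items():
        out = df.copy()
        cols = list(TABLE_COLUMNS[name])
        out = out[cols] if len(out) else pd.DataFrame(columns=cols)
        if len(out):
            out = out.sort_values(_PRIMARY_KEYS[name], kind="mergesort")
        for col in cols:
            if col in _DATE_COLUMNS and len(out):
                out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
            elif col in _BOOL_COLUMNS and len(out):
                out[col] = out[col].astype(bool).astype(int)
        path = directory / TABLE_FILENAMES[name]
        out.to_csv(path, index=False, lineterminator="\n")
        written[name] = path
    return written


def bundles_equal(a: Bundle, b: Bundle) -> bool:
    """True when two bundles hold identical records (row order ignored)."""
    for name in TABLE_COLUMNS:
        key = _PRIMARY_KEYS[name]
        ta = getattr(a, name)
        tb = getattr(b, name)
        if len(ta) != len(tb):
            return False
        if not len(ta):
            continue
        ta = ta.sort_values(key, kind="mergesort").reset_index(drop=True)
        tb = tb.sort_values(key, kind="mergesort").reset_index(drop=True)
        try:
            pd.testing.assert_frame_equal(
                ta[list(TABLE_COLUMNS[name])],
                tb[list(TABLE_COLUMNS[name])],
                check_dtype=False,
            )
        except AssertionError:
            return False
    return True
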