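"""Panel building, DD/DDD estimators, matching, and quartile arithmetic."""

import numpy as np
import pandas as pd
import pytest

from stormsurge.claims_model import StudyWindows
from stormsurge.surge_estimation import (
    DesignError,
    build_panel,
    counterfactual_post_mean,
    dd_estimate,
    ddd_mcs,
    disposition_split,
    extrapolate,
    match_beneficiaries,
    member_dd,
    stratify_by_quartile,
    triple_difference_regression,
)


# ---------------------------------------------------------------------------
# Arithmetic operations
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "count,fraction,expected",
    [(100, 1.0, 100), (100, 0.2, 500), (312, 0.2, 1560), (0, 0.5, 0)],
)
def test_extrapolate(count, fraction, expected):
    assert extrapolate(count, fraction) == expected


def test_extrapolate_rejects_bad_fraction():
    with pytest.raises(ValueError):
        extrapolate(100, 0.0)
    with pytest.raises(ValueError):
        extrapolate(100, 1.5)


@pytest.mark.parametrize(
    "discharged,admitted,expected",
    [(249, 63, (80, 20)), (50, 50, (50, 50)), (1, 0, (100, 0))],
)
def test_disposition_split(discharged, admitted, expected):
    assert disposition_split(discharged, admitted) == expected


def test_disposition_split_undefined_when_empty():
    with pytest.raises(ValueError):
        disposition_split(0, 0)


# ---------------------------------------------------------------------------
# Panel construction
# ---------------------------------------------------------------------------


def _beneficiaries(n, county="ocean"):
    return pd.DataFrame(
        {
            "bene_id": [f"B{i:04d}" for i in range(n)],
            "birth_year": 1940,
            "sex": ["F", "M"] * (n // 2) + ["F"] * (n % 2),
            "race": "white",
            "state": "NJ",
            "county_id": county,
            "ffs_flag": True,
            "enrolled_months": "1" * 24,
        }
    )


def _visit(vid, bene, date, admitted=False):
    return {
        "visit_id": vid,
        "bene_id": bene,
        "visit_date": pd.Timestamp(date),
        "disposition": "admitted" if admitted else "discharged",
        "linked_claim_id": "C" if admitted else "",
    }


_COUNTY = pd.DataFrame(
    {"county_id": ["ocean"], "chi_score": [80.0], "quartile": ["Q4"]}
)


class TestBuildPanel:
    def test_member_without_visits_gets_four_zero_rows(self):
        benes = _beneficiaries(2)
        visits = pd.DataFrame([_visit("V1", "B0001", "2012-06-01")])
        panel = build_panel(benes["bene_id"], benes, visits, _COUNTY)
        assert len(panel) == 8
        b0 = panel[panel["bene_id"] == "B0000"]
        assert (b0["ed_visits"] == 0).all()
        assert panel.attrs["visits_outside_windows"] == 1

    def test_single_post_storm_admission(self):
        benes = _beneficiaries(1)
        visits = pd.DataFrame(
            [_visit("V1", "B0000", "2012-10-30", admitted=True)]
        )
        panel = build_panel(benes["bene_id"], benes, visits, _COUNTY)
        row = panel[(panel["year"] == "study") & (panel["period"] == "post")]
        assert int(row["ed_visits"].iloc[0]) == 1
        assert int(row["ed_admissions"].iloc[0]) == 1
        assert int(row["ed_discharges"].iloc[0]) == 0
        assert row["quartile"].iloc[0] == "Q4"
        assert int(row["age"].iloc[0]) == 72
        prior = panel[panel["year"] == "prior"]
        assert (prior["age"] == 71).all()

    def test_margins_match_brute_force_recount(self, windows):
        rng = np.random.default_rng(21)
        benes = _beneficiaries(300)
        dates = pd.date_range("2011-10-01", "2012-11-20", freq="D")
        rows = [
            _visit(
                f"V{i:05d}",
                f"B{int(rng.integers(0, 300)):04d}",
                dates[int(rng.integers(0, len(dates)))],
                admitted=bool(rng.integers(0, 2)),
            )
            for i in range(1_000)
        ]
        visits = pd.DataFrame(rows)
        panel = build_panel(benes["bene_id"], benes, visits, _COUNTY, windows)
        assert len(panel) == 4 * 300
        # brute-force recount per cell
        for (year, period), (start, end) in windows.by_cell().items():
            lo, hi = pd.Timestamp(start), pd.Timestamp(end)
            sub = visits[(visits["visit_date"] >= lo) & (visits["visit_date"] <= hi)]
            cell = panel[(panel["year"] == year) & (panel["period"] == period)]
            assert cell["ed_visits"].sum() == len(sub)
            assert cell["ed_admissions"].sum() == (
                sub["disposition"] == "admitted"
            ).sum()
        assert (
            panel["ed_visits"] == panel["ed_discharges"] + panel["ed_admissions"]
        ).all()


# ---------------------------------------------------------------------------
# DD estimation
# ---------------------------------------------------------------------------


def _panel_from_cells(n, cells, ages=None):
    """Build a panel where cell (year, period) means are as given."""
    rng = np.random.default_rng(0)
    rows = []
    for i in range(n):
        for (year, period), mean in cells.items():
            rows.append(
                {
                    "bene_id": f"B{i:04d}",
                    "year": year,
                    "period": period,
                    "ed_visits": int(rng.random() < mean),
                    "ed_discharges": 0,
                    "ed_admissions": 0,
                    "age": 70 + (i % 20),
                    "sex": "F" if i % 2 else "M",
                    "race": "white",
                    "quartile": "Q4",
                }
            )
    df = pd.DataFrame(rows)
    df["ed_discharges"] = df["ed_visits"]
    return df


class TestDdEstimate:
    def test_mirrored_years_give_zero_interaction(self):
        cells = {
            ("study", "pre"): 0.2, ("study", "post"): 0.2,
            ("prior", "pre"): 0.2, ("prior", "post"): 0.2,
        }
        panel = _panel_from_cells(400, cells)
        # force exact mirroring: copy prior-year outcomes into study year
        wide = panel.pivot_table(
            index="bene_id", columns=["year", "period"], values="ed_visits"
        )
        prior = panel[panel["year"] == "prior"].copy()
        study = prior.copy()
        study["year"] = "study"
        mirrored = pd.concat([prior, study], ignore_index=True)
        res = dd_estimate(mirrored, adjust=False)
        assert res.effect.estimate == pytest.approx(0.0, abs=1e-12)

    def test_unadjusted_interaction_equals_cell_mean_contrast(self):
        cells = {
            ("study", "pre"): 0.10, ("study", "post"): 0.18,
            ("prior", "pre"): 0.11, ("prior", "post"): 0.12,
        }
        panel = _panel_from_cells(500, cells)
        res = dd_estimate(panel, adjust=False)
        m = panel.groupby(["year", "period"])["ed_visits"].mean()
        contrast = (
            m[("study", "post")] - m[("study", "pre")]
            - m[("prior", "post")] + m[("prior", "pre")]
        )
        assert res.effect.estimate == pytest.approx(contrast, rel=1e-9)
        cf = counterfactual_post_mean(panel)
        assert res.percent_surge == pytest.approx(
            100 * contrast / cf, rel=1e-9
        )

    def test_missing_cell_raises_design_error(self):
        cells = {
            ("study", "pre"): 0.1, ("study", "post"): 0.1,
            ("prior", "pre"): 0.1, ("prior", "post"): 0.1,
        }
        panel = _panel_from_cells(50, cells)
        broken = panel[~((panel["year"] == "prior") & (panel["period"] == "pre"))]
        with pytest.raises(DesignError, match="prior"):
            dd_estimate(broken)

    def test_member_dd_mean_equals_interaction(self):
        cells = {
            ("study", "pre"): 0.1, ("study", "post"): 0.2,
            ("prior", "pre"): 0.1, ("prior", "post"): 0.12,
        }
        panel = _panel_from_cells(400, cells)
        res = dd_estimate(panel, adjust=False)
        assert member_dd(panel)["dd"].mean() == pytest.approx(
            res.effect.estimate, rel=1e-9
        )


# ---------------------------------------------------------------------------
# Matching and the Monte Carlo triple difference
# ---------------------------------------------------------------------------


def _demo(n, seed=0, age_lo=65, age_hi=90):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "bene_id": [f"P{i:05d}" for i in range(n)],
            "age": rng.integers(age_lo, age_hi, n),
            "sex": rng.choice(["F", "M"], n),
            "race": rng.choice(["white", "black"], n),
        }
    )


class TestMatching:
    def test_pool_copy_preserves_cell_counts(self):
        nj = _demo(500, seed=1)
        idx = match_beneficiaries(nj, nj, rng=4)
        matched = nj.iloc[idx]

        def cells(df):
            return (
                df.assign(band=(df["age"] // 5) * 5)
                .groupby(["band", "sex", "race"])
                .size()
                .sort_index()
            )

        pd.testing.assert_series_equal(cells(nj), cells(matched))

    def test_single_member_cell_reused_with_replacement(self):
        nj = pd.DataFrame(
            {
                "bene_id": ["A", "B", "C"],
                "age": [70, 71, 72],
                "sex": ["F", "F", "F"],
                "race": ["white"] * 3,
            }
        )
        pool = pd.DataFrame(
            {"bene_id": ["P"], "age": [73], "sex": ["F"], "race": ["white"]}
        )
        idx = match_beneficiaries(nj, pool, rng=0)
        assert list(idx) == [0, 0, 0]

    def test_widens_bands_when_cell_empty(self):
        nj = pd.DataFrame(
            {"bene_id": ["A"], "age": [65], "sex": ["F"], "race": ["white"]}
        )
        pool = pd.DataFrame(
            {"bene_id": ["P"], "age": [69], "sex": ["F"], "race": ["white"]}
        )
        # 65 vs 69 share the 5-year band [65, 70) -> direct match
        assert list(match_beneficiaries(nj, pool, rng=0)) == [0]
        pool2 = pd.DataFrame(
            {"bene_id": ["P"], "age": [62], "sex": ["F"], "race": ["white"]}
        )
        # 62 is in [60, 65): only the widened 10-year band [60, 70) matches
        assert list(match_beneficiaries(nj, pool2, rng=0)) == [0]

    def test_unmatchable_cell_raises(self):
        nj = pd.DataFrame(
            {"bene_id": ["A"], "age": [65], "sex": ["F"], "race": ["white"]}
        )
        pool = pd.DataFrame(
            {"bene_id": ["P"], "age": [85], "sex": ["M"], "race": ["black"]}
        )
        with pytest.raises(ValueError, match="no comparison-pool member"):
            match_beneficiaries(nj, pool, rng=0)


class TestDddMcs:
    def _panels(self, n=400, comp_shift=0.0, seed=0):
        cells_nj = {
            ("study", "pre"): 0.10, ("study", "post"): 0.16,
            ("prior", "pre"): 0.10, ("prior", "post"): 0.10,
        }
        cells_comp = {
            k: v + comp_shift if k == ("study", "post") else v
            for k, v in cells_nj.items()
        }
        cells_comp[("study", "post")] = 0.10 + comp_shift
        nj = _panel_from_cells(n, cells_nj)
        comp = _panel_from_cells(n, cells_comp)
        comp["bene_id"] = "P" + comp["bene_id"].str.slice(1)
        return nj, comp

    def test_single_iteration_has_no_ci(self):
        nj, comp = self._panels(100)
        res = ddd_mcs(nj, comp, iterations=1, seed=3)
        assert res.iterations == 1
        assert len(res.estimates) == 1
        assert res.ci_low is None and res.ci_high is None

    def test_deterministic_under_seed(self):
        nj, comp = self._panels(150)
        a = ddd_mcs(nj, comp, iterations=20, seed=5)
        b = ddd_mcs(nj, comp, iterations=20, seed=5)
        assert np.array_equal(a.estimates, b.estimates)

    def test_triple_regression_equals_difference_of_dds(self):
        nj, comp = self._panels(200, comp_shift=0.05)
        reg = triple_difference_regression(nj, comp, adjust=False)
        expected = member_dd(nj)["dd"].mean() - member_dd(comp)["dd"].mean()
        assert reg.estimate == pytest.approx(expected, rel=1e-9)

    def test_identical_pool_keeps_ddd_near_dd(self):
        nj, comp = self._panels(600)
        dd = dd_estimate(nj, adjust=False)
        res = ddd_mcs(nj, comp, iterations=200, seed=9)
        assert abs(res.point - dd.effect.estimate) < 3 * max(res.sd(), 1e-9)


# ---------------------------------------------------------------------------
# Quartile stratification
# ---------------------------------------------------------------------------


class TestStratify:
    def test_single_quartile_equals_statewide(self):
        cells = {
            ("study", "pre"): 0.10, ("study", "post"): 0.15,
            ("prior", "pre"): 0.10, ("prior", "post"): 0.10,
        }
        panel = _panel_from_cells(300, cells)  # every row quartile Q4
        table = stratify_by_quartile(panel, outcomes=("ed_visits",))
        state = table[(table["stratum"] == "statewide")].iloc[0]
        q4 = table[(table["stratum"] == "Q4")].iloc[0]
        assert q4["percent_surge"] == pytest.approx(state["percent_surge"])

    def test_empty_quartile_flagged_absent(self):
        cells = {
            ("study", "pre"): 0.1, ("study", "post"): 0.1,
            ("prior", "pre"): 0.1, ("prior", "post"): 0.1,
        }
        panel = _panel_from_cells(100, cells)
        table = stratify_by_quartile(panel, outcomes=("ed_visits",))
        q1 = table[table["stratum"] == "Q1"].iloc[0]
        assert q1["status"] == "absent"
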