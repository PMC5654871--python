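"""Pre-storm estimators against closed-form oracles and planted effects."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from stormsurge.prestorm_stats import (
    InsufficientDataError,
    adjusted_discharge_model,
    alos_shift,
    compare_cmi,
    compare_proportions,
    relative_change,
)


class TestRelativeChange:
    @pytest.mark.parametrize(
        "baseline,comparison,expected",
        [
            (51.8, 55.5, 7.1),   # statewide discharge proportions
            (9.0, 12.5, 38.9),   # SNF-transfer share of ED admissions
            (50.4, 55.8, 10.7),  # discharges in the two hardest-hit quartiles
        ],
    )
    def test_published_worked_examples(self, baseline, comparison, expected):
        assert relative_change(baseline, comparison) == expected

    @given(st.floats(min_value=0.1, max_value=99.9))
    def test_identity_is_zero(self, x):
        assert relative_change(x, x) == 0.0

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            relative_change(0.0, 5.0)


class TestCompareProportions:
    def test_identical_proportions_null(self):
        est, rel = compare_proportions(50, 100, 500, 1000)
        assert est.estimate == pytest.approx(0.0)
        assert est.p_value == pytest.approx(1.0)
        assert rel == 0.0

    def test_statistic_matches_hand_computed_chi_square(self):
        # 2x2 table (10/100 vs 20/100): chi2 = sum (O-E)^2/E without
        # continuity correction, computed independently here
        observed = np.array([[10, 90], [20, 80]])
        total = observed.sum()
        expected = np.outer(observed.sum(1), observed.sum(0)) / total
        chi2 = ((observed - expected) ** 2 / expected).sum()
        p_oracle = stats.chi2.sf(chi2, df=1)
        est, rel = compare_proportions(10, 100, 20, 100)
        assert est.p_value == pytest.approx(p_oracle, rel=1e-10)
        assert rel == 100.0

    def test_degenerate_table_flagged(self):
        est, _ = compare_proportions(0, 50, 0, 60)
        assert est.status == "degenerate"
        assert est.p_value is None

    def test_p_uniform_under_null(self):
        """Across seeded replicates of a true null, p-values are uniform."""
        rng = np.random.default_rng(123)
        pvals = []
        for _ in range(200):
            a = int(rng.binomial(400, 0.3))
            b = int(rng.binomial(400, 0.3))
            est, _ = compare_proportions(a, 400, b, 400)
            pvals.append(est.p_value)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_input_validation(self):
        with pytest.raises(ValueError):
            compare_proportions(5, 0, 1, 10)
        with pytest.raises(ValueError):
            compare_proportions(11, 10, 1, 10)


def _logistic_rows(rng, n, odds_ratio):
    study = rng.integers(0, 2, n)
    age = rng.integers(65, 95, n)
    sex = np.where(rng.random(n) < 0.5, "F", "M")
    race = rng.choice(["white", "black", "other"], n, p=[0.7, 0.2, 0.1])
    logit = -0.2 + math.log(odds_ratio) * study + 0.01 * (age - 75)
    p = 1 / (1 + np.exp(-logit))
    return pd.DataFrame(
        {
            "outcome": rng.random(n) < p,
            "study_week": study,
            "age": age,
            "sex": sex,
            "race": race,
        }
    )


class TestAdjustedDischargeModel:
    def test_recovers_planted_odds_ratio(self):
        rng = np.random.default_rng(11)
        rows = _logistic_rows(rng, 20_000, odds_ratio=1.5)
        est = adjusted_discharge_model(rows)
        assert est.status == "ok"
        se_log = est.se
        assert abs(math.log(est.estimate) - math.log(1.5)) < 3 * se_log

    def test_null_coverage(self):
        """CI covers OR=1 in at least 93 of 100 seeded replicates."""
        rng = np.random.default_rng(29)
        covered = 0
        for _ in range(100):
            rows = _logistic_rows(rng, 1_500, odds_ratio=1.0)
            est = adjusted_discharge_model(rows)
            if est.status == "ok" and est.ci_low <= 1.0 <= est.ci_high:
                covered += 1
        assert covered >= 93

    def test_degenerate_outcome_flagged(self):
        rows = _logistic_rows(np.random.default_rng(0), 100, 1.0)
        rows["outcome"] = True
        est = adjusted_discharge_model(rows)
        assert est.status == "non_convergence"
        assert est.estimate is None


class TestCompareCmi:
    def test_identical_lists_null(self):
        est = compare_cmi([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert est.estimate == 0.0
        assert est.p_value == pytest.approx(1.0)

    def test_matches_textbook_welch_formula(self):
        a, b = [1.0, 2.0, 3.0], [1.0, 2.0, 3.0, 4.0, 5.0]
        est = compare_cmi(a, b)
        # independent Welch computation
        ma, mb = np.mean(a), np.mean(b)
        va, vb = np.var(a, ddof=1) / len(a), np.var(b, ddof=1) / len(b)
        t = (mb - ma) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        p = 2 * stats.t.sf(abs(t), df)
        assert est.estimate == pytest.approx(mb - ma)
        assert est.p_value == pytest.approx(p, rel=1e-10)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            compare_cmi([1.0], [1.0, 2.0])

    def test_detects_planted_severity_shift(self):
        rng = np.random.default_rng(13)
        prior = np.exp(rng.normal(0.2, 0.5, 400))
        study = np.exp(rng.normal(0.2 + math.log(1.4), 0.5, 400))
        est = compare_cmi(prior, study)
        assert est.estimate > 0
        assert est.p_value < 0.001


class TestAlosShift:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["claim_id", "bene_id", "drg_code",
                                           "los", "label"])

    def test_identical_groups_zero_effect(self):
        rows = []
        for i, (code, los) in enumerate([("A", 3), ("A", 5), ("B", 7), ("B", 9)]):
            rows.append((f"T{i}", f"B{i}", code, los, "target"))
            rows.append((f"R{i}", f"B{i}", code, los, "reference"))
        est = alos_shift(self._frame(rows))
        assert est.estimate == pytest.approx(0.0, abs=1e-10)

    def test_two_stratum_closed_form(self):
        # balanced two-stratum design: the stratified OLS coefficient is
        # the mean of the within-stratum target-minus-reference differences
        rows = [
            ("T1", "B1", "A", 4.0, "target"), ("T2", "B2", "A", 6.0, "target"),
            ("R1", "B3", "A", 3.0, "reference"), ("R2", "B4", "A", 5.0, "reference"),
            ("T3", "B5", "B", 10.0, "target"), ("T4", "B6", "B", 12.0, "target"),
            ("R5", "B7", "B", 7.0, "reference"), ("R6", "B8", "B", 9.0, "reference"),
        ]
        est = alos_shift(self._frame(rows))
        within = [(5.0 - 4.0), (11.0 - 8.0)]  # per-stratum mean differences
        assert est.estimate == pytest.approx(np.mean(within))

    def test_single_stratum_falls_back(self):
        rows = [
            ("T1", "B1", "A", 4.0, "target"),
            ("T2", "B2", "A", 6.0, "target"),
            ("R1", "B3", "A", 3.0, "reference"),
            ("R2", "B4", "A", 4.0, "reference"),
        ]
        est = alos_shift(self._frame(rows))
        assert est.status == "single_stratum"
        assert est.estimate == pytest.approx(5.0 - 3.5)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(17)
        rows = [
            (f"C{i}", f"B{i}", rng.choice(["A", "B", "C"]),
             float(rng.integers(1, 15)),
             "target" if rng.random() < 0.5 else "reference")
            for i in range(60)
        ]
        frame = self._frame(rows)
        est1 = alos_shift(frame)
        est2 = alos_shift(frame.sample(frac=1.0, random_state=1))
        assert est1.estimate == pytest.approx(est2.estimate)
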