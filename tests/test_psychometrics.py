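"""Reliability and validity statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from leascore import (
    UndefinedStatisticError,
    UsageError,
    agreement_report,
    cronbach_alpha,
    independent_t_test,
    mean_protocol_difference,
    partial_r,
    pearson_r,
)


class TestCronbachAlpha:
    worked = np.array([[2, 4], [3, 3], [4, 5], [5, 6]], dtype=float)

    def test_worked_example_closed_form(self):
        # item variances 5/3 and 5/3, total variance 6 -> alpha = 8/9
        res = cronbach_alpha(self.worked)
        assert res.estimate == pytest.approx(8 / 9, abs=1e-9)
        assert res.n == 4

    def test_parallel_items_give_alpha_1(self):
        col = np.array([1.0, 2.0, 5.0, 3.0])
        res = cronbach_alpha(np.column_stack([col, col]))
        assert res.estimate == pytest.approx(1.0, abs=1e-12)

    def test_independent_items_give_alpha_near_0(self):
        rng = np.random.default_rng(42)
        M = rng.normal(size=(10_000, 2))
        assert abs(cronbach_alpha(M).estimate) < 0.05

    def test_feldt_ci_brackets_estimate_and_matches_pingouin(self):
        import pingouin as pg

        res = cronbach_alpha(self.worked)
        lo, hi = res.ci95
        assert lo <= res.estimate <= hi
        pg_alpha, pg_ci = pg.cronbach_alpha(
            data=pd.DataFrame(self.worked), ci=0.95
        )
        assert res.estimate == pytest.approx(pg_alpha, abs=1e-9)
        assert lo == pytest.approx(pg_ci[0], abs=5e-3)  # pingouin rounds its CI
        assert hi == pytest.approx(pg_ci[1], abs=5e-3)

    def test_invariances(self):
        base = cronbach_alpha(self.worked).estimate
        shifted = self.worked.copy()
        shifted[:, 0] += 7.0  # constant added to one item
        assert cronbach_alpha(shifted).estimate == pytest.approx(base, abs=1e-12)
        assert cronbach_alpha(self.worked * 3.5).estimate == pytest.approx(
            base, abs=1e-12
        )

    def test_zero_total_variance_is_undefined(self):
        M = np.array([[1, 2], [2, 1], [0, 3]], dtype=float)  # all totals 3
        with pytest.raises(UndefinedStatisticError):
            cronbach_alpha(M)


class TestPearson:
    @pytest.mark.parametrize(
        "x, y, r", [([1, 2, 3], [2, 4, 6], 1.0), ([1, 2, 3], [6, 4, 2], -1.0)]
    )
    def test_exact_linearity(self, x, y, r):
        assert pearson_r(x, y).estimate == pytest.approx(r, abs=1e-12)

    def test_worked_example(self):
        res = pearson_r([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.estimate == pytest.approx(0.8, abs=1e-9)
        assert res.df == 2
        lo, hi = res.ci95
        assert lo <= 0.8 <= hi

    def test_affine_invariance_and_antisymmetry(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=50), rng.normal(size=50)
        r = pearson_r(x, y).estimate
        assert pearson_r(3.0 * x + 5.0, y).estimate == pytest.approx(r, abs=1e-12)
        assert pearson_r(x, -y).estimate == pytest.approx(-r, abs=1e-12)

    def test_ci_width_shrinks_with_n(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=1000)
        x = z + rng.normal(scale=1.0, size=1000)
        widths = []
        for n in (10, 100, 1000):
            lo, hi = pearson_r(x[:n], z[:n]).ci95
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_zero_variance_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            pearson_r([1, 1, 1, 1], [1, 2, 3, 4])


class TestPartial:
    def test_no_covariates_reduces_to_pearson(self):
        x, y = [1, 2, 3, 4], [1, 3, 2, 4]
        assert partial_r(x, y, []).estimate == pearson_r(x, y).estimate

    def test_first_order_closed_form(self, exact_correlation_data):
        x, y, z = exact_correlation_data
        res = partial_r(x, y, [z])
        assert res.estimate == pytest.approx(7 / 15, abs=1e-9)
        assert res.df == len(x) - 3

    def test_residual_method_equals_recursion_formula(self):
        rng = np.random.default_rng(3)
        x, y, z = rng.normal(size=(3, 40))
        rxy = np.corrcoef(x, y)[0, 1]
        rxz = np.corrcoef(x, z)[0, 1]
        ryz = np.corrcoef(y, z)[0, 1]
        expected = (rxy - rxz * ryz) / math.sqrt((1 - rxz**2) * (1 - ryz**2))
        assert partial_r(x, y, [z]).estimate == pytest.approx(expected, abs=1e-9)

    def test_covariate_carrying_all_signal_gives_near_zero(self):
        rng = np.random.default_rng(4)
        n = 10_000
        z = rng.normal(size=n)
        x = rng.normal(size=n)
        y = 2.0 * z + rng.normal(size=n)  # y depends on z only
        assert abs(partial_r(x, y, [z]).estimate) < 0.03

    def test_uncorrelated_covariate_approaches_pearson(self):
        rng = np.random.default_rng(5)
        n = 10_000
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        w = rng.normal(size=n)
        assert partial_r(x, y, [w]).estimate == pytest.approx(
            pearson_r(x, y).estimate, abs=0.02
        )

    def test_rank_deficient_covariates_rejected(self):
        from leascore import DegenerateDesignError

        rng = np.random.default_rng(6)
        x, y, z = rng.normal(size=(3, 20))
        with pytest.raises(DegenerateDesignError):
            partial_r(x, y, [z, 2.0 * z])


class TestWelch:
    def test_identical_samples(self):
        res = independent_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=1e-12)

    def test_worked_example(self):
        res = independent_t_test([1, 2, 3], [4, 5, 6])
        assert res.statistic == pytest.approx(-3.0 / math.sqrt(2 / 3), abs=1e-9)
        assert res.df == pytest.approx(4.0, abs=1e-9)
        assert res.estimate == pytest.approx(-3.0, abs=1e-12)
        lo, hi = res.ci95
        assert lo <= -3.0 <= hi

    def test_evidence_grows_with_shift(self):
        rng = np.random.default_rng(7)
        b = rng.normal(size=200)
        p_small = independent_t_test(b + 0.2, b).p_value
        p_large = independent_t_test(b + 2.0, b).p_value
        assert p_large < p_small


class TestMeanDifference:
    @pytest.mark.parametrize(
        "m, ref, expected",
        [
            ([10, 20], [10, 20], 0.0),
            ([12, 19], [10, 20], 1.5),
            ([11, 21, 31], [10, 20, 30], 1.0),
        ],
    )
    def test_mean_absolute_difference(self, m, ref, expected):
        assert mean_protocol_difference(m, ref) == pytest.approx(expected)

    def test_length_mismatch(self):
        with pytest.raises(UsageError):
            mean_protocol_difference([1, 2], [1, 2, 3])


def _toy_score_table() -> pd.DataFrame:
    rng = np.random.default_rng(8)
    idx = pd.Index([f"r{i:02d}" for i in range(12)], name="respondent_id")
    items = rng.integers(0, 5, size=(12, 20)) + np.arange(12)[:, None] // 3
    table = pd.DataFrame(
        items, index=idx, columns=[f"3345plus_item{i:02d}" for i in range(1, 21)]
    )
    table["3345plus_protocol"] = table.sum(axis=1)
    for i in range(1, 21):
        table[f"334_item{i:02d}"] = 2  # constant method
    table["334_protocol"] = 40
    return table


class TestAgreementReport:
    def test_reference_equal_to_method_scores(self):
        table = _toy_score_table()
        ref = table["3345plus_protocol"].astype(float)
        rep = agreement_report(table, ref, methods=["3345plus"])
        entry = rep["methods"]["3345plus"]
        assert entry["r"]["estimate"] == pytest.approx(1.0, abs=1e-12)
        assert entry["mean_difference"] == 0.0
        assert rep["n"] == 12

    def test_constant_method_error_is_isolated(self):
        table = _toy_score_table()
        ref = table["3345plus_protocol"].astype(float)
        rep = agreement_report(table, ref, methods=["3345plus", "334"])
        assert "error" in rep["methods"]["334"]["r"]
        assert "error" in rep["methods"]["334"]["alpha"]
        assert rep["methods"]["3345plus"]["r"]["estimate"] == pytest.approx(1.0)

    def test_empty_intersection_is_usage_error(self):
        table = _toy_score_table()
        ref = pd.Series([1.0, 2.0], index=["x1", "x2"])
        with pytest.raises(UsageError):
            agreement_report(table, ref)
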