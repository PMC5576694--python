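"""RECIST classes, Kaplan–Meier estimation, log-rank and contingency tests."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from tkiresist import datasets
from tkiresist.cohort import (
    CohortRecord,
    classify_recist,
    contingency_test,
    km_median_survival,
    logrank_test,
    response_rates,
    summarize_cohort,
)
from tkiresist.simulate import CohortSimSpec, gen_cohort


def rec(t, event=True, pid=None):
    return CohortRecord(patient_id=pid or f"r{t}", pfs_months=float(t), pfs_event=event)


class TestRecist:
    @pytest.mark.parametrize(
        "change,expected",
        [(-35, "PR"), (25, "PD"), (-30, "SD"), (20, "SD"), (0, "SD"),
         (-30.001, "PR"), (20.001, "PD"), (None, None)],
    )
    def test_classes(self, change, expected):
        assert classify_recist(change) == expected

    @given(st.floats(-100, 500, allow_nan=False))
    def test_classes_partition_percent_changes(self, change):
        assert classify_recist(change) in {"PR", "SD", "PD"}

    def test_response_rates(self):
        rates = response_rates(["PR", "PR", "SD", "PD", "CR"])
        assert rates["orr"] == pytest.approx(3 / 5)
        assert rates["dcr"] == pytest.approx(4 / 5)


class TestKaplanMeier:
    def test_uncensored_median_is_empirical(self):
        curve = km_median_survival([rec(t) for t in (1, 2, 3, 4, 100)])
        assert curve.median == 3

    def test_uncensored_curve_equals_empirical_survival(self):
        times = [1.0, 2.0, 2.0, 5.0, 7.0]
        curve = km_median_survival([rec(t, pid=str(i)) for i, t in enumerate(times)])
        for t in (0.5, 1.5, 2.5, 6.0, 8.0):
            empirical = np.mean([x > t for x in times])
            assert curve.survival_at(t) == pytest.approx(empirical)

    def test_survival_starts_at_one_and_never_increases(self):
        records = gen_cohort(CohortSimSpec(n_patients=200, censor_fraction=0.3, seed=4))
        curve = km_median_survival(records)
        assert curve.survival_at(0) == 1.0
        assert (np.diff(curve.survival) <= 1e-12).all()

    def test_all_censored_median_undefined(self):
        curve = km_median_survival([rec(t, event=False) for t in (1, 2, 3)])
        assert curve.median is None

    def test_negative_times_rejected_at_record_construction(self):
        with pytest.raises(ValueError, match=">= 0"):
            CohortRecord(patient_id="x", pfs_months=-1.0, pfs_event=True)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            km_median_survival([])

    def test_recovers_true_exponential_median(self):
        spec = CohortSimSpec(
            n_patients=2000,
            median_pfs_by_group={"all": 2.8},
            median_os_by_group={"all": 8.8},
            censor_fraction=0.2,
            seed=12,
        )
        curve = km_median_survival(gen_cohort(spec))
        assert curve.median == pytest.approx(2.8, abs=0.2)


class TestLogrank:
    def test_group_against_itself_is_null(self):
        grp = [rec(t, pid=str(i)) for i, t in enumerate((1, 2, 3, 4, 5))]
        res = logrank_test(grp, list(grp))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_five_event_toy_matches_hand_computed_statistic(self):
        # O_A=3, E_A=49/15, V=0.96222... on events A:{1,3,5}, B:{2,4}
        a = [rec(t, pid=f"a{t}") for t in (1, 3, 5)]
        b = [rec(t, pid=f"b{t}") for t in (2, 4)]
        res = logrank_test(a, b)
        assert res.statistic == pytest.approx(0.0739030023094688, abs=1e-9)
        assert res.p_value == pytest.approx(0.7857365379599127, abs=1e-9)

    def test_symmetric_under_group_swap(self):
        a = [rec(t, pid=f"a{i}") for i, t in enumerate((1, 4, 6, 9))]
        b = [rec(t, pid=f"b{i}") for i, t in enumerate((2, 3, 8))]
        assert logrank_test(a, b).statistic == pytest.approx(logrank_test(b, a).statistic)

    def test_zero_events_reported_undefined(self):
        a = [rec(1, event=False)]
        b = [rec(2, event=False)]
        res = logrank_test(a, b)
        assert not res.defined and math.isnan(res.statistic)

    def test_detects_threefold_hazard_difference(self):
        reject = 0
        for seed in range(20):
            spec = CohortSimSpec(
                n_patients=400,
                median_pfs_by_group={"a": 3.0, "b": 9.0},
                median_os_by_group={"a": 3.0, "b": 9.0},
                censor_fraction=0.0,
                seed=seed,
            )
            records = gen_cohort(spec)
            a = [r for r in records if r.group == "a"]
            b = [r for r in records if r.group == "b"]
            reject += logrank_test(a, b).p_value < 0.01
        assert reject >= 19


def fisher_exact_by_enumeration(table):
    """Two-sided Fisher p by summing hypergeometric probabilities <= observed."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = stats.hypergeom.pmf(x, n, r1, c1)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return total


class TestContingency:
    def test_tki_t790m_table_is_highly_significant(self):
        table = [[18, 1], [2, 6]]
        assert contingency_test(table, "chisq").p_value < 0.001
        assert contingency_test(table, "fisher").p_value < 0.001

    def test_balanced_table_is_null(self):
        res = contingency_test([[5, 5], [5, 5]], "chisq")
        assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)

    def test_fisher_matches_hypergeometric_enumeration(self, rng):
        for _ in range(25):
            table = rng.integers(0, 12, size=(2, 2))
            got = contingency_test(table, "fisher").p_value
            expected = fisher_exact_by_enumeration(table)
            assert got == pytest.approx(expected, rel=1e-6, abs=1e-12)

    def test_chisq_invariant_under_transposition(self, rng):
        for _ in range(10):
            table = rng.integers(1, 30, size=(2, 2))
            assert contingency_test(table, "chisq").p_value == pytest.approx(
                contingency_test(table.T, "chisq").p_value
            )

    def test_zero_margin_undefined_for_chisq_but_not_fisher(self):
        table = [[0, 0], [3, 4]]
        assert not contingency_test(table, "chisq").defined
        assert contingency_test(table, "fisher").p_value == pytest.approx(1.0)


class TestCohortSummary:
    def test_t790m_rate_from_expanded_mutation_table(self):
        records = datasets.records_from_table1(column="pre_afatinib")
        summary = summarize_cohort(records)
        assert summary["n_egfr_positive"] == 29
        assert summary["n_t790m_positive"] == 22
        assert summary["t790m_pct"] == 76

    def test_per_tki_rates_from_characteristics_table(self):
        summary = summarize_cohort(datasets.records_from_table2())
        assert summary["per_tki"]["erlotinib_t790m_pct"] == 95
        assert summary["per_tki"]["gefitinib_t790m_pct"] == 25
        assert summary["tki_t790m_table"].tolist() == [[18, 1], [2, 6]]

    def test_single_positive_patient_is_100pct(self):
        records = [CohortRecord(patient_id="1", egfr_status="Exon 19", t790m=True)]
        assert summarize_cohort(records)["t790m_pct"] == 100

    def test_empty_cohort_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_cohort([])
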