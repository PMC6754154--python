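"""Raw-score change analyses: rates, anchors, patterns, partition, chi-square."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from phqtraj.cohort import SimConfig, generate_cohort
from phqtraj.patterns import (
    DegenerateTableError,
    InsufficientDataError,
    SUBGROUPS,
    analysis_population,
    anchor_deltas,
    association,
    chi_square_homogeneity,
    chi_square_table,
    classify_cohort,
    classify_patterns,
    partition_counts,
    short_term_rate_pairs,
)
from phqtraj.cohort import Demographics
from tests.conftest import make_visit, pattern_oracle


class TestShortTermRates:
    def test_rate_arithmetic(self):
        recs = [make_visit("p", 0, 16, 1), make_visit("p", 14, 12, 1)]
        (pair,) = short_term_rate_pairs(recs)
        # per-item average change (12/8 - 16/8) over two weeks
        assert pair.phq8_change == pytest.approx(-0.25)
        assert pair.item9_change == pytest.approx(0.0)

    def test_gap_beyond_one_month_skipped(self):
        recs = [make_visit("p", 0, 16, 1), make_visit("p", 45, 12, 1)]
        assert short_term_rate_pairs(recs) == []

    def test_matches_enumeration_oracle(self):
        days = [0, 10, 50, 64]
        totals = [16, 10, 12, 20]
        item9s = [2, 1, 1, 3]
        recs = [make_visit("p", d, t, i) for d, t, i in zip(days, totals, item9s)]
        pairs = short_term_rate_pairs(recs)
        expected = []
        for j in range(3):
            gap = days[j + 1] - days[j]
            if gap <= 30.44:
                expected.append(
                    (
                        (totals[j + 1] - totals[j]) / 8.0 / (gap / 7.0),
                        (item9s[j + 1] - item9s[j]) / (gap / 7.0),
                    )
                )
        assert [(p.phq8_change, p.item9_change) for p in pairs] == pytest.approx(expected)


class TestAnchorDeltas:
    def test_single_record_in_window(self):
        recs = [make_visit("p", 0, 16, 2), make_visit("p", 91, 8, 1)]
        (pair,) = anchor_deltas(recs, 3)
        assert pair.phq8_change == pytest.approx(8 / 8 - 16 / 8)
        assert pair.item9_change == pytest.approx(-1.0)

    def test_empty_window_skipped(self):
        recs = [make_visit("p", 0, 16, 2), make_visit("p", 30, 8, 1)]
        assert anchor_deltas(recs, 6) == []

    def test_windowed_mean_of_two_records(self):
        recs = [
            make_visit("p", 0, 16, 0),
            make_visit("p", 85, 8, 1),
            make_visit("p", 99, 12, 1),
        ]
        (pair,) = anchor_deltas(recs, 3)
        assert pair.phq8_change == pytest.approx((8 + 12) / 2 / 8 - 16 / 8)
        assert pair.item9_change == pytest.approx(1.0)


class TestAssociation:
    def test_monotone_pairs_give_rho_one(self):
        from phqtraj.patterns import ChangePair

        pairs = [ChangePair("p", "short_term_rate", float(i), float(i**3)) for i in range(6)]
        assert association(pairs)["spearman_rho"] == pytest.approx(1.0)

    def test_exact_line_regression(self):
        from phqtraj.patterns import ChangePair

        pairs = [ChangePair("p", "short_term_rate", float(i), 2.0 * i) for i in range(5)]
        res = association(pairs)
        assert res["ols_slope"] == pytest.approx(2.0)
        assert res["ols_r2"] == pytest.approx(1.0)

    def test_ties_match_rank_then_pearson_oracle(self, rng):
        from phqtraj.patterns import ChangePair

        x = np.round(rng.normal(size=10), 1)
        y = np.round(x + rng.normal(scale=0.5, size=10), 1)
        pairs = [ChangePair("p", "short_term_rate", a, b) for a, b in zip(x, y)]
        rho = association(pairs)["spearman_rho"]
        rx = stats.rankdata(x)  # average ranks for ties
        ry = stats.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_positive_association_recovered_on_cohorts(self):
        # Item 9 is generated as a positive transform of PHQ-8, so pooled
        # change associations must come out positive at every horizon
        for seed in range(3):
            visits, _, _ = generate_cohort(SimConfig(n_patients=100, seed=seed))
            assert association(short_term_rate_pairs(visits))["spearman_rho"] > 0
            for m in (3, 6):
                assert association(anchor_deltas(visits, m))["spearman_rho"] > 0

    def test_too_few_pairs_rejected(self):
        from phqtraj.patterns import ChangePair

        with pytest.raises(InsufficientDataError):
            association([ChangePair("p", "short_term_rate", 1.0, 1.0)] * 2)


class TestClassifyPatterns:
    def test_worked_example_b_only(self):
        recs = [make_visit("p", 0, 10, 0), make_visit("p", 10, 6, 1), make_visit("p", 20, 8, 1)]
        assert classify_patterns(recs, 2).subgroup == "b_only"

    def test_flat_series_none(self):
        recs = [make_visit("p", d, 10, 1) for d in (0, 10, 20)]
        assert classify_patterns(recs, 2).subgroup == "none"

    def test_both_patterns_fire(self):
        recs = [
            make_visit("p", 0, 10, 1),
            make_visit("p", 10, 13, 0),
            make_visit("p", 20, 10, 1),
        ]
        assert classify_patterns(recs, 3).subgroup == "both"

    def test_single_visit_is_none(self):
        assert classify_patterns([make_visit("p", 0, 10, 1)], 2).subgroup == "none"

    @settings(max_examples=300, deadline=None)
    @given(
        series=st.lists(
            st.tuples(st.integers(0, 24), st.integers(0, 3)), min_size=2, max_size=10
        ),
        d=st.sampled_from([2, 3, 4]),
    )
    def test_matches_consecutive_pair_oracle(self, series, d):
        recs = [make_visit("p", 10 * i, t, i9) for i, (t, i9) in enumerate(series)]
        assert classify_patterns(recs, d).subgroup == pattern_oracle(series, d)

    def test_threshold_monotonicity_on_cohort(self):
        visits, _, _ = generate_cohort(SimConfig(n_patients=40, noise_sd=1.5, seed=13))
        population = analysis_population(visits)
        fired = {}
        for d in (2, 3, 4):
            labels = classify_cohort(visits, d, population)
            fired[d] = {l.patient_id for l in labels if l.subgroup != "none"}
        assert fired[4] <= fired[3] <= fired[2]


class TestPartition:
    def test_one_patient_per_subgroup(self):
        from phqtraj.patterns import PatternLabel

        labels = [PatternLabel(f"p{i}", 2, g) for i, g in enumerate(SUBGROUPS)]
        part = partition_counts(labels)
        assert all(c == 1 for c in part["counts"].values())
        assert all(p == pytest.approx(25.0) for p in part["percentages"].values())

    def test_all_none(self):
        from phqtraj.patterns import PatternLabel

        labels = [PatternLabel(f"p{i}", 3, "none") for i in range(5)]
        part = partition_counts(labels)
        assert part["counts"] == {"a_only": 0, "b_only": 0, "both": 0, "none": 5}

    def test_partition_exhaustive_and_exclusive_on_cohort(self):
        visits, _, _ = generate_cohort(SimConfig(n_patients=50, noise_sd=1.0, seed=17))
        population = analysis_population(visits)
        for d in (2, 3, 4):
            labels = classify_cohort(visits, d, population)
            assert len(labels) == len(population)
            assert len({l.patient_id for l in labels}) == len(labels)
            part = partition_counts(labels)
            assert sum(part["counts"].values()) == len(population)
            assert sum(part["percentages"].values()) == pytest.approx(100.0)


class TestChiSquare:
    def test_homogeneous_table(self):
        res = chi_square_table([[10, 10], [10, 10]])
        assert res["statistic"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)

    def test_2x2_closed_form(self):
        # n (ad - bc)^2 / (r1 r2 c1 c2)
        res = chi_square_table([[20, 10], [10, 20]])
        assert res["statistic"] == pytest.approx(20 / 3)
        assert res["dof"] == 1

    def test_low_expected_flag(self):
        res = chi_square_table([[2, 10], [5, 40]])
        assert res["low_expected_flag"]

    def test_zero_marginal_rejected(self):
        with pytest.raises(DegenerateTableError):
            chi_square_table([[0, 0], [5, 5]])

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(25):
            table = rng.integers(1, 40, size=(3, 4))
            res = chi_square_table(table)
            ref = stats.chi2_contingency(table, correction=False)
            assert res["statistic"] == pytest.approx(ref.statistic, abs=1e-9)
            assert res["p"] == pytest.approx(ref.pvalue, abs=1e-9)
            assert res["dof"] == ref.dof

    def test_homogeneity_from_labels(self):
        from phqtraj.patterns import PatternLabel

        labels = [PatternLabel(f"p{i}", 2, SUBGROUPS[i % 4]) for i in range(40)]
        demo = [
            Demographics(f"p{i}", "45-64", "F" if i % 2 else "M", "white", "0")
            for i in range(40)
        ]
        res = chi_square_homogeneity(labels, demo, "sex")
        assert res["dof"] == 3
        assert 0.0 <= res["p"] <= 1.0
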