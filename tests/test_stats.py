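"""Symptom statistics: rank correlation, Fisher intervals, chi-squared,
severity-distribution diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amsnet.published import TABLE1_MEAN_ROW, TABLE1_N, TABLE1_RHO
from amsnet.stats import (
    SymptomCorrMatrix,
    chi_squared_independence,
    fisher_ci,
    isolated_symptoms,
    ks_normality,
    skewness,
    spearman_rho,
    sqrt_transform,
    summary_stats,
    symptom_matrix,
    symptom_network,
    treatment_percentages,
)


def midrank_spearman(x, y):
    """Brute-force oracle: average ranks by hand, then textbook Pearson."""
    def midranks(v):
        v = np.asarray(v, float)
        order = np.argsort(v)
        ranks = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks
    rx, ry = midranks(x), midranks(y)
    rxc, ryc = rx - rx.mean(), ry - ry.mean()
    return float((rxc * ryc).sum() / np.sqrt((rxc**2).sum() * (ryc**2).sum()))


class TestSpearman:
    def test_perfect_monotone_agreement(self):
        assert spearman_rho([1, 2, 3, 5], [10, 20, 30, 40]) == pytest.approx(1.0)

    def test_perfect_inversion(self):
        assert spearman_rho([1, 2, 3, 5], [40, 30, 20, 10]) == pytest.approx(-1.0)

    def test_ties_use_midranks(self):
        x, y = (1, 2, 2, 4), (10, 20, 30, 40)
        assert spearman_rho(x, y) == pytest.approx(midrank_spearman(x, y))

    def test_matches_brute_force_with_random_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.integers(0, 5, 12).astype(float)
            y = rng.integers(0, 5, 12).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            assert spearman_rho(x, y) == pytest.approx(midrank_spearman(x, y))

    def test_constant_input_undefined(self):
        assert np.isnan(spearman_rho([1, 1, 1, 1], [1, 2, 3, 4]))

    @given(st.lists(st.integers(0, 10_000), min_size=5, max_size=20, unique=True))
    @settings(max_examples=30)
    def test_invariant_under_strictly_monotone_transform(self, xs):
        ys = np.linspace(0, 1, len(xs))
        base = spearman_rho(xs, ys)
        warped = spearman_rho(np.exp(np.asarray(xs, dtype=float) / 1000.0), ys)
        assert warped == pytest.approx(base)


class TestFisherCI:
    @pytest.mark.parametrize(
        "rho,expected",
        [(0.25, (0.13, 0.36)),  # sleep-headache
         (0.57, (0.48, 0.65))], # dizziness-headache
    )
    def test_reproduces_published_pairwise_intervals(self, rho, expected):
        lo, hi = fisher_ci(rho, TABLE1_N)
        assert (round(lo, 2), round(hi, 2)) == expected

    def test_zero_coefficient_gives_symmetric_interval(self):
        lo, hi = fisher_ci(0.0, 100)
        assert lo == pytest.approx(-hi)

    def test_width_shrinks_with_n_and_stays_inside_unit_interval(self):
        widths = []
        for n in (10, 50, 200, 1000):
            lo, hi = fisher_ci(0.6, n)
            assert -1.0 < lo < hi < 1.0
            widths.append(hi - lo)
        assert widths == sorted(widths, reverse=True)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            fisher_ci(0.5, 3)


class TestSymptomMatrix:
    def test_per_symptom_means_reproduce_published_row(self):
        matrix = SymptomCorrMatrix.from_pairwise(TABLE1_RHO, TABLE1_N)
        means = matrix.per_symptom_mean
        for symptom, printed in TABLE1_MEAN_ROW.items():
            assert abs(means[symptom] - printed) <= 0.005 + 1e-12

    def test_identical_columns_give_unit_matrix(self):
        base = np.arange(10, dtype=float)
        profiles = pd.DataFrame({s: base for s in
                                 ("sleep", "gi_upset", "dizziness", "headache", "fatigue")})
        matrix = symptom_matrix(profiles)
        assert np.allclose(matrix.rho.to_numpy(), 1.0)
        assert np.allclose(matrix.per_symptom_mean.to_numpy(), 1.0)

    def test_matrix_symmetric_with_unit_diagonal(self, small_dataset):
        from amsnet.records import qc_filter, symptom_profile_frame
        from amsnet.pipeline import select_one_per_subject

        passed = small_dataset[qc_filter(small_dataset)]
        profiles = symptom_profile_frame(select_one_per_subject(passed))
        matrix = symptom_matrix(profiles)
        rho = matrix.rho.to_numpy()
        assert np.allclose(rho, rho.T)
        assert np.allclose(np.diag(rho), 1.0)
        assert ((matrix.ci_low.to_numpy() <= rho) | np.eye(5, dtype=bool)).all()

    def test_too_few_subjects_rejected(self):
        profiles = pd.DataFrame(
            np.ones((3, 5)), columns=("sleep", "gi_upset", "dizziness", "headache", "fatigue")
        )
        with pytest.raises(ValueError):
            symptom_matrix(profiles)


class TestSymptomNetwork:
    def test_sleep_isolated_at_published_threshold(self):
        matrix = SymptomCorrMatrix.from_pairwise(TABLE1_RHO, TABLE1_N)
        g = symptom_network(matrix, cutoff=0.4)
        assert isolated_symptoms(g) == ["sleep"]
        expected_edges = {
            ("gi_upset", "dizziness"), ("gi_upset", "headache"),
            ("gi_upset", "fatigue"), ("dizziness", "headache"),
            ("dizziness", "fatigue"),
        }
        assert {tuple(sorted(e)) for e in g.edges} == \
               {tuple(sorted(e)) for e in expected_edges}

    def test_cutoff_extremes(self):
        matrix = SymptomCorrMatrix.from_pairwise(TABLE1_RHO, TABLE1_N)
        assert symptom_network(matrix, cutoff=1.01).number_of_edges() == 0
        assert symptom_network(matrix, cutoff=-1.0).number_of_edges() == 10


class TestChiSquared:
    def test_hand_computed_diagonal_table(self):
        stat, dof, p = chi_squared_independence(np.array([[10, 0], [0, 10]]))
        assert stat == pytest.approx(20.0)
        assert dof == 1

    def test_identical_row_distributions_give_zero(self):
        stat, _, _ = chi_squared_independence(np.array([[10, 20], [20, 40]]))
        assert stat == pytest.approx(0.0)

    def test_invariant_under_permutations(self):
        rng = np.random.default_rng(5)
        table = rng.integers(5, 60, (3, 4))
        stat, dof, p = chi_squared_independence(table)
        stat2, dof2, p2 = chi_squared_independence(table[::-1, ::-1])
        assert stat2 == pytest.approx(stat) and dof2 == dof and p2 == pytest.approx(p)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_squared_independence(np.array([[0, 0], [1, 2]]))


class TestPercentages:
    def test_column_percentages(self):
        table = pd.DataFrame({"c1": [130, 157, 57]}, index=["p", "a", "s"])
        assert list(treatment_percentages(table)["c1"]) == [37.8, 45.6, 16.6]

    def test_single_row_is_100(self):
        table = pd.DataFrame({"c1": [12]}, index=["p"])
        assert treatment_percentages(table).iloc[0, 0] == 100.0

    def test_zero_column_rejected(self):
        with pytest.raises(ValueError):
            treatment_percentages(pd.DataFrame({"c1": [0, 0]}))


class TestSeverityDiagnostics:
    def test_sqrt_transform_values(self):
        np.testing.assert_allclose(sqrt_transform([0, 100, 400]), [0, 10, 20])

    def test_negative_scores_rejected(self):
        with pytest.raises(ValueError):
            sqrt_transform([-1.0])

    def test_ks_calibrated_under_normal_null(self):
        # a calibrated estimated-parameter test exceeds p=0.10 for ~90% of
        # null samples; assert the rate sits in a wide binomial band around it
        hits = 0
        reps = 200
        for seed in range(reps):
            x = np.random.default_rng(seed).normal(50, 10, 500)
            _, p = ks_normality(x)
            hits += p > 0.10
        assert 0.82 <= hits / reps <= 0.97

    def test_ks_rejects_heavy_skew(self):
        x = np.random.default_rng(0).exponential(1.0, 2000)
        _, p = ks_normality(x)
        assert p < 0.01

    def test_sqrt_reduces_skewness_of_synthetic_totals(self):
        from amsnet.records import qc_filter, total_vas
        from amsnet.synthetic import simulate_dataset
        from conftest import low_severity_config

        df = simulate_dataset(low_severity_config(seed=1))
        totals = total_vas(df[qc_filter(df)])
        before = skewness(totals)
        after = skewness(sqrt_transform(totals))
        assert before > 0
        assert abs(after) < abs(before)

    def test_summary_stats(self):
        s = summary_stats([1, 1, 2, 4, 4])
        assert s.median == 2
        assert s.iqr == (1, 4)
        assert summary_stats([1, 2, 3]).mean == pytest.approx(2.0)

    def test_single_value_sd_undefined(self):
        with pytest.raises(ValueError):
            summary_stats([2.0])
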