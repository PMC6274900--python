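"""Frequency tables, missing-mass redistribution, row aggregation and the
chi-square score, anchored on the published worked example."""

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from incompfs import (MCFS, IncompleteMatrix, LabelVector, aggregate_rows,
                      build_frequency_table, chi_square_pvalue,
                      discretize_feature, expected_frequencies,
                      redistribute_missing, score_feature)
from incompfs.exceptions import UnsupervisedInputError
from incompfs.mcfs import ContingencyTable


def _feature(table9, name):
    X, y = table9
    j = X.feature_names.index(name)
    x, mask = X.column(j)
    return discretize_feature(x, mask, strategy="distinct"), y


def _cols(F_or_M, labels):
    """Column indices putting classes in the order ``labels``."""
    return [F_or_M.col_labels.index(c) for c in labels]


class TestBuildFrequencyTable:
    def test_worked_example_a1(self, table9):
        feat, y = _feature(table9, "a1")
        F = build_frequency_table(feat, y)
        yes_no = _cols(F, ["yes", "no"]) + [F.l]
        # rows low/medium/high/?, columns yes/no/?
        np.testing.assert_array_equal(
            F.F[:, yes_no],
            [[1, 1, 0], [2, 0, 0], [1, 1, 0], [1, 1, 0]])
        assert F.N == 6

    def test_worked_example_a2_hand_count(self, table9):
        feat, y = _feature(table9, "a2")
        F = build_frequency_table(feat, y)
        yes, no = _cols(F, ["yes", "no"])
        assert F.F[0, yes] == 2            # (low, yes)
        assert F.F[1, yes] == 1 and F.F[1, no] == 1   # medium
        assert F.F[2, yes] == 2 and F.F[2, no] == 1   # high
        assert F.F[3, no] == 1             # (?, no)
        assert F.F[:, F.l].sum() == 0      # no class-missing mass

    def test_fully_observed_has_empty_margins(self):
        feat = discretize_feature(np.array([1., 1, 2, 2]), strategy="distinct")
        F = build_frequency_table(
            feat, LabelVector(np.array(["a", "b", "a", "b"], dtype=object)))
        assert F.F[F.m, :].sum() == 0 and F.F[:, F.l].sum() == 0
        assert F.total == F.N == 4

    def test_single_class_raises(self):
        feat = discretize_feature(np.array([1., 2, 3]), strategy="distinct")
        with pytest.raises(UnsupervisedInputError):
            build_frequency_table(
                feat, LabelVector(np.array(["a", "a", "a"], dtype=object)))


class TestRedistributeMissing:
    def test_worked_example_exact_rationals(self, table9):
        feat, y = _feature(table9, "a1")
        M = redistribute_missing(build_frequency_table(feat, y))
        yes_no = _cols(M, ["yes", "no"])
        np.testing.assert_allclose(
            M.M[:, yes_no],
            [[4 / 3, 4 / 3], [7 / 3, 1 / 3], [4 / 3, 4 / 3]], atol=1e-12)
        assert abs(M.grand_total - 8) < 1e-12

    def test_complete_table_unchanged(self):
        F_aug = np.zeros((3, 3))
        F_aug[:2, :2] = [[3, 1], [0, 4]]
        from incompfs.mcfs import FrequencyTable
        M = redistribute_missing(FrequencyTable(F_aug, [0, 1], ["a", "b"]))
        np.testing.assert_allclose(M.M, [[3, 1], [0, 4]])

    def test_worked_example_a2_low_no_cell(self, table9):
        feat, y = _feature(table9, "a2")
        M = redistribute_missing(build_frequency_table(feat, y))
        no = _cols(M, ["no"])[0]
        # N=7, r_low=2, one (?, no) record: 0 + 1*2/7
        assert abs(M.M[0, no] - 2 / 7) < 1e-12

    def test_all_missing_feature_is_unscorable(self):
        from incompfs.mcfs import FrequencyTable
        F = np.zeros((3, 3))
        F[2, :2] = [4, 3]  # every sample has the feature missing
        assert redistribute_missing(FrequencyTable(F, [0, 1], ["a", "b"])) is None

    def test_mass_conservation_random_tables(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            m, l = rng.integers(2, 8), rng.integers(2, 5)
            F = rng.integers(0, 6, size=(m + 1, l + 1)).astype(float)
            from incompfs.mcfs import FrequencyTable
            ft = FrequencyTable(F, list(range(m)), list(range(l)))
            if ft.N == 0:
                continue
            M = redistribute_missing(ft)
            assert abs(M.grand_total - ft.total) < 1e-9


class TestExpectedFrequencies:
    def test_uniform_table(self):
        np.testing.assert_allclose(
            expected_frequencies(np.array([[1., 1], [1, 1]])), 1.0)

    def test_worked_example_e11(self, table9):
        feat, y = _feature(table9, "a1")
        M = redistribute_missing(build_frequency_table(feat, y))
        E = expected_frequencies(M)
        yes = _cols(M, ["yes"])[0]
        assert abs(E[0, yes] - 5 / 3) < 1e-12  # (8/3)(5)/8

    def test_marginals_preserved(self):
        rng = np.random.default_rng(5)
        A = rng.random((4, 3)) + 0.1
        E = expected_frequencies(A)
        np.testing.assert_allclose(E.sum(axis=1), A.sum(axis=1))
        np.testing.assert_allclose(E.sum(axis=0), A.sum(axis=0))
        assert abs(E.sum() - A.sum()) < 1e-9


class TestAggregateRows:
    def test_valid_table_passes_through(self):
        A = np.full((4, 2), 20.0)
        out = aggregate_rows(ContingencyTable(A))
        np.testing.assert_array_equal(out.M, A)

    def test_two_row_table_never_touched(self):
        A = np.array([[0.5, 0.2], [0.1, 0.3]])
        out = aggregate_rows(ContingencyTable(A))
        np.testing.assert_array_equal(out.M, A)

    def test_small_rows_merge_upward(self):
        A = np.array([[1., 1], [1, 1], [20, 20], [20, 20]])
        out = aggregate_rows(ContingencyTable(A))
        # the two tiny adjacent rows collapse together (possibly further)
        assert out.M.shape[0] < 4
        assert abs(out.M.sum() - A.sum()) < 1e-9
        E = expected_frequencies(out.M)
        assert (E > 5).mean() >= 0.8 or out.M.shape[0] == 2

    def test_merge_count_bound_and_mass(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            m, l = rng.integers(3, 8), rng.integers(2, 4)
            A = rng.random((m, l)) * rng.choice([0.5, 3.0])
            out = aggregate_rows(ContingencyTable(A))
            assert 2 <= out.M.shape[0] <= m
            assert abs(out.M.sum() - A.sum()) < 1e-9


class TestChiSquare:
    def test_independent_table_scores_zero(self):
        A = np.array([[2., 4], [1, 2], [3, 6]])
        s = chi_square_pvalue(ContingencyTable(A))
        assert s.chi2 == pytest.approx(0, abs=1e-12)
        assert s.p_value == pytest.approx(1.0)

    def test_textbook_diagonal_table(self):
        s = chi_square_pvalue(ContingencyTable(np.array([[10., 0], [0, 10]])))
        assert s.chi2 == pytest.approx(20.0, abs=1e-12)
        assert s.df == 1

    def test_homogeneity_degree_one(self):
        A = np.array([[8., 2], [3, 7]])
        s1 = chi_square_pvalue(ContingencyTable(A))
        s2 = chi_square_pvalue(ContingencyTable(2 * A))
        assert s2.chi2 == pytest.approx(2 * s1.chi2, rel=1e-12)

    def test_zero_column_dropped_reduces_df(self):
        A = np.array([[5., 0, 5], [2, 0, 8], [7, 0, 3]])
        s = chi_square_pvalue(ContingencyTable(A))
        assert s.df == (3 - 1) * (2 - 1)

    def test_degenerate_when_one_row_left(self):
        s = chi_square_pvalue(ContingencyTable(np.array([[5., 5], [0, 0]])))
        assert s.degenerate and s.p_value == 1.0

    def test_matches_scipy_on_complete_tables(self):
        rng = np.random.default_rng(21)
        done = 0
        while done < 200:
            T = rng.integers(10, 31, size=(rng.integers(2, 6),
                                           rng.integers(2, 5))).astype(float)
            if not (expected_frequencies(T) > 5).all():
                continue
            done += 1
            s = chi_square_pvalue(ContingencyTable(T))
            c2, p, dof, _ = chi2_contingency(T, correction=False)
            assert s.chi2 == pytest.approx(c2, abs=1e-9)
            assert s.p_value == pytest.approx(p, abs=1e-9)
            assert s.df == dof


@pytest.fixture(scope="module")
def dataset():
    from incompfs import SyntheticSpec, generate_dataset
    return generate_dataset(SyntheticSpec(seed=4))


class TestRanking:

    def test_informative_features_rank_top(self, dataset):
        X, y, informative = dataset
        res = MCFS(X, y).fit()
        assert set(informative) <= set(res.order[:10])

    def test_selection_nesting_across_alphas(self, dataset):
        X, y, _ = dataset
        res = MCFS(X, y).fit()
        prev = None
        for alpha in [0.01, 0.005, 0.001, 0.0005, 0.0001]:
            sel = set(res.selection_at(alpha))
            if prev is not None:
                assert sel <= prev
            prev = sel

    def test_ranking_invariant_to_feature_order(self, dataset):
        X, y, _ = dataset
        rng = np.random.default_rng(0)
        perm = rng.permutation(X.n_features)
        res1 = MCFS(X, y).fit()
        res2 = MCFS(X.subset_features(perm), y).fit()
        names1 = [X.feature_names[j] for j in res1.order]
        names2 = [X.subset_features(perm).feature_names[j] for j in res2.order]
        # identical up to the declared tie-break: same (p, chi2) sequence and
        # the same features inside every tie group
        key1 = [(res1.p_values[j], res1.chi2[j]) for j in res1.order]
        key2 = [(res2.p_values[j], res2.chi2[j]) for j in res2.order]
        np.testing.assert_allclose(key1, key2, rtol=1e-12)
        groups1, groups2 = {}, {}
        for n, k in zip(names1, key1):
            groups1.setdefault(round(k[0], 12), set()).add(n)
        for n, k in zip(names2, key2):
            groups2.setdefault(round(k[0], 12), set()).add(n)
        assert groups1 == groups2

    def test_degenerate_features_rank_last_with_p_one(self):
        values = np.array([[1., 7, 1], [2, 7, 1], [3, 7, 2], [4, 7, 2]])
        values[:, 2] = [1, 2, 1, 2]
        X = IncompleteMatrix.from_values(values, ["g", "const", "ok"])
        y = LabelVector(np.array(["a", "a", "b", "b"], dtype=object))
        res = MCFS(X, y, n_bins=2).fit()
        const_idx = X.feature_names.index("const")
        assert res.p_values[const_idx] == 1.0
        assert res.order[-1] == const_idx or res.p_values[res.order[-1]] == 1.0

    def test_score_feature_handles_missing_labels(self):
        feat = discretize_feature(np.array([1., 1, 2, 2, 1, 2]),
                                  strategy="distinct")
        y = LabelVector(np.array(["a", "b", None, "a", "b", "a"], dtype=object))
        s = score_feature(feat, y)
        assert 0 <= s.p_value <= 1 and not s.degenerate
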