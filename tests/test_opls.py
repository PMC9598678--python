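"""PLS/OPLS-DA fitting, back-scaled loadings, Q²Y and permutation validation."""

import numpy as np
import pytest

from crossmet import (
    backscale_loadings,
    cross_validated_q2,
    fit_opls_da,
    fit_pls,
    permutation_test,
    select_n_orth,
)
from crossmet.opls import _subject_folds
from tests.conftest import paired_within


def make_xy(rng, n=24, p=8, signal=2.0, orth=1.0):
    """Two-class data: y-aligned direction + y-orthogonal structure + noise."""
    y = np.repeat([1.0, -1.0], n // 2)
    rng.shuffle(y)
    load = rng.normal(size=p)
    t_orth = rng.normal(size=n)
    load_orth = rng.normal(size=p)
    X = signal * np.outer(y, load) + orth * np.outer(t_orth, load_orth)
    X += 0.1 * rng.normal(size=(n, p))
    return X - X.mean(axis=0), y


class TestPls:
    def test_single_informative_column_weight_indicator(self):
        y = np.repeat([1.0, -1.0], 5)
        X = np.zeros((10, 4))
        X[:, 2] = y
        m = fit_pls(X, y, 1)
        np.testing.assert_allclose(np.abs(m.W[:, 0]), [0, 0, 1, 0], atol=1e-12)

    def test_rank_one_x_fully_explained_by_one_component(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=12)
        X = np.outer(t, rng.normal(size=5))
        y = t + 0.01 * rng.normal(size=12)
        m = fit_pls(X - X.mean(0), y - y.mean(), 1)
        np.testing.assert_allclose(m.E, 0.0, atol=1e-10)

    def test_full_rank_coefficients_match_least_squares_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 4))
        X -= X.mean(axis=0)
        y = rng.normal(size=20)
        y -= y.mean()
        m = fit_pls(X, y, 4)
        beta = np.linalg.pinv(X) @ y
        np.testing.assert_allclose(m.coef.ravel(), beta, atol=1e-8)

    def test_score_orthogonality(self):
        rng = np.random.default_rng(2)
        X, y = make_xy(rng)
        m = fit_pls(X, y, 3)
        g = m.T.T @ m.T
        np.testing.assert_allclose(g - np.diag(np.diag(g)), 0.0, atol=1e-8)

    def test_excess_components_rejected(self):
        X = np.outer(np.arange(6.0), np.ones(3))
        with pytest.raises(ValueError, match="rank"):
            fit_pls(X - X.mean(0), np.arange(6.0), 2)


class TestOplsDa:
    def test_no_orthogonal_structure_leaves_tiny_orthogonal_variance(self):
        rng = np.random.default_rng(3)
        X, y = make_xy(rng, signal=3.0, orth=0.0)
        m = fit_opls_da(X, y, n_orth=1)
        if m.To.size:
            assert m.To.var() < 1e-2 * m.Tp.var()

    @pytest.mark.parametrize("n_orth", [0, 1, 2, 3])
    def test_predictions_equal_pls_with_matching_components(self, n_orth):
        rng = np.random.default_rng(4 + n_orth)
        X, y = make_xy(rng, n=30, p=12)
        m = fit_opls_da(X, y, n_orth=n_orth)
        pls = fit_pls(X, y - y.mean(), 1 + m.n_orth)
        np.testing.assert_allclose(
            m.predict(X), pls.predict(X).ravel() + y.mean(), atol=1e-8
        )

    def test_predictive_orthogonal_scores_are_orthogonal(self):
        rng = np.random.default_rng(5)
        X, y = make_xy(rng)
        m = fit_opls_da(X, y, n_orth=2)
        assert m.scores_orthogonality < 1e-8 * np.linalg.norm(m.Tp) * max(
            1.0, np.linalg.norm(m.To)
        )

    def test_label_flip_symmetry(self):
        rng = np.random.default_rng(6)
        X, y = make_xy(rng)
        m1 = fit_opls_da(X, y, n_orth=1)
        m2 = fit_opls_da(X, -y, n_orth=1)
        np.testing.assert_allclose(m2.predict(X), -m1.predict(X), atol=1e-10)
        np.testing.assert_allclose(
            np.abs(m2.backscaled["covariance"]), np.abs(m1.backscaled["covariance"]), atol=1e-12
        )

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(8, 3))
        with pytest.raises(ValueError, match="two classes"):
            fit_opls_da(X, np.ones(8))

    def test_string_labels_accepted(self):
        rng = np.random.default_rng(7)
        X, y = make_xy(rng)
        labels = np.where(y > 0, "FOO", "VOO")
        m = fit_opls_da(X, labels, n_orth=1)
        assert np.isfinite(m.predict(X)).all()


class TestBackscale:
    def test_variable_identical_to_y_has_unit_r2(self):
        rng = np.random.default_rng(8)
        y = np.repeat([1.0, -1.0], 6)
        X = rng.normal(size=(12, 3))
        X[:, 1] = y
        m = fit_opls_da(X, y, n_orth=0)
        bs = backscale_loadings(m, X)
        assert bs["r2"].iloc[1] == pytest.approx(1.0, abs=1e-12)

    def test_zero_variable_has_zero_covariance_and_r2(self):
        rng = np.random.default_rng(9)
        y = np.repeat([1.0, -1.0], 6)
        X = rng.normal(size=(12, 3))
        X[:, 0] = 0.0
        m = fit_opls_da(X, y, n_orth=0)
        bs = backscale_loadings(m, X)
        assert bs["covariance"].iloc[0] == 0.0
        assert bs["r2"].iloc[0] == 0.0

    def test_covariance_matches_direct_oracle(self):
        rng = np.random.default_rng(10)
        X, y = make_xy(rng)
        m = fit_opls_da(X, y, n_orth=1)
        bs = backscale_loadings(m, X)
        yc = y - y.mean()
        for j in range(X.shape[1]):
            direct = np.cov(X[:, j], yc, ddof=1)[0, 1]
            assert bs["covariance"].iloc[j] == pytest.approx(direct, abs=1e-10)

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(11)
        X, y = make_xy(rng)
        m = fit_opls_da(X, y, n_orth=1)
        with pytest.raises(ValueError, match="rows"):
            backscale_loadings(m, X[:-2])


class TestCrossValidation:
    def test_separable_data_gives_high_q2(self, planted_noise_dataset):
        Xw, y, subjects, _ = paired_within(planted_noise_dataset, ("B", "A"))
        q2 = cross_validated_q2(Xw, y, subjects, n_orth=1, seed=0)
        assert q2 > 0.9

    def test_null_data_gives_nonpositive_q2_in_expectation(self):
        rng = np.random.default_rng(12)
        vals = []
        for _ in range(100):
            n_subj = 10
            X = rng.normal(size=(2 * n_subj, 5))
            subjects = np.repeat(np.arange(n_subj), 2)
            y = np.tile([1.0, -1.0], n_subj)
            vals.append(cross_validated_q2(X, y, subjects, n_orth=1, seed=rng))
        assert np.mean(vals) < 0.0

    def test_matches_explicit_leave_fold_out_loop(self, two_arm_dataset):
        Xw, y, subjects, _ = paired_within(two_arm_dataset, ("B", "A"))
        seed, folds = 5, 7
        q2 = cross_validated_q2(Xw, y, subjects, n_orth=1, folds=folds, seed=seed)
        # independent loop with the same subject partition
        fold_subjects = _subject_folds(subjects, folds, np.random.default_rng(seed))
        press = 0.0
        for held in fold_subjects:
            te = np.isin(subjects, held)
            m = fit_opls_da(Xw[~te], y[~te], n_orth=1)
            press += float(((y[te] - m.predict(Xw[te])) ** 2).sum())
        expected = 1.0 - press / float(((y - y.mean()) ** 2).sum())
        assert q2 == pytest.approx(expected, abs=1e-12)

    def test_q2_invariant_to_column_permutation(self, two_arm_dataset):
        rng = np.random.default_rng(13)
        Xw, y, subjects, _ = paired_within(two_arm_dataset, ("B", "A"))
        perm = rng.permutation(Xw.shape[1])
        q2a = cross_validated_q2(Xw, y, subjects, seed=3)
        q2b = cross_validated_q2(Xw[:, perm], y, subjects, seed=3)
        assert q2a == pytest.approx(q2b, abs=1e-10)

    def test_select_n_orth_scores_all_candidates(self, two_arm_dataset):
        Xw, y, subjects, _ = paired_within(two_arm_dataset, ("B", "A"))
        best, scores = select_n_orth(Xw, y, subjects, candidates=(0, 1, 2), seed=4)
        assert set(scores) == {0, 1, 2}
        assert scores[best] == max(scores.values())

    def test_fewer_than_two_folds_rejected(self, two_arm_dataset):
        Xw, y, subjects, _ = paired_within(two_arm_dataset, ("B", "A"))
        with pytest.raises(ValueError, match="folds"):
            cross_validated_q2(Xw, y, subjects, folds=1)


class TestPermutationTest:
    def test_strong_signal_reaches_floor_p(self, planted_noise_dataset):
        Xw, y, subjects, _ = paired_within(planted_noise_dataset, ("B", "A"))
        p, q2, perm = permutation_test(Xw, y, subjects, n_perm=99, seed=1)
        assert p == pytest.approx(1 / 100)
        assert q2 > 0.9
        assert perm.size == 99

    def test_p_bounded_below_by_add_one_floor(self, two_arm_dataset):
        Xw, y, subjects, _ = paired_within(two_arm_dataset, ("B", "A"))
        p, _, _ = permutation_test(Xw, y, subjects, n_perm=19, seed=2)
        assert 1 / 20 <= p <= 1.0
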