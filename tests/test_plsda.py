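"""NIPALS PLS-DA / OPLS-DA: algebraic identities, oracles, validation."""

import numpy as np
import pandas as pd
import pytest

from herbnet.exceptions import InputError, ParameterError, PreprocessingError
from herbnet.plsda import (
    OPLSDA,
    PLSDA,
    permutation_validate,
    q2_cross_validation,
    vip_scores,
)
from herbnet.simulate import MetaboSimSpec, gen_metabolites


def _random_xy(seed, n=16, p=30):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
    X[y == "b", :3] += rng.uniform(0.5, 2.0)
    return X, y


class TestFit:
    def test_separating_variable_drives_first_score(self):
        rng = np.random.default_rng(0)
        n = 20
        y = np.array(["c"] * 10 + ["t"] * 10)
        X = rng.normal(size=(n, 5)) * 0.05
        X[:, 2] += np.where(y == "t", 5.0, 0.0)
        m = PLSDA(n_components=1, scale=False).fit(X, y)
        code = (y == "t").astype(float)
        assert abs(np.corrcoef(m.x_scores_[:, 0], code)[0, 1]) > 0.99

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 6))
        y = ["a"] * 6 + ["b"] * 6
        m = PLSDA(n_components=6).fit(X, y)
        assert m.r2x_ >= 1 - 1e-6

    def test_sample_permutation_equivariance(self):
        X, y = _random_xy(2)
        m1 = PLSDA(2).fit(X, y)
        perm = np.random.default_rng(3).permutation(len(y))
        m2 = PLSDA(2).fit(X[perm], y[perm])
        np.testing.assert_allclose(m2.x_scores_, m1.x_scores_[perm], atol=1e-10)
        assert m2.r2x_ == pytest.approx(m1.r2x_)
        assert m2.r2y_ == pytest.approx(m1.r2y_)

    def test_scores_orthogonal_weights_unit_norm(self):
        X, y = _random_xy(4)
        m = PLSDA(4).fit(X, y)
        T = m.x_scores_
        gram = T.T @ T
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8
        np.testing.assert_allclose(
            np.linalg.norm(m.x_weights_, axis=0), 1.0, atol=1e-10
        )

    def test_r2x_monotone_in_components(self):
        X, y = _random_xy(5)
        m = PLSDA(5).fit(X, y)
        assert (np.diff(m.r2x_per_component_) >= -1e-12).all()
        assert 0 <= m.r2x_ <= 1

    def test_constant_variable_named_in_error(self):
        X, y = _random_xy(6)
        X[:, 7] = 3.14
        with pytest.raises(PreprocessingError, match="7"):
            PLSDA(2).fit(X, y)

    def test_too_many_components_rejected(self):
        X, y = _random_xy(7, n=8, p=4)
        with pytest.raises(ParameterError):
            PLSDA(10).fit(X, y)

    def test_three_groups_rejected(self):
        X = np.random.default_rng(8).normal(size=(9, 4))
        with pytest.raises(InputError):
            PLSDA(2).fit(X, ["a", "b", "c"] * 3)

    def test_predict_recovers_training_labels_on_separated_data(self):
        X, groups, _ = gen_metabolites(MetaboSimSpec(seed=1))
        m = PLSDA(2).fit(X.T, groups)
        assert (m.predict(X.T) == np.asarray(groups)).mean() == 1.0

    def test_matches_sklearn_nipals_up_to_sign(self):
        # independent cross-check: scikit-learn's NIPALS PLS on the same
        # dummy-coded response reproduces scores and weights up to sign
        from sklearn.cross_decomposition import PLSRegression

        X, y = _random_xy(9)
        m = PLSDA(3).fit(X, y)
        sk = PLSRegression(n_components=3, scale=True).fit(
            X, (y == "b").astype(float)
        )
        for a in range(3):
            c = np.corrcoef(m.x_scores_[:, a], sk.x_scores_[:, a])[0, 1]
            assert abs(c) > 1 - 1e-8


class TestVIP:
    def test_single_informative_variable_of_four(self):
        # all weight on variable 1 -> vip = (sqrt(4), 0, 0, 0)
        rng = np.random.default_rng(10)
        y = np.array(["a", "b"] * 8)
        code = (y == "b").astype(float)
        # variables 2-4 exactly orthogonal to the centred response
        X = np.column_stack([
            code + rng.normal(0, 1e-9, 16),
            np.tile([1.0, 1.0, -1.0, -1.0], 4),
            np.tile([1.0, -1.0, -1.0, 1.0], 4),
            np.tile([-1.0, -1.0, 1.0, 1.0], 4),
        ])
        m = PLSDA(1, scale=False).fit(X, y)
        np.testing.assert_allclose(vip_scores(m), [2.0, 0.0, 0.0, 0.0], atol=1e-6)

    def test_mean_squared_vip_is_one(self):
        for seed in range(5):
            X, y = _random_xy(seed)
            m = PLSDA(3).fit(X, y)
            v = vip_scores(m)
            assert (v**2).mean() == pytest.approx(1.0, abs=1e-8)

    def test_matches_literal_formula_reimplementation(self):
        for seed in range(10):
            X, y = _random_xy(seed, n=14, p=12)
            m = PLSDA(3).fit(X, y)
            # independent literal coding of the Wold VIP formula
            ssy = m.ssy_explained_
            p = X.shape[1]
            expected = np.array([
                np.sqrt(p * sum(ssy[a] * m.x_weights_[j, a] ** 2 for a in range(3))
                        / ssy.sum())
                for j in range(p)
            ])
            np.testing.assert_allclose(vip_scores(m), expected, atol=1e-10)


class TestQ2:
    def test_null_data_has_low_q2(self):
        X, groups, _ = gen_metabolites(MetaboSimSpec(n_diff=0, seed=3))
        assert q2_cross_validation(X.T, groups) < 0.2

    def test_planted_data_has_high_q2(self):
        X, groups, _ = gen_metabolites(MetaboSimSpec(seed=3))
        assert q2_cross_validation(X.T, groups) > 0.7

    def test_q2_below_r2y(self):
        for seed in range(5):
            X, y = _random_xy(seed, n=21, p=25)
            m = PLSDA(2).fit(X, y)
            assert q2_cross_validation(X, y, 2) <= m.r2y_ + 1e-10

    def test_fold_emptying_a_group_rejected(self):
        # a singleton group must empty the training set of the fold
        # holding it out
        X = np.random.default_rng(0).normal(size=(8, 5))
        y = ["a"] * 1 + ["b"] * 7
        with pytest.raises(InputError):
            q2_cross_validation(X, y, n_components=1, n_folds=7)


class TestPermutation:
    def test_planted_signal_is_valid(self):
        X, groups, _ = gen_metabolites(MetaboSimSpec(seed=1))
        rec = permutation_validate(X.T, groups, n_permutations=100, seed=5)
        assert rec.valid
        assert rec.original_q2 > np.quantile(rec.permuted_q2, 0.95)
        assert len(rec.permuted_q2) == 100

    def test_same_seed_reproduces_permuted_q2(self):
        X, groups, _ = gen_metabolites(
            MetaboSimSpec(n_metabolites=60, n_per_group=6, seed=2)
        )
        a = permutation_validate(X.T, groups, n_permutations=20, seed=7)
        b = permutation_validate(X.T, groups, n_permutations=20, seed=7)
        np.testing.assert_array_equal(a.permuted_q2, b.permuted_q2)

    def test_too_few_permutations_rejected(self):
        X, groups, _ = gen_metabolites(MetaboSimSpec(n_metabolites=30, seed=2))
        with pytest.raises(ParameterError):
            permutation_validate(X.T, groups, n_permutations=5)


class TestOPLSDA:
    def test_no_orthogonal_structure_falls_back(self):
        rng = np.random.default_rng(20)
        y = np.array(["a"] * 8 + ["b"] * 8)
        code = (y == "b").astype(float)
        # X built purely from the response direction: nothing orthogonal
        X = np.outer(code - code.mean(), rng.normal(size=6))
        X += rng.normal(0, 1e-12, X.shape)
        with pytest.warns(UserWarning, match="orthogonal"):
            m = OPLSDA(scale=False).fit(X, y)
        p = PLSDA(1, scale=False).fit(X, y)
        cos = np.dot(m.t_pred_, p.x_scores_[:, 0]) / (
            np.linalg.norm(m.t_pred_) * np.linalg.norm(p.x_scores_[:, 0])
        )
        assert abs(cos) > 0.999

    def test_s_plot_correlations_bounded(self):
        X, groups, _ = gen_metabolites(MetaboSimSpec(seed=4))
        m = OPLSDA().fit(X.T, groups)
        corr = m.s_plot_["correlation"]
        assert ((corr >= -1 - 1e-12) & (corr <= 1 + 1e-12)).all()

    def test_planted_variables_stand_out_in_s_plot(self):
        X, groups, truth = gen_metabolites(MetaboSimSpec(seed=4))
        m = OPLSDA().fit(X.T, groups)
        corr = m.s_plot_["correlation"].abs()
        null_q90 = corr.drop(index=truth).quantile(0.9)
        assert (corr.loc[truth] > null_q90).all()
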