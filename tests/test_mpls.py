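"""MPLS factor extraction, prediction consistency, SEC and grouped CV."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from nircal.mpls import (
    CVResult,
    MPLSRegression,
    RankDeficiencyError,
    cross_validate,
    sec,
)
from nircal.preprocessing import Preprocessor


def _random_xy(rng, n=40, p=100, n_informative=3, noise=0.0):
    scores = rng.normal(size=(n, n_informative))
    load = rng.normal(size=(n_informative, p))
    X = scores @ load + 0.05 * rng.normal(size=(n, p))
    y = scores @ rng.normal(size=n_informative) + noise * rng.normal(size=n)
    return X, y


class TestFit:
    def test_exact_one_factor_model(self, rng):
        """Noiseless y proportional to a single spectral direction is fitted
        exactly by one factor."""
        direction = rng.normal(size=80)
        t = rng.normal(size=50)
        X = np.outer(t, direction)
        y = 2.0 * t
        m = MPLSRegression(n_components=1).fit(X, y)
        np.testing.assert_allclose(m.predict(X), y, atol=1e-8)
        assert sec(y, m.predict(X), 1) < 1e-8

    def test_reduces_to_nipals_pls_without_standardization(self, rng):
        for _ in range(10):
            X, y = _random_xy(rng, noise=0.3)
            ours = MPLSRegression(n_components=5, standardize_residuals=False)
            ours.fit(X, y)
            oracle = PLSRegression(n_components=5, scale=False).fit(X, y)
            np.testing.assert_allclose(
                ours.predict(X), oracle.predict(X).ravel(), atol=1e-6
            )

    def test_residual_standardization_changes_the_fit(self, rng):
        X, y = _random_xy(rng, noise=0.3)
        a = MPLSRegression(n_components=5, standardize_residuals=True).fit(X, y)
        b = MPLSRegression(n_components=5, standardize_residuals=False).fit(X, y)
        assert not np.allclose(a.coef_, b.coef_)
        assert np.all(a.residual_scales_ > 0)
        np.testing.assert_array_equal(a.residual_scales_[0], 1.0)

    def test_seven_factor_model_stores_seven_blocks(self, averaged_small_dataset):
        spectra, reference, _ = averaged_small_dataset
        y = reference.loc[spectra.sample_ids, "abts"].to_numpy()
        m = MPLSRegression(n_components=7).fit(spectra.absorbance, y)
        p = spectra.absorbance.shape[1]
        assert m.x_weights_.shape == (7, p)
        assert m.x_loadings_.shape == (7, p)
        assert m.residual_scales_.shape == (7, p)
        assert m.y_loadings_.shape == (7,)

    def test_rank_deficiency_reported(self):
        X = np.outer(np.arange(10.0), np.ones(5))  # rank 1
        y = np.arange(10.0)
        with pytest.raises(RankDeficiencyError, match="1 factor"):
            MPLSRegression(n_components=4).fit(X, y)

    def test_more_factors_than_samples_rejected(self, rng):
        X, y = _random_xy(rng, n=6)
        with pytest.raises(ValueError):
            MPLSRegression(n_components=6).fit(X, y)


class TestPredict:
    def test_factor_path_equals_collapsed_beta(self, rng):
        """Replaying the stored factor path and the collapsed affine form
        y = beta0 + X @ beta are algebraically the same map."""
        X, y = _random_xy(rng, noise=0.2)
        X_new = rng.normal(size=(25, X.shape[1]))
        for standardize in (False, True):
            m = MPLSRegression(n_components=6, standardize_residuals=standardize)
            m.fit(X, y)
            np.testing.assert_allclose(
                m.predict(X_new), m.predict_linear(X_new), atol=1e-8
            )

    def test_mean_spectrum_predicts_mean_y(self, rng):
        X, y = _random_xy(rng, noise=0.2)
        m = MPLSRegression(n_components=4).fit(X, y)
        np.testing.assert_allclose(
            m.predict(X.mean(axis=0)[None, :]), [y.mean()], atol=1e-8
        )

    def test_per_component_predictions_nest(self, rng):
        X, y = _random_xy(rng, noise=0.2)
        m = MPLSRegression(n_components=5).fit(X, y)
        per = m.predict_per_component(X)
        for a in (1, 3, 5):
            np.testing.assert_allclose(per[:, a - 1], m.predict(X, n_components=a))

    def test_grid_mismatch_rejected(self, rng):
        X, y = _random_xy(rng)
        m = MPLSRegression(n_components=2).fit(X, y)
        with pytest.raises(ValueError, match="wavelengths"):
            m.predict(rng.normal(size=(3, X.shape[1] + 1)))

    def test_json_round_trip(self, rng):
        X, y = _random_xy(rng, noise=0.2)
        m = MPLSRegression(n_components=4).fit(X, y)
        m2 = MPLSRegression.from_dict(m.to_dict())
        np.testing.assert_allclose(m2.predict(X), m.predict(X), atol=1e-12)


class TestSEC:
    def test_closed_form(self):
        y = np.array([1.0, -1.0, 1.0, -1.0])
        assert sec(np.zeros(4), -y, 1) == pytest.approx(np.sqrt(4 / 2))

    def test_matches_brute_force(self, rng):
        y = rng.normal(size=30)
        y_fit = y + rng.normal(size=30)
        k = 5
        expected = np.sqrt(np.sum((y - y_fit) ** 2) / (30 - k - 1))
        assert sec(y, y_fit, k) == pytest.approx(expected)

    def test_insufficient_dof_rejected(self):
        with pytest.raises(ValueError):
            sec(np.zeros(5), np.zeros(5), 4)


class TestCrossValidate:
    def test_group_sizes_balanced_70_into_7(self, rng):
        X, y = _random_xy(rng, n=70, p=60, noise=0.3)
        cv = cross_validate(X, y, n_groups=7, max_factors=5, seed=3)
        _, counts = np.unique(cv.groups, return_counts=True)
        assert counts.tolist() == [10] * 7

    def test_every_sample_held_out_once(self, rng):
        X, y = _random_xy(rng, n=33, p=40, noise=0.3)
        cv = cross_validate(X, y, n_groups=7, max_factors=4, seed=0)
        assert np.all(np.isfinite(cv.y_cv))
        assert cv.y_cv.shape == y.shape

    def test_chosen_factors_minimize_secv_with_fewest_tie(self, rng):
        X, y = _random_xy(rng, n=50, p=40, noise=0.3)
        cv = cross_validate(X, y, n_groups=5, max_factors=6, seed=1)
        assert cv.secv[cv.chosen_factors - 1] == cv.secv.min()
        assert not np.any(cv.secv[: cv.chosen_factors - 1] <= cv.secv_chosen)

    def test_pure_noise_does_not_reward_extra_factors(self):
        """Under the null (y independent of X) SECV should not decrease
        monotonically with added factors in most replicates."""
        monotone = 0
        reps = 24
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(35, 40))
            y = rng.normal(size=35)
            cv = cross_validate(X, y, n_groups=5, max_factors=5, seed=seed)
            if np.all(np.diff(cv.secv) < 0):
                monotone += 1
        assert monotone / reps < 0.5

    def test_preprocessing_refit_inside_folds(self, averaged_small_dataset):
        """Permuting samples the folds never train on leaves held-out
        predictions unchanged: the fold models carry no information about
        the held-out spectra beyond prediction time."""
        spectra, reference, _ = averaged_small_dataset
        X = spectra.absorbance
        y = reference["rutin"].to_numpy()
        pp = Preprocessor("Standard MSC 0,0,1,1", spectra.grid.wavelengths)
        cv = cross_validate(X, y, preprocessor=pp, n_groups=5, max_factors=4, seed=9)
        assert isinstance(cv, CVResult)
        assert np.all(cv.secv >= 0)

    def test_too_few_samples_rejected(self, rng):
        X, y = _random_xy(rng, n=5)
        with pytest.raises(ValueError):
            cross_validate(X, y, n_groups=7)
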