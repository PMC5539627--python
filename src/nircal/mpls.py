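"""Modified partial least squares (MPLS) regression.

MPLS is the NIPALS PLS1 algorithm with one change: after each factor is
extracted and deflated, the spectral residual at every wavelength is
standardized — each residual column is divided by its standard deviation —
before the next factor is computed.  Down-weighting wavelengths that are
already well explained tends to make the calibration more stable than
standard PLS on NIR data.  With the standardization turned off the
algorithm reduces exactly to NIPALS PLS1, which is used as a cross-check
in the test suite.

The fitted model stores the per-factor weights, loadings and residual
scale vectors so that prediction can replay the factor path on new
spectra, plus the collapsed affine form

    y = beta0 + beta_1 x_l1 + beta_2 x_l2 + ... + beta_P x_lP

obtained by pushing the coordinate basis through that path, which is the
form reported when inspecting which wavelengths drive a calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["MPLSRegression", "sec", "cross_validate", "CVResult"]


class RankDeficiencyError(ValueError):
    """Requested more factors than the data support."""


class MPLSRegression(RegressorMixin, BaseEstimator):
    """Modified PLS regression for a single response.

    Parameters
    ----------
    n_components : int, default 7
        Number of latent factors to extract.
    standardize_residuals : bool, default True
        Divide the X-residual columns by their standard deviation after each
        deflation (the "modified" step).  ``False`` gives standard NIPALS
        PLS1.
    scale_floor : float, default 1e-10
        Residual standard deviations below this floor (relative to the
        largest) are clipped, so fully explained wavelengths do not blow up
        the rescaling.

    Attributes
    ----------
    x_mean_, y_mean_ : centring statistics.
    x_weights_, x_loadings_, y_loadings_ : per-factor NIPALS vectors, shaped
        (n_components, P) / (n_components, P) / (n_components,).
    residual_scales_ : (n_components, P) scale vectors; row ``a`` was applied
        to the residual before extracting factor ``a`` (row 0 is all ones).
    coef_, intercept_ : collapsed affine coefficients (beta, beta0).
    """

    def __init__(self, n_components=7, standardize_residuals=True, scale_floor=1e-10):
        self.n_components = n_components
        self.standardize_residuals = standardize_residuals
        self.scale_floor = scale_floor

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        n, p = X.shape
        if y.shape[0] != n:
            raise ValueError(f"X has {n} rows but y has {y.shape[0]}")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("X and y must be finite")
        a_max = int(self.n_components)
        if a_max < 1:
            raise ValueError("n_components must be >= 1")
        if n <= a_max:
            raise ValueError(
                f"need more samples ({n}) than factors ({a_max})"
            )

        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(y.mean())
        E = X - self.x_mean_
        f = y - self.y_mean_

        W = np.zeros((a_max, p))
        P = np.zeros((a_max, p))
        q = np.zeros(a_max)
        S = np.ones((a_max, p))

        for a in range(a_max):
            if a > 0 and self.standardize_residuals:
                s = E.std(axis=0, ddof=1)
                floor = self.scale_floor * max(s.max(), 1.0)
                S[a] = np.maximum(s, floor)
                E = E / S[a]
            w = E.T @ f
            wnorm = np.linalg.norm(w)
            if wnorm < 1e-12 * max(1.0, np.linalg.norm(f)) or wnorm == 0.0:
                raise RankDeficiencyError(
                    f"data support only {a} factors, {a_max} requested"
                )
            w /= wnorm
            W[a] = w
            t = E @ w
            tt = t @ t
            if tt < 1e-24:
                raise RankDeficiencyError(
                    f"data support only {a} factors, {a_max} requested"
                )
            P[a] = E.T @ t / tt
            q[a] = f @ t / tt
            E = E - np.outer(t, P[a])
            f = f - q[a] * t

        self.x_weights_ = W
        self.x_loadings_ = P
        self.y_loadings_ = q
        self.residual_scales_ = S
        self.n_features_in_ = p
        self.intercept_, self.coef_ = self._collapse()
        return self

    def _replay_scores(self, X, n_components=None):
        """Replay the factor path on (raw) X, returning the score matrix."""
        check_is_fitted(self, "coef_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} wavelengths, got {X.shape[1]}"
            )
        a_max = self.x_loadings_.shape[0] if n_components is None else n_components
        E = X - self.x_mean_
        T = np.zeros((X.shape[0], a_max))
        for a in range(a_max):
            if a > 0 and self.standardize_residuals:
                E = E / self.residual_scales_[a]
            t = E @ self.x_weights_[a]
            T[:, a] = t
            E = E - np.outer(t, self.x_loadings_[a])
        return T

    def predict(self, X, n_components=None):
        """Predict y by replaying the stored factor path."""
        T = self._replay_scores(X, n_components)
        a = T.shape[1]
        return self.y_mean_ + T @ self.y_loadings_[:a]

    def predict_per_component(self, X):
        """Predictions using 1..n_components factors, shaped (N, A)."""
        T = self._replay_scores(X)
        return self.y_mean_ + np.cumsum(T * self.y_loadings_, axis=1)

    def predict_linear(self, X):
        """Predict via the collapsed coefficients beta0 + X @ beta.

        Algebraically identical to :meth:`predict`; kept separate so the
        equivalence can be asserted.
        """
        check_is_fitted(self, "coef_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.intercept_ + X @ self.coef_

    def _collapse(self):
        """Collapse the factor path into (intercept, coefficient vector)."""
        p = self.n_features_in_
        basis = np.vstack([np.zeros(p), np.eye(p)]) + self.x_mean_
        T = self._replay_scores_unchecked(basis)
        preds = self.y_mean_ + T @ self.y_loadings_
        beta = preds[1:] - preds[0]
        beta0 = preds[0] - self.x_mean_ @ beta
        return float(beta0), beta

    def _replay_scores_unchecked(self, X):
        E = X - self.x_mean_
        a_max = self.x_loadings_.shape[0]
        T = np.zeros((X.shape[0], a_max))
        for a in range(a_max):
            if a > 0 and self.standardize_residuals:
                E = E / self.residual_scales_[a]
            t = E @ self.x_weights_[a]
            T[:, a] = t
            E = E - np.outer(t, self.x_loadings_[a])
        return T

    # -- serialization --------------------------------------------------------

    def to_dict(self) -> dict:
        check_is_fitted(self, "coef_")
        return {
            "n_components": int(self.n_components),
            "standardize_residuals": bool(self.standardize_residuals),
            "x_mean": self.x_mean_.tolist(),
            "y_mean": self.y_mean_,
            "x_weights": self.x_weights_.tolist(),
            "x_loadings": self.x_loadings_.tolist(),
            "y_loadings": self.y_loadings_.tolist(),
            "residual_scales": self.residual_scales_.tolist(),
            "intercept": self.intercept_,
            "coef": self.coef_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MPLSRegression":
        m = cls(
            n_components=d["n_components"],
            standardize_residuals=d["standardize_residuals"],
        )
        m.x_mean_ = np.asarray(d["x_mean"], dtype=float)
        m.y_mean_ = float(d["y_mean"])
        m.x_weights_ = np.asarray(d["x_weights"], dtype=float)
        m.x_loadings_ = np.asarray(d["x_loadings"], dtype=float)
        m.y_loadings_ = np.asarray(d["y_loadings"], dtype=float)
        m.residual_scales_ = np.asarray(d["residual_scales"], dtype=float)
        m.intercept_ = float(d["intercept"])
        m.coef_ = np.asarray(d["coef"], dtype=float)
        m.n_features_in_ = m.x_mean_.size
        return m


def sec(y, y_fit, n_factors: int) -> float:
    """Standard error of calibration: sqrt(RSS / (N - n_factors - 1))."""
    y = np.asarray(y, dtype=float).ravel()
    y_fit = np.asarray(y_fit, dtype=float).ravel()
    if y.shape != y_fit.shape:
        raise ValueError("y and y_fit must have equal length")
    n = y.size
    dof = n - n_factors - 1
    if dof <= 0:
        raise ValueError(f"SEC undefined: N={n} with {n_factors} factors")
    return float(np.sqrt(np.sum((y - y_fit) ** 2) / dof))


@dataclass
class CVResult:
    """Grouped cross-validation summary for factor selection.

    ``secv`` holds the root-mean-square cross-validation error for each
    candidate factor count (index a = a+1 factors); ``y_cv`` the held-out
    predictions at the chosen count, aligned with the input samples.
    """

    n_groups: int
    factor_counts: np.ndarray
    secv: np.ndarray
    chosen_factors: int
    y_cv: np.ndarray
    y_cv_per_factor: np.ndarray = field(repr=False, default=None)
    groups: np.ndarray = field(repr=False, default=None)

    @property
    def secv_chosen(self) -> float:
        return float(self.secv[self.chosen_factors - 1])


def _assign_groups(n: int, n_groups: int, rng: np.random.Generator) -> np.ndarray:
    """Random, size-balanced group labels (no contiguity structure)."""
    labels = np.concatenate([np.arange(n_groups)] * (n // n_groups + 1))[:n]
    return labels[rng.permutation(n)]


def cross_validate(
    X,
    y,
    preprocessor=None,
    n_groups: int = 7,
    max_factors: int = 10,
    seed: int = 0,
    standardize_residuals: bool = True,
) -> CVResult:
    """Grouped cross-validation of the full preprocessing + MPLS pipeline.

    Samples are randomly assigned to ``n_groups`` groups; each group is
    predicted by a model fitted on the others.  All calibration-dependent
    statistics — the preprocessing state (e.g. the MSC reference) and the
    MPLS centring/scales — are recomputed inside every fold, so the held-out
    predictions carry no information leakage.  The chosen factor count
    minimizes SECV, with ties resolved toward fewer factors.

    ``X`` is the raw (untreated) spectra matrix when ``preprocessor`` is
    given, otherwise it is used as-is.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < n_groups:
        raise ValueError(f"need at least {n_groups} samples, got {n}")
    max_factors = int(min(max_factors, n - int(np.ceil(n / n_groups)) - 1))
    if max_factors < 1:
        raise ValueError("too few samples for even one factor")

    rng = np.random.default_rng(seed)
    groups = _assign_groups(n, n_groups, rng)

    y_cv = np.full((n, max_factors), np.nan)
    for g in range(n_groups):
        held = groups == g
        Xtr, ytr = X[~held], y[~held]
        Xte = X[held]
        if preprocessor is not None:
            pp = clone_preprocessor(preprocessor)
            Xtr_t = pp.fit_transform(Xtr)
            Xte_t = pp.transform(Xte)
        else:
            Xtr_t, Xte_t = Xtr, Xte
        model = MPLSRegression(
            n_components=max_factors, standardize_residuals=standardize_residuals
        ).fit(Xtr_t, ytr)
        y_cv[held] = model.predict_per_component(Xte_t)

    secv = np.sqrt(np.mean((y_cv - y[:, None]) ** 2, axis=0))
    chosen = int(np.argmin(secv)) + 1  # argmin takes the first min: fewer factors
    return CVResult(
        n_groups=n_groups,
        factor_counts=np.arange(1, max_factors + 1),
        secv=secv,
        chosen_factors=chosen,
        y_cv=y_cv[:, chosen - 1],
        y_cv_per_factor=y_cv,
        groups=groups,
    )


def clone_preprocessor(pp):
    """Fresh unfitted copy of a preprocessor (sklearn clone semantics)."""
    from sklearn.base import clone

    return clone(pp)
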