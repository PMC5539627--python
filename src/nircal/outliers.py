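"""Two-stage calibration-sample screening.

Stage 1 (spectral): samples whose normalized Mahalanobis distance H in
factor-score space exceeds 3 are removed before any regression — they sit
outside the spectral population the model should describe.  Stage 2
(chemical): after fitting, samples whose cross-validated y-residual exceeds
2.5 cross-validation standard errors (the T statistic) are removed — their
reference chemistry disagrees with their spectrum.  Both comparisons are
strict, and each stage runs once (no iteration to convergence) unless
``iterate`` is requested.

H follows the GH convention: the squared Mahalanobis distance divided by
the number of factors k, so E[H] is about 1 for calibration samples and
the fixed threshold 3 is meaningful regardless of k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .mpls import cross_validate, clone_preprocessor


@dataclass
class OutlierReport:
    """Bookkeeping for one screening pass.

    The removed sets are disjoint and ``len(retained_ids) +
    len(removed_by_h) + len(removed_by_t) == N`` always holds.
    """

    sample_ids: list
    h: np.ndarray
    t: np.ndarray
    removed_by_h: list = field(default_factory=list)
    removed_by_t: list = field(default_factory=list)

    def __post_init__(self) -> None:
        overlap = set(self.removed_by_h) & set(self.removed_by_t)
        if overlap:
            raise ValueError(f"samples removed by both criteria: {sorted(overlap)}")
        removed = set(self.removed_by_h) | set(self.removed_by_t)
        unknown = removed - set(self.sample_ids)
        if unknown:
            raise ValueError(f"removed ids not in roster: {sorted(unknown)}")

    @property
    def retained_ids(self) -> list:
        removed = set(self.removed_by_h) | set(self.removed_by_t)
        return [s for s in self.sample_ids if s not in removed]

    @property
    def n_retained(self) -> int:
        return len(self.retained_ids)

    def to_frame(self) -> pd.DataFrame:
        removed_by = []
        for s in self.sample_ids:
            if s in self.removed_by_h:
                removed_by.append("H")
            elif s in self.removed_by_t:
                removed_by.append("T")
            else:
                removed_by.append("")
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "H": self.h, "T": self.t,
             "removed_by": removed_by}
        )


def assemble_report(sample_ids, removed_by_h, removed_by_t) -> OutlierReport:
    """Build a report from explicit removal lists (statistics unknown)."""
    n = len(sample_ids)
    return OutlierReport(
        sample_ids=list(sample_ids),
        h=np.full(n, np.nan),
        t=np.full(n, np.nan),
        removed_by_h=list(removed_by_h),
        removed_by_t=list(removed_by_t),
    )


def global_h(scores: np.ndarray) -> np.ndarray:
    """Normalized (GH) Mahalanobis distance of each sample in score space.

    ``H_i = d_i^2 / k`` where ``d_i`` is the Mahalanobis distance of sample
    i from the score centroid and k the number of score dimensions; the mean
    over calibration samples is ~1.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    n, k = scores.shape
    if n <= k:
        raise ValueError(f"need more samples ({n}) than score dimensions ({k})")
    centred = scores - scores.mean(axis=0)
    cov = centred.T @ centred / (n - 1)
    try:
        sol = np.linalg.solve(cov, centred.T)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular score covariance") from exc
    d2 = np.einsum("ij,ji->i", centred, sol)
    return d2 / k


def leverage_scores(X_treated: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """Scores of the treated calibration spectra on their first k PCs."""
    return PCA(n_components=k, random_state=seed).fit_transform(X_treated)


def t_statistic(y, y_cv_pred, scale: float) -> np.ndarray:
    """Standardized absolute y-residual: |y - y_cv| / scale (scale = SECV)."""
    if scale <= 0:
        raise ValueError(f"scale must be positive, got {scale}")
    y = np.asarray(y, dtype=float).ravel()
    y_cv_pred = np.asarray(y_cv_pred, dtype=float).ravel()
    return np.abs(y - y_cv_pred) / scale


@dataclass
class ScreenResult:
    report: OutlierReport
    X_retained: np.ndarray
    y_retained: np.ndarray
    cv_result: object  # CVResult on the H-retained set


def screen(
    X,
    y,
    sample_ids,
    preprocessor,
    n_factors: int = 8,
    h_threshold: float = 3.0,
    t_threshold: float = 2.5,
    n_groups: int = 7,
    max_factors: int = 10,
    seed: int = 0,
    iterate: bool = False,
) -> ScreenResult:
    """Run the H-then-T screening pass on a calibration set.

    ``X`` is the raw spectra matrix; the preprocessor is fitted on the full
    calibration set for the H stage and refitted on the H-survivors for the
    cross-validated T stage.  ``n_factors`` sets the score dimensionality of
    the H statistic.  Strict inequalities at both thresholds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    ids = list(sample_ids)
    n = X.shape[0]
    if len(ids) != n or y.size != n:
        raise ValueError("X, y and sample_ids must agree in length")

    # Stage 1: spectral outliers via GH on PCA scores of the treated spectra.
    pp = clone_preprocessor(preprocessor)
    Xt = pp.fit_transform(X)
    h = global_h(leverage_scores(Xt, min(n_factors, n - 1, Xt.shape[1])))
    keep_h = h <= h_threshold
    removed_by_h = [ids[i] for i in np.nonzero(~keep_h)[0]]
    if keep_h.sum() < n_factors + 2:
        raise ValueError("H screening removed too many samples to refit")

    # Stage 2: chemical outliers via cross-validated T on the survivors.
    X2, y2 = X[keep_h], y[keep_h]
    ids2 = [ids[i] for i in np.nonzero(keep_h)[0]]
    cv = cross_validate(
        X2, y2, preprocessor=preprocessor, n_groups=n_groups,
        max_factors=max_factors, seed=seed,
    )
    t2 = t_statistic(y2, cv.y_cv, cv.secv_chosen)
    keep_t = t2 <= t_threshold
    removed_by_t = [ids2[i] for i in np.nonzero(~keep_t)[0]]

    t_full = np.full(n, np.nan)
    t_full[np.nonzero(keep_h)[0]] = t2
    report = OutlierReport(
        sample_ids=ids, h=h, t=t_full,
        removed_by_h=removed_by_h, removed_by_t=removed_by_t,
    )
    if report.n_retained == 0:
        raise ValueError("screening eliminated every sample")

    X3, y3 = X2[keep_t], y2[keep_t]
    if iterate and (removed_by_h or removed_by_t):
        ids3 = [s for s in ids2 if s not in removed_by_t]
        inner = screen(
            X3, y3, ids3, preprocessor, n_factors=n_factors,
            h_threshold=h_threshold, t_threshold=t_threshold,
            n_groups=n_groups, max_factors=max_factors, seed=seed,
            iterate=True,
        )
        merged = OutlierReport(
            sample_ids=ids, h=h, t=t_full,
            removed_by_h=removed_by_h + inner.report.removed_by_h,
            removed_by_t=removed_by_t + inner.report.removed_by_t,
        )
        return ScreenResult(merged, inner.X_retained, inner.y_retained, inner.cv_result)
    return ScreenResult(report, X3, y3, cv)
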