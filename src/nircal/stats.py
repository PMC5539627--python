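"""Calibration/validation summary statistics and model diagnostics."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = [
    "rmsep",
    "r_squared",
    "regression_line",
    "paired_t_test",
    "top_beta_wavelengths",
]


def _pair(y_ref, y_nir):
    y_ref = np.asarray(y_ref, dtype=float).ravel()
    y_nir = np.asarray(y_nir, dtype=float).ravel()
    if y_ref.shape != y_nir.shape:
        raise ValueError("reference and predicted vectors must have equal length")
    return y_ref, y_nir


def rmsep(y_ref, y_nir) -> float:
    """Root mean square error of prediction, sqrt(mean((nir - ref)^2))."""
    y_ref, y_nir = _pair(y_ref, y_nir)
    if y_ref.size == 0:
        raise ValueError("RMSEP undefined for empty input")
    return float(np.sqrt(np.mean((y_nir - y_ref) ** 2)))


def r_squared(y_ref, y_nir) -> float:
    """Squared Pearson correlation between reference and predicted values."""
    y_ref, y_nir = _pair(y_ref, y_nir)
    if np.std(y_ref) == 0:
        raise ValueError("R^2 undefined: reference values have zero variance")
    if np.std(y_nir) == 0:
        return 0.0
    r = np.corrcoef(y_ref, y_nir)[0, 1]
    return float(r * r)


def regression_line(y_ref, y_nir):
    """Least-squares line of predicted on reference: C_NIR = slope*C_Ref + b."""
    y_ref, y_nir = _pair(y_ref, y_nir)
    if y_ref.size < 2:
        raise ValueError("need at least two pairs")
    if np.std(y_ref) == 0:
        raise ValueError("degenerate regression: reference has zero variance")
    res = sps.linregress(y_ref, y_nir)
    return float(res.slope), float(res.intercept)


def paired_t_test(y_ref, y_nir) -> float:
    """Two-sided paired Student t-test p-value on the differences.

    Agreement between the two methods is judged at 0.05: p above the
    threshold means no detectable systematic difference.  Degenerate cases:
    identical vectors give p = 1; constant nonzero differences give p -> 0.
    """
    y_ref, y_nir = _pair(y_ref, y_nir)
    if y_ref.size < 2:
        raise ValueError("paired t-test needs at least two pairs")
    d = y_nir - y_ref
    sd = d.std(ddof=1)
    if sd == 0:
        return 1.0 if np.allclose(d, 0) else 0.0
    t = d.mean() / (sd / np.sqrt(d.size))
    return float(2 * sps.t.sf(abs(t), d.size - 1))


def top_beta_wavelengths(model, wavelengths, k: int = 5):
    """The k wavelengths with the largest |beta| in the collapsed model.

    Returns ``[(wavelength, beta), ...]`` sorted by decreasing |beta|;
    ties break toward the lower wavelength.
    """
    beta = np.asarray(model.coef_, dtype=float).ravel()
    wl = np.asarray(wavelengths, dtype=float).ravel()
    if beta.size != wl.size:
        raise ValueError(
            f"model has {beta.size} coefficients but axis has {wl.size} wavelengths"
        )
    if k > beta.size:
        raise ValueError(f"k={k} exceeds {beta.size} wavelengths")
    order = np.lexsort((wl, -np.abs(beta)))[:k]
    return [(float(wl[i]), float(beta[i])) for i in order]
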