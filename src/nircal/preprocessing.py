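"""Spectral pretreatments: scatter correction and gap-segment derivatives.

Treatments are named by a scatter method plus the four-digit WinISI-style
code ``d,g,s1,s2``: derivative order, gap over which each difference is
taken, and the widths (in points) of the running-average smoothing applied
before and after the derivative.  ``"Standard MSC 2,4,4,1"`` therefore means
multiplicative scatter correction followed by a second gap derivative with
gap 4, a 4-point pre-smooth and no second smooth.

All operators act row-wise on an N x P absorbance matrix.  Scatter
correction is applied before the derivative; statistics that depend on the
calibration set (the MSC reference spectrum) are frozen at fit time and
replayed unchanged on validation spectra.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

SCATTER_METHODS = ("none", "msc", "snv", "dt", "snv-dt")

_SCATTER_ALIASES = {
    "none": "none",
    "standard msc": "msc",
    "msc": "msc",
    "snv only": "snv",
    "snv": "snv",
    "detrend only": "dt",
    "detrend": "dt",
    "dt": "dt",
    "snv-dt": "snv-dt",
    "snv dt": "snv-dt",
    "snvdt": "snv-dt",
}

_CANONICAL_WORDS = {
    "none": "None",
    "msc": "Standard MSC",
    "snv": "SNV only",
    "dt": "Detrend only",
    "snv-dt": "SNV-DT",
}


@dataclass(frozen=True)
class PreprocessSpec:
    """A parsed treatment: scatter method plus the d,g,s1,s2 code."""

    scatter: str = "none"
    derivative: int = 0
    gap: int = 0
    smooth1: int = 1
    smooth2: int = 1

    def __post_init__(self) -> None:
        if self.scatter not in SCATTER_METHODS:
            raise ValueError(f"unknown scatter method {self.scatter!r}")
        if self.derivative < 0 or self.gap < 0:
            raise ValueError("derivative order and gap must be non-negative")
        if self.smooth1 < 1 or self.smooth2 < 1:
            raise ValueError("smoothing windows must be >= 1 point")
        if self.derivative > 0 and self.gap < 1:
            raise ValueError("a derivative (d > 0) requires gap >= 1")

    def __str__(self) -> str:
        return (
            f"{_CANONICAL_WORDS[self.scatter]} "
            f"{self.derivative},{self.gap},{self.smooth1},{self.smooth2}"
        )


_TREATMENT_RE = re.compile(
    r"^\s*(?P<words>.*?)\s*(?P<code>\d+\s*,\s*\d+\s*,\s*\d+\s*,\s*\d+)\s*$"
)


def parse_treatment(text: str) -> PreprocessSpec:
    """Parse a treatment string such as ``"Standard MSC 2,4,4,1"``.

    Recognised scatter words: ``Standard MSC``, ``SNV only``, ``Detrend
    only``, ``SNV-DT``, ``None`` (and the bare method names).
    """
    m = _TREATMENT_RE.match(text)
    if not m:
        raise ValueError(
            f"cannot parse treatment {text!r}: expected '<scatter words> d,g,s1,s2'"
        )
    words = m.group("words").strip().lower().replace("–", "-")
    if not words:
        words = "none"
    scatter = _SCATTER_ALIASES.get(words)
    if scatter is None:
        raise ValueError(f"unknown scatter method token {m.group('words')!r}")
    d, g, s1, s2 = (int(t) for t in re.split(r"\s*,\s*", m.group("code")))
    return PreprocessSpec(scatter, d, g, s1, s2)


# -- scatter corrections ------------------------------------------------------

def snv(m: np.ndarray) -> np.ndarray:
    """Standard normal variate: centre each row and scale to unit sample sd.

    Uses the P-1 divisor so a row like [1, 2, 3] maps exactly to [-1, 0, 1].
    """
    m = np.atleast_2d(np.asarray(m, dtype=float))
    mu = m.mean(axis=1, keepdims=True)
    sd = m.std(axis=1, ddof=1, keepdims=True)
    flat = np.nonzero(sd.ravel() < 1e-14)[0]
    if flat.size:
        raise ValueError(f"SNV undefined for constant row {flat[0]}")
    return (m - mu) / sd


def detrend(m: np.ndarray, wavelengths: np.ndarray) -> np.ndarray:
    """Remove a least-squares quadratic baseline in wavelength from each row."""
    m = np.atleast_2d(np.asarray(m, dtype=float))
    wl = np.asarray(wavelengths, dtype=float)
    if wl.size < 3:
        raise ValueError("detrend requires at least 3 points")
    if m.shape[1] != wl.size:
        raise ValueError("matrix width does not match the wavelength axis")
    # orthonormal basis for span{1, wl, wl^2}; residual = projection complement
    span = np.ptp(wl)
    z = (wl - wl.mean()) / (span / 2 if span else 1.0)
    design = np.column_stack([np.ones_like(z), z, z**2])
    q, _ = np.linalg.qr(design)
    return m - (m @ q) @ q.T


def msc(m: np.ndarray, reference: np.ndarray | None = None):
    """Multiplicative scatter correction against a reference spectrum.

    Each row x is regressed as ``x ~ a + b * reference``; the corrected row
    is ``(x - a) / b``.  Returns ``(corrected, coef)`` where ``coef`` is an
    N x 2 array of per-row (offset a, slope b) so validation spectra can be
    corrected with the calibration reference.

    ``reference`` defaults to the column mean of ``m`` itself.
    """
    m = np.atleast_2d(np.asarray(m, dtype=float))
    ref = m.mean(axis=0) if reference is None else np.asarray(reference, dtype=float)
    if ref.std() < 1e-14:
        raise ValueError("MSC reference spectrum has no spread")
    rc = ref - ref.mean()
    denom = rc @ rc
    b = (m - m.mean(axis=1, keepdims=True)) @ rc / denom
    a = m.mean(axis=1) - b * ref.mean()
    small = np.nonzero(np.abs(b) < 1e-12)[0]
    if small.size:
        raise ValueError(f"MSC slope numerically zero for row {small[0]}")
    corrected = (m - a[:, None]) / b[:, None]
    return corrected, np.column_stack([a, b])


# -- derivative / smoothing ---------------------------------------------------

def _running_mean(m: np.ndarray, wl: np.ndarray, s: int):
    if s == 1:
        return m, wl
    if s > m.shape[1]:
        raise ValueError(f"smoothing window {s} exceeds {m.shape[1]} points")
    kernel = np.ones(s) / s
    out = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="valid"), 1, m)
    wl_out = np.convolve(wl, kernel, mode="valid")
    return out, wl_out


def _gap_difference(m: np.ndarray, wl: np.ndarray, g: int):
    if g >= m.shape[1]:
        raise ValueError(f"gap {g} exceeds {m.shape[1]} points")
    out = m[:, g:] - m[:, :-g]
    wl_out = 0.5 * (wl[g:] + wl[:-g])
    return out, wl_out


def gap_segment_derivative(
    m: np.ndarray,
    d: int,
    g: int,
    s1: int = 1,
    s2: int = 1,
    wavelengths: np.ndarray | None = None,
):
    """Norris-style gap derivative with running-average segment smoothing.

    Applies, in order: an ``s1``-point running mean, ``d`` successive gap
    differences ``x[i+g] - x[i]``, and an ``s2``-point running mean.  ``s=1``
    means no smoothing and ``d=0`` no derivative.  Points consumed by the
    windows are dropped, so the output is narrower than the input by
    ``(s1-1) + d*g + (s2-1)`` points.

    Returns ``(matrix, wavelengths)`` where the wavelengths annotate the
    centre of each surviving window.
    """
    m = np.atleast_2d(np.asarray(m, dtype=float))
    wl = (
        np.arange(m.shape[1], dtype=float)
        if wavelengths is None
        else np.asarray(wavelengths, dtype=float)
    )
    spec = PreprocessSpec("none", d, g, s1, s2)  # reuse the invariants
    lost = (spec.smooth1 - 1) + spec.derivative * spec.gap + (spec.smooth2 - 1)
    if lost >= m.shape[1]:
        raise ValueError(
            f"treatment consumes {lost} points but spectra have only {m.shape[1]}"
        )
    m, wl = _running_mean(m, wl, s1)
    for _ in range(d):
        m, wl = _gap_difference(m, wl, g)
    m, wl = _running_mean(m, wl, s2)
    return m, wl


# -- the combined treatment as a (fit/transform) estimator --------------------

class Preprocessor(TransformerMixin, BaseEstimator):
    """Apply a full treatment (scatter correction + derivative/smoothing).

    Parameters
    ----------
    treatment : str or PreprocessSpec, default ``"None 0,0,1,1"``
        The treatment to apply; strings are parsed with
        :func:`parse_treatment`.
    wavelengths : array-like, optional
        Wavelength axis of the input columns; required for detrend and used
        to annotate the output axis.

    Attributes
    ----------
    spec_ : PreprocessSpec
        The parsed treatment.
    msc_reference_ : ndarray or None
        The calibration mean spectrum frozen at fit time (MSC only).
    output_wavelengths_ : ndarray
        Wavelength axis of the transformed matrix (edges consumed by the
        derivative/smoothing windows are dropped).
    """

    def __init__(self, treatment="None 0,0,1,1", wavelengths=None):
        self.treatment = treatment
        self.wavelengths = wavelengths

    def _spec(self) -> PreprocessSpec:
        if isinstance(self.treatment, PreprocessSpec):
            return self.treatment
        return parse_treatment(self.treatment)

    def _wl(self, n_cols: int) -> np.ndarray:
        if self.wavelengths is None:
            return np.arange(n_cols, dtype=float)
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.size != n_cols:
            raise ValueError(
                f"wavelengths has {wl.size} entries but spectra have {n_cols} columns"
            )
        return wl

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        self.spec_ = self._spec()
        self.n_features_in_ = X.shape[1]
        self.msc_reference_ = X.mean(axis=0) if self.spec_.scatter == "msc" else None
        _, self.output_wavelengths_ = gap_segment_derivative(
            X[:1],
            self.spec_.derivative,
            self.spec_.gap,
            self.spec_.smooth1,
            self.spec_.smooth2,
            self._wl(X.shape[1]),
        )
        return self

    def transform(self, X):
        if not hasattr(self, "spec_"):
            raise RuntimeError("Preprocessor must be fitted before transform")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} wavelengths, got {X.shape[1]}"
            )
        wl = self._wl(X.shape[1])
        spec = self.spec_
        if spec.scatter == "msc":
            X, _ = msc(X, self.msc_reference_)
        elif spec.scatter == "snv":
            X = snv(X)
        elif spec.scatter == "dt":
            X = detrend(X, wl)
        elif spec.scatter == "snv-dt":
            X = detrend(snv(X), wl)
        X, _ = gap_segment_derivative(
            X, spec.derivative, spec.gap, spec.smooth1, spec.smooth2, wl
        )
        return X


def apply_treatment(spec, m, wavelengths=None, calibration_reference=None):
    """One-shot functional form of :class:`Preprocessor`.

    ``calibration_reference`` (a matrix) supplies the frozen MSC statistics;
    it defaults to ``m`` itself.
    """
    pp = Preprocessor(treatment=spec, wavelengths=wavelengths)
    pp.fit(m if calibration_reference is None else calibration_reference)
    return pp.transform(m), pp.output_wavelengths_
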