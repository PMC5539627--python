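"""Spectrophotometric reference-assay arithmetic.

These are the wet-lab-side calculations that produce the reference values a
NIR calibration is trained against: linear standard curves for quercetin,
rutin, pinocembrin and Trolox; conversion of measured absorbance into
mg analyte per g propolis; the Trolox-equivalent antioxidant capacity
(TEAC) from ABTS radical scavenging; and the % inhibition of the linoleic
acid/beta-carotene bleaching assay,

    inhibition = 100 * (A0 - A1) / A0,

with A0 the absorbance at time zero and A1 after 60 min at 470 nm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

ANALYTES = ("quercetin", "rutin", "pinocembrin", "trolox")


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares line of instrument response against concentration."""

    analyte: str
    slope: float
    intercept: float
    r2: float
    conc_min: float
    conc_max: float

    def response(self, concentration):
        return self.intercept + self.slope * np.asarray(concentration, dtype=float)

    def invert(self, response):
        """Concentration at a given response (inverse evaluation)."""
        return (np.asarray(response, dtype=float) - self.intercept) / self.slope


@dataclass(frozen=True)
class AbsorbancePair:
    """Absorbance at time zero (A0 > 0) and after 60 minutes (A1 >= 0)."""

    a0: float
    a1: float

    def __post_init__(self) -> None:
        if self.a0 <= 0:
            raise ValueError(f"A0 must be positive, got {self.a0}")
        if self.a1 < 0:
            raise ValueError(f"A1 must be non-negative, got {self.a1}")


def fit_standard_curve(concentrations, responses, analyte: str = "quercetin") -> StandardCurve:
    """Fit a calibration line from >= 3 distinct concentration points."""
    c = np.asarray(concentrations, dtype=float).ravel()
    r = np.asarray(responses, dtype=float).ravel()
    if c.size != r.size:
        raise ValueError("concentrations and responses must have equal length")
    if np.unique(c).size < 3:
        raise ValueError("standard curve needs at least 3 distinct concentrations")
    res = sps.linregress(c, r)
    if abs(res.slope) < 1e-15:
        raise ValueError("degenerate standard curve: zero slope")
    return StandardCurve(
        analyte=analyte,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        conc_min=float(c.min()),
        conc_max=float(c.max()),
    )


def quantify(
    absorbance,
    curve: StandardCurve,
    dilution_factor: float = 100.0,
    mass_basis_g: float = 1.0,
):
    """Convert absorbance to mg analyte per g sample via a standard curve.

    The extract is assumed diluted ``dilution_factor``-fold (1:100 by
    default) from ``mass_basis_g`` grams of sample, so the curve
    concentration is scaled back up accordingly.  Warns when the absorbance
    falls outside the fitted range of the curve.
    """
    a = np.asarray(absorbance, dtype=float)
    lo, hi = sorted((curve.response(curve.conc_min), curve.response(curve.conc_max)))
    if np.any(a < lo - 1e-12) or np.any(a > hi + 1e-12):
        warnings.warn(
            f"absorbance outside the fitted range of the {curve.analyte} curve; "
            "extrapolating",
            stacklevel=2,
        )
    conc = curve.invert(a)
    return conc * dilution_factor / mass_basis_g


def simulate_absorbance(
    concentration,
    curve: StandardCurve,
    dilution_factor: float = 100.0,
    mass_basis_g: float = 1.0,
):
    """Forward model of :func:`quantify` (exact inverse, used for checks)."""
    c = np.asarray(concentration, dtype=float)
    return curve.response(c * mass_basis_g / dilution_factor)


def percent_inhibition(pair_or_a0, a1: float | None = None) -> float:
    """Antioxidant activity of the beta-carotene bleaching assay in percent.

    ``100 * (A0 - A1) / A0``; invariant to rescaling both absorbances and
    monotone decreasing in A1.
    """
    if a1 is None:
        pair = pair_or_a0
    else:
        pair = AbsorbancePair(float(pair_or_a0), float(a1))
    return 100.0 * (pair.a0 - pair.a1) / pair.a0


def abts_endpoint(inhibition_by_minute, minute: int = 10) -> float:
    """Summarize an ABTS kinetic series by its endpoint read.

    ``inhibition_by_minute`` holds one % inhibition value per minute
    (minute 1 first); the assay records one read per minute for 10 minutes
    and the value entering the Trolox plot is the configured endpoint
    (default minute 10).
    """
    series = np.asarray(inhibition_by_minute, dtype=float).ravel()
    if not 1 <= minute <= series.size:
        raise ValueError(
            f"endpoint minute {minute} outside the recorded 1..{series.size}"
        )
    return float(series[minute - 1])


def teac(
    inhibition_percent,
    trolox_curve: StandardCurve,
    sample_mass_mg: float = 1.0,
):
    """Trolox-equivalent antioxidant capacity in nmol Trolox / mg sample.

    The Trolox curve maps Trolox amount (nmol) to % inhibition of the ABTS
    radical; TEAC inverse-evaluates it at the sample's % inhibition and
    normalizes by sample mass.  Responses outside the fitted curve range are
    extrapolated with a warning.
    """
    resp = np.asarray(inhibition_percent, dtype=float)
    lo, hi = sorted(
        (trolox_curve.response(trolox_curve.conc_min),
         trolox_curve.response(trolox_curve.conc_max))
    )
    if np.any(resp < lo - 1e-12) or np.any(resp > hi + 1e-12):
        warnings.warn(
            "inhibition outside the fitted Trolox curve range; extrapolating",
            stacklevel=2,
        )
    if sample_mass_mg <= 0:
        raise ValueError("sample mass must be positive")
    return trolox_curve.invert(resp) / sample_mass_mg
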