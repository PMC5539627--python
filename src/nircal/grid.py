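"""Wavelength grid for NIR absorbance spectra.

Spectra are recorded as log(1/R) on an evenly spaced wavelength axis;
the instrument configuration emulated here covers 1100-2000 nm at 2 nm
steps (451 points).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_START_NM = 1100.0
DEFAULT_END_NM = 2000.0
DEFAULT_STEP_NM = 2.0


@dataclass(frozen=True)
class WavelengthGrid:
    """Evenly spaced wavelength axis in nanometres.

    Parameters
    ----------
    start_nm, end_nm : float
        First and last wavelength; ``start_nm < end_nm``.
    step_nm : float
        Positive increment; ``(end_nm - start_nm) / step_nm`` must be an
        integer so the grid closes exactly on ``end_nm``.
    """

    start_nm: float = DEFAULT_START_NM
    end_nm: float = DEFAULT_END_NM
    step_nm: float = DEFAULT_STEP_NM

    def __post_init__(self) -> None:
        if not self.start_nm < self.end_nm:
            raise ValueError(
                f"start_nm ({self.start_nm}) must be < end_nm ({self.end_nm})"
            )
        if self.step_nm <= 0:
            raise ValueError(f"step_nm must be positive, got {self.step_nm}")
        span = (self.end_nm - self.start_nm) / self.step_nm
        if abs(span - round(span)) > 1e-9:
            raise ValueError(
                f"grid does not close: ({self.start_nm}..{self.end_nm}) "
                f"is not a whole number of {self.step_nm} nm steps"
            )

    @property
    def n_points(self) -> int:
        return int(round((self.end_nm - self.start_nm) / self.step_nm)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(self.n_points)

    @classmethod
    def from_wavelengths(cls, wl: np.ndarray) -> "WavelengthGrid":
        """Infer a grid from an explicit, evenly spaced wavelength vector."""
        wl = np.asarray(wl, dtype=float)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("need at least two wavelengths")
        diffs = np.diff(wl)
        if np.any(diffs <= 0):
            bad = int(np.argmax(diffs <= 0))
            raise ValueError(
                f"wavelengths not strictly increasing at index {bad} "
                f"({wl[bad]} -> {wl[bad + 1]})"
            )
        step = diffs[0]
        if not np.allclose(diffs, step, rtol=0, atol=1e-6 * step):
            raise ValueError("wavelengths are not evenly spaced")
        return cls(float(wl[0]), float(wl[-1]), float(step))


DEFAULT_GRID = WavelengthGrid()
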