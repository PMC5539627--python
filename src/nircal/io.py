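"""Spectra and reference-table I/O, replicate averaging and the
calibration/validation split.

CSV layout for spectra: first row is the wavelength header, first column
the sample id, optional second column a replicate id, remaining cells the
absorbance values (log 1/R).  Reference tables are plain CSV keyed by
sample id with one column per constituent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .grid import WavelengthGrid

# Constituent labels as they appear in reference-table headers, keyed by the
# short names used throughout the package.
CONSTITUENT_LABELS = {
    "quercetin": "Total flavones + flavonols (mg quercetin/g propolis)",
    "rutin": "Total flavones + flavonols (mg rutin/g propolis)",
    "pinocembrin": "Total flavanones + dihydroflavonols (mg pinocembrin/g propolis extract)",
    "abts": "ABTS (nmol Trolox/mg propolis)",
    "inhibition": "Linoleic acid/beta-carotene (% inhibition)",
}
CONSTITUENTS = tuple(CONSTITUENT_LABELS)
_LABEL_TO_SHORT = {v: k for k, v in CONSTITUENT_LABELS.items()}


class SpectraFormatError(ValueError):
    """Raised when a spectra file violates the expected layout."""


@dataclass
class SpectraSet:
    """A matrix of absorbance spectra on a shared wavelength grid.

    ``absorbance`` is N x P with one row per spectrum; ``sample_ids`` has one
    entry per row and ``replicate_ids`` (optional) distinguishes repeated
    scans of the same sample.
    """

    grid: WavelengthGrid
    absorbance: np.ndarray
    sample_ids: list = field(default_factory=list)
    replicate_ids: Optional[list] = None

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.ndim != 2:
            raise ValueError("absorbance must be 2-D (samples x wavelengths)")
        n, p = self.absorbance.shape
        if p != self.grid.n_points:
            raise ValueError(
                f"absorbance has {p} columns but grid has {self.grid.n_points} points"
            )
        if len(self.sample_ids) != n:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n} spectra rows"
            )
        if self.replicate_ids is not None and len(self.replicate_ids) != n:
            raise ValueError("replicate_ids length must match row count")
        if not np.all(np.isfinite(self.absorbance)):
            bad = int(np.argwhere(~np.isfinite(self.absorbance))[0, 0])
            raise SpectraFormatError(
                f"non-finite absorbance in row {bad} (sample {self.sample_ids[bad]!r})"
            )

    @property
    def n_spectra(self) -> int:
        return self.absorbance.shape[0]

    def select(self, ids: Sequence) -> "SpectraSet":
        """Subset rows whose sample id is in ``ids`` (order of ``ids``)."""
        wanted = list(ids)
        rows: list[int] = []
        for sid in wanted:
            hits = [i for i, s in enumerate(self.sample_ids) if s == sid]
            if not hits:
                raise KeyError(f"sample id {sid!r} not present")
            rows.extend(hits)
        return SpectraSet(
            grid=self.grid,
            absorbance=self.absorbance[rows],
            sample_ids=[self.sample_ids[i] for i in rows],
            replicate_ids=None
            if self.replicate_ids is None
            else [self.replicate_ids[i] for i in rows],
        )


def read_spectra(path, format: str = "csv") -> SpectraSet:
    """Read a :class:`SpectraSet` from CSV or JCAMP-DX."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        return _read_spectra_csv(path)
    if format == "jcamp":
        return _read_spectra_jcamp(path)
    raise ValueError(f"unknown spectra format {format!r}")


def _read_spectra_csv(path: Path) -> SpectraSet:
    df = pd.read_csv(path, header=0, dtype=str)
    cols = list(df.columns)

    def _is_number(s: str) -> bool:
        try:
            float(s)
            return True
        except (TypeError, ValueError):
            return False

    n_id_cols = 0
    while n_id_cols < len(cols) and not _is_number(cols[n_id_cols]):
        n_id_cols += 1
    if n_id_cols == 0 or n_id_cols > 2:
        raise SpectraFormatError(
            f"{path}: expected 1-2 leading id columns, found {n_id_cols}"
        )
    wl = np.array([float(c) for c in cols[n_id_cols:]])
    if wl.size != np.unique(wl).size:
        dup = wl[pd.Series(wl).duplicated().to_numpy()][0]
        raise SpectraFormatError(f"{path}: wavelength column {dup} repeated")
    try:
        grid = WavelengthGrid.from_wavelengths(wl)
    except ValueError as exc:
        raise SpectraFormatError(f"{path}: {exc}") from exc

    values = df.iloc[:, n_id_cols:]
    try:
        absorbance = values.astype(float).to_numpy()
    except ValueError as exc:
        raise SpectraFormatError(f"{path}: non-numeric absorbance ({exc})") from exc
    if not np.all(np.isfinite(absorbance)):
        row = int(np.argwhere(~np.isfinite(absorbance))[0, 0])
        raise SpectraFormatError(f"{path}: NaN/inf absorbance in data row {row}")

    sample_ids = df.iloc[:, 0].tolist()
    replicate_ids = df.iloc[:, 1].tolist() if n_id_cols == 2 else None
    return SpectraSet(grid, absorbance, sample_ids, replicate_ids)


def write_spectra(s: SpectraSet, path) -> None:
    """Write spectra in the CSV layout :func:`read_spectra` accepts."""
    wl = s.grid.wavelengths
    cols = {"sample_id": s.sample_ids}
    if s.replicate_ids is not None:
        cols["replicate_id"] = s.replicate_ids
    df = pd.DataFrame(cols)
    spec = pd.DataFrame(s.absorbance, columns=[_format_wl(w) for w in wl])
    pd.concat([df, spec], axis=1).to_csv(path, index=False)


def _format_wl(w: float) -> str:
    return f"{w:g}"


# -- JCAMP-DX -----------------------------------------------------------------
# Minimal AFFN reader/writer for single-spectrum files using the
# XYDATA=(X++(Y..Y)) form; enough for instrument-export round trips.

def _read_spectra_jcamp(path: Path) -> SpectraSet:
    header: dict[str, str] = {}
    ydata: list[float] = []
    in_table = False
    title = path.stem
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, val = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            val = val.strip()
            if key == "TITLE":
                title = val or title
            if key == "XYDATA":
                in_table = True
                continue
            if key == "END":
                in_table = False
            header[key] = val
            continue
        if in_table:
            toks = re.split(r"[,\s]+", line)
            # first token is the leading X of the line; the rest are Y values
            ydata.extend(float(t) for t in toks[1:])
    for req in ("FIRSTX", "DELTAX", "NPOINTS"):
        if req not in header:
            raise SpectraFormatError(f"{path}: missing ##{req}= record")
    firstx = float(header["FIRSTX"])
    deltax = float(header["DELTAX"])
    npoints = int(float(header["NPOINTS"]))
    if deltax <= 0:
        raise SpectraFormatError(f"{path}: DELTAX must be positive (got {deltax})")
    if len(ydata) != npoints:
        raise SpectraFormatError(
            f"{path}: NPOINTS={npoints} but table holds {len(ydata)} values"
        )
    yfactor = float(header.get("YFACTOR", "1"))
    xfactor = float(header.get("XFACTOR", "1"))
    y = np.asarray(ydata) * yfactor
    grid = WavelengthGrid(
        firstx * xfactor,
        (firstx + deltax * (npoints - 1)) * xfactor,
        deltax * xfactor,
    )
    return SpectraSet(grid, y[None, :], [title])


def write_jcamp(s: SpectraSet, path, row: int = 0) -> None:
    """Write one spectrum row as a minimal AFFN JCAMP-DX file."""
    wl = s.grid.wavelengths
    y = s.absorbance[row]
    lines = [
        f"##TITLE={s.sample_ids[row]}",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=NEAR INFRARED SPECTRUM",
        "##XUNITS=NANOMETERS",
        "##YUNITS=ABSORBANCE",
        f"##FIRSTX={wl[0]:g}",
        f"##LASTX={wl[-1]:g}",
        f"##DELTAX={s.grid.step_nm:g}",
        f"##NPOINTS={len(y)}",
        "##XFACTOR=1",
        "##YFACTOR=1",
        "##XYDATA=(X++(Y..Y))",
    ]
    per_line = 6
    for i in range(0, len(y), per_line):
        chunk = y[i : i + per_line]
        lines.append(" ".join([f"{wl[i]:g}"] + [repr(float(v)) for v in chunk]))
    lines.append("##END=")
    Path(path).write_text("\n".join(lines) + "\n")


# -- reference tables ---------------------------------------------------------

def read_reference(path) -> pd.DataFrame:
    """Read a per-sample constituent table.

    Returns a DataFrame indexed by sample id with short constituent names as
    columns; full header labels (see :data:`CONSTITUENT_LABELS`) are mapped
    back to the short names.
    """
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df = df.rename(columns=lambda c: _LABEL_TO_SHORT.get(c.strip(), c.strip()))
    _validate_reference(df)
    return df


def write_reference(ref: pd.DataFrame, path) -> None:
    out = ref.rename(columns=CONSTITUENT_LABELS)
    out.index.name = "sample_id"
    out.to_csv(path)


def _validate_reference(ref: pd.DataFrame) -> None:
    for col in ref.columns:
        v = ref[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError(f"reference column {col!r} contains non-finite values")
        if col == "inhibition":
            if np.any(v < 0) or np.any(v > 100):
                raise ValueError("% inhibition must lie in [0, 100]")
        elif col in CONSTITUENT_LABELS and np.any(v < 0):
            raise ValueError(f"constituent {col!r} must be non-negative")


# -- replicate averaging and the calibration/validation split ----------------

def average_replicates(s: SpectraSet) -> SpectraSet:
    """Average replicate scans into one spectrum per sample.

    Requires ``replicate_ids``; output rows follow the order in which sample
    ids first appear.
    """
    if s.replicate_ids is None:
        raise ValueError("average_replicates requires replicate_ids")
    order: list = []
    groups: dict = {}
    for i, sid in enumerate(s.sample_ids):
        if sid not in groups:
            groups[sid] = []
            order.append(sid)
        groups[sid].append(i)
    means = np.vstack([s.absorbance[groups[sid]].mean(axis=0) for sid in order])
    return SpectraSet(s.grid, means, order, None)


def split_calibration_validation(
    s: SpectraSet,
    reference: pd.DataFrame,
    n_cal: int,
    seed: int,
):
    """Randomly partition samples into calibration and validation sets.

    Returns ``((cal_spectra, cal_reference), (val_spectra, val_reference))``.
    The partition is disjoint and exhaustive and reproducible for a fixed
    ``seed``.
    """
    ids = list(dict.fromkeys(s.sample_ids))
    n = len(ids)
    if n_cal >= n:
        raise ValueError(f"n_cal ({n_cal}) must be smaller than N ({n})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    cal_ids = [ids[i] for i in sorted(perm[:n_cal])]
    val_ids = [ids[i] for i in sorted(perm[n_cal:])]
    cal = (s.select(cal_ids), reference.loc[cal_ids])
    val = (s.select(val_ids), reference.loc[val_ids])
    return cal, val
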