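"""Synthetic propolis NIR datasets with known ground truth.

The generator emulates the statistical structure the calibration pipeline
assumes rather than the radiative physics of a real instrument: each sample
is a linear (Beer-Lambert) mixture of a few surrogate pure-component
spectra — a "flavone" component carrying the flavones/flavonols signal, a
"flavanone" component for flavanones/dihydroflavonols, and an inert
"matrix/wax" component — on the 1100-2000 nm grid, plus a per-sample
quadratic baseline drift.  Each of the three replicate scans then receives
its own multiplicative scatter (offset + slope) and additive white noise,
which is what MSC/SNV/detrend corrections are designed to undo.

Reference chemistry: the flavonoid constituents are affine in the latent
component concentrations (quercetin- and rutin-equivalents share the
flavone latent, mirroring two standards quantifying one flavonoid class),
and the two antioxidant measures (ABTS TEAC and beta-carotene % inhibition)
are noisy linear combinations of the flavonoid latents — antioxidant
capacity tracks phenolic composition.  Ranges default to those observed
across the Galicia / Castilla y Leon / Bio-Bio sample sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .grid import WavelengthGrid, DEFAULT_GRID
from .io import SpectraSet, CONSTITUENTS


@dataclass(frozen=True)
class Band:
    """One Gaussian absorption band."""

    center_nm: float
    width_nm: float
    amplitude: float = 1.0


# Broad bulk-absorption bands shared by every sample: the ground propolis
# matrix dominates the raw absorbance, and the constituent signals ride on
# top of it as minor perturbations (mg/g-level analytes).  A dominant common
# background is also what makes MSC/SNV well-posed: the per-spectrum scale
# they estimate then reflects scatter, not composition.
DEFAULT_BACKGROUND: tuple[Band, ...] = (
    Band(1206.0, 150.0, 0.45),
    Band(1452.0, 120.0, 1.0),
    Band(1726.0, 110.0, 0.6),
    Band(1934.0, 140.0, 0.85),
)

# Surrogate analyte bands are kept narrow (~20 nm) relative to the broad
# matrix background so that gap-derivative treatments retain analyte signal
# while flattening the background — the regime derivative pretreatments
# are designed for.
DEFAULT_COMPONENTS: dict[str, tuple[Band, ...]] = {
    "flavone": (
        Band(1414.0, 18.0, 0.6),
        Band(1690.0, 22.0, 1.0),
        Band(1928.0, 20.0, 0.7),
    ),
    "flavanone": (
        Band(1204.0, 16.0, 0.5),
        Band(1520.0, 20.0, 1.0),
        Band(1760.0, 24.0, 0.6),
    ),
    "matrix": (
        Band(1390.0, 60.0, 0.8),
        Band(1640.0, 45.0, 1.0),
        Band(1860.0, 55.0, 0.5),
    ),
}

# Constituent value ranges (units as in the reference table).
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "quercetin": (0.0, 63.3),     # mg quercetin / g propolis
    "rutin": (0.0, 161.1),        # mg rutin / g propolis
    "pinocembrin": (27.0, 149.7), # mg pinocembrin / g propolis extract
    "abts": (641.2, 8215.4),      # nmol Trolox / mg propolis
    "inhibition": (22.0, 88.0),   # % inhibition
}

# Region means of the latent (0-1) flavone / flavanone / matrix levels for
# the optional three-cluster mode.
REGION_LATENT_MEANS = {
    "galicia": (0.40, 0.30, 0.55),
    "castilla_y_leon": (0.55, 0.40, 0.45),
    "bio_bio": (0.38, 0.65, 0.50),
}
REGION_WEIGHTS = {"galicia": 14, "castilla_y_leon": 33, "bio_bio": 52}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one simulated dataset.

    Defaults mirror the emulated study: 99 samples scanned in triplicate on
    a 1100-2000 nm / 2 nm grid, with mild multiplicative scatter, quadratic
    baseline drift and 0.005 AU additive noise.
    """

    n_samples: int = 99
    n_replicates: int = 3
    grid: WavelengthGrid = DEFAULT_GRID
    components: dict = field(default_factory=lambda: dict(DEFAULT_COMPONENTS))
    component_amplitudes: dict = field(
        default_factory=lambda: {"flavone": 0.15, "flavanone": 0.15, "matrix": 0.10}
    )
    background_bands: tuple = DEFAULT_BACKGROUND
    background_amplitude: float = 0.8
    ranges: dict = field(default_factory=lambda: dict(DEFAULT_RANGES))
    scatter: bool = True
    scatter_slope_range: tuple = (0.9, 1.1)
    scatter_offset_range: tuple = (-0.05, 0.05)
    baseline_offset_range: tuple = (0.0, 0.1)
    baseline_slope_range: tuple = (-0.05, 0.05)
    baseline_curvature_range: tuple = (-0.05, 0.05)
    noise_sd: float = 0.005
    rutin_latent_noise: float = 0.02
    antioxidant_weights: dict = field(
        default_factory=lambda: {
            "abts": (0.7, 0.3),        # (flavone, flavanone) weights
            "inhibition": (0.5, 0.5),
        }
    )
    antioxidant_latent_noise: float = 0.03
    region_clusters: bool = False
    region_latent_sd: float = 0.12


def make_pure_spectra(config: SyntheticConfig) -> dict[str, np.ndarray]:
    """Unit-peak pure-component spectra as sums of Gaussian bands."""
    wl = config.grid.wavelengths
    out = {}
    for name, bands in config.components.items():
        spec = np.zeros_like(wl)
        peak = 0.0
        for band in bands:
            if not (config.grid.start_nm <= band.center_nm <= config.grid.end_nm):
                raise ValueError(
                    f"band at {band.center_nm} nm lies outside the grid "
                    f"({config.grid.start_nm}-{config.grid.end_nm} nm)"
                )
            spec = spec + band.amplitude * np.exp(
                -0.5 * ((wl - band.center_nm) / band.width_nm) ** 2
            )
            peak = max(peak, band.amplitude)
        if spec.max() > 0:
            spec = spec / spec.max()
        out[name] = spec
    return out


def _draw_latents(config: SyntheticConfig, rng: np.random.Generator):
    n = config.n_samples
    names = list(config.components)
    if not config.region_clusters:
        u = rng.uniform(0.0, 1.0, size=(n, len(names)))
        regions = np.array(["pooled"] * n)
        return u, regions
    region_names = list(REGION_LATENT_MEANS)
    w = np.array([REGION_WEIGHTS[r] for r in region_names], dtype=float)
    regions = rng.choice(region_names, size=n, p=w / w.sum())
    u = np.empty((n, len(names)))
    for i, r in enumerate(regions):
        mu = np.asarray(REGION_LATENT_MEANS[r][: len(names)])
        u[i] = np.clip(rng.normal(mu, config.region_latent_sd), 0.0, 1.0)
    return u, regions


def simulate_dataset(config: SyntheticConfig, seed: int):
    """Simulate spectra (with replicates), a reference table and the truth.

    Returns ``(SpectraSet, reference DataFrame, truth dict)``.  The truth
    record stores the latent concentrations, the per-sample baseline and the
    per-replicate scatter so tests can score recovery exactly.  Everything
    is a pure function of ``(config, seed)``.
    """
    rng = np.random.default_rng(seed)
    wl = config.grid.wavelengths
    pure = make_pure_spectra(config)
    names = list(config.components)
    u, regions = _draw_latents(config, rng)
    n = config.n_samples

    # reference chemistry from the latents
    def span(key):
        lo, hi = config.ranges[key]
        return lo, hi - lo

    u_f = u[:, names.index("flavone")] if "flavone" in names else u[:, 0]
    u_fn = u[:, names.index("flavanone")] if "flavanone" in names else u[:, -1]

    ref = {}
    lo, d = span("quercetin")
    ref["quercetin"] = lo + d * u_f
    lo, d = span("rutin")
    u_r = np.clip(u_f + rng.normal(0, config.rutin_latent_noise, n), 0, 1)
    ref["rutin"] = lo + d * u_r
    lo, d = span("pinocembrin")
    ref["pinocembrin"] = lo + d * u_fn
    for key in ("abts", "inhibition"):
        wf, wfn = config.antioxidant_weights[key]
        mix = (wf * u_f + wfn * u_fn) / (wf + wfn)
        mix = np.clip(mix + rng.normal(0, config.antioxidant_latent_noise, n), 0, 1)
        lo, d = span(key)
        ref[key] = lo + d * mix
    reference = pd.DataFrame(ref, index=[f"S{i + 1:03d}" for i in range(n)])
    reference = reference[[c for c in CONSTITUENTS if c in reference.columns]]
    reference.index.name = "sample_id"

    # clean sample spectra: common background + linear mixture + baseline
    z = (wl - wl.mean()) / ((wl[-1] - wl[0]) / 2)
    background = np.zeros_like(wl)
    for band in config.background_bands:
        background = background + band.amplitude * np.exp(
            -0.5 * ((wl - band.center_nm) / band.width_nm) ** 2
        )
    if background.max() > 0:
        background = config.background_amplitude * background / background.max()
    amps = np.array([config.component_amplitudes[nm] for nm in names])
    clean = background + (u * amps) @ np.vstack([pure[nm] for nm in names])
    b0 = rng.uniform(*config.baseline_offset_range, n)
    b1 = rng.uniform(*config.baseline_slope_range, n)
    b2 = rng.uniform(*config.baseline_curvature_range, n)
    clean = clean + b0[:, None] + b1[:, None] * z + b2[:, None] * z**2

    # replicate scans: multiplicative scatter + white noise
    n_rep = config.n_replicates
    rows, sample_ids, replicate_ids = [], [], []
    scatter_a = np.zeros((n, n_rep))
    scatter_b = np.ones((n, n_rep))
    if config.scatter:
        scatter_a = rng.uniform(*config.scatter_offset_range, (n, n_rep))
        scatter_b = rng.uniform(*config.scatter_slope_range, (n, n_rep))
    noise = (
        rng.normal(0.0, config.noise_sd, (n, n_rep, wl.size))
        if config.noise_sd > 0
        else np.zeros((n, n_rep, wl.size))
    )
    for i, sid in enumerate(reference.index):
        for r in range(n_rep):
            rows.append(scatter_a[i, r] + scatter_b[i, r] * clean[i] + noise[i, r])
            sample_ids.append(sid)
            replicate_ids.append(f"r{r + 1}")
    spectra = SpectraSet(config.grid, np.vstack(rows), sample_ids, replicate_ids)

    truth = {
        "latents": {nm: u[:, j].copy() for j, nm in enumerate(names)},
        "regions": regions,
        "baseline": np.column_stack([b0, b1, b2]),
        "scatter_offset": scatter_a,
        "scatter_slope": scatter_b,
        "pure_spectra": pure,
        "config": config,
        "seed": seed,
    }
    return spectra, reference, truth


def inject_outliers(
    spectra: SpectraSet,
    reference: pd.DataFrame,
    n_spectral: int,
    n_chemical: int,
    seed: int,
    constituent: str = "quercetin",
):
    """Corrupt a dataset with spectral and chemical outliers.

    Spectral outliers have the multiplicative scatter slope of every
    replicate scan inflated tenfold.  Chemical outliers have their
    ``constituent`` reference value replaced by that of the most distant
    sample (a gross mislabel), so the spectrum and the chemistry disagree.
    Returns ``(spectra, reference, labels)`` with
    ``labels = {"spectral": [...], "chemical": [...]}``; the two sets are
    disjoint.
    """
    ids = list(dict.fromkeys(spectra.sample_ids))
    n = len(ids)
    if n_spectral + n_chemical >= n:
        raise ValueError("cannot corrupt that many of the available samples")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n, size=n_spectral + n_chemical, replace=False)
    spectral_ids = [ids[i] for i in chosen[:n_spectral]]
    chemical_ids = [ids[i] for i in chosen[n_spectral:]]

    absorbance = spectra.absorbance.copy()
    for sid in spectral_ids:
        rows = [i for i, s in enumerate(spectra.sample_ids) if s == sid]
        absorbance[rows] *= 10.0
    out_spectra = SpectraSet(
        spectra.grid, absorbance, list(spectra.sample_ids),
        None if spectra.replicate_ids is None else list(spectra.replicate_ids),
    )

    out_ref = reference.copy()
    col = out_ref[constituent].to_numpy(dtype=float)
    for sid in chemical_ids:
        i = ids.index(sid)
        donor = int(np.argmax(np.abs(col - col[i])))
        out_ref.loc[sid, constituent] = col[donor]
    labels = {"spectral": spectral_ids, "chemical": chemical_ids}
    return out_spectra, out_ref, labels


def low_noise_config(**overrides) -> SyntheticConfig:
    """A clean-instrument variant (no scatter, no baseline, no noise)."""
    cfg = SyntheticConfig(
        scatter=False,
        baseline_offset_range=(0.0, 0.0),
        baseline_slope_range=(0.0, 0.0),
        baseline_curvature_range=(0.0, 0.0),
        noise_sd=0.0,
        rutin_latent_noise=0.0,
        antioxidant_latent_noise=0.0,
    )
    return replace(cfg, **overrides)
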