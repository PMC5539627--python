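"""End-to-end study pipeline.

simulate (or load) -> average replicates -> random 70/29 split ->
per-constituent treatment -> H/T outlier screening -> MPLS with grouped
cross-validation -> calibration report -> external validation report.

Every stage is deterministic given the run seed; calibration-dependent
statistics (MSC reference, centring, residual scales) are frozen into the
serialized model so external validation can run in a separate invocation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict, is_dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .grid import WavelengthGrid
from .io import (
    CONSTITUENTS,
    CONSTITUENT_LABELS,
    SpectraSet,
    average_replicates,
    read_reference,
    read_spectra,
    split_calibration_validation,
    write_reference,
    write_spectra,
)
from .mpls import MPLSRegression, cross_validate, sec
from .outliers import screen
from .preprocessing import Preprocessor, parse_treatment
from .stats import paired_t_test, r_squared, regression_line, rmsep

logger = logging.getLogger("nircal")

# Per-constituent defaults: treatment strings and latent-variable counts as
# used in the emulated study's calibration table.
DEFAULT_TREATMENTS = {
    "quercetin": "Standard MSC 2,4,4,1",
    "rutin": "Detrend only 0,0,1,1",
    "pinocembrin": "Standard MSC 2,4,4,1",
    "abts": "Detrend only 2,10,10,1",
    "inhibition": "SNV only 1,4,4,1",
}
DEFAULT_FIXED_FACTORS = {
    "quercetin": 8,
    "rutin": 7,
    "pinocembrin": 7,
    "abts": 7,
    "inhibition": 8,
}


@dataclass
class RunConfig:
    """Configuration of one full calibration/validation run."""

    seed: int = 1
    n_cal: int = 70
    n_groups: int = 7
    h_threshold: float = 3.0
    t_threshold: float = 2.5
    factor_policy: str = "auto"  # "auto" (CV-chosen) or "fixed"
    max_factors: int = 10
    treatments: dict = field(default_factory=lambda: dict(DEFAULT_TREATMENTS))
    fixed_factors: dict = field(default_factory=lambda: dict(DEFAULT_FIXED_FACTORS))
    simulate: Optional[object] = None  # SyntheticConfig, or None to read files
    spectra_path: Optional[str] = None
    reference_path: Optional[str] = None
    outdir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.h_threshold <= 0 or self.t_threshold <= 0:
            raise ValueError("outlier thresholds must be positive")
        if self.factor_policy not in ("auto", "fixed"):
            raise ValueError("factor_policy must be 'auto' or 'fixed'")
        for c in self.treatments:
            parse_treatment(self.treatments[c])  # fail early on bad strings

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        from .synth import SyntheticConfig

        raw = dict(raw)
        sim = raw.pop("simulate", None)
        if sim is not None and not isinstance(sim, SyntheticConfig):
            sim = SyntheticConfig(**sim)
        treatments = dict(DEFAULT_TREATMENTS)
        treatments.update(raw.pop("treatments", {}))
        fixed = dict(DEFAULT_FIXED_FACTORS)
        fixed.update(raw.pop("fixed_factors", {}))
        return cls(simulate=sim, treatments=treatments, fixed_factors=fixed, **raw)


@dataclass
class CalibrationResult:
    """One row of the calibration report (per constituent)."""

    constituent: str
    treatment: str
    n_retained: int
    n_removed_h: int
    n_removed_t: int
    n_factors: int
    y_min: float
    y_max: float
    sd: float
    sec: float
    secv: float
    r2: float
    rmsep_cv: float
    slope: float
    intercept: float


@dataclass
class ValidationResult:
    """One row of the external-validation report (per constituent)."""

    constituent: str
    n: int
    p_value: float
    residual_mean: float
    rmsep: float
    r2: float


@dataclass
class ConstituentModel:
    """Everything needed to predict a constituent on new spectra."""

    constituent: str
    treatment: str
    grid: WavelengthGrid
    n_factors: int
    preprocessor: Preprocessor
    model: MPLSRegression

    def predict(self, spectra: SpectraSet) -> np.ndarray:
        if spectra.grid != self.grid:
            raise ValueError(
                f"spectra grid {spectra.grid} does not match model grid {self.grid}"
            )
        return self.model.predict(self.preprocessor.transform(spectra.absorbance))

    def to_json(self) -> str:
        return json.dumps(
            {
                "constituent": self.constituent,
                "treatment": self.treatment,
                "grid": {
                    "start_nm": self.grid.start_nm,
                    "end_nm": self.grid.end_nm,
                    "step_nm": self.grid.step_nm,
                },
                "n_factors": self.n_factors,
                "msc_reference": None
                if self.preprocessor.msc_reference_ is None
                else self.preprocessor.msc_reference_.tolist(),
                "output_wavelengths": self.preprocessor.output_wavelengths_.tolist(),
                "mpls": self.model.to_dict(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ConstituentModel":
        d = json.loads(text)
        grid = WavelengthGrid(**d["grid"])
        pp = Preprocessor(treatment=d["treatment"], wavelengths=grid.wavelengths)
        pp.spec_ = parse_treatment(d["treatment"])
        pp.n_features_in_ = grid.n_points
        pp.msc_reference_ = (
            None if d["msc_reference"] is None else np.asarray(d["msc_reference"])
        )
        pp.output_wavelengths_ = np.asarray(d["output_wavelengths"])
        return cls(
            constituent=d["constituent"],
            treatment=d["treatment"],
            grid=grid,
            n_factors=d["n_factors"],
            preprocessor=pp,
            model=MPLSRegression.from_dict(d["mpls"]),
        )


@dataclass
class StudyData:
    """The replicate-averaged, split inputs of one run."""

    cal_spectra: SpectraSet
    cal_reference: pd.DataFrame
    val_spectra: SpectraSet
    val_reference: pd.DataFrame


def load_inputs(config: RunConfig):
    """Simulate or read the raw spectra + reference table."""
    if config.simulate is not None:
        from .synth import simulate_dataset

        spectra, reference, _ = simulate_dataset(config.simulate, config.seed)
        return spectra, reference
    if not (config.spectra_path and config.reference_path):
        raise ValueError("config needs either a simulate block or input paths")
    return read_spectra(config.spectra_path), read_reference(config.reference_path)


def prepare_study_data(config: RunConfig) -> StudyData:
    spectra, reference = load_inputs(config)
    if spectra.replicate_ids is not None:
        spectra = average_replicates(spectra)
    (cal_s, cal_r), (val_s, val_r) = split_calibration_validation(
        spectra, reference, config.n_cal, config.seed
    )
    return StudyData(cal_s, cal_r, val_s, val_r)


def calibrate_constituent(
    config: RunConfig, data: StudyData, constituent: str, cv_seed: int
):
    """Screen, cross-validate and fit one constituent's calibration."""
    treatment = config.treatments[constituent]
    wl = data.cal_spectra.grid.wavelengths
    pp_proto = Preprocessor(treatment=treatment, wavelengths=wl)
    y = data.cal_reference[constituent].to_numpy(dtype=float)
    X = data.cal_spectra.absorbance
    ids = list(data.cal_spectra.sample_ids)
    n_factors_h = config.fixed_factors.get(constituent, config.max_factors)

    result = screen(
        X, y, ids, pp_proto,
        n_factors=n_factors_h,
        h_threshold=config.h_threshold,
        t_threshold=config.t_threshold,
        n_groups=config.n_groups,
        max_factors=config.max_factors,
        seed=cv_seed,
    )
    Xr, yr = result.X_retained, result.y_retained
    logger.info(
        "%s: removed %d by H (%s), %d by T (%s); %d retained",
        constituent,
        len(result.report.removed_by_h), result.report.removed_by_h,
        len(result.report.removed_by_t), result.report.removed_by_t,
        result.report.n_retained,
    )

    # cross-validation on the final retained set
    cv = cross_validate(
        Xr, yr, preprocessor=pp_proto, n_groups=config.n_groups,
        max_factors=config.max_factors, seed=cv_seed,
    )
    if config.factor_policy == "fixed":
        n_factors = min(config.fixed_factors[constituent], cv.y_cv_per_factor.shape[1])
    else:
        n_factors = cv.chosen_factors
    y_cv = cv.y_cv_per_factor[:, n_factors - 1]
    secv = float(np.sqrt(np.mean((y_cv - yr) ** 2)))

    # final model on the retained calibration set
    pp = Preprocessor(treatment=treatment, wavelengths=wl).fit(Xr)
    model = MPLSRegression(n_components=n_factors).fit(pp.transform(Xr), yr)
    y_fit = model.predict(pp.transform(Xr))
    slope, intercept = regression_line(yr, y_cv)

    calres = CalibrationResult(
        constituent=constituent,
        treatment=treatment,
        n_retained=int(yr.size),
        n_removed_h=len(result.report.removed_by_h),
        n_removed_t=len(result.report.removed_by_t),
        n_factors=int(n_factors),
        y_min=float(yr.min()),
        y_max=float(yr.max()),
        sd=float(yr.std(ddof=1)),
        sec=sec(yr, y_fit, n_factors),
        secv=secv,
        r2=r_squared(yr, y_cv),
        rmsep_cv=rmsep(yr, y_cv),
        slope=slope,
        intercept=intercept,
    )
    cmodel = ConstituentModel(
        constituent=constituent,
        treatment=treatment,
        grid=data.cal_spectra.grid,
        n_factors=int(n_factors),
        preprocessor=pp,
        model=model,
    )
    return calres, cmodel, result.report


def run_calibration(config: RunConfig, data: StudyData | None = None):
    """Calibrate every configured constituent.

    Returns ``(results, models, reports, data)``; writes report files when
    ``config.outdir`` is set.
    """
    if data is None:
        data = prepare_study_data(config)
    results, models, reports = {}, {}, {}
    for idx, constituent in enumerate(config.treatments):
        cv_seed = int(config.seed) + 1000 * (idx + 1)
        calres, cmodel, report = calibrate_constituent(config, data, constituent, cv_seed)
        results[constituent] = calres
        models[constituent] = cmodel
        reports[constituent] = report
    if config.outdir:
        _write_calibration_outputs(config, data, results, models, reports)
    return results, models, reports, data


def run_external_validation(
    config: RunConfig,
    models: dict,
    val_spectra: SpectraSet,
    val_reference: pd.DataFrame,
):
    """Predict the held-out samples with frozen models and compare methods.

    Validation spectra are replicate-averaged if needed, passed through the
    frozen preprocessing and the stored factor path, and the NIR predictions
    are compared with the reference chemistry by paired t-test, residual
    mean, RMSEP and R^2.
    """
    if val_spectra.replicate_ids is not None:
        val_spectra = average_replicates(val_spectra)
    out = {}
    for constituent, cmodel in models.items():
        y_ref = val_reference.loc[list(val_spectra.sample_ids), constituent].to_numpy(
            dtype=float
        )
        y_nir = cmodel.predict(val_spectra)
        out[constituent] = ValidationResult(
            constituent=constituent,
            n=int(y_ref.size),
            p_value=paired_t_test(y_ref, y_nir),
            residual_mean=float(np.mean(y_nir - y_ref)),
            rmsep=rmsep(y_ref, y_nir),
            r2=r_squared(y_ref, y_nir),
        )
    if config.outdir:
        path = Path(config.outdir) / "validation.csv"
        validation_frame(out).to_csv(path, index=False)
        logger.info("wrote %s", path)
    return out


def run_study(config: RunConfig):
    """Full replica: calibration plus external validation."""
    results, models, reports, data = run_calibration(config)
    val = run_external_validation(config, models, data.val_spectra, data.val_reference)
    return results, val, models, reports, data


# -- report tables ------------------------------------------------------------

def calibration_frame(results: dict) -> pd.DataFrame:
    rows = []
    for r in results.values():
        rows.append(
            {
                "Constituent": CONSTITUENT_LABELS.get(r.constituent, r.constituent),
                "Mathematical Treatment": r.treatment,
                "N": r.n_retained,
                "Removed (H)": r.n_removed_h,
                "Removed (T)": r.n_removed_t,
                "Latent variables": r.n_factors,
                "Min": round(r.y_min, 4),
                "Max": round(r.y_max, 4),
                "SEC": round(r.sec, 4),
                "SECV": round(r.secv, 4),
                "SD": round(r.sd, 4),
                "R2": round(r.r2, 4),
                "RMSEP": round(r.rmsep_cv, 4),
                "Slope": round(r.slope, 4),
                "Intercept": round(r.intercept, 4),
            }
        )
    return pd.DataFrame(rows)


def validation_frame(results: dict) -> pd.DataFrame:
    rows = []
    for r in results.values():
        rows.append(
            {
                "Constituent": CONSTITUENT_LABELS.get(r.constituent, r.constituent),
                "N": r.n,
                "p (Level of Significance)": round(r.p_value, 4),
                "Residual Mean": round(r.residual_mean, 4),
                "RMSEP": round(r.rmsep, 4),
                "R2": round(r.r2, 4),
            }
        )
    return pd.DataFrame(rows)


def _write_calibration_outputs(config, data, results, models, reports) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    calibration_frame(results).to_csv(outdir / "calibration.csv", index=False)
    (outdir / "models").mkdir(exist_ok=True)
    for constituent, cmodel in models.items():
        (outdir / "models" / f"{constituent}.json").write_text(cmodel.to_json())
        reports[constituent].to_frame().to_csv(
            outdir / f"outliers_{constituent}.csv", index=False
        )
    # persist the held-out set so validation can run in a later invocation
    write_spectra(data.val_spectra, outdir / "validation_spectra.csv")
    write_reference(data.val_reference, outdir / "validation_reference.csv")
    logger.info("wrote calibration outputs to %s", outdir)
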