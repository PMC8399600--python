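"""End-to-end calibration and prediction workflows.

The stage order is fixed: load → pretreat (per scan) → average
replicate scans → fit PLS1 + full cross-validation → figures of merit →
report. Averaging always follows pretreatment; the config cannot
reorder it, because scatter correction must see the individual scans.

A run is reproducible from its config: the report carries the config
hash, package version and seed, and contains no timestamps.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import ParameterError
from .figures_of_merit import FiguresOfMerit, compute_fom
from .pls import CalibrationMetrics, PLSModel, cross_validate, fit_nipals, predict
from .preprocessing import PRESETS, PreprocessPlan, apply_plan
from .spectra_core import (
    RegionSpec,
    SpectraSet,
    average_replicates,
    read_spectra,
)


@dataclass
class PipelineConfig:
    """Serializable description of one calibration run."""

    spectra_path: str | None = None
    meta_path: str | None = None
    regions: RegionSpec = field(default_factory=RegionSpec.model_default)
    plan: PreprocessPlan | str = "reference"
    max_factors: int = 8
    cv: int | str = "loo"
    n_factors_override: int | None = None
    var_x: float | None = None
    seed: int = 0

    def resolved_plan(self) -> PreprocessPlan:
        if isinstance(self.plan, str):
            try:
                return PRESETS[self.plan]()
            except KeyError:
                raise ParameterError(
                    f"unknown preset {self.plan!r}; available {sorted(PRESETS)}"
                ) from None
        return self.plan

    def to_dict(self) -> dict:
        return {
            "spectra_path": self.spectra_path,
            "meta_path": self.meta_path,
            "regions": [list(iv) for iv in self.regions.keep_intervals],
            "plan": self.plan if isinstance(self.plan, str) else self.plan.to_list(),
            "max_factors": self.max_factors,
            "cv": self.cv,
            "n_factors_override": self.n_factors_override,
            "var_x": self.var_x,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "regions" in d:
            d["regions"] = RegionSpec(tuple(tuple(iv) for iv in d["regions"]))
        plan = d.get("plan", "reference")
        if not isinstance(plan, str):
            d["plan"] = PreprocessPlan.from_list(plan)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunReport:
    """All numbers produced by one calibration run, plus provenance."""

    metrics: CalibrationMetrics
    fom: FiguresOfMerit
    model: PLSModel
    n_samples: int
    n_wavenumbers: int
    config_digest: str
    seed: int
    version: str = __version__

    def metrics_frame(self) -> pd.DataFrame:
        m = self.metrics
        return pd.DataFrame(
            {
                "n_factors": np.arange(1, m.max_factors + 1),
                "rmsec": m.rmsec,
                "r2_cal": m.r2_cal,
                "rmsev": m.rmsev,
                "r2_val": m.r2_val,
            }
        )

    def to_text(self) -> str:
        c = self.metrics.at_chosen()
        f = self.fom
        lines = [
            "nirtpc calibration report",
            f"package version: {self.version}",
            f"config: {self.config_digest}  seed: {self.seed}",
            f"calibration samples: {self.n_samples}  wavenumbers: {self.n_wavenumbers}",
            "",
            f"chosen factors: {c['n_factors']}",
            f"RMSEC: {c['rmsec']:.2f} mg/L   R2_cal: {c['r2_cal']:.4f}",
            f"RMSEV: {c['rmsev']:.2f} mg/L   R2_val: {c['r2_val']:.4f}",
            "",
            f"SEN: {f.sen:.6g}   var(x): {f.var_x:.6g}   var(y_cal): {f.var_ycal:.6g}",
            f"h0: {f.h0_min:.4f} to {f.h0_max:.4f}",
            f"LOD: {f.lod_min:.1f} to {f.lod_max:.1f} mg/L",
            f"LOQ: {f.loq_min:.1f} to {f.loq_max:.1f} mg/L",
            f"working range: {f.working_range[0]:.1f} to {f.working_range[1]:.1f} mg/L",
            "",
            "per-factor error curves:",
            self.metrics_frame().to_string(
                index=False, float_format=lambda x: f"{x:.4f}"
            ),
        ]
        return "\n".join(lines) + "\n"

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.txt").write_text(self.to_text())
        self.metrics_frame().to_csv(out / "metrics.csv", index=False)
        fom_row = {
            "sen": self.fom.sen,
            "var_x": self.fom.var_x,
            "var_ycal": self.fom.var_ycal,
            "h0_min": self.fom.h0_min,
            "h0_max": self.fom.h0_max,
            **self.fom.report_row(),
        }
        pd.DataFrame([fom_row]).to_csv(out / "fom.csv", index=False)
        self.model.save(out / "model.json")


def preprocess_and_average(
    s: SpectraSet, plan: PreprocessPlan, regions: RegionSpec
) -> SpectraSet:
    """Pretreat scans, then average replicate scans (fixed order)."""
    return average_replicates(apply_plan(s, plan, regions))


def calibrate_set(s: SpectraSet, config: PipelineConfig) -> RunReport:
    """Run the calibration workflow on an in-memory spectra set."""
    plan = config.resolved_plan()
    cal = s.select((s.meta["role"] == "calibration").to_numpy())
    prepared = preprocess_and_average(cal, plan, config.regions)
    X = prepared.absorbance
    y = prepared.concentrations()
    max_a = min(config.max_factors, X.shape[0] - 1, X.shape[1])
    metrics = cross_validate(X, y, max_a, cv=config.cv)
    chosen = config.n_factors_override or metrics.chosen_factors
    model = fit_nipals(X, y, chosen)
    fom = compute_fom(model, X, y, var_x=config.var_x)
    return RunReport(
        metrics=metrics,
        fom=fom,
        model=model,
        n_samples=X.shape[0],
        n_wavenumbers=X.shape[1],
        config_digest=config.digest(),
        seed=config.seed,
    )


def run_calibration(config: PipelineConfig, outdir=None) -> RunReport:
    """Load the configured spectra, calibrate, optionally write reports."""
    if config.spectra_path is None or config.meta_path is None:
        raise ParameterError("config must set spectra_path and meta_path")
    s = read_spectra(config.spectra_path, config.meta_path)
    report = calibrate_set(s, config)
    if outdir is not None:
        report.write(outdir)
    return report


def predict_set(
    model: PLSModel,
    s: SpectraSet,
    config: PipelineConfig,
    dilution: float | pd.Series | None = None,
) -> pd.DataFrame:
    """Predict concentrations for new spectra.

    Scans are pretreated like the calibration data and predicted
    individually; per replicate group the mean and sd across scans are
    reported. A dilution factor (scalar, or per-group Series) multiplies
    the reported content.
    """
    plan = config.resolved_plan()
    pretreated = apply_plan(s, plan, config.regions)
    if pretreated.n_wavenumbers != model.n_wavenumbers:
        raise ParameterError(
            f"model expects {model.n_wavenumbers} wavenumbers after reduction, "
            f"got {pretreated.n_wavenumbers}"
        )
    yhat = predict(model, pretreated.absorbance)
    df = pd.DataFrame(
        {
            "replicate_group": pretreated.meta["replicate_group"],
            "prediction": yhat,
        }
    )
    agg = (
        df.groupby("replicate_group", sort=False)["prediction"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .rename(
            columns={
                "mean": "predicted_mg_l",
                "std": "sd_across_scans",
                "count": "n_scans",
            }
        )
    )
    if dilution is None:
        agg["dilution_factor"] = 1.0
    elif np.isscalar(dilution):
        agg["dilution_factor"] = float(dilution)
    else:
        agg["dilution_factor"] = (
            agg["replicate_group"].map(dilution).fillna(1.0).astype(float)
        )
    agg["content_mg_l"] = agg["predicted_mg_l"] * agg["dilution_factor"]
    return agg
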