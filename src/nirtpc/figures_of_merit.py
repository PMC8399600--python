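"""Multivariate figures of merit: sensitivity, background leverage and
interval-valued LOD/LOQ for a PLS calibration.

For an inverse multivariate calibration the detection limit is not a
single number: the uncertainty of a predicted concentration depends on
where the background sample sits in the calibration score space. The
construction used here propagates both error sources (instrumental
signal variance and calibration-concentration variance) through the
model:

    LOD(h0) = 3.3 · [ SEN⁻²·var(x) + h0·SEN⁻²·var(x) + h0·var(y_cal) ]^½
    LOQ(h0) = 3 · LOD(h0)

where SEN = 1/‖b‖₂ is the multivariate sensitivity, var(x) the variance
of the instrumental signals, var(y_cal) the variance of the calibration
concentrations, and h0 the leverage of an analyte-free (background)
sample. Scanning h0 over the calibration set's background leverages
yields the min/max interval [LOD_min, LOD_max].

The background leverage of calibration sample n removes the analyte
contribution from its score vector before measuring the distance to the
score-space center: with s the least-squares regression of the score
columns on the centered concentrations,

    t0_n = t_n − y_c,n · s,      h0_n = Σ_a t0_na² / Σ_m t_ma² .
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateDataError, DesignError, ParameterError
from .pls import PLSModel
from .spectra_core import SpectraSet


@dataclass
class FiguresOfMerit:
    sen: float                      # signal units per mg L⁻¹
    var_x: float                    # squared signal units
    var_ycal: float                 # (mg L⁻¹)²
    h0_min: float
    h0_max: float
    lod_min: float                  # mg L⁻¹
    lod_max: float
    loq_min: float
    loq_max: float
    working_range: tuple[float, float]  # [LOQ_min, upper calibration bound]

    def report_row(self) -> dict:
        """Rounded presentation values (1 decimal, mg L⁻¹)."""
        return {
            "LOD_min": round(self.lod_min, 1),
            "LOD_max": round(self.lod_max, 1),
            "LOQ_min": round(self.loq_min, 1),
            "LOQ_max": round(self.loq_max, 1),
            "working_range_low": round(self.working_range[0], 1),
            "working_range_high": round(self.working_range[1], 1),
        }


def sensitivity(model: PLSModel) -> float:
    """Multivariate sensitivity: inverse Euclidean length of b."""
    nrm = float(np.linalg.norm(model.coef))
    if nrm == 0:
        raise DegenerateDataError("zero regression coefficient vector")
    return 1.0 / nrm


def background_leverages(model: PLSModel, y_cal: np.ndarray) -> np.ndarray:
    """Leverage of each calibration sample after removing its analyte
    contribution from the score vector (see module docstring)."""
    T = model.scores
    y = np.asarray(y_cal, dtype=float).ravel()
    if T.shape[0] != y.size:
        raise ParameterError(f"{T.shape[0]} score rows but {y.size} concentrations")
    if T.shape[0] < 2:
        raise DesignError("background leverages need at least two calibration samples")
    yc = y - y.mean()
    yy = yc @ yc
    s = (T.T @ yc) / yy if yy > 0 else np.zeros(T.shape[1])
    T0 = T - np.outer(yc, s)
    denom = (T**2).sum(axis=0)
    return (T0**2 / denom).sum(axis=1)


def lod(sen: float, var_x: float, h0: float, var_ycal: float) -> float:
    """Multivariate limit of detection at background leverage h0, mg L⁻¹."""
    if sen <= 0:
        raise ParameterError(f"sensitivity must be positive, got {sen}")
    for name, v in (("var_x", var_x), ("h0", h0), ("var_ycal", var_ycal)):
        if v < 0:
            raise ParameterError(f"{name} must be non-negative, got {v}")
    inv2 = sen**-2
    return 3.3 * float(np.sqrt(inv2 * var_x + h0 * inv2 * var_x + h0 * var_ycal))


def loq(lod_value: float) -> float:
    """Limit of quantification: 3 × LOD."""
    if lod_value < 0:
        raise ParameterError(f"LOD must be non-negative, got {lod_value}")
    return 3.0 * lod_value


def residual_signal_variance(model: PLSModel, X_cal: np.ndarray) -> float:
    """Default var(x) estimate: mean squared X-residual after A-factor
    reconstruction, averaged over the calibration spectra."""
    Xc = np.asarray(X_cal, dtype=float) - model.x_mean
    resid = Xc - model.scores @ model.x_loadings.T
    return float((resid**2).mean())


def compute_fom(
    model: PLSModel,
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    var_x: float | None = None,
) -> FiguresOfMerit:
    """Assemble the full figures-of-merit block for a fitted calibration.

    ``var_x`` defaults to the model's residual signal variance on the
    calibration spectra; a blank-replicate variance measured separately
    may be passed instead.
    """
    y = np.asarray(y_cal, dtype=float).ravel()
    sen = sensitivity(model)
    if var_x is None:
        var_x = residual_signal_variance(model, X_cal)
    var_ycal = float(np.var(y, ddof=1))
    h0 = background_leverages(model, y)
    h0_min, h0_max = float(h0.min()), float(h0.max())
    lod_min = lod(sen, var_x, h0_min, var_ycal)
    lod_max = lod(sen, var_x, h0_max, var_ycal)
    loq_min, loq_max = loq(lod_min), loq(lod_max)
    return FiguresOfMerit(
        sen=sen,
        var_x=float(var_x),
        var_ycal=var_ycal,
        h0_min=h0_min,
        h0_max=h0_max,
        lod_min=lod_min,
        lod_max=lod_max,
        loq_min=loq_min,
        loq_max=loq_max,
        working_range=(loq_min, float(np.max(y))),
    )


def compute_fom_set(model: PLSModel, calibration: SpectraSet, var_x: float | None = None) -> FiguresOfMerit:
    """Figures of merit from a (preprocessed, averaged) calibration set."""
    return compute_fom(model, calibration.absorbance, calibration.concentrations(), var_x)
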