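"""Quantification math for the comparison methods and for extraction
optimisation.

Covers the desk-side calculations of the wet-lab reference workflows:

* ordinary-least-squares linear calibration curves with inverse
  prediction (Folin–Ciocalteu photometry at 765 nm, HPLC-UV at 276 nm),
* the Löwenthal permanganate titration conversion factor

      F = c_GA · V_s / ((V_t − V_b) · c · t)

  and its rearrangement to polyphenol content

      content [mg L⁻¹ GAE] = (V_t − V_b) · c · t · F / V_s ,

* the sorbent adsorption capacity q = (C0 − Ce)·V/M in mg per g.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import ConsistencyError, DesignError, ParameterError


@dataclass(frozen=True)
class LinearCalibration:
    """OLS calibration line signal = slope·concentration + intercept."""

    slope: float
    intercept: float
    r_squared: float

    def predict(self, concentration):
        return self.slope * np.asarray(concentration, dtype=float) + self.intercept

    def predict_inverse(self, signal):
        """Concentration from measured signal: (signal − intercept)/slope."""
        return (np.asarray(signal, dtype=float) - self.intercept) / self.slope


def fit_linear_calibration(x, y) -> LinearCalibration:
    """Fit an OLS calibration line (standard concentrations on x)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 2:
        raise DesignError("calibration needs >= 2 paired (concentration, signal) points")
    if np.ptp(x) == 0:
        raise DesignError("calibration standards are all at the same concentration")
    res = stats.linregress(x, y)
    return LinearCalibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def adsorption_capacity(c0: float, ce: float, volume_l: float, mass_g: float) -> float:
    """Adsorbed amount per gram of sorbent: q = (C0 − Ce)·V/M [mg g⁻¹]."""
    if volume_l <= 0 or mass_g <= 0:
        raise ParameterError("volume and sorbent mass must be positive")
    if ce < 0 or c0 < 0:
        raise ParameterError("concentrations must be non-negative")
    if ce > c0:
        raise ConsistencyError(
            f"equilibrium concentration {ce} exceeds initial concentration {c0}"
        )
    return (c0 - ce) * volume_l / mass_g


def loewenthal_factor(
    cga: float, vs: float, vt: float, vb: float, c: float, t: float
) -> float:
    """Conversion factor F = c_GA·V_s / ((V_t − V_b)·c·t) from one standard.

    Units: cga mg L⁻¹, volumes mL, c mol L⁻¹; t is the dimensionless
    titer of the permanganate solution.
    """
    if c <= 0 or t <= 0:
        raise ParameterError("permanganate concentration and titer must be positive")
    if vs <= 0:
        raise ParameterError("sample volume must be positive")
    if vt <= vb:
        raise ConsistencyError(
            f"titration volume {vt} must exceed the blank volume {vb}"
        )
    return cga * vs / ((vt - vb) * c * t)


def loewenthal_calibration(
    standards: Sequence[tuple[float, float]],
    vs: float,
    vb: float,
    c: float,
    t: float,
) -> tuple[float, float]:
    """Aggregate F over several (c_GA, V_t) standards.

    Returns the arithmetic mean of the per-standard factors and its sd
    (0.0 for a single standard).
    """
    if len(standards) == 0:
        raise DesignError("need at least one titration standard")
    fs = np.array([loewenthal_factor(cga, vs, vt, vb, c, t) for cga, vt in standards])
    return float(fs.mean()), float(fs.std(ddof=1)) if fs.size > 1 else 0.0


def polyphenol_content(
    f: float, vt: float, vb: float, c: float, t: float, vs: float
) -> float:
    """Titration result to mg L⁻¹ GAE: (V_t − V_b)·c·t·F/V_s.

    The blank-equal titration (V_t = V_b) gives 0; V_t < V_b is
    physically inconsistent.
    """
    if c <= 0 or t <= 0 or vs <= 0 or f <= 0:
        raise ParameterError("c, t, Vs and F must be positive")
    if vt < vb:
        raise ConsistencyError(f"titration volume {vt} below blank volume {vb}")
    return (vt - vb) * c * t * f / vs
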