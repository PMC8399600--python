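"""Spectral pretreatment operators and composable pretreatment plans.

Diffuse-reflectance spectra of a powdered sorbent carry multiplicative
scatter (non-uniform particle size), baseline drift and high-frequency
noise on top of the chemical signal. The operators here are the standard
row-wise corrections used in NIR chemometrics:

* SNV — per-spectrum standardisation to mean 0, sd 1 (sample sd, n−1),
* MSC — per-spectrum affine regression against a reference spectrum and
  inversion of the fitted slope/intercept,
* detrend — subtraction of a per-spectrum polynomial baseline in the
  column index,
* Savitzky–Golay — local polynomial smoothing / derivatives.

All operators act on rows independently, so they commute with any
permutation or subsetting of samples.

The shipped preset ``"reference"`` is the chain used for the published
solid-phase NIR calibration: detrend (degree 1) → region reduction →
Savitzky–Golay smoothing (polynomial order 0, 19 points) → SNV, followed
downstream by replicate averaging (averaging always happens after
pretreatment).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .exceptions import DegenerateDataError, ParameterError
from .spectra_core import RegionSpec, SpectraSet, reduce_regions

STEP_KINDS = ("snv", "msc", "detrend", "sg_smooth", "sg_derivative", "reduce")


@dataclass(frozen=True)
class PreprocessStep:
    """One pretreatment operator with its parameters."""

    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in STEP_KINDS:
            raise ParameterError(f"unknown step kind {self.kind!r}; allowed {STEP_KINDS}")
        p = dict(self.params)
        if self.kind == "detrend":
            deg = p.get("degree", 1)
            if deg not in (0, 1, 2):
                raise ParameterError(f"detrend degree must be 0, 1 or 2, got {deg}")
        if self.kind in ("sg_smooth", "sg_derivative"):
            window = p.get("window", 19)
            polyorder = p.get("polyorder", 0 if self.kind == "sg_smooth" else 2)
            deriv = p.get("deriv", 0 if self.kind == "sg_smooth" else 1)
            if window % 2 == 0 or window <= polyorder:
                raise ParameterError(
                    f"SG window must be odd and exceed polyorder (window={window}, polyorder={polyorder})"
                )
            if self.kind == "sg_derivative" and deriv not in (1, 2):
                raise ParameterError(f"derivative order must be 1 or 2, got {deriv}")
            if polyorder < deriv:
                raise ParameterError("SG polyorder must be >= derivative order")
        object.__setattr__(self, "params", p)

    def to_dict(self) -> dict:
        return {"kind": self.kind, **self.params}

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessStep":
        d = dict(d)
        return cls(d.pop("kind"), d)


@dataclass(frozen=True)
class PreprocessPlan:
    """Ordered chain of pretreatment steps."""

    steps: tuple[PreprocessStep, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "steps", tuple(self.steps))

    def to_list(self) -> list[dict]:
        return [s.to_dict() for s in self.steps]

    @classmethod
    def from_list(cls, items) -> "PreprocessPlan":
        return cls(tuple(PreprocessStep.from_dict(d) for d in items))


def reference_plan() -> PreprocessPlan:
    """The packaged default chain: detrend(1) → reduce → SG(0, 19) → SNV."""
    return PreprocessPlan(
        (
            PreprocessStep("detrend", {"degree": 1}),
            PreprocessStep("reduce"),
            PreprocessStep("sg_smooth", {"window": 19, "polyorder": 0}),
            PreprocessStep("snv"),
        )
    )


def linear_plan() -> PreprocessPlan:
    """The linear portion of the reference chain (no SNV).

    Detrending, region reduction and Savitzky–Golay smoothing are linear
    maps of the spectrum, so a set of spectra affine in concentration
    stays exactly affine — useful for exactness checks and for strictly
    linear calibration problems.
    """
    return PreprocessPlan(
        (
            PreprocessStep("detrend", {"degree": 1}),
            PreprocessStep("reduce"),
            PreprocessStep("sg_smooth", {"window": 19, "polyorder": 0}),
        )
    )


PRESETS = {"reference": reference_plan, "linear": linear_plan}


def snv(s: SpectraSet) -> SpectraSet:
    """Standard normal variate: each row to mean 0, sd 1 (n−1 denominator)."""
    A = s.absorbance
    if A.shape[1] < 2:
        raise ParameterError("SNV needs at least two wavenumbers per spectrum")
    mu = A.mean(axis=1, keepdims=True)
    sd = A.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        bad = s.meta.loc[np.flatnonzero(sd.ravel() == 0), "sample_id"].tolist()
        raise DegenerateDataError(f"constant spectra cannot be SNV-scaled: {bad}")
    return s.with_absorbance((A - mu) / sd)


def msc(s: SpectraSet, reference: np.ndarray | None = None) -> SpectraSet:
    """Multiplicative scatter correction against a reference spectrum.

    Each row x is regressed as x ≈ a + b·reference (ordinary least
    squares over wavenumbers) and replaced by (x − a)/b. The reference
    defaults to the mean spectrum of the set, which is then a fixed
    point of the correction.
    """
    A = s.absorbance
    ref = A.mean(axis=0) if reference is None else np.asarray(reference, dtype=float)
    if ref.shape != (A.shape[1],):
        raise ParameterError(
            f"reference length {ref.size} does not match {A.shape[1]} wavenumbers"
        )
    ref_c = ref - ref.mean()
    denom = ref_c @ ref_c
    if denom == 0:
        raise DegenerateDataError("MSC reference spectrum has zero variance")
    slope = (A - A.mean(axis=1, keepdims=True)) @ ref_c / denom
    intercept = A.mean(axis=1) - slope * ref.mean()
    return s.with_absorbance((A - intercept[:, None]) / slope[:, None])


def detrend(s: SpectraSet, degree: int = 1) -> SpectraSet:
    """Subtract a per-row least-squares polynomial (in the column index).

    The residual is orthogonal to the polynomial basis of that degree.
    """
    if degree not in (0, 1, 2):
        raise ParameterError(f"detrend degree must be 0, 1 or 2, got {degree}")
    p = s.n_wavenumbers
    if p <= degree:
        raise ParameterError("spectrum shorter than the detrend polynomial basis")
    x = np.linspace(-1.0, 1.0, p)
    B = np.vander(x, degree + 1)
    Q, _ = np.linalg.qr(B)
    A = s.absorbance
    return s.with_absorbance(A - (A @ Q) @ Q.T)


def sg_filter(
    s: SpectraSet, window: int, polyorder: int, deriv: int = 0
) -> SpectraSet:
    """Savitzky–Golay smoothing (deriv=0) or differentiation per row.

    Derivatives are returned per cm⁻¹ with respect to wavenumber (the
    column spacing and the grid direction are folded into the scaling),
    so first-derivative spectra have units of absorbance · cm. Edges are
    handled by evaluating the polynomial fitted to the terminal window.
    """
    p = s.n_wavenumbers
    if window % 2 == 0:
        raise ParameterError(f"SG window must be odd, got {window}")
    if window <= polyorder:
        raise ParameterError("SG window must exceed the polynomial order")
    if window > p:
        raise ParameterError(f"SG window {window} larger than spectrum length {p}")
    if deriv not in (0, 1, 2):
        raise ParameterError(f"derivative order must be 0, 1 or 2, got {deriv}")
    if polyorder < deriv:
        raise ParameterError("SG polyorder must be >= derivative order")
    out = savgol_filter(
        s.absorbance,
        window_length=window,
        polyorder=polyorder,
        deriv=deriv,
        delta=s.grid.spacing,
        axis=1,
        mode="interp",
    )
    if deriv % 2 == 1 and s.grid.step < 0:
        out = -out  # descending grid: d/dν flips sign relative to the column axis
    return s.with_absorbance(out)


def apply_step(s: SpectraSet, step: PreprocessStep, region: RegionSpec | None) -> SpectraSet:
    k, prm = step.kind, step.params
    if k == "snv":
        return snv(s)
    if k == "msc":
        return msc(s, prm.get("reference"))
    if k == "detrend":
        return detrend(s, prm.get("degree", 1))
    if k == "sg_smooth":
        return sg_filter(s, prm.get("window", 19), prm.get("polyorder", 0), 0)
    if k == "sg_derivative":
        return sg_filter(
            s, prm.get("window", 19), prm.get("polyorder", 2), prm.get("deriv", 1)
        )
    if k == "reduce":
        if region is None:
            raise ParameterError("plan contains a reduce step but no regions were given")
        return reduce_regions(s, region)
    raise ParameterError(f"unknown step kind {k!r}")  # pragma: no cover


def apply_plan(
    s: SpectraSet, plan: PreprocessPlan, region: RegionSpec | None = None
) -> SpectraSet:
    """Run a pretreatment chain over a spectra set.

    Region reduction happens where the plan places its ``reduce`` step;
    if the plan has none but a region spec is supplied, reduction is
    applied first.
    """
    has_reduce = any(st.kind == "reduce" for st in plan.steps)
    if region is not None and not has_reduce:
        s = reduce_regions(s, region)
    for st in plan.steps:
        s = apply_step(s, st, region)
    return s
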