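"""Synthetic NIR spectra with known ground truth.

Emulates diffuse-reflectance spectra of gallic acid adsorbed on a PVP
sorbent, with the statistical structure the calibration pipeline
assumes:

* a broad sorbent background,
* analyte-correlated Gaussian bands confined to the wavenumber regions
  where adsorbed phenols absorb (4350–4400, 4500–4640, 5000–5320,
  6000–6550, 6900–7330, 7360–8040 cm⁻¹),
* a residual-water OH-stretch band at 5344–4960 cm⁻¹ whose amplitude
  varies sample to sample (freeze-drying never removes all moisture),
* per-scan multiplicative scatter (non-uniform particle size), baseline
  offset and tilt,
* additive noise that is markedly larger outside 4068–9612 cm⁻¹,
  reproducing the noisy spectral ends that motivate region exclusion.

The analyte signal is linear in the adsorbed loading q = conc ·
adsorption_fraction(pH) · V/M (mg analyte per g sorbent), so every
generated spectrum has an exact known ground truth.

Randomness is driven by one global seed; each (sample, scan) pair draws
from its own counter-derived substream, so subsetting or reordering a
design never changes the numbers drawn for the remaining samples.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .exceptions import DesignError, ParameterError
from .spectra_core import SpectraSet, WavenumberGrid

#: Wavenumber regions (cm⁻¹) where the adsorbed analyte absorbs.
ANALYTE_REGIONS = (
    (4350.0, 4400.0),
    (4500.0, 4640.0),
    (5000.0, 5320.0),
    (6000.0, 6550.0),
    (6900.0, 7330.0),
    (7360.0, 8040.0),
)

#: Residual-moisture OH-stretch band (cm⁻¹).
WATER_REGION = (4960.0, 5344.0)

#: Low-noise interior of the spectrum; extra noise is injected outside.
INTERIOR = (4068.0, 9612.0)

#: Extraction recovery (fraction of analyte adsorbed) at the calibrated
#: pH values of the dispersive solid-phase protocol.
ADSORPTION_FRACTIONS = {3.5: 0.974, 6.0: 0.303, 8.0: 0.359}


def adsorption_fraction(ph: float) -> float:
    """Fraction of analyte bound to the sorbent at a calibrated pH.

    Only the three pH values characterised experimentally are accepted;
    hydrogen-bond-driven binding is too nonlinear in pH to interpolate.
    """
    for known, frac in ADSORPTION_FRACTIONS.items():
        if abs(ph - known) < 1e-9:
            return frac
    raise ParameterError(
        f"no calibrated adsorption fraction at pH {ph}; known: {sorted(ADSORPTION_FRACTIONS)}"
    )


@dataclass(frozen=True)
class ComponentSpectrum:
    """Pure-component spectrum as a sum of Gaussian bands.

    ``bands`` is a sequence of (center cm⁻¹, width cm⁻¹, amplitude);
    width is the Gaussian sigma.
    """

    name: str
    bands: tuple[tuple[float, float, float], ...]
    role: str = "analyte"  # sorbent_background | analyte | water | interferent

    def __post_init__(self) -> None:
        object.__setattr__(self, "bands", tuple(tuple(b) for b in self.bands))
        for center, width, _amp in self.bands:
            if not 4000.0 <= center <= 10000.0:
                raise ParameterError(f"band center {center} outside the NIR window")
            if width <= 0:
                raise ParameterError(f"band width must be positive, got {width}")


def gaussian_spectrum(c: ComponentSpectrum, grid: WavenumberGrid) -> np.ndarray:
    """Evaluate the component's Gaussian bands on the grid."""
    v = grid.values
    out = np.zeros(v.size)
    for center, width, amp in c.bands:
        out += amp * np.exp(-0.5 * ((v - center) / width) ** 2)
    return out


def _mid_width(lo: float, hi: float) -> tuple[float, float]:
    return (lo + hi) / 2.0, (hi - lo) / 4.0


def analyte_component(unit_amplitude: float = 0.02) -> ComponentSpectrum:
    """Adsorbed-analyte spectrum per unit loading (mg analyte / g sorbent).

    One Gaussian per absorbing region, centered mid-region with sigma a
    quarter of the region width; relative band strengths are free
    parameters of the generator, fixed here once.
    """
    rel = (0.6, 0.8, 0.9, 1.0, 0.5, 0.7)
    bands = []
    for (lo, hi), r in zip(ANALYTE_REGIONS, rel):
        c, w = _mid_width(lo, hi)
        bands.append((c, w, unit_amplitude * r))
    return ComponentSpectrum("analyte", tuple(bands), "analyte")


def water_component() -> ComponentSpectrum:
    """Residual-moisture band, unit peak amplitude (scaled per sample)."""
    c, w = _mid_width(*WATER_REGION)
    return ComponentSpectrum("water", ((c, w, 1.0),), "water")


def background_component() -> ComponentSpectrum:
    """Broad sorbent background (PVP matrix + baseline absorbance)."""
    return ComponentSpectrum(
        "sorbent_background",
        (
            (4450.0, 700.0, 0.55),
            (5800.0, 1100.0, 0.75),
            (7100.0, 900.0, 0.35),
            (8600.0, 1300.0, 0.45),
        ),
        "sorbent_background",
    )


def glucose_component() -> ComponentSpectrum:
    """Residual-sugar contamination bands, overlapping the analyte regions
    (glucose left in the resin despite washing)."""
    return ComponentSpectrum(
        "glucose",
        ((4560.0, 50.0, 0.8), (5150.0, 70.0, 0.5), (6250.0, 120.0, 1.0)),
        "interferent",
    )


@dataclass(frozen=True)
class NoiseModel:
    """Stochastic imperfections of the measurement, all in absorbance units.

    Defaults are set so the reference pipeline reaches R²cal ≈ 0.999 on
    the 52-point calibration design — the error regime of a well-run
    solid-phase NIR calibration.
    """

    additive_sd: float = 0.035
    scatter_slope_sd: float = 0.05
    baseline_offset_sd: float = 0.02
    baseline_tilt_sd: float = 0.01
    edge_noise_sd: float = 0.1
    water_amplitude_range: tuple[float, float] = (0.15, 0.35)

    def __post_init__(self) -> None:
        for name in ("additive_sd", "scatter_slope_sd", "baseline_offset_sd",
                     "baseline_tilt_sd", "edge_noise_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        lo, hi = self.water_amplitude_range
        if lo < 0 or hi < lo:
            raise ParameterError("water_amplitude_range must satisfy 0 <= low <= high")

    @classmethod
    def zero(cls, water_amplitude: float = 0.25) -> "NoiseModel":
        """Noise-free instrument with a fixed residual-water amplitude."""
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, (water_amplitude, water_amplitude))


@dataclass(frozen=True)
class StudyDesign:
    """Ground-truth design of a synthetic extraction + NIR study.

    ``concentrations`` lists the true solution concentration (mg L⁻¹)
    of every physical sample; each is scanned ``scans_per_sample``
    times. The extraction uses ``volume_l`` of solution on ``sorbent_g``
    of sorbent at the given pH.
    """

    concentrations: tuple[float, ...]
    scans_per_sample: int = 3
    ph: float = 3.5
    volume_l: float = 0.004
    sorbent_g: float = 0.1
    seed: int = 0
    role: str = "calibration"
    label: str = "cal"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "concentrations", tuple(float(c) for c in self.concentrations)
        )
        if len(self.concentrations) == 0:
            raise DesignError("design needs at least one sample")
        if any(c < 0 for c in self.concentrations):
            raise DesignError("concentrations must be non-negative")
        if self.scans_per_sample < 1:
            raise DesignError("scans_per_sample must be >= 1")
        adsorption_fraction(self.ph)  # validate early

    @property
    def n_samples(self) -> int:
        return len(self.concentrations)


def calibration_design(
    seed: int = 0,
    max_concentration: float = 300.0,
    step: float = 25.0,
    replicates: int = 4,
    extended: bool = False,
    **kwargs,
) -> StudyDesign:
    """The standard calibration ladder: 0–300 mg L⁻¹ in 25 mg L⁻¹ steps,
    four replicate extractions per level (52 samples). ``extended=True``
    appends 350–500 mg L⁻¹ in 50 mg L⁻¹ steps, four each (68 samples).
    """
    levels = list(np.arange(0.0, max_concentration + step / 2, step))
    if extended:
        levels += list(np.arange(max_concentration + 50.0, 500.0 + 25.0, 50.0))
    conc = tuple(c for c in levels for _ in range(replicates))
    return StudyDesign(concentrations=conc, seed=seed, **kwargs)


def default_components() -> dict[str, ComponentSpectrum]:
    return {
        "background": background_component(),
        "analyte": analyte_component(),
        "water": water_component(),
    }


def generate_set(
    design: StudyDesign,
    components: dict[str, ComponentSpectrum] | None = None,
    noise: NoiseModel | None = None,
    grid: WavenumberGrid | None = None,
    contaminant: ComponentSpectrum | None = None,
    contaminant_amplitude_range: tuple[float, float] = (0.0, 0.0),
) -> tuple[SpectraSet, pd.DataFrame]:
    """Generate spectra for a study design, with a ground-truth table.

    Per scan row:

        A = [background + q·analyte + w·water (+ g·contaminant)] · slope
            + offset + tilt·ramp + noise

    where q is the adsorbed loading (mg g⁻¹), w the per-sample water
    amplitude, slope/offset/tilt the per-scan scatter draws, and the
    additive noise has extra variance outside the 4068–9612 cm⁻¹
    interior. Deterministic given ``design.seed``.

    Returns the SpectraSet (one row per scan) and a table with the true
    concentration, adsorbed loading and nuisance draws for every scan.
    """
    comp = components or default_components()
    nm = noise or NoiseModel()
    g = grid or WavenumberGrid.default()
    v = g.values
    frac = adsorption_fraction(design.ph)
    lpg = design.volume_l / design.sorbent_g  # litres of solution per g sorbent

    bg = gaussian_spectrum(comp["background"], g)
    an = gaussian_spectrum(comp["analyte"], g)
    wa = gaussian_spectrum(comp["water"], g)
    co = gaussian_spectrum(contaminant, g) if contaminant is not None else None
    ramp = np.linspace(-1.0, 1.0, v.size)
    edge = ~((v >= INTERIOR[0]) & (v <= INTERIOR[1]))

    rows, meta, truth = [], [], []
    w_lo, w_hi = nm.water_amplitude_range
    c_lo, c_hi = contaminant_amplitude_range
    for i, conc in enumerate(design.concentrations):
        rng_s = np.random.default_rng([design.seed, 1, i])
        water_amp = rng_s.uniform(w_lo, w_hi)
        contam_amp = rng_s.uniform(c_lo, c_hi) if co is not None else 0.0
        q = conc * frac * lpg  # mg analyte per g sorbent
        clean = bg + q * an + water_amp * wa
        if co is not None:
            clean = clean + contam_amp * co
        sid = f"{design.label}-{i:03d}"
        for k in range(design.scans_per_sample):
            rng = np.random.default_rng([design.seed, 2, i, k])
            slope = 1.0 + rng.normal(0.0, nm.scatter_slope_sd)
            offset = rng.normal(0.0, nm.baseline_offset_sd)
            tilt = rng.normal(0.0, nm.baseline_tilt_sd)
            eps = rng.normal(0.0, nm.additive_sd, v.size)
            if nm.edge_noise_sd > 0:
                eps[edge] += rng.normal(0.0, nm.edge_noise_sd, int(edge.sum()))
            rows.append(clean * slope + offset + tilt * ramp + eps)
            meta.append(
                {
                    "sample_id": f"{sid}-s{k}",
                    "concentration": conc,
                    "replicate_group": sid,
                    "role": design.role,
                }
            )
            truth.append(
                {
                    "sample_id": f"{sid}-s{k}",
                    "replicate_group": sid,
                    "scan": k,
                    "concentration": conc,
                    "adsorbed_fraction": frac,
                    "loading_mg_per_g": q,
                    "water_amplitude": water_amp,
                    "contaminant_amplitude": contam_amp,
                    "scatter_slope": slope,
                }
            )
    return (
        SpectraSet(g, np.vstack(rows), pd.DataFrame(meta)),
        pd.DataFrame(truth),
    )


def repeatability_design(seed: int, n: int = 10, concentration: float = 150.0) -> StudyDesign:
    """n independent extractions of one standard concentration."""
    return StudyDesign(
        concentrations=(concentration,) * n,
        seed=seed,
        role="validation",
        label="rep",
    )


def generate_validation_suite(
    seed: int,
    noise: NoiseModel | None = None,
    nominal: float = 150.0,
    n: int = 10,
    glucose_amplitude_range: tuple[float, float] = (0.0, 0.03),
    glucose_scatter_factor: float = 3.0,
) -> dict:
    """Repeatability and selectivity datasets with known ground truth.

    * ``repeatability``: n extractions of the nominal standard.
    * ``selectivity``: control plus three spiked conditions. Ascorbic
      acid and tyrosine do not bind the sorbent at pH 3.5 and are washed
      away, so their sets differ from the control only by the random
      stream. Glucose at high concentration leaves residual sugar in the
      resin: its set carries contamination bands overlapping the analyte
      regions and inflated scatter (sticky, non-uniform particles).
    """
    nm = noise or NoiseModel()
    sets = {}
    rep_set, rep_truth = generate_set(repeatability_design(seed, n, nominal), noise=nm)
    sets["repeatability"] = rep_set
    sets["repeatability_truth"] = rep_truth

    sel = {}
    for j, name in enumerate(["control", "ascorbic_acid", "tyrosine"]):
        d = StudyDesign(
            concentrations=(nominal,) * n,
            seed=seed + 1000 * (j + 1),
            role="validation",
            label=name,
        )
        sel[name], _ = generate_set(d, noise=nm)
    d = StudyDesign(
        concentrations=(nominal,) * n,
        seed=seed + 4000,
        role="validation",
        label="glucose",
    )
    glucose_noise = replace(nm, scatter_slope_sd=nm.scatter_slope_sd * glucose_scatter_factor)
    sel["glucose"], _ = generate_set(
        d,
        noise=glucose_noise,
        contaminant=glucose_component(),
        contaminant_amplitude_range=glucose_amplitude_range,
    )
    sets["selectivity"] = sel
    sets["nominal"] = nominal
    return sets
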