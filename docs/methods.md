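# Methods

## Problem and model

`nirtpc` implements an inverse multivariate calibration for total
polyphenolic content (TPC, mg L⁻¹ gallic acid equivalents): polyphenols
are bound onto insoluble polyvinylpyrrolidone (PVP) by dispersive
solid-phase extraction, the dried sorbent is measured by FT-NIR in
diffuse reflection (10,000–4000 cm⁻¹), and the concentration is
predicted from the spectrum by PLS1 regression. The package covers
everything downstream of the instrument: spectral pretreatment, NIPALS
PLS1 with full cross-validation, interval-valued multivariate detection
limits, validation statistics, and the quantification arithmetic of the
two classical comparison methods (Folin–Ciocalteu photometry, Löwenthal
permanganate titration).

The calibration model is linear in the pretreated spectrum x:

    ŷ = ȳ + (x − x̄)ᵀ b,     b = W (PᵀW)⁻¹ q

with W, P, q accumulated factor-by-factor by NIPALS (weights from the
X–y covariance, scores t = Xw, deflation of X and y per factor). X and
y are mean-centered, never variance-scaled — standard for spectra,
where the channel scale is physically meaningful.

## Wavenumber regions

Two intervals are retained for modelling, 9612–5344 and 4960–4068 cm⁻¹
(closed bounds, `MODEL_REGIONS`). The excluded 5344–4960 cm⁻¹ band is
the OH-stretch of residual water, which survives freeze-drying and
varies sample to sample; the excluded ends (10,000–9612, 4068–4000)
carry high detector noise. Grids are stored in instrument order
(descending) at 8 cm⁻¹ spacing; after region exclusion a grid keeps a
uniform base spacing with gaps that are whole multiples of it, and all
operators treat the reduced axis as contiguous columns (the same
convention chemometrics packages use after "reduction").

## Pretreatment

Operators act row-wise (per spectrum) and therefore commute with any
sample permutation:

* **SNV** — (x − mean)/sd with the n−1 sd. Errors on constant rows.
* **MSC** — per-row OLS against a reference spectrum (default: set
  mean), then (x − a)/b. The reference is a fixed point.
* **Detrend** — subtract a per-row polynomial (degree 0–2) in the
  column index; the default chain uses degree 1 (the degree is an
  assumption, configurable).
* **Savitzky–Golay** — local polynomial smoothing or 1st/2nd
  derivatives. Derivatives are scaled per cm⁻¹ of wavenumber (grid
  direction folded in, so a positive absorbance slope versus
  wavenumber gives a positive derivative). Edges use polynomial
  evaluation on the terminal window (`mode="interp"`).

The shipped preset `"reference"` is detrend(1) → region reduction →
SG(polyorder 0, window 19) → SNV; `"linear"` is the same chain without
the final SNV. Replicate scans (3 per sample) are averaged **after**
pretreatment — the pipeline enforces this order, because scatter
correction must see individual scans.

A consequence worth knowing: detrend, reduction and SG are linear maps,
so spectra affine in concentration stay affine and a noise-free
calibration is solved exactly (machine precision). SNV is *not* linear
(it divides by a row sd that depends on the analyte level), so even
noise-free SNV-treated data carry a small curvature error (~0.7 mg L⁻¹
RMSEC on the default design, R²cal ≈ 0.99995). Exactness tests
therefore run on the linear chain; the full preset is held to the
R² ≥ 0.9999 standard at zero noise.

## Cross-validation and factor choice

"Full cross-validation" is leave-one-out: every sample is predicted by
a model fitted without it, for each factor count up to `max_factors`
(default 8). Contiguous k-segment CV is available as an option. RMSEC /
RMSEV and R²cal / R²val are reported per factor count; R² is
1 − SS_res/SS_tot about the overall mean, with R²val computed on the
LOO predictions. The chosen factor count is the first one reaching the
global RMSEV minimum (a parsimony multiplier is available, and a fixed
override emulates reports that state their factor count outright).

## Figures of merit

Multivariate sensitivity is SEN = 1/‖b‖₂. Detection limits follow the
error-propagation construction for inverse PLS calibration:

    LOD(h0) = 3.3 [ SEN⁻² var(x) + h0 SEN⁻² var(x) + h0 var(y_cal) ]^½
    LOQ(h0) = 3 LOD(h0)

where var(x) is the instrumental signal variance, var(y_cal) the
(n−1) variance of calibration concentrations, and h0 the score-space
leverage of an analyte-free sample. For each calibration sample the
analyte contribution is removed from its score vector (t0 = t − y_c s,
s the regression of score columns on centered concentrations) and
h0 = Σ_a t0_a²/Σ_m t_ma²; scanning min/max h0 over the calibration set
gives the [LOD_min, LOD_max] interval. The working range is reported as
[LOQ_min, top calibration concentration]. LOQ is always computed from
the unrounded LOD (rounding first loses a digit: 3 × 12.3 = 36.9, not
36.8).

var(x) is not observable without blank replicates, so the default
estimate is the mean squared X-residual after A-factor reconstruction
over the calibration spectra; a user-supplied blank-replicate variance
is accepted instead.

A practical caveat established on the synthetic testbed: at realistic
noise the h0·var(y_cal) term dominates LOD_min, and h0_min — the
minimum of a leverage distribution — is essentially independent of the
spectral noise level while fluctuating strongly between datasets. LOD
is therefore *not* reliably monotone in the noise σ of a single study;
the σ-monotone component is SEN⁻²·var(x), and LOD itself becomes
monotone once that term dominates (high-noise regime). The tests assert
exactly these two statements.

## Validation statistics

Recovery = 100·measured/nominal; RSD = 100·sd/mean (sd with n−1);
CI95 = mean ± 1.96·sd/√n. Reports round to one decimal; dispersions are
always labelled sd or sem explicitly, because "±" alone is ambiguous in
the literature (published tables occasionally mix the two). The
selectivity report lists, per interferent condition, the measured mean
± sd and the recovery against the shared nominal — the two
representations are linked by the recovery identity and tested as such.

## Reference-method calculators

Folin–Ciocalteu and HPLC-UV quantification use an OLS calibration line
(signal vs standard concentration) inverted for unknowns. The Löwenthal
titration converts permanganate volume to GAE through the empirical
factor F = c_GA·V_s/((V_t − V_b)·c·t); multi-standard calibrations
aggregate F as the arithmetic mean over standards (with sd) — the
aggregation rule is a package choice, since only the 150–350 mg L⁻¹
duplicate design is standard. Content = (V_t − V_b)·c·t·F/V_s is the
exact algebraic inverse, and is tested as such. Sorbent loading is
q = (C0 − Ce)·V/M (mg g⁻¹).

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
not radiative transfer. Each scan is

    A = [background + q·analyte + w·water (+ g·contaminant)] · slope
        + offset + tilt·ramp + ε

* Gaussian bands; analyte bands sit mid-region in the six
  analyte-correlated intervals (4350–4400 … 7360–8040 cm⁻¹) with sigma
  a quarter of the region width — band positions are constrained by the
  correlated regions, amplitudes are free generator parameters fixed
  once (peak scale 0.02 AU per mg g⁻¹ loading).
* The adsorbed loading is q = conc · fraction(pH) · V/M with fractions
  hard-coded at the three characterised pH values (0.974 at pH 3.5,
  0.303 at 6, 0.359 at 8; no interpolation — binding is too nonlinear
  in pH) and V/M = 4 mL / 100 mg.
* The water band (5344–4960 cm⁻¹) is always present with per-sample
  amplitude U(0.15, 0.35) — residual moisture survives freeze-drying.
* slope ~ N(1, 0.05) per scan models particle-size scatter; offset and
  tilt are small baseline draws; ε is white with σ = 0.035 AU plus an
  extra σ = 0.1 AU outside 9612–4068 cm⁻¹, so the spectral ends are
  strictly noisier than the interior (the rationale for excluding
  them).
* σ = 0.035 was fixed by calibrating the generator to the target error
  regime R²cal ≈ 0.999 on the 52-point design (RMSEC ≈ 2.9, RMSEV ≈ 7
  mg L⁻¹ at the default chain); all other defaults were set a priori.

Randomness: one global seed; each (sample, scan) derives a
counter-keyed substream (`default_rng([seed, stream, i, k])`), so
subsetting a design never changes the remaining draws.

The default study is the 13-level ladder 0–300 mg L⁻¹ in 25 mg L⁻¹
steps, 4 replicate extractions per level, 3 scans each (52 samples, 156
spectra); `extended=True` appends 350–500 in 50 mg L⁻¹ steps (68
samples). The validation suite adds a 10-replicate repeatability set at
150 mg L⁻¹ and four selectivity conditions: ascorbate and tyrosine are
inert (washed off the sorbent at pH 3.5 — their sets share the
control's generating law exactly), glucose carries residual-sugar
contamination bands overlapping the analyte regions (amplitude
U(0, 0.03)) plus 3× scatter, which produces the expected positive
recovery bias with inflated spread.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: extraction-to-extraction
chemistry variability (the synthetic repeatability RSD of ~1–5 % is
well below the ~10 % typical of the wet protocol), instrument line
shapes and wavelength error, drift between reference scans, and real
matrix interferents. Conclusions transfer at the level of algorithmic
correctness and error-propagation behaviour, not absolute performance
numbers.

## Numerical choices

* NIPALS tolerance 1e-10 on the weight vector, max 500 iterations
  (PLS1 converges in one pass; the guard future-proofs a multi-response
  extension). Deflation stops early if the X–y covariance is exhausted
  (below 1e-14 of its initial norm), truncating the model rather than
  fitting noise of rank-deficient data.
* b is assembled as W(PᵀW)⁻¹q via `solve`, not an explicit inverse.
* SNV/MSC degenerate inputs (constant spectrum, zero-variance
  reference) raise typed errors rather than emitting infinities.
* CSV I/O writes 17 significant digits, round-tripping to < 1e-12
  relative.
* Reports round to 1 decimal (mg L⁻¹ and %); full precision is kept
  internally and in the JSON model artifact.

## Reproducibility

Every stochastic entry point takes a seed; a pipeline run is a pure
function of (config, seed) and the report embeds the config hash,
package version and seed, with no timestamps — two runs of the same
config are byte-identical.
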