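"""Ground-truth synthetic spectra: determinism, structure, noise geometry."""

import numpy as np
import pytest

from nirtpc import (
    NoiseModel,
    PipelineConfig,
    WavenumberGrid,
    calibrate_set,
    calibration_design,
    generate_set,
)
from nirtpc.exceptions import ParameterError
from nirtpc.synthetic import (
    ANALYTE_REGIONS,
    INTERIOR,
    adsorption_fraction,
    analyte_component,
    background_component,
    gaussian_spectrum,
    generate_validation_suite,
    water_component,
    ComponentSpectrum,
)


class TestComponents:
    def test_single_band_peaks_at_center(self):
        g = WavenumberGrid.default()
        c = ComponentSpectrum("x", ((6000.0, 50.0, 1.0),))
        spec = gaussian_spectrum(c, g)
        assert spec[g.values == 6000.0][0] == pytest.approx(1.0)
        assert spec.max() == pytest.approx(1.0)

    def test_no_bands_gives_zero_spectrum(self):
        g = WavenumberGrid.default()
        np.testing.assert_array_equal(gaussian_spectrum(ComponentSpectrum("x", ()), g), 0.0)

    def test_analyte_mass_concentrated_in_listed_regions(self):
        """>= 99% of the analyte area lies within 3 sigma of the band regions."""
        g = WavenumberGrid.default()
        spec = gaussian_spectrum(analyte_component(), g)
        v = g.values
        inside = np.zeros(v.size, dtype=bool)
        for lo, hi in ANALYTE_REGIONS:
            width = (hi - lo) / 4
            inside |= (v >= lo - 3 * width) & (v <= hi + 3 * width)
        assert spec[inside].sum() / spec.sum() >= 0.99

    def test_band_outside_nir_window_rejected(self):
        with pytest.raises(ParameterError):
            ComponentSpectrum("x", ((3000.0, 50.0, 1.0),))


class TestAdsorptionFraction:
    @pytest.mark.parametrize("ph, frac", [(3.5, 0.974), (6.0, 0.303), (8.0, 0.359)])
    def test_calibrated_ph_values(self, ph, frac):
        assert adsorption_fraction(ph) == frac

    def test_uncalibrated_ph_rejected(self):
        with pytest.raises(ParameterError):
            adsorption_fraction(5.0)


class TestGenerateSet:
    def test_blank_is_background_plus_water_only(self):
        design = calibration_design(seed=0, max_concentration=0.0, replicates=1)
        s, truth = generate_set(design, noise=NoiseModel.zero(water_amplitude=0.25))
        g = s.grid
        expect = (
            gaussian_spectrum(background_component(), g)
            + 0.25 * gaussian_spectrum(water_component(), g)
        )
        np.testing.assert_allclose(s.absorbance[0], expect, atol=1e-12)

    def test_net_analyte_signal_linear_in_concentration(self):
        d1 = calibration_design(seed=0, max_concentration=100.0, step=100.0, replicates=1)
        s1, _ = generate_set(d1, noise=NoiseModel.zero())
        # rows: conc 0 and conc 100; net signal at 2c doubles
        blank, low = s1.absorbance[0::3][0], s1.absorbance[3]
        d2 = calibration_design(seed=0, max_concentration=200.0, step=200.0, replicates=1)
        s2, _ = generate_set(d2, noise=NoiseModel.zero())
        high = s2.absorbance[3]
        np.testing.assert_allclose(high - blank, 2 * (low - blank), atol=1e-10)

    def test_determinism_and_seed_sensitivity(self):
        d = calibration_design(seed=5)
        a, ta = generate_set(d)
        b, tb = generate_set(d)
        np.testing.assert_array_equal(a.absorbance, b.absorbance)
        assert ta.equals(tb)
        c, _ = generate_set(calibration_design(seed=6))
        assert np.abs(a.absorbance - c.absorbance).max() > 1e-6

    def test_design_counts(self):
        s, truth = generate_set(calibration_design(seed=0))
        assert s.n_samples == 156          # 13 levels x 4 replicates x 3 scans
        assert truth["replicate_group"].nunique() == 52
        s68, _ = generate_set(calibration_design(seed=0, extended=True))
        assert s68.n_samples == 68 * 3

    def test_water_band_present_at_zero_analyte(self):
        design = calibration_design(seed=1, max_concentration=0.0, replicates=1)
        s, _ = generate_set(design)
        g = s.grid.values
        water = (g >= 5000) & (g <= 5300)
        flank = (g >= 5600) & (g <= 5900)
        assert s.absorbance[:, water].mean() > s.absorbance[:, flank].mean()

    def test_edge_noise_exceeds_interior_noise(self):
        """Columns outside the retained interior carry strictly larger
        empirical noise sd — the rationale for excluding the spectral ends."""
        s, _ = generate_set(calibration_design(seed=2))
        # noise sd per column, concentration effects removed via per-group residuals
        A = s.absorbance
        groups = s.meta["replicate_group"].to_numpy()
        resid = np.vstack(
            [A[groups == grp] - A[groups == grp].mean(axis=0) for grp in np.unique(groups)]
        )
        col_sd = resid.std(axis=0, ddof=1)
        v = s.grid.values
        edge = ~((v >= INTERIOR[0]) & (v <= INTERIOR[1]))
        assert col_sd[edge].min() > col_sd[~edge].max()

    def test_ground_truth_table_carries_loading(self):
        s, truth = generate_set(calibration_design(seed=3))
        expect = truth["concentration"] * 0.974 * 0.004 / 0.1
        np.testing.assert_allclose(truth["loading_mg_per_g"], expect, rtol=1e-12)


class TestValidationSuite:
    def test_repeatability_counts(self):
        suite = generate_validation_suite(seed=0)
        rep = suite["repeatability"]
        assert rep.n_samples == 30          # 10 samples x 3 scans
        assert rep.meta["replicate_group"].nunique() == 10
        assert set(suite["selectivity"]) == {"control", "ascorbic_acid", "tyrosine", "glucose"}

    def test_inert_interferents_share_the_control_mechanism(self):
        """Ascorbate/tyrosine act through 'no interference': at equal seed
        their sets are the control set exactly (washed off the sorbent)."""
        from nirtpc.synthetic import StudyDesign

        kw = dict(concentrations=(150.0,) * 10, seed=42, role="validation")
        ctrl, _ = generate_set(StudyDesign(label="control", **kw))
        asc, _ = generate_set(StudyDesign(label="ascorbic_acid", **kw))
        np.testing.assert_array_equal(ctrl.absorbance, asc.absorbance)

    def test_glucose_contamination_biases_predictions(self):
        """With contamination on, predictions drift high and spread wider
        than the control in most seeds (the residual-sugar pattern)."""
        from nirtpc import predict_set
        from nirtpc.validation_stats import summarize

        biases, ratios = [], []
        for seed in range(10):
            s, _ = generate_set(calibration_design(seed=seed))
            rep = calibrate_set(s, PipelineConfig(seed=seed))
            suite = generate_validation_suite(seed=seed)
            stats = {}
            for name in ("control", "glucose"):
                p = predict_set(rep.model, suite["selectivity"][name], PipelineConfig(seed=seed))
                stats[name] = summarize(p["predicted_mg_l"])
            biases.append(stats["glucose"].mean - stats["control"].mean)
            ratios.append(stats["glucose"].sd / stats["control"].sd)
        assert sum(b > 0 for b in biases) >= 9
        assert sum(r > 1 for r in ratios) >= 6
        assert np.mean(ratios) > 1.0
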