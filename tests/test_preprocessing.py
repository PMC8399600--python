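"""Pretreatment operators: postconditions, exact cases, row independence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from nirtpc import (
    PreprocessPlan,
    PreprocessStep,
    RegionSpec,
    apply_plan,
    detrend,
    msc,
    sg_filter,
    snv,
)
from nirtpc.exceptions import DegenerateDataError, ParameterError
from nirtpc.preprocessing import linear_plan, reference_plan
from nirtpc.spectra_core import MODEL_REGIONS
from nirtpc.synthetic import calibration_design, generate_set

from conftest import make_set


class TestSNV:
    def test_postconditions_every_row(self, random_set):
        out = snv(random_set)
        np.testing.assert_allclose(out.absorbance.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.absorbance.std(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_hand_computed_row(self):
        s = make_set(np.array([[1.0, 2.0, 3.0]]), concentrations=[1.0])
        out = snv(s)
        np.testing.assert_allclose(out.absorbance[0], [-1.0, 0.0, 1.0], atol=1e-12)

    def test_standardized_row_is_fixed_point(self):
        row = np.array([[-1.0, 0.0, 1.0]])
        s = make_set(row, concentrations=[1.0])
        np.testing.assert_allclose(snv(s).absorbance, row, atol=1e-12)

    def test_constant_row_raises(self):
        s = make_set(np.array([[5.0, 5.0, 5.0]]), concentrations=[1.0])
        with pytest.raises(DegenerateDataError):
            snv(s)


class TestMSC:
    def test_exact_affine_distortion_removed(self, random_set):
        ref = random_set.absorbance.mean(axis=0)
        distorted = make_set(2.0 * np.tile(ref, (4, 1)) + 3.0,
                             concentrations=[1.0] * 4)
        out = msc(distorted, reference=ref)
        np.testing.assert_allclose(out.absorbance, np.tile(ref, (4, 1)), atol=1e-10)

    def test_reference_is_fixed_point(self, random_set):
        ref = random_set.absorbance.mean(axis=0)
        s = make_set(ref[None, :], concentrations=[1.0])
        np.testing.assert_allclose(msc(s, reference=ref).absorbance[0], ref, atol=1e-10)

    def test_corrected_rows_refit_to_slope_one_intercept_zero(self, random_set):
        out = msc(random_set)
        ref = random_set.absorbance.mean(axis=0)
        for row in out.absorbance:
            slope, intercept = np.polyfit(ref, row, 1)
            assert abs(slope - 1.0) < 1e-10
            assert abs(intercept) < 1e-10

    def test_zero_variance_reference_raises(self, random_set):
        with pytest.raises(DegenerateDataError):
            msc(random_set, reference=np.ones(20))


class TestDetrend:
    @pytest.mark.parametrize("degree", [0, 1, 2])
    def test_polynomial_rows_removed_exactly(self, degree):
        x = np.arange(20.0)
        row = 2.0 + 0.3 * x + (0.01 * x**2 if degree == 2 else 0.0)
        if degree == 0:
            row = np.full(20, 7.0)
        s = make_set(row[None, :], concentrations=[1.0])
        out = detrend(s, degree=degree)
        np.testing.assert_allclose(out.absorbance, 0.0, atol=1e-10)

    def test_degree_zero_is_mean_removal(self, random_set):
        out = detrend(random_set, degree=0)
        expect = random_set.absorbance - random_set.absorbance.mean(axis=1, keepdims=True)
        np.testing.assert_allclose(out.absorbance, expect, atol=1e-12)

    def test_residual_orthogonal_to_basis(self, random_set):
        out = detrend(random_set, degree=2)
        x = np.linspace(-1, 1, 20)
        for k in range(3):
            assert np.abs(out.absorbance @ x**k).max() < 1e-9

    def test_invalid_degree_rejected(self, random_set):
        with pytest.raises(ParameterError):
            detrend(random_set, degree=3)


class TestSavitzkyGolay:
    def test_constant_row_invariant(self):
        s = make_set(np.full((1, 25), 3.7), concentrations=[1.0])
        out = sg_filter(s, window=19, polyorder=0)
        np.testing.assert_allclose(out.absorbance, 3.7, atol=1e-12)

    def test_width3_moving_average_interior(self):
        s = make_set(np.array([[0.0, 3.0, 0.0, 3.0, 0.0]]), concentrations=[1.0])
        out = sg_filter(s, window=3, polyorder=0)
        np.testing.assert_allclose(out.absorbance[0, 1:4], [1.0, 2.0, 1.0], atol=1e-12)
        assert out.absorbance[0, 2] == pytest.approx(2.0)

    def test_first_derivative_of_line_is_slope(self):
        # absorbance linear in wavenumber: A = 0.01·nu  ->  dA/dnu = 0.01
        p = 15
        grid_vals = np.arange(10000.0, 10000.0 - 8 * p, -8.0)
        s = make_set((0.01 * grid_vals)[None, :], concentrations=[1.0])
        out = sg_filter(s, window=5, polyorder=1, deriv=1)
        np.testing.assert_allclose(out.absorbance[0, 2:-2], 0.01, atol=1e-10)

    def test_polynomial_reproduction_in_smoothing(self, random_set):
        x = np.arange(20.0)
        row = 1.0 + 0.2 * x - 0.01 * x**2
        s = make_set(row[None, :], concentrations=[1.0])
        out = sg_filter(s, window=7, polyorder=2)
        np.testing.assert_allclose(out.absorbance[0], row, atol=1e-9)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"window": 4, "polyorder": 0},            # even window
            {"window": 3, "polyorder": 3},            # window <= polyorder
            {"window": 99, "polyorder": 0},           # window > spectrum
            {"window": 5, "polyorder": 1, "deriv": 2},  # polyorder < deriv
        ],
    )
    def test_bad_parameters_rejected(self, random_set, kwargs):
        with pytest.raises(ParameterError):
            sg_filter(random_set, **kwargs)


class TestPlans:
    def test_reference_chain_ends_in_snv_postcondition(self):
        s, _ = generate_set(calibration_design(seed=5))
        out = apply_plan(s, reference_plan(), RegionSpec(MODEL_REGIONS))
        np.testing.assert_allclose(out.absorbance.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.absorbance.std(axis=1, ddof=1), 1.0, atol=1e-10)

    def test_empty_plan_full_region_is_identity(self, random_set):
        out = apply_plan(random_set, PreprocessPlan(()), RegionSpec(((4000.0, 10000.0),)))
        np.testing.assert_array_equal(out.absorbance, random_set.absorbance)

    def test_reference_chain_not_idempotent(self):
        s, _ = generate_set(calibration_design(seed=5))
        r = RegionSpec(MODEL_REGIONS)
        once = apply_plan(s, reference_plan(), r)
        twice = apply_plan(once, reference_plan(), RegionSpec(((4068.0, 9612.0),)))
        assert np.abs(once.absorbance - twice.absorbance).max() > 1e-6

    def test_plan_serialization_round_trip(self):
        plan = reference_plan()
        assert PreprocessPlan.from_list(plan.to_list()) == plan

    def test_linear_plan_preserves_affinity_in_concentration(self):
        # rows affine in c stay affine under detrend/reduce/SG
        rng = np.random.default_rng(0)
        base, direction = rng.normal(size=20), rng.normal(size=20)
        c = np.array([0.0, 1.0, 2.0])
        s = make_set(base + c[:, None] * direction, concentrations=c)
        out = apply_plan(s, linear_plan(), RegionSpec(((4000.0, 10000.0),)))
        mid = (out.absorbance[0] + out.absorbance[2]) / 2
        np.testing.assert_allclose(out.absorbance[1], mid, atol=1e-10)


@settings(deadline=None, max_examples=25)
@given(
    A=arrays(
        np.float64,
        (4, 12),
        elements=st.floats(-5, 5, allow_nan=False, width=64),
    ),
    perm_seed=st.integers(0, 100),
)
def test_operators_commute_with_row_permutation(A, perm_seed):
    """All operators are row-independent (MSC with an explicit reference)."""
    A = A + np.linspace(0, 1, 12)  # avoid constant rows
    s = make_set(A, concentrations=[1.0] * 4)
    perm = np.random.default_rng(perm_seed).permutation(4)
    ref = A.mean(axis=0)
    for op in (
        snv,
        lambda t: msc(t, reference=ref),
        lambda t: detrend(t, 1),
        lambda t: sg_filter(t, 5, 2),
    ):
        left = op(s).absorbance[perm]
        right = op(s.select(perm)).absorbance
        np.testing.assert_allclose(left, right, rtol=1e-12, atol=1e-12)
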