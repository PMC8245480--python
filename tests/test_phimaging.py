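"""Ratiometric pH imaging: ratio images, calibration, kymograph profiles."""

import numpy as np
import pytest

from seepflux.errors import (
    InsufficientDataError,
    InvalidInputError,
    OutOfRangeError,
)
from seepflux.phimaging import (
    CalibrationCurve,
    CalibrationPoint,
    DualChannelStack,
    KymographSpec,
    PiecewiseLinearCalibration,
    compute_ratio_image,
    extract_kymograph,
    fit_calibration,
    ratio_to_ph,
)
from seepflux.synthetic import PhSceneSpec, generate_ph_stack, ph_depth_profile

TITRATION_PHS = (8.0, 7.8, 7.7, 7.55, 7.2, 7.0, 6.8)  # flow-cell titration design


def _stack(i488, i561, b488=0.0, b561=0.0):
    return DualChannelStack(
        intensities_488=np.full((2, 3, 3), float(i488)),
        intensities_561=np.full((2, 3, 3), float(i561)),
        voxel_size_um=(1.0, 1.0, 1.0),
        background_488=b488,
        background_561=b561,
    )


class TestRatioImage:
    def test_background_subtracted_ratio(self):
        ri = compute_ratio_image(_stack(1100, 600, 100, 100))
        assert np.allclose(ri.ratios, 2.0)
        assert not ri.mask.any()

    def test_zero_denominator_masked(self):
        ri = compute_ratio_image(_stack(1100, 100, 100, 100))
        assert ri.mask.all()
        assert np.isnan(ri.ratios).all()

    def test_identity_without_backgrounds(self):
        ri = compute_ratio_image(_stack(500, 500))
        assert np.allclose(ri.ratios, 1.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InvalidInputError, match="shape"):
            DualChannelStack(
                intensities_488=np.zeros((2, 3, 3)),
                intensities_561=np.zeros((2, 3, 4)),
                voxel_size_um=(1, 1, 1),
            )


class TestCalibration:
    def test_sigmoid_parameters_recovered_from_noiseless_titration(self):
        truth = CalibrationCurve(r_min=0.2, r_max=2.0, pka=7.5)
        pts = [CalibrationPoint(ph, float(truth.ratio(ph))) for ph in TITRATION_PHS]
        fit = fit_calibration(pts)
        assert fit.r_min == pytest.approx(0.2, abs=1e-6)
        assert fit.r_max == pytest.approx(2.0, abs=1e-6)
        assert fit.pka == pytest.approx(7.5, abs=1e-6)
        assert fit.fit_residual_rms < 1e-8
        assert fit.direction == "increasing"

    def test_midpoint_and_asymptote(self):
        c = CalibrationCurve(0.2, 2.0, 7.5)
        assert c.ratio(7.5) == pytest.approx(1.1)  # (r_min + r_max)/2
        assert c.ratio(100.0) == pytest.approx(2.0)

    def test_analytic_inverse_round_trip(self):
        c = CalibrationCurve(0.2, 2.0, 7.5)
        grid = np.linspace(6.8, 8.0, 200)
        assert np.max(np.abs(c.ph(c.ratio(grid)) - grid)) < 1e-10

    def test_boundary_ratio_out_of_range(self):
        c = CalibrationCurve(0.2, 2.0, 7.5)
        with pytest.raises(OutOfRangeError):
            c.ph(2.0)
        with pytest.raises(OutOfRangeError):
            ratio_to_ph(c, 0.1)

    def test_clamp_flag_pulls_inside_range(self):
        c = CalibrationCurve(0.2, 2.0, 7.5)
        assert ratio_to_ph(c, 2.5, clamp=True) > 10  # far alkaline extrapolation

    def test_too_few_points_rejected(self):
        pts = [CalibrationPoint(ph, 1.0 + 0.1 * i) for i, ph in enumerate((7.0, 7.2, 7.4))]
        with pytest.raises(InsufficientDataError):
            fit_calibration(pts)

    def test_non_monotone_points_warn(self):
        truth = CalibrationCurve(0.2, 2.0, 7.5)
        pts = [CalibrationPoint(ph, float(truth.ratio(ph))) for ph in TITRATION_PHS]
        pts[3] = CalibrationPoint(pts[3].ph, 0.21)  # gross outlier breaks monotonicity
        with pytest.warns(UserWarning, match="non-monotone"):
            fit_calibration(pts)

    def test_piecewise_linear_alternative(self):
        truth = CalibrationCurve(0.2, 2.0, 7.5)
        pts = [CalibrationPoint(ph, float(truth.ratio(ph))) for ph in TITRATION_PHS]
        lin = fit_calibration(pts, form="linear")
        assert isinstance(lin, PiecewiseLinearCalibration)
        # interpolates the titration points exactly and inverts consistently
        for p in pts[1:-1]:
            assert lin.ratio(p.ph) == pytest.approx(p.ratio, rel=1e-12)
            assert lin.ph(p.ratio) == pytest.approx(p.ph, rel=1e-12)

    def test_decreasing_dye_direction_inferred(self):
        truth = CalibrationCurve(r_min=2.0, r_max=0.2, pka=7.5)
        pts = [CalibrationPoint(ph, float(truth.ratio(ph))) for ph in TITRATION_PHS]
        fit = fit_calibration(pts)
        assert fit.direction == "decreasing"
        grid = np.linspace(6.9, 7.9, 50)
        assert np.max(np.abs(fit.ph(fit.ratio(grid)) - grid)) < 1e-6


class TestKymograph:
    def _profile(self, spec, **kw):
        stack, _ = generate_ph_stack(spec)
        ri = compute_ratio_image(stack)
        ks = KymographSpec(start_um=(0.0, 128.0), end_um=(500.0, 128.0), **kw)
        return extract_kymograph(ri, ks, spec.calibration), ri

    def test_constant_field_gives_constant_profile(self):
        spec = PhSceneSpec(
            ph_mineral=7.85, ph_min=7.85, ph_bulk=7.85, noise_cv=0.0, seed=1
        )
        prof, _ = self._profile(spec)
        assert np.allclose(prof.ph_values, 7.85, atol=1e-9)

    def test_prescribed_gradient_recovered_under_noise(self):
        spec = PhSceneSpec(noise_cv=0.02, seed=3)
        prof, _ = self._profile(spec)
        truth = ph_depth_profile(spec)(prof.depths_um)
        rms = float(np.sqrt(np.nanmean((prof.ph_values - truth) ** 2)))
        assert rms <= 0.05
        assert prof.summary["ph_min"] == pytest.approx(7.33, abs=0.05)

    def test_band_widening_invariant_on_laterally_uniform_field(self):
        spec = PhSceneSpec(noise_cv=0.0)
        stack, _ = generate_ph_stack(spec)
        ri = compute_ratio_image(stack)
        curve = spec.calibration
        narrow = extract_kymograph(
            ri, KymographSpec((0, 128), (500, 128), width_um=13.0), curve
        )
        wide = extract_kymograph(
            ri, KymographSpec((0, 128), (500, 128), width_um=10000.0), curve
        )
        assert np.allclose(narrow.ph_values, wide.ph_values, atol=1e-9)

    def test_summary_orders_mineral_min_bulk(self):
        spec = PhSceneSpec(noise_cv=0.0)
        prof, _ = self._profile(spec)
        s = prof.summary
        assert s["ph_at_mineral"] == pytest.approx(7.65, abs=1e-6)
        assert s["ph_min"] == pytest.approx(7.33, abs=1e-6)
        assert s["ph_bulk"] == pytest.approx(7.76, abs=1e-6)
        assert s["ph_min"] <= min(s["ph_at_mineral"], s["ph_bulk"])

    def test_depth_range_limits_planes(self):
        spec = PhSceneSpec(noise_cv=0.0)
        prof, _ = self._profile(spec, depth_range_um=(0.0, 20.0))
        assert prof.depths_um.max() <= 20.0

    def test_fully_masked_plane_yields_missing_value(self):
        spec = PhSceneSpec(noise_cv=0.0)
        stack, _ = generate_ph_stack(spec)
        stack.intensities_561[5] = 0.0  # kill one plane's denominator
        ri = compute_ratio_image(stack)
        prof = extract_kymograph(
            ri, KymographSpec((0, 128), (500, 128)), spec.calibration
        )
        assert np.isnan(prof.ph_values[5])
        assert np.isfinite(prof.ph_values[6])

    def test_empty_depth_range_rejected(self):
        spec = PhSceneSpec(noise_cv=0.0)
        stack, _ = generate_ph_stack(spec)
        ri = compute_ratio_image(stack)
        with pytest.raises(InvalidInputError):
            extract_kymograph(
                ri,
                KymographSpec((0, 128), (500, 128), depth_range_um=(1000.0, 2000.0)),
                spec.calibration,
            )

    def test_intensity_first_averaging_matches_on_noiseless_data(self):
        spec = PhSceneSpec(noise_cv=0.0)
        stack, _ = generate_ph_stack(spec)
        ri = compute_ratio_image(stack)
        ks = KymographSpec((0, 128), (500, 128))
        a = extract_kymograph(ri, ks, spec.calibration, averaging="ratio")
        b = extract_kymograph(ri, ks, spec.calibration, averaging="intensity")
        assert np.allclose(a.ph_values, b.ph_values, atol=1e-9)


class TestInvariants:
    def test_masking_never_decreases_through_downstream_ops(self):
        spec = PhSceneSpec(noise_cv=0.05, seed=9, background_488=500.0)
        stack, _ = generate_ph_stack(spec)
        # push some voxels below background so they mask out
        stack.intensities_488[::7] = 0.0
        ri = compute_ratio_image(stack)
        n_unmasked_before = ri.n_unmasked
        prof = extract_kymograph(
            ri, KymographSpec((0, 128), (500, 128)), spec.calibration
        )
        assert ri.n_unmasked <= n_unmasked_before
        assert np.isfinite(prof.ph_values).sum() <= prof.ph_values.size

    def test_recovered_ratio_monotone_in_true_ph(self):
        curve = CalibrationCurve(0.2, 2.0, 7.5)
        phs = np.linspace(6.9, 7.9, 12)
        ratios = []
        for ph in phs:
            spec = PhSceneSpec(
                ph_mineral=ph, ph_min=ph, ph_bulk=ph, calibration=curve,
                noise_cv=0.0, shape=(4, 8, 8),
            )
            stack, _ = generate_ph_stack(spec)
            ratios.append(float(np.nanmean(compute_ratio_image(stack).ratios)))
        assert np.all(np.diff(ratios) > 0)
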