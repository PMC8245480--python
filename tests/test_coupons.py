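"""Coupon mass-loss stage: geometry, unit chain, regression, calibrations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seepflux.constants import CONSTANTS
from seepflux.coupons import (
    ArealDissolution,
    CouponRecord,
    DissolutionRate,
    cells_per_ml_from_od,
    condition_rate_ratio,
    coupon_areal_dissolution,
    estimate_coupon_surface_area,
    fit_dissolution_rate,
)
from seepflux.errors import (
    DegenerateDesignError,
    InsufficientDataError,
    InvalidInputError,
)


class TestSurfaceArea:
    def test_closed_cylinder_from_mass_and_density(self):
        # hand evaluation: V = 0.75/2.93 = 0.25597 cm^3, t = 0.20207 cm
        area = estimate_coupon_surface_area(750.0, 12.7, 2.93)
        assert area == pytest.approx(3.3397, abs=5e-4)

    def test_zero_thickness_limit_keeps_two_faces(self):
        faces = 2 * math.pi * 0.635**2
        assert estimate_coupon_surface_area(1e-9, 12.7, 2.93) == pytest.approx(
            faces, rel=1e-6
        )

    def test_doubling_density_halves_lateral_term_only(self):
        faces = 2 * math.pi * 0.635**2
        lateral = estimate_coupon_surface_area(750, 12.7, 2.93) - faces
        lateral2 = estimate_coupon_surface_area(750, 12.7, 2 * 2.93) - faces
        assert lateral2 == pytest.approx(lateral / 2, rel=1e-12)

    @pytest.mark.parametrize("bad", [(0, 12.7, 2.93), (750, -1, 2.93), (750, 12.7, 0)])
    def test_nonpositive_arguments_rejected(self, bad):
        with pytest.raises(InvalidInputError):
            estimate_coupon_surface_area(*bad)

    def test_implausible_thickness_warns_but_returns(self):
        with pytest.warns(UserWarning, match="thickness"):
            area = estimate_coupon_surface_area(20000.0, 12.7, 2.93)
        assert area > 0


class TestArealDissolution:
    def test_unit_conversion_oracle(self):
        # Dm = 10 mg with mean mass 750 mg -> SA 3.3397 cm^2:
        # 10 / 0.1000869 = 99.913 umol; / 3.3397 = 29.917 umol/cm^2
        rec = CouponRecord("c", "thiosulfate", 755.0, 745.0, 96.0)
        d = coupon_areal_dissolution(rec)
        total_umol = d.areal_amount_umol_cm2 * d.surface_area_cm2
        assert total_umol == pytest.approx(99.913, abs=1e-3)
        assert d.areal_amount_umol_cm2 == pytest.approx(29.917, abs=5e-3)
        assert not d.flagged

    def test_no_mass_change_gives_zero(self):
        rec = CouponRecord("c", "abiotic", 750.0, 750.0, 96.0)
        assert coupon_areal_dissolution(rec).areal_amount_umol_cm2 == 0.0

    def test_mass_gain_is_flagged_not_dropped(self):
        rec = CouponRecord("c", "abiotic", 750.0, 751.0, 96.0)
        d = coupon_areal_dissolution(rec)
        assert d.flagged
        total_umol = d.areal_amount_umol_cm2 * d.surface_area_cm2
        assert total_umol == pytest.approx(-9.9913, abs=1e-3)

    @pytest.mark.parametrize("choice", ["initial", "final", "mean"])
    def test_mass_for_area_choices_give_distinct_but_close_areas(self, choice):
        rec = CouponRecord("c", "thiosulfate", 760.0, 740.0, 96.0)
        d = coupon_areal_dissolution(rec, mass_for_area=choice)
        expected_mass = {"initial": 760.0, "final": 740.0, "mean": 750.0}[choice]
        assert d.surface_area_cm2 == pytest.approx(
            estimate_coupon_surface_area(expected_mass), rel=1e-12
        )

    @given(
        dm=st.floats(-20, 50),
        m0=st.floats(300, 1200),
        choice=st.sampled_from(["initial", "final", "mean"]),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_unit_chain_invariant(self, dm, m0, choice):
        """areal_amount x surface_area x (molar mass/1000) == mass loss."""
        rec = CouponRecord("c", "thiosulfate", m0, m0 - dm, 50.0)
        d = coupon_areal_dissolution(rec, mass_for_area=choice)
        back = d.areal_amount_umol_cm2 * d.surface_area_cm2 * CONSTANTS.mg_per_umol_caco3
        assert back == pytest.approx(dm, rel=1e-9, abs=1e-9)


def _pts(pairs, cond="thiosulfate"):
    return [
        ArealDissolution(f"c{i}", cond, y, 1.0, t) for i, (t, y) in enumerate(pairs)
    ]


class TestFitDissolutionRate:
    def test_exact_line_annualized_by_8760(self):
        r = fit_dissolution_rate(_pts([(96, 5.0), (192, 10.0), (288, 15.0)]))
        assert r.slope_per_hour == pytest.approx(0.0520833, abs=1e-7)
        assert r.rate == pytest.approx(456.25, abs=1e-10)
        assert r.rate_se == pytest.approx(0.0, abs=1e-9)
        assert r.rate == pytest.approx(r.slope_per_hour * 8760, rel=1e-15)

    def test_flat_series_gives_zero_rate(self):
        r = fit_dissolution_rate(_pts([(96, 0.0), (192, 0.0), (288, 0.0)]))
        assert r.rate == 0.0

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        t = np.repeat([96.0, 192, 288, 384, 480], 2)
        y = 0.02 * t + rng.normal(0, 2.0, t.size)
        r = fit_dissolution_rate(_pts(zip(t, y)))
        # brute-force normal equations + textbook slope s.e.
        X = np.column_stack([np.ones_like(t), t])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        s2 = resid @ resid / (t.size - 2)
        se = math.sqrt(s2 / np.sum((t - t.mean()) ** 2))
        assert r.slope_per_hour == pytest.approx(beta[1], rel=1e-10)
        assert r.intercept == pytest.approx(beta[0], rel=1e-10)
        assert r.rate_se == pytest.approx(se * 8760, rel=1e-10)

    def test_matches_statsmodels_ols(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(11)
        t = np.repeat(np.arange(1, 7) * 96.0, 2)
        y = 0.05 * t + 1.0 + rng.normal(0, 3.0, t.size)
        r = fit_dissolution_rate(_pts(zip(t, y)))
        fit = sm.OLS(y, sm.add_constant(t)).fit()
        assert r.slope_per_hour == pytest.approx(fit.params[1], rel=1e-10)
        assert r.rate_se == pytest.approx(fit.bse[1] * 8760, rel=1e-10)

    def test_force_origin_option(self):
        r = fit_dissolution_rate(
            _pts([(96, 5.0), (192, 10.0), (288, 15.0)]), force_origin=True
        )
        assert r.intercept == 0.0
        assert r.rate == pytest.approx(456.25, abs=1e-9)

    def test_identical_times_degenerate(self):
        with pytest.raises(DegenerateDesignError):
            fit_dissolution_rate(_pts([(96, 5.0), (96, 6.0)]))

    def test_single_point_insufficient(self):
        with pytest.raises(InsufficientDataError):
            fit_dissolution_rate(_pts([(96, 5.0)]))

    def test_condition_filter(self):
        pts = _pts([(96, 5.0), (192, 10.0)]) + _pts([(96, 1.0), (192, 1.5)], "abiotic")
        r = fit_dissolution_rate(pts, "abiotic")
        assert r.condition == "abiotic"
        assert r.n_coupons == 2


class TestRateRecovery:
    def test_mean_recovered_rate_unbiased_over_replicates(self):
        """Noise at 10% of the mean areal loss; 100 seeded replicates."""
        from seepflux.synthetic import CouponExperimentSpec, generate_coupon_experiment

        true_rate = 1773.97
        mean_t = 336.0  # mean of 96..576 h
        mean_areal = true_rate * mean_t / 8760.0
        sd_mg = 0.10 * mean_areal * CONSTANTS.mg_per_umol_caco3 * \
            estimate_coupon_surface_area(750.0)
        rates, ses = [], []
        for seed in range(100):
            spec = CouponExperimentSpec(
                true_rate=true_rate, mass_noise_sd_mg=sd_mg, seed=seed
            )
            records, _ = generate_coupon_experiment(spec)
            diss = [coupon_areal_dissolution(r) for r in records]
            fit = fit_dissolution_rate(diss, "thiosulfate")
            rates.append(fit.rate)
            ses.append(fit.rate_se)
        rates = np.asarray(rates)
        se_of_mean = rates.std(ddof=1) / math.sqrt(rates.size)
        assert abs(rates.mean() - true_rate) < 2 * se_of_mean
        # reported per-fit s.e. consistent with the empirical spread
        assert 0.6 < np.mean(ses) / rates.std(ddof=1) < 1.6


class TestRatiosAndOd:
    def _rate(self, v, cond="thiosulfate"):
        return DissolutionRate(cond, v, 0.0, 2, v / 8760, 0.0)

    def test_printed_rate_ratios(self):
        assert condition_rate_ratio(
            self._rate(1773.97), self._rate(152.81, "heterotrophic")
        ) == pytest.approx(11.609, abs=1e-3)
        assert condition_rate_ratio(
            self._rate(1773.97), self._rate(272.99, "abiotic")
        ) == pytest.approx(6.498, abs=1e-3)

    def test_identity_and_zero_denominator(self):
        r = self._rate(5.0)
        assert condition_rate_ratio(r, r) == 1.0
        with pytest.raises(InvalidInputError, match="zero"):
            condition_rate_ratio(r, self._rate(0.0))

    def test_od_calibration_line(self):
        assert cells_per_ml_from_od(0.07) == pytest.approx(2.3e8, rel=1e-6)
        assert cells_per_ml_from_od(0.0) == 2e7
        assert cells_per_ml_from_od(1.0) == pytest.approx(3.02e9)
        with pytest.raises(InvalidInputError):
            cells_per_ml_from_od(-0.1)
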