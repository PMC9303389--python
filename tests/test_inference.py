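"""Bell torque-law and Michaelis-Menten fits with derived quantities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stallkin.inference import (
    BellFit,
    barrier_reduction,
    extrapolate_zero_torque,
    fit_bell,
    fit_mm,
    negative_torque_report,
)
from stallkin.paper_data import bell_points_no_rapa, bell_points_rapa

NO_RAPA = [(37.0, 12600.0), (42.0, 10800.0), (52.0, 2500.0)]
RAPA = [(12.0, 983.0), (18.0, 542.0), (22.0, 365.0), (27.0, 223.0), (30.0, 181.0)]


def _normal_equations(points):
    """Independent OLS oracle: explicit normal equations on ln(1/t)."""
    x = np.array([t for t, _ in points])
    y = np.log(1.0 / np.array([l for _, l in points]))
    n = len(x)
    sxx = (x**2).sum() - x.sum() ** 2 / n
    sxy = (x * y).sum() - x.sum() * y.sum() / n
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    return slope, intercept


class TestBellFit:
    def test_two_point_line_is_exact(self):
        points = [(10.0, math.exp(5.0)), (20.0, math.exp(4.0))]
        fit = fit_bell(points)
        assert fit.slope == pytest.approx(0.1, abs=1e-12)
        assert fit.intercept == pytest.approx(-6.0, abs=1e-12)

    def test_enzyme_free_slope_matches_printed_value(self):
        fit = fit_bell(NO_RAPA)
        assert fit.slope == pytest.approx(0.11, abs=0.02)
        assert fit.slope == pytest.approx(0.1133, abs=0.0005)

    def test_enzymatic_slope_matches_printed_value(self):
        fit = fit_bell(RAPA)
        assert fit.slope == pytest.approx(0.09, abs=0.01)
        assert fit.slope == pytest.approx(0.0953, abs=0.0005)

    def test_table_selectors_agree_with_literals(self):
        assert sorted(bell_points_no_rapa()) == sorted(NO_RAPA)
        assert sorted(bell_points_rapa()) == sorted(RAPA)

    @settings(derandomize=True, max_examples=60)
    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=1.0, max_value=60.0),
                st.floats(min_value=1.0, max_value=1e5),
            ),
            min_size=2,
            max_size=8,
            unique_by=lambda p: round(p[0], 3),
        )
    )
    def test_matches_normal_equations_oracle(self, points):
        slope, intercept = _normal_equations(points)
        fit = fit_bell(points)
        assert fit.slope == pytest.approx(slope, rel=1e-9, abs=1e-12)
        assert fit.intercept == pytest.approx(intercept, rel=1e-9, abs=1e-12)

    def test_weighted_fit_runs_and_downweights_noisy_point(self):
        from stallkin.survival import ExpFit

        points = [
            (10.0, ExpFit(1000.0, 10.0, 100)),
            (20.0, ExpFit(400.0, 4.0, 100)),
            (30.0, ExpFit(500.0, 400.0, 2)),  # wildly uncertain outlier
        ]
        fw = fit_bell(points, weighted=True)
        fu = fit_bell(points, weighted=False)
        two_point = fit_bell(points[:2])
        assert abs(fw.slope - two_point.slope) < abs(fu.slope - two_point.slope)

    def test_single_point_refused(self):
        with pytest.raises(ValueError):
            fit_bell([(10.0, 100.0)])

    def test_nonpositive_lifetime_refused(self):
        with pytest.raises(ValueError):
            fit_bell([(10.0, 100.0), (20.0, -5.0)])

    def test_duplicate_torques_refused(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_bell([(10.0, 100.0), (10.0, 200.0)])


class TestZeroTorqueExtrapolation:
    def test_enzyme_free_lifetime_near_1e6_s(self):
        t0 = extrapolate_zero_torque(fit_bell(NO_RAPA))
        assert t0 == pytest.approx(9e5, rel=0.20)

    def test_enzymatic_lifetime_near_2800_s(self):
        t0 = extrapolate_zero_torque(fit_bell(RAPA))
        assert t0 == pytest.approx(2800.0, rel=0.15)

    def test_flat_line_through_lnk_minus2(self):
        fit = BellFit(slope=0.0, intercept=-2.0, slope_se=0.0, intercept_se=0.0, n_points=2)
        assert extrapolate_zero_torque(fit) == pytest.approx(math.exp(2.0))


class TestBarrierReduction:
    def test_printed_value_near_5p8_kbt(self):
        red = barrier_reduction(fit_bell(NO_RAPA), fit_bell(RAPA))
        assert red.delta_kbt == pytest.approx(5.8, rel=0.10)
        assert red.delta_kcal_per_mol == pytest.approx(3.4, rel=0.10)

    def test_identical_fits_give_zero(self):
        fit = fit_bell(RAPA)
        red = barrier_reduction(fit, fit)
        assert red.delta_kbt == pytest.approx(0.0, abs=1e-12)

    def test_lifetime_ratio_e_gives_one_kbt(self):
        a = BellFit(slope=0.1, intercept=-5.0, slope_se=0, intercept_se=0, n_points=2)
        b = BellFit(slope=0.1, intercept=-4.0, slope_se=0, intercept_se=0, n_points=2)
        assert barrier_reduction(a, b).delta_kbt == pytest.approx(1.0)


class TestNegativeTorqueReport:
    def test_enzymatic_extrapolation_comparable_to_slow_intrinsic_lifetimes(self):
        """The fitted enzymatic law at -12 pN·nm predicts removal on the
        ~1e4 s scale of the slower intrinsic measurements — the observed
        non-dissociation contradicts this naive extrapolation."""
        rep = negative_torque_report(fit_bell(RAPA), torque=-12.0)
        assert 3000.0 < rep["predicted_lifetime"] < 30000.0

    def test_enzyme_free_extrapolation_is_finite(self):
        rep = negative_torque_report(fit_bell(NO_RAPA), torque=-12.0)
        assert np.isfinite(rep["predicted_lifetime"])
        assert rep["predicted_lifetime"] > 0


class TestMMFit:
    def test_noiseless_points_recover_parameters_exactly(self):
        km, kcat = 5.0, 1e-3
        concs = [1.0, 5.0, 20.0, 100.0, 500.0]
        points = [(c, (km + c) / (kcat * c)) for c in concs]
        fit = fit_mm(points)
        assert fit.Km == pytest.approx(km, rel=1e-6)
        assert fit.kcat == pytest.approx(kcat, rel=1e-6)

    def test_enzyme_concentration_series(self):
        fit = fit_mm(
            [(3.0, 3270.0), (10.0, 1800.0), (100.0, 983.0), (500.0, 965.0)],
            substrate="RapA",
        )
        assert fit.Km == pytest.approx(7.2, abs=1.0)
        assert fit.kcat == pytest.approx(1.1e-3, rel=0.10)
        assert fit.saturated_lifetime == pytest.approx(1.0 / fit.kcat)

    def test_atp_concentration_series(self):
        fit = fit_mm(
            [(125.0, 1870.0), (200.0, 1600.0), (400.0, 1080.0), (1000.0, 983.0)],
            substrate="ATP",
        )
        assert fit.Km == pytest.approx(160.0, abs=35.0)

    def test_nonpositive_concentration_refused(self):
        with pytest.raises(ValueError, match="concentration"):
            fit_mm([(0.0, 100.0), (1.0, 50.0), (2.0, 40.0)])

    def test_too_few_points_refused(self):
        with pytest.raises(ValueError):
            fit_mm([(1.0, 100.0), (2.0, 60.0)])


class TestThetaReporting:
    def test_theta_consistent_with_slope_and_kbt(self):
        fit = fit_bell(NO_RAPA)
        assert fit.theta_rad == pytest.approx(fit.slope * fit.kbt)
        assert fit.theta_deg == pytest.approx(math.degrees(fit.theta_rad))
        assert 0.0 < fit.theta_bp < 1.0  # slightly less than one base pair
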