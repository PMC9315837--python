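import math

import numpy as np
import pytest

import memchrom as mc
from memchrom.core import FluidContext
from memchrom.pore_model import (
    PoreBundle,
    PoreSizeDistribution,
    breakthrough,
    default_time_grid,
    discretize_psd,
    flow_fractions,
    pore_count,
    pore_flowrate,
    pore_velocity,
)

MU_CM = 1.5e-4
SUPPORT_FACTOR = math.sqrt(2 * math.log(1e5))  # ~4.7985 sigma at theta = 1e-5


def two_point_psd(r1=1.0, r2=2.0):
    """Hand-built two-class distribution with equal pore counts (not flows)."""
    return PoreSizeDistribution(
        mu=0.5 * (r1 + r2),
        sigma=0.1,
        r_min=0.0,
        r_max=math.inf,
        theta=1e-5,
        n_bins=2,
        radii=np.array([r1, r2]),
        density=np.array([0.5, 0.5]),
        bin_width=1.0,
    )


class TestDiscretization:
    def test_support_edge_follows_density_threshold(self, psd_narrow):
        lo, hi = psd_narrow.support
        assert hi == pytest.approx(MU_CM + SUPPORT_FACTOR * 0.10e-4, rel=1e-9)
        assert lo == pytest.approx(MU_CM - SUPPORT_FACTOR * 0.10e-4, rel=1e-9)

    def test_catalogue_bounds_bind_for_broad_distribution(self, make_psd):
        psd = make_psd(0.35, r_max_um=2.5)
        assert psd.support[1] == pytest.approx(2.5e-4, rel=1e-12)

    def test_weights_normalized(self, make_psd):
        for sigma in (0.10, 0.35):
            psd = make_psd(sigma)
            assert psd.raw_moment(0) == pytest.approx(1.0, abs=1e-12)

    def test_mode_density_before_truncation(self, psd_narrow):
        # renormalization is negligible at theta = 1e-5, so the density at the
        # bin nearest mu is close to the Gaussian mode 1/(sqrt(2 pi) sigma)
        k = np.argmin(np.abs(psd_narrow.radii - MU_CM))
        mode = 1.0 / (math.sqrt(2 * math.pi) * 0.10e-4)
        assert psd_narrow.density[k] == pytest.approx(mode, rel=1e-3)

    def test_monodisperse_limit_concentrates_weight(self):
        psd = discretize_psd(MU_CM, 1e-10, r_min=0.5e-4, r_max=6.5e-4)
        k = np.argmax(psd.density)
        assert psd.radii[k] == pytest.approx(MU_CM, rel=1e-5)
        assert psd.raw_moment(2) == pytest.approx(MU_CM**2, rel=1e-9)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(mu=1.5, sigma=-0.1),
            dict(mu=1.5, sigma=0.1, r_min=2.0),
            dict(mu=1.5, sigma=0.1, r_max=1.0),
            dict(mu=1.5, sigma=0.1, theta=2.0),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            discretize_psd(**kwargs)

    def test_second_moment_matches_gaussian_formula(self, make_psd):
        # truncation at theta = 1e-5 leaves mu^2 + sigma^2 intact to ~1e-4
        psd = make_psd(0.10)
        assert psd.raw_moment(2) == pytest.approx(
            MU_CM**2 + (0.10e-4) ** 2, rel=1e-4
        )


class TestPoreCount:
    def test_single_pore_fills_void_area(self):
        # eps*A = pi cm^2 and r = 1 cm: exactly one pore
        col = mc.MembraneColumn(thickness=0.1, area=2 * math.pi, void_fraction=0.5)
        psd = two_point_psd(1.0, 1.0)  # both classes at r = 1
        # M2 = 1^2 * (0.5+0.5) * 1 = 1
        assert pore_count(psd, col) == pytest.approx(1.0, rel=1e-12)

    def test_linear_in_area(self, psd_narrow, disc_column):
        double = mc.MembraneColumn(
            disc_column.thickness, 2 * disc_column.area, disc_column.void_fraction
        )
        assert pore_count(psd_narrow, double) == pytest.approx(
            2 * pore_count(psd_narrow, disc_column), rel=1e-14
        )

    def test_disc_membrane_magnitude(self, psd_narrow, disc_column):
        n_p = pore_count(psd_narrow, disc_column)
        expected = 0.8 * disc_column.area / (math.pi * (MU_CM**2 + (0.1e-4) ** 2))
        assert n_p == pytest.approx(expected, rel=1e-4)


class TestHagenPoiseuille:
    fluid = FluidContext(pressure_drop=1.0e4, viscosity=0.01)

    def test_quartic_radius_law(self, disc_column):
        assert pore_flowrate(2e-4, disc_column, self.fluid) == pytest.approx(
            16 * pore_flowrate(1e-4, disc_column, self.fluid), rel=1e-14
        )

    def test_inverse_in_length(self, psd_narrow, disc_column):
        thick = mc.MembraneColumn(
            2 * disc_column.thickness, disc_column.area, disc_column.void_fraction
        )
        assert pore_flowrate(1e-4, thick, self.fluid) == pytest.approx(
            0.5 * pore_flowrate(1e-4, disc_column, self.fluid), rel=1e-14
        )

    def test_identity_construction(self):
        col = mc.MembraneColumn(thickness=0.1, area=1.0, void_fraction=0.5)
        r = 2e-4
        fluid = FluidContext(8 * 0.01 * 0.1 / (math.pi * r**4), 0.01)
        assert pore_flowrate(r, col, fluid) == pytest.approx(1.0, rel=1e-12)

    def test_flow_conservation_against_total(self, bundle_narrow):
        """Back-computing dP from the total flowrate, the per-pore flows
        weighted by the pore count integrate back to F."""
        b = bundle_narrow
        col, psd = b.column, b.psd
        eta = 0.01
        dp = 8 * eta * col.thickness * b.conditions.flowrate / (
            math.pi * b.n_pores * psd.raw_moment(4)
        )
        fluid = FluidContext(dp, eta)
        per_pore = pore_flowrate(psd.radii, col, fluid)
        total = b.n_pores * np.sum(per_pore * psd.density) * psd.bin_width
        assert total == pytest.approx(b.conditions.flowrate, rel=1e-10)


class TestFlowWeighting:
    def test_two_class_r4_ratio(self, disc_column, conditions_1ml):
        bundle = PoreBundle(two_point_psd(1.0, 2.0), disc_column, conditions_1ml)
        np.testing.assert_allclose(
            flow_fractions(bundle), [1 / 17, 16 / 17], rtol=1e-14
        )

    def test_fractions_sum_to_one(self, make_psd, disc_column, conditions_1ml):
        bundle = PoreBundle(make_psd(0.35), disc_column, conditions_1ml)
        assert flow_fractions(bundle).sum() == pytest.approx(1.0, abs=1e-12)

    def test_monodisperse_velocity_equals_interstitial(self, disc_column, conditions_1ml):
        psd = discretize_psd(MU_CM, 1e-10, r_min=0.5e-4, r_max=6.5e-4)
        bundle = PoreBundle(psd, disc_column, conditions_1ml)
        assert pore_velocity(bundle, MU_CM) == pytest.approx(
            bundle.interstitial_velocity, rel=1e-9
        )

    def test_moment_ratio_matches_gaussian_moments(self, bundle_narrow):
        mu, s = MU_CM, 0.10e-4
        m2 = mu**2 + s**2
        m4 = mu**4 + 6 * mu**2 * s**2 + 3 * s**4
        assert bundle_narrow.m2 / bundle_narrow.m4 == pytest.approx(m2 / m4, rel=1e-4)

    def test_velocity_increasing_residence_decreasing(self, bundle_narrow):
        assert np.all(np.diff(bundle_narrow.velocities) > 0)
        assert np.all(np.diff(bundle_narrow.residence_times) < 0)


class TestResidenceTimeIdentities:
    def test_flow_weighted_mean_residence_is_plug_flow_time(self, bundle_narrow):
        """E_w[tau] = L/<v>: the flow-weighted mean residence time is exactly
        the plug-flow time, independent of the distribution."""
        expected = bundle_narrow.column.thickness / bundle_narrow.interstitial_velocity
        assert bundle_narrow.tau_mean() == pytest.approx(expected, rel=1e-10)

    def test_variance_matches_closed_form(self, make_psd, disc_column, conditions_1ml):
        """Var_w(tau) = (L/<v>)^2 (M4 M0/M2^2 - 1) for the truncated moments."""
        bundle = PoreBundle(make_psd(0.26), disc_column, conditions_1ml)
        psd = bundle.psd
        ratio = psd.raw_moment(4) * psd.raw_moment(0) / psd.raw_moment(2) ** 2 - 1.0
        closed = (bundle.column.thickness / bundle.interstitial_velocity) ** 2 * ratio
        assert bundle.tau_variance() == pytest.approx(closed, rel=5e-3)


class TestBreakthrough:
    def test_monodisperse_is_a_delayed_step(self, disc_column, conditions_1ml):
        psd = discretize_psd(MU_CM, 1e-10, r_min=0.5e-4, r_max=6.5e-4)
        bundle = PoreBundle(psd, disc_column, conditions_1ml)
        t_plug = bundle.column.thickness / bundle.interstitial_velocity
        t = np.linspace(0, 2 * t_plug, 2001)
        out = breakthrough(bundle, time_grid=t)
        assert np.all(out.values[t < 0.999 * t_plug] == 0.0)
        assert np.all(out.values[t > 1.001 * t_plug] == pytest.approx(1.0, abs=1e-9))

    def test_step_response_monotone_and_bounded(self, bundle_narrow):
        out = bundle_narrow.breakthrough()
        assert np.all(np.diff(out.values) >= 0)
        assert out.values.min() >= 0.0
        assert out.values.max() <= 1.0 + 1e-12

    def test_zero_before_fastest_pore(self, bundle_narrow):
        out = bundle_narrow.breakthrough()
        assert np.all(out.values[out.times < bundle_narrow.t_lag] == 0.0)
        assert out.values[out.times > 1.01 * bundle_narrow.t_lag].max() > 0

    def test_exact_self_similarity_in_flowrate(self, psd_narrow, disc_column):
        """Scaling F by a and time by 1/a reproduces the same curve bit-near:
        the pure bundle model depends on time only through t*<v>."""
        a = 5.0
        c1 = mc.OperatingConditions.ml_per_min(1.0)
        c5 = mc.OperatingConditions.ml_per_min(a)
        b1 = PoreBundle(psd_narrow, disc_column, c1)
        b5 = PoreBundle(psd_narrow, disc_column, c5)
        t = np.linspace(0.0, 12.0, 3000)
        out1 = breakthrough(b1, time_grid=t)
        out5 = breakthrough(b5, time_grid=t / a)
        np.testing.assert_allclose(out5.values, out1.values, atol=1e-12)

    def test_truncated_grid_warns(self, bundle_narrow):
        t = np.linspace(0.0, 0.9 * bundle_narrow.residence_times.max(), 500)
        with pytest.warns(UserWarning, match="truncated"):
            breakthrough(bundle_narrow, time_grid=t)

    def test_sampled_inlet_superposition_matches_ideal_step(self, bundle_narrow):
        grid = default_time_grid(bundle_narrow)
        ideal = breakthrough(bundle_narrow, time_grid=grid)
        step = mc.Signal(np.array([0.0, grid[-1]]), np.array([1.0, 1.0]), kind="inlet")
        sampled = breakthrough(bundle_narrow, time_grid=grid, inlet=step)
        np.testing.assert_allclose(sampled.values, ideal.values, atol=1e-12)

    def test_discrete_first_moment_is_plug_flow_time(self, bundle_narrow):
        from memchrom.moments import discrete_peak_moments

        m = discrete_peak_moments(bundle_narrow)
        t_plug = bundle_narrow.column.thickness / bundle_narrow.interstitial_velocity
        assert m.mu1 == pytest.approx(t_plug, rel=1e-10)
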