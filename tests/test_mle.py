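import math

import numpy as np
import pytest
from scipy import stats as sps

from homingcues.geometry import Point2D, from_polar, polar_decompose
from homingcues.mle import (CombinedModel, FanModel, RingModel,
                            bootstrap_parameter_cis, combine_rings,
                            combined_loglik, compare_models, evaluate_surface,
                            fan_logdensity, fit_pi_model,
                            kappa_from_circular_std,
                            kappa_from_resultant_length, landmark_rings,
                            ring_logdensity)
from homingcues.synthetic import simulate_pi_endpoints


def _series_i0(x, terms=40):
    """Modified Bessel I0 by its power series, as an independent oracle."""
    total, term = 0.0, 1.0
    for k in range(terms):
        if k > 0:
            term *= (x * x / 4.0) / (k * k)
        total += term
    return total


class TestRingDensity:
    def test_peak_value(self):
        ring = RingModel(Point2D(0, 0), mu_d=10.0, sigma=2.0)
        assert ring_logdensity(10.0, ring) == pytest.approx(
            math.log(1.0 / (2.0 * math.sqrt(2.0 * math.pi))), abs=1e-9)

    def test_one_sigma_identity(self):
        ring = RingModel(Point2D(0, 0), mu_d=10.0, sigma=2.0)
        peak = ring_logdensity(10.0, ring)
        assert ring_logdensity(12.0, ring) == pytest.approx(peak - 0.5, abs=1e-12)
        assert ring_logdensity(8.0, ring) == pytest.approx(peak - 0.5, abs=1e-12)

    def test_unit_mass_by_quadrature(self):
        ring = RingModel(Point2D(0, 0), mu_d=10.0, sigma=2.0)
        d = np.linspace(10.0 - 20.0, 10.0 + 20.0, 200001)
        mass = np.trapezoid(np.exp(ring_logdensity(d, ring)), d)
        assert mass == pytest.approx(1.0, abs=1e-8)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            RingModel(Point2D(0, 0), mu_d=10.0, sigma=0.0)


class TestFanDensity:
    def test_uniform_limit(self):
        fan = FanModel(Point2D(0, 0), 0.0, mu_x=0.0, kappa=0.0)
        x = np.linspace(-math.pi, math.pi, 7)
        assert np.allclose(fan_logdensity(x, fan), math.log(1.0 / (2.0 * math.pi)))

    def test_peak_against_bessel_series(self):
        fan = FanModel(Point2D(0, 0), 0.0, mu_x=0.5, kappa=2.0)
        expected = 2.0 - math.log(2.0 * math.pi * _series_i0(2.0))
        assert fan_logdensity(0.5, fan) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("kappa", [0.1, 1.0, 5.0, 50.0])
    def test_unit_mass_by_quadrature(self, kappa):
        fan = FanModel(Point2D(0, 0), 0.0, mu_x=0.3, kappa=kappa)
        x = np.linspace(-math.pi, math.pi, 200001)
        mass = np.trapezoid(np.exp(fan_logdensity(x, fan)), x)
        assert mass == pytest.approx(1.0, abs=1e-8)

    def test_negative_kappa_rejected(self):
        with pytest.raises(ValueError):
            FanModel(Point2D(0, 0), 0.0, mu_x=0.0, kappa=-1.0)

    def test_gaussian_limit_at_large_kappa(self):
        # von Mises(mu, kappa) approaches Normal(mu, 1/sqrt(kappa)); at
        # kappa = 100 the densities agree to O(1/kappa) ~ 5e-3 at the peak
        fan = FanModel(Point2D(0, 0), 0.0, mu_x=0.0, kappa=100.0)
        x = np.linspace(-0.5, 0.5, 2001)
        diff = np.abs(np.exp(fan_logdensity(x, fan)) - sps.norm.pdf(x, 0.0, 0.1))
        assert diff.max() < 0.01


class TestKappaEstimators:
    def test_reciprocal_rule(self):
        assert kappa_from_circular_std(0.5) == pytest.approx(2.0)

    def test_uniform_limit(self):
        assert kappa_from_circular_std(float("inf")) == 0.0
        assert kappa_from_circular_std(1e9) < 1e-8

    def test_invalid_std(self):
        with pytest.raises(ValueError):
            kappa_from_circular_std(0.0)

    def test_mle_recovery_from_samples(self):
        rng = np.random.default_rng(0)
        x = rng.vonmises(0.0, 4.0, size=20000)
        r = float(np.hypot(np.cos(x).mean(), np.sin(x).mean()))
        assert kappa_from_resultant_length(r) == pytest.approx(4.0, abs=0.2)


class TestCombineRings:
    def test_single_ring_equals_ring_density(self):
        ring = RingModel(Point2D(0, 0), mu_d=10.0, sigma=2.0)
        point = Point2D(6.0, 8.0)  # at distance 10
        for mode in ("integration", "alternation"):
            assert combine_rings([ring], mode, point) == pytest.approx(
                float(ring_logdensity(10.0, ring)), abs=1e-12)

    def test_identical_cocentered_rings_preserve_argmax(self):
        ring = RingModel(Point2D(0, 0), mu_d=10.0, sigma=2.0)
        radii = np.arange(0.05, 25.0, 0.1)
        single = np.asarray([combine_rings([ring], "integration", Point2D(r, 0.0))
                             for r in radii])
        double = np.asarray([combine_rings([ring, ring], "integration", Point2D(r, 0.0))
                             for r in radii])
        assert radii[single.argmax()] == radii[double.argmax()]

    def test_two_ring_integration_peaks_at_circle_intersections(self):
        # circles of radius 10 around (0,0) and (12,0) intersect at (6, +-8)
        rings = [RingModel(Point2D(0, 0), 10.0, 1.0),
                 RingModel(Point2D(12, 0), 10.0, 1.0)]
        xs = np.arange(-5.0, 17.0, 0.1)
        ys = np.arange(0.2, 12.0, 0.1)  # upper half plane
        xx, yy = np.meshgrid(xs, ys)
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        model = CombinedModel(fan=FanModel(Point2D(0, -100), math.pi / 2, 0.0, 0.0),
                              rings_lm=tuple(rings), mode="integration")
        logs = model.log_density_at(pts)
        best = pts[int(np.argmax(logs))]
        assert abs(best[0] - 6.0) <= 0.5 and abs(best[1] - 8.0) <= 0.5

    def test_empty_ring_list_rejected(self):
        with pytest.raises(ValueError):
            combine_rings([], "integration", Point2D(0, 0))


class TestCombinedLoglik:
    def _pi_model(self, course):
        fan = FanModel(course.release, course.release_heading, course.ideal_turn, 5.0)
        ring = RingModel(course.release, 25.0, 2.0)
        return CombinedModel(fan=fan, ring_pi=ring)

    def test_single_endpoint_at_joint_mode(self, course):
        model = self._pi_model(course)
        mode_point = from_polar(course.release, course.release_heading,
                                25.0, course.ideal_turn)
        ll = combined_loglik(model, np.asarray([mode_point]))
        peak = (float(model.fan.logpdf(model.fan.mu_x))
                + float(model.ring_pi.logpdf(25.0)))
        assert ll == pytest.approx(peak, abs=1e-12)

    def test_doubling_dataset_doubles_loglik(self, course):
        model = self._pi_model(course)
        pts = simulate_pi_endpoints(course.release, course.release_heading,
                                    25.0, 2.0, course.ideal_turn, 5.0, 50, seed=0)
        ll = combined_loglik(model, pts)
        assert combined_loglik(model, np.vstack([pts, pts])) == pytest.approx(
            2.0 * ll, rel=1e-12)

    def test_matches_naive_product_then_log(self, course, env3):
        fan = FanModel(course.release, course.release_heading, course.ideal_turn, 5.0)
        ring_pi = RingModel(course.release, 25.0, 2.0)
        rings = landmark_rings(env3, sigma=2.0)
        model = CombinedModel(fan=fan, ring_pi=ring_pi, rings_lm=rings,
                              mode="alternation")
        rng = np.random.default_rng(3)
        pts = rng.uniform(-15, 15, size=(100, 2))
        naive = 0.0
        for px, py in pts:
            d, x = polar_decompose([[px, py]], course.release, course.release_heading)
            g_pi = math.exp(float(ring_pi.logpdf(d)[0]))
            f = math.exp(float(fan.logpdf(x)[0]))
            g_lm = np.mean([math.exp(float(r.logpdf(
                math.hypot(px - r.center[0], py - r.center[1])))) for r in rings])
            naive += math.log(f * g_pi * g_lm)
        assert combined_loglik(model, pts) == pytest.approx(naive, abs=1e-9)

    def test_endpoint_at_vertex_excluded_with_warning(self, course):
        model = self._pi_model(course)
        pts = np.asarray([list(course.release), [0.0, 0.0]])
        with pytest.warns(UserWarning, match="vertex"):
            ll = combined_loglik(model, pts)
        assert ll == pytest.approx(combined_loglik(model, pts[1:]))


class TestFitPiModel:
    def test_parameter_recovery(self, course):
        truth = dict(mu_d=10.0, sigma=2.0, mu_x=math.pi / 2, kappa=6.0)
        pts = simulate_pi_endpoints(course.release, course.release_heading,
                                    n=2000, seed=11, **truth)
        fit = fit_pi_model(pts, course.release, course.release_heading,
                           kappa_estimator="mle")
        assert fit.converged
        assert fit.params["mu_d"] == pytest.approx(truth["mu_d"], abs=0.15)
        assert fit.params["sigma"] == pytest.approx(truth["sigma"], abs=0.15)
        assert fit.params["mu_x"] == pytest.approx(truth["mu_x"], abs=0.05)
        assert fit.params["kappa"] == pytest.approx(truth["kappa"], rel=0.15)
        assert fit.aic == pytest.approx(8.0 - 2.0 * fit.loglik)
        assert fit.bic == pytest.approx(4.0 * math.log(fit.n_obs) - 2.0 * fit.loglik)

    def test_identical_endpoints_flagged_degenerate(self, course):
        pts = np.tile([[1.0, 2.0]], (10, 1))
        fit = fit_pi_model(pts, course.release, course.release_heading)
        assert not fit.converged and fit.params["sigma"] == 0.0

    def test_invariant_to_trial_order(self, course):
        pts = simulate_pi_endpoints(course.release, course.release_heading,
                                    10.0, 2.0, 0.5, 4.0, 500, seed=12)
        fit_a = fit_pi_model(pts, course.release, course.release_heading)
        fit_b = fit_pi_model(pts[::-1], course.release, course.release_heading)
        for key in fit_a.params:
            assert fit_a.params[key] == pytest.approx(fit_b.params[key], abs=1e-12)

    def test_insufficient_data(self, course):
        with pytest.raises(ValueError):
            fit_pi_model(np.asarray([[1.0, 2.0], [3.0, 4.0]]),
                         course.release, course.release_heading)

    def test_mle_dominates_foreign_parameters(self, course):
        """A model fitted on its own data never has lower likelihood than the
        same model carrying parameters fitted elsewhere."""
        own = simulate_pi_endpoints(course.release, course.release_heading,
                                    24.0, 3.0, course.ideal_turn, 4.0, 400, seed=13)
        other = simulate_pi_endpoints(course.release, course.release_heading,
                                      27.0, 5.0, course.ideal_turn + 0.3, 2.0,
                                      400, seed=14)
        fit_own = fit_pi_model(own, course.release, course.release_heading,
                               kappa_estimator="mle")
        fit_other = fit_pi_model(other, course.release, course.release_heading,
                                 kappa_estimator="mle")
        assert combined_loglik(fit_own.model, own) >= combined_loglik(
            fit_other.model, own)


class TestCompareModels:
    def test_same_k_orderings_consistent(self, course, env3):
        fan = FanModel(course.release, course.release_heading, course.ideal_turn, 5.0)
        ring_pi = RingModel(course.release, 25.0, 3.0)
        rings = landmark_rings(env3, sigma=2.0)
        integ = CombinedModel(fan=fan, ring_pi=ring_pi, rings_lm=rings,
                              mode="integration")
        pts = simulate_pi_endpoints(course.release, course.release_heading,
                                    25.0, 3.0, course.ideal_turn, 5.0, 200, seed=15)
        table = compare_models({"integration": integ,
                                "alternation": integ.with_mode("alternation")}, pts)
        assert table.attrs["consistent"]
        assert set(table["rank"]) == {1, 2}


class TestBootstrap:
    def test_constant_data_zero_width(self, course):
        pts = np.tile([[0.0, 5.0]], (30, 1))
        cis = bootstrap_parameter_cis(pts, Point2D(0, 0), math.pi / 2, B=200, seed=0)
        assert cis["mu_d"] == (5.0, 5.0)
        assert cis["sigma"] == (0.0, 0.0)
        assert cis["n_skipped"] == 200

    def test_width_shrinks_with_sample_size(self, course):
        widths = []
        for n in (50, 200, 800):
            pts = simulate_pi_endpoints(course.release, course.release_heading,
                                        10.0, 2.0, 0.5, 4.0, n, seed=16)
            cis = bootstrap_parameter_cis(pts, course.release,
                                          course.release_heading, B=400, seed=1)
            lo, hi = cis["mu_d"]
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_small_b_rejected(self, course):
        pts = simulate_pi_endpoints(course.release, course.release_heading,
                                    10.0, 2.0, 0.5, 4.0, 50, seed=17)
        with pytest.raises(ValueError):
            bootstrap_parameter_cis(pts, course.release, course.release_heading, B=50)


class TestSurfaces:
    def test_fan_only_wedge_mass(self):
        fan = FanModel(Point2D(0, 0), math.pi / 2, mu_x=0.0, kappa=10.0)
        model = CombinedModel(fan=fan)
        surf = evaluate_surface(model, extent=(-20, 20, -20, 20), resolution=0.25)
        assert surf.values.sum() == pytest.approx(1.0, abs=1e-8)
        xx, yy = np.meshgrid(surf.x_centers, surf.y_centers)
        _, x = polar_decompose(np.column_stack([xx.ravel(), yy.ravel()]),
                               Point2D(0, 0), math.pi / 2)
        outside = np.abs(x) > 4.0 / math.sqrt(10.0)
        assert surf.values.ravel()[outside].sum() < 0.01

    def test_ring_only_radial_profile_peaks_at_mu_d(self):
        ring = RingModel(Point2D(0, 0), mu_d=10.0, sigma=1.0)
        model = CombinedModel(fan=FanModel(Point2D(0, 0), 0.0, 0.0, 0.0),
                              ring_pi=ring)
        surf = evaluate_surface(model, resolution=0.25)
        xx, yy = np.meshgrid(surf.x_centers, surf.y_centers)
        radii = np.hypot(xx.ravel(), yy.ravel())
        bins = np.arange(0.0, radii.max() + 0.25, 0.25)
        profile, _ = np.histogram(radii, bins=bins, weights=surf.values.ravel())
        counts, _ = np.histogram(radii, bins=bins)
        with np.errstate(invalid="ignore"):
            mean_density = profile / counts
        peak_radius = bins[np.nanargmax(mean_density)]
        assert abs(peak_radius - 10.0) <= 0.5

    def test_full_model_argmax_near_goal(self, course, env3):
        fan = FanModel(course.release, course.release_heading, course.ideal_turn, 20.0)
        ring_pi = RingModel(course.release, course.home.distance, 2.0)
        model = CombinedModel(fan=fan, ring_pi=ring_pi,
                              rings_lm=landmark_rings(env3, sigma=1.0),
                              mode="integration")
        surf = evaluate_surface(model, resolution=0.25)
        peak = surf.argmax
        assert math.hypot(peak.x, peak.y) < 1.0

    def test_integration_entropy_not_above_alternation(self, course, env3):
        fan = FanModel(course.release, course.release_heading, course.ideal_turn, 6.0)
        ring_pi = RingModel(course.release, course.home.distance, 3.0)
        rings = landmark_rings(env3, sigma=2.0)
        integ = CombinedModel(fan=fan, ring_pi=ring_pi, rings_lm=rings,
                              mode="integration")
        alt = integ.with_mode("alternation")
        extent = (-40, 40, -40, 40)

        def entropy(model):
            p = evaluate_surface(model, extent=extent, resolution=0.25).values.ravel()
            p = p[p > 0]
            return float(-(p * np.log(p)).sum())

        assert entropy(integ) <= entropy(alt)

    def test_bad_resolution_rejected(self, course):
        fan = FanModel(course.release, course.release_heading, 0.0, 1.0)
        model = CombinedModel(fan=fan, ring_pi=RingModel(course.release, 10.0, 1.0))
        with pytest.raises(ValueError):
            evaluate_surface(model, resolution=0.0)


def test_normalized_loglik_converges_with_resolution(course, env3):
    """The grid-normalised log-likelihood approaches a fine-grid reference as
    the resolution shrinks (monotone error decrease over three levels)."""
    fan = FanModel(course.release, course.release_heading, course.ideal_turn, 6.0)
    ring_pi = RingModel(course.release, course.home.distance, 3.0)
    model = CombinedModel(fan=fan, ring_pi=ring_pi,
                          rings_lm=landmark_rings(env3, sigma=2.0),
                          mode="integration")
    pts = simulate_pi_endpoints(course.release, course.release_heading,
                                25.0, 3.0, course.ideal_turn, 6.0, 100, seed=18)
    ref = combined_loglik(model, pts, normalize=True, resolution=0.125)
    errors = [abs(combined_loglik(model, pts, normalize=True, resolution=r) - ref)
              for r in (2.0, 1.0, 0.5)]
    assert errors[0] > errors[1] > errors[2]
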