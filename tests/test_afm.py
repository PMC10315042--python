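"""Hertz forward model, contact detection, fitting, and map aggregation."""

import numpy as np
import pytest
from scipy.optimize import curve_fit

from ecmech.afm import (
    ForceCurve,
    ForceMap,
    NoContactError,
    analyze_curve,
    find_contact_point,
    fit_hertz,
    hertz_forward,
    map_mean_modulus,
    normalize_by_cell_count,
    to_indentation,
)
from ecmech.synthetic import noise_for_snr, simulate_force_curve, simulate_force_map


class TestHertzForward:
    def test_zero_indentation_zero_force(self):
        assert hertz_forward(1e4, 0.5, 20e-9, 0.0) == 0.0

    def test_linear_in_modulus(self, rng):
        delta = rng.uniform(0.0, 200e-9, 20)
        np.testing.assert_allclose(
            hertz_forward(2e4, 0.5, 20e-9, delta),
            2.0 * hertz_forward(1e4, 0.5, 20e-9, delta),
            rtol=1e-12,
        )

    def test_reference_value(self):
        # 10 kPa, nu 0.5, 20 nm tip, 100 nm indentation: frozen closed form
        assert hertz_forward(1e4, 0.5, 20e-9, 100e-9) == pytest.approx(
            7.95046392e-11, rel=1e-8
        )

    def test_invalid_poisson_ratio(self):
        with pytest.raises(ValueError):
            hertz_forward(1e4, 1.0, 20e-9, 1e-9)


def _flat_curve(n=50, k=5.0):
    z = np.linspace(0.0, 400e-9, n)
    return z, np.zeros(n), k


class TestToIndentation:
    def test_rigid_surface_gives_zero_indentation(self):
        # past contact the deflection tracks piezo displacement exactly
        n, ic = 60, 30
        z = np.linspace(0.0, 600e-9, n)
        d = np.where(np.arange(n) >= ic, z - z[ic], 0.0)
        ind = to_indentation(ForceCurve(z, d), ic)
        np.testing.assert_allclose(ind.delta[ic:], 0.0, atol=1e-18)

    def test_zero_deflection_gives_zero_force_full_travel(self):
        z, d, k = _flat_curve()
        ind = to_indentation(ForceCurve(z, d, k=k), 25)
        np.testing.assert_allclose(ind.force, 0.0, atol=1e-18)
        np.testing.assert_allclose(ind.delta[25:], z[25:] - z[25], rtol=1e-12)

    @pytest.mark.parametrize("bad_index", [0, 49])
    def test_contact_at_curve_edge_rejected(self, bad_index):
        z, d, k = _flat_curve()
        with pytest.raises(ValueError, match="contact index"):
            to_indentation(ForceCurve(z, d, k=k), bad_index)

    def test_round_trip_against_forward_model(self):
        # with the true contact point, the recovered (delta, F) samples obey
        # the forward law to solver precision
        sim = simulate_force_curve(25e3, seed=5)
        ind = to_indentation(sim.curve, sim.contact_index)
        post = slice(sim.contact_index, None)
        np.testing.assert_allclose(
            ind.force[post],
            hertz_forward(25e3, 0.5, 20e-9, ind.delta[post]),
            rtol=1e-12,
            atol=1e-20,
        )


class TestFindContactPoint:
    def test_noiseless_curve_exact(self):
        for E in (2e3, 80e3):
            sim = simulate_force_curve(E, seed=2)
            assert abs(find_contact_point(sim.curve) - sim.contact_index) <= 1

    def test_flat_curve_flagged_no_contact(self):
        sim = simulate_force_curve(0.0, seed=3)
        with pytest.raises(NoContactError):
            find_contact_point(sim.curve)

    def test_pure_noise_flagged_no_contact(self):
        sim = simulate_force_curve(0.0, noise_sd=1e-10, seed=4)
        with pytest.raises(NoContactError):
            find_contact_point(sim.curve)

    def test_short_curve_rejected(self):
        # a 10-sample curve cannot host both a baseline and a 9-point fit window
        z = np.linspace(0.0, 1e-7, 10)
        with pytest.raises(NoContactError, match="too short"):
            find_contact_point(ForceCurve(z, np.zeros(10)), min_post_points=9)


class TestFitHertz:
    @pytest.mark.parametrize("E_true", [0.5e3, 5e3, 50e3, 500e3])
    def test_noiseless_round_trip(self, E_true):
        sim = simulate_force_curve(E_true, seed=1)
        fit = analyze_curve(sim.curve)
        assert fit.E == pytest.approx(E_true, rel=1e-6)
        assert fit.accepted

    def test_multiplicative_noise_one_percent(self, rng):
        sim = simulate_force_curve(10e3, n_points=400, seed=6)
        ind = to_indentation(sim.curve, sim.contact_index)
        ind.force *= 1.0 + 0.01 * rng.standard_normal(ind.force.size)
        fit = fit_hertz(ind, 0.5, 20e-9)
        assert fit.E == pytest.approx(10e3, rel=0.02)

    def test_zero_force_gives_zero_modulus(self):
        z, d, k = _flat_curve()
        ind = to_indentation(ForceCurve(z, d, k=k), 25)
        assert fit_hertz(ind, 0.5, 20e-9).E == 0.0

    def test_insufficient_post_contact_points(self):
        sim = simulate_force_curve(10e3, seed=1)
        ind = to_indentation(sim.curve, sim.contact_index)
        ind.contact_index = len(ind.delta) - 3
        with pytest.raises(ValueError, match="at least 5"):
            fit_hertz(ind, 0.5, 20e-9)

    def test_garbage_fit_rejected_by_residual_threshold(self, rng):
        sim = simulate_force_curve(10e3, seed=7)
        ind = to_indentation(sim.curve, sim.contact_index)
        peak = float(np.max(ind.force))
        ind.force += rng.normal(0.0, peak, size=ind.force.size)  # SNR << 1
        assert not fit_hertz(ind, 0.5, 20e-9).accepted

    def test_linearized_fit_matches_nonlinear_optimizer(self):
        """Dual route: closed-form slope vs scipy curve_fit on noiseless data."""
        for E_true in (2e3, 40e3):
            sim = simulate_force_curve(E_true, seed=8)
            ind = to_indentation(sim.curve, sim.contact_index)
            post = ind.delta > 0
            popt, _ = curve_fit(
                lambda d, E: hertz_forward(E, 0.5, 20e-9, d),
                ind.delta[post],
                ind.force[post],
                p0=[1e3],
            )
            fit = fit_hertz(ind, 0.5, 20e-9)
            assert fit.E == pytest.approx(popt[0], rel=1e-6)


class TestForceMapAggregation:
    def test_constant_map_mean_equals_truth(self):
        fmap, _ = simulate_force_map(30e3, shape=(2, 2), seed=1, n_points=100)
        summary = map_mean_modulus(fmap)
        assert summary.mean_E == pytest.approx(30e3, rel=1e-6)
        assert summary.n_fitted == 4 and summary.n_rejected == 0

    def test_no_contact_curve_counted_as_rejected(self):
        fmap, _ = simulate_force_map(30e3, shape=(2, 2), seed=1, n_points=100)
        flat = simulate_force_curve(0.0, n_points=100, seed=2).curve
        fmap.curves[0][0] = flat
        summary = map_mean_modulus(fmap)
        assert summary.n_fitted == 3 and summary.n_rejected == 1
        assert summary.mean_E == pytest.approx(30e3, rel=1e-6)

    def test_mean_is_permutation_invariant(self):
        fmap, _ = simulate_force_map(
            20e3, shape=(2, 3), E_sigma_log=0.3, seed=9, n_points=100
        )
        summary = map_mean_modulus(fmap)
        flipped = ForceMap([row[::-1] for row in fmap.curves[::-1]], label="flip")
        assert map_mean_modulus(flipped).mean_E == pytest.approx(
            summary.mean_E, rel=1e-12
        )

    def test_lognormal_map_mean_tracks_distribution_mean(self):
        sigma = 0.3
        fmap, E_grid = simulate_force_map(
            20e3, shape=(10, 10), E_sigma_log=sigma, seed=12, n_points=100
        )
        summary = map_mean_modulus(fmap)
        dist_mean = 20e3 * np.exp(sigma**2 / 2)
        se = dist_mean * np.sqrt(np.exp(sigma**2) - 1) / 10.0
        assert abs(summary.mean_E - dist_mean) < 3 * se
        # noiseless fits recover the drawn ground truth exactly
        assert summary.mean_E == pytest.approx(E_grid.mean(), rel=1e-6)

    def test_all_rejected_map_raises(self):
        flat = simulate_force_curve(0.0, n_points=100, seed=2).curve
        fmap = ForceMap([[flat, flat]], label="dead")
        with pytest.raises(ValueError, match="no curve produced an accepted fit"):
            map_mean_modulus(fmap)


class TestNormalization:
    def test_divides_by_cell_count(self):
        assert normalize_by_cell_count(100e3, 4) == pytest.approx(25e3)
        assert normalize_by_cell_count(7.7e3, 1) == 7.7e3

    def test_invalid_cell_count(self):
        with pytest.raises(ValueError):
            normalize_by_cell_count(1e3, 0)

    def test_normalization_preserves_group_difference_sign(self):
        soft, _ = simulate_force_map(5e3, shape=(2, 2), seed=3, n_points=100)
        stiff, _ = simulate_force_map(50e3, shape=(2, 2), seed=4, n_points=100)
        cells = 10
        e_soft = normalize_by_cell_count(map_mean_modulus(soft).mean_E, cells)
        e_stiff = normalize_by_cell_count(map_mean_modulus(stiff).mean_E, cells)
        assert e_stiff > e_soft


class TestUnitsAndValidation:
    def test_curve_validation(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            ForceCurve(np.zeros(12), np.zeros(12))
        with pytest.raises(ValueError, match="spring constant"):
            ForceCurve(np.linspace(0, 1e-7, 12), np.zeros(12), k=-1.0)

    def test_modulus_invariant_under_consistent_unit_rescaling(self):
        # same physical curve expressed in different but consistent SI inputs
        sim = simulate_force_curve(10e3, seed=10)
        fit_m = analyze_curve(sim.curve)
        # re-expressing z and deflection identically (no-op) must not drift
        clone = ForceCurve(
            sim.curve.piezo_z.copy(), sim.curve.deflection.copy(), k=5.0, R=20e-9, nu=0.5
        )
        assert analyze_curve(clone).E == pytest.approx(fit_m.E, rel=1e-12)
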