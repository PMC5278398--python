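"""Lever amplification model, least-squares fits, and the bench simulator."""

import numpy as np
import pytest

from hingeforce.mechanics import (
    BenchSweep,
    LeverGeometry,
    amplification_factor,
    estimate_amplification,
    fit_line,
    simulate_bench,
    transmit_force,
)


def normal_equations(x, y):
    """Independent OLS oracle: explicit 2x2 normal-equations solve."""
    n = len(x)
    A = np.array([[n, x.sum()], [x.sum(), (x * x).sum()]])
    b = np.array([y.sum(), (x * y).sum()])
    intercept, slope = np.linalg.solve(A, b)
    return slope, intercept


class TestAmplificationFactor:
    @pytest.mark.parametrize(
        "l_temple, l_hinge, expected",
        [(69.0, 9.0, 7.67), (10.0, 10.0, 1.0), (100.0, 10.0, 10.0)],
    )
    def test_geometric_ratio(self, l_temple, l_hinge, expected):
        factor = amplification_factor(LeverGeometry(l_temple, l_hinge))
        assert factor == pytest.approx(expected, abs=0.01)

    @pytest.mark.parametrize("l_temple, l_hinge", [(-1, 5), (5, 0), (5, 9)])
    def test_invalid_geometry_rejected(self, l_temple, l_hinge):
        with pytest.raises(ValueError):
            LeverGeometry(l_temple, l_hinge)


class TestTransmitForce:
    def test_examples(self):
        geom = LeverGeometry(69.0, 9.0)
        assert transmit_force(1.0, geom) == pytest.approx(7.67, abs=0.01)
        assert transmit_force(0.0, geom) == 0.0
        assert transmit_force(2.0, LeverGeometry(50.0, 10.0)) == pytest.approx(10.0)

    def test_linear_and_homogeneous(self):
        geom = LeverGeometry(69.0, 9.0)
        f = np.array([0.1, 0.5, 2.0])
        np.testing.assert_allclose(transmit_force(3 * f, geom), 3 * transmit_force(f, geom))
        np.testing.assert_allclose(
            transmit_force(f[0] + f[1], geom),
            transmit_force(f[0], geom) + transmit_force(f[1], geom),
        )

    def test_negative_force_rejected(self):
        with pytest.raises(ValueError):
            transmit_force(-0.1, LeverGeometry(69.0, 9.0))


class TestFitLine:
    def test_exact_line(self):
        x = np.arange(5.0)
        fit = fit_line(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)
        assert 0 < fit.p_value <= 1

    def test_flat_response(self):
        fit = fit_line(np.arange(5.0), np.full(5, 3.0))
        assert fit.slope == 0.0
        assert fit.r_squared == 0.0

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        x = rng.uniform(0, 10, 50)
        y = 3.2 * x - 1.7 + rng.normal(0, 0.5, 50)
        fit = fit_line(x, y)
        slope, intercept = normal_equations(x, y)
        assert fit.slope == pytest.approx(slope, abs=1e-9)
        assert fit.intercept == pytest.approx(intercept, abs=1e-9)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            fit_line(np.arange(2.0), np.arange(2.0))
        with pytest.raises(ValueError):
            fit_line(np.ones(5), np.arange(5.0))
        with pytest.raises(ValueError):
            fit_line(np.arange(5.0), np.arange(4.0))


class TestBenchSimulation:
    def test_noise_free_ratio_is_geometric_everywhere(self):
        geom = LeverGeometry(69.0, 9.0)
        sweep = simulate_bench(geom, noise_sd=0.0)
        positive = sweep.F_temple > 0
        np.testing.assert_allclose(
            sweep.F_hinge[positive] / sweep.F_temple[positive],
            amplification_factor(geom),
        )

    def test_noise_free_regression_recovers_factor_exactly(self):
        geom = LeverGeometry(69.0, 9.0)
        fit = estimate_amplification(simulate_bench(geom, noise_sd=0.0))
        assert fit.slope == pytest.approx(amplification_factor(geom), rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_hinge_displacement_slope_is_stiffness_times_factor(self):
        # 0.44 N/mm temple stiffness through a factor-7.52 lever
        geom = LeverGeometry(75.2, 10.0)
        sweep = simulate_bench(geom, stiffness_temple=0.44, noise_sd=0.0)
        fit = fit_line(sweep.displacement, sweep.F_hinge)
        assert fit.slope == pytest.approx(3.31, rel=0.01)

    def test_noisy_slope_within_5_percent_over_100_seeds(self):
        geom = LeverGeometry(69.0, 9.0)
        truth = amplification_factor(geom)
        # noise sd = 2% of the temple force range (0.44 N/mm over 5 mm)
        noise_sd = 0.02 * 0.44 * 5.0
        slopes = [
            estimate_amplification(
                simulate_bench(geom, noise_sd=noise_sd, seed=seed)
            ).slope
            for seed in range(100)
        ]
        deviation = np.abs(np.array(slopes) / truth - 1)
        assert deviation.max() < 0.05

    def test_low_force_restriction_widens_slope_spread(self):
        # mirrors the bench observation that data below 0.5 N scatter more
        geom = LeverGeometry(69.0, 9.0)
        noise_sd = 0.05
        full, restricted = [], []
        for seed in range(50):
            sweep = simulate_bench(geom, noise_sd=noise_sd, seed=seed)
            full.append(estimate_amplification(sweep).slope)
            low = sweep.F_temple < 0.5
            sub = BenchSweep(
                displacement=sweep.displacement[low],
                F_temple=sweep.F_temple[low],
                F_hinge=sweep.F_hinge[low],
            )
            restricted.append(estimate_amplification(sub).slope)
        assert np.std(restricted) > np.std(full)

    def test_determinism(self):
        a = simulate_bench(noise_sd=0.1, seed=3)
        b = simulate_bench(noise_sd=0.1, seed=3)
        np.testing.assert_array_equal(a.F_temple, b.F_temple)
        np.testing.assert_array_equal(a.F_hinge, b.F_hinge)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            simulate_bench(n_steps=2)
        with pytest.raises(ValueError):
            simulate_bench(step=0.0)

    def test_sweep_validation(self):
        with pytest.raises(ValueError):
            BenchSweep(
                displacement=np.array([1.0, 0.5]),
                F_temple=np.zeros(2),
                F_hinge=np.zeros(2),
            )
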