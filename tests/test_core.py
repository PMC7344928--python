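"""Unit tests for the stencil operators and the explicit solver."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import diffdenoise as dd
from diffdenoise.exceptions import (
    InvalidInputError,
    NumericalDivergenceError,
    ParameterError,
    ShapeError,
)
from oracles import (
    div_oracle,
    energy_oracle,
    grad_oracle,
    lambda_oracle,
    linear_smooth_oracle,
    step_oracle,
)


class TestCenteredGradient:
    def test_constant_field_has_zero_gradient(self):
        g = dd.centered_gradient(np.full((5, 6), 3.7), dx=0.5)
        assert np.array_equal(g.row, np.zeros((5, 6)))
        assert np.array_equal(g.col, np.zeros((5, 6)))

    def test_column_ramp_with_edge_replication(self):
        # u_ij = j: interior derivative 1, halved at the replicated borders
        u = np.tile(np.arange(6.0), (4, 1))
        g = dd.centered_gradient(u, dx=1.0)
        expected = np.tile([0.5, 1, 1, 1, 1, 0.5], (4, 1))
        np.testing.assert_allclose(g.col, expected)
        np.testing.assert_allclose(g.row, 0.0)

    def test_center_spike_stencil_values(self):
        u = np.zeros((3, 3))
        u[1, 1] = 1.0
        g = dd.centered_gradient(u)
        assert g.col[1, 0] == 0.5
        assert g.col[1, 1] == 0.0
        assert g.col[1, 2] == -0.5

    @pytest.mark.parametrize("shape", [(5, 5), (6, 9), (9, 6)])
    def test_matches_loop_oracle(self, rng, shape):
        u = rng.random(shape)
        g = dd.centered_gradient(u, dx=0.7)
        gr, gc = grad_oracle(u, dx=0.7)
        np.testing.assert_allclose(g.row, gr, atol=1e-12, rtol=0)
        np.testing.assert_allclose(g.col, gc, atol=1e-12, rtol=0)

    def test_rejects_nonfinite_and_small_inputs(self):
        with pytest.raises(InvalidInputError):
            dd.centered_gradient(np.array([[1, 2, np.nan]] * 3))
        with pytest.raises(ShapeError):
            dd.centered_gradient(np.ones((2, 5)))


class TestEstimateLambda:
    def test_constant_image_returns_floor(self):
        assert dd.estimate_lambda(np.ones((4, 4))) == 1e-12

    def test_center_spike_hand_enumeration(self):
        # 3x3 spike: four gradient vectors of norm 0.5, the rest zero
        u = np.zeros((3, 3))
        u[1, 1] = 1.0
        assert dd.estimate_lambda(u, 0.9) == pytest.approx(0.9 * 2.0 / 9, abs=1e-15)

    def test_scale_equivariance(self, rng):
        u = rng.random((8, 8))
        lam = dd.estimate_lambda(u)
        for c in (0.5, 3.0, 17.0):
            assert dd.estimate_lambda(c * u) == pytest.approx(c * lam, rel=1e-12)

    def test_matches_loop_oracle(self, rng):
        u = rng.random((6, 7))
        assert dd.estimate_lambda(u, 0.9, 1e-12, 1.3) == pytest.approx(
            lambda_oracle(u, 0.9, 1e-12, 1.3), abs=1e-14
        )


class TestEdgeWeights:
    def test_analytic_values(self):
        # w(0) = 1, w(lambda) = 1/2, w(3 lambda) = 1/10
        lam = 0.37
        g = dd.VectorField(np.array([[0.0, lam, 3 * lam]] * 3), np.zeros((3, 3)))
        w = dd.edge_weights(g, lam)
        np.testing.assert_allclose(w[:, 0], 1.0)
        np.testing.assert_allclose(w[:, 1], 0.5)
        np.testing.assert_allclose(w[:, 2], 0.1)

    def test_range_and_joint_scale_invariance(self, rng):
        g = dd.VectorField(rng.normal(size=(6, 6)), rng.normal(size=(6, 6)))
        w = dd.edge_weights(g, 0.2)
        assert np.all(w > 0) and np.all(w <= 1)
        w_scaled = dd.edge_weights(dd.VectorField(5 * g.row, 5 * g.col), 5 * 0.2)
        np.testing.assert_allclose(w, w_scaled, rtol=1e-12)

    def test_nonpositive_lambda_rejected(self):
        g = dd.VectorField(np.zeros((3, 3)), np.zeros((3, 3)))
        with pytest.raises(ParameterError):
            dd.edge_weights(g, 0.0)


class TestDivergence:
    def test_constant_vector_field_vanishes(self):
        F = dd.VectorField(np.full((5, 5), 2.0), np.full((5, 5), -1.0))
        np.testing.assert_array_equal(dd.divergence(F), np.zeros((5, 5)))

    def test_ramp_divergence(self):
        F = dd.VectorField(np.zeros((4, 6)), np.tile(np.arange(6.0), (4, 1)))
        d = dd.divergence(F)
        np.testing.assert_allclose(d[:, 1:-1], 1.0)

    def test_wide_stencil_exact_on_quadratic(self):
        # D0 o D0 applied to j^2 is exact (= 2) away from the borders
        u = np.tile(np.arange(9.0) ** 2, (5, 1))
        d = dd.divergence(dd.centered_gradient(u))
        np.testing.assert_allclose(d[:, 2:-2], 2.0, atol=1e-12)

    def test_matches_loop_oracle(self, rng):
        fr, fc = rng.random((8, 5)), rng.random((8, 5))
        np.testing.assert_allclose(
            dd.divergence(dd.VectorField(fr, fc), dx=0.9),
            div_oracle(fr, fc, dx=0.9),
            atol=1e-12,
            rtol=0,
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            dd.divergence(dd.VectorField(np.zeros((4, 4)), np.zeros((5, 4))))


class TestDiffusionStep:
    def test_constant_fixed_point_is_exact(self):
        u = np.full((6, 6), 0.42)
        cfg = dd.SolverConfig(alpha=0.1, beta=0.3, n_steps=1)
        out = dd.diffusion_step(u, u.copy(), cfg, lam=0.1)
        np.testing.assert_array_equal(out, u)

    def test_two_constants_closed_form(self):
        a, b = 0.2, 0.9
        cfg = dd.SolverConfig(alpha=0.1, beta=0.3, dt=1.0, n_steps=1)
        out = dd.diffusion_step(np.full((5, 5), a), np.full((5, 5), b), cfg, lam=1.0)
        np.testing.assert_allclose(out, a + 0.1 * 0.3 * (b - a), rtol=1e-15)

    def test_matches_loop_oracle(self, random_pair):
        u, f = random_pair
        cfg = dd.SolverConfig(alpha=0.1, beta=0.3, dt=1.0, dx=1.0, n_steps=1)
        lam = dd.estimate_lambda(u)
        np.testing.assert_allclose(
            dd.diffusion_step(u, f, cfg, lam),
            step_oracle(u, f, 0.1, 0.3, 1.0, 1.0, lam),
            atol=1e-12,
            rtol=0,
        )

    def test_shape_mismatch_rejected(self):
        cfg = dd.SolverConfig()
        with pytest.raises(ShapeError):
            dd.diffusion_step(np.zeros((4, 4)), np.zeros((5, 5)), cfg, 1.0)


class TestSolve:
    def test_zero_steps_returns_input_with_single_record(self, rng):
        f = rng.random((5, 5))
        u, trace = dd.solve(f, dd.SolverConfig(n_steps=0))
        np.testing.assert_array_equal(u, f)
        assert len(trace.records) == 1 and trace.records[0].step == 0

    def test_linear_limit_matches_loop_oracle(self, rng):
        # w forced to 1 (lambda = inf) and beta = 0: pure wide-stencil smoothing
        f = rng.random((7, 7))
        cfg = dd.SolverConfig(
            alpha=0.2, beta=0.0, n_steps=5, lambda_mode=math.inf, record_every=5
        )
        u, _ = dd.solve(f, cfg)
        np.testing.assert_allclose(
            u, linear_smooth_oracle(f.copy(), 0.2, 1.0, 1.0, 5), atol=1e-12, rtol=0
        )

    def test_single_step_equals_diffusion_step(self, rng):
        f = rng.random((6, 6))
        cfg = dd.SolverConfig(alpha=0.1, beta=0.2, n_steps=1)
        u, trace = dd.solve(f, cfg)
        lam = dd.estimate_lambda(f)
        np.testing.assert_allclose(
            u, dd.diffusion_step(f, f, cfg, lam), atol=1e-14, rtol=0
        )
        assert trace.records[-1].lambda_used == pytest.approx(lam)

    def test_constant_image_invariant_many_steps(self):
        f = np.full((9, 9), 0.31)
        for beta in (0.0, 0.5):
            u, _ = dd.solve(f, dd.SolverConfig(alpha=0.5, beta=beta, n_steps=50))
            np.testing.assert_array_equal(u, f)

    def test_trace_steps_increase_and_tau_matches(self, rng):
        f = rng.random((6, 6))
        cfg = dd.SolverConfig(alpha=0.1, beta=0.3, n_steps=25, record_every=7)
        _, trace = dd.solve(f, cfg)
        steps = trace.steps
        assert steps[0] == 0 and steps[-1] == 25
        assert np.all(np.diff(steps) > 0)
        for r in trace.records:
            assert r.tau == pytest.approx(0.1 * 0.3 * r.step)

    def test_tau_falls_back_to_step_count_without_fidelity(self, rng):
        _, trace = dd.solve(
            rng.random((5, 5)), dd.SolverConfig(alpha=0.1, beta=0.0, n_steps=4)
        )
        assert [r.tau for r in trace.records] == [0.0, 1.0, 2.0, 3.0, 4.0]

    def test_reference_shape_mismatch_rejected(self, rng):
        with pytest.raises(ShapeError):
            dd.solve(
                rng.random((5, 5)),
                dd.SolverConfig(n_steps=1),
                reference=np.zeros((6, 6)),
            )

    def test_divergence_error_names_the_step(self):
        # alpha far beyond the stability bound on a worst-mode field blows up
        i = np.arange(32)
        f = 0.5 + 0.4 * np.cos(np.pi * (i[:, None] + 0.5) / 2) * np.cos(
            np.pi * (i[None, :] + 0.5) / 2
        )
        with pytest.warns(RuntimeWarning):
            cfg = dd.SolverConfig(
                alpha=10.0, beta=0.0, n_steps=500, lambda_mode=math.inf,
                record_every=1,
            )
        with pytest.raises(NumericalDivergenceError) as exc:
            dd.solve(f, cfg)
        assert exc.value.step > 0

    def test_early_stop_on_stale_psnr(self, rng):
        f0 = dd.make_cartoon_phantom(64, 0)
        f = dd.add_gaussian_noise(f0, variance=0.05, seed=0)
        cfg = dd.SolverConfig(
            alpha=0.1, beta=0.02, n_steps=4000, record_every=20,
            patience=3, track_ssim=False,
        )
        _, trace = dd.solve(f, cfg, reference=f0)
        assert trace.records[-1].step < 4000


class TestEnergy:
    def test_constant_closed_form(self):
        u = np.full((4, 5), 0.6)
        w = np.ones((4, 5))
        cfg = dd.SolverConfig(alpha=0.1, beta=0.3, n_steps=1)
        lam = 0.25
        # only the lambda^2 (w - ln w) = lambda^2 term survives
        assert dd.energy(u, u.copy(), w, cfg, lam) == pytest.approx(
            lam**2 * 20, rel=1e-14
        )

    def test_matches_scalar_oracle(self, rng):
        u, f = rng.random((4, 4)), rng.random((4, 4))
        lam = dd.estimate_lambda(u)
        w = dd.edge_weights(dd.centered_gradient(u), lam)
        cfg = dd.SolverConfig(alpha=0.1, beta=0.3, n_steps=1)
        assert dd.energy(u, f, w, cfg, lam) == pytest.approx(
            energy_oracle(u, f, w, 0.1, 0.3, 1.0, lam), abs=1e-12
        )

    def test_edge_stopping_weight_is_pointwise_optimal(self, rng):
        # the closed-form w minimises the integrand among perturbed weights
        u, f = rng.random((4, 4)), rng.random((4, 4))
        lam = dd.estimate_lambda(u)
        cfg = dd.SolverConfig(alpha=0.1, beta=0.3, n_steps=1)
        w_bar = dd.edge_weights(dd.centered_gradient(u), lam)
        e_bar = dd.energy(u, f, w_bar, cfg, lam)
        for _ in range(100):
            w_pert = np.clip(w_bar * rng.uniform(0.2, 1.8, w_bar.shape), 1e-9, 1.0)
            assert dd.energy(u, f, w_pert, cfg, lam) >= e_bar - 1e-12

    def test_invalid_weight_rejected(self, rng):
        u, f = rng.random((4, 4)), rng.random((4, 4))
        cfg = dd.SolverConfig()
        with pytest.raises(ParameterError):
            dd.energy(u, f, np.full((4, 4), 1.5), cfg, 1.0)


class TestRescaleBeta:
    @pytest.mark.parametrize(
        "beta,L,expected",
        [
            (0.3, 512, 0.3),
            (0.3, 1024, 0.15),
            (0.2, 171, 0.2 * 512 / 171),
        ],
    )
    def test_values(self, beta, L, expected):
        assert dd.rescale_beta(beta, L) == pytest.approx(expected, rel=1e-12)

    def test_invalid_resolution(self):
        with pytest.raises(ParameterError):
            dd.rescale_beta(0.3, 0)


class TestBestBetaSweep:
    def test_single_candidate_is_argmax(self, rng):
        f0 = dd.make_cartoon_phantom(64, 0)
        f = dd.add_gaussian_noise(f0, variance=0.05, seed=0)
        cfg = dd.SolverConfig(alpha=0.1, n_steps=20, record_every=5)
        sweep = dd.best_beta_sweep(f, f0, [0.1], cfg)
        assert sweep.best_beta == 0.1
        assert sweep.best_beta_final == 0.1

    def test_matches_independent_solve_runs(self):
        # no state may leak between the beta runs
        f0 = dd.make_cartoon_phantom(64, 1)
        f = dd.add_gaussian_noise(f0, variance=0.05, seed=1)
        betas = [0.05, 0.3]
        cfg = dd.SolverConfig(alpha=0.1, n_steps=30, record_every=5)
        sweep = dd.best_beta_sweep(f, f0, betas, cfg)
        for entry in sweep.entries:
            solo_cfg = dd.SolverConfig(
                alpha=0.1, beta=entry.beta, n_steps=30, record_every=5,
                track_ssim=False,
            )
            u, trace = dd.solve(f, solo_cfg, reference=f0)
            np.testing.assert_array_equal(entry.final_image, u)
            assert entry.final_psnr == trace.records[-1].psnr

    def test_empty_betas_rejected(self, rng):
        f = rng.random((5, 5))
        with pytest.raises(ParameterError):
            dd.best_beta_sweep(f, f, [], dd.SolverConfig())


class TestSolverConfig:
    def test_rejects_bad_parameters(self):
        with pytest.raises(ParameterError):
            dd.SolverConfig(alpha=-1)
        with pytest.raises(ParameterError):
            dd.SolverConfig(beta=-0.1)
        with pytest.raises(ParameterError):
            dd.SolverConfig(lambda_mode="bogus")
        with pytest.raises(ParameterError):
            dd.SolverConfig(lambda_mode=-2.0)

    def test_warns_beyond_stability_bound(self):
        with pytest.warns(RuntimeWarning):
            dd.SolverConfig(alpha=1.2)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    c=st.floats(min_value=0.01, max_value=100),
    seed=st.integers(min_value=0, max_value=2**16),
)
def test_lambda_scale_equivariance_property(c, seed):
    u = np.random.default_rng(seed).random((6, 6))
    lam = dd.estimate_lambda(u)
    if c * lam > 1e-10:  # above the floor
        assert dd.estimate_lambda(c * u) == pytest.approx(c * lam, rel=1e-9)
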