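"""The alternating Bregman TV solver: deblur step, outer loop, histories."""

import numpy as np
import pytest

from bregrestore import (
    DegradationSpec,
    SolverConfig,
    chambolle_denoise,
    convolve,
    deblur_step,
    degrade,
    gaussian_kernel,
    psnr,
    relative_difference,
    restore_tv,
)


def dense_normal_solve(f_k, g, kernel, cfg):
    """Direct dense solve of (lam A^T A + gam I) u = lam A^T f_k + gam g."""
    n = f_k.size
    A = np.zeros((n, n))
    for i in range(n):
        e = np.zeros(n)
        e[i] = 1.0
        A[:, i] = convolve(e.reshape(f_k.shape), kernel).ravel()
    M = cfg.lambda_fid * A.T @ A + cfg.gamma_couple * np.eye(n)
    rhs = cfg.lambda_fid * A.T @ f_k.ravel() + cfg.gamma_couple * g.ravel()
    return np.linalg.solve(M, rhs).reshape(f_k.shape)


class TestDeblurStep:
    def test_identity_kernel_closed_form(self, rng, identity_kernel):
        cfg = SolverConfig(lambda_fid=100.0, gamma_couple=10.0)
        f_k, g = rng.random((16, 16)), rng.random((16, 16))
        u = deblur_step(f_k, g, identity_kernel, cfg)
        closed = (100.0 * f_k + 10.0 * g) / 110.0
        assert np.abs(u - closed).max() < 1e-12

    def test_fft_matches_dense_solve(self, rng):
        from bregrestore import PSFKernel

        kernel = PSFKernel.from_array(rng.random((3, 3)))
        cfg = SolverConfig(lambda_fid=7.0, gamma_couple=3.0)
        f_k, g = rng.random((16, 16)), rng.random((16, 16))
        u_fft = deblur_step(f_k, g, kernel, cfg)
        u_dense = dense_normal_solve(f_k, g, kernel, cfg)
        assert np.abs(u_fft - u_dense).max() < 1e-8

    def test_cg_agrees_with_fft(self, rng, blur5):
        cfg_fft = SolverConfig(lambda_fid=50.0, gamma_couple=5.0, deblur_mode="fft")
        cfg_cg = SolverConfig(
            lambda_fid=50.0, gamma_couple=5.0, deblur_mode="cg", cg_tol=1e-12
        )
        f_k, g = rng.random((16, 16)), rng.random((16, 16))
        u_fft = deblur_step(f_k, g, blur5, cfg_fft)
        u_cg = deblur_step(f_k, g, blur5, cfg_cg)
        assert np.abs(u_fft - u_cg).max() < 1e-6


class TestRelativeDifference:
    def test_closed_forms(self, rng):
        u = rng.random((6, 6)) + 0.1
        assert relative_difference(u, u) == 0.0
        assert abs(relative_difference(u, 2 * u) - 1.0) < 1e-12

    def test_matches_loop_computation(self, rng):
        a, b = rng.random((7, 7)), rng.random((7, 7))
        num = sum((b[i, j] - a[i, j]) ** 2 for i in range(7) for j in range(7))
        den = sum(a[i, j] ** 2 for i in range(7) for j in range(7))
        assert abs(relative_difference(a, b) - np.sqrt(num / den)) < 1e-12

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError):
            relative_difference(np.zeros((4, 4)), np.ones((4, 4)))


class TestRestoreTV:
    def test_identity_noiseless_recovers_input(self, piecewise64, identity_kernel):
        # fidelity-dominated limit: the returned iterate is the denoised g,
        # whose deviation from f scales as 1/gamma, so both weights are large
        cfg = SolverConfig(lambda_fid=1e4, gamma_couple=1e4, max_outer=5, outer_tol=1e-12)
        res = restore_tv(piecewise64, identity_kernel, cfg)
        assert psnr(piecewise64, res.restored) > 60.0

    def test_residual_monotone_on_noiseless_blur(self, smooth64, blur5):
        f = convolve(smooth64, blur5)
        res = restore_tv(f, blur5, SolverConfig(max_outer=30, outer_tol=1e-12))
        r = np.array(res.state.residual_history)
        assert np.all(np.diff(r) <= 1e-12)
        assert len(r) == len(res.state.reldiff_history) == res.iterations_used

    def test_psnr_improves_on_degraded_input(self, piecewise64, blur5):
        f = degrade(piecewise64, DegradationSpec(blur5, 0.01, seed=0))
        res = restore_tv(f, blur5)
        assert psnr(piecewise64, res.restored) > psnr(piecewise64, f) + 2.0

    def test_noiseless_residual_vanishes(self, smooth64, blur5):
        # fixed-point consistency: an invertible blur with no noise is undone
        f = convolve(smooth64, blur5)
        res = restore_tv(f, blur5, SolverConfig(max_outer=50, outer_tol=1e-12))
        assert res.state.residual_history[-1] < 1e-3 * np.linalg.norm(f)

    def test_identity_reduces_to_iterated_denoising(self, rng, identity_kernel):
        # with A = I and one inner alternation, the first u is the closed form
        f = rng.random((16, 16))
        cfg = SolverConfig(inner_iters=1, max_outer=1, outer_tol=1e-12)
        res = restore_tv(f, identity_kernel, cfg)
        u1 = (cfg.lambda_fid * f + cfg.gamma_couple * f) / (cfg.lambda_fid + cfg.gamma_couple)
        g1 = chambolle_denoise(u1, cfg.gamma_couple, tol=cfg.denoise_tol, max_iter=cfg.denoise_max_iter)
        assert np.abs(res.restored - g1).max() < 1e-14

    def test_inner_alternation_decreases_split_objective(self, rng, blur5):
        # with the outer loop frozen, the alternation minimizes
        #   lam/2 ||Au - f||^2 + TV(g) + gam/2 ||u - g||^2
        from bregrestore.tv import tv_norm

        f = degrade(rng.random((32, 32)), DegradationSpec(blur5, 0.01, seed=1))
        cfg = SolverConfig(denoise_tol=1e-8, denoise_max_iter=400)
        u, g = f.copy(), f.copy()
        energies = []
        for _ in range(8):
            u = deblur_step(f, g, blur5, cfg)
            g = chambolle_denoise(u, cfg.gamma_couple, tol=cfg.denoise_tol, max_iter=cfg.denoise_max_iter)
            e = (
                0.5 * cfg.lambda_fid * np.sum((convolve(u, blur5) - f) ** 2)
                + tv_norm(g)
                + 0.5 * cfg.gamma_couple * np.sum((u - g) ** 2)
            )
            energies.append(e)
        assert np.all(np.diff(np.array(energies)) <= 1e-8)

    def test_max_outer_without_tol_flags_nonconvergence(self, piecewise64, blur5):
        f = degrade(piecewise64, DegradationSpec(blur5, 0.02, seed=0))
        res = restore_tv(f, blur5, SolverConfig(max_outer=3, outer_tol=1e-12))
        assert not res.converged and res.iterations_used == 3

    def test_deterministic(self, piecewise64, blur5):
        f = degrade(piecewise64, DegradationSpec(blur5, 0.01, seed=0))
        cfg = SolverConfig(max_outer=5, outer_tol=1e-12)
        a = restore_tv(f, blur5, cfg)
        b = restore_tv(f, blur5, cfg)
        assert np.array_equal(a.restored, b.restored)
        assert a.state.residual_history == b.state.residual_history
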