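"""Adjoint gradient/Hessian correctness and the inexact Newton-CG solver."""

import numpy as np
import pytest

import gliomatwin as gt
from gliomatwin.linear import DenseGaussianPrior, LinearInverseProblem
from conftest import make_inverse_problem


@pytest.fixture(scope="module")
def points(small_problem):
    """Three random parameter points around the prior mean."""
    rng = np.random.default_rng(10)
    pr = small_problem.prior
    return [pr.mean + s * rng.standard_normal(small_problem.dim)
            for s in (0.0, 0.1, 0.2)]


class TestAdjointGradient:
    def test_central_difference_check(self, small_problem, points):
        """Directional derivatives at 3 points x 5 directions, RT events
        inside the window, relative error < 1e-5."""
        rng = np.random.default_rng(1)
        for m in points:
            g = small_problem.grad(m)
            for _ in range(5):
                v = rng.standard_normal(small_problem.dim)
                v /= np.linalg.norm(v)
                eps = 1e-5
                fd = (
                    small_problem.cost(m + eps * v).total
                    - small_problem.cost(m - eps * v).total
                ) / (2 * eps)
                assert abs(fd - g @ v) / max(abs(fd), 1e-12) < 1e-5

    def test_prior_only_gradient_decouples(self, small_disk, therapy_schedule):
        """With (effectively) infinite noise the gradient is the prior's."""
        problem, _, _ = make_inverse_problem(
            small_disk, therapy_schedule, noise_var=1e12
        )
        rng = np.random.default_rng(2)
        m = problem.prior.mean + 0.2 * rng.standard_normal(problem.dim)
        g = problem.grad(m)
        _, gp = problem.prior.cost_and_grad(m)
        assert np.allclose(g, gp, atol=1e-6 * np.linalg.norm(gp))

    def test_zero_gradient_at_global_minimum(self, small_disk, therapy_schedule):
        """Noise-free data generated at the prior mean: gradient vanishes."""
        problem, _, _ = make_inverse_problem(
            small_disk, therapy_schedule, data_shift=0.0
        )
        # regenerate data exactly at the prior mean parameter
        pm = problem.prior.mean
        sol = problem._forward(pm)
        data = np.column_stack(
            [problem.B @ sol.states[n] for n in sorted(problem.obs_step)]
        )
        problem.obs.data = data
        g = problem.grad(pm)
        gn = float(np.sqrt(g @ problem.prior.cov_action(g)))
        assert gn < 1e-10


class TestHessianAction:
    @pytest.mark.parametrize("mode", ["gauss_newton", "full"])
    def test_symmetry(self, small_problem, points, mode):
        rng = np.random.default_rng(3)
        m = points[1]
        small_problem.grad(m)  # populate adjoint cache for full mode
        for _ in range(3):
            v, w = rng.standard_normal((2, small_problem.dim))
            Hv = small_problem.hess_action(m, v, mode=mode)
            Hw = small_problem.hess_action(m, w, mode=mode)
            denom = abs(v @ Hv) + abs(w @ Hw)
            assert abs(v @ Hw - w @ Hv) / denom < 1e-8

    def test_gauss_newton_psd(self, small_problem, points):
        rng = np.random.default_rng(4)
        for m in points[:2]:
            for _ in range(3):
                v = rng.standard_normal(small_problem.dim)
                Hv = small_problem.misfit_hess_action(m, v, "gauss_newton")
                assert v @ Hv >= -1e-10 * (v @ v)

    def test_full_mode_matches_gradient_differences(self, small_problem, points):
        rng = np.random.default_rng(5)
        m = points[1]
        small_problem.grad(m)
        for _ in range(2):
            v = rng.standard_normal(small_problem.dim)
            v /= np.linalg.norm(v)
            Hv = small_problem.hess_action(m, v, mode="full")
            eps = 1e-5
            fd = (small_problem.grad(m + eps * v)
                  - small_problem.grad(m - eps * v)) / (2 * eps)
            small_problem.grad(m)  # restore cache at m
            assert np.linalg.norm(fd - Hv) / np.linalg.norm(fd) < 1e-4

    def test_invalid_mode_raises(self, small_problem, points):
        with pytest.raises(ValueError):
            small_problem.misfit_hess_action(points[0], np.zeros(small_problem.dim), "bogus")


def _random_linear_problem(n=12, nobs=30, seed=0):
    rng = np.random.default_rng(seed)
    G = rng.standard_normal((nobs, n))
    b = rng.standard_normal(nobs) * 0.1
    A = rng.standard_normal((n, n))
    cov = A @ A.T / n + np.eye(n)
    prior = DenseGaussianPrior(rng.standard_normal(n), cov)
    m_true = prior.sample(1, seed + 1)[0]
    data = G @ m_true + b + 0.05 * rng.standard_normal(nobs)
    return LinearInverseProblem(G, b, data, 0.05**2, prior)


class TestNewtonCG:
    def test_one_newton_iteration_on_quadratic(self):
        """Linear forward map: Newton lands on the analytic minimizer."""
        problem = _random_linear_problem()
        mean, _ = problem.analytic_posterior()
        res = gt.solve_map(
            problem,
            settings=gt.NewtonCGSettings(
                max_newton=3, grad_rtol=1e-6, ew_eta_max=1e-9, gn_iters=0,
                max_cg=500,
            ),
        )
        assert res.newton_iters == 1
        assert np.linalg.norm(res.m_map - mean) / np.linalg.norm(mean) < 1e-8

    def test_recovery_contract_and_monotone_cost(self, small_disk, therapy_schedule):
        """MAP misfit beats the prior-mean misfit; cost is non-increasing."""
        problem, _, _ = make_inverse_problem(
            small_disk, therapy_schedule, data_shift=0.005
        )
        res = gt.solve_map(
            problem, settings=gt.NewtonCGSettings(max_newton=15, grad_rtol=1e-4)
        )
        totals = [c[0] for c in res.cost_history]
        assert all(b <= a + 1e-12 for a, b in zip(totals[:-1], totals[1:]))
        misfit0 = res.cost_history[0][1]
        assert res.cost_history[-1][1] < misfit0

    def test_default_settings_match_reference_protocol(self):
        s = gt.NewtonCGSettings()
        assert s.max_newton == 50          # reference iteration cap
        assert 0 < s.grad_rtol < 1         # relative gradient criterion
        assert s.ew_eta_max == 0.5

    def test_mesh_independence_trend(self, therapy_schedule):
        """Newton iteration counts at h and h/~1.4 differ by <= 2."""
        iters = []
        for h in (6.0, 4.2):
            d = gt.build_synthetic_brain(2, 30.0, h, "annulus", 0)
            problem, _, _ = make_inverse_problem(
                d, therapy_schedule, data_shift=0.005
            )
            res = gt.solve_map(
                problem,
                settings=gt.NewtonCGSettings(max_newton=25, grad_rtol=1e-4),
            )
            assert res.converged
            iters.append(res.newton_iters)
        assert abs(iters[0] - iters[1]) <= 2

    def test_invalid_settings_raise(self):
        with pytest.raises(ValueError):
            gt.NewtonCGSettings(armijo_backtrack=1.5)
        with pytest.raises(ValueError):
            gt.NewtonCGSettings(grad_rtol=-1.0)


class TestTissueSplitMode:
    def test_gradient_with_gray_white_split_prior(self, small_disk, therapy_schedule):
        """Cohort-style mode: independent gray/white diffusion fields
        combined by the tissue indicator; adjoint gradient stays exact."""
        base, _, u0 = make_inverse_problem(small_disk, therapy_schedule)
        chi = small_disk.tissue_label.astype(float)
        pmap = gt.TissueSplitParameterMap(chi)
        prior = gt.cohort_block_prior(small_disk, rho_gm_mm=60.0,
                                      rho_wm_mm=120.0, rho_kappa_mm=60.0)
        problem = gt.TumorInverseProblem(
            small_disk, prior, base.obs, u0, base.schedule, base.settings,
            param_map=pmap,
        )
        assert problem.dim == 3 * small_disk.n_vertices
        rng = np.random.default_rng(0)
        m = prior.mean + 0.1 * rng.standard_normal(problem.dim)
        g = problem.grad(m)
        for _ in range(3):
            v = rng.standard_normal(problem.dim)
            v /= np.linalg.norm(v)
            eps = 1e-5
            fd = (problem.cost(m + eps * v).total
                  - problem.cost(m - eps * v).total) / (2 * eps)
            assert abs(fd - g @ v) / max(abs(fd), 1e-12) < 1e-5

    def test_split_field_assembly(self, small_disk):
        chi = small_disk.tissue_label.astype(float)
        pmap = gt.TissueSplitParameterMap(chi)
        n = small_disk.n_vertices
        m = np.concatenate([np.full(n, -1.0), np.full(n, -2.0), np.full(n, -1.5)])
        fields = pmap.to_fields(m)
        gray = chi.astype(bool)
        assert np.allclose(fields.mD[gray], -1.0)
        assert np.allclose(fields.mD[~gray], -2.0)
        assert np.allclose(fields.mkappa, -1.5)
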