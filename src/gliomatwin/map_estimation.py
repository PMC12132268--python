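"""MAP estimation: discrete adjoints and inexact Newton-CG.

The negative log-posterior

    J(m) = Phi(m; d) + 0.5 ||m - m_pr||^2_{Gamma_pr^{-1}}

is minimized with an inexact Newton conjugate-gradient method: CG inner
solves preconditioned by the prior covariance, forcing term by the
Eisenstat-Walker rule, negative-curvature termination (Steihaug), and Armijo
backtracking.  Gradients and Hessian actions come from the exact adjoint of
the discrete implicit-Euler scheme (discretize-then-optimize), so they are
consistent with the implemented cost to machine precision: each gradient is
one forward and one backward (time-reversed, linearized) solve, and each
Hessian action one incremental forward plus one incremental adjoint solve
reusing the factorized per-step Jacobians.  The radiotherapy kill factor
transposes onto the adjoint at the same step boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward import ForwardSettings, ParameterField, TreatmentSchedule, solve_forward
from .geometry import TissueDomain, observation_matrix
from .likelihood import ObservationSet
from .prior import BlockPrior


# ---------------------------------------------------------------------------
# Parameter maps: optimization blocks -> nodal (mD, mkappa)
# ---------------------------------------------------------------------------
class IdentityParameterMap:
    """Blocks are the nodal fields themselves: m = [mD, mkappa]."""

    def __init__(self, n_vertices: int):
        self.n = n_vertices
        self.dim = 2 * n_vertices

    def to_fields(self, m: np.ndarray) -> ParameterField:
        return ParameterField(mD=m[: self.n], mkappa=m[self.n:])

    def push_direction(self, v: np.ndarray):
        return v[: self.n], v[self.n:]

    def pull_gradient(self, gD: np.ndarray, gk: np.ndarray) -> np.ndarray:
        return np.concatenate([gD, gk])


class TissueSplitParameterMap:
    """Gray/white-split diffusion: m = [mD_gm, mD_wm, mkappa].

    The nodal log-diffusivity is chi_gm * mD_gm + (1 - chi_gm) * mD_wm, so the
    field is independent across the tissue interface (cohort-style prior).
    """

    def __init__(self, chi_gm: np.ndarray):
        self.chi = np.asarray(chi_gm, dtype=float)
        self.n = len(self.chi)
        self.dim = 3 * self.n

    def to_fields(self, m: np.ndarray) -> ParameterField:
        n = self.n
        mD = self.chi * m[:n] + (1.0 - self.chi) * m[n : 2 * n]
        return ParameterField(mD=mD, mkappa=m[2 * n :])

    def push_direction(self, v: np.ndarray):
        n = self.n
        return self.chi * v[:n] + (1.0 - self.chi) * v[n : 2 * n], v[2 * n :]

    def pull_gradient(self, gD: np.ndarray, gk: np.ndarray) -> np.ndarray:
        return np.concatenate([self.chi * gD, (1.0 - self.chi) * gD, gk])


# ---------------------------------------------------------------------------
# The PDE-constrained inverse problem
# ---------------------------------------------------------------------------
@dataclass
class CostParts:
    total: float
    misfit: float
    prior: float


class TumorInverseProblem:
    """Bundles domain, observations, prior and forward settings.

    Exposes ``cost``, ``grad`` and ``hess_action`` on the optimization
    parameter vector (block coordinates of ``param_map``); the Laplace
    machinery consumes ``misfit_hess_action`` and ``prior``.
    """

    def __init__(
        self,
        domain: TissueDomain,
        prior: BlockPrior,
        obs: ObservationSet,
        u0: np.ndarray,
        schedule: TreatmentSchedule,
        settings: ForwardSettings,
        param_map=None,
    ):
        self.domain = domain
        self.prior = prior
        self.obs = obs
        self.u0 = np.asarray(u0, dtype=float)
        self.schedule = schedule
        self.settings = settings
        self.param_map = param_map or IdentityParameterMap(domain.n_vertices)
        if prior.dim != self.param_map.dim:
            raise ValueError("prior block dimension does not match parameter map")
        self.B = observation_matrix(domain, obs.grid)
        self.BtB = (self.B.T @ self.B).tocsr()
        # observation times must sit on the step grid
        nsteps = int(round((settings.tf - settings.t0) / settings.dt))
        times = settings.t0 + settings.dt * np.arange(nsteps + 1)
        self.obs_step = {}
        for i, t in enumerate(obs.times):
            n = int(np.argmin(np.abs(times - t)))
            if abs(times[n] - t) > 1e-6 or n == 0:
                raise ValueError(f"observation time {t} not on the step grid in (t0, tf]")
            self.obs_step[n] = i
        self._cache_key = None
        self._sol = None
        self._adjoint = None

    @property
    def dim(self) -> int:
        return self.param_map.dim

    def _mass(self):
        if not hasattr(self, "_M"):
            import scipy.sparse as sp

            self._M = (
                sp.diags(self.domain.lumped_mass).tocsr()
                if self.settings.lumped_mass
                else self.domain.mass
            )
        return self._M

    # -- forward / cost -----------------------------------------------------
    def _forward(self, m: np.ndarray):
        key = np.asarray(m, dtype=float).tobytes()
        if key != self._cache_key:
            fields = self.param_map.to_fields(np.asarray(m, dtype=float))
            self._sol = solve_forward(
                self.u0, fields, self.schedule, self.settings, self.domain,
                keep_lu=True,
            )
            self._fields = fields
            self._cache_key = key
            self._adjoint = None
        return self._sol

    def misfit(self, m: np.ndarray) -> float:
        sol = self._forward(m)
        phi = 0.0
        for n, i in self.obs_step.items():
            r = self.B @ sol.states[n] - self.obs.data[:, i]
            phi += 0.5 * float(r @ r) / self.obs.noise_var
        return phi

    def cost(self, m: np.ndarray) -> CostParts:
        phi = self.misfit(m)
        pc, _ = self.prior.cost_and_grad(m)
        return CostParts(total=phi + pc, misfit=phi, prior=pc)

    # -- first-order adjoint ------------------------------------------------
    def misfit_grad(self, m: np.ndarray) -> np.ndarray:
        sol = self._forward(m)
        M = self._mass()
        dt = self.settings.dt
        expD, kap = self._fields.D, self._fields.kappa
        N = len(sol.times) - 1
        gD = np.zeros(self.domain.n_vertices)
        gk = np.zeros(self.domain.n_vertices)
        p_next = None
        adj = [None] * (N + 1)
        for n in range(N, 0, -1):
            u_n = sol.states[n]
            rhs = np.zeros(self.domain.n_vertices)
            if p_next is not None:
                rhs += (sol.kill[n] / dt) * (M @ p_next)
            if n in self.obs_step:
                r = self.B @ u_n - self.obs.data[:, self.obs_step[n]]
                rhs -= self.B.T @ (r / self.obs.noise_var)
            p_n = sol.lu[n - 1].solve(rhs, trans="T")
            adj[n] = p_n
            Mp = M @ p_n
            gD += expD * self.domain.grad_pairing(u_n, p_n)
            gk += -kap * u_n * (1.0 - u_n) * Mp
            p_next = p_n
        self._adjoint = adj
        return self.param_map.pull_gradient(gD, gk)

    def grad(self, m: np.ndarray) -> np.ndarray:
        g = self.misfit_grad(m)
        _, gp = self.prior.cost_and_grad(m)
        return g + gp

    # -- second-order adjoint (Hessian action) ------------------------------
    def misfit_hess_action(
        self, m: np.ndarray, v: np.ndarray, mode: str = "gauss_newton"
    ) -> np.ndarray:
        if mode not in ("gauss_newton", "full"):
            raise ValueError("mode must be 'gauss_newton' or 'full'")
        sol = self._forward(m)
        if mode == "full" and self._adjoint is None:
            self.misfit_grad(m)
        adj = self._adjoint
        M = self._mass()
        dt = self.settings.dt
        expD, kap = self._fields.D, self._fields.kappa
        N = len(sol.times) - 1
        vD, vk = self.param_map.push_direction(np.asarray(v, dtype=float))
        dK = self.domain.stiffness(expD * vD)  # coefficient d/dmD[v] per cell

        # incremental forward: J_n uh_n = (kill_{n-1}/dt) M uh_{n-1} - C_n v
        uh = [np.zeros(self.domain.n_vertices)]
        for n in range(1, N + 1):
            u_n = sol.states[n]
            rhs = (sol.kill[n - 1] / dt) * (M @ uh[-1])
            rhs -= dK @ u_n - M @ (kap * vk * u_n * (1.0 - u_n))
            uh.append(sol.lu[n - 1].solve(rhs))

        # incremental adjoint + parameter-side accumulation
        HD = np.zeros(self.domain.n_vertices)
        Hk = np.zeros(self.domain.n_vertices)
        ph_next = None
        for n in range(N, 0, -1):
            u_n = sol.states[n]
            rhs = np.zeros(self.domain.n_vertices)
            if ph_next is not None:
                rhs += (sol.kill[n] / dt) * (M @ ph_next)
            if n in self.obs_step:
                rhs -= self.BtB @ uh[n] / self.obs.noise_var
            if mode == "full":
                p_n = adj[n]
                Mp = M @ p_n
                rhs -= 2.0 * kap * Mp * uh[n]
                rhs -= dK @ p_n - vk * kap * (1.0 - 2.0 * u_n) * Mp
            ph = sol.lu[n - 1].solve(rhs, trans="T")
            Mph = M @ ph
            HD += expD * self.domain.grad_pairing(u_n, ph)
            Hk += -kap * u_n * (1.0 - u_n) * Mph
            if mode == "full":
                p_n = adj[n]
                Mp = M @ p_n
                gD_n = expD * self.domain.grad_pairing(u_n, p_n)
                gk_n = -kap * u_n * (1.0 - u_n) * Mp
                HD += gD_n * vD + expD * self.domain.grad_pairing(uh[n], p_n)
                Hk += gk_n * vk - kap * (1.0 - 2.0 * u_n) * uh[n] * Mp
            ph_next = ph
        return self.param_map.pull_gradient(HD, Hk)

    def hess_action(
        self, m: np.ndarray, v: np.ndarray,
        mode: str = "gauss_newton", include_prior: bool = True,
    ) -> np.ndarray:
        Hv = self.misfit_hess_action(m, v, mode)
        if include_prior:
            Hv = Hv + self.prior.precision_action(v)
        return Hv


# -- spec-style convenience wrappers ----------------------------------------
def neg_log_posterior(problem: TumorInverseProblem, m: np.ndarray) -> CostParts:
    """Total cost and its (misfit, prior) components."""
    return problem.cost(m)


def gradient_adjoint(problem: TumorInverseProblem, m: np.ndarray) -> np.ndarray:
    """Adjoint gradient of the negative log-posterior."""
    return problem.grad(m)


def hessian_action(
    problem: TumorInverseProblem, m: np.ndarray, v: np.ndarray,
    mode: str = "gauss_newton", include_prior: bool = True,
) -> np.ndarray:
    return problem.hess_action(m, v, mode, include_prior)


# ---------------------------------------------------------------------------
# Inexact Newton-CG
# ---------------------------------------------------------------------------
@dataclass
class NewtonCGSettings:
    max_newton: int = 50
    grad_rtol: float = 1e-6
    grad_atol: float = 1e-12
    ew_eta_max: float = 0.5
    ew_c: float = 1.0
    armijo_c: float = 1e-4
    armijo_backtrack: float = 0.5
    max_backtracks: int = 25
    max_cg: int = 100
    gn_iters: int = 5

    def __post_init__(self):
        if not (0 < self.armijo_backtrack < 1 and 0 < self.armijo_c < 1):
            raise ValueError("Armijo constants out of range")
        if min(self.grad_rtol, self.grad_atol, self.ew_eta_max) <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class MAPResult:
    m_map: np.ndarray
    cost_history: list = field(default_factory=list)  # (total, misfit, prior)
    grad_norm_history: list = field(default_factory=list)
    converged: bool = False
    newton_iters: int = 0
    total_cg_iters: int = 0
    step_log: list = field(default_factory=list)


def _pcg(hess, prec, g, eta, max_cg):
    """Prior-preconditioned CG on H x = -g with Steihaug termination.

    Returns (x, iterations, hit_negative_curvature).
    """
    x = np.zeros_like(g)
    r = -g
    z = prec(r)
    d = z.copy()
    rz = float(r @ z)
    rz0 = rz
    if rz0 <= 0:
        return prec(-g), 0, False
    for j in range(max_cg):
        Hd = hess(d)
        curv = float(d @ Hd)
        if curv <= 0:
            if j == 0:
                x = d  # preconditioned steepest descent
            return x, j + 1, True
        alpha = rz / curv
        x += alpha * d
        r -= alpha * Hd
        z = prec(r)
        rz_new = float(r @ z)
        if np.sqrt(max(rz_new, 0.0)) <= eta * np.sqrt(rz0):
            return x, j + 1, False
        beta = rz_new / rz
        d = z + beta * d
        rz = rz_new
    return x, max_cg, False


def solve_map(
    problem,
    m0: np.ndarray | None = None,
    settings: NewtonCGSettings | None = None,
) -> MAPResult:
    """Inexact Newton-CG minimization of the negative log-posterior.

    The first ``gn_iters`` Newton iterations use the Gauss-Newton Hessian for
    robustness far from the minimizer, then the full Hessian.  Convergence is
    declared on the relative decrease of the gradient norm measured in the
    prior-covariance inner product (mesh-independent).
    """
    settings = settings or NewtonCGSettings()
    prior = problem.prior
    m = prior.mean.copy() if m0 is None else np.asarray(m0, dtype=float).copy()

    res = MAPResult(m_map=m)
    cost = problem.cost(m)
    g = problem.grad(m)
    gnorm = float(np.sqrt(g @ prior.cov_action(g)))
    g0norm = gnorm
    res.cost_history.append((cost.total, cost.misfit, cost.prior))
    res.grad_norm_history.append(gnorm)
    gnorm_prev = None

    for it in range(settings.max_newton):
        if gnorm <= max(settings.grad_rtol * g0norm, settings.grad_atol):
            res.converged = True
            break
        mode = "gauss_newton" if it < settings.gn_iters else "full"
        eta = settings.ew_eta_max if gnorm_prev is None else min(
            settings.ew_eta_max, settings.ew_c * gnorm / gnorm_prev
        )
        dm, cg_iters, neg_curv = _pcg(
            lambda v: problem.hess_action(m, v, mode=mode, include_prior=True),
            prior.cov_action, g, eta, settings.max_cg,
        )
        res.total_cg_iters += cg_iters
        gd = float(g @ dm)
        if gd >= 0:  # not a descent direction; fall back to precond. gradient
            dm = prior.cov_action(-g)
            gd = float(g @ dm)
        alpha = 1.0
        accepted = False
        for _ in range(settings.max_backtracks):
            try:
                trial = problem.cost(m + alpha * dm)
            except RuntimeError:
                # forward solve diverged at the trial point: shrink the step
                alpha *= settings.armijo_backtrack
                continue
            if trial.total <= cost.total + settings.armijo_c * alpha * gd:
                accepted = True
                break
            alpha *= settings.armijo_backtrack
        if not accepted:
            break  # return best iterate, flagged not converged
        m = m + alpha * dm
        cost = trial
        g = problem.grad(m)
        gnorm_prev = gnorm
        gnorm = float(np.sqrt(g @ prior.cov_action(g)))
        res.newton_iters = it + 1
        res.cost_history.append((cost.total, cost.misfit, cost.prior))
        res.grad_norm_history.append(gnorm)
        res.step_log.append(
            dict(iter=it + 1, total=cost.total, misfit=cost.misfit,
                 prior=cost.prior, gnorm=gnorm, cg_iters=cg_iters,
                 alpha=alpha, mode=mode, neg_curvature=neg_curv)
        )
    else:
        if gnorm <= max(settings.grad_rtol * g0norm, settings.grad_atol):
            res.converged = True
    res.m_map = m
    return res
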