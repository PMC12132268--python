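"""Reaction-diffusion tumor growth with chemoradiation.

State: tumor volume fraction u(x, t) in [0, 1] (cellularity normalized by the
tissue carrying capacity), governed by

    du/dt - div(D grad u) - kappa u (1 - u) = f(u, t)   on Omega,
    grad u . n = 0                                      on the boundary,

with spatially varying diffusion D(x) = exp(mD) [mm^2/day] and proliferation
kappa(x) = exp(mkappa) [1/day].  Therapy enters through f: radiotherapy is an
instantaneous multiplicative kill by the linear-quadratic surviving fraction
at each fraction time, chemotherapy a decaying-exponential death rate.

Discretization: P1 FEM in space (group-FEM treatment of the logistic term:
the nodal product kappa*u*(1-u) is interpolated and hit with the mass
matrix) and implicit Euler in time, solved per step by a damped Newton
iteration with the analytic Jacobian.  The mass matrix is LUMPED by default:
on Delaunay meshes this makes each implicit step an M-matrix solve, which
preserves the invariant region [0, 1] — essential here because the logistic
term is unstable below zero, so consistent-mass undershoots at a steep tumor
front grow exponentially at rate kappa over a multi-month horizon.  The
consistent matrix remains available (``ForwardSettings.lumped_mass=False``).  The per-step Jacobian factorizations
are optionally retained: the adjoint and incremental (Hessian-action) solves
downstream reuse them, so each Hessian action costs only triangular solves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .geometry import TissueDomain, VoxelGrid, observation_matrix

_TIME_TOL = 1e-9


@dataclass
class ParameterField:
    """Block log-parameter m = (mD, mkappa) as nodal fields."""

    mD: np.ndarray
    mkappa: np.ndarray

    @property
    def D(self) -> np.ndarray:
        return np.exp(self.mD)

    @property
    def kappa(self) -> np.ndarray:
        return np.exp(self.mkappa)

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.mD, self.mkappa])

    @classmethod
    def from_vector(cls, vec: np.ndarray) -> "ParameterField":
        n = len(vec) // 2
        return cls(mD=np.asarray(vec[:n]), mkappa=np.asarray(vec[n:]))

    @classmethod
    def constant(cls, domain: TissueDomain, D: float, kappa: float) -> "ParameterField":
        n = domain.n_vertices
        return cls(np.full(n, np.log(D)), np.full(n, np.log(kappa)))


@dataclass
class TreatmentSchedule:
    """Radiotherapy fraction times/doses and chemotherapy administrations.

    alpha_rt [1/Gy] and beta_rt = alpha_rt / alpha_over_beta [1/Gy^2] are the
    linear-quadratic radiosensitivities; alpha_ct (dimensionless efficacy) and
    beta_ct [1/day] (clearance rate) define the chemotherapy death-rate model.
    """

    rt_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    rt_doses: np.ndarray = field(default_factory=lambda: np.empty(0))
    alpha_rt: float = 0.025
    alpha_over_beta: float = 10.0
    ct_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    ct_doses: np.ndarray = field(default_factory=lambda: np.empty(0))
    alpha_ct: float = 0.9
    beta_ct: float = 24.0 / 1.8

    def __post_init__(self):
        self.rt_times = np.atleast_1d(np.asarray(self.rt_times, dtype=float))
        self.rt_doses = np.atleast_1d(np.asarray(self.rt_doses, dtype=float))
        self.ct_times = np.atleast_1d(np.asarray(self.ct_times, dtype=float))
        self.ct_doses = np.atleast_1d(np.asarray(self.ct_doses, dtype=float))
        if np.isscalar(self.rt_doses) or self.rt_doses.size == 1 and self.rt_times.size > 1:
            self.rt_doses = np.full(self.rt_times.shape, float(self.rt_doses))
        if self.ct_doses.size == 1 and self.ct_times.size > 1:
            self.ct_doses = np.full(self.ct_times.shape, float(self.ct_doses))
        for arr, nm in ((self.rt_times, "rt_times"), (self.ct_times, "ct_times")):
            if arr.size > 1 and np.any(np.diff(arr) < 0):
                raise ValueError(f"{nm} must be sorted ascending")
        if np.any(self.rt_doses < 0) or np.any(self.ct_doses < 0):
            raise ValueError("doses must be nonnegative")

    @property
    def beta_rt(self) -> float:
        return self.alpha_rt / self.alpha_over_beta

    def survival_at(self, t: float) -> float:
        """Product of LQ surviving fractions over RT events at time t."""
        s = 1.0
        for tau, z in zip(self.rt_times, self.rt_doses):
            if abs(tau - t) <= _TIME_TOL:
                s *= surviving_fraction_lq(z, self.alpha_rt, self.beta_rt)
        return s

    @classmethod
    def none(cls) -> "TreatmentSchedule":
        return cls()


@dataclass
class ForwardSettings:
    """Time discretization and per-step Newton controls."""

    dt: float = 1.0
    t0: float = 0.0
    tf: float = 86.0
    newton_tol: float = 1e-10
    max_newton_per_step: int = 25
    lumped_mass: bool = True

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.tf <= self.t0:
            raise ValueError("tf must exceed t0")


def surviving_fraction_lq(dose: float, alpha_rt: float, beta_rt: float) -> float:
    """Linear-quadratic surviving fraction exp(-alpha z - beta z^2)."""
    if dose < 0:
        raise ValueError("dose must be nonnegative")
    return float(np.exp(-alpha_rt * dose - beta_rt * dose**2))


def chemo_factor(t: float, schedule: TreatmentSchedule) -> float:
    """Instantaneous chemotherapy death rate c(t) [1/day].

    Zero before the first administration; afterwards
    alpha_ct * sum_k z_k exp(-beta_ct (t - tau_k)) over doses with tau_k <= t.
    """
    if schedule.ct_times.size == 0 or t < schedule.ct_times[0] - _TIME_TOL:
        return 0.0
    mask = schedule.ct_times <= t + _TIME_TOL
    dt = t - schedule.ct_times[mask]
    return float(
        schedule.alpha_ct
        * np.sum(schedule.ct_doses[mask] * np.exp(-schedule.beta_ct * np.clip(dt, 0.0, None)))
    )


def chemo_step_average(a: float, b: float, schedule: TreatmentSchedule) -> float:
    """Exact mean of c(t) over the step (a, b].

    Integrating the decaying exponentials preserves the delivered drug
    exposure (AUC) regardless of dt, which matters when the clearance time
    (1.8 h) is much shorter than the one-day step.
    """
    if schedule.ct_times.size == 0 or b <= schedule.ct_times[0] - _TIME_TOL:
        return 0.0
    beta = schedule.beta_ct
    total = 0.0
    for tau, z in zip(schedule.ct_times, schedule.ct_doses):
        if tau >= b - _TIME_TOL:
            continue
        lo = max(a, tau)
        total += z * (np.exp(-beta * (lo - tau)) - np.exp(-beta * (b - tau))) / beta
    return float(schedule.alpha_ct * total / (b - a))


def apply_radiotherapy(u: np.ndarray, dose: float, schedule: TreatmentSchedule) -> np.ndarray:
    """Instantaneous multiplicative kill: S_rt(dose) * u, pointwise."""
    s = surviving_fraction_lq(dose, schedule.alpha_rt, schedule.beta_rt)
    return s * u


class StepFailure(RuntimeError):
    def __init__(self, msg, residual_history):
        super().__init__(msg)
        self.residual_history = residual_history


@dataclass
class ForwardSolution:
    """Trajectory of nodal states plus what the adjoint machinery needs.

    ``states[n]`` is the state at ``times[n]`` *before* any radiotherapy kill
    applied at that step boundary; ``kill[n]`` is the multiplicative surviving
    factor applied to states[n] before the next step (1.0 when no fraction).
    ``lu[n-1]`` is the factorized converged implicit-Euler Jacobian of step n.
    """

    times: np.ndarray
    states: list
    kill: np.ndarray
    chemo: np.ndarray  # step-averaged chemo rate used by step n (index n-1)
    lu: list | None = None

    def state_at(self, t: float) -> np.ndarray:
        n = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[n] - t) > 1e-6:
            raise KeyError(f"time {t} is not on the step grid")
        return self.states[n]

    @property
    def final(self) -> np.ndarray:
        return self.states[-1]


class ForwardOperators:
    """Cached mesh operators for one (domain, parameter) pair."""

    def __init__(self, domain: TissueDomain, m: ParameterField, lumped: bool = True):
        self.domain = domain
        self.M = sp.diags(domain.lumped_mass).tocsr() if lumped else domain.mass
        self.K = domain.stiffness(m.D)
        self.kappa = m.kappa


def _newton_step_solve(
    M, K, kappa, u_in, dt, cbar, newton_tol, max_iter
):
    """Solve M(u - u_in)/dt + K u - M(kappa u(1-u)) + cbar M u = 0."""
    A = M / dt + K + cbar * M
    u = u_in.copy()
    b0 = M @ (u_in / dt)
    scale = max(np.linalg.norm(b0), 1e-30)
    hist = []
    lu = None
    for _ in range(max_iter):
        r = A @ u - M @ (kappa * u * (1 - u)) - b0
        rn = np.linalg.norm(r) / scale
        hist.append(rn)
        J = A - M.multiply(kappa * (1 - 2 * u))
        lu = splu(J.tocsc())
        if rn <= newton_tol:
            return u, lu, hist
        du = lu.solve(r)
        # damped update: halve on residual increase
        alpha = 1.0
        for _ in range(20):
            u_try = u - alpha * du
            r_try = A @ u_try - M @ (kappa * u_try * (1 - u_try)) - b0
            if np.linalg.norm(r_try) / scale < rn or alpha < 1e-4:
                break
            alpha *= 0.5
        u = u - alpha * du
    r = A @ u - M @ (kappa * u * (1 - u)) - b0
    rn = np.linalg.norm(r) / scale
    hist.append(rn)
    if rn <= newton_tol * 100:  # accept near-converged
        J = A - M.multiply(kappa * (1 - 2 * u))
        return u, splu(J.tocsc()), hist
    raise StepFailure(f"implicit Euler Newton failed (residual {rn:.3e})", hist)


def step_implicit_euler(
    domain: TissueDomain,
    u_prev: np.ndarray,
    m: ParameterField,
    t_next: float,
    dt: float,
    schedule: TreatmentSchedule,
    settings: ForwardSettings | None = None,
) -> np.ndarray:
    """One implicit-Euler step ending at t_next (no RT kill applied here)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not np.all(np.isfinite(u_prev)):
        raise ValueError("u_prev must be finite")
    settings = settings or ForwardSettings(dt=dt, t0=t_next - dt, tf=t_next)
    ops = ForwardOperators(domain, m, lumped=settings.lumped_mass)
    cbar = chemo_step_average(t_next - dt, t_next, schedule)
    u, _, _ = _newton_step_solve(
        ops.M, ops.K, ops.kappa, u_prev, dt, cbar,
        settings.newton_tol, settings.max_newton_per_step,
    )
    return u


def solve_forward(
    u0: np.ndarray,
    m: ParameterField,
    schedule: TreatmentSchedule,
    settings: ForwardSettings,
    domain: TissueDomain,
    keep_lu: bool = False,
) -> ForwardSolution:
    """March implicit Euler from t0 to tf with instantaneous RT kills.

    RT fraction times are snapped to the nearest step boundary (they coincide
    for integer-day fractions at dt = 1).  At a boundary the ordering is:
    step result -> recorded state -> multiplicative kill -> next step.
    """
    nsteps = int(round((settings.tf - settings.t0) / settings.dt))
    if abs(settings.t0 + nsteps * settings.dt - settings.tf) > 1e-8 * max(1.0, settings.tf):
        raise ValueError("(tf - t0) must be an integer number of steps")
    times = settings.t0 + settings.dt * np.arange(nsteps + 1)
    kill = np.ones(nsteps + 1)
    for tau, z in zip(schedule.rt_times, schedule.rt_doses):
        if tau < times[0] - _TIME_TOL or tau > times[-1] + _TIME_TOL:
            continue
        n = int(np.argmin(np.abs(times - tau)))
        kill[n] *= surviving_fraction_lq(z, schedule.alpha_rt, schedule.beta_rt)

    ops = ForwardOperators(domain, m, lumped=settings.lumped_mass)
    states = [np.asarray(u0, dtype=float).copy()]
    lus = [] if keep_lu else None
    chemo = np.empty(nsteps)
    u = states[0]
    for n in range(1, nsteps + 1):
        u_in = kill[n - 1] * u
        cbar = chemo_step_average(times[n - 1], times[n], schedule)
        chemo[n - 1] = cbar
        u, lu, _ = _newton_step_solve(
            ops.M, ops.K, ops.kappa, u_in, settings.dt, cbar,
            settings.newton_tol, settings.max_newton_per_step,
        )
        if not np.all(np.isfinite(u)):
            raise StepFailure(f"non-finite state at t={times[n]}", [])
        states.append(u)
        if keep_lu:
            lus.append(lu)
    return ForwardSolution(times=times, states=states, kill=kill, chemo=chemo, lu=lus)


def observe(u: np.ndarray, domain: TissueDomain, grid: VoxelGrid) -> np.ndarray:
    """Length-n_observed vector of the state at unmasked voxel centers."""
    return observation_matrix(domain, grid) @ np.asarray(u, dtype=float)


def total_mass(u: np.ndarray, domain: TissueDomain, lumped: bool = True) -> float:
    """Integral of the nodal field over the domain."""
    u = np.asarray(u, dtype=float)
    if lumped:
        return float(domain.lumped_mass @ u)
    return float((domain.mass @ u).sum())
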