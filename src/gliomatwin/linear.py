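"""Linear-Gaussian inverse problem: the exactness fixture.

For a linear forward map F(m) = G m + b with additive Gaussian noise and a
Gaussian prior, the posterior is Gaussian in closed form, so the Newton-CG
solver must converge in one step to the analytic mean and the Laplace
approximation (at full rank) must reproduce the analytic covariance.  The
class exposes the same interface as the PDE problem (cost/grad/hess_action,
prior with cov/precision actions) so the optimization and Laplace machinery
run on it unchanged.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp


class DenseGaussianPrior:
    """N(mean, C) with dense covariance; same interface as BlockPrior."""

    def __init__(self, mean: np.ndarray, cov: np.ndarray):
        self.mean = np.asarray(mean, dtype=float)
        self.cov = np.asarray(cov, dtype=float)
        self.dim = len(self.mean)
        self._prec = sla.inv(self.cov)
        self._sqrt = sla.cholesky(self.cov, lower=True)

    def cov_action(self, v):
        return self.cov @ np.asarray(v, dtype=float)

    def precision_action(self, v):
        return self._prec @ np.asarray(v, dtype=float)

    def precision_matrix(self):
        return sp.csr_matrix(self._prec)

    def sample_fluctuation(self, n, rng):
        return (self._sqrt @ rng.standard_normal((self.dim, n))).T

    def sample(self, n, seed):
        rng = np.random.default_rng(seed)
        return self.mean[None, :] + self.sample_fluctuation(n, rng)

    def cost_and_grad(self, m):
        d = np.asarray(m, dtype=float) - self.mean
        g = self._prec @ d
        return 0.5 * float(d @ g), g


class LinearInverseProblem:
    """Gaussian-linear model d = G m + b + noise, noise ~ N(0, sigma2 I)."""

    def __init__(self, G: np.ndarray, b: np.ndarray, data: np.ndarray,
                 noise_var: float, prior: DenseGaussianPrior):
        self.G = np.asarray(G, dtype=float)
        self.b = np.asarray(b, dtype=float)
        self.data = np.asarray(data, dtype=float)
        self.noise_var = float(noise_var)
        self.prior = prior
        self.dim = self.G.shape[1]

    def misfit(self, m):
        r = self.G @ m + self.b - self.data
        return 0.5 * float(r @ r) / self.noise_var

    def cost(self, m):
        from .map_estimation import CostParts

        phi = self.misfit(m)
        pc, _ = self.prior.cost_and_grad(m)
        return CostParts(total=phi + pc, misfit=phi, prior=pc)

    def misfit_grad(self, m):
        r = self.G @ m + self.b - self.data
        return self.G.T @ r / self.noise_var

    def grad(self, m):
        _, gp = self.prior.cost_and_grad(m)
        return self.misfit_grad(m) + gp

    def misfit_hess_action(self, m, v, mode="gauss_newton"):
        return self.G.T @ (self.G @ np.asarray(v, dtype=float)) / self.noise_var

    def hess_action(self, m, v, mode="gauss_newton", include_prior=True):
        Hv = self.misfit_hess_action(m, v, mode)
        if include_prior:
            Hv = Hv + self.prior.precision_action(v)
        return Hv

    # -- closed-form reference ---------------------------------------------
    def analytic_posterior(self):
        """Exact Gaussian posterior (mean, covariance)."""
        Hm = self.G.T @ self.G / self.noise_var
        prec = Hm + self.prior._prec
        cov = sla.inv(prec)
        rhs = self.G.T @ (self.data - self.b) / self.noise_var \
            + self.prior._prec @ self.prior.mean
        return cov @ rhs, cov
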