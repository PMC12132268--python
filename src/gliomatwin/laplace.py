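"""Low-rank Laplace approximation to the Bayesian posterior.

At the MAP point the posterior is approximated by the Gaussian
N(m_MAP, Gamma_post) with Gamma_post = (H_misfit + Gamma_pr^{-1})^{-1}.
Because the data inform only a limited number of directions, H_misfit is
effectively low rank relative to the prior: the leading pairs of the
generalized eigenproblem

    H_misfit v_j = lambda_j Gamma_pr^{-1} v_j,    v_i^T Gamma_pr^{-1} v_j = delta_ij,

captured with a double-pass randomized eigensolver, give the
Sherman-Morrison-Woodbury form

    Gamma_post ~= Gamma_pr - sum_j [lambda_j / (1 + lambda_j)] v_j v_j^T,

which is exact for linear forward maps at full rank.  Sampling uses the exact
low-rank transformation of prior fluctuations,

    m = m_MAP + (I - V diag(1 - (1+lambda)^{-1/2}) V^T Gamma_pr^{-1}) w,

with w a zero-mean prior sample, whose covariance is exactly the SMW form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla


@dataclass
class EigenPairSet:
    """Leading generalized eigenpairs, Gamma_pr^{-1}-orthonormal."""

    eigenvalues: np.ndarray  # (k,) sorted descending, clipped at 0
    vectors: np.ndarray      # (dim, k)
    oversampling: int = 0
    rank_deficient: bool = False

    @property
    def k(self) -> int:
        return len(self.eigenvalues)


def _b_orthonormalize(Y: np.ndarray, b_action, passes: int = 2) -> np.ndarray:
    """Return Q with Q^T B Q = I; drops near-null directions.

    CholQR with re-orthonormalization (two passes recover near machine
    precision even when Y is poorly conditioned); falls back to eigenvalue
    whitening on rank deficiency.
    """
    Q = Y
    for _ in range(passes):
        BQ = np.column_stack([b_action(Q[:, j]) for j in range(Q.shape[1])])
        W = Q.T @ BQ
        W = 0.5 * (W + W.T)
        try:
            R = sla.cholesky(W, lower=False)
            Q = sla.solve_triangular(R, Q.T, trans="T", lower=False).T
        except sla.LinAlgError:
            s, U = sla.eigh(W)
            keep = s > max(s.max(), 0.0) * 1e-12
            Q = Q @ (U[:, keep] / np.sqrt(s[keep]))
    return Q


def misfit_hessian_gevp(
    problem,
    m_map: np.ndarray,
    k: int = 50,
    p: int = 10,
    seed: int = 0,
    mode: str = "gauss_newton",
    power_iter: int = 0,
) -> EigenPairSet:
    """Double-pass randomized solve of H_misfit v = lambda Gamma_pr^{-1} v.

    ``problem`` must expose ``misfit_hess_action(m, v, mode)`` and ``prior``
    (with ``cov_action`` / ``precision_action``).  Negative eigenvalue
    estimates are truncated to zero; if fewer than k directions carry energy
    the returned set is shorter and flagged.  ``power_iter`` extra
    applications of (Gamma_pr H) sharpen the captured subspace when the
    spectrum decays slowly, at one Hessian sweep each.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    prior = problem.prior
    dim = len(np.asarray(m_map))
    r = min(k + p, dim)
    rng = np.random.default_rng(seed)
    Omega = rng.standard_normal((dim, r))

    def hm(v):
        return problem.misfit_hess_action(m_map, v, mode)

    # pass 1: range finder in the Gamma_pr^{-1} geometry
    Y = np.column_stack([prior.cov_action(hm(Omega[:, j])) for j in range(r)])
    for _ in range(power_iter):
        Y = _b_orthonormalize(Y, prior.precision_action, passes=1)
        Y = np.column_stack(
            [prior.cov_action(hm(Y[:, j])) for j in range(Y.shape[1])]
        )
    Q = _b_orthonormalize(Y, prior.precision_action)
    # pass 2: small projected problem
    HQ = np.column_stack([hm(Q[:, j]) for j in range(Q.shape[1])])
    T = Q.T @ HQ
    T = 0.5 * (T + T.T)
    lam, S = sla.eigh(T)
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    S = S[:, order]
    kk = min(k, len(lam))
    rank_deficient = kk < k
    lam_k = np.clip(lam[:kk], 0.0, None)
    V = Q @ S[:, :kk]
    return EigenPairSet(
        eigenvalues=lam_k, vectors=V, oversampling=p, rank_deficient=rank_deficient
    )


@dataclass
class LaplacePosterior:
    """Gaussian posterior approximation N(m_MAP, low-rank corrected prior)."""

    m_map: np.ndarray
    pairs: EigenPairSet
    prior: object  # BlockPrior or any object with the prior interface

    def cov_action(self, v: np.ndarray) -> np.ndarray:
        """Gamma_post v via the Sherman-Morrison-Woodbury identity."""
        out = self.prior.cov_action(v)
        if self.pairs.k:
            lam, V = self.pairs.eigenvalues, self.pairs.vectors
            out = out - V @ ((lam / (1.0 + lam)) * (V.T @ np.asarray(v, dtype=float)))
        return out

    def sample(self, n: int, seed: int) -> np.ndarray:
        """(n, dim) seeded samples with the low-rank posterior covariance."""
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = np.random.default_rng(seed)
        W = self.prior.sample_fluctuation(n, rng)  # (n, dim), cov = Gamma_pr
        if self.pairs.k:
            lam, V = self.pairs.eigenvalues, self.pairs.vectors
            d = 1.0 - 1.0 / np.sqrt(1.0 + lam)
            BW = (self._precision_matrix() @ W.T).T  # Gamma_pr^{-1} w per sample
            W = W - ((BW @ V) * d[None, :]) @ V.T
        return self.m_map[None, :] + W

    def _precision_matrix(self):
        if not hasattr(self, "_Bprec"):
            self._Bprec = self.prior.precision_matrix()
        return self._Bprec

    def pointwise_variance(self, n_probe: int = 64, seed: int = 0) -> np.ndarray:
        """Monte-Carlo estimate of diag(Gamma_post) from seeded samples."""
        s = self.sample(max(n_probe, 2), seed)
        return s.var(axis=0, ddof=1)


def posterior_cov_action(post: LaplacePosterior, v: np.ndarray) -> np.ndarray:
    return post.cov_action(v)


def sample_laplace(post: LaplacePosterior, n: int, seed: int) -> np.ndarray:
    return post.sample(n, seed)
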