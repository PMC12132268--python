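"""Quantify parameter uncertainty with the low-rank Laplace approximation.

After MAP calibration, the posterior covariance is the inverse Hessian of
the negative log-posterior — intractable to form directly, but the data
inform only a limited number of directions.  This script computes the
leading eigenpairs of the prior-preconditioned data-misfit Hessian with the
randomized solver, builds the Sherman-Morrison-Woodbury posterior, and shows
(a) the spectral decay that makes the low-rank approach work and (b) the
variance reduction from prior to posterior along the leading modes.
"""

import numpy as np

import gliomatwin as gt

spec = gt.default_spec(
    radius_mm=45.0, h_fine_mm=3.0, h_coarse_mm=4.5, voxel_mm=4.0,
    pre_days=10, therapy_days=14, post_days=11, prediction_days=10,
    imaging="weekly", seed=11,
)
data = gt.generate_observations(spec)
prior = gt.default_block_prior(data.coarse_domain)
problem = gt.TumorInverseProblem(
    data.coarse_domain, prior, data.obs, data.u0_coarse,
    data.schedule, spec.forward_settings(),
)
result = gt.solve_map(problem, settings=gt.NewtonCGSettings(max_newton=25, grad_rtol=1e-5))
pairs = gt.misfit_hessian_gevp(problem, result.m_map, k=20, p=10, seed=0)
post = gt.LaplacePosterior(m_map=result.m_map, pairs=pairs, prior=prior)

print("leading generalized eigenvalues (information content per mode):")
for j in range(0, 20, 4):
    print("  " + "  ".join(f"lam_{i+1}={pairs.eigenvalues[i]:.3e}"
                           for i in range(j, min(j + 4, pairs.k))))
print("eigenvalues >> 1 mark directions where the data overwhelm the prior")

print("\nvariance along the leading eigenvectors (prior -> posterior):")
for j in (0, 4, 9, 19):
    v = pairs.vectors[:, j]
    vp = v @ prior.cov_action(v)
    vq = v @ post.cov_action(v)
    print(f"  mode {j + 1:>2}: {vp:.3e} -> {vq:.3e}   (x{vq / vp:.4f})")

samples = gt.sample_laplace(post, 500, seed=1)
print(f"\n500 posterior samples drawn; nodal sd of log-D ranges "
      f"{samples[:, :data.coarse_domain.n_vertices].std(axis=0).min():.3f}"
      f" - {samples[:, :data.coarse_domain.n_vertices].std(axis=0).max():.3f}"
      f" (prior sd {np.sqrt(0.05):.3f}); tightest where the tumor was observed")
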