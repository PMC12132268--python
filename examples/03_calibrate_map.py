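"""Calibrate the growth model to noisy longitudinal imaging (MAP estimate).

Generates a reduced virtual patient (shorter timeline, coarser meshes than
the reference study so this runs in ~half a minute), then minimizes the
negative log-posterior with the adjoint-based inexact Newton-CG solver.
The printed history shows the data misfit falling by orders of magnitude;
the recovered diffusivity is higher in tumor-active white matter than in
gray matter even though the inversion never sees the tissue map.
"""

import numpy as np

import gliomatwin as gt
from gliomatwin.geometry import voxels_to_fem

spec = gt.default_spec(
    radius_mm=45.0, h_fine_mm=3.0, h_coarse_mm=4.5, voxel_mm=4.0,
    pre_days=10, therapy_days=14, post_days=11, prediction_days=10,
    imaging="weekly", seed=11,
)
data = gt.generate_observations(spec)
print(f"observations: {data.obs.data.shape[0]} voxels x {data.obs.n_times} visits, "
      f"noise sd {spec.noise_sd}")

prior = gt.default_block_prior(data.coarse_domain)
problem = gt.TumorInverseProblem(
    data.coarse_domain, prior, data.obs, data.u0_coarse,
    data.schedule, spec.forward_settings(),
)
result = gt.solve_map(problem, settings=gt.NewtonCGSettings(max_newton=25, grad_rtol=1e-5))

print(f"{'iter':>4} {'total':>12} {'misfit':>12} {'prior':>10} {'|g|':>10}")
for i, ((tot, mis, pri), gn) in enumerate(
    zip(result.cost_history, result.grad_norm_history)
):
    print(f"{i:>4} {tot:>12.1f} {mis:>12.1f} {pri:>10.2f} {gn:>10.3e}")
print(f"converged: {result.converged} after {result.newton_iters} Newton / "
      f"{result.total_cg_iters} CG iterations")

fields = problem.param_map.to_fields(result.m_map)
u_last = voxels_to_fem(data.obs.data[:, -1], data.grid, data.coarse_domain)
active = u_last > spec.threshold
gray = data.coarse_domain.tissue_label.astype(bool)
print(f"inferred D under active tumor (white matter): "
      f"{fields.D[active & ~gray].mean():.3f} mm^2/day (truth {spec.D_white}); "
      f"inactive-region mean {fields.D[~active].mean():.3f} "
      f"(prior mean {np.exp(-1.30):.3f})")
print("D is pulled toward the truth where the data are informative;"
      " elsewhere the prior mean dominates")
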