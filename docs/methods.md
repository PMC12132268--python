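# Methods

`gliomatwin` builds a predictive digital twin of high-grade glioma growth:
a mechanistic tumor model calibrated to longitudinal imaging by scalable
Bayesian inversion, with parameter uncertainty propagated to clinical
quantities of interest.  This note records the model, the numerical choices,
and what the synthetic experiments do and do not establish.

## Forward model

The tumor state is the volume fraction u(x, t) ∈ [0, 1] (cell density
normalized by the tissue carrying capacity) on a bounded domain Ω with a
no-flux (homogeneous Neumann) boundary — the tumor does not grow past the
skull.  Growth combines Fickian invasion and logistic proliferation, with
therapy as a sink:

    ∂u/∂t − ∇·(D ∇u) − κ u (1 − u) = f(u, t),

with spatially varying diffusivity D(x) [mm²/day] and proliferation rate
κ(x) [1/day].  Therapy enters in two parts:

- **Radiotherapy** is an instantaneous kill at each fraction time: the state
  is multiplied by the linear-quadratic surviving fraction
  S = exp(−α_rt z − β_rt z²) for dose z [Gy].  This is the exact integral of
  a Dirac-in-time kill term and introduces no free dimensional constant.
- **Chemotherapy** is a decaying-exponential death rate
  c(t) = α_ct Σ_k z_k exp(−β_ct (t − τ_k)) after each administration, with
  efficacy α_ct (dimensionless) and clearance rate β_ct [1/day].

Reference parameters (virtual patient): D = 0.03 mm²/day in gray matter,
0.3 in white matter, κ = 0.15/day everywhere, α_rt = 0.025/Gy with
α/β = 10 Gy, α_ct = 0.9, clearance time 1.8 h (β_ct = 24/1.8 per day),
2 Gy weekday fractions and daily chemotherapy over a six-week block.

### Discretization

First-order Lagrange (P1) simplices for state, parameter and adjoint;
implicit Euler in time with dt = 1 day; each step solved by damped Newton
with the analytic Jacobian to relative residual 1e−10.  Two deliberate
choices:

- **Lumped mass matrix (default).** The logistic term is unstable below
  u = 0: any negative undershoot grows like exp(κ t), and with a
  consistent mass matrix the front-induced undershoots (~1e−3 at h = 3 mm)
  destroy the solution over a four-month horizon.  Row-sum lumping on
  Delaunay meshes makes each implicit step an M-matrix solve, which keeps u
  inside [0, 1] up to solver tolerance.  The consistent matrix remains
  available (`ForwardSettings.lumped_mass = False`) for short-horizon use.
- **Step-averaged chemotherapy.** The clearance time (1.8 h) is far shorter
  than the time step, so sampling c(t) at the step endpoint aliases the
  concentration peak and makes the kill strongly dt-dependent.  The solver
  instead uses the exact mean of c over each step, which preserves the
  delivered drug exposure (AUC) for any dt and remains fully implicit.

Radiotherapy kills are applied at step boundaries (fraction times snap to
the step grid); a state recorded at a fraction day is the pre-kill state.

## Observation model and likelihood

Observations are voxel-resolved cellularity estimates d(x̄, t_i) on an
axis-aligned grid (centers at origin + (index + ½)·spacing), restricted to
the n_d voxels whose centers fall inside the mesh.  The observation operator
is P1 (barycentric) interpolation at voxel centers — exact for linear
fields.  Noise is additive iid Gaussian; the misfit is

    Φ(m; d) = Σ_i ‖B u(t_i) − d_i‖² / (2 σ²_noise),

with σ_noise = 0.02 absolute on the volume-fraction scale for the synthetic
study ("2% noise"; the cohort-style value 0.0625² ≈ 3.9e−3 variance is
available as configuration).  Noisy values are not clamped to [0, 1] for
inference — the Gaussian likelihood assumes unclamped noise.  Utilities map
ADC images to cellularity (d = (ADC_w − ADC)/(ADC_w − ADC_min), clipped) and
tumor ROI masks to the literature values 0.8 / 0.16 (enhancing /
non-enhancing).

## Prior

Each log-parameter block (m_D = log D, m_κ = log κ; positivity by
construction) is an independent Gaussian random field with Matérn-type
covariance C = (δ − γΔ)⁻², i.e. the squared inverse of an elliptic operator
with a Robin boundary term β = sqrt(γδ) damping boundary-variance
artifacts.  The Whittle–Matérn correspondence (smoothness ν = 2 − d/2) maps
the interpretable hyperparameters — pointwise variance σ² and correlation
length ρ — onto (γ, δ):

    κ_m = sqrt(8ν)/ρ,  γ = sqrt(Γ(ν) / (Γ(2) (4π)^{d/2} κ_m^{2ν} σ²)),
    δ = κ_m² γ.

The mapping is certified empirically (sampled interior variance within 10%,
correlation-length within 20%); the Robin constant 1.0 was chosen by that
same calibration — it keeps the *interior* variance within a few percent of
σ² even when ρ is comparable to the domain size, the regime the reference
configuration (σ² = 0.05, ρ = 180 mm) lives in, at the cost of some
under-dispersion at the boundary.

Discretely, with A the assembled operator and M_L the lumped mass matrix,
Γ_pr = A⁻¹ M_L A⁻¹; the precision A M_L⁻¹ A needs only sparse products, and
exact samples are m_pr + A⁻¹ M_L^{1/2} z.  Defaults follow the reference
virtual-patient configuration (mean m_D = −1.30, σ² = 0.05; mean
m_κ = −1.00, σ² = 0.02; ρ = 180 mm); a cohort-style mode splits m_D into
independent gray/white fields combined by the tissue indicator, with longer
correlation in white matter (ρ 180/360 mm) and the cohort means/variances.

## MAP estimation

The negative log-posterior Φ(m; d) + ½‖m − m_pr‖²_{Γ_pr⁻¹} is minimized by
an inexact Newton-CG method: conjugate gradients preconditioned by the prior
covariance, Eisenstat–Walker forcing η_k = min(0.5, ‖g_k‖/‖g_{k−1}‖),
Steihaug termination on negative curvature, and Armijo backtracking (c =
1e−4, halving, 25 tries; a trial point whose forward solve diverges is
treated as +∞ cost).  Convergence is declared on the relative decrease of
the gradient norm in the Γ_pr inner product (mesh-independent), default
rtol 1e−6, with at most 50 Newton iterations.  The first five iterations
use the Gauss-Newton Hessian for robustness, then the full Hessian.

Gradients and Hessian actions are **discrete adjoints** (discretize-then-
optimize): the adjoint marches the transposed converged Jacobian of each
implicit-Euler step backwards in time, with observation residuals injected
at imaging steps and the radiotherapy surviving fraction transposing onto
the adjoint at the same boundaries.  The per-step LU factorizations from
the forward solve are cached, so a gradient costs one forward plus one
(cheap) backward sweep, and each Hessian action only triangular solves.
Central finite differences confirm the gradient to ~1e−9 and the full
Hessian action to ~1e−9 relative on randomized problems including
radiotherapy discontinuities.

## Low-rank Laplace posterior

The posterior is approximated by N(m_MAP, Γ_post) with
Γ_post = (H_misfit + Γ_pr⁻¹)⁻¹ — exact for linear forward maps.  Because
the data inform few directions, the prior-preconditioned generalized
eigenproblem H_misfit v = λ Γ_pr⁻¹ v has rapidly decaying spectrum; a
double-pass randomized eigensolver (Gaussian probes, B-orthonormalization
by twice-iterated CholQR, optional power iterations for slowly decaying
spectra) returns the top k pairs (defaults k = 50, oversampling 10).  The
Gauss-Newton Hessian is used in the eigenproblem so all λ_j ≥ 0 and the
Sherman–Morrison–Woodbury form

    Γ_post ≈ Γ_pr − Σ_j [λ_j/(1+λ_j)] v_j v_jᵀ

is well defined.  Sampling applies the exact low-rank transformation
m = m_MAP + (I − V diag(1 − (1+λ)^{−1/2}) Vᵀ Γ_pr⁻¹) w to prior
fluctuations w; the sample covariance provably equals the SMW form, and is
verified against dense references on small meshes.

## Prediction and quantities of interest

A prediction is a forward solve over (t₀, t_pred).  Four QoIs summarize a
predicted state against a reference, using the measurable-tumor threshold
ū = 0.1: total tumor cellularity ∫ û dx, tumor volume ∫ 1{û > 0} dx (both by
vertex quadrature — appropriate for thresholded integrands), Lin's
concordance correlation coefficient on voxel values (penalizing departure
from the identity line), and the Dice overlap of thresholded regions
(defined as 1 when both regions are empty).  Pushforward distributions are
plain Monte Carlo — sample, predict, score — with per-sample failures
recorded, not fatal; prior vs posterior distributions are compared by
two-sided Mann-Whitney U (location) and Levene (spread) tests.

Two prediction protocols are implemented: the clinical-deployment
convention (default) reconstructs the initial state from the final imaging
visit (nearest-voxel lookup, clamped to [0, 1], sub-threshold values zeroed
— they are noise speckle that the logistic term would otherwise amplify
into spurious domain-wide growth) and simulates the 30-day window beyond
imaging; the alternative simulates from the true t = 0 seed through the
whole history.

## The virtual patient (synthetic-data generator)

The generator emulates a controlled in-silico experiment: a 2-D disk
(default radius 60 mm) with a white-matter core and a gray-matter annulus
(r > 0.7R), a centered Gaussian seed (width 5 mm, amplitude 0.8), 14 days
untreated growth + 42 days chemoradiation + 30 days untreated, imaging
daily/weekly/fortnightly, 2% noise, prediction 30 days past the last scan.
Data are generated on a fine mesh (h = 2.5 mm) and inverted on a strictly
coarser one (h = 4 mm) sharing the voxel grid, so the inversion never sees
its own discretization (inverse-crime guard).  All randomness flows from a
single seed through named substreams; identical seeds give byte-identical
bundles.

The 60 mm radius is a deliberate scaling decision: the Fisher front speed
2·sqrt(Dκ) ≈ 0.42 mm/day in white matter consumes a 50-mm disk within the
116-day course, which would pin the volume QoI of truth, prior and
posterior alike at the domain area.  At 60 mm the truth occupies roughly
half the domain at prediction time.  One ceiling artifact remains and is
intrinsic to any bounded scaled domain: the *uncalibrated prior* (mean
D ≈ 0.27, κ ≈ 0.37) still overgrows until its predictions fill the disk, so
the prior-predictive volume distribution is biased high with artificially
small spread.  The location/spread significance tests are unaffected; the
strict "posterior variance < prior variance" property is asserted for the
CCC only.

What a green synthetic run does **not** establish: behavior on real
anatomy (convoluted geometry, ventricles, hemispheric restriction),
registration or segmentation error (observations here are perfectly
aligned), model misspecification (data are generated by the same family of
dynamics, only at a different resolution), or 3-D scale (the machinery is
dimension-generic and 3-D runs work at small size, but all reference
numbers here are 2-D).

## Numerical defaults at a glance

| quantity | default | unit | note |
| --- | --- | --- | --- |
| dt | 1 | day | implicit Euler |
| Newton step tol | 1e−10 | – | per-step relative residual |
| measurable threshold ū | 0.1 | – | volume fraction |
| σ_noise (synthetic) | 0.02 | – | absolute, volume fraction |
| prior m_D | −1.30 / 0.05 | log mm²/day | mean / variance |
| prior m_κ | −1.00 / 0.02 | log 1/day | mean / variance |
| ρ | 180 | mm | both blocks |
| Robin constant | 1.0 | – | times sqrt(γδ) |
| max Newton / CG | 50 / 100 | – | MAP solver |
| grad rtol | 1e−6 | – | Γ_pr-norm of gradient |
| eigenpairs k / oversampling | 50 / 10 | – | randomized GEVP |
| pushforward samples | 500 | – | Monte Carlo |

## Known limitations

- No mass effect, anisotropy, multi-species or vascular coupling; the
  two-field reaction-diffusion model absorbs all heterogeneity into D and κ.
- Radiotherapy timing resolves only to the time step; sub-day fractionation
  requires a smaller dt.
- The randomized eigensolver's plain double-pass estimates are biased low
  by a few percent when the spectrum decays slowly; power iterations
  (`power_iter`) recover oracle accuracy at one Hessian sweep each.
- Nearest-voxel reconstruction of initial states from data is
  piecewise-constant; fine spatial structure below the voxel size is lost.
- 3-D meshes come from Delaunay triangulation of structured shells and may
  contain slivers near the boundary; adequate for small verification
  domains, not for production anatomy.
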