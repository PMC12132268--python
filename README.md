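# gliomatwin

Predictive digital twins of high-grade glioma growth with quantified
uncertainty — for computational oncologists and researchers in
PDE-constrained Bayesian inference who want a desk-scale, fully inspectable
implementation of the whole loop: mechanistic forward model → Bayesian
calibration from longitudinal imaging → probabilistic prediction of
clinical quantities of interest.

## The model and the inference

Tumor burden is the volume fraction u(x, t) ∈ [0, 1] governed by a
semi-linear reaction-diffusion equation with chemoradiation:

    ∂u/∂t − ∇·(D ∇u) − κ u (1 − u) = f(u, t)  in Ω,   ∇u·n = 0 on ∂Ω,

where D(x) [mm²/day] is invasion, κ(x) [1/day] proliferation, and f the
therapy effect: instantaneous linear-quadratic kills
S_rt = exp(−α_rt z − β_rt z²) at radiotherapy fractions and a
decaying-exponential chemotherapy death rate α_ct Σ_k e^{−β_ct (t−τ_k)}.

Calibration infers the log-fields m = (log D, log κ) from voxel-resolved
cellularity observations d(x̄, t_i) under additive Gaussian noise, with
Matérn Gaussian random-field priors C_pr = (δ − γΔ)⁻².  The posterior is
approximated by the Laplace method at the MAP point,

    m_MAP = argmin  Σ_i ‖B u(t_i) − d_i‖²/(2σ²) + ½‖m − m_pr‖²_{C_pr⁻¹},
    Γ_post ≈ Γ_pr − Σ_{j≤k} [λ_j/(1+λ_j)] v_j v_jᵀ,

where (λ_j, v_j) solve the prior-preconditioned eigenproblem
H_misfit v = λ Γ_pr⁻¹ v (randomized, matrix-free).  The MAP solve is an
adjoint-based inexact Newton-CG method (Eisenstat–Walker forcing, Steihaug
truncation, Armijo line search); gradients and Hessian actions are exact
discrete adjoints of the implicit-Euler/P1 scheme.  Parameter uncertainty
is pushed through the prediction map by Monte Carlo to distributions of
tumor volume, total cellularity, concordance correlation (CCC) and Dice
overlap.

Everything runs on numpy/scipy P1 finite elements on 2-D (default) or
small 3-D simplicial meshes; a built-in virtual-patient generator
synthesizes ground truth, therapy schedules and noisy imaging so the whole
pipeline is testable without any data download.

## Worked example

`examples/` holds one narrative script per capability; each builds its own
small input and prints what it computes.

```bash
python examples/01_forward_simulation.py
```

```
mesh: 755 vertices, domain area 11301 mm^2
therapy window: days 14-56
  day   TTC mm^2    TV mm^2
    0      111.8      311.6
   14      380.3     1014.9
   42      267.0     1014.9
   56      332.3     1517.7
   86     3258.9     5539.0
  116     6548.7     7851.2
```

Total tumor cellularity (TTC, the integral of the thresholded volume
fraction) falls during the six-week chemoradiation block (days 14–56) and
regrows sharply once therapy ends — the characteristic retreat-and-recur
course.  Continuing with `03_calibrate_map.py`:

```
observations: 401 voxels x 5 visits, noise sd 0.02
iter        total       misfit      prior        |g|
   0     361001.0     361001.0       0.00  1.656e+05
   4       1058.3       1037.2      21.10  3.059e+02
   7       1032.0       1007.2      24.84  1.369e+00
converged: True after 7 Newton / 14 CG iterations
inferred D under active tumor (white matter): 0.216 mm^2/day (truth 0.3)
```

The data misfit drops by ~350× in a handful of Newton iterations and the
inferred diffusivity approaches the white-matter truth where the tumor was
observed, while the prior mean dominates elsewhere.
`04_laplace_uncertainty.py` shows the eigenvalue decay that justifies the
low-rank posterior and the variance reduction along data-informed modes;
`05_imaging_frequency.py` runs the reduced imaging-frequency study (daily
vs weekly vs fortnightly imaging), where the leading eigenvalue — the
information the data carry — grows with imaging frequency and every
calibrated posterior beats the prior-predictive distribution at
p < 0.001.

## Layout

```
src/gliomatwin/
  geometry.py        meshes, tissue labels, voxel grids, interpolation
  fem.py             P1 assembly primitives
  forward.py         reaction-diffusion + chemoradiation solver
  prior.py           Matérn random-field priors (elliptic-operator form)
  likelihood.py      observation sets and the Gaussian misfit
  map_estimation.py  discrete adjoints + inexact Newton-CG
  laplace.py         randomized GEVP, low-rank posterior, sampler
  qoi.py             prediction map, QoIs, pushforwards, tests
  patient.py         virtual-patient generator
  pipeline.py        generate -> calibrate -> predict drivers
  linear.py          linear-Gaussian fixture (exactness checks)
  io.py              VTK / NIfTI / table export
docs/methods.md      model, numerics, assumptions, limitations
examples/            runnable narrative scripts
```
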