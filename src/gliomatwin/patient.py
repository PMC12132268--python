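"""Synthetic virtual patient: ground truth, therapy schedule, noisy imaging.

The generator emulates a controlled in-silico experiment: a tumor seeded in a
disk-shaped tissue domain grows untreated for two weeks, receives six weeks
of concurrent chemoradiation (Stupp-style: 2 Gy weekday radiotherapy
fractions with daily chemotherapy), then grows untreated for another month.
Ground-truth diffusivity is tissue-dependent (0.03 mm^2/day in gray matter,
0.3 in white) with uniform proliferation 0.15/day.  Voxel observations of the
volume fraction are taken daily, weekly or fortnightly and polluted with
additive Gaussian noise of standard deviation 0.02 (absolute, on the [0, 1]
volume-fraction scale).

To avoid the inverse crime, data are generated on a strictly finer mesh than
the one handed to the inversion; the observation grid and its mask are shared
between the two.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .forward import (
    ForwardSettings,
    ParameterField,
    TreatmentSchedule,
    solve_forward,
)
from .geometry import (
    TissueDomain,
    VoxelGrid,
    build_synthetic_brain,
    make_voxel_grid,
    observation_matrix,
)
from .likelihood import ObservationSet


@dataclass
class VirtualPatientSpec:
    """Fully determines one synthetic experiment (the 'stated world')."""

    dim: int = 2
    radius_mm: float = 60.0      # sized so ~4 months of front propagation
    tissue_spec: str = "annulus:0.7"  # (2*sqrt(D*kappa) ~ 0.42 mm/day) fits
    h_fine_mm: float = 2.5       # data-generation mesh
    h_coarse_mm: float = 4.0     # inversion mesh (strictly coarser)
    voxel_mm: float = 2.5
    # ground-truth parameters (as printed for the in-silico study)
    D_gray: float = 0.03         # mm^2/day
    D_white: float = 0.3
    kappa: float = 0.15          # 1/day
    # therapy
    alpha_rt: float = 0.025      # 1/Gy
    alpha_over_beta: float = 10.0  # Gy
    rt_dose_gy: float = 2.0
    rt_weekdays_only: bool = True
    alpha_ct: float = 0.9
    beta_ct: float = 24.0 / 1.8  # 1/day (1.8 h clearance)
    ct_dose: float = 1.0
    # timeline [days]
    pre_days: int = 14
    therapy_days: int = 42
    post_days: int = 30
    prediction_days: int = 30
    dt: float = 1.0
    # imaging & noise
    imaging: str = "weekly"      # daily | weekly | fortnightly | explicit list
    imaging_days: np.ndarray | None = None
    noise_sd: float = 0.02
    threshold: float = 0.1
    # tumor seed
    seed_center: tuple = (0.0, 0.0)
    seed_width_mm: float = 5.0
    seed_amplitude: float = 0.8
    # rng
    seed: int = 0

    def __post_init__(self):
        if not self.h_fine_mm < self.h_coarse_mm:
            raise ValueError(
                "inverse-crime guard: data mesh must be strictly finer "
                "than the inversion mesh"
            )

    @property
    def tf(self) -> float:
        return float(self.pre_days + self.therapy_days + self.post_days)

    @property
    def t_pred(self) -> float:
        return self.tf + self.prediction_days

    def schedule(self) -> TreatmentSchedule:
        start, end = self.pre_days, self.pre_days + self.therapy_days
        days = np.arange(start, end)
        rt_days = (
            days[(days - start) % 7 < 5] if self.rt_weekdays_only else days
        )
        return TreatmentSchedule(
            rt_times=rt_days.astype(float),
            rt_doses=np.full(len(rt_days), self.rt_dose_gy),
            alpha_rt=self.alpha_rt,
            alpha_over_beta=self.alpha_over_beta,
            ct_times=days.astype(float),
            ct_doses=np.full(len(days), self.ct_dose),
            alpha_ct=self.alpha_ct,
            beta_ct=self.beta_ct,
        )

    def imaging_schedule(self) -> np.ndarray:
        if self.imaging_days is not None:
            return np.asarray(self.imaging_days, dtype=float)
        steps = {"daily": 1, "weekly": 7, "fortnightly": 14}
        if self.imaging not in steps:
            raise ValueError(f"unknown imaging schedule {self.imaging!r}")
        s = steps[self.imaging]
        return np.arange(s, self.tf + 0.5, s, dtype=float)

    def forward_settings(self) -> ForwardSettings:
        return ForwardSettings(dt=self.dt, t0=0.0, tf=self.tf)


def default_spec(**overrides) -> VirtualPatientSpec:
    """The reference in-silico experiment, desk-scaled to a 2-D disk."""
    return replace(VirtualPatientSpec(), **overrides) if overrides else VirtualPatientSpec()


def seed_tumor(
    domain: TissueDomain,
    center,
    width_mm: float,
    amplitude: float,
) -> np.ndarray:
    """Gaussian tumor seed u0(x) = amplitude * exp(-|x-c|^2 / (2 w^2)), <= 1."""
    if not 0.0 < amplitude <= 1.0:
        raise ValueError("amplitude must be in (0, 1]")
    c = np.asarray(center, dtype=float)
    r2 = ((domain.vertices - c[None, :]) ** 2).sum(axis=1)
    return np.minimum(amplitude * np.exp(-r2 / (2.0 * width_mm**2)), 1.0)


def cellularity_from_adc(adc: np.ndarray, adc_w: float, adc_min: float) -> np.ndarray:
    """Tumor volume fraction from apparent diffusion coefficient maps.

    d = (ADC_w - ADC) / (ADC_w - ADC_min), clipped to [0, 1]; ADC_w is the
    free-water value (no cells), ADC_min the in-tumor minimum (max packing).
    """
    if not adc_w > adc_min:
        raise ValueError("adc_w must exceed adc_min")
    d = (adc_w - np.asarray(adc, dtype=float)) / (adc_w - adc_min)
    return np.clip(d, 0.0, 1.0)


def roi_cellularity(
    enhancing_mask: np.ndarray,
    nonenhancing_mask: np.ndarray,
    enhancing_value: float = 0.8,
    nonenhancing_value: float = 0.16,
) -> np.ndarray:
    """Volume fraction from tumor ROI masks when no ADC is available."""
    e = np.asarray(enhancing_mask).astype(bool)
    ne = np.asarray(nonenhancing_mask).astype(bool)
    if np.any(e & ne):
        raise ValueError("enhancing and non-enhancing masks must be disjoint")
    return enhancing_value * e + nonenhancing_value * ne


@dataclass
class VirtualPatientData:
    """Truth bundle + observations, ready for calibration and scoring."""

    spec: VirtualPatientSpec
    fine_domain: TissueDomain
    coarse_domain: TissueDomain
    grid: VoxelGrid
    truth: ParameterField            # on the fine mesh
    u0_fine: np.ndarray
    u0_coarse: np.ndarray
    obs: ObservationSet              # noisy, paired with the coarse mesh
    clean_data: np.ndarray           # noise-free voxel stack (nd, nt)
    schedule: TreatmentSchedule
    truth_course: dict               # day -> fine-mesh state (obs + key days)
    u_pred_true: np.ndarray          # fine-mesh truth at t_pred
    truth_pred_voxels: np.ndarray    # noise-free voxel truth at t_pred


def true_parameter_field(domain: TissueDomain, spec: VirtualPatientSpec) -> ParameterField:
    """Piecewise-constant-by-tissue truth (gray rim slow, white core fast)."""
    gray = domain.tissue_label.astype(bool)
    mD = np.where(gray, np.log(spec.D_gray), np.log(spec.D_white))
    mk = np.full(domain.n_vertices, np.log(spec.kappa))
    return ParameterField(mD=mD, mkappa=mk)


def generate_observations(spec: VirtualPatientSpec) -> VirtualPatientData:
    """Fine-mesh truth solve, voxel sampling, seeded noise pollution."""
    ss = np.random.SeedSequence(spec.seed)
    noise_seed = ss.spawn(1)[0]

    fine = build_synthetic_brain(
        spec.dim, spec.radius_mm, spec.h_fine_mm, spec.tissue_spec, spec.seed
    )
    coarse = build_synthetic_brain(
        spec.dim, spec.radius_mm, spec.h_coarse_mm, spec.tissue_spec, spec.seed
    )
    grid = make_voxel_grid(fine, spec.voxel_mm)
    truth = true_parameter_field(fine, spec)
    u0_fine = seed_tumor(fine, spec.seed_center, spec.seed_width_mm, spec.seed_amplitude)
    u0_coarse = seed_tumor(coarse, spec.seed_center, spec.seed_width_mm, spec.seed_amplitude)
    schedule = spec.schedule()

    # one continuous truth solve through the prediction horizon
    settings = ForwardSettings(dt=spec.dt, t0=0.0, tf=spec.t_pred)
    sol = solve_forward(u0_fine, truth, schedule, settings, fine)

    B = observation_matrix(fine, grid)
    days = spec.imaging_schedule()
    clean = np.column_stack([B @ sol.state_at(t) for t in days])
    rng = np.random.default_rng(noise_seed)
    if spec.noise_sd > 0:
        noisy = clean + spec.noise_sd * rng.standard_normal(clean.shape)
    else:
        noisy = clean.copy()
    # noise_var must stay positive for the Gaussian likelihood even in the
    # noise-free verification limit
    obs = ObservationSet(
        times=days, data=noisy, noise_var=max(spec.noise_sd**2, 1e-12),
        grid=grid,
    )

    keep = set(days.tolist()) | {0.0, spec.tf, spec.t_pred}
    course = {t: sol.state_at(t) for t in sorted(keep)}
    u_pred_true = sol.state_at(spec.t_pred)
    return VirtualPatientData(
        spec=spec,
        fine_domain=fine,
        coarse_domain=coarse,
        grid=grid,
        truth=truth,
        u0_fine=u0_fine,
        u0_coarse=u0_coarse,
        obs=obs,
        clean_data=clean,
        schedule=schedule,
        truth_course=course,
        u_pred_true=u_pred_true,
        truth_pred_voxels=B @ u_pred_true,
    )
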