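"""Additive-Gaussian observation model and the data-misfit functional.

Observations are voxel-resolved cellularity values d(x_bar, t_i) at imaging
times t_i, modeled as the P1 interpolation of the FEM state at the unmasked
voxel centers plus iid N(0, sigma_noise^2) noise.  The negative log-likelihood
sums the per-visit misfits:

    Phi(m; d) = sum_i  (1 / (2 sigma^2)) || F_i(m) - d_i ||^2 .
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward import ForwardSettings, ParameterField, TreatmentSchedule, solve_forward
from .geometry import TissueDomain, VoxelGrid, observation_matrix


@dataclass
class ObservationSet:
    """Longitudinal voxel observations with acquisition times.

    data has shape (n_observed, n_times): column i is the length-nd vector of
    unmasked voxel values at times[i].
    """

    times: np.ndarray
    data: np.ndarray
    noise_var: float
    grid: VoxelGrid

    def __post_init__(self):
        self.times = np.atleast_1d(np.asarray(self.times, dtype=float))
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 1:
            self.data = self.data[:, None]
        if self.data.shape != (self.grid.n_observed, len(self.times)):
            raise ValueError(
                f"data must be (n_observed, n_times) = "
                f"({self.grid.n_observed}, {len(self.times)}), got {self.data.shape}"
            )
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("observation times must be strictly increasing")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("observation data must be finite")
        if not self.noise_var > 0:
            raise ValueError("noise_var must be positive")

    @property
    def n_times(self) -> int:
        return len(self.times)

    def save(self, path):
        np.savez(
            path,
            times=self.times,
            data=self.data,
            noise_var=self.noise_var,
            origin=self.grid.origin,
            spacing=self.grid.spacing,
            shape=np.asarray(self.grid.shape),
            inside_mask=self.grid.inside_mask,
        )

    @classmethod
    def load(cls, path) -> "ObservationSet":
        with np.load(path) as z:
            grid = VoxelGrid(
                origin=z["origin"],
                spacing=z["spacing"],
                shape=tuple(int(s) for s in z["shape"]),
                inside_mask=z["inside_mask"],
            )
            return cls(
                times=z["times"], data=z["data"],
                noise_var=float(z["noise_var"]), grid=grid,
            )


def misfit_from_solution(sol, B, obs: ObservationSet) -> float:
    phi = 0.0
    for i, t in enumerate(obs.times):
        pred = B @ sol.state_at(t)
        r = pred - obs.data[:, i]
        phi += 0.5 * float(r @ r) / obs.noise_var
    return phi


def neg_log_likelihood(
    m: ParameterField,
    obs: ObservationSet,
    u0: np.ndarray,
    schedule: TreatmentSchedule,
    settings: ForwardSettings,
    domain: TissueDomain,
) -> float:
    """Data misfit Phi(m; d): forward solve + observation at every visit."""
    if obs.times[0] <= settings.t0 or obs.times[-1] > settings.tf + 1e-9:
        raise ValueError("observation times must lie in (t0, tf]")
    sol = solve_forward(u0, m, schedule, settings, domain)
    B = observation_matrix(domain, obs.grid)
    return misfit_from_solution(sol, B, obs)
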