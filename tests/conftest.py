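"""Shared fixtures: small meshes and a miniature calibration problem.

Everything is generated at test time; meshes are kept tiny (tens to a few
hundred vertices) so the whole suite stays fast on one CPU.
"""

import numpy as np
import pytest
from hypothesis import settings

import gliomatwin as gt
from gliomatwin.geometry import observation_matrix

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def disk():
    """Mid-sized disk: ~500 vertices, annular gray rim."""
    return gt.build_synthetic_brain(2, 50.0, 4.5, "annulus", seed=0)


@pytest.fixture(scope="session")
def small_disk():
    """Small disk: ~100 vertices, for dense-oracle tests."""
    return gt.build_synthetic_brain(2, 30.0, 6.0, "annulus", seed=0)


@pytest.fixture(scope="session")
def tiny_disk():
    """Tiny all-white disk (~40 vertices) for dense GEVP/Laplace oracles."""
    return gt.build_synthetic_brain(2, 20.0, 4.5, "all_white", seed=0)


@pytest.fixture(scope="session")
def therapy_schedule():
    """Short chemoradiation burst inside a 10-day window."""
    return gt.TreatmentSchedule(
        rt_times=[3.0, 5.0, 7.0], rt_doses=[2.0, 2.0, 2.0],
        ct_times=[2.0, 3.0, 4.0, 5.0], ct_doses=[1.0, 1.0, 1.0, 1.0],
    )


def make_inverse_problem(domain, schedule, tf=10.0, noise_var=4e-4,
                         rho_mm=60.0, voxel_mm=4.0, data_shift=0.01,
                         obs_times=(2.0, 5.0, 8.0, 10.0)):
    """Small synthetic inverse problem with data from a known parameter."""
    settings_ = gt.ForwardSettings(dt=1.0, t0=0.0, tf=tf)
    grid = gt.make_voxel_grid(domain, voxel_mm)
    u0 = 0.6 * np.exp(
        -((domain.vertices - np.array([5.0, 3.0])) ** 2).sum(axis=1) / (2 * 36.0)
    )
    truth = gt.ParameterField.constant(domain, 0.15, 0.2)
    sol = gt.solve_forward(u0, truth, schedule, settings_, domain)
    B = observation_matrix(domain, grid)
    data = np.column_stack([B @ sol.state_at(t) for t in obs_times]) + data_shift
    obs = gt.ObservationSet(
        times=np.asarray(obs_times), data=data, noise_var=noise_var, grid=grid
    )
    prior = gt.default_block_prior(domain, rho_mm=rho_mm)
    problem = gt.TumorInverseProblem(domain, prior, obs, u0, schedule, settings_)
    return problem, truth, u0


@pytest.fixture(scope="session")
def small_problem(small_disk, therapy_schedule):
    """Inverse problem on the small disk with RT events in the window."""
    problem, truth, u0 = make_inverse_problem(small_disk, therapy_schedule)
    return problem


@pytest.fixture(scope="session")
def tiny_patient_spec():
    """Scaled-down virtual patient for integration tests (fast timeline)."""
    return gt.default_spec(
        radius_mm=40.0, h_fine_mm=3.5, h_coarse_mm=5.0, voxel_mm=4.0,
        pre_days=7, therapy_days=14, post_days=7, prediction_days=10,
        imaging="weekly", seed=11,
    )
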