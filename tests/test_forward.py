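"""Forward model: LQ survival, chemotherapy, implicit Euler, conservation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import brentq

import gliomatwin as gt
from gliomatwin.forward import chemo_step_average, total_mass


class TestLQSurvival:
    def test_zero_dose_full_survival(self):
        assert gt.surviving_fraction_lq(0.0, 0.025, 0.0025) == 1.0

    def test_reference_fraction_value(self):
        """2 Gy at alpha=0.025/Gy, alpha/beta=10 Gy: hand evaluation."""
        s = gt.surviving_fraction_lq(2.0, 0.025, 0.025 / 10.0)
        assert s == pytest.approx(np.exp(-0.025 * 2.0 - 0.0025 * 4.0), rel=1e-12)

    @given(z=st.floats(0.1, 20.0), dz=st.floats(0.1, 5.0))
    def test_monotone_in_dose(self, z, dz):
        assert gt.surviving_fraction_lq(z + dz, 0.025, 0.0025) < \
            gt.surviving_fraction_lq(z, 0.025, 0.0025)

    def test_negative_dose_raises(self):
        with pytest.raises(ValueError):
            gt.surviving_fraction_lq(-1.0, 0.025, 0.0025)


class TestChemoFactor:
    def test_zero_before_first_dose(self, therapy_schedule):
        assert gt.chemo_factor(1.0, therapy_schedule) == 0.0

    def test_single_dose_at_administration(self):
        s = gt.TreatmentSchedule(ct_times=[0.0], ct_doses=[1.0], alpha_ct=0.9)
        assert gt.chemo_factor(0.0, s) == pytest.approx(0.9)

    def test_two_dose_superposition_oracle(self):
        """Two doses one day apart: direct two-term summation."""
        s = gt.TreatmentSchedule(
            ct_times=[0.0, 1.0], ct_doses=[1.0, 1.0], alpha_ct=0.9,
            beta_ct=24.0 / 1.8,
        )
        t = 1.5
        expect = 0.9 * (np.exp(-s.beta_ct * 1.5) + np.exp(-s.beta_ct * 0.5))
        assert gt.chemo_factor(t, s) == pytest.approx(expect, rel=1e-12)

    def test_step_average_is_exposure_preserving(self):
        """Step-averaged rate integrates the instantaneous rate exactly."""
        s = gt.TreatmentSchedule(
            ct_times=[0.0, 1.0, 2.0], ct_doses=[1.0, 1.0, 1.0], alpha_ct=0.9,
        )
        a, b = 1.0, 2.0
        # quadrature oracle on the open interval (a, b): the dose at t=2
        # contributes only from tau <= t, measure zero inside (1, 2)
        ts = np.linspace(a + 1e-9, b - 1e-9, 20001)
        quad = np.trapezoid([gt.chemo_factor(t, s) for t in ts], ts) / (b - a)
        assert chemo_step_average(a, b, s) == pytest.approx(quad, rel=1e-3)


class TestImplicitEuler:
    def test_constant_state_is_steady_without_reaction(self, small_disk):
        """Neumann diffusion of a constant stays constant."""
        m = gt.ParameterField.constant(small_disk, 0.3, 1e-12)
        u = gt.step_implicit_euler(
            small_disk, np.full(small_disk.n_vertices, 0.4), m, 1.0, 1.0,
            gt.TreatmentSchedule.none(),
        )
        assert np.allclose(u, 0.4, atol=1e-10)

    def test_extinction_fixed_point(self, small_disk):
        m = gt.ParameterField.constant(small_disk, 0.3, 0.15)
        st_ = gt.ForwardSettings(dt=1.0, t0=0.0, tf=5.0)
        sol = gt.solve_forward(
            np.zeros(small_disk.n_vertices), m, gt.TreatmentSchedule.none(),
            st_, small_disk,
        )
        assert np.allclose(sol.final, 0.0)

    def test_homogeneous_matches_scalar_logistic_recursion(self, small_disk):
        """Uniform state follows the scalar implicit-Euler logistic exactly."""
        kappa = 0.15
        m = gt.ParameterField.constant(small_disk, 0.2, kappa)
        st_ = gt.ForwardSettings(dt=1.0, t0=0.0, tf=10.0)
        sol = gt.solve_forward(
            np.full(small_disk.n_vertices, 0.5), m,
            gt.TreatmentSchedule.none(), st_, small_disk,
        )
        u = 0.5
        for n in range(1, 11):
            u = brentq(lambda x: x - u - 1.0 * kappa * x * (1 - x), 0.0, 1.5,
                       xtol=1e-14)
            spread = np.ptp(sol.states[n])
            assert spread < 1e-9  # stays spatially uniform
            assert sol.states[n][0] == pytest.approx(u, abs=1e-8)

    def test_dt_convergence_to_logistic_closed_form(self, small_disk):
        """Implicit Euler converges (first order) to the logistic solution."""
        kappa, u0, T = 0.15, 0.5, 4.0
        exact = u0 / (u0 + (1 - u0) * np.exp(-kappa * T))
        errs = []
        for dt in (1.0, 0.5, 0.25):
            m = gt.ParameterField.constant(small_disk, 0.2, kappa)
            st_ = gt.ForwardSettings(dt=dt, t0=0.0, tf=T)
            sol = gt.solve_forward(
                np.full(small_disk.n_vertices, u0), m,
                gt.TreatmentSchedule.none(), st_, small_disk,
            )
            errs.append(abs(sol.final[0] - exact))
        assert errs[0] > errs[1] > errs[2]
        assert errs[0] / errs[1] == pytest.approx(2.0, rel=0.25)  # O(dt)

    def test_mass_conservation_without_reaction(self, small_disk):
        """kappa = 0, no treatment: integral of u conserved to 1e-8."""
        m = gt.ParameterField.constant(small_disk, 0.5, 1e-14)
        st_ = gt.ForwardSettings(dt=1.0, t0=0.0, tf=20.0)
        u0 = np.exp(-((small_disk.vertices**2).sum(axis=1)) / 100.0)
        sol = gt.solve_forward(u0, m, gt.TreatmentSchedule.none(), st_, small_disk)
        m0 = total_mass(sol.states[0], small_disk)
        assert abs(total_mass(sol.final, small_disk) - m0) / m0 < 1e-8

    def test_nonfinite_input_raises(self, small_disk):
        m = gt.ParameterField.constant(small_disk, 0.3, 0.15)
        bad = np.full(small_disk.n_vertices, np.nan)
        with pytest.raises(ValueError):
            gt.step_implicit_euler(small_disk, bad, m, 1.0, 1.0,
                                   gt.TreatmentSchedule.none())


class TestRadiotherapy:
    def test_zero_dose_identity(self, small_disk):
        u = np.linspace(0, 1, small_disk.n_vertices)
        s = gt.TreatmentSchedule.none()
        assert np.array_equal(gt.apply_radiotherapy(u, 0.0, s), u)

    def test_kill_on_zero_state(self):
        s = gt.TreatmentSchedule.none()
        assert np.all(gt.apply_radiotherapy(np.zeros(5), 2.0, s) == 0.0)

    def test_total_cellularity_scales_by_survival(self, small_disk):
        u = np.random.default_rng(0).uniform(0, 1, small_disk.n_vertices)
        s = gt.TreatmentSchedule.none()
        srt = gt.surviving_fraction_lq(2.0, s.alpha_rt, s.beta_rt)
        before = total_mass(u, small_disk)
        after = total_mass(gt.apply_radiotherapy(u, 2.0, s), small_disk)
        assert after == pytest.approx(srt * before, rel=1e-12)

    @given(a=st.floats(0.1, 3.0))
    def test_commutes_with_scaling(self, a):
        u = np.linspace(0.0, 1.0, 17)
        s = gt.TreatmentSchedule.none()
        assert np.allclose(
            gt.apply_radiotherapy(a * u, 2.0, s),
            a * gt.apply_radiotherapy(u, 2.0, s),
        )


class TestSolveForward:
    def test_rt_event_equals_split_solve_composition(self, small_disk):
        """One RT kill = solve, multiplicative kill, solve (composition)."""
        sched = gt.TreatmentSchedule(rt_times=[3.0], rt_doses=[2.0])
        m = gt.ParameterField.constant(small_disk, 0.2, 0.15)
        u0 = 0.6 * np.exp(-((small_disk.vertices**2).sum(axis=1)) / 150.0)
        full = gt.solve_forward(
            u0, m, sched, gt.ForwardSettings(dt=1.0, t0=0.0, tf=6.0), small_disk
        )
        first = gt.solve_forward(
            u0, m, gt.TreatmentSchedule.none(),
            gt.ForwardSettings(dt=1.0, t0=0.0, tf=3.0), small_disk,
        )
        killed = gt.apply_radiotherapy(first.final, 2.0, sched)
        second = gt.solve_forward(
            killed, m, gt.TreatmentSchedule.none(),
            gt.ForwardSettings(dt=1.0, t0=3.0, tf=6.0), small_disk,
        )
        assert np.allclose(full.final, second.final, atol=1e-9)

    def test_invariant_region(self, tiny_patient_spec):
        """Virtual-patient course keeps u within [-1e-6, 1+1e-6] at dt=1."""
        data = gt.generate_observations(tiny_patient_spec)
        for u in data.truth_course.values():
            assert u.min() >= -1e-6
            assert u.max() <= 1.0 + 1e-6

    def test_observe_matches_interpolation(self, small_disk):
        g = gt.make_voxel_grid(small_disk, 5.0)
        u = np.random.default_rng(1).uniform(0, 1, small_disk.n_vertices)
        from gliomatwin.geometry import fem_to_voxels

        assert np.allclose(
            gt.observe(u, small_disk, g),
            fem_to_voxels(u, small_disk, g)[g.inside_mask],
        )


def test_three_dimensional_ball_smoke():
    """The solver is dimension-generic: uniform logistic on a small ball."""
    d = gt.build_synthetic_brain(3, 20.0, 4.8, "all_white", 0)
    m = gt.ParameterField.constant(d, 0.2, 0.15)
    sol = gt.solve_forward(
        np.full(d.n_vertices, 0.5), m, gt.TreatmentSchedule.none(),
        gt.ForwardSettings(dt=1.0, t0=0.0, tf=3.0), d,
    )
    u = 0.5
    for _ in range(3):
        u = brentq(lambda x: x - u - 0.15 * x * (1 - x), 0.0, 1.5, xtol=1e-14)
    assert np.ptp(sol.final) < 1e-8
    assert sol.final[0] == pytest.approx(u, abs=1e-7)
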