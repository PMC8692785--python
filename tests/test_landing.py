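"""Forward-dynamic landing model: torque laws, contact, controller,
integration invariants, and peak extraction."""

import math

import numpy as np
import pytest

from sprainsim.kinematics import AxisSet, rotation_about_axis
from sprainsim.landing import (DEFAULT_PARAMETERS, BraceModel,
                               MuscleController, PassiveBushingModel,
                               SimulationInputs, Trajectory, brace_torque,
                               contact_normal_force, extract_peak_outcomes,
                               muscle_moment, passive_torque,
                               simulate_drop_landing, write_trajectory_csv)

STUDY2 = SimulationInputs()  # 30 deg incline, no brace, no muscle input


class TestPassiveTorque:
    def test_zero_angle_gives_zero_torque(self):
        assert passive_torque(0.0, 100.0) == pytest.approx(0.0)

    @pytest.mark.parametrize("theta", [-30.0, -5.0, 4.0, 21.0, 47.0])
    def test_flexibility_rescales_displacement_axis(self, theta):
        assert passive_torque(theta, 50.0) == pytest.approx(
            passive_torque(2 * theta, 100.0))
        assert passive_torque(theta, 200.0) == pytest.approx(
            passive_torque(theta / 2, 100.0))

    def test_restoring_and_odd_symmetric(self):
        # default double-exponential: tau(20) = A(e^-20B - 1) - C(e^20B - 1)
        p = DEFAULT_PARAMETERS
        expected = (p.bushing_A_Nm * (math.exp(-p.bushing_B_per_deg * 20) - 1)
                    - p.bushing_C_Nm * (math.exp(p.bushing_D_per_deg * 20) - 1))
        got = passive_torque(20.0, 100.0)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got < 0.0
        assert passive_torque(-20.0, 100.0) == pytest.approx(-got, rel=1e-12)

    def test_scale_of_default_curve(self):
        # roughly 25 N m borne near 45-50 deg of supination
        assert 20.0 < -passive_torque(47.0, 100.0) < 30.0

    def test_invalid_flexibility(self):
        with pytest.raises(ValueError):
            passive_torque(10.0, 0.0)
        with pytest.raises(ValueError):
            passive_torque(10.0, -50.0)

    def test_strain_energy_matches_numeric_integral(self):
        bushing = PassiveBushingModel(flexibility_pct=80.0)
        theta = 35.0
        grid = np.linspace(0.0, theta, 20001)
        u_num = -np.trapezoid(bushing.torque(grid), grid) * math.pi / 180.0
        assert bushing.strain_energy_J(theta) == pytest.approx(u_num,
                                                               rel=1e-6)


class TestBraceTorque:
    def test_zero_scale_means_no_brace(self):
        for theta in (-40.0, -1.0, 0.0, 12.0, 55.0):
            assert brace_torque(theta, 0.0) == 0.0

    def test_scale_100_duplicates_passive_anatomy(self):
        for theta in (-25.0, 10.0, 40.0):
            assert brace_torque(theta, 100.0) == pytest.approx(
                passive_torque(theta, 100.0))

    def test_scale_150_is_stiffer_than_anatomy(self):
        # excursion at fixed torque is 2/3 of baseline
        assert brace_torque(10.0, 150.0) == pytest.approx(
            passive_torque(15.0, 100.0))
        assert abs(brace_torque(20.0, 150.0)) > abs(
            passive_torque(20.0, 100.0))

    def test_negative_scale_rejected(self):
        with pytest.raises(ValueError):
            brace_torque(5.0, -10.0)


class TestContactNormalForce:
    def test_no_penetration_no_force(self):
        assert contact_normal_force(0.0, 1.0, 50.0, 5.0, 0.004) == 0.0
        assert contact_normal_force(-0.01, -2.0, 50.0, 5.0, 0.004) == 0.0

    def test_static_worked_value(self):
        # 5 mm penetration, 50 MPa/m modulus, 40 cm^2 point area -> 1000 N
        assert contact_normal_force(0.005, 0.0, 50.0, 5.0,
                                    0.004) == pytest.approx(1000.0)

    def test_never_tensile(self):
        assert contact_normal_force(0.005, -10.0, 50.0, 5.0, 0.004) == 0.0

    def test_dissipation_raises_loading_force(self):
        loading = contact_normal_force(0.005, 0.5, 50.0, 5.0, 0.004)
        assert loading == pytest.approx(1000.0 * (1 + 5.0 * 0.5))

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            contact_normal_force(0.01, 0.0, -1.0, 5.0, 0.004)
        with pytest.raises(ValueError):
            contact_normal_force(float("nan"), 0.0, 50.0, 5.0, 0.004)


class TestMuscleController:
    def make_history(self, excursion_deg, t_end=1.0, ref=0.0):
        t = np.linspace(0.0, t_end, 101)
        return np.column_stack([t, np.full_like(t, ref + excursion_deg)])

    def test_silent_controller_outputs_zero(self):
        c = MuscleController(coactivation_pct=0.0, reflex_gain=0.0)
        hist = self.make_history(30.0)
        for t in (0.0, 0.2, 0.9):
            assert muscle_moment(hist, t, c) == 0.0

    def test_symmetric_coactivation_has_no_bias_but_stiffens(self):
        c = MuscleController(coactivation_pct=60.0)
        assert c.moment(0.0, 0.0) == pytest.approx(0.0)
        resist_sup = c.moment(5.0, 0.0)
        resist_pro = c.moment(-5.0, 0.0)
        assert resist_sup < 0.0 < resist_pro
        assert resist_sup == pytest.approx(-resist_pro)

    def test_reflex_hand_value(self):
        # moment = gain * k_reflex * delayed excursion (evertor-directed)
        c = MuscleController(reflex_gain=10.0, k_reflex_Nm_per_deg=1.0)
        hist = self.make_history(5.0)
        assert muscle_moment(hist, 0.5, c) == pytest.approx(-50.0)
        c_default = MuscleController(reflex_gain=10.0)
        assert muscle_moment(hist, 0.5, c_default) == pytest.approx(
            -10.0 * c_default.k_reflex_Nm_per_deg * 5.0)

    def test_reflex_ignores_pronation_excursion(self):
        c = MuscleController(reflex_gain=10.0)
        hist = self.make_history(-5.0)
        assert muscle_moment(hist, 0.5, c) == 0.0

    def test_startup_uses_contact_posture(self):
        c = MuscleController(reflex_gain=10.0, reference_posture_deg=0.0)
        hist = self.make_history(5.0, t_end=0.01)  # shorter than latency
        assert muscle_moment(hist, 0.01, c) == 0.0

    def test_torque_bounded_by_strength(self):
        c = MuscleController(reflex_gain=10.0, strength_pct=50.0,
                             k_reflex_Nm_per_deg=1.0)
        hist = self.make_history(40.0)
        cap = 0.5 * c.tau_max_evertor_Nm
        assert muscle_moment(hist, 0.5, c) == pytest.approx(-cap)

    def test_invalid_history(self):
        with pytest.raises(ValueError):
            muscle_moment(np.zeros((0, 2)), 0.0, MuscleController())


class TestSimulateDropLanding:
    def test_equilibrium_start_stays_quiet(self):
        inp = SimulationInputs(incline_deg=0.0, drop_height_m=0.0,
                               talocrural_contact_deg=0.0,
                               subtalar_contact_deg=0.0)
        out = extract_peak_outcomes(simulate_drop_landing(inp))
        assert abs(out.peak_subtalar_supination_deg) < 0.5

    def test_deterministic_bit_identical(self):
        a = simulate_drop_landing(STUDY2)
        b = simulate_drop_landing(STUDY2)
        np.testing.assert_array_equal(a.subtalar_deg, b.subtalar_deg)
        np.testing.assert_array_equal(a.passive_moment_Nm, b.passive_moment_Nm)
        np.testing.assert_array_equal(a.contact_force_N, b.contact_force_N)

    def test_contact_force_nonnegative(self):
        traj = simulate_drop_landing(STUDY2)
        assert np.all(traj.contact_force_N >= 0.0)
        assert np.all(traj.contact_penetration_m >= 0.0)

    def test_peak_supination_increases_with_drop_height(self):
        peaks = []
        for h in (0.25, 0.35):
            inp = SimulationInputs(drop_height_m=h)
            peaks.append(extract_peak_outcomes(
                simulate_drop_landing(inp)).peak_subtalar_supination_deg)
        assert peaks[1] > peaks[0]

    def test_incline_drives_supination(self):
        level = extract_peak_outcomes(simulate_drop_landing(
            SimulationInputs(incline_deg=0.0)))
        incline = extract_peak_outcomes(simulate_drop_landing(STUDY2))
        assert (incline.peak_subtalar_supination_deg
                > level.peak_subtalar_supination_deg + 10.0)

    def test_strength_has_no_effect_without_active_pathway(self):
        base = dict(coactivation_pct=0.0, reflex_gain=0.0)
        weak = simulate_drop_landing(SimulationInputs(strength_pct=90.0,
                                                      **base))
        strong = simulate_drop_landing(SimulationInputs(strength_pct=110.0,
                                                        **base))
        np.testing.assert_array_equal(weak.subtalar_deg, strong.subtalar_deg)

    def test_energy_non_increasing_without_muscle_input(self):
        inp = STUDY2
        traj = simulate_drop_landing(inp)
        e = mechanical_energy(traj)
        ke0 = 0.5 * DEFAULT_PARAMETERS.body_mass_kg * (
            2 * 9.81 * inp.drop_height_m)
        assert np.all(np.diff(e) < 1e-3 * ke0)

    def test_finite_state_throughout(self):
        traj = simulate_drop_landing(STUDY2)
        for arr in (traj.subtalar_deg, traj.talocrural_deg,
                    traj.mass_height_m, traj.mass_lateral_m):
            assert np.all(np.isfinite(arr))
        assert np.all(np.diff(traj.time_s) > 0)


def mechanical_energy(traj):
    """Independent audit: kinetic + gravitational + bushing strain +
    contact elastic energy at each sample (J)."""
    p = traj.params
    inp = traj.inputs
    axes = traj.axis_set
    bushing = PassiveBushingModel(p.bushing_A_Nm, p.bushing_B_per_deg,
                                  p.bushing_C_Nm, p.bushing_D_per_deg,
                                  inp.passive_flexibility_pct)
    brace = BraceModel(inp.brace_scale_pct, p.bushing_A_Nm, p.bushing_B_per_deg,
                       p.bushing_C_Nm, p.bushing_D_per_deg)
    w1 = np.radians(traj.talocrural_velocity_deg_s)
    w2 = np.radians(traj.subtalar_velocity_deg_s)
    ke = (0.5 * p.body_mass_kg * (traj.mass_velocity_m_s ** 2
                                  + traj.mass_lateral_velocity_m_s ** 2)
          + 0.5 * p.inertia_talocrural_kgm2 * w1 ** 2
          + 0.5 * p.inertia_subtalar_kgm2 * w2 ** 2)
    com = np.array(p.foot_com_m)
    com_y = np.empty(len(traj))
    for i in range(len(traj)):
        r = (rotation_about_axis(axes.talocrural_axis, traj.talocrural_deg[i])
             @ rotation_about_axis(axes.subtalar_axis, traj.subtalar_deg[i]))
        com_y[i] = (r @ com)[1]
    pe = (p.body_mass_kg * 9.81 * traj.mass_height_m
          + p.foot_mass_kg * 9.81 * com_y)
    strain = (bushing.strain_energy_J(traj.talocrural_deg)
              + bushing.strain_energy_J(traj.subtalar_deg)
              + brace.strain_energy_J(traj.talocrural_deg)
              + brace.strain_energy_J(traj.subtalar_deg))
    k_point = p.contact_area_m2 * inp.contact_modulus_MPa_per_m * 1e6
    contact = 0.5 * k_point * np.sum(traj.contact_penetration_m ** 2, axis=1)
    return ke + pe + strain + contact


def make_synthetic_trajectory(subtalar_deg, passive_moment=None,
                              axes=None, hz=2000.0):
    n = len(subtalar_deg)
    t = np.arange(n) / hz
    zeros = np.zeros(n)
    pm = passive_moment if passive_moment is not None else np.zeros((n, 3))
    return Trajectory(
        time_s=t, mass_height_m=zeros, mass_velocity_m_s=zeros,
        mass_lateral_m=zeros, mass_lateral_velocity_m_s=zeros,
        talocrural_deg=zeros, talocrural_velocity_deg_s=zeros,
        subtalar_deg=np.asarray(subtalar_deg, float),
        subtalar_velocity_deg_s=np.gradient(subtalar_deg, t) if n > 1
        else zeros,
        jcs_dorsiflexion_deg=zeros, jcs_inversion_deg=zeros,
        jcs_internal_deg=zeros, passive_moment_Nm=pm,
        brace_moment_Nm=np.zeros((n, 3)), contact_force_N=zeros,
        contact_penetration_m=np.zeros((n, 4)),
        inputs=SimulationInputs(), axis_set=axes or AxisSet(),
        params=DEFAULT_PARAMETERS)


class TestExtractPeakOutcomes:
    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            extract_peak_outcomes(make_synthetic_trajectory(np.empty(0)))

    def test_constant_trace_peaks_at_first_sample(self):
        traj = make_synthetic_trajectory(np.full(100, 12.5))
        out = extract_peak_outcomes(traj)
        assert out.peak_subtalar_supination_deg == pytest.approx(12.5)
        assert out.peak_supination_time_s == pytest.approx(0.0)

    def test_sinusoid_peaks_at_analytic_argmax(self):
        hz, amp, freq = 2000.0, 30.0, 4.0
        t = np.arange(int(hz)) / hz
        traj = make_synthetic_trajectory(amp * np.sin(2 * np.pi * freq * t))
        out = extract_peak_outcomes(traj)
        assert out.peak_subtalar_supination_deg == pytest.approx(amp,
                                                                 abs=1e-3)
        assert out.peak_supination_time_s == pytest.approx(
            1.0 / (4 * freq), abs=1.0 / hz)

    def test_moment_projections_match_hand_dot_products(self):
        axes = AxisSet()
        th2 = np.array([0.0, 10.0, 40.0, 20.0])
        m = np.array([3.0, -2.0, 7.0])
        pm = np.tile(m, (4, 1))
        out = extract_peak_outcomes(make_synthetic_trajectory(th2, pm, axes))
        a2w = axes.subtalar_axis  # talocrural angle is zero throughout
        assert out.passive_moment_subtalar_Nm == pytest.approx(
            float(np.dot(m, rotation_about_axis(axes.talocrural_axis, 0.0)
                         @ a2w)))
        assert out.passive_moment_talocrural_Nm == pytest.approx(
            float(np.dot(m, axes.talocrural_axis)))
        assert out.peak_supination_time_s == pytest.approx(2 / 2000.0)

    def test_outcomes_serialise_flat(self):
        out = extract_peak_outcomes(make_synthetic_trajectory(
            np.linspace(0, 20, 50)))
        d = out.to_dict()
        assert d["peak_subtalar_supination_deg"] == pytest.approx(20.0)
        assert all(isinstance(v, float) for v in d.values())


class TestTrajectoryIO:
    def test_csv_roundtrip(self, tmp_path):
        import pandas as pd
        traj = simulate_drop_landing(SimulationInputs(drop_height_m=0.1))
        path = tmp_path / "traj.csv"
        write_trajectory_csv(traj, path)
        df = pd.read_csv(path, float_precision="round_trip")
        np.testing.assert_array_equal(df["subtalar_deg"].to_numpy(),
                                      traj.subtalar_deg)
        assert {"time_s", "jcs_inversion_deg",
                "talocrural_deg"} <= set(df.columns)
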