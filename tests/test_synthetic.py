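import numpy as np
import pytest

from limbpoint.dynamics import decompose_torques, mean_muscle_torque, mechanical_energy
from limbpoint.kinematics import analyze_markers, crop_to_movement, detect_reversal_phase
from limbpoint.limb_model import Anthropometrics, LimbModel, SegmentParams
from limbpoint.proprioception import mds_score
from limbpoint.protocol import make_target
from limbpoint.synthetic import (
    MIN_JERK_PEAK_FACTOR,
    CohortConfig,
    ParticipantProfile,
    computed_torque,
    forward_simulate,
    make_profile,
    plan_min_jerk,
    plan_out_and_back,
    simulate_cohort,
    simulate_jps_trial,
    simulate_mds_session,
    simulate_mds_trial,
    simulate_trial,
    static_torque,
)

CONTROL_ROM = {"hip": 64.7, "knee": 103.1, "ankle": 17.1}


def undistorted_profile(model):
    return ParticipantProfile("U", "control", model.anthropometrics, CONTROL_ROM, 0.0, {})


class TestMinJerk:
    def test_degenerate_plan_is_constant(self):
        plan = plan_min_jerk([10.0, 20.0, 5.0], [10.0, 20.0, 5.0], 0.5, 65.0)
        _, q, qd, qdd = plan.sample(65.0)
        assert np.allclose(q, q[0])
        assert np.allclose(qd, 0.0)
        assert np.allclose(qdd, 0.0)

    def test_midpoint_symmetry(self):
        plan = plan_min_jerk([0.0], [40.0], 0.8, 65.0)
        q, _, _ = plan.at(0.4)
        assert q[0, 0] == pytest.approx(20.0)

    def test_peak_speed_closed_form(self):
        delta, dur = 40.0, 0.8
        plan = plan_min_jerk([0.0], [delta], dur, 65.0)
        t = np.linspace(0, dur, 4001)
        _, qd, _ = plan.at(t)
        assert qd.max() == pytest.approx(MIN_JERK_PEAK_FACTOR * delta / dur, rel=1e-6)

    def test_boundary_conditions(self):
        plan = plan_out_and_back([0.0, 0.0, 0.0], [30.0, 50.0, 10.0], 0.6, 65.0, hold=0.2)
        for t in (0.0, plan.duration):
            _, qd, qdd = plan.at(t)
            assert np.allclose(qd, 0.0, atol=1e-9)
            assert np.allclose(qdd, 0.0, atol=1e-9)

    def test_invalid_duration_rejected(self):
        with pytest.raises(ValueError):
            plan_min_jerk([0.0], [1.0], 0.0, 65.0)


class TestComputedTorque:
    def test_vertical_chain_needs_no_torque(self, model):
        theta = np.full((4, 3), np.deg2rad(270.0))
        tau = static_torque(model, theta)
        assert np.abs(tau).max() < 1e-10

    def test_static_torque_balances_gravity(self, model):
        rng = np.random.default_rng(2)
        theta = rng.uniform(3.5, 6.5, (10, 3))
        tau = static_torque(model, theta)
        d = decompose_torques(model, seg_rad=theta, omega=np.zeros_like(theta),
                              alpha=np.zeros_like(theta))
        assert np.allclose(tau, -d.gravitational, atol=1e-8)


class TestForwardSimulate:
    def zero_g_model(self):
        seg = SegmentParams(mass=1.0, length=0.4, com=0.2, inertia=0.02)
        return LimbModel(
            anthropometrics=Anthropometrics(thigh=seg, shank=seg, foot=seg, gravity=0.0)
        )

    def test_zero_torque_zero_gravity_state_constant(self):
        model = self.zero_g_model()
        theta0 = np.array([4.0, 4.5, 5.0])
        _, th, om, al, tau = forward_simulate(
            model, lambda t, a, b: np.zeros(3), theta0, np.zeros(3), 1.0, 65.0
        )
        assert np.allclose(th, theta0, atol=1e-12)
        assert np.allclose(om, 0.0, atol=1e-12)
        assert np.allclose(tau, 0.0)

    def test_passive_swing_conserves_energy(self, model):
        """Frictionless passive swing: energy drift < 0.1% over 2 s."""
        theta0 = np.deg2rad(np.array([300.0, 280.0, 330.0]))
        _, th, om, _, _ = forward_simulate(
            model, lambda t, a, b: np.zeros(3), theta0, np.zeros(3), 2.0, 65.0
        )
        E = mechanical_energy(model, th, om)
        # reference scale: total mechanical energy span of the swing
        scale = max(abs(E[0]), E.max() - E.min())
        assert np.abs(E - E[0]).max() < 1e-3 * scale

    def test_divergence_guard_raises(self, model):
        from limbpoint.synthetic import SimulationDivergence

        big = np.array([500.0, 0.0, 0.0])
        with pytest.raises(SimulationDivergence):
            forward_simulate(model, lambda t, a, b: big,
                             np.deg2rad([270.0, 270.0, 360.0]), np.zeros(3), 5.0, 65.0)

    def test_computed_torque_reproduces_plan(self, model):
        """Open-loop computed torque tracks the planned trajectory."""
        from limbpoint.limb_model import segment_from_joint

        plan = plan_out_and_back(np.zeros(3), [38.8, 61.9, 10.3], 0.7, 65.0, hold=0.2)
        fs_fine = 65.0 * 32
        t, q, qd, qdd = plan.sample(fs_fine)
        seg = np.deg2rad(segment_from_joint(q))
        om = np.deg2rad(np.stack([qd[:, 0], qd[:, 0] - qd[:, 1],
                                  qd[:, 0] - qd[:, 1] + qd[:, 2]], -1))
        al = np.deg2rad(np.stack([qdd[:, 0], qdd[:, 0] - qdd[:, 1],
                                  qdd[:, 0] - qdd[:, 1] + qdd[:, 2]], -1))
        tau = computed_torque(model, seg, om, al)

        def torque_fn(tt, a, b):
            i = int(np.clip(round(tt * fs_fine), 0, len(t) - 1))
            return tau[i]

        tt, th, _, _, _ = forward_simulate(model, torque_fn, seg[0], om[0],
                                           plan.duration, 65.0)
        seg_plan = np.deg2rad(segment_from_joint(plan.at(tt)[0]))
        rms_deg = np.rad2deg(np.sqrt(((th - seg_plan) ** 2).mean()))
        assert rms_deg < 0.2


class TestSimulateTrial:
    def test_undistorted_trial_hits_target(self, model, noiseless_trial):
        kin = crop_to_movement(
            analyze_markers(noiseless_trial.markers, noiseless_trial.fs, filter_data=False)
        )
        ph = detect_reversal_phase(kin.toe_speed)
        dist = np.linalg.norm(
            kin.markers["toe"][ph.reversal] - noiseless_trial.target.target_point
        )
        assert dist < 1e-3  # within 1 mm

    def test_same_seed_bit_identical(self, model):
        prof = undistorted_profile(model)
        target = make_target(model, np.zeros(3), CONTROL_ROM, {"hip"})
        a = simulate_trial(prof, target, seed=77)
        b = simulate_trial(prof, target, seed=77)
        assert np.array_equal(a.seg_rad, b.seg_rad)
        assert np.array_equal(a.commanded_torque, b.commanded_torque)
        assert all(np.array_equal(a.markers[k], b.markers[k]) for k in a.markers)
        c = simulate_trial(prof, target, seed=78)
        assert not np.array_equal(a.seg_rad, c.seg_rad)

    def test_hip_extensor_deficit_shows_in_measured_torque(self, model):
        """A hip-extensor deficit at the KA target makes the measured mean hip
        muscle torque less extensor (less negative) than the matched control."""
        target = make_target(model, np.zeros(3), CONTROL_ROM, {"knee", "ankle"})

        def measured_hip(profile):
            tr = simulate_trial(profile, target, seed=31, out_duration=1.0,
                                marker_noise_sd=0.0)
            kin = crop_to_movement(analyze_markers(tr.markers, tr.fs))
            ph = detect_reversal_phase(kin.toe_speed)
            d = decompose_torques(model, kin)
            return mean_muscle_torque(d, ph)[0]

        base = undistorted_profile(model)
        deficit = ParticipantProfile("D", "SCI", model.anthropometrics, CONTROL_ROM,
                                     0.0, {("KA", "hip"): -0.5})
        assert measured_hip(deficit) > measured_hip(base)


class TestProprioceptionSimulation:
    def test_jps_ideal_observer_exact(self, model):
        prof = undistorted_profile(model)
        rng = np.random.default_rng(0)
        target, reproduced = simulate_jps_trial(prof, "hip", 25.0, rng,
                                                baseline_sd=0.0, rho_slope=1.0)
        assert (target, reproduced) == (25.0, 25.0)

    def test_jps_error_monotone_in_rho(self, model):
        rng = np.random.default_rng(1)
        maes = []
        for rho in (0.0, 0.5, 1.5, 3.0):
            prof = ParticipantProfile("P", "SCI", model.anthropometrics, CONTROL_ROM,
                                      rho, {})
            errs = [abs(np.subtract(*simulate_jps_trial(prof, "hip", 25.0, rng)))
                    for _ in range(1000)]
            maes.append(np.mean(errs))
        assert maes == sorted(maes)

    def test_mds_ideal_and_worst_case(self, model):
        rng = np.random.default_rng(2)
        ideal = ParticipantProfile("I", "control", model.anthropometrics, CONTROL_ROM,
                                   0.0, {})
        t = simulate_mds_trial(ideal, 1.0, "flexion", False, rng, score_floor=0.0)
        assert t.excursion_deg == 0.0 and t.correct_direction
        assert mds_score([t]) == 0.0
        worst = ParticipantProfile("W", "SCI", model.anthropometrics, CONTROL_ROM,
                                   3.0, {})
        t = simulate_mds_trial(worst, 1.0, "flexion", False, rng)
        assert t.excursion_deg == 10.0 and not t.correct_direction
        assert mds_score([t]) == 2.0

    def test_mds_session_layout(self, model):
        prof = undistorted_profile(model)
        trials = simulate_mds_session(prof, "hip", "pointing", np.random.default_rng(3))
        assert len(trials) == 11
        assert sum(t.catch for t in trials) == 1
        assert all(not t.moved for t in trials if t.catch)

    def test_mds_score_monotone_in_rho(self, model):
        scores = []
        rng = np.random.default_rng(4)
        for rho in (0.1, 0.5, 1.0, 1.8):
            prof = ParticipantProfile("P", "SCI", model.anthropometrics, CONTROL_ROM,
                                      rho, {})
            vals = [mds_score([simulate_mds_trial(prof, 1.0, "flexion", False, rng)])
                    for _ in range(400)]
            scores.append(np.mean(vals))
        assert scores == sorted(scores)
        assert all(0.0 <= s <= 2.0 for s in scores)


class TestCohort:
    def test_profiles_follow_group_conditions(self):
        rng = np.random.default_rng(5)
        cfg = CohortConfig()
        from limbpoint.synthetic import make_cohort_profiles

        profiles = make_cohort_profiles(cfg, rng)
        assert len(profiles) == 28
        groups = [p.group for p in profiles]
        assert groups.count("control") == 12 and groups.count("SCI") == 16
        sci_rho = [p.rho for p in profiles if p.group == "SCI"]
        assert sci_rho == pytest.approx(list(cfg.sci_rho))
        # SCI distortions monotone in rho for each link
        from limbpoint.synthetic import DEFAULT_DISTORTION_LINKS

        for key, (off, slope) in DEFAULT_DISTORTION_LINKS.items():
            vals = [(p.rho, p.distortions[key]) for p in profiles if p.group == "SCI"]
            vals.sort()
            deltas = np.diff([v for _, v in vals])
            assert (deltas <= 1e-12).all() if slope < 0 else (deltas >= -1e-12).all()

    def test_tiny_cohort_counts_and_determinism(self):
        cfg = CohortConfig(n_control=1, n_sci=1, trials_per_combo_per_block=1,
                           marker_noise_sd=0.001)
        a = simulate_cohort(cfg, seed=9)
        assert len(a.profiles) == 2
        assert len(a.trials) == 2 * 7 * 2  # participants x combos x blocks
        b = simulate_cohort(cfg, seed=9)
        assert np.array_equal(a.trials[5].seg_rad, b.trials[5].seg_rad)
        assert a.proprioception.equals(b.proprioception)
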