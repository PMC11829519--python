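import numpy as np
import pytest

from limbpoint.dynamics import (
    TorqueDecomposition,
    decompose_torques,
    joint_angular_velocity,
    mean_muscle_torque,
    mechanical_energy,
    muscle_power,
    newton_euler_joint_torques,
)
from limbpoint.kinematics import ReversalPhase
from limbpoint.synthetic import computed_torque


def random_states(n, seed=0):
    rng = np.random.default_rng(seed)
    theta = rng.uniform(3.0, 7.0, (n, 3))
    omega = rng.normal(0, 4.0, (n, 3))
    alpha = rng.normal(0, 25.0, (n, 3))
    return theta, omega, alpha


class TestStatics:
    def test_static_pose_net_zero_muscle_balances_gravity(self, model):
        rng = np.random.default_rng(1)
        theta = rng.uniform(3.0, 7.0, (20, 3))
        z = np.zeros_like(theta)
        d = decompose_torques(model, seg_rad=theta, omega=z, alpha=z)
        assert np.abs(d.net).max() < 1e-12
        assert np.abs(d.interaction).max() < 1e-12
        assert np.allclose(d.muscle, -d.gravitational, atol=1e-12)

    def test_vertical_chain_has_zero_gravitational_torque(self, model):
        theta = np.full((3, 3), np.deg2rad(270.0))
        z = np.zeros_like(theta)
        d = decompose_torques(model, seg_rad=theta, omega=z, alpha=z)
        assert np.abs(d.gravitational).max() < 1e-12

    def test_hip_gravity_torque_for_horizontal_leg(self, model):
        """Straight horizontal leg: hip gravity torque is -g * sum(m_s * x_com,s)."""
        theta = np.zeros((1, 3))  # all segments along +x
        z = np.zeros_like(theta)
        d = decompose_torques(model, seg_rad=theta, omega=z, alpha=z)
        a = model.anthropometrics
        l1, l2 = a.thigh.length, a.shank.length
        expected = -a.gravity * (
            a.thigh.mass * a.thigh.com
            + a.shank.mass * (l1 + a.shank.com)
            + a.foot.mass * (l1 + l2 + a.foot.com)
        )
        assert d.gravitational[0, 0] == pytest.approx(expected, rel=1e-12)


class TestDecompositionIdentities:
    def test_identity_and_parse_sum_on_random_states(self, model):
        theta, omega, alpha = random_states(300, seed=2)
        d = decompose_torques(model, seg_rad=theta, omega=omega, alpha=alpha)
        residual = d.net - (d.muscle + d.gravitational + d.interaction)
        assert np.abs(residual).max() <= 1e-9
        parse = d.interaction_parsed.sum(axis=(2, 3)) - d.interaction
        assert np.abs(parse).max() <= 1e-9
        assert np.abs(d.hip_linear).max() == 0.0

    def test_interaction_zero_when_other_segments_still(self, model):
        # joint j's interaction vanishes when the other two segments have
        # zero angular velocity and acceleration, whatever segment d(j) does
        rng = np.random.default_rng(3)
        for j in range(3):
            theta = rng.uniform(3.0, 7.0, (10, 3))
            omega = np.zeros((10, 3))
            alpha = np.zeros((10, 3))
            omega[:, j] = rng.normal(0, 5, 10)
            alpha[:, j] = rng.normal(0, 30, 10)
            d = decompose_torques(model, seg_rad=theta, omega=omega, alpha=alpha)
            assert np.abs(d.interaction[:, j]).max() < 1e-12

    def test_own_segment_parsed_entries_structurally_zero(self, model):
        theta, omega, alpha = random_states(20, seed=4)
        d = decompose_torques(model, seg_rad=theta, omega=omega, alpha=alpha)
        for j in range(3):
            assert np.abs(d.interaction_parsed[:, j, j, :]).max() == 0.0

    def test_literal_muscle_sign_flag_flips_muscle(self, model):
        theta, omega, alpha = random_states(5, seed=5)
        a = decompose_torques(model, seg_rad=theta, omega=omega, alpha=alpha)
        b = decompose_torques(model, seg_rad=theta, omega=omega, alpha=alpha,
                              literal_muscle_sign=True)
        assert np.allclose(b.muscle, -a.muscle)

    def test_shape_and_finiteness_validation(self, model):
        with pytest.raises(ValueError):
            decompose_torques(model, seg_rad=np.zeros((5, 3)), omega=np.zeros((4, 3)),
                              alpha=np.zeros((5, 3)))
        bad = np.full((5, 3), np.nan)
        with pytest.raises(ValueError):
            decompose_torques(model, seg_rad=bad, omega=np.zeros((5, 3)),
                              alpha=np.zeros((5, 3)))


class TestCrossFormulation:
    def test_newton_euler_matches_lagrangian_on_random_states(self, model):
        theta, omega, alpha = random_states(500, seed=6)
        d = decompose_torques(model, seg_rad=theta, omega=omega, alpha=alpha)
        tau_lag = computed_torque(model, theta, omega, alpha)
        assert np.abs(d.muscle - tau_lag).max() <= 1e-6

    def test_whole_leg_rigid_pendulum_closed_form(self, model):
        """All segments collinear and moving together: hip torque is the
        compound-pendulum equation I_hip * alpha + g * m * d_com * cos(theta)."""
        a = model.anthropometrics
        l1, l2 = a.thigh.length, a.shank.length
        dists = np.array([a.thigh.com, l1 + a.shank.com, l1 + l2 + a.foot.com])
        masses = np.array([a.thigh.mass, a.shank.mass, a.foot.mass])
        inertias = np.array([a.thigh.inertia, a.shank.inertia, a.foot.inertia])
        I_hip = float(np.sum(inertias + masses * dists**2))
        th, om, al = 4.2, 1.3, -7.0
        theta = np.full((1, 3), th)
        omega = np.full((1, 3), om)
        alpha = np.full((1, 3), al)
        tau = newton_euler_joint_torques(model, theta, omega, alpha)
        expected = I_hip * al + a.gravity * float(np.sum(masses * dists)) * np.cos(th)
        assert tau[0, 0] == pytest.approx(expected, rel=1e-10)

    def test_foot_pendulum_closed_form(self, model):
        """Only the foot moves: ankle torque is the single-pendulum equation."""
        a = model.anthropometrics
        theta = np.array([[4.71238898038469, 4.71238898038469, 5.5]])
        omega = np.array([[0.0, 0.0, 2.0]])
        alpha = np.array([[0.0, 0.0, -9.0]])
        tau = newton_euler_joint_torques(model, theta, omega, alpha)
        I_eff = a.foot.inertia + a.foot.mass * a.foot.com**2
        expected = I_eff * (-9.0) + a.gravity * a.foot.mass * a.foot.com * np.cos(5.5)
        assert tau[0, 2] == pytest.approx(expected, rel=1e-10)

    def test_against_sympy_lagrangian_oracle(self, model):
        """Symbolic Euler--Lagrange equations as a third, independent route."""
        sympy = pytest.importorskip("sympy")
        import sympy as sp

        t = sp.Symbol("t")
        q = [sp.Function(f"q{i}")(t) for i in range(3)]
        a = model.anthropometrics
        m = [p.mass for p in a.segments]
        l = [p.length for p in a.segments]
        r = [p.com for p in a.segments]
        inert = [p.inertia for p in a.segments]
        g = a.gravity
        x = [r[0] * sp.cos(q[0]),
             l[0] * sp.cos(q[0]) + r[1] * sp.cos(q[1]),
             l[0] * sp.cos(q[0]) + l[1] * sp.cos(q[1]) + r[2] * sp.cos(q[2])]
        y = [r[0] * sp.sin(q[0]),
             l[0] * sp.sin(q[0]) + r[1] * sp.sin(q[1]),
             l[0] * sp.sin(q[0]) + l[1] * sp.sin(q[1]) + r[2] * sp.sin(q[2])]
        T = sum(
            sp.Rational(1, 2) * m[i] * (sp.diff(x[i], t) ** 2 + sp.diff(y[i], t) ** 2)
            + sp.Rational(1, 2) * inert[i] * sp.diff(q[i], t) ** 2
            for i in range(3)
        )
        V = sum(m[i] * g * y[i] for i in range(3))
        L = T - V
        Q = [sp.diff(sp.diff(L, sp.diff(q[i], t)), t) - sp.diff(L, q[i]) for i in range(3)]
        qs = sp.symbols("a0:3")
        vs = sp.symbols("b0:3")
        ws = sp.symbols("c0:3")
        subs = {}
        for i in range(3):
            subs[sp.diff(q[i], t, 2)] = ws[i]
            subs[sp.diff(q[i], t)] = vs[i]
            subs[q[i]] = qs[i]
        fQ = sp.lambdify(qs + vs + ws, [qq.subs(subs) for qq in Q], "numpy")

        theta, omega, alpha = random_states(10, seed=7)
        for k in range(10):
            Qnum = np.array(fQ(*theta[k], *omega[k], *alpha[k]))
            tau_ccw = Qnum[::-1].cumsum()[::-1]  # joint torques from generalized
            expected = tau_ccw * np.array([1.0, -1.0, 1.0])
            tau = newton_euler_joint_torques(model, theta[k:k+1], omega[k:k+1], alpha[k:k+1])
            got = tau[0] * np.array([1.0, -1.0, 1.0])
            assert np.allclose(got, expected, atol=1e-8)


class TestPowerAndMeans:
    def _fake_decomp(self, muscle):
        n = muscle.shape[0]
        z = np.zeros_like(muscle)
        return TorqueDecomposition(net=z, gravitational=z, interaction=z,
                                   muscle=muscle, interaction_parsed=np.zeros((n, 3, 3, 2)),
                                   hip_linear=z)

    def test_flexor_torque_during_flexion_is_generative(self):
        muscle = np.full((4, 3), 10.0)
        omega = np.zeros((4, 3))
        omega[:, 0] = 1.0  # hip flexing at 1 rad/s
        d = self._fake_decomp(muscle)
        P = muscle_power(d, omega=omega)
        assert np.allclose(P[:, 0], 10.0)

    def test_stationary_joint_zero_power(self):
        muscle = np.full((4, 3), 5.0)
        P = muscle_power(self._fake_decomp(muscle), omega=np.zeros((4, 3)))
        assert np.allclose(P, 0.0)

    def test_joint_angular_velocity_map(self):
        omega = np.array([[1.0, 0.25, -0.5]])
        phi_dot = joint_angular_velocity(omega)
        assert np.allclose(phi_dot, [[1.0, 0.75, -0.75]])

    def test_mean_muscle_torque_window(self):
        muscle = np.zeros((20, 3))
        muscle[:, 0] = 3.5
        muscle[:, 1] = np.arange(20) - 7.0  # antisymmetric about sample 7 window mid
        d = self._fake_decomp(muscle)
        phase = ReversalPhase(first_peak=3, reversal=11, second_peak=15)
        m = mean_muscle_torque(d, phase)
        assert m[0] == pytest.approx(3.5)
        assert m[1] == pytest.approx(0.0)  # samples 3..11 centred on 7

    def test_energy_balance_on_noiseless_trial(self, model, noiseless_trial):
        """Summed joint muscle power integrates to the mechanical-energy change."""
        tr = noiseless_trial
        P = (tr.commanded_torque * joint_angular_velocity(tr.omega)).sum(axis=1)
        E = mechanical_energy(model, tr.seg_rad, tr.omega)
        work = np.concatenate([[0.0], np.cumsum((P[1:] + P[:-1]) / 2) / tr.fs])
        dE = E - E[0]
        span = dE.max() - dE.min()
        assert np.abs(work - dE).max() < 0.005 * span
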