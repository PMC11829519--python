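"""Synthetic cohort generator: torque-driven forward-simulated pointing trials.

Every downstream stage of the pipeline is testable against this module with
no external data.  Trials are planned as smooth minimum-jerk out-and-back
joint rotations to each target, converted to joint torques by an inverse
model, optionally distorted to emulate group-specific motor-strategy
deficits, and integrated forward through the three-link equations of motion.
Marker trajectories are produced by the forward kinematics plus i.i.d.
Gaussian capture noise.

The torque computation here (:func:`computed_torque`) is an energy/Lagrangian
formulation -- mass matrix assembled from centre-of-mass Jacobians, velocity
and gravity terms from complex-step derivatives of the kinetic and potential
energy -- deliberately independent of the Newton--Euler recursion in
:mod:`limbpoint.dynamics`, so the two serve as cross-formulation oracles.

Each participant carries a proprioceptive-noise parameter ``rho`` (a.u., on
the scale of the movement-detection-sense score): it scales the smooth
zero-mean torque noise added to the command, drives the strategy-distortion
coefficients, and sets the error magnitudes of the simulated joint-position
and movement-detection test trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import FLEXOR_SIGN
from .limb_model import Anthropometrics, JOINTS, LimbModel, forward_kinematics, segment_from_joint
from .proprioception import MDS_MAX_EXCURSION, MdsTrial
from .protocol import ScheduleRecord, TargetSpec, make_target, make_trial_schedule

# ---------------------------------------------------------------------------
# minimum-jerk planning

#: Peak-speed factor of the quintic minimum-jerk profile: max |ds/dt| = 1.875 d/T.
MIN_JERK_PEAK_FACTOR = 1.875


@dataclass(frozen=True)
class PlanSegment:
    t0: float
    t1: float
    q0: np.ndarray
    q1: np.ndarray


@dataclass(frozen=True)
class JointPlan:
    """Piecewise minimum-jerk joint trajectory with analytic derivatives (deg)."""

    segments: tuple[PlanSegment, ...]

    @property
    def duration(self) -> float:
        return self.segments[-1].t1

    def at(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Angles (deg), velocities (deg/s), accelerations (deg/s^2) at times t.

        Times are clamped to the plan's span.
        """
        t = np.clip(np.atleast_1d(np.asarray(t, float)), 0.0, self.duration)
        q = np.empty(t.shape + self.segments[0].q0.shape)
        qd = np.zeros_like(q)
        qdd = np.zeros_like(q)
        for seg in self.segments:
            mask = (t >= seg.t0) & (t <= seg.t1) if seg is self.segments[-1] else (
                (t >= seg.t0) & (t < seg.t1)
            )
            if not mask.any():
                continue
            T = seg.t1 - seg.t0
            tau = (t[mask] - seg.t0) / T
            s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
            sd = (30 * tau**2 - 60 * tau**3 + 30 * tau**4) / T
            sdd = (60 * tau - 180 * tau**2 + 120 * tau**3) / T**2
            dq = seg.q1 - seg.q0
            q[mask] = seg.q0 + np.outer(s, dq)
            qd[mask] = np.outer(sd, dq)
            qdd[mask] = np.outer(sdd, dq)
        return q, qd, qdd

    def sample(self, fs: float) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Time base and sampled (q, qd, qdd) at ``fs`` Hz."""
        n = int(np.floor(self.duration * fs)) + 1
        t = np.arange(n) / fs
        return (t, *self.at(t))


def plan_min_jerk(start_deg, end_deg, duration: float, fs: float) -> JointPlan:
    """Single minimum-jerk reach from ``start_deg`` to ``end_deg``.

    Boundary velocities and accelerations are zero; the peak joint speed is
    1.875 |end - start| / duration.  Use :meth:`JointPlan.sample` to obtain
    the time series at ``fs``.
    """
    if duration <= 0 or fs <= 0:
        raise ValueError("duration and sampling rate must be positive")
    q0 = np.atleast_1d(np.asarray(start_deg, float))
    q1 = np.atleast_1d(np.asarray(end_deg, float))
    return JointPlan(segments=(PlanSegment(0.0, duration, q0, q1),))


def plan_out_and_back(
    home_deg, final_deg, out_duration: float, fs: float, hold: float = 0.3
) -> JointPlan:
    """Out-and-back plan: hold, minimum-jerk out, minimum-jerk back, hold."""
    if out_duration <= 0:
        raise ValueError("out_duration must be positive")
    q0 = np.atleast_1d(np.asarray(home_deg, float))
    q1 = np.atleast_1d(np.asarray(final_deg, float))
    t = 0.0
    segs = []
    if hold > 0:
        segs.append(PlanSegment(t, t + hold, q0, q0))
        t += hold
    segs.append(PlanSegment(t, t + out_duration, q0, q1))
    t += out_duration
    segs.append(PlanSegment(t, t + out_duration, q1, q0))
    t += out_duration
    if hold > 0:
        segs.append(PlanSegment(t, t + hold, q0, q0))
    return JointPlan(segments=tuple(segs))


# ---------------------------------------------------------------------------
# Lagrangian (energy-based) torque computation

_CSTEP = 1e-20


def _limb_params(model: LimbModel):
    a = model.anthropometrics
    m = np.array([p.mass for p in a.segments])
    l = np.array([p.length for p in a.segments])
    r = np.array([p.com for p in a.segments])
    inertia = np.array([p.inertia for p in a.segments])
    return m, l, r, inertia, a.gravity


def _mass_matrix(model: LimbModel, theta: np.ndarray) -> np.ndarray:
    """Mass matrix (n, 3, 3) assembled from COM Jacobians, M = sum m J^T J + I."""
    m, l, r, inertia, _ = _limb_params(model)
    n = theta.shape[0]
    perp = np.stack([-np.sin(theta), np.cos(theta)], axis=-1)  # (n, 3, 2)
    lever = np.array([
        [r[0], 0.0, 0.0],
        [l[0], r[1], 0.0],
        [l[0], l[1], r[2]],
    ])  # lever[i, k]: d c_i / d theta_k = lever[i,k] * perp_k
    M = np.zeros((n, 3, 3), dtype=theta.dtype)
    for i in range(3):
        Ji = lever[i][None, None, :] * perp.transpose(0, 2, 1)  # (n, 2, 3)
        M += m[i] * np.einsum("nci,ncj->nij", Ji, Ji)
    M += np.diag(inertia)[None, :, :].astype(theta.dtype)
    return M


def _potential(model: LimbModel, theta: np.ndarray) -> np.ndarray:
    m, l, r, inertia, g = _limb_params(model)
    y = np.sin(theta)
    ycom = np.stack([
        r[0] * y[:, 0],
        l[0] * y[:, 0] + r[1] * y[:, 1],
        l[0] * y[:, 0] + l[1] * y[:, 1] + r[2] * y[:, 2],
    ], axis=-1)
    return (m[None, :] * g * ycom).sum(axis=1)


def _generalized_torques(model: LimbModel, theta, omega, alpha) -> np.ndarray:
    """Generalized torques conjugate to the segment angles (n, 3).

    Q = M qdd + dM/dt qd - grad_q T + grad_q V, with configuration gradients
    taken by complex-step differentiation of the energy terms.
    """
    theta = np.asarray(theta, float)
    omega = np.asarray(omega, float)
    alpha = np.asarray(alpha, float)
    M = _mass_matrix(model, theta)
    Q = np.einsum("nij,nj->ni", M, alpha)
    for k in range(3):
        pert = theta.astype(complex)
        pert[:, k] += 1j * _CSTEP
        dMk = _mass_matrix(model, pert).imag / _CSTEP       # (n, 3, 3)
        dVk = _potential(model, pert).imag / _CSTEP         # (n,)
        Q += np.einsum("nij,nj->ni", dMk, omega) * omega[:, k : k + 1]
        Q[:, k] -= 0.5 * np.einsum("ni,nij,nj->n", omega, dMk, omega)
        Q[:, k] += dVk
    return Q


def computed_torque(model: LimbModel, seg_rad, omega, alpha) -> np.ndarray:
    """Joint torques (N m, flexor/dorsiflexor-positive) that reproduce a trajectory.

    The inverse model is exact for the planned trajectory: feeding the result
    back through :func:`forward_simulate` reproduces the plan to integrator
    tolerance.  Independent (energy-based) formulation from the Newton--Euler
    decomposition in :mod:`limbpoint.dynamics`.
    """
    Q = _generalized_torques(model, seg_rad, omega, alpha)
    tau_ccw = np.flip(np.cumsum(np.flip(Q, axis=1), axis=1), axis=1)
    return tau_ccw * FLEXOR_SIGN[None, :]


def static_torque(model: LimbModel, seg_rad) -> np.ndarray:
    """Gravity-balancing joint torques (flexor-positive) at given postures."""
    z = np.zeros_like(np.asarray(seg_rad, float))
    return computed_torque(model, seg_rad, z, z)


# ---------------------------------------------------------------------------
# forward dynamics

class SimulationDivergence(RuntimeError):
    pass


def _fd_constants(model: LimbModel):
    """Constant coefficients of the equations of motion, precomputed per model."""
    m, l, r, inertia, g = _limb_params(model)
    mu = np.array([m[0] * r[0] + (m[1] + m[2]) * l[0],
                   m[1] * r[1] + m[2] * l[1],
                   m[2] * r[2]])
    a01, a02, a12 = l[0] * mu[1], l[0] * mu[2], l[1] * mu[2]
    diag = np.array([inertia[0] + m[0] * r[0] ** 2 + (m[1] + m[2]) * l[0] ** 2,
                     inertia[1] + m[1] * r[1] ** 2 + m[2] * l[1] ** 2,
                     inertia[2] + m[2] * r[2] ** 2])
    return diag, (a01, a02, a12), mu, g


def _make_accel(model: LimbModel):
    """Closure computing segment angular accelerations from applied joint torques.

    Closed-form mass matrix and velocity/gravity vector; used only inside the
    integrator where the complex-step energy formulation would be too slow.
    """
    diag, (a01, a02, a12), mu, g = _fd_constants(model)

    d0, d1, d2 = diag
    mu0, mu1, mu2 = mu
    from math import cos, sin

    def accel(theta: np.ndarray, omega: np.ndarray, tau_flex: np.ndarray) -> np.ndarray:
        t0, t1, t2 = theta
        c0, c1, c2 = cos(t0), cos(t1), cos(t2)
        s0, s1, s2 = sin(t0), sin(t1), sin(t2)
        c01 = c0 * c1 + s0 * s1
        c02 = c0 * c2 + s0 * s2
        c12 = c1 * c2 + s1 * s2
        s01 = s0 * c1 - c0 * s1
        s02 = s0 * c2 - c0 * s2
        s12 = s1 * c2 - c1 * s2
        m01 = a01 * c01
        m02 = a02 * c02
        m12 = a12 * c12
        w0, w1, w2 = omega[0] ** 2, omega[1] ** 2, omega[2] ** 2
        b0 = a01 * s01 * w1 + a02 * s02 * w2 + g * mu0 * c0
        b1 = -a01 * s01 * w0 + a12 * s12 * w2 + g * mu1 * c1
        b2 = -a02 * s02 * w0 - a12 * s12 * w1 + g * mu2 * c2
        th, tk, ta = tau_flex[0], -tau_flex[1], tau_flex[2]
        r0 = th - tk - b0
        r1 = tk - ta - b1
        r2 = ta - b2
        # Cramer's rule on the symmetric 3x3 mass matrix
        A00 = d1 * d2 - m12 * m12
        A01 = m02 * m12 - m01 * d2
        A02 = m01 * m12 - m02 * d1
        det = d0 * A00 + m01 * A01 + m02 * A02
        A11 = d0 * d2 - m02 * m02
        A12 = m01 * m02 - d0 * m12
        A22 = d0 * d1 - m01 * m01
        return np.array([
            (A00 * r0 + A01 * r1 + A02 * r2) / det,
            (A01 * r0 + A11 * r1 + A12 * r2) / det,
            (A02 * r0 + A12 * r1 + A22 * r2) / det,
        ])

    return accel


def forward_simulate(
    model: LimbModel,
    torque_fn,
    initial_seg_rad,
    initial_omega,
    duration: float,
    fs: float,
    substeps: int = 16,
    omega_limit: float = 50.0,
):
    """Integrate the three-link equations of motion under applied joint torques.

    ``torque_fn(t, seg_rad, omega)`` returns flexor-positive joint torques
    (3,); state-independent (open-loop) commands simply ignore the state.
    Fixed-step 4th-order Runge--Kutta with ``substeps`` internal steps per
    output sample (16 substeps at 65 Hz is an internal rate of 1040 Hz);
    returns (time, seg_rad, omega, alpha, applied_torque) sampled at ``fs``.
    Aborts with a diagnostic if any segment speed exceeds ``omega_limit``
    rad/s.
    """
    if fs <= 0 or duration <= 0:
        raise ValueError("duration and sampling rate must be positive")
    n_out = int(np.floor(duration * fs)) + 1
    h = 1.0 / (fs * substeps)
    theta = np.array(initial_seg_rad, float)
    omega = np.array(initial_omega, float)
    out_theta = np.empty((n_out, 3))
    out_omega = np.empty((n_out, 3))
    out_alpha = np.empty((n_out, 3))
    out_tau = np.empty((n_out, 3))
    accel = _make_accel(model)

    def deriv(t, th, om):
        return om, accel(th, om, np.asarray(torque_fn(t, th, om), float))

    t = 0.0
    for i in range(n_out):
        out_theta[i], out_omega[i] = theta, omega
        out_tau[i] = np.asarray(torque_fn(t, theta, omega), float)
        out_alpha[i] = accel(theta, omega, out_tau[i])
        if i == n_out - 1:
            break
        for _ in range(substeps):
            k1v, k1a = deriv(t, theta, omega)
            k2v, k2a = deriv(t + h / 2, theta + h / 2 * k1v, omega + h / 2 * k1a)
            k3v, k3a = deriv(t + h / 2, theta + h / 2 * k2v, omega + h / 2 * k2a)
            k4v, k4a = deriv(t + h, theta + h * k3v, omega + h * k3a)
            theta = theta + h / 6 * (k1v + 2 * k2v + 2 * k3v + k4v)
            omega = omega + h / 6 * (k1a + 2 * k2a + 2 * k3a + k4a)
            t += h
            if np.any(np.abs(omega) > omega_limit):
                raise SimulationDivergence(
                    f"integration diverged at t={t:.3f} s: |segment speed| exceeded "
                    f"{omega_limit} rad/s (max {np.abs(omega).max():.1f})"
                )
    return np.arange(n_out) / fs, out_theta, out_omega, out_alpha, out_tau


# ---------------------------------------------------------------------------
# participant profiles and cohorts

#: Default severity spectrum of the simulated SCI group: per-participant
#: movement-detection-sense scores (a.u.) spanning the range observed in
#: motor-incomplete SCI cohorts (0.13-2.43); the proprioceptive-noise
#: parameter rho is set to these values when 16 SCI participants are drawn.
DEFAULT_SCI_MDS = (
    0.47, 1.28, 2.43, 1.70, 0.50, 1.61, 2.23, 0.29,
    0.13, 1.02, 0.51, 0.49, 1.54, 0.74, 0.72, 0.78,
)

#: Group mean (SD) active ROM in degrees for (hip, knee, ankle).
ROM_STATS = {
    "control": ((64.7, 18.5), (103.1, 12.1), (17.1, 6.3)),
    "SCI": ((47.5, 10.0), (86.6, 17.8), (10.5, 8.2)),
}

#: Group mean (SD) body mass (kg) and stature (m).
BODY_STATS = {"control": ((71.0, 13.0), (1.70, 0.09)), "SCI": ((75.0, 15.0), (1.69, 0.09))}

#: Strategy-distortion coefficients as linear functions of rho:
#: multiplier = offset + slope * rho, applied to the movement-related
#: (gravity-compensated) part of the commanded torque at the named joint
#: when pointing to the named target class.  Negative values are deficits.
DEFAULT_DISTORTION_LINKS = {
    ("KA", "hip"): (-0.15, -0.25),     # hip-extensor deficit, grows with rho
    ("HKA", "knee"): (0.35, -0.15),    # knee-flexor excess; negative rho slope
    ("HA", "knee"): (-0.10, -0.15),    # knee-extensor deficit
    ("HKA", "ankle"): (-0.10, -0.15),  # ankle-dorsiflexor deficit
}

#: JPS reproduction-error SD (deg) = baseline + slope * rho.
JPS_BASELINE_SD = 6.6
JPS_RHO_SLOPE = 8.5

#: Per-joint torque-noise SD (N m) per unit rho, scaled to segment inertia.
TORQUE_NOISE_SD = np.array([0.40, 0.30, 0.015])

#: Low-gain joint-space tracking (PD) gains standing in for reflexive and
#: impedance corrections: N m/rad and N m s/rad per joint (hip, knee, ankle).
TRACKING_KP = np.array([20.0, 10.0, 0.5])
TRACKING_KD = np.array([4.0, 2.0, 0.1])


@dataclass(frozen=True)
class ParticipantProfile:
    """Latent description of one simulated participant."""

    pid: str
    group: str                         # "control" or "SCI"
    anthropometrics: Anthropometrics
    rom_deg: dict
    rho: float                         # proprioceptive-noise parameter (a.u.)
    distortions: dict = field(default_factory=dict)  # (class, joint) -> multiplier

    @property
    def model(self) -> LimbModel:
        return LimbModel(anthropometrics=self.anthropometrics)

    def distortion(self, target_class: str, joint: str) -> float:
        return self.distortions.get((target_class, joint), 0.0)


def make_profile(
    pid: str,
    group: str,
    rng: np.random.Generator,
    rho: float | None = None,
    distortion_links: dict = DEFAULT_DISTORTION_LINKS,
    control_distortion_sd: float = 0.02,
) -> ParticipantProfile:
    """Draw one participant: anthropometrics, ROM, rho and strategy distortions."""
    (m_mu, m_sd), (h_mu, h_sd) = BODY_STATS[group]
    mass = float(np.clip(rng.normal(m_mu, m_sd), 45, 110))
    height = float(np.clip(rng.normal(h_mu, h_sd), 1.45, 1.95))
    rom = {}
    for joint, (mu, sd) in zip(JOINTS, ROM_STATS[group]):
        rom[joint] = float(np.clip(rng.normal(mu, sd), 5.0, 140.0))
    if rho is None:
        if group == "control":
            rho = float(np.clip(rng.normal(0.20, 0.08), 0.05, 0.40))
        else:
            rho = float(np.exp(rng.normal(np.log(0.85), 0.65)))
    if group == "control":
        distortions = {
            key: float(rng.normal(0.0, control_distortion_sd)) for key in distortion_links
        }
    else:
        distortions = {
            key: offset + slope * rho for key, (offset, slope) in distortion_links.items()
        }
    return ParticipantProfile(
        pid=pid,
        group=group,
        anthropometrics=Anthropometrics.from_body(mass, height),
        rom_deg=rom,
        rho=float(rho),
        distortions=distortions,
    )


@dataclass
class SimulatedTrial:
    """One forward-simulated pointing trial."""

    record: ScheduleRecord
    target: TargetSpec
    fs: float
    time: np.ndarray
    commanded_torque: np.ndarray       # (n, 3) flexor-positive N m at fs
    seg_rad: np.ndarray                # true segment angles (n, 3)
    omega: np.ndarray
    alpha: np.ndarray
    markers: dict                      # noisy marker positions at fs
    out_duration: float
    seed: int
    pid: str = ""


def _smooth_noise(rng: np.random.Generator, n: int, fs: float, sd: np.ndarray) -> np.ndarray:
    """Zero-mean low-frequency torque noise, SD per joint, shape (n, 3)."""
    from .kinematics import lowpass_filter

    white = rng.standard_normal((n + 200, 3))
    smooth = lowpass_filter(white, fs, cutoff=3.0)[100 : 100 + n]
    smooth = smooth - smooth.mean(axis=0)
    scale = smooth.std(axis=0)
    scale[scale == 0] = 1.0
    return smooth / scale * sd[None, :]


def simulate_trial(
    profile: ParticipantProfile,
    target: TargetSpec,
    seed: int,
    record: ScheduleRecord | None = None,
    fs: float = 65.0,
    out_duration: float | None = None,
    marker_noise_sd: float = 0.002,
    hold: float = 0.3,
    rho_override: float | None = None,
    pid: str = "",
) -> SimulatedTrial:
    """Simulate one out-and-back pointing trial for a participant.

    The nominal plan is a minimum-jerk out-and-back movement to the target's
    final joint angles; the out-phase duration is drawn so that the measured
    movement time (first toe-speed peak to reversal) matches observed pointing
    behaviour (mean 0.64 s, SD 0.23 s).  The commanded feedforward torque is
    the planned computed torque times (1 + distortion) at the class-specific
    joint, plus smooth zero-mean noise scaled by rho.  A fixed low-gain
    joint-space PD term tracks the plan, standing in for reflexive/impedance
    corrections; it bounds the drift an uncompensated feedforward command
    accumulates over a multi-second trial while leaving distortion- and
    noise-driven errors of a few centimetres in place.  The stored commanded
    torque is the total applied torque including this corrective term.
    """
    rng = np.random.default_rng(seed)
    model = profile.model
    rho = profile.rho if rho_override is None else rho_override
    if out_duration is None:
        # measured movement time is about half the out-phase duration
        out_duration = float(np.clip(rng.normal(1.28, 0.46), 0.6, 2.4))
    plan = plan_out_and_back(
        target.home_joint_deg, target.final_joint_deg, out_duration, fs, hold=hold
    )
    duration = plan.duration

    def plan_state(t):
        q, qd, qdd = plan.at(np.atleast_1d(t))
        seg = np.deg2rad(segment_from_joint(q))
        # segment rates from joint rates: thigh' = hip', shank' = hip'-knee',
        # foot' = shank' + ankle'
        omg = np.deg2rad(np.stack(
            [qd[:, 0], qd[:, 0] - qd[:, 1], qd[:, 0] - qd[:, 1] + qd[:, 2]], axis=-1
        ))
        alp = np.deg2rad(np.stack(
            [qdd[:, 0], qdd[:, 0] - qdd[:, 1], qdd[:, 0] - qdd[:, 1] + qdd[:, 2]], axis=-1
        ))
        return seg, omg, alp

    # commanded torque on a fine grid, then interpolate inside the integrator
    fine_fs = fs * 32
    n_fine = int(np.floor(duration * fine_fs)) + 1
    t_fine = np.arange(n_fine) / fine_fs
    seg_f, omg_f, alp_f = plan_state(t_fine)
    tau_plan = computed_torque(model, seg_f, omg_f, alp_f)
    gains = np.array([1.0 + profile.distortion(target.target_class, j) for j in JOINTS])
    tau_ff = gains[None, :] * tau_plan
    tau_ff = tau_ff + _smooth_noise(rng, n_fine, fine_fs, rho * TORQUE_NOISE_SD)

    # planned joint angles/velocities (rad) on the fine grid for the PD term
    phi_plan = np.stack([
        seg_f[:, 0] - 1.5 * np.pi,
        seg_f[:, 0] - seg_f[:, 1],
        seg_f[:, 2] - seg_f[:, 1] - 0.5 * np.pi,
    ], axis=-1)
    phidot_plan = np.stack([
        omg_f[:, 0], omg_f[:, 0] - omg_f[:, 1], omg_f[:, 2] - omg_f[:, 1],
    ], axis=-1)

    def _interp(arr, t):
        i = np.clip(t * fine_fs, 0, n_fine - 1)
        i0 = int(i)
        i1 = min(i0 + 1, n_fine - 1)
        w = i - i0
        return (1 - w) * arr[i0] + w * arr[i1]

    def torque_fn(t, th, om):
        phi = np.array([th[0] - 1.5 * np.pi, th[0] - th[1], th[2] - th[1] - 0.5 * np.pi])
        phidot = np.array([om[0], om[0] - om[1], om[2] - om[1]])
        fb = TRACKING_KP * (_interp(phi_plan, t) - phi) + TRACKING_KD * (
            _interp(phidot_plan, t) - phidot
        )
        return _interp(tau_ff, t) + fb

    seg0, omg0, _ = plan_state(0.0)
    t_out, seg, omega, alpha, tau_applied = forward_simulate(
        model, torque_fn, seg0[0], omg0[0], duration, fs
    )
    markers = forward_kinematics(model, np.rad2deg(seg))
    for k in markers:
        markers[k] = markers[k] + rng.normal(0.0, marker_noise_sd, markers[k].shape)
    return SimulatedTrial(
        record=record,
        target=target,
        fs=fs,
        time=t_out,
        commanded_torque=tau_applied,
        seg_rad=seg,
        omega=omega,
        alpha=alpha,
        markers=markers,
        out_duration=out_duration,
        seed=seed,
        pid=pid or profile.pid,
    )


# ---------------------------------------------------------------------------
# proprioception test simulation

def simulate_jps_trial(
    profile: ParticipantProfile,
    joint: str,
    target_deg: float,
    rng: np.random.Generator,
    baseline_sd: float = JPS_BASELINE_SD,
    rho_slope: float = JPS_RHO_SLOPE,
) -> tuple[float, float]:
    """One joint-position-sense trial: (target, reproduced) angles in degrees."""
    sd = baseline_sd + rho_slope * profile.rho
    return float(target_deg), float(target_deg + rng.normal(0.0, sd))


def simulate_mds_trial(
    profile: ParticipantProfile,
    speed_deg_s: float,
    direction: str,
    catch: bool,
    rng: np.random.Generator,
    joint: str = "hip",
    leg: str = "right",
    score_floor: float = 0.02,
) -> MdsTrial:
    """One movement-detection-sense trial.

    The detection threshold (pre-detection excursion) and the probability of
    a wrong direction judgment both increase with rho: the expected per-trial
    score tracks rho, saturating at the formula maximum of 2.  Catch trials
    produce no movement.  ``score_floor`` is the ideal-observer floor; with
    ``rho = 0`` and ``score_floor = 0`` the trial is perfect (zero excursion,
    correct response).
    """
    if catch:
        return MdsTrial(
            excursion_deg=0.0, correct_direction=True, catch=True,
            speed_deg_s=speed_deg_s, joint=joint, leg=leg, moved=False,
        )
    s = float(np.clip(max(profile.rho, score_floor), 0.0, None))
    raw = MDS_MAX_EXCURSION * s * rng.uniform(0.7, 1.3)
    excursion = float(np.clip(raw, 0.0, MDS_MAX_EXCURSION))
    p_wrong = float(np.clip(s - 1.0, score_floor, 1.0)) if s > 0 else 0.0
    correct = bool(rng.uniform() >= p_wrong)
    return MdsTrial(
        excursion_deg=excursion, correct_direction=correct, catch=False,
        speed_deg_s=speed_deg_s, joint=joint, leg=leg, moved=True,
    )


MDS_SPEEDS = (0.5, 1.0, 2.0)


def simulate_mds_session(
    profile: ParticipantProfile, joint: str, leg: str, rng: np.random.Generator
) -> list[MdsTrial]:
    """Eleven MDS trials per joint per leg: 5 flexion, 5 extension, 1 catch."""
    trials = []
    for direction in ("flexion", "extension"):
        for k in range(5):
            speed = MDS_SPEEDS[k % len(MDS_SPEEDS)]
            trials.append(simulate_mds_trial(profile, speed, direction, False, rng,
                                             joint=joint, leg=leg))
    trials.append(simulate_mds_trial(profile, 1.0, "flexion", True, rng,
                                     joint=joint, leg=leg))
    return trials


def simulate_jps_session(
    profile: ParticipantProfile, joint: str, leg: str, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Six JPS trials per joint per leg, targets of 25 deg flexion or extension."""
    out = []
    for k in range(6):
        target = 25.0 if k % 2 == 0 else -25.0
        out.append(simulate_jps_trial(profile, joint, target, rng))
    return out


def proprioception_table(profiles: list[ParticipantProfile], seed: int) -> pd.DataFrame:
    """Long table of simulated JPS and MDS trials for a cohort (pointing leg)."""
    rng = np.random.default_rng(seed)
    rows = []
    for prof in profiles:
        for joint in ("hip", "knee"):
            for target, reproduced in simulate_jps_session(prof, joint, "pointing", rng):
                rows.append(dict(
                    participant=prof.pid, test="jps", joint=joint, leg="pointing",
                    target_deg=target, reproduced_deg=reproduced,
                    excursion_deg=np.nan, correct_direction=True, catch=False, moved=False,
                ))
            for t in simulate_mds_session(prof, joint, "pointing", rng):
                rows.append(dict(
                    participant=prof.pid, test="mds", joint=joint, leg="pointing",
                    target_deg=np.nan, reproduced_deg=np.nan,
                    excursion_deg=t.excursion_deg, correct_direction=t.correct_direction,
                    catch=t.catch, moved=t.moved,
                ))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort generation

@dataclass
class CohortConfig:
    """Study conditions of the simulated cohort.

    Defaults follow the protocol: 12 controls and 16 SCI participants, two
    blocks (full then obstructed vision) with six trials of each of the seven
    targets per block, markers at 65 Hz with 2 mm capture noise, targets at
    60% of each joint's active ROM.
    """

    n_control: int = 12
    n_sci: int = 16
    trials_per_combo_per_block: int = 6
    fs: float = 65.0
    fraction: float = 0.6
    marker_noise_sd: float = 0.002
    distortion_links: dict = field(default_factory=lambda: dict(DEFAULT_DISTORTION_LINKS))
    sci_rho: tuple = DEFAULT_SCI_MDS


@dataclass
class Cohort:
    config: CohortConfig
    profiles: list
    targets: dict                      # (pid, combo) -> TargetSpec
    trials: list                       # SimulatedTrial
    proprioception: pd.DataFrame


def make_cohort_profiles(config: CohortConfig, rng: np.random.Generator) -> list[ParticipantProfile]:
    profiles = []
    for i in range(config.n_control):
        profiles.append(make_profile(f"C{i + 1:02d}", "control", rng,
                                     distortion_links=config.distortion_links))
    for i in range(config.n_sci):
        rho = config.sci_rho[i] if i < len(config.sci_rho) else None
        profiles.append(make_profile(f"S{i + 1:02d}", "SCI", rng, rho=rho,
                                     distortion_links=config.distortion_links))
    return profiles


def simulate_cohort(config: CohortConfig, seed: int) -> Cohort:
    """Simulate a full cohort: pointing trials plus proprioception sessions.

    Deterministic given (config, seed).  Forward simulation is the dominant
    cost; reduce ``trials_per_combo_per_block`` for quick runs.
    """
    master = np.random.default_rng(seed)
    profiles = make_cohort_profiles(config, master)
    home = np.zeros(3)
    targets = {}
    trials = []
    for p_idx, prof in enumerate(profiles):
        schedule = make_trial_schedule(seed=int(master.integers(2**31)))
        if config.trials_per_combo_per_block < 6:
            keep = {}
            kept = []
            for rec in schedule:
                key = (rec.block, rec.combo)
                keep[key] = keep.get(key, 0) + 1
                if keep[key] <= config.trials_per_combo_per_block:
                    kept.append(rec)
            schedule = kept
        for rec in schedule:
            key = (prof.pid, rec.combo)
            if key not in targets:
                targets[key] = make_target(prof.model, home, prof.rom_deg, rec.combo,
                                           fraction=config.fraction)
            trial_seed = int(master.integers(2**31))
            trials.append(simulate_trial(
                prof, targets[key], trial_seed, record=rec, fs=config.fs,
                marker_noise_sd=config.marker_noise_sd,
            ))
    proprio = proprioception_table(profiles, seed=int(master.integers(2**31)))
    return Cohort(config=config, profiles=profiles, targets=targets,
                  trials=trials, proprioception=proprio)
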