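"""Joint-torque decomposition for the planar three-link limb with a fixed hip.

For each joint the applied (generalized muscle) torque is obtained by a
Newton--Euler recursion over the chain distal to that joint.  Every term of
the equations of motion is then partitioned by its kinematic source:

* gravitational torque: the moment of gravity on the distal chain about the
  joint (all terms proportional to g);
* interaction torque: terms proportional to the squared angular velocity
  (centripetal) or angular acceleration of segments *other than* the joint's
  own distal segment, parsed by source segment and kind;
* net torque: the remaining inertial terms, i.e. those driven by the motion
  of the joint's own distal segment;
* muscle torque: the residual, net minus gravitational minus interaction.
  It equals the physically applied joint torque and includes both active
  contraction and passive tissue contributions.

Torque components due to hip linear acceleration are identically zero because
the hip anchor is fixed.  All outputs are flexor/dorsiflexor-positive: hip
flexion and ankle dorsiflexion are +CCW moments on the distal segment, knee
flexion is a -CCW relative shank moment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinematics import ReversalPhase, TrialKinematics
from .limb_model import JOINTS, SEGMENTS, LimbModel

#: CCW-to-flexor-positive sign map for (hip, knee, ankle).
FLEXOR_SIGN = np.array([1.0, -1.0, 1.0])

INTERACTION_KINDS = ("alpha", "omega2")


def _params(model: LimbModel):
    a = model.anthropometrics
    m = np.array([p.mass for p in a.segments])
    l = np.array([p.length for p in a.segments])
    r = np.array([p.com for p in a.segments])
    inertia = np.array([p.inertia for p in a.segments])
    return m, l, r, inertia, a.gravity


def _coefficients(model: LimbModel, seg_rad: np.ndarray):
    """Per-sample coefficient arrays of the joint-torque equations.

    For joint j (CCW on the distal chain):
        tau_j = sum_s A[j,s] alpha_s + sum_s B[j,s] omega_s^2 + G[j]
    Returns A, B of shape (n, 3, 3) and G of shape (n, 3).
    """
    m, l, r, inertia, g = _params(model)
    n = seg_rad.shape[0]
    mu = np.array([m[0] * r[0] + (m[1] + m[2]) * l[0],
                   m[1] * r[1] + m[2] * l[1],
                   m[2] * r[2]])
    a_pair = np.zeros((3, 3))
    a_pair[0, 1] = a_pair[1, 0] = l[0] * mu[1]
    a_pair[0, 2] = a_pair[2, 0] = l[0] * mu[2]
    a_pair[1, 2] = a_pair[2, 1] = l[1] * mu[2]
    diag = np.array([inertia[0] + m[0] * r[0] ** 2 + (m[1] + m[2]) * l[0] ** 2,
                     inertia[1] + m[1] * r[1] ** 2 + m[2] * l[1] ** 2,
                     inertia[2] + m[2] * r[2] ** 2])
    dth = seg_rad[:, :, None] - seg_rad[:, None, :]          # (n, i, s)
    M = a_pair[None, :, :] * np.cos(dth)
    M[:, range(3), range(3)] = diag
    C = a_pair[None, :, :] * np.sin(dth)                      # row i, source s
    Grow = g * mu[None, :] * np.cos(seg_rad)                  # (n, i)
    # joint j collects rows i >= j (reverse cumulative sum over the row axis)
    A = np.flip(np.cumsum(np.flip(M, axis=1), axis=1), axis=1)
    B = np.flip(np.cumsum(np.flip(C, axis=1), axis=1), axis=1)
    G = np.flip(np.cumsum(np.flip(Grow, axis=1), axis=1), axis=1)
    return A, B, G


def newton_euler_joint_torques(model: LimbModel, seg_rad, omega, alpha) -> np.ndarray:
    """Applied joint torques (N m, CCW on the distal segment), shape (n, 3).

    Backward Newton--Euler recursion: segment COM accelerations are propagated
    from the fixed hip, then joint forces and moments are accumulated from the
    foot back to the hip.
    """
    m, l, r, inertia, g = _params(model)
    seg_rad = np.asarray(seg_rad, float)
    omega = np.asarray(omega, float)
    alpha = np.asarray(alpha, float)
    n = seg_rad.shape[0]
    u = np.stack([np.cos(seg_rad), np.sin(seg_rad)], axis=-1)       # (n, 3, 2)
    perp = np.stack([-np.sin(seg_rad), np.cos(seg_rad)], axis=-1)   # z x u
    # joint and COM positions relative to the fixed hip
    p = np.zeros((n, 4, 2))
    a_joint = np.zeros((n, 4, 2))  # hip anchor fixed: zero linear acceleration
    for i in range(3):
        p[:, i + 1] = p[:, i] + l[i] * u[:, i]
        a_joint[:, i + 1] = a_joint[:, i] + l[i] * (
            alpha[:, i, None] * perp[:, i] - omega[:, i, None] ** 2 * u[:, i]
        )
    c = p[:, :3] + r[None, :, None] * u
    a_com = a_joint[:, :3] + r[None, :, None] * (
        alpha[:, :, None] * perp - omega[:, :, None] ** 2 * u
    )
    grav = np.array([0.0, -g])
    cross = lambda a, b: a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]
    tau = np.zeros((n, 3))
    F_dist = np.zeros((n, 2))
    tau_dist = np.zeros(n)
    for i in (2, 1, 0):
        # moment balance about the segment COM; F_dist is the force the distal
        # neighbour exerts on segment i at joint i+1 (reaction convention)
        inertial = m[i] * (a_com[:, i] - grav)                 # (n, 2)
        tau[:, i] = (
            inertia[i] * alpha[:, i]
            + tau_dist
            - cross(p[:, i] - c[:, i], inertial)
            + cross(p[:, i + 1] - p[:, i], F_dist)
        )
        F_dist = F_dist + inertial
        tau_dist = tau[:, i]
    return tau


@dataclass
class TorqueDecomposition:
    """Per-joint torque components (N m, flexor/dorsiflexor-positive), each (n, 3).

    ``interaction_parsed`` has shape (n, 3 joints, 3 source segments, 2 kinds),
    kinds ordered (angular acceleration, squared angular velocity); entries for
    a joint's own distal segment are structurally zero.  ``hip_linear`` is the
    hip-linear-acceleration component, identically zero for the fixed anchor.
    """

    net: np.ndarray
    gravitational: np.ndarray
    interaction: np.ndarray
    muscle: np.ndarray
    interaction_parsed: np.ndarray
    hip_linear: np.ndarray

    def to_frame(self, time: np.ndarray) -> pd.DataFrame:
        """Long-format table (time, joint, component, source, value)."""
        rows = []
        comps = {
            "net": self.net,
            "gravitational": self.gravitational,
            "interaction": self.interaction,
            "muscle": self.muscle,
        }
        for j, joint in enumerate(JOINTS):
            for name, arr in comps.items():
                rows.append(pd.DataFrame({
                    "time": time, "joint": joint, "component": name,
                    "source": "", "value": arr[:, j],
                }))
            for s, seg in enumerate(SEGMENTS):
                for k, kind in enumerate(INTERACTION_KINDS):
                    rows.append(pd.DataFrame({
                        "time": time, "joint": joint,
                        "component": f"interaction_{kind}",
                        "source": seg,
                        "value": self.interaction_parsed[:, j, s, k],
                    }))
        return pd.concat(rows, ignore_index=True)


def decompose_torques(
    model: LimbModel,
    kin: TrialKinematics | None = None,
    *,
    seg_rad: np.ndarray | None = None,
    omega: np.ndarray | None = None,
    alpha: np.ndarray | None = None,
    literal_muscle_sign: bool = False,
) -> TorqueDecomposition:
    """Decompose joint torques for a trial (or raw angle/velocity/accel arrays).

    ``literal_muscle_sign`` flips the muscle torque to (gravity + interaction)
    minus net, the literal reading of "subtracting the net torque from the sum
    of the gravitational and interaction torques"; the default keeps muscle =
    net - (gravity + interaction), which makes flexor muscle torques positive
    during flexion against gravity.
    """
    if kin is not None:
        seg_rad = np.deg2rad(kin.seg_deg)
        omega, alpha = kin.omega, kin.alpha
    seg_rad = np.asarray(seg_rad, float)
    omega = np.asarray(omega, float)
    alpha = np.asarray(alpha, float)
    if not (seg_rad.shape == omega.shape == alpha.shape) or seg_rad.ndim != 2:
        raise ValueError("segment angle, velocity and acceleration series must share shape (n, 3)")
    if not (np.isfinite(seg_rad).all() and np.isfinite(omega).all() and np.isfinite(alpha).all()):
        raise ValueError("non-finite kinematics passed to decompose_torques")

    tau_ccw = newton_euler_joint_torques(model, seg_rad, omega, alpha)
    A, B, G = _coefficients(model, seg_rad)

    # gravity torque about each joint, computed geometrically (moment of the
    # distal chain's weight about the joint centre)
    m, l, r, inertia, g = _params(model)
    u = np.stack([np.cos(seg_rad), np.sin(seg_rad)], axis=-1)
    n = seg_rad.shape[0]
    p = np.zeros((n, 4, 2))
    for i in range(3):
        p[:, i + 1] = p[:, i] + l[i] * u[:, i]
    c = p[:, :3] + r[None, :, None] * u
    grav_ccw = np.zeros((n, 3))
    for j in range(3):
        for s in range(j, 3):
            dx = c[:, s, 0] - p[:, j, 0]
            grav_ccw[:, j] += -m[s] * g * dx  # cross((c - p), (0, -mg)) z-component

    # parsed interaction components (negated coupling terms; own segment zero)
    parsed_ccw = np.zeros((n, 3, 3, 2))
    for j in range(3):
        for s in range(3):
            if s == j:
                continue
            parsed_ccw[:, j, s, 0] = -A[:, j, s] * alpha[:, s]
            parsed_ccw[:, j, s, 1] = -B[:, j, s] * omega[:, s] ** 2
    int_ccw = parsed_ccw.sum(axis=(2, 3))
    net_ccw = tau_ccw + grav_ccw + int_ccw

    sign = FLEXOR_SIGN[None, :]
    mus = sign * tau_ccw
    if literal_muscle_sign:
        mus = -mus
    return TorqueDecomposition(
        net=sign * net_ccw,
        gravitational=sign * grav_ccw,
        interaction=sign * int_ccw,
        muscle=mus,
        interaction_parsed=sign[:, :, None, None] * parsed_ccw,
        hip_linear=np.zeros((n, 3)),
    )


def joint_angular_velocity(omega: np.ndarray) -> np.ndarray:
    """Flexion-positive joint angular velocities (rad/s) from segment velocities."""
    return np.stack(
        [omega[:, 0], omega[:, 0] - omega[:, 1], omega[:, 2] - omega[:, 1]], axis=-1
    )


def muscle_power(decomp: TorqueDecomposition, kin: TrialKinematics | None = None,
                 omega: np.ndarray | None = None) -> np.ndarray:
    """Muscle power (W) per joint: muscle torque times flexion-positive joint velocity.

    Positive values are generative, negative absorptive.
    """
    if kin is not None:
        omega = kin.omega
    return decomp.muscle * joint_angular_velocity(np.asarray(omega, float))


def mean_muscle_torque(decomp: TorqueDecomposition, phase: ReversalPhase) -> np.ndarray:
    """Signed mean muscle torque (N m) per joint over the first half of the
    reversal phase, samples [first_peak, reversal] inclusive."""
    window = decomp.muscle[phase.first_peak : phase.reversal + 1]
    return window.mean(axis=0)


def mechanical_energy(model: LimbModel, seg_rad: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """Total mechanical energy (J) per sample: kinetic plus gravitational potential.

    Potential energy is measured from the hip anchor height.
    """
    m, l, r, inertia, g = _params(model)
    seg_rad = np.asarray(seg_rad, float)
    omega = np.asarray(omega, float)
    n = seg_rad.shape[0]
    u = np.stack([np.cos(seg_rad), np.sin(seg_rad)], axis=-1)
    perp = np.stack([-np.sin(seg_rad), np.cos(seg_rad)], axis=-1)
    p = np.zeros((n, 4, 2))
    v_joint = np.zeros((n, 4, 2))
    for i in range(3):
        p[:, i + 1] = p[:, i] + l[i] * u[:, i]
        v_joint[:, i + 1] = v_joint[:, i] + l[i] * omega[:, i, None] * perp[:, i]
    c = p[:, :3] + r[None, :, None] * u
    v_com = v_joint[:, :3] + r[None, :, None] * omega[:, :, None] * perp
    ke = 0.5 * (m[None, :] * (v_com ** 2).sum(axis=-1) + inertia[None, :] * omega ** 2).sum(axis=1)
    pe = (m[None, :] * g * c[:, :, 1]).sum(axis=1)
    return ke + pe
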