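"""Planar three-segment limb model: anthropometrics, angle conventions, kinematic maps.

The limb is modelled as three rigid segments (thigh, shank, foot) connected by
frictionless hinge joints (hip, knee, ankle) moving in the sagittal plane.  The
coordinate frame is x anterior-positive, y upward-positive, with the participant
facing +x.  Segment angles are measured counter-clockwise from the +x (right
horizontal) axis and are unwrapped, so an upright stance has the thigh and shank
at 270 deg (pointing straight down) and the foot at 360 deg (pointing anteriorly).

Joint angles are flexion/dorsiflexion-positive with 0 = neutral standing:

    hip flexion      = theta_thigh - 270
    knee flexion     = theta_thigh - theta_shank
    ankle dorsiflex. = theta_foot - theta_shank - 90

Angles cross the public API in degrees; trigonometry is done in radians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SEGMENTS = ("thigh", "shank", "foot")
JOINTS = ("hip", "knee", "ankle")

#: Neutral-standing segment angles (deg): thigh/shank straight down, foot anterior.
NEUTRAL_SEGMENT_ANGLES = np.array([270.0, 270.0, 360.0])

# Segment inertial parameters as fractions of body mass / stature (Winter's
# anthropometric tables): mass fraction, segment length fraction of height,
# proximal COM fraction of segment length, radius of gyration about the COM
# as a fraction of segment length.
_WINTER = {
    "thigh": dict(mass=0.100, length=0.245, com=0.433, rog=0.323),
    "shank": dict(mass=0.0465, length=0.246, com=0.433, rog=0.302),
    # foot "length" here is the ankle-to-toe distance used as the lever of the
    # toe marker; Winter's foot length fraction of stature:
    "foot": dict(mass=0.0145, length=0.152, com=0.500, rog=0.475),
}


@dataclass(frozen=True)
class SegmentParams:
    """Inertial parameters of one rigid segment.

    mass
        Segment mass (kg).
    length
        Proximal-to-distal joint (or toe marker) distance (m).
    com
        Proximal-joint-to-centre-of-mass distance (m).
    inertia
        Moment of inertia about the segment COM (kg m^2).
    """

    mass: float
    length: float
    com: float
    inertia: float

    def __post_init__(self) -> None:
        if not (self.mass > 0 and self.length > 0):
            raise ValueError("segment mass and length must be strictly positive")
        if not (0.0 <= self.com <= self.length):
            raise ValueError("COM distance must lie within the segment")
        if self.inertia < 0:
            raise ValueError("moment of inertia must be non-negative")


@dataclass(frozen=True)
class Anthropometrics:
    """Per-segment inertial parameters plus body mass and gravity."""

    thigh: SegmentParams
    shank: SegmentParams
    foot: SegmentParams
    body_mass: float = float("nan")
    gravity: float = 9.81

    @property
    def segments(self) -> tuple[SegmentParams, SegmentParams, SegmentParams]:
        return (self.thigh, self.shank, self.foot)

    @classmethod
    def from_body(cls, body_mass: float, height: float, gravity: float = 9.81) -> "Anthropometrics":
        """Scale segment parameters from body mass (kg) and stature (m)."""
        segs = {}
        for name, w in _WINTER.items():
            m = w["mass"] * body_mass
            l = w["length"] * height
            segs[name] = SegmentParams(
                mass=m, length=l, com=w["com"] * l, inertia=m * (w["rog"] * l) ** 2
            )
        return cls(body_mass=body_mass, gravity=gravity, **segs)

    @classmethod
    def from_dict(cls, d: dict) -> "Anthropometrics":
        segs = {s: SegmentParams(**d[s]) for s in SEGMENTS}
        return cls(
            body_mass=float(d.get("body_mass", float("nan"))),
            gravity=float(d.get("gravity", 9.81)),
            **segs,
        )

    def to_dict(self) -> dict:
        d = {
            s: dict(mass=p.mass, length=p.length, com=p.com, inertia=p.inertia)
            for s, p in zip(SEGMENTS, self.segments)
        }
        d["body_mass"] = self.body_mass
        d["gravity"] = self.gravity
        return d


@dataclass(frozen=True)
class LimbModel:
    """Three-segment planar chain with a fixed hip anchor.

    The hip anchor is held fixed within a trial: torque components due to hip
    linear acceleration are zeroed in the dynamics, so measured hip-marker
    drift is retained only for display.
    """

    anthropometrics: Anthropometrics
    hip_anchor: tuple[float, float] = (0.0, 0.0)
    side: str = "right"

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.array([p.length for p in self.anthropometrics.segments])


def joint_from_segment(seg_angles_deg: np.ndarray) -> np.ndarray:
    """Map segment angles (deg, CCW from right horizontal) to joint angles.

    Accepts shape (..., 3) ordered (thigh, shank, foot); returns (..., 3)
    ordered (hip, knee, ankle), flexion/dorsiflexion-positive.
    """
    seg = np.asarray(seg_angles_deg, dtype=float)
    thigh, shank, foot = seg[..., 0], seg[..., 1], seg[..., 2]
    return np.stack(
        [thigh - 270.0, thigh - shank, foot - shank - 90.0], axis=-1
    )


def segment_from_joint(joint_angles_deg: np.ndarray) -> np.ndarray:
    """Exact inverse of :func:`joint_from_segment`."""
    jnt = np.asarray(joint_angles_deg, dtype=float)
    hip, knee, ankle = jnt[..., 0], jnt[..., 1], jnt[..., 2]
    thigh = hip + 270.0
    shank = thigh - knee
    foot = shank + 90.0 + ankle
    return np.stack([thigh, shank, foot], axis=-1)


def forward_kinematics(model: LimbModel, seg_angles_deg: np.ndarray) -> dict[str, np.ndarray]:
    """Marker positions (m) of hip, knee, ankle and toe for given segment angles.

    ``seg_angles_deg`` has shape (..., 3); each returned marker has shape (..., 2).
    """
    seg = np.deg2rad(np.asarray(seg_angles_deg, dtype=float))
    l1, l2, l3 = model.segment_lengths
    hip = np.broadcast_to(
        np.asarray(model.hip_anchor, dtype=float), seg.shape[:-1] + (2,)
    ).copy()
    u = np.stack([np.cos(seg), np.sin(seg)], axis=-1)  # (..., 3, 2)
    knee = hip + l1 * u[..., 0, :]
    ankle = knee + l2 * u[..., 1, :]
    toe = ankle + l3 * u[..., 2, :]
    return {"hip": hip, "knee": knee, "ankle": ankle, "toe": toe}
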