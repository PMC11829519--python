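"""Pointing-task protocol: targets, toe-trajectory templates, and trial schedules.

Targets are defined per participant by rotating a chosen subset of joints
(hip, knee, ankle) from the home posture to 60% of that joint's active range
of motion.  The seven protocol targets are collapsed into three classes for
analysis (HKA, KA, HA); the ankle-only target has no listed class and is
labelled ``uncollapsed`` and excluded from three-class analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .limb_model import LimbModel, forward_kinematics, segment_from_joint

JOINT_INDEX = {"hip": 0, "knee": 1, "ankle": 2}

#: The seven protocol joint combinations (frozenset of flexed joints).
PROTOCOL_COMBOS: tuple[frozenset, ...] = (
    frozenset({"hip"}),
    frozenset({"knee"}),
    frozenset({"ankle"}),
    frozenset({"hip", "ankle"}),
    frozenset({"knee", "ankle"}),
    frozenset({"hip", "knee"}),
    frozenset({"hip", "knee", "ankle"}),
)

TRIALS_PER_COMBO_PER_BLOCK = 6
BLOCK_VISION = ("full", "obstructed")  # block 1 full vision, block 2 obstructed

_COLLAPSE = {
    frozenset({"hip"}): "HA",
    frozenset({"hip", "ankle"}): "HA",
    frozenset({"knee"}): "KA",
    frozenset({"knee", "ankle"}): "KA",
    frozenset({"hip", "knee"}): "HKA",
    frozenset({"hip", "knee", "ankle"}): "HKA",
}


def combo_label(combo: frozenset) -> str:
    return "-".join(j for j in ("hip", "knee", "ankle") if j in combo)


def combo_from_label(label: str) -> frozenset:
    return frozenset(label.split("-"))


def collapse_target_class(combo: frozenset) -> str:
    """Collapse a joint combination into its analysis class.

    Hip-only pools with hip-ankle (HA), knee-only with knee-ankle (KA), and
    hip-knee with hip-knee-ankle (HKA).  Combinations outside the collapse
    rule (the ankle-only target) return ``"uncollapsed"``.
    """
    return _COLLAPSE.get(frozenset(combo), "uncollapsed")


@dataclass(frozen=True)
class TargetSpec:
    """A pointing target: final posture, toe point, and trajectory template."""

    combo: frozenset
    target_class: str
    home_joint_deg: np.ndarray        # (3,) joint angles of the home posture
    final_joint_deg: np.ndarray       # (3,) joint angles at the target
    target_point: np.ndarray          # (2,) toe position at the target (m)
    template: np.ndarray              # (n, 2) toe path home -> target (m)
    fraction: float = 0.6

    def to_dict(self) -> dict:
        return {
            "combo": combo_label(self.combo),
            "target_class": self.target_class,
            "home_joint_deg": list(map(float, self.home_joint_deg)),
            "final_joint_deg": list(map(float, self.final_joint_deg)),
            "target_point": list(map(float, self.target_point)),
            "template": self.template.tolist(),
            "fraction": self.fraction,
        }


def make_target(
    model: LimbModel,
    home_joint_deg: np.ndarray,
    rom_deg: dict[str, float],
    combo: frozenset,
    fraction: float = 0.6,
    n_template: int = 101,
) -> TargetSpec:
    """Build a target by flexing the combo's joints to ``fraction`` of their ROM.

    The trajectory template is the toe path obtained by interpolating all
    flexed joints synchronously (linearly in joint space) from home to the
    final posture, evaluated through the forward kinematics.
    """
    combo = frozenset(combo)
    if not combo:
        raise ValueError("target combo must contain at least one joint")
    if not (0.0 < fraction <= 1.0) and fraction != 0.0:
        raise ValueError("fraction must lie in (0, 1] (or 0 for the degenerate home target)")
    home = np.asarray(home_joint_deg, dtype=float)
    final = home.copy()
    for j in combo:
        if j not in rom_deg:
            raise KeyError(f"missing active ROM for flexed joint {j!r}")
        if rom_deg[j] <= 0:
            raise ValueError(f"active ROM for {j!r} must be positive")
        final[JOINT_INDEX[j]] = home[JOINT_INDEX[j]] + fraction * rom_deg[j]
    alphas = np.linspace(0.0, 1.0, n_template)[:, None]
    joint_path = home[None, :] * (1 - alphas) + final[None, :] * alphas
    toe_path = forward_kinematics(model, segment_from_joint(joint_path))["toe"]
    return TargetSpec(
        combo=combo,
        target_class=collapse_target_class(combo),
        home_joint_deg=home,
        final_joint_deg=final,
        target_point=toe_path[-1].copy(),
        template=toe_path,
        fraction=fraction,
    )


@dataclass(frozen=True)
class ScheduleRecord:
    block: int                # 1-based block index
    vision: str               # "full" or "obstructed"
    combo: frozenset
    target_class: str
    trial_index: int          # 0-based position within the session


def make_trial_schedule(seed: int, combos: tuple[frozenset, ...] = PROTOCOL_COMBOS) -> list[ScheduleRecord]:
    """Randomized session schedule: two blocks of 42 trials (6 per combo).

    Block 1 runs under full vision and block 2 under obstructed vision; within
    each block the seven combos appear exactly six times in seeded-random order.
    """
    rng = np.random.default_rng(seed)
    records: list[ScheduleRecord] = []
    idx = 0
    for block, vision in enumerate(BLOCK_VISION, start=1):
        pool = [c for c in combos for _ in range(TRIALS_PER_COMBO_PER_BLOCK)]
        order = rng.permutation(len(pool))
        for k in order:
            combo = pool[k]
            records.append(
                ScheduleRecord(
                    block=block,
                    vision=vision,
                    combo=combo,
                    target_class=collapse_target_class(combo),
                    trial_index=idx,
                )
            )
            idx += 1
    return records
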