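"""Joint position sense (JPS) and movement detection sense (MDS) scoring.

JPS is the mean absolute difference (deg) between the memorized target angle
and the reproduced angle across trials; higher is poorer.  MDS scores each
non-catch trial as the pre-detection joint excursion divided by 10 deg (the
maximum possible excursion) plus the direction response (0 correct,
1 incorrect), averaged across trials; the score runs from 0 (best) to 2
(worst).  Catch trials are excluded from the score and reported separately
as a validity flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Maximum possible joint excursion in an MDS trial (deg).
MDS_MAX_EXCURSION = 10.0


@dataclass(frozen=True)
class JpsTrial:
    target_deg: float
    reproduced_deg: float
    joint: str = "hip"
    leg: str = "right"

    def __post_init__(self):
        if not (np.isfinite(self.target_deg) and np.isfinite(self.reproduced_deg)):
            raise ValueError("JPS trial angles must be finite")


@dataclass(frozen=True)
class MdsTrial:
    excursion_deg: float          # pre-detection excursion; undefined for catch trials
    correct_direction: bool
    catch: bool = False
    speed_deg_s: float = 1.0
    joint: str = "hip"
    leg: str = "right"
    moved: bool = True            # whether the joint moved (catch outcome flag)


def jps_score(trials: list[JpsTrial]) -> float:
    """Mean absolute target-reproduction error in degrees (higher = poorer)."""
    if not trials:
        raise ValueError("jps_score requires at least one trial")
    return float(np.mean([abs(t.target_deg - t.reproduced_deg) for t in trials]))


def mds_score(trials: list[MdsTrial]) -> float:
    """Mean per-trial MDS score over non-catch trials, bounded to [0, 2]."""
    scored = [t for t in trials if not t.catch]
    if not scored:
        raise ValueError("mds_score requires at least one non-catch trial")
    vals = []
    for t in scored:
        if not (0.0 <= t.excursion_deg <= MDS_MAX_EXCURSION):
            raise ValueError(
                f"excursion {t.excursion_deg} deg outside [0, {MDS_MAX_EXCURSION}]"
            )
        vals.append(t.excursion_deg / MDS_MAX_EXCURSION + (0.0 if t.correct_direction else 1.0))
    return float(np.mean(vals))


def catch_trial_valid(trials: list[MdsTrial]) -> bool:
    """True when no catch trial registered movement (a session validity flag)."""
    return all(not t.moved for t in trials if t.catch)


def score_sessions(frame: pd.DataFrame) -> pd.DataFrame:
    """Score a long table of proprioception trials per participant.

    Expects columns: participant, test (``jps``/``mds``), joint, leg, and the
    per-test fields (target_deg/reproduced_deg or excursion_deg/
    correct_direction/catch).  Returns per-participant per-joint/leg scores
    plus a pooled score per test (mean across hip and knee of the test leg,
    the convention used for single per-leg summary values).
    """
    out = []
    for (pid, test, joint, leg), g in frame.groupby(["participant", "test", "joint", "leg"]):
        if test == "jps":
            score = jps_score([
                JpsTrial(r.target_deg, r.reproduced_deg, joint, leg)
                for r in g.itertuples()
            ])
        elif test == "mds":
            trials = [
                MdsTrial(
                    excursion_deg=0.0 if bool(r.catch) else float(r.excursion_deg),
                    correct_direction=bool(r.correct_direction),
                    catch=bool(r.catch),
                    moved=bool(getattr(r, "moved", not bool(r.catch))),
                    joint=joint,
                    leg=leg,
                )
                for r in g.itertuples()
            ]
            score = mds_score(trials)
        else:
            raise ValueError(f"unknown proprioception test {test!r}")
        out.append(dict(participant=pid, test=test, joint=joint, leg=leg, score=score))
    per_joint = pd.DataFrame(out)
    pooled = (
        per_joint.groupby(["participant", "test", "leg"], as_index=False)["score"]
        .mean()
        .assign(joint="pooled")
    )
    return pd.concat([per_joint, pooled], ignore_index=True)
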