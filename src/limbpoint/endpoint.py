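"""End-point performance metrics: end-point errors and foot-path area.

End-point errors are the signed horizontal (anterior-positive) and vertical
(upward-positive) distances, in cm, between the toe at the reversal point and
the target.  Foot-path area is the area enclosed between the outbound and
return toe paths over the reversal phase: the trapezoid path integrals of
y dx over the two halves traverse opposite x-directions, so their sum is the
enclosed area.
"""

from __future__ import annotations

import math

import numpy as np

from .kinematics import ReversalPhase

#: Floor applied before the log transform of foot-path area (m^2).
AREA_FLOOR = 1e-6


def endpoint_errors(toe_at_reversal: np.ndarray, target_point: np.ndarray) -> tuple[float, float]:
    """Signed (horizontal, vertical) end-point errors in cm.

    Positive horizontal error means the toe was anterior to the target;
    negative vertical error means undershooting the target in height.
    """
    d = (np.asarray(toe_at_reversal, float) - np.asarray(target_point, float)) * 100.0
    return float(d[0]), float(d[1])


def foot_path_area(toe_xy: np.ndarray, phase: ReversalPhase) -> float:
    """Foot-path area (m^2) enclosed by the toe over the reversal phase.

    Integrates y dx by the trapezoid rule over the outbound half (first peak
    to reversal) and the return half (reversal to second peak); the unsigned
    sum of the two signed integrals is the enclosed area (the difference
    between the two half-areas).  Exactly zero for a retraced path.
    """
    xy = np.asarray(toe_xy, float)
    if not np.isfinite(xy).all():
        raise ValueError("non-finite toe trajectory")
    seg = xy[phase.first_peak : phase.second_peak + 1]
    # summing every trapezoid term with fsum makes an exactly retraced return
    # path cancel the outbound terms to an exact zero
    terms = 0.5 * (seg[1:, 1] + seg[:-1, 1]) * (seg[1:, 0] - seg[:-1, 0])
    return abs(math.fsum(terms))


def log_area(area_m2: float, floor: float = AREA_FLOOR) -> float:
    """Natural log of the foot-path area with a small floor for degenerate paths."""
    if area_m2 < 0:
        raise ValueError("area must be non-negative")
    return float(np.log(max(area_m2, floor)))
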