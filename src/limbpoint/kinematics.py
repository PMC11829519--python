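"""Trial kinematics: filtering, segment angles, derivatives, reversal detection.

The analysis chain mirrors standard motion-capture practice: marker
trajectories are low-pass filtered with a zero-phase (dual-pass) Butterworth
filter at 6 Hz, segment angles are computed from marker vectors and unwrapped,
and derivatives are taken by central differences.  The out-and-back movement
is segmented from the toe-speed profile: the *reversal phase* spans the two
dominant speed peaks and the *reversal point* is the speed minimum between
them, where the toe turns around.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .limb_model import NEUTRAL_SEGMENT_ANGLES


class ReversalDetectionError(ValueError):
    """Raised when the toe-speed profile does not contain an out-and-back movement."""


def lowpass_filter(series: np.ndarray, fs: float, cutoff: float = 6.0, order: int = 2) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter (applied forward and backward).

    ``order`` is the single-pass order; the default 2nd-order dual pass gives
    4th-order effective attenuation, the dominant biomechanics convention.
    Operates along axis 0; raises ValueError when the series is shorter than
    the filter warm-up.
    """
    x = np.asarray(series, dtype=float)
    if fs <= 2 * cutoff:
        raise ValueError(f"sampling rate {fs} Hz must exceed twice the cutoff {cutoff} Hz")
    sos = signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
    # padlen as used by sosfiltfilt's default padding
    padlen = 3 * (2 * sos.shape[0] + 1 - min((sos[:, 2] == 0).sum(), (sos[:, 5] == 0).sum()))
    if x.shape[0] <= padlen:
        raise ValueError(
            f"series of length {x.shape[0]} is shorter than the filter warm-up ({padlen + 1} samples)"
        )
    return signal.sosfiltfilt(sos, x, axis=0)


def differentiate(series: np.ndarray, fs: float) -> np.ndarray:
    """Time derivative along axis 0: central differences interior, one-sided ends."""
    return np.gradient(np.asarray(series, dtype=float), 1.0 / fs, axis=0)


def compute_segment_angles(markers: dict[str, np.ndarray]) -> np.ndarray:
    """Unwrapped segment angles (deg, CCW from the right horizontal), shape (n, 3).

    Each segment angle is the atan2 of the distal-minus-proximal marker vector,
    unwrapped over time and shifted by whole turns so the series starts in the
    neutral-stance branch (thigh/shank near 270 deg, foot near 360 deg).
    """
    pairs = [("hip", "knee"), ("knee", "ankle"), ("ankle", "toe")]
    cols = []
    for k, (prox, dist) in enumerate(pairs):
        v = np.asarray(markers[dist], dtype=float) - np.asarray(markers[prox], dtype=float)
        ang = np.unwrap(np.arctan2(v[:, 1], v[:, 0]))
        deg = np.rad2deg(ang)
        # choose the 360-degree branch closest to the neutral stance
        shift = 360.0 * np.round((NEUTRAL_SEGMENT_ANGLES[k] - deg[0]) / 360.0)
        cols.append(deg + shift)
    return np.stack(cols, axis=-1)


@dataclass(frozen=True)
class ReversalPhase:
    """Indices of the first speed peak, the reversal point, and the second peak."""

    first_peak: int
    reversal: int
    second_peak: int

    def __post_init__(self) -> None:
        if not (self.first_peak < self.reversal < self.second_peak):
            raise ValueError("reversal indices must satisfy first_peak < reversal < second_peak")


def detect_reversal_phase(toe_speed: np.ndarray, prominence_frac: float = 0.10) -> ReversalPhase:
    """Locate the reversal phase from the toe-speed profile.

    Finds local speed maxima with prominence at least ``prominence_frac`` of
    the global maximum, takes the two largest (ties to the earlier index), and
    places the reversal point at the speed minimum strictly between them.
    """
    v = np.asarray(toe_speed, dtype=float)
    if v.ndim != 1 or v.size < 3:
        raise ReversalDetectionError("toe-speed series too short for reversal detection")
    vmax = float(np.max(v))
    if not np.isfinite(vmax) or vmax <= 0:
        raise ReversalDetectionError("toe-speed series has no motion")
    peaks, _ = signal.find_peaks(v, prominence=prominence_frac * vmax)
    if len(peaks) < 2:
        raise ReversalDetectionError("no reversal detected: fewer than two prominent speed peaks")
    # two largest local maxima; ties broken to the earliest index
    order = np.lexsort((peaks, -v[peaks]))
    top2 = np.sort(peaks[order[:2]])
    i1, i2 = int(top2[0]), int(top2[1])
    interior = v[i1 + 1 : i2]
    i_rev = i1 + 1 + int(np.argmin(interior))
    return ReversalPhase(first_peak=i1, reversal=i_rev, second_peak=i2)


def movement_time(phase: ReversalPhase, fs: float) -> float:
    """Duration (s) of the first half of the reversal phase (peak to reversal)."""
    return (phase.reversal - phase.first_peak) / fs


@dataclass
class TrialKinematics:
    """Filtered kinematic series for one trial (all arrays share the time base).

    Attributes
    ----------
    fs : sampling rate (Hz)
    time : (n,) seconds
    markers : filtered marker positions, each (n, 2) m
    seg_deg : (n, 3) segment angles (deg)
    omega : (n, 3) segment angular velocities (rad/s)
    alpha : (n, 3) segment angular accelerations (rad/s^2)
    toe_velocity : (n, 2) m/s
    toe_speed : (n,) m/s
    """

    fs: float
    time: np.ndarray
    markers: dict[str, np.ndarray]
    seg_deg: np.ndarray
    omega: np.ndarray
    alpha: np.ndarray
    toe_velocity: np.ndarray
    toe_speed: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.time.shape[0]


def fill_marker_gaps(markers: dict[str, np.ndarray], max_gap: int = 3) -> dict[str, np.ndarray]:
    """Linearly fill runs of up to ``max_gap`` consecutive NaN samples per marker."""
    out = {}
    for name, arr in markers.items():
        x = np.array(arr, dtype=float)
        for col in range(x.shape[1]):
            y = x[:, col]
            isnan = np.isnan(y)
            if not isnan.any():
                continue
            # identify NaN runs
            idx = np.flatnonzero(isnan)
            splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
            for run in splits:
                if len(run) > max_gap or run[0] == 0 or run[-1] == y.size - 1:
                    raise ValueError(
                        f"marker {name!r} has an unfillable gap of {len(run)} samples"
                    )
            good = ~isnan
            y[isnan] = np.interp(np.flatnonzero(isnan), np.flatnonzero(good), y[good])
        out[name] = x
    return out


def analyze_markers(
    markers: dict[str, np.ndarray],
    fs: float,
    cutoff: float = 6.0,
    filter_data: bool = True,
) -> TrialKinematics:
    """Full kinematic chain: gap fill, filter, angles, derivatives, toe velocity.

    ``filter_data=False`` bypasses the low-pass filter (used for noiseless
    simulation checks); the derivative chain is unchanged.
    """
    markers = fill_marker_gaps(markers)
    if filter_data:
        markers = {k: lowpass_filter(v, fs, cutoff) for k, v in markers.items()}
    else:
        markers = {k: np.asarray(v, dtype=float) for k, v in markers.items()}
    n = markers["toe"].shape[0]
    seg_deg = compute_segment_angles(markers)
    seg_rad = np.deg2rad(seg_deg)
    omega = differentiate(seg_rad, fs)
    alpha = differentiate(omega, fs)
    toe_velocity = differentiate(markers["toe"], fs)
    toe_speed = np.linalg.norm(toe_velocity, axis=1)
    return TrialKinematics(
        fs=fs,
        time=np.arange(n) / fs,
        markers=markers,
        seg_deg=seg_deg,
        omega=omega,
        alpha=alpha,
        toe_velocity=toe_velocity,
        toe_speed=toe_speed,
    )


def crop_to_movement(kin: TrialKinematics, speed_frac: float = 0.02, pad: int = 5) -> TrialKinematics:
    """Restrict a trial to the moving portion (speed above ``speed_frac`` of max).

    Keeps the contiguous span from the first to the last sample exceeding the
    threshold, padded by ``pad`` samples on each side.
    """
    v = kin.toe_speed
    above = np.flatnonzero(v > speed_frac * np.max(v))
    if above.size == 0:
        return kin
    lo = max(0, int(above[0]) - pad)
    hi = min(kin.n_samples, int(above[-1]) + pad + 1)
    sl = slice(lo, hi)
    return TrialKinematics(
        fs=kin.fs,
        time=kin.time[sl],
        markers={k: v_[sl] for k, v_ in kin.markers.items()},
        seg_deg=kin.seg_deg[sl],
        omega=kin.omega[sl],
        alpha=kin.alpha[sl],
        toe_velocity=kin.toe_velocity[sl],
        toe_speed=kin.toe_speed[sl],
    )
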