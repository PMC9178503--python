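"""Reference frames and the experiment gain.

On the circular track the animal's position is measured in the laboratory
frame.  The projected visual cues (polarizing landmarks, or a position-free
stripe pattern) define additional rotating reference frames.  The coupling
between the animal's movement and the cue movement is the experiment gain

    G = (displacement of the animal in the cue frame)
        / (displacement of the animal in the laboratory frame),

so G = 1 means stationary cues.  The gain is scheduled as a function of
laboratory-frame distance run, in four epochs: a unity baseline (Epoch 1), a
linear ramp (Epoch 2), a constant hold at the final gain (Epoch 3), and a
cue-off period where gain bookkeeping continues (Epoch 4).

Angles are in degrees throughout; the unwrapped (cumulative) representation
is canonical and the wrapped angle in [0, 360) is derived from it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GainProfile",
    "AngularTrajectory",
    "FramePosition",
    "gain_at",
    "lab_to_frame",
    "cue_rotation",
    "latency_angular_error",
    "arc_error",
    "wrap_angle",
    "unwrap_angle",
    "lap_count",
]

DEG_PER_LAP = 360.0


@dataclass(frozen=True)
class GainProfile:
    """Gain schedule for one cue set as a function of lab-frame laps.

    Parameters
    ----------
    epoch_laps : tuple of 4 floats
        Duration of Epochs 1-4 in laboratory-frame laps.
    final_gain : float
        Gain reached at the end of the Epoch-2 ramp and held afterwards.
    cue : {"landmark", "stripe"}
        Which cue set this schedule governs.
    landmarks_visible_epochs : tuple of 4 bools
        Per-epoch cue visibility; by convention the cues are extinguished
        in Epoch 4.
    """

    epoch_laps: tuple[float, float, float, float] = (10.0, 10.0, 15.0, 5.0)
    final_gain: float = 1.0
    cue: str = "landmark"
    landmarks_visible_epochs: tuple[bool, bool, bool, bool] = (
        True,
        True,
        True,
        False,
    )

    def __post_init__(self) -> None:
        if len(self.epoch_laps) != 4 or any(e < 0 for e in self.epoch_laps):
            raise ValueError("epoch_laps must be 4 non-negative lap counts")
        if self.final_gain < 0:
            raise ValueError("final_gain must be non-negative")
        if self.cue not in ("landmark", "stripe"):
            raise ValueError("cue must be 'landmark' or 'stripe'")

    @property
    def ramp_rate(self) -> float:
        """Gain change per laboratory lap during the Epoch-2 ramp."""
        e2 = self.epoch_laps[1]
        if e2 == 0:
            return 0.0
        return (self.final_gain - 1.0) / e2

    @property
    def epoch_boundaries_deg(self) -> np.ndarray:
        """Cumulative epoch end positions in unwrapped lab degrees."""
        return np.cumsum(self.epoch_laps) * DEG_PER_LAP

    @property
    def total_laps(self) -> float:
        return float(sum(self.epoch_laps))

    def epoch_of(self, lab_distance_deg):
        """1-based epoch index for a lab-frame distance (degrees)."""
        d = np.asarray(lab_distance_deg, dtype=float)
        idx = np.searchsorted(self.epoch_boundaries_deg, d, side="right") + 1
        return np.minimum(idx, 4) if d.ndim else int(min(idx, 4))

    def landmarks_visible_at(self, lab_distance_deg) -> np.ndarray:
        ep = np.asarray(self.epoch_of(lab_distance_deg))
        vis = np.asarray(self.landmarks_visible_epochs)
        return vis[np.minimum(ep, 4) - 1]

    def to_dict(self) -> dict:
        return {
            "epoch_laps": list(self.epoch_laps),
            "final_gain": self.final_gain,
            "cue": self.cue,
            "landmarks_visible_epochs": list(self.landmarks_visible_epochs),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GainProfile":
        return cls(
            epoch_laps=tuple(d["epoch_laps"]),
            final_gain=float(d["final_gain"]),
            cue=d.get("cue", "landmark"),
            landmarks_visible_epochs=tuple(
                d.get("landmarks_visible_epochs", (True, True, True, False))
            ),
        )


@dataclass
class AngularTrajectory:
    """Timestamped lab-frame trajectory of the animal on the circular track.

    `lab_angle_unwrapped` is cumulative degrees (laps x 360 + wrapped angle);
    `linear_speed` is cm/s along the running circle of radius `track_radius`.
    If `linear_speed` is omitted it is derived from the angular trajectory.
    """

    time: np.ndarray
    lab_angle_unwrapped: np.ndarray
    linear_speed: np.ndarray | None = None
    track_radius: float = 75.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.lab_angle_unwrapped = np.asarray(self.lab_angle_unwrapped, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.lab_angle_unwrapped.shape:
            raise ValueError("time and angle must be 1-D arrays of equal length")
        if len(self.time) >= 2 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.track_radius <= 0:
            raise ValueError("track_radius must be positive")
        if self.linear_speed is None:
            self.linear_speed = self.derived_speed()
        else:
            self.linear_speed = np.asarray(self.linear_speed, dtype=float)
            if self.linear_speed.shape != self.time.shape:
                raise ValueError("linear_speed length mismatch")

    def derived_speed(self, smooth_window_s: float = 0.25) -> np.ndarray:
        """Linear speed (cm/s) from central differences of the angle.

        A boxcar smoothing window (default 0.25 s) suppresses sample-rate
        quantization noise before the speed is used for gating.
        """
        ang_speed = np.gradient(self.lab_angle_unwrapped, self.time)  # deg/s
        speed = np.abs(ang_speed) * self.track_radius * np.pi / 180.0
        if len(self.time) >= 3 and smooth_window_s > 0:
            dt = np.median(np.diff(self.time))
            w = max(1, int(round(smooth_window_s / dt)))
            if w > 1:
                kernel = np.ones(w) / w
                speed = np.convolve(speed, kernel, mode="same")
        return speed

    @property
    def wrapped_angle(self) -> np.ndarray:
        return wrap_angle(self.lab_angle_unwrapped)

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])


@dataclass
class FramePosition:
    """Unwrapped angular position series expressed in a named frame."""

    frame: str
    angle_unwrapped: np.ndarray
    time: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def wrapped(self) -> np.ndarray:
        return wrap_angle(self.angle_unwrapped)


# ---------------------------------------------------------------------------
# gain schedule evaluation


def gain_at(profile: GainProfile, lab_distance_deg):
    """Experiment gain at an unwrapped lab-frame distance (degrees).

    Unity through Epoch 1, linear ramp through Epoch 2, and the final gain
    thereafter (the schedule is continuous and piecewise linear in lab
    distance).  Distances beyond the scheduled session keep the final gain.
    """
    d = np.asarray(lab_distance_deg, dtype=float)
    if np.any(d < 0):
        raise ValueError("lab_distance must be non-negative")
    b = profile.epoch_boundaries_deg
    xp = np.array([0.0, b[0], b[1], b[3] if b[3] > b[1] else b[1] + 1.0])
    fp = np.array([1.0, 1.0, profile.final_gain, profile.final_gain])
    out = np.interp(d, xp, fp)
    return float(out) if np.isscalar(lab_distance_deg) else out


def lab_to_frame(
    traj: AngularTrajectory,
    profile: GainProfile,
    start_angle: float = 0.0,
) -> FramePosition:
    """Transform a lab-frame trajectory into the cue (landmark/stripe) frame.

    The cue-frame displacement accumulates as the path integral of the gain
    against lab displacement, evaluated by trapezoidal accumulation over the
    trajectory samples.  With G identically 1 this is the identity map.
    """
    theta = traj.lab_angle_unwrapped
    if np.any(np.diff(traj.time) <= 0):
        raise ValueError("trajectory time must be strictly increasing")
    g = gain_at(profile, np.maximum(theta - theta[0], 0.0) + 0.0)
    # gain is scheduled on distance run from session start; trajectory is
    # assumed to start at the session origin
    dtheta = np.diff(theta)
    increments = 0.5 * (g[:-1] + g[1:]) * dtheta
    frame_angle = np.empty_like(theta)
    frame_angle[0] = start_angle
    frame_angle[1:] = start_angle + np.cumsum(increments)
    return FramePosition(frame=profile.cue, angle_unwrapped=frame_angle, time=traj.time)


def cue_rotation(traj: AngularTrajectory, profile: GainProfile) -> np.ndarray:
    """Angular position of the cue set in the lab frame (degrees).

    phi(t) = theta_lab(t) - theta_frame(t).  At G > 1 the cues rotate
    opposite to the running direction; at G = 0 they track the animal.
    The instantaneous cue angular speed is |1 - G| times the animal's.
    """
    fp = lab_to_frame(traj, profile, start_angle=traj.lab_angle_unwrapped[0])
    return traj.lab_angle_unwrapped - fp.angle_unwrapped


def latency_angular_error(
    rat_angular_speed: float, gain: float, latency: float
) -> float:
    """Angular error (degrees) of the projected scene caused by feedback lag.

    The cues rotate at |1 - G| times the animal's angular speed, so a
    feedback latency displaces the projected scene by
    speed * |1 - G| * latency degrees.
    """
    if latency < 0:
        raise ValueError("latency must be non-negative")
    return float(rat_angular_speed * abs(1.0 - gain) * latency)


def arc_error(angular_error_deg: float, radius_m: float) -> float:
    """Arc length (meters) subtended by an angular error at a given radius."""
    if radius_m <= 0:
        raise ValueError("radius must be positive")
    return float(radius_m * angular_error_deg * np.pi / 180.0)


# ---------------------------------------------------------------------------
# angle utilities


def wrap_angle(angle_deg):
    """Wrap angles into [0, 360)."""
    r = np.mod(angle_deg, 360.0)
    # mod of a tiny negative value rounds to 360.0 exactly; keep the range
    return np.where(r >= 360.0, 0.0, r) if np.ndim(r) else (0.0 if r >= 360.0 else r)


def unwrap_angle(angle_deg) -> np.ndarray:
    """Unwrap a wrapped angle sequence assuming < 180 deg steps.

    Steps of 180 deg or more between consecutive samples are ambiguous and
    trigger a warning; they are resolved toward the smaller jump.
    """
    a = np.asarray(angle_deg, dtype=float)
    if a.size >= 2:
        step = np.abs(np.diff(np.mod(a, 360.0)))
        step = np.minimum(step, 360.0 - step)
        if np.any(step >= 180.0 - 1e-12):
            warnings.warn(
                "angle sequence contains steps >= 180 deg; unwrapping is ambiguous",
                stacklevel=2,
            )
    return np.unwrap(a, period=360.0)


def lap_count(angle_unwrapped_deg):
    """Completed laps: floor(unwrapped angle / 360)."""
    return np.floor(np.asarray(angle_unwrapped_deg, dtype=float) / 360.0).astype(int)
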