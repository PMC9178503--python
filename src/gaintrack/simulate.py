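"""Synthetic-session generator with known ground truth.

Generates everything a recorded gain-manipulation session contains —
run/pause trajectory, place-cell spike trains, a theta-band LFP, and sync
pulse trains on two (optionally corrupted) clocks — so that every analysis
stage in this package can be validated against ground truth.

Behavioral defaults are calibrated to the published aggregate statistics of
freely running rats on the 150 cm circular track: running speed near
24.6 cm/s, roughly one pause per lap, and pause durations near 9 s.  Place
cells are inhomogeneous Poisson processes with a circular-Gaussian tuning
curve locked to a chosen reference frame, optional per-lap drift and
activity windows (remapping), and theta modulation with linear phase
precession across the field.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .frames import (
    AngularTrajectory,
    GainProfile,
    FramePosition,
    lab_to_frame,
    DEG_PER_LAP,
)

__all__ = [
    "BehaviorConfig",
    "PlaceCellSpec",
    "LFP",
    "PulseTrain",
    "SyntheticSession",
    "simulate_trajectory",
    "simulate_lfp",
    "simulate_spikes",
    "simulate_pulse_train",
    "corrupt_clock",
    "simulate_session",
    "tuning_concentration",
]


@dataclass(frozen=True)
class BehaviorConfig:
    """Run/pause behavior parameters for the trajectory generator.

    Defaults emulate the aggregate behavior of rats on the circular track:
    mean running speed 24.6 cm/s, ~0.9 pauses per lap, mean pause duration
    8.8 s.
    """

    mean_speed: float = 24.6  # cm/s while running
    speed_sd: float = 3.0  # cm/s, between-bout variability
    pauses_per_lap: float = 0.9
    pause_duration_mean: float = 8.8  # s
    track_radius: float = 75.0  # cm
    session_laps: float = 40.0  # lab laps
    sample_rate: float = 50.0  # Hz, camera-rate analogue
    seed: int = 0

    def __post_init__(self) -> None:
        if self.session_laps <= 0:
            raise ValueError("session_laps must be positive")
        if self.mean_speed <= 0 or self.sample_rate <= 0:
            raise ValueError("rates must be positive")
        if self.pauses_per_lap < 0 or self.pause_duration_mean <= 0:
            raise ValueError("pause parameters must be non-negative")


@dataclass(frozen=True)
class PlaceCellSpec:
    """Ground-truth tuning of one simulated place cell.

    `width` is the full width of the tuning curve at 10% of its peak above
    baseline, matching the sweep-boundary definition used by the detector.
    `active_lap_range` restricts the place-specific drive to a window of
    laps in the owning frame (for remapping injection); `drift_per_lab_lap`
    moves the field center in its frame per laboratory lap.
    `precession_span` is the total theta phase (degrees) traversed by the
    preferred firing phase across the field, from early (high) to late
    (low) phases.
    """

    frame: str = "landmark"  # lab | landmark | stripe
    center: float = 180.0  # deg in the owning frame
    width: float = 40.0  # deg, full width at 10% of peak
    peak_rate: float = 15.0  # spikes/s
    baseline_rate: float = 0.1  # spikes/s
    active_lap_range: tuple[float, float] | None = None  # frame laps
    drift_per_lab_lap: float = 0.0  # deg per lab lap
    theta_modulation_depth: float = 0.0  # 0..1
    precession_span: float = 0.0  # deg of theta phase across the field

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be positive")
        if not (self.peak_rate > self.baseline_rate >= 0):
            raise ValueError("need peak_rate > baseline_rate >= 0")
        if not (0 <= self.theta_modulation_depth <= 1):
            raise ValueError("theta_modulation_depth must be in [0, 1]")


@dataclass
class LFP:
    """Sampled LFP trace with (for synthetic data) its ground-truth phase."""

    values: np.ndarray
    rate: float  # Hz
    time: np.ndarray | None = None
    truth_phase_deg: np.ndarray | None = None  # 0 at oscillation peaks

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.time is None:
            self.time = np.arange(len(self.values)) / self.rate


@dataclass
class PulseTrain:
    """TTL sync-pulse onsets on one clock."""

    onsets: np.ndarray
    pulse_width: float = 1.0

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        if self.onsets.size >= 2:
            gaps = np.diff(self.onsets)
            if np.any(gaps <= 0):
                raise ValueError("onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.onsets)


@dataclass
class SyntheticSession:
    """A complete simulated session plus the ground truth that produced it."""

    trajectory: AngularTrajectory
    profile: GainProfile
    spike_trains: dict[int, np.ndarray]
    cell_specs: dict[int, PlaceCellSpec]
    lfp: LFP | None = None
    pulses_a: PulseTrain | None = None
    pulses_b: PulseTrain | None = None
    pulse_correspondence: list[tuple[int, int]] | None = None
    behavior: BehaviorConfig | None = None
    frame_positions: dict[str, FramePosition] = field(default_factory=dict)

    def frame_position(self, frame: str) -> FramePosition:
        """Trajectory expressed in a frame, cached per session."""
        if frame not in self.frame_positions:
            if frame == "lab":
                fp = FramePosition(
                    "lab",
                    self.trajectory.lab_angle_unwrapped,
                    self.trajectory.time,
                )
            else:
                fp = lab_to_frame(self.trajectory, self.profile)
            self.frame_positions[frame] = fp
        return self.frame_positions[frame]


# ---------------------------------------------------------------------------
# trajectory


def simulate_trajectory(
    config: BehaviorConfig, profile: GainProfile | None = None
) -> AngularTrajectory:
    """Simulate run/pause locomotion on the circular track.

    Running speed is drawn once per run bout from a truncated normal around
    `mean_speed`; pause onsets form a Poisson process in lab distance with
    `pauses_per_lap` events per lap; pause durations are gamma distributed
    (shape 2) with the configured mean.  Sampling is at `sample_rate`.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    total_deg = config.session_laps * DEG_PER_LAP
    dt = 1.0 / config.sample_rate
    rad_deg = 180.0 / np.pi / config.track_radius  # deg per cm

    n_pauses = rng.poisson(config.pauses_per_lap * config.session_laps)
    pause_positions = np.sort(rng.uniform(0.0, total_deg, size=n_pauses))
    pause_durations = rng.gamma(2.0, config.pause_duration_mean / 2.0, size=n_pauses)

    def draw_speed() -> float:
        a = (5.0 - config.mean_speed) / config.speed_sd
        return float(
            stats.truncnorm.rvs(
                a, np.inf, loc=config.mean_speed, scale=config.speed_sd,
                random_state=rng,
            )
        )

    times = [0.0]
    angles = [0.0]
    speeds = []
    t, ang = 0.0, 0.0
    next_pause = 0
    bout_speed = draw_speed()
    pause_left = 0.0
    speeds.append(bout_speed)
    while ang < total_deg:
        if pause_left > 0:
            pause_left -= dt
            t += dt
            if pause_left <= 0:
                bout_speed = draw_speed()
            times.append(t)
            angles.append(ang)
            speeds.append(0.0 if pause_left > 0 else bout_speed)
            continue
        d_ang = bout_speed * rad_deg * dt
        if next_pause < n_pauses and ang + d_ang >= pause_positions[next_pause]:
            ang = pause_positions[next_pause]
            pause_left = pause_durations[next_pause]
            next_pause += 1
        else:
            ang += d_ang
        t += dt
        times.append(t)
        angles.append(ang)
        speeds.append(bout_speed if pause_left <= 0 else 0.0)

    return AngularTrajectory(
        time=np.array(times),
        lab_angle_unwrapped=np.array(angles),
        linear_speed=np.array(speeds),
        track_radius=config.track_radius,
    )


# ---------------------------------------------------------------------------
# LFP


def simulate_lfp(
    theta_freq=8.0,
    amplitude: float = 1.0,
    noise_sd: float = 0.0,
    duration: float = 10.0,
    rate: float = 250.0,
    seed: int = 0,
) -> LFP:
    """Sinusoidal theta-band LFP plus white noise, with truth phase retained.

    `theta_freq` may be a scalar (Hz) or an array of per-sample frequencies
    (e.g. a 6-12 Hz sweep).  Phase convention: 0 deg at signal peaks.
    """
    if np.any(np.asarray(rate) < 4 * np.max(theta_freq)):
        raise ValueError("sample rate must be at least 4x the theta frequency")
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    f = np.broadcast_to(np.asarray(theta_freq, dtype=float), (n,))
    phase = 2 * np.pi * np.concatenate([[0.0], np.cumsum(0.5 * (f[1:] + f[:-1]) / rate)])
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    values = amplitude * np.cos(phase)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=n)
    return LFP(
        values=values,
        rate=rate,
        time=t,
        truth_phase_deg=np.degrees(phase),
    )


# ---------------------------------------------------------------------------
# spikes


def tuning_concentration(width_deg: float, threshold: float = 0.10) -> float:
    """Concentration of the circular-Gaussian tuning curve.

    Chosen so that the curve falls to `threshold` of its peak at half the
    full `width`, i.e. the simulator's width definition coincides with the
    sweep detector's boundary definition.
    """
    half = np.radians(min(width_deg / 2.0, 179.9))
    return float(np.log(threshold) / (np.cos(half) - 1.0))


def _rate_function(
    spec: PlaceCellSpec,
    t: np.ndarray,
    frame_angle: np.ndarray,
    lab_angle: np.ndarray,
) -> np.ndarray:
    """Place-specific firing rate (spikes/s) at the trajectory samples."""
    kappa = tuning_concentration(spec.width)
    lab_laps = lab_angle / DEG_PER_LAP
    center = spec.center + spec.drift_per_lab_lap * lab_laps
    delta = np.radians(frame_angle - center)
    tuning = np.exp(kappa * (np.cos(delta) - 1.0))
    rate = spec.baseline_rate + (spec.peak_rate - spec.baseline_rate) * tuning
    if spec.active_lap_range is not None:
        frame_laps = frame_angle / DEG_PER_LAP
        lo, hi = spec.active_lap_range
        outside = (frame_laps < lo) | (frame_laps >= hi)
        rate = np.where(outside, spec.baseline_rate, rate)
    return rate


def _preferred_phase_deg(
    spec: PlaceCellSpec, frame_angle: np.ndarray, lab_angle: np.ndarray
) -> np.ndarray:
    """Preferred theta phase, decreasing linearly across the field."""
    lab_laps = lab_angle / DEG_PER_LAP
    center = spec.center + spec.drift_per_lab_lap * lab_laps
    half = spec.width / 2.0
    # normalized position within the field, 0 at entry, 1 at exit
    delta = (frame_angle - center + half) % DEG_PER_LAP
    x = np.clip(delta / spec.width, 0.0, 1.0)
    return spec.precession_span * (0.5 - x)


def simulate_spikes(
    spec: PlaceCellSpec,
    traj: AngularTrajectory,
    profile: GainProfile,
    lfp: LFP | None = None,
    seed: int = 0,
    unit_id: int = 0,
) -> np.ndarray:
    """Inhomogeneous-Poisson spike train for one place cell, by thinning.

    The rate is the frame-locked tuning curve evaluated along the
    trajectory, multiplied (if an LFP is supplied) by a theta factor
    1 + depth * cos(phase - preferred), where the preferred phase recedes
    linearly across the field over `precession_span` degrees.
    """
    if spec.frame == "lab":
        frame_angle = traj.lab_angle_unwrapped
    else:
        if spec.frame != profile.cue:
            raise ValueError(
                f"spec frame {spec.frame!r} has no gain schedule (profile governs "
                f"{profile.cue!r})"
            )
        frame_angle = lab_to_frame(traj, profile).angle_unwrapped

    rng = np.random.default_rng(np.random.SeedSequence([seed, 2, unit_id]))
    lam_max = spec.peak_rate * (1.0 + spec.theta_modulation_depth) * 1.0001
    t0, t1 = traj.time[0], traj.time[-1]
    n_cand = rng.poisson(lam_max * (t1 - t0))
    cand = np.sort(rng.uniform(t0, t1, size=n_cand))

    ang_c = np.interp(cand, traj.time, frame_angle)
    lab_c = np.interp(cand, traj.time, traj.lab_angle_unwrapped)
    rate = _rate_function(spec, cand, ang_c, lab_c)
    if lfp is not None and spec.theta_modulation_depth > 0:
        if lfp.truth_phase_deg is None:
            raise ValueError("LFP must carry truth phase for theta modulation")
        phase = np.interp(cand, lfp.time, lfp.truth_phase_deg)
        pref = _preferred_phase_deg(spec, ang_c, lab_c)
        rate = rate * (
            1.0
            + spec.theta_modulation_depth * np.cos(np.radians(phase - pref))
        )
    if np.any(rate > lam_max):
        raise RuntimeError("thinning envelope exceeded")  # must not happen
    keep = rng.uniform(0.0, lam_max, size=n_cand) < rate
    return cand[keep]


def simulate_tracked_motion(
    duration: float,
    rate: float,
    band: tuple[float, float] = (0.2, 2.0),
    gain: float = 3.0,
    delay: float = 0.105,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Band-limited marker motion and its delayed, gain-scaled cue response.

    Emulates the latency measurement: a tracked head-marker moved with
    energy in `band` Hz, and the projected cue responding at `gain` times
    the marker speed in the opposite direction after `delay` seconds.
    Returns (time, input_motion, output_motion).
    """
    from scipy import signal as _sg

    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    t = np.arange(0.0, duration, 1.0 / rate)
    sos = _sg.butter(4, band, btype="bandpass", fs=rate, output="sos")
    x = _sg.sosfiltfilt(sos, rng.normal(0.0, 1.0, len(t)))
    y = -gain * np.interp(t - delay, t, x)
    return t, x, y


# ---------------------------------------------------------------------------
# sync pulses


def simulate_pulse_train(
    mean_interval: float = 10.0,
    pulse_width: float = 1.0,
    duration: float = 600.0,
    seed: int = 0,
) -> PulseTrain:
    """Randomized TTL pulse train: exponential inter-pulse intervals.

    Intervals have the stated mean and are truncated below at
    pulse_width + 0.5 s so pulses never overlap.
    """
    if mean_interval <= pulse_width:
        raise ValueError("mean_interval must exceed pulse_width")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    floor = pulse_width + 0.5
    onsets = []
    t = float(rng.exponential(mean_interval))
    while t < duration:
        onsets.append(t)
        gap = float(rng.exponential(mean_interval))
        while gap < floor:
            gap = float(rng.exponential(mean_interval))
        t += gap
    return PulseTrain(onsets=np.array(onsets), pulse_width=pulse_width)


def corrupt_clock(
    pulses: PulseTrain,
    offset: float = 0.0,
    drift: float = 0.0,
    jitter_sd: float = 0.0,
    drop_prob: float = 0.0,
    extra_rate: float = 0.0,
    seed: int = 0,
) -> tuple[PulseTrain, list[tuple[int, int]]]:
    """Re-express a pulse train on a second, imperfect clock.

    t' = offset + (1 + drift) * t + jitter, with random pulse drops and
    spurious insertions.  Returns the corrupted train and the ground-truth
    correspondence as (index in `pulses`, index in returned train) pairs.
    """
    if not (0 <= drop_prob < 1):
        raise ValueError("drop_prob must be in [0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    t = pulses.onsets
    mapped = offset + (1.0 + drift) * t
    if jitter_sd > 0:
        mapped = mapped + rng.normal(0.0, jitter_sd, size=len(t))
    kept = rng.uniform(size=len(t)) >= drop_prob
    events = [(mt, i) for mt, i, k in zip(mapped, range(len(t)), kept) if k]
    if extra_rate > 0 and len(mapped) > 0:
        span = mapped.max() - mapped.min()
        n_extra = rng.poisson(extra_rate * span)
        for e in rng.uniform(mapped.min(), mapped.max(), size=n_extra):
            events.append((float(e), -1))
    events.sort()
    # enforce the minimum separation invariant of a physical pulse train
    cleaned: list[tuple[float, int]] = []
    for mt, i in events:
        if cleaned and mt - cleaned[-1][0] <= pulses.pulse_width:
            continue
        cleaned.append((mt, i))
    onsets = np.array([mt for mt, _ in cleaned])
    correspondence = [
        (i, j) for j, (_, i) in enumerate(cleaned) if i >= 0
    ]
    return PulseTrain(onsets=onsets, pulse_width=pulses.pulse_width), correspondence


# ---------------------------------------------------------------------------
# full session


def simulate_session(
    behavior: BehaviorConfig | None = None,
    profile: GainProfile | None = None,
    cell_specs: dict[int, PlaceCellSpec] | list[PlaceCellSpec] | None = None,
    lfp_noise_sd: float = 0.0,
    theta_freq: float = 8.0,
    pulse_duration: float | None = None,
    clock_offset: float = 0.0,
    clock_drift: float = 0.0,
    clock_jitter_sd: float = 0.0,
    clock_drop_prob: float = 0.0,
    seed: int = 0,
) -> SyntheticSession:
    """Build a complete synthetic session from one seed.

    All randomness derives from `seed` via independent substreams, so a
    session is bit-reproducible and per-unit spike trains are stable under
    changes to the unit list.
    """
    behavior = behavior or BehaviorConfig(seed=seed)
    if behavior.seed != seed:
        behavior = BehaviorConfig(**{**asdict(behavior), "seed": seed})
    profile = profile or GainProfile()
    if cell_specs is None:
        cell_specs = {}
    if isinstance(cell_specs, list):
        cell_specs = dict(enumerate(cell_specs))

    traj = simulate_trajectory(behavior, profile)
    lfp = simulate_lfp(
        theta_freq=theta_freq,
        noise_sd=lfp_noise_sd,
        duration=traj.duration,
        rate=250.0,
        seed=seed,
    )
    spikes = {
        uid: simulate_spikes(spec, traj, profile, lfp=lfp, seed=seed, unit_id=uid)
        for uid, spec in cell_specs.items()
    }
    dur = pulse_duration if pulse_duration is not None else traj.duration
    pulses_a = simulate_pulse_train(duration=dur, seed=seed)
    pulses_b, corr = corrupt_clock(
        pulses_a,
        offset=clock_offset,
        drift=clock_drift,
        jitter_sd=clock_jitter_sd,
        drop_prob=clock_drop_prob,
        seed=seed,
    )
    return SyntheticSession(
        trajectory=traj,
        profile=profile,
        spike_trains=spikes,
        cell_specs=cell_specs,
        lfp=lfp,
        pulses_a=pulses_a,
        pulses_b=pulses_b,
        pulse_correspondence=corr,
        behavior=behavior,
    )
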