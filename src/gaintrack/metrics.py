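"""Rate maps and place-field metrics in any reference frame.

Implements occupancy-corrected rate maps with speed gating, the spatial
information score, peak rate, per-field reliability, per-sweep lab-frame
scaling, drift rate, and interspike-interval histograms.

Two spatial-information conventions are provided.  ``spatial_information``
is the score used throughout this package's figures-of-merit:

    SI = (1/B) * sum_i  lambda_i * log2(lambda_i / lambda)

with B the number of bins, lambda_i the occupancy-corrected rate in bin i
and lambda the unit's mean rate (total spikes / total included time).
``spatial_information_per_spike`` is the conventional occupancy-weighted
bits-per-spike score, supplied for comparison with the wider literature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detection import PlaceField, Sweep
from .frames import (
    AngularTrajectory,
    GainProfile,
    lab_to_frame,
    wrap_angle,
    DEG_PER_LAP,
)

__all__ = [
    "RateMap",
    "rate_map",
    "spatial_information",
    "spatial_information_per_spike",
    "peak_rate",
    "reliability",
    "scaling_factor",
    "drift_rate",
    "isi_histogram",
    "signed_circular_difference",
]

SPEED_THRESHOLD_CM_S = 5.0


@dataclass
class RateMap:
    """Binned occupancy-corrected firing rates in one reference frame."""

    frame: str
    bin_edges: np.ndarray  # degrees, length n_bins + 1
    occupancy: np.ndarray  # seconds per bin
    spike_counts: np.ndarray
    rate: np.ndarray  # spikes/s; NaN where occupancy is zero
    mean_rate: float  # total spikes / total included time

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def rate_map(
    spike_times: np.ndarray,
    traj: AngularTrajectory,
    profile: GainProfile,
    frame: str = "landmark",
    n_bins: int = 72,
    speed_threshold: float = SPEED_THRESHOLD_CM_S,
) -> RateMap:
    """Occupancy-corrected rate map with speed gating.

    Samples (and spikes) where the animal's linear speed does not exceed
    `speed_threshold` (default 5 cm/s) are excluded.  The track is divided
    into `n_bins` equal angular bins (default 72 bins of 5 degrees).
    """
    spike_times = np.asarray(spike_times, dtype=float)
    if frame == "lab":
        angle = traj.lab_angle_unwrapped
    else:
        angle = lab_to_frame(traj, profile).angle_unwrapped
    speed = traj.linear_speed
    t = traj.time
    dt = np.gradient(t)
    included = speed > speed_threshold
    if not included.any():
        raise ValueError("no samples above the speed threshold")

    edges = np.linspace(0.0, DEG_PER_LAP, n_bins + 1)
    wrapped = wrap_angle(angle)
    occupancy, _ = np.histogram(wrapped[included], bins=edges, weights=dt[included])

    spk_speed = np.interp(spike_times, t, speed)
    spk_angle = np.interp(spike_times, t, angle)
    spk_keep = spk_speed > speed_threshold
    counts, _ = np.histogram(wrap_angle(spk_angle[spk_keep]), bins=edges)

    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(occupancy > 0, counts / occupancy, np.nan)
    total_time = float(occupancy.sum())
    mean_rate = float(counts.sum() / total_time) if total_time > 0 else np.nan
    return RateMap(
        frame=frame,
        bin_edges=edges,
        occupancy=occupancy,
        spike_counts=counts,
        rate=rate,
        mean_rate=mean_rate,
    )


def spatial_information(rmap: RateMap) -> float:
    """Spatial information score, (1/B) sum_i lambda_i log2(lambda_i/lambda).

    Bins with zero rate contribute zero (the x log x -> 0 limit); bins with
    zero occupancy are excluded.  Raises if the mean rate is zero.
    """
    lam = rmap.mean_rate
    if not np.isfinite(lam) or lam <= 0:
        raise ValueError("mean rate must be positive for spatial information")
    li = rmap.rate
    valid = np.isfinite(li) & (li > 0)
    contrib = li[valid] * np.log2(li[valid] / lam)
    return float(contrib.sum() / rmap.n_bins)


def spatial_information_per_spike(rmap: RateMap) -> float:
    """Conventional bits-per-spike score, sum_i p_i (li/lam) log2(li/lam)."""
    lam = rmap.mean_rate
    if not np.isfinite(lam) or lam <= 0:
        raise ValueError("mean rate must be positive for spatial information")
    occ = rmap.occupancy
    p = occ / occ.sum()
    li = rmap.rate
    valid = np.isfinite(li) & (li > 0)
    contrib = p[valid] * (li[valid] / lam) * np.log2(li[valid] / lam)
    return float(contrib.sum())


def peak_rate(rmap: RateMap) -> float:
    """Maximum occupancy-corrected rate over occupied bins."""
    valid = np.isfinite(rmap.rate)
    if not valid.any():
        raise ValueError("rate map has no occupied bins")
    return float(np.nanmax(rmap.rate))


def reliability(field: PlaceField, frame_laps_run: int) -> float:
    """Fraction of cue-frame laps on which the field produced a sweep."""
    if frame_laps_run < 1:
        raise ValueError("frame_laps_run must be >= 1")
    active = {s.lap for s in field.sweeps}
    return len(active) / frame_laps_run


def _epoch1_sweeps(field: PlaceField, profile: GainProfile) -> list[Sweep]:
    e1_end = profile.epoch_laps[0] * DEG_PER_LAP
    out = []
    for s in field.sweeps:
        if s.lab_start is None or s.lab_end is None:
            raise ValueError("sweeps need lab extents; run assign_sweep_gain first")
        if s.lab_end <= e1_end:
            out.append(s)
    return out


def scaling_factor(field: PlaceField, sweep: Sweep, profile: GainProfile) -> float:
    """Per-sweep lab-frame scaling factor f_p.

    f_p = (mean lab-frame sweep size of the field during Epoch 1)
          / (lab-frame size of this sweep).

    For a field locked to the cue frame, the lab size of a sweep shrinks as
    the gain grows, so f_p tracks the sweep gain g_p (the unity-line
    property).  Raises if the field has no Epoch-1 sweeps.
    """
    e1 = _epoch1_sweeps(field, profile)
    if not e1:
        raise ValueError("field has no Epoch-1 sweeps; scaling undefined")
    baseline = float(np.mean([s.lab_extent for s in e1]))
    if sweep.lab_extent is None or sweep.lab_extent <= 0:
        raise ValueError("sweep needs a positive lab extent")
    return baseline / sweep.lab_extent


def signed_circular_difference(a_deg: float, b_deg: float) -> float:
    """Signed angular difference a - b wrapped into (-180, 180]."""
    d = (a_deg - b_deg) % DEG_PER_LAP
    if d > 180.0:
        d -= DEG_PER_LAP
    return float(d)


def _circular_mean_deg(angles_deg: np.ndarray) -> float:
    z = np.mean(np.exp(1j * np.radians(angles_deg)))
    return float(np.degrees(np.angle(z)) % DEG_PER_LAP)


def drift_rate(field: PlaceField, lab_laps_run: float, n_edge: int = 3) -> float:
    """Signed drift rate d_p of a field in the cue frame, degrees per lab lap.

    d_p = ang(m_end, m_start) / lab_laps_run, where m_start and m_end are the
    circular means of the wrapped centers of the first and last `n_edge`
    sweeps (in session order) and ang is the signed wrapped difference.
    Positive drift is in the running direction.  Fields with fewer than
    2 * n_edge sweeps use all available sweeps at each end (overlapping if
    necessary); fewer than 2 sweeps is undefined.
    """
    if lab_laps_run <= 0:
        raise ValueError("lab_laps_run must be positive")
    sweeps = sorted(
        field.sweeps,
        key=lambda s: s.lab_start if s.lab_start is not None else s.start,
    )
    if len(sweeps) < 2:
        raise ValueError("drift rate needs at least 2 sweeps")
    k = min(n_edge, len(sweeps))
    m_start = _circular_mean_deg(np.array([s.center % DEG_PER_LAP for s in sweeps[:k]]))
    m_end = _circular_mean_deg(np.array([s.center % DEG_PER_LAP for s in sweeps[-k:]]))
    return signed_circular_difference(m_end, m_start) / lab_laps_run


def isi_histogram(
    spike_times: np.ndarray,
    max_isi: float = 0.5,
    bin_width: float = 0.005,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of interspike intervals no longer than `max_isi` seconds.

    Returns (bin_edges, counts).
    """
    t = np.asarray(spike_times, dtype=float)
    if t.size and np.any(np.diff(t) < 0):
        raise ValueError("spike times must be sorted")
    isi = np.diff(t)
    isi = isi[isi <= max_isi]
    edges = np.arange(0.0, max_isi + bin_width / 2, bin_width)
    counts, _ = np.histogram(isi, bins=edges)
    return edges, counts
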