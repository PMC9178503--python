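"""Place-field sweep detection and clustering.

A *sweep* is a single traversal of a place field on one lap.  Sweeps are
detected from spike locations in the unwrapped cue frame: a firing-rate
analogue is built by Gaussian kernel density estimation on a fine angular
grid, local maxima are found, and each sweep is the maximal contiguous grid
interval around a peak where the density exceeds a fraction of that peak.
Sweeps are then curated (spurious sweeps with too few spikes or too few
neighbors are deleted, iterated to a fixpoint) and clustered into place
fields, defined as maximal sets in which every sweep is in spatio-temporal
proximity to at least two others.

The two estimator classes (`SweepDetector`, `PlaceFieldClusterer`) follow
scikit-learn conventions (``get_params``/``set_params``, fitted attributes
with trailing underscores); the module-level functions are thin wrappers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal, sparse
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator

from .frames import AngularTrajectory, GainProfile, gain_at, DEG_PER_LAP

__all__ = [
    "DetectionParams",
    "Sweep",
    "PlaceField",
    "firing_rate_analogue",
    "detect_sweeps",
    "filter_and_cluster",
    "merge_fields",
    "assign_sweep_gain",
    "field_gain_bin",
    "DEFAULT_GAIN_BIN_EDGES",
    "SweepDetector",
    "PlaceFieldClusterer",
]


@dataclass(frozen=True)
class DetectionParams:
    """Tunable parameters of the sweep detector and field clusterer.

    All angular quantities are degrees in the cue frame.
    """

    kde_bin: float = 0.5  # grid spacing of the firing-rate analogue
    kde_bandwidth: float = 8.0  # Gaussian kernel bandwidth
    peak_fraction: float = 0.10  # sweep boundary threshold, fraction of peak
    min_sweep: float = 5.0  # smallest admissible sweep extent
    max_sweep: float = 120.0  # largest admissible sweep extent
    window_laps: int = 15  # proximity window, frame laps (centered)
    proximity: float = 15.0  # proximity radius on wrapped centers
    min_proximal: int = 3  # minimum proximal sweeps to survive
    min_spikes: int = 4  # minimum spikes per sweep to survive

    def __post_init__(self) -> None:
        if not (0 < self.min_sweep < self.max_sweep):
            raise ValueError("need 0 < min_sweep < max_sweep")
        if not (0 < self.peak_fraction < 1):
            raise ValueError("peak_fraction must be in (0, 1)")


@dataclass
class Sweep:
    """One pass through a place field, in unwrapped cue-frame degrees."""

    unit_id: int
    start: float
    end: float
    spike_count: int
    lab_start: float | None = None  # unwrapped lab degrees at sweep entry
    lab_end: float | None = None
    g_p: float | None = None  # sweep gain

    @property
    def center(self) -> float:
        """Geometric midpoint (not the firing-rate peak)."""
        return 0.5 * (self.start + self.end)

    @property
    def extent(self) -> float:
        return self.end - self.start

    @property
    def lap(self) -> int:
        """Frame lap containing the sweep center."""
        return int(np.floor(self.center / DEG_PER_LAP))

    @property
    def lab_extent(self) -> float | None:
        if self.lab_start is None or self.lab_end is None:
            return None
        return self.lab_end - self.lab_start


@dataclass
class PlaceField:
    """A clustered set of sweeps of one unit, ordered by position."""

    field_id: int
    unit_id: int
    sweeps: list[Sweep]

    def __post_init__(self) -> None:
        if any(s.unit_id != self.unit_id for s in self.sweeps):
            raise ValueError("all sweeps of a field must share unit_id")
        self.sweeps = sorted(self.sweeps, key=lambda s: s.center)

    @property
    def n_sweeps(self) -> int:
        return len(self.sweeps)

    @property
    def laps(self) -> np.ndarray:
        return np.array(sorted({s.lap for s in self.sweeps}))

    @property
    def wrapped_center(self) -> float:
        """Circular mean of wrapped sweep centers (degrees in [0, 360))."""
        c = np.radians([s.center for s in self.sweeps])
        return float(np.degrees(np.angle(np.mean(np.exp(1j * c)))) % 360.0)


# ---------------------------------------------------------------------------
# KDE firing-rate analogue


def firing_rate_analogue(
    spike_angles: np.ndarray, params: DetectionParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Kernel density estimate of spike locations on a fine angular grid.

    Spike angles are unwrapped cue-frame degrees.  Returns (grid, density);
    the grid spans the spike range padded by three bandwidths and the
    density integrates to one over the grid.  Empty input yields empty
    arrays.
    """
    params = params or DetectionParams()
    a = np.sort(np.asarray(spike_angles, dtype=float))
    if a.size == 0:
        return np.empty(0), np.empty(0)
    pad = 3.0 * params.kde_bandwidth
    lo = np.floor((a[0] - pad) / params.kde_bin) * params.kde_bin
    hi = np.ceil((a[-1] + pad) / params.kde_bin) * params.kde_bin
    grid = np.arange(lo, hi + 0.5 * params.kde_bin, params.kde_bin)
    # bin spikes onto the grid then convolve with a sampled Gaussian kernel;
    # at kde_bin << bandwidth this matches the direct KDE to high accuracy
    edges = np.concatenate([grid - 0.5 * params.kde_bin, [grid[-1] + 0.5 * params.kde_bin]])
    counts, _ = np.histogram(a, bins=edges)
    half_k = int(np.ceil(5.0 * params.kde_bandwidth / params.kde_bin))
    x = np.arange(-half_k, half_k + 1) * params.kde_bin
    kernel = np.exp(-0.5 * (x / params.kde_bandwidth) ** 2)
    kernel /= kernel.sum() * params.kde_bin
    density = signal.fftconvolve(counts.astype(float), kernel, mode="same")
    density = np.clip(density, 0.0, None) / a.size
    # suppress FFT roundoff noise, which would otherwise seed spurious
    # local maxima with meaninglessly low per-peak thresholds
    density[density < 1e-9 * density.max()] = 0.0
    return grid, density


# ---------------------------------------------------------------------------
# sweep detection


def detect_sweeps(
    grid: np.ndarray,
    density: np.ndarray,
    spike_angles: np.ndarray,
    params: DetectionParams | None = None,
    unit_id: int = 0,
) -> list[Sweep]:
    """Delimit sweeps around each local maximum of the firing-rate analogue.

    For every local maximum, the sweep is the maximal contiguous grid
    interval containing it where the density stays above ``peak_fraction``
    of that peak's density.  Intervals narrower than ``min_sweep`` or wider
    than ``max_sweep`` are discarded; coincident intervals produced by
    multiple peaks in one threshold region are merged into a single sweep.
    """
    params = params or DetectionParams()
    if grid.size == 0:
        return []
    spikes = np.sort(np.asarray(spike_angles, dtype=float))
    peaks, _ = signal.find_peaks(density)
    if density.size and density[0] > density[1:2].max(initial=-np.inf):
        peaks = np.concatenate([[0], peaks])
    if density.size >= 2 and density[-1] > density[-2]:
        peaks = np.concatenate([peaks, [density.size - 1]])

    intervals: list[tuple[int, int]] = []
    for p in peaks:
        thr = params.peak_fraction * density[p]
        above = density > thr
        i = p
        while i > 0 and above[i - 1]:
            i -= 1
        j = p
        while j < len(density) - 1 and above[j + 1]:
            j += 1
        intervals.append((i, j))

    # merge intervals that overlap (several peaks inside one region)
    intervals.sort()
    merged: list[list[int]] = []
    for i, j in intervals:
        if merged and i <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], j)
        else:
            merged.append([i, j])

    sweeps = []
    for i, j in merged:
        start, end = float(grid[i]), float(grid[j])
        extent = end - start
        if not (params.min_sweep <= extent <= params.max_sweep):
            continue
        n_in = int(np.searchsorted(spikes, end, side="right") - np.searchsorted(spikes, start, side="left"))
        sweeps.append(Sweep(unit_id=unit_id, start=start, end=end, spike_count=n_in))
    return sweeps


# ---------------------------------------------------------------------------
# curation and clustering


def _circ_dist(a: float, b: float) -> float:
    """Absolute angular distance on the circle, degrees in [0, 180]."""
    d = abs(a - b) % DEG_PER_LAP
    return min(d, DEG_PER_LAP - d)


def _proximal_matrix(sweeps: list[Sweep], params: DetectionParams) -> np.ndarray:
    """Boolean matrix: sweep j is in proximity of sweep i.

    Proximity requires the other sweep's center within ``proximity`` degrees
    in wrapped frame coordinates AND within the ``window_laps``-lap window
    centered on sweep i's lap, excluding sweeps on i's own lap.
    """
    n = len(sweeps)
    centers = np.array([s.center for s in sweeps])
    laps = np.array([s.lap for s in sweeps])
    half = params.window_laps // 2
    d = np.abs(centers[:, None] % DEG_PER_LAP - centers[None, :] % DEG_PER_LAP)
    d = np.minimum(d, DEG_PER_LAP - d)
    dl = np.abs(laps[:, None] - laps[None, :])
    prox = (d <= params.proximity) & (dl <= half) & (dl > 0)
    np.fill_diagonal(prox, False)
    return prox


def filter_and_cluster(
    sweeps: list[Sweep], params: DetectionParams | None = None
) -> list[PlaceField]:
    """Delete spurious sweeps and partition the survivors into place fields.

    A sweep is deleted when it has fewer than ``min_proximal`` proximal
    sweeps among the current survivors, or fewer than ``min_spikes`` spikes.
    Deletion is applied simultaneously to all failing sweeps and iterated to
    a fixpoint, which makes the result independent of input order.  The
    surviving sweeps are partitioned into connected components of the
    proximity graph; every member of a component is then proximal to at
    least two other members.
    """
    params = params or DetectionParams()
    survivors = [s for s in sweeps if s.spike_count >= params.min_spikes]
    while survivors:
        prox = _proximal_matrix(survivors, params)
        counts = prox.sum(axis=1)
        keep = counts >= params.min_proximal
        if keep.all():
            break
        survivors = [s for s, k in zip(survivors, keep) if k]
    if not survivors:
        return []
    prox = _proximal_matrix(survivors, params)
    n_comp, labels = connected_components(
        sparse.csr_matrix(prox), directed=False
    )
    by_unit_order = sorted(range(n_comp), key=lambda c: min(
        survivors[i].center for i in range(len(survivors)) if labels[i] == c
    ))
    fields = []
    for fid, comp in enumerate(by_unit_order):
        members = [s for s, l in zip(survivors, labels) if l == comp]
        unit_ids = {s.unit_id for s in members}
        if len(unit_ids) != 1:
            raise ValueError("filter_and_cluster expects sweeps from one unit")
        fields.append(PlaceField(field_id=fid, unit_id=members[0].unit_id, sweeps=members))
    return fields


def merge_fields(
    fields: list[PlaceField], ids_to_merge: list[int]
) -> list[PlaceField]:
    """Curation merge: union the sweeps of the named fields into one.

    Mirrors the manual step of joining fields that the automatic clustering
    over-segmented; the proximity invariant is deliberately not re-checked.
    """
    chosen = [f for f in fields if f.field_id in set(ids_to_merge)]
    if not chosen:
        return list(fields)
    units = {f.unit_id for f in chosen}
    if len(units) != 1:
        raise ValueError("cannot merge fields from different units")
    seen: set[tuple[float, float]] = set()
    merged_sweeps = []
    for f in chosen:
        for s in f.sweeps:
            key = (s.start, s.end)
            if key not in seen:
                seen.add(key)
                merged_sweeps.append(s)
    merged = PlaceField(
        field_id=min(f.field_id for f in chosen),
        unit_id=chosen[0].unit_id,
        sweeps=merged_sweeps,
    )
    rest = [f for f in fields if f.field_id not in set(ids_to_merge)]
    out = sorted(rest + [merged], key=lambda f: f.field_id)
    return out


# ---------------------------------------------------------------------------
# sweep gain


def _frame_to_lab(
    frame_angles, traj: AngularTrajectory, profile: GainProfile
) -> np.ndarray:
    """Map unwrapped cue-frame angles back to unwrapped lab angles."""
    from .frames import lab_to_frame

    fp = lab_to_frame(traj, profile)
    frame_ang = fp.angle_unwrapped
    lab_ang = traj.lab_angle_unwrapped
    # the frame angle is non-decreasing for non-negative gain; deduplicate
    # flat stretches (pauses) for interpolation
    mono = np.maximum.accumulate(frame_ang)
    keep = np.concatenate([[True], np.diff(mono) > 0])
    return np.interp(frame_angles, mono[keep], lab_ang[keep])


def assign_sweep_gain(
    sweep: Sweep, traj: AngularTrajectory, profile: GainProfile
) -> Sweep:
    """Attach the sweep gain g_p and the lab-frame extent to a sweep.

    g_p is the mean of the experiment gain at the start and at the end of
    the sweep; the lab extent is found by mapping the sweep boundaries back
    through the trajectory into lab coordinates.
    """
    lab_start, lab_end = _frame_to_lab(
        np.array([sweep.start, sweep.end]), traj, profile
    )
    g = 0.5 * (gain_at(profile, lab_start) + gain_at(profile, lab_end))
    return replace(sweep, lab_start=float(lab_start), lab_end=float(lab_end), g_p=float(g))


DEFAULT_GAIN_BIN_EDGES = (0.0, 0.6, 0.9, 1.1, 1.4, 2.0)


def field_gain_bin(
    field: PlaceField, bin_edges=DEFAULT_GAIN_BIN_EDGES
) -> int:
    """Gain-range bin of a field, from the g_p of its last sweep.

    The last sweep is the one latest in the session (largest lab position),
    so a field is assigned to the last gain at which it was active.  Returns
    the bin index into ``bin_edges``; a g_p outside the edges goes to the
    overflow bin (index ``len(bin_edges) - 1``) with a warning.
    """
    if not field.sweeps:
        raise ValueError("field has no sweeps")
    last = max(
        field.sweeps,
        key=lambda s: s.lab_end if s.lab_end is not None else s.end,
    )
    if last.g_p is None:
        raise ValueError("sweeps need g_p; run assign_sweep_gain first")
    edges = np.asarray(bin_edges, dtype=float)
    if not (edges[0] <= last.g_p <= edges[-1]):
        warnings.warn(
            f"g_p={last.g_p:.3f} outside gain bin edges; using overflow bin",
            stacklevel=2,
        )
        return len(edges) - 1
    return int(np.clip(np.searchsorted(edges, last.g_p, side="right") - 1, 0, len(edges) - 2))


def detect_session_fields(
    session,
    params: DetectionParams | None = None,
    speed_threshold: float = 5.0,
) -> dict[int, list[PlaceField]]:
    """Run the full detection pipeline on a session, unit by unit.

    Spikes while the animal moves at or below `speed_threshold` cm/s are
    excluded before the firing-rate analogue is built (pause-time firing
    would otherwise pile up at single angles and distort sweep boundaries).
    Sweeps get their lab extents and gains attached, then are curated and
    clustered into fields.
    """
    params = params or DetectionParams()
    traj = session.trajectory
    fp = session.frame_position(session.profile.cue)
    out: dict[int, list[PlaceField]] = {}
    for uid, times in session.spike_trains.items():
        speed = np.interp(times, traj.time, traj.linear_speed)
        times = np.asarray(times)[speed > speed_threshold]
        angles = np.interp(times, traj.time, fp.angle_unwrapped)
        grid, dens = firing_rate_analogue(angles, params)
        sweeps = detect_sweeps(grid, dens, angles, params, unit_id=uid)
        sweeps = [assign_sweep_gain(s, traj, session.profile) for s in sweeps]
        out[uid] = filter_and_cluster(sweeps, params)
    return out


# ---------------------------------------------------------------------------
# estimators


class SweepDetector(BaseEstimator):
    """Detect place-field sweeps from spike angles in the cue frame.

    Parameters mirror :class:`DetectionParams`.  ``fit`` takes the unwrapped
    cue-frame spike angles (degrees) of a single unit.

    Attributes
    ----------
    grid_, density_ : ndarray
        The firing-rate analogue.
    sweeps_ : list of Sweep
        Detected sweeps, before curation.
    """

    def __init__(
        self,
        kde_bin: float = 0.5,
        kde_bandwidth: float = 8.0,
        peak_fraction: float = 0.10,
        min_sweep: float = 5.0,
        max_sweep: float = 120.0,
        min_spikes: int = 4,
    ):
        self.kde_bin = kde_bin
        self.kde_bandwidth = kde_bandwidth
        self.peak_fraction = peak_fraction
        self.min_sweep = min_sweep
        self.max_sweep = max_sweep
        self.min_spikes = min_spikes

    def _params(self) -> DetectionParams:
        return DetectionParams(
            kde_bin=self.kde_bin,
            kde_bandwidth=self.kde_bandwidth,
            peak_fraction=self.peak_fraction,
            min_sweep=self.min_sweep,
            max_sweep=self.max_sweep,
            min_spikes=self.min_spikes,
        )

    def fit(self, X, y=None, unit_id: int = 0):
        X = np.asarray(X, dtype=float).ravel()
        params = self._params()
        self.grid_, self.density_ = firing_rate_analogue(X, params)
        self.sweeps_ = detect_sweeps(self.grid_, self.density_, X, params, unit_id=unit_id)
        return self


class PlaceFieldClusterer(BaseEstimator):
    """Curate sweeps and cluster them into place fields.

    ``fit`` takes a list of :class:`Sweep` from one unit.  ``labels_`` gives
    the field index per input sweep, with -1 for sweeps deleted as spurious.
    """

    def __init__(
        self,
        window_laps: int = 15,
        proximity: float = 15.0,
        min_proximal: int = 3,
        min_spikes: int = 4,
    ):
        self.window_laps = window_laps
        self.proximity = proximity
        self.min_proximal = min_proximal
        self.min_spikes = min_spikes

    def fit(self, X, y=None):
        sweeps = list(X)
        params = DetectionParams(
            window_laps=self.window_laps,
            proximity=self.proximity,
            min_proximal=self.min_proximal,
            min_spikes=self.min_spikes,
        )
        self.fields_ = filter_and_cluster(sweeps, params)
        key_to_label = {
            (s.start, s.end): f.field_id for f in self.fields_ for s in f.sweeps
        }
        self.labels_ = np.array(
            [key_to_label.get((s.start, s.end), -1) for s in sweeps]
        )
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
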