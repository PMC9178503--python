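"""Clock synchronization via pulse-train alignment, and latency estimation.

Two acquisition systems record the same randomized TTL pulse train on
unsynchronized clocks.  Because the absolute offset between clocks is
unknown, the alignment operates on the inter-pulse-interval sequences: the
Needleman-Wunsch global alignment matches intervals whose durations agree,
tolerating dropped and spurious pulses as gaps.  The matched onset pairs
then determine the affine clock map (offset + slope) by least squares.

Feedback latency is estimated separately, as the lag maximizing the
normalized cross-correlation between an input motion (the tracked head
marker) and the output motion (the projected cue), with parabolic
sub-sample refinement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .simulate import PulseTrain

__all__ = [
    "ClockMap",
    "AlignmentResult",
    "align_pulse_trains",
    "fit_clock_map",
    "apply_clock_map",
    "estimate_latency",
    "ClockSynchronizer",
    "LatencyEstimator",
]


@dataclass(frozen=True)
class ClockMap:
    """Affine mapping between two clocks: b = offset + slope * a."""

    offset: float
    slope: float
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be positive")

    def inverse(self) -> "ClockMap":
        return ClockMap(
            offset=-self.offset / self.slope,
            slope=1.0 / self.slope,
            residual_rms=self.residual_rms / self.slope,
        )


@dataclass
class AlignmentResult:
    """Monotone matching between two pulse trains."""

    pairs: list[tuple[int, int]]  # onset index pairs, strictly increasing
    score: float
    unmatched_a: int
    unmatched_b: int


def _nw_align_intervals(
    da: np.ndarray,
    db: np.ndarray,
    gap_penalty: float,
    interval_tolerance: float,
) -> tuple[float, list[tuple[int, int]]]:
    """Needleman-Wunsch on two interval sequences.

    Match score is -|da_i - db_j| / interval_tolerance; gaps cost
    `gap_penalty` each.  Ties break toward a match, then toward consuming
    `a` first, making the traceback deterministic.
    """
    n, m = len(da), len(db)
    score = np.zeros((n + 1, m + 1))
    score[1:, 0] = gap_penalty * np.arange(1, n + 1)
    score[0, 1:] = gap_penalty * np.arange(1, m + 1)
    move = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    move[1:, 0] = 1
    move[0, 1:] = 2
    for i in range(1, n + 1):
        sub = -np.abs(da[i - 1] - db) / interval_tolerance
        row = score[i]
        prev = score[i - 1]
        for j in range(1, m + 1):
            diag = prev[j - 1] + sub[j - 1]
            up = prev[j] + gap_penalty
            left = row[j - 1] + gap_penalty
            best = diag
            mv = 0
            if up > best:
                best, mv = up, 1
            if left > best:
                best, mv = left, 2
            row[j] = best
            move[i, j] = mv
    pairs = []
    i, j = n, m
    while i > 0 or j > 0:
        mv = move[i, j]
        if mv == 0:
            pairs.append((i - 1, j - 1))
            i -= 1
            j -= 1
        elif mv == 1:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return float(score[n, m]), pairs


def align_pulse_trains(
    a: PulseTrain,
    b: PulseTrain,
    gap_penalty: float = -1.0,
    interval_tolerance: float = 1.0,
) -> AlignmentResult:
    """Globally align two pulse trains recorded on different clocks.

    The inter-pulse-interval sequences are aligned by Needleman-Wunsch;
    each matched interval pair (i, j) pairs onsets (i, j) and
    (i+1, j+1).  Returns the monotone onset matching, the alignment score,
    and per-side unmatched counts.
    """
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each pulse train needs at least 2 pulses")
    da, db = np.diff(a.onsets), np.diff(b.onsets)
    score, interval_pairs = _nw_align_intervals(
        da, db, gap_penalty, interval_tolerance
    )
    onset_pairs: list[tuple[int, int]] = []
    for i, j in interval_pairs:
        for p in ((i, j), (i + 1, j + 1)):
            if not onset_pairs or (
                p[0] > onset_pairs[-1][0] and p[1] > onset_pairs[-1][1]
            ):
                onset_pairs.append(p)
    matched_a = {p[0] for p in onset_pairs}
    matched_b = {p[1] for p in onset_pairs}
    return AlignmentResult(
        pairs=onset_pairs,
        score=score,
        unmatched_a=len(a) - len(matched_a),
        unmatched_b=len(b) - len(matched_b),
    )


def fit_clock_map(
    result: AlignmentResult, a: PulseTrain, b: PulseTrain
) -> ClockMap:
    """Least-squares affine clock map b = offset + slope * a over matches."""
    if len(result.pairs) < 2:
        raise ValueError("need at least 2 matched pairs to fit a clock map")
    ta = np.array([a.onsets[i] for i, _ in result.pairs])
    tb = np.array([b.onsets[j] for _, j in result.pairs])
    slope, offset = np.polyfit(ta, tb, 1)
    resid = tb - (offset + slope * ta)
    return ClockMap(
        offset=float(offset),
        slope=float(slope),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def apply_clock_map(times, cmap: ClockMap):
    """Map timestamps from clock a to clock b."""
    return cmap.offset + cmap.slope * np.asarray(times, dtype=float)


# ---------------------------------------------------------------------------
# latency


def estimate_latency(
    input_motion: np.ndarray,
    output_motion: np.ndarray,
    rate: float,
    max_lag: float = 0.5,
) -> float:
    """Feedback latency (s) as the peak of the normalized cross-correlation.

    The sign of the correlation is corrected first (the cue moves opposite
    to the animal at gains above 1), the integer-sample lag maximizing the
    correlation within `max_lag` is found, and the estimate is refined to
    sub-sample resolution by parabolic interpolation of the correlation
    peak.  A positive latency means the output lags the input.
    """
    x = np.asarray(input_motion, dtype=float)
    y = np.asarray(output_motion, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("latency undefined for a flat series")
    x = (x - x.mean()) / x.std()
    y = (y - y.mean()) / y.std()
    n = len(x)
    corr = np.correlate(y, x, mode="full") / n  # index n-1 <-> zero lag
    lags = np.arange(-(n - 1), n)
    max_samples = int(round(max_lag * rate))
    window = np.abs(lags) <= max_samples
    c = corr[window]
    l = lags[window]
    sign = np.sign(c[np.argmax(np.abs(c))]) or 1.0
    c = sign * c
    k = int(np.argmax(c))
    lag = float(l[k])
    if 0 < k < len(c) - 1:  # parabolic sub-sample refinement
        denom = c[k - 1] - 2 * c[k] + c[k + 1]
        if denom != 0:
            lag += 0.5 * (c[k - 1] - c[k + 1]) / denom
    return lag / rate


# ---------------------------------------------------------------------------
# estimators


class ClockSynchronizer(BaseEstimator):
    """Fit an affine clock map from two recordings of one TTL pulse train.

    ``fit(a, b)`` aligns the trains and fits the map; ``transform`` maps
    clock-a timestamps onto clock b, ``inverse_transform`` the reverse.

    Attributes
    ----------
    alignment_ : AlignmentResult
    clock_map_ : ClockMap
    offset_, slope_, residual_rms_ : float
    """

    def __init__(self, gap_penalty: float = -1.0, interval_tolerance: float = 1.0):
        self.gap_penalty = gap_penalty
        self.interval_tolerance = interval_tolerance

    def fit(self, X, y=None):
        a, b = X if y is None else (X, y)
        if not isinstance(a, PulseTrain):
            a = PulseTrain(onsets=np.asarray(a, dtype=float))
        if not isinstance(b, PulseTrain):
            b = PulseTrain(onsets=np.asarray(b, dtype=float))
        self.alignment_ = align_pulse_trains(
            a, b, self.gap_penalty, self.interval_tolerance
        )
        self.clock_map_ = fit_clock_map(self.alignment_, a, b)
        self.offset_ = self.clock_map_.offset
        self.slope_ = self.clock_map_.slope
        self.residual_rms_ = self.clock_map_.residual_rms
        return self

    def transform(self, X):
        return apply_clock_map(X, self.clock_map_)

    def inverse_transform(self, X):
        return apply_clock_map(X, self.clock_map_.inverse())


class LatencyEstimator(BaseEstimator):
    """Cross-correlation latency estimator for co-sampled motion series.

    ``fit(X, y)`` with X the input motion and y the delayed output motion
    sets ``latency_`` in seconds.
    """

    def __init__(self, rate: float = 45.0, max_lag: float = 0.5):
        self.rate = rate
        self.max_lag = max_lag

    def fit(self, X, y):
        self.latency_ = estimate_latency(
            np.asarray(X, dtype=float).ravel(),
            np.asarray(y, dtype=float).ravel(),
            rate=self.rate,
            max_lag=self.max_lag,
        )
        return self
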