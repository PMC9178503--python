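"""Theta-band LFP filtering, phase extraction, and phase precession.

The hippocampal theta rhythm (6-12 Hz) organizes place-cell spike timing:
as the animal advances through a place field, spikes occur at progressively
earlier theta phases (phase precession).  This module extracts instantaneous
theta phase from an LFP trace (band-pass filter + analytic signal),
interpolates phase to spike times, and accumulates 2-D histograms of spike
phase against normalized position within a sweep.

Phase convention: 0 degrees at the peaks of the filtered signal, enforced
by shifting the analytic phase so its circular mean at detected signal
peaks is zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import optimize, signal
from sklearn.base import BaseEstimator, TransformerMixin

from .detection import PlaceField, Sweep
from .simulate import LFP

__all__ = [
    "PhaseSeries",
    "downsample",
    "bandpass_theta",
    "instantaneous_phase",
    "spike_phases",
    "precession_histogram",
    "precession_slope",
    "ThetaPhaseExtractor",
]

THETA_BAND = (6.0, 12.0)
FILTER_ORDER = 15  # design order of the Butterworth band-pass prototype


@dataclass
class PhaseSeries:
    """Continuous (unwrapped) theta phase in degrees over time."""

    time: np.ndarray
    phase_unwrapped: np.ndarray  # degrees, monotone for band-limited input

    @property
    def wrapped(self) -> np.ndarray:
        """Phase wrapped into (-180, 180]."""
        return wrap_phase(self.phase_unwrapped)


def wrap_phase(phase_deg):
    """Wrap phase into (-180, 180]."""
    return -((-np.asarray(phase_deg, dtype=float) + 180.0) % 360.0 - 180.0)


def downsample(lfp: LFP, target_rate: float = 250.0) -> LFP:
    """Anti-aliased resampling to `target_rate` (polyphase filtering)."""
    if target_rate > lfp.rate:
        raise ValueError("target rate exceeds source rate")
    if target_rate == lfp.rate:
        return lfp
    frac = Fraction(target_rate / lfp.rate).limit_denominator(10000)
    values = signal.resample_poly(lfp.values, frac.numerator, frac.denominator)
    t0 = float(lfp.time[0]) if lfp.time is not None else 0.0
    time = t0 + np.arange(len(values)) / target_rate
    return LFP(values=values, rate=target_rate, time=time)


def bandpass_theta(
    lfp: LFP,
    band: tuple[float, float] = THETA_BAND,
    order: int = FILTER_ORDER,
) -> LFP:
    """Zero-phase Butterworth band-pass to the theta band.

    The filter is designed at the given prototype order and realized as
    cascaded second-order sections for numerical stability; zero group
    delay comes from forward-backward application.
    """
    if lfp.rate < 100:
        raise ValueError("sample rate must be at least 100 Hz")
    sos = signal.butter(order, band, btype="bandpass", fs=lfp.rate, output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1)
    if len(lfp.values) <= 3 * padlen:
        raise ValueError("signal too short for the band-pass filter to settle")
    values = signal.sosfiltfilt(sos, lfp.values)
    return LFP(values=values, rate=lfp.rate, time=lfp.time)


def instantaneous_phase(filtered: LFP, min_peak_separation_hz: float = 12.0) -> PhaseSeries:
    """Theta phase as the angle of the analytic signal, 0 deg at peaks.

    After the Hilbert construction the phase is shifted by a constant so
    that the circular mean phase at local maxima of the filtered signal is
    zero (peak separation constrained by the upper band edge).
    """
    x = filtered.values
    if np.ptp(x) == 0:
        raise ValueError("phase undefined for a constant signal")
    analytic = signal.hilbert(x)
    phase = np.degrees(np.angle(analytic))
    phase_unwrapped = np.unwrap(phase, period=360.0)
    peaks, _ = signal.find_peaks(
        x, distance=max(1, int(filtered.rate / min_peak_separation_hz))
    )
    if peaks.size:
        mean_at_peaks = np.angle(np.mean(np.exp(1j * np.radians(phase[peaks]))))
        phase_unwrapped = phase_unwrapped - np.degrees(mean_at_peaks)
    return PhaseSeries(time=np.asarray(filtered.time), phase_unwrapped=phase_unwrapped)


def spike_phases(phases: PhaseSeries, spike_times: np.ndarray) -> np.ndarray:
    """Theta phase at each spike, by interpolation on the unwrapped phase.

    Interpolating the unwrapped phase avoids +-180 deg wrap artifacts near
    cycle boundaries; the result is wrapped into (-180, 180].
    """
    t = np.asarray(spike_times, dtype=float)
    if t.size and (t.min() < phases.time[0] or t.max() > phases.time[-1]):
        raise ValueError("spike times outside the phase series span")
    ph = np.interp(t, phases.time, phases.phase_unwrapped)
    return wrap_phase(ph)


def precession_histogram(
    sweeps: list[Sweep],
    spike_frame_angles: np.ndarray,
    spike_phase_deg: np.ndarray,
    n_pos_bins: int = 20,
    n_phase_bins: int = 36,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """2-D histogram of spike theta phase vs normalized sweep position.

    For every spike falling inside a sweep (unwrapped frame coordinates),
    the x coordinate is (angle - start) / (end - start) in [0, 1] and the y
    coordinate is its theta phase.  Returns (hist, pos_edges, phase_edges,
    n_unassigned) where hist has shape (n_pos_bins, n_phase_bins) and
    n_unassigned counts spikes outside every sweep.
    """
    ang = np.asarray(spike_frame_angles, dtype=float)
    ph = np.asarray(spike_phase_deg, dtype=float)
    if ang.shape != ph.shape:
        raise ValueError("angles and phases must align")
    xs, ys = [], []
    assigned = np.zeros(len(ang), dtype=bool)
    for s in sweeps:
        inside = (ang >= s.start) & (ang <= s.end)
        if s.end > s.start:
            xs.append((ang[inside] - s.start) / (s.end - s.start))
            ys.append(ph[inside])
            assigned |= inside
    x = np.concatenate(xs) if xs else np.empty(0)
    y = np.concatenate(ys) if ys else np.empty(0)
    pos_edges = np.linspace(0.0, 1.0, n_pos_bins + 1)
    phase_edges = np.linspace(-180.0, 180.0, n_phase_bins + 1)
    hist, _, _ = np.histogram2d(x, y, bins=(pos_edges, phase_edges))
    return hist, pos_edges, phase_edges, int((~assigned).sum())


def precession_slope(
    norm_positions: np.ndarray, phase_deg: np.ndarray
) -> tuple[float, float]:
    """Circular-linear regression of spike phase on normalized position.

    Fits phase = slope * x + intercept by maximizing the mean resultant
    length of the circular residuals; slope is in degrees of theta phase
    per unit of normalized sweep extent.  Returns (slope, mean resultant
    length at the optimum).
    """
    x = np.asarray(norm_positions, dtype=float)
    ph = np.radians(np.asarray(phase_deg, dtype=float))
    if x.size < 4:
        raise ValueError("need at least 4 spikes for a slope fit")

    def neg_resultant(slope_deg: float) -> float:
        r = ph - np.radians(slope_deg) * x
        return -np.abs(np.mean(np.exp(1j * r)))

    grid = np.linspace(-720.0, 720.0, 289)
    best = grid[int(np.argmin([neg_resultant(s) for s in grid]))]
    res = optimize.minimize_scalar(
        neg_resultant, bounds=(best - 10.0, best + 10.0), method="bounded"
    )
    return float(res.x), float(-res.fun)


class ThetaPhaseExtractor(BaseEstimator, TransformerMixin):
    """End-to-end theta phase extraction as a scikit-learn transformer.

    ``fit`` takes an :class:`~gaintrack.simulate.LFP`; ``transform`` maps
    spike times to theta phases in degrees.

    Attributes
    ----------
    filtered_ : LFP
        Band-passed (and, if needed, downsampled) LFP.
    phases_ : PhaseSeries
        Instantaneous theta phase.
    """

    def __init__(
        self,
        target_rate: float = 250.0,
        band: tuple[float, float] = THETA_BAND,
        order: int = FILTER_ORDER,
    ):
        self.target_rate = target_rate
        self.band = band
        self.order = order

    def fit(self, X: LFP, y=None):
        lfp = X
        if lfp.rate > self.target_rate:
            lfp = downsample(lfp, self.target_rate)
        self.filtered_ = bandpass_theta(lfp, band=self.band, order=self.order)
        self.phases_ = instantaneous_phase(self.filtered_)
        return self

    def transform(self, X) -> np.ndarray:
        return spike_phases(self.phases_, np.asarray(X, dtype=float).ravel())
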