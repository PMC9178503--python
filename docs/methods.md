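# Methods

This note records the models, conventions, numerical choices, and known
limitations behind `gaintrack`, in the spirit of a package methods
appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Reference frames and the experiment gain

Positions on the circular track are angles. The canonical representation
is the *unwrapped* angle in degrees (laps × 360 + wrapped angle); wrapped
angles in [0, 360) are derived views. All public thresholds are quoted in
degrees because that is how the field reports them.

The experiment gain `G` is the ratio of the animal's displacement in the
cue frame to its displacement in the laboratory frame. It is scheduled as
a function of laboratory *distance run* (laps), not time: the ramp rate is
fixed per lap, so session duration depends on how far the final gain is
from 1, matching the behavior of the original protocol. The schedule is
continuous and piecewise linear across four epochs: unity (Epoch 1),
linear ramp (Epoch 2), hold at `final_gain` (Epochs 3–4). Epoch 4 toggles
cue visibility only; gain bookkeeping continues.

The cue-frame trajectory is the path integral `θ_f(t) = θ_f(0) + ∫ G dθ_lab`,
evaluated by trapezoidal accumulation over trajectory samples. This is
exact for constant-gain stretches and exact to sampling resolution across
the ramp (the integrand is piecewise linear in distance). Cue rotation is
defined as `φ = θ_lab − θ_frame`, so at `G > 1` the cues rotate opposite
to the running direction; positive angles increase in the running
direction throughout.

The latency error budget is closed-form: a feedback latency `τ` displaces
the projected scene by `angular speed × |1 − G| × τ` degrees, an arc of
`radius × θ·π/180` at the dome surface. The two extreme manipulations
`G = 0` and `G = 2` are symmetric under `|1 − G|`.

## Synthetic sessions

The simulator produces the complete data a recorded session would yield,
with ground truth retained, so every analysis stage is testable without
any recorded data.

**Behavior.** Run/pause locomotion at a 50 Hz camera-rate analogue.
Running speed is drawn per run bout from a truncated normal (mean
24.6 cm/s, sd 3 cm/s, floor 5 cm/s); pause onsets are a Poisson process in
lab distance at 0.9 events/lap; pause durations are gamma (shape 2) with
mean 8.8 s. The means are calibrated to the published aggregate behavior
on this apparatus; the distribution families are package choices, since
the published aggregates do not constrain them. (The published inter-pause
columns are not mutually consistent with the pauses-per-lap column at face
value, so the simulator calibrates to velocity, pauses/lap, and pause
duration.)

**Place cells.** Inhomogeneous Poisson spiking by thinning. The tuning
curve is a circular Gaussian `exp(κ(cos Δ − 1))` in the owning frame, with
`κ` chosen so the curve falls to 10% of peak at half the nominal `width` —
the same 10% convention the sweep detector uses. Options: per-lab-lap
center drift, an active-lap window (remapping injection), and theta
modulation `1 + depth·cos(φ_theta − φ_pref(x))` where the preferred phase
falls linearly by `precession_span` degrees across the normalized field
extent. A session seed spawns independent substreams per component and per
unit, so sessions are bit-reproducible and a unit's spikes do not change
when other units are added.

**LFP.** A sinusoid at the theta frequency (default 8 Hz; a per-sample
frequency array is accepted) plus white noise, at 250 Hz, with the exact
phase retained as ground truth. Where a test quotes an SNR it means
RMS(signal) / RMS(broadband noise) before any filtering.

**Sync pulses.** Exponential inter-pulse intervals with mean 10 s,
truncated below at pulse width + 0.5 s so pulses never overlap; the
memoryless choice makes alignment maximally hard at a given mean.
`corrupt_clock` re-expresses a train on a second clock
(`t' = offset + (1+drift)·t + jitter`, with drops and spurious
insertions) and returns the true correspondence for scoring.

What the simulator does *not* emulate: bursting and refractoriness,
interneurons, speed-dependent theta frequency, non-place cells, 2-D
foraging, and electrode artifacts. Passing tests therefore demonstrate
correctness of the analysis pipeline on its stated model, not performance
on every pathology of real recordings.

## Sweep detection and field construction

Spike angles in the unwrapped cue frame are the input. Spikes while the
animal moves at ≤ 5 cm/s are excluded first — the same speed gate the rate
maps use. This is a package decision: place-cell firing during pauses
piles up at a single angle and otherwise distorts the density profile that
defines sweep boundaries.

The firing-rate analogue is a Gaussian KDE sampled on a 0.5° grid
(bandwidth 8°), computed by binning and FFT convolution (error ≪ bin
width), spanning the spike range padded by three bandwidths. Densities
below 1e-9 of the maximum are zeroed: FFT roundoff otherwise seeds
spurious local maxima whose *relative* thresholds are meaninglessly low.

For each local maximum, the sweep is the maximal contiguous interval
around it with density above 10% of **that peak's** density. The
alternative global-maximum reading would erase legitimate low-rate fields
of multi-field cells; with the per-peak reading, overlapping threshold
regions from multiple peaks merge into a single sweep. Sweeps outside
5–120° are discarded. A sweep's center is its geometric midpoint; its lap
is the frame lap containing the center.

Note a deliberate property of this definition: the detected 10%-width of a
field whose true 10%-width is `w` is inflated by the kernel to roughly
`2·sqrt(2 ln 10)·sqrt(σ² + bw²)` (≈ 53° for a 40° field at bandwidth 8).
The inflation is identical in the cue and lab measurements of the same
sweep, so it cancels in the scaling factor `f_p`.

Curation deletes any sweep with fewer than 4 spikes or fewer than 3
proximal sweeps — proximity meaning another sweep's center within 15° in
wrapped cue coordinates *and* within the 15-lap window centered on the
sweep's lap, excluding its own lap. Deletion is applied simultaneously to
all failing sweeps and iterated to a fixpoint; like a k-core, the
surviving set is unique, which makes the result independent of input
order (the published description iterates in an unspecified order).
Survivors are partitioned into connected components of the proximity
graph; each component is a place field, and every member is then proximal
to at least two other members. The 15-lap window is counted in cue-frame
laps, where sweeps live. A curation merge operation unions over-segmented
fields without re-checking the invariant, mirroring the manual step.

Each sweep's gain `g_p` is the mean of the experiment gain at its start
and end, and its lab extent comes from mapping the sweep boundaries back
through the trajectory (the frame→lab map is inverted by interpolation on
the monotone frame trajectory). Fields are binned into gain ranges by the
`g_p` of their last sweep; the default edges (0, 0.6, 0.9, 1.1, 1.4, 2.0)
fix only the published lowest bin, the rest are package defaults.

## Field metrics

Rate maps use 72 bins of 5°, occupancy and spikes gated at speed > 5 cm/s.
When a trajectory carries no speed channel, speed is derived by central
differences with 0.25 s boxcar smoothing. The mean rate `λ` is the
occupancy-weighted grand mean (total spikes / total gated time).

The spatial information score is implemented exactly as printed in the
source protocol, `(1/B) Σ λᵢ log₂(λᵢ/λ)` with zero-rate bins contributing
zero; note this differs from the conventional occupancy-weighted
bits-per-spike score, which is provided separately as
`spatial_information_per_spike` for comparison with the wider literature.

Reliability `r_p` is the fraction of cue-frame laps with at least one
sweep of the field — exact integer arithmetic. The scaling factor
`f_p = mean lab-frame sweep size in Epoch 1 / lab-frame size of the sweep`;
the lab-frame reading of both terms is what makes the `f_p` vs `g_p`
scatter land on the unity line for cue-locked fields. Drift
`d_p = ang(m_end, m_start) / lab laps run`, with `m_start`/`m_end` the
circular means of the first/last three sweep centers and `ang` the signed
wrapped difference in (−180°, 180°] — signed, because drift direction
carries the science (negative at low gains, positive at high).

Statistical noise floor: with a 15 Hz-peak, 40°-wide field crossed at
~25 cm/s, a sweep contains roughly 16 spikes, and the KDE
threshold-crossing noise puts an irreducible ~13% standard deviation on
individual sweep extents. Per-sweep `f_p` therefore scatters around `g_p`
with median absolute deviation ≈ 0.1 at gain 1.5, while the *median
signed* deviation (the unity-line bias) is ≈ 0.01. Tightening the
per-sweep scatter requires proportionally brighter cells, not algorithm
changes.

## Theta analysis

The LFP is resampled to 250 Hz (polyphase, anti-aliased) and band-passed
to 6–12 Hz with a Butterworth design of prototype order 15, applied
forward-backward for zero phase. The filter is realized as cascaded
second-order sections: a transfer-function realization of that order is
numerically unstable at 250 Hz, and the SOS realization meets the same
frequency response (verified in tests: ≥ 95% passband transmission at
8 Hz, ≥ 20 dB attenuation at 2 and 25 Hz, zero lag).

Phase is the angle of the analytic signal (Hilbert construction), then
shifted by a constant so the circular mean phase at local maxima of the
filtered trace (minimum separation one cycle at 12 Hz) is 0°. Spike
phases are interpolated on the *unwrapped* phase and wrapped afterwards,
avoiding ±180° artifacts near cycle boundaries.

Precession histograms accumulate spike phase against
`(angle − sweep start)/(sweep extent)` over all sweeps; spikes outside
every sweep are counted and reported, not silently dropped. The
circular–linear slope fit maximizes the mean resultant length of the
residuals over a slope grid with bounded refinement. Recovery tests
normalize position by the *true* field extent from the simulator: the KDE
broadening above stretches the sweep-normalized axis by a known factor
(≈ 53/40 for the default geometry), which would bias a slope compared
against the injected span; the sweep-normalized histogram itself is the
figure convention and is unchanged.

## Synchronization and latency

Because the unknown clock offset makes absolute onset times incomparable,
the Needleman–Wunsch alignment operates on the two inter-pulse-interval
sequences: match score `−|Δinterval| / tolerance` (default tolerance 1 s),
gap penalty −1, ties broken toward a match and then toward consuming the
first train — fully deterministic. Matched interval pairs (i, j) imply
onset pairs (i, j) and (i+1, j+1); the monotone union of these is the
returned correspondence. On instances small enough to enumerate, the DP
score equals exhaustive search over all monotone matchings (tested). The
once-per-lap hall-effect backup pulse is just a second pulse train, not a
separate code path.

The clock map `b ≈ offset + slope·a` is ordinary least squares over the
matched onsets, with the residual RMS reported so outliers are visible.
Under the simulator's stress conditions (offset up to ±10 s, drift up to
±1e-4, 2 ms jitter, 5% drops over 600 s) the median offset error across
50 seeds is below 5 ms (tested).

Latency is the lag maximizing the normalized cross-correlation of the
input (tracked marker) and output (projected cue) motion, after sign
correction — the cue counter-rotates at gains above 1 — with parabolic
sub-sample refinement around the integer-lag peak. The test signal is
band-limited (0.2–2 Hz) stationary motion, emulating a hand-moved marker
crown; with it, a 105 ms delay is recovered within one camera frame at
every tested frame rate from 30 to 90 Hz, reproducing the
frame-rate-independence property of the measurement.

## Problem sizes

The test suite simulates one 40-lap, 5-cell session (the standard
fixture, ~18 minutes of behavior), several 10–20 lap single-cell
sessions, 60 s LFP segments, and 600 s pulse trains × 50 seeds; the whole
suite runs in a few seconds on one CPU. These sizes were chosen to give
each statistical assertion comfortable power at its stated tolerance.

## Known limitations

- Sweep extents inherit the KDE bandwidth; absolute field sizes are
  broadened by a known, cancellable factor, and per-sweep size noise
  scales as the inverse square root of spikes per pass.
- Fields centered exactly on the lap seam (0°/360°) get their per-lap
  sweep labels split between adjacent lap indices, deflating `r_p`; place
  field centers are continuous in reality, so the seam case is a measure-
  zero nuisance handled by convention (lap of the sweep center).
- The unwrap convention assumes < 180° between consecutive samples; at the
  45–90 Hz tracking rates of this apparatus that allows angular speeds far
  above anything a rat produces.
- `filter_and_cluster` expects single-unit input; cross-unit clustering is
  rejected, not merged.
- The latency estimator assumes co-sampled, jointly stationary series; a
  drifting camera clock should be corrected with the clock map first.
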