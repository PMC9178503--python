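"""Sweep detection, curation, and clustering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gaintrack as gt
from gaintrack.detection import DetectionParams, Sweep, _proximal_matrix


def make_sweep(center, lap=None, n_spikes=10, width=20.0, unit=0):
    """Sweep at a wrapped center on a given frame lap."""
    if lap is None:
        lap = int(center // 360)
        center = center % 360
    start = lap * 360.0 + center - width / 2
    return Sweep(unit_id=unit, start=start, end=start + width, spike_count=n_spikes)


# ---------------------------------------------------------------------------
# firing-rate analogue


class TestFiringRateAnalogue:
    def test_single_spike_peaks_at_spike(self):
        grid, dens = gt.firing_rate_analogue(np.array([100.0]))
        assert grid[np.argmax(dens)] == pytest.approx(100.0, abs=0.5)
        assert np.all(dens >= 0)

    def test_integrates_to_one(self):
        rng = np.random.default_rng(0)
        grid, dens = gt.firing_rate_analogue(rng.uniform(0, 720, 200))
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)

    def test_two_clusters_give_two_modes_at_means(self):
        rng = np.random.default_rng(1)
        a = rng.normal(100.0, 2.0, 300)
        b = rng.normal(160.0, 2.0, 300)
        grid, dens = gt.firing_rate_analogue(np.concatenate([a, b]))
        # direct KDE oracle on the same grid
        oracle = np.zeros_like(grid)
        for x in np.concatenate([a, b]):
            oracle += np.exp(-0.5 * ((grid - x) / 8.0) ** 2)
        oracle /= oracle.sum() * 0.5
        np.testing.assert_allclose(dens, oracle, atol=1e-4)
        from scipy.signal import find_peaks

        peaks = grid[find_peaks(dens)[0]]
        big = peaks[dens[np.searchsorted(grid, peaks)] > 0.2 * dens.max()]
        assert len(big) == 2
        assert abs(big[0] - a.mean()) < 1.0 and abs(big[1] - b.mean()) < 1.0

    def test_uniform_spikes_are_flat_inside(self):
        rng = np.random.default_rng(2)
        grid, dens = gt.firing_rate_analogue(rng.uniform(0, 3600, 20000))
        interior = (grid > 100) & (grid < 3500)
        cv = dens[interior].std() / dens[interior].mean()
        assert cv < 0.1

    def test_empty_input_gives_empty_result(self):
        grid, dens = gt.firing_rate_analogue(np.empty(0))
        assert grid.size == 0 and dens.size == 0


# ---------------------------------------------------------------------------
# sweep boundaries


class TestDetectSweeps:
    @staticmethod
    def _detect(spikes, **kw):
        params = DetectionParams(**kw) if kw else DetectionParams()
        grid, dens = gt.firing_rate_analogue(spikes, params)
        return gt.detect_sweeps(grid, dens, spikes, params)

    def test_per_lap_field_yields_one_sweep_per_lap(self):
        # noiseless 40-degree field crossed on 20 laps
        rng = np.random.default_rng(3)
        spikes = np.concatenate(
            [lap * 360.0 + 180.0 + rng.normal(0, 9.3, 25) for lap in range(20)]
        )
        sweeps = self._detect(np.sort(spikes))
        assert len(sweeps) == 20
        for s in sweeps:
            assert 30.0 <= s.extent <= 80.0
            assert s.spike_count >= 20

    def test_narrow_field_rejected_by_size_gate(self):
        # all spikes at nearly one angle: KDE width ~ 2*bandwidth exceeds
        # min_sweep, so shrink the bandwidth to exercise the gate
        spikes = np.sort(np.random.default_rng(4).normal(100.0, 0.3, 50))
        sweeps = self._detect(spikes, kde_bandwidth=1.0, min_sweep=5.0)
        assert sweeps == []

    def test_wide_field_rejected_by_size_gate(self):
        spikes = np.sort(np.random.default_rng(5).uniform(0.0, 150.0, 400))
        sweeps = self._detect(spikes)
        assert all(s.extent <= 120.0 for s in sweeps)
        # the dominant threshold region spans ~150 degrees -> discarded
        assert not any(s.spike_count > 200 for s in sweeps)

    def test_sweep_center_is_geometric_midpoint(self):
        rng = np.random.default_rng(6)
        sweeps = self._detect(np.sort(rng.normal(500.0, 9.0, 60)))
        (s,) = sweeps
        assert s.center == pytest.approx((s.start + s.end) / 2)


# ---------------------------------------------------------------------------
# curation + clustering


def oracle_filter(sweeps, params):
    """One-at-a-time deletion to fixpoint, in the given order, repeated.

    Independent reference for the simultaneous-deletion fixpoint: the
    surviving set is the unique maximal subset where every sweep has at
    least `min_proximal` proximal companions and `min_spikes` spikes.
    """
    current = [s for s in sweeps if s.spike_count >= params.min_spikes]
    changed = True
    while changed:
        changed = False
        for i, s in enumerate(current):
            prox = _proximal_matrix(current, params)
            if prox[i].sum() < params.min_proximal:
                current.pop(i)
                changed = True
                break
    return current


class TestFilterAndCluster:
    def test_stable_field_with_strays(self):
        # 25 proximal sweeps + 2 strays 90 degrees away -> one field
        sweeps = [make_sweep(180.0, lap=k) for k in range(25)]
        sweeps += [make_sweep(270.0, lap=5), make_sweep(270.0, lap=30)]
        fields = gt.filter_and_cluster(sweeps)
        assert len(fields) == 1
        assert fields[0].n_sweeps == 25

    def test_two_isolated_sweeps_give_no_fields(self):
        sweeps = [make_sweep(100.0, lap=0), make_sweep(100.0, lap=1)]
        assert gt.filter_and_cluster(sweeps) == []

    def test_two_fields_far_apart_are_separated(self):
        a = [make_sweep(60.0, lap=k) for k in range(12)]
        b = [make_sweep(180.0, lap=k) for k in range(12)]
        fields = gt.filter_and_cluster(a + b)
        assert len(fields) == 2
        assert sorted(f.n_sweeps for f in fields) == [12, 12]
        centers = sorted(f.wrapped_center for f in fields)
        assert centers[0] == pytest.approx(60.0, abs=1.0)
        assert centers[1] == pytest.approx(180.0, abs=1.0)

    def test_low_spike_sweeps_deleted(self):
        sweeps = [make_sweep(180.0, lap=k, n_spikes=3) for k in range(20)]
        assert gt.filter_and_cluster(sweeps) == []

    def test_remapping_window_limits_proximity(self):
        # two bursts of activity at the same angle but 30 laps apart are
        # separate fields: the 15-lap window cannot connect them
        early = [make_sweep(90.0, lap=k) for k in range(8)]
        late = [make_sweep(90.0, lap=40 + k) for k in range(8)]
        fields = gt.filter_and_cluster(early + late)
        assert len(fields) == 2

    @given(st.permutations(list(range(18))))
    @settings(deadline=None, max_examples=25)
    def test_order_independence(self, order):
        rng = np.random.default_rng(7)
        base = [
            make_sweep(float(rng.uniform(0, 360)), lap=int(rng.integers(0, 20)),
                       n_spikes=int(rng.integers(2, 12)))
            for _ in range(18)
        ]
        shuffled = [base[i] for i in order]
        f1 = gt.filter_and_cluster(base)
        f2 = gt.filter_and_cluster(shuffled)
        key = lambda fields: sorted(
            tuple(sorted((s.start, s.end) for s in f.sweeps)) for f in fields
        )
        assert key(f1) == key(f2)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_one_at_a_time_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 28))
        sweeps = [
            make_sweep(float(rng.uniform(0, 360)), lap=int(rng.integers(0, 25)),
                       n_spikes=int(rng.integers(2, 10)))
            for _ in range(n)
        ]
        params = DetectionParams()
        survivors = oracle_filter(sweeps, params)
        got = [s for f in gt.filter_and_cluster(sweeps, params) for s in f.sweeps]
        assert sorted((s.start, s.end) for s in got) == sorted(
            (s.start, s.end) for s in survivors
        )


class TestMergeFields:
    def _fields(self):
        a = [make_sweep(60.0, lap=k) for k in range(10)]
        b = [make_sweep(95.0, lap=10 + k) for k in range(10)]
        return gt.filter_and_cluster(a + b)

    def test_merge_unions_sweeps(self):
        fields = self._fields()
        assert len(fields) == 2
        merged = gt.merge_fields(fields, [f.field_id for f in fields])
        assert len(merged) == 1
        assert merged[0].n_sweeps == 20

    def test_merge_with_itself_is_identity(self):
        fields = self._fields()
        out = gt.merge_fields(fields, [fields[0].field_id])
        assert len(out) == 2
        assert out[0].n_sweeps == fields[0].n_sweeps

    def test_cross_unit_merge_rejected(self):
        a = [make_sweep(60.0, lap=k, unit=0) for k in range(10)]
        b = [make_sweep(180.0, lap=k, unit=1) for k in range(10)]
        fa = gt.filter_and_cluster(a)
        fb = gt.filter_and_cluster(b)
        fb[0].field_id = 1
        with pytest.raises(ValueError):
            gt.merge_fields(fa + fb, [0, 1])


# ---------------------------------------------------------------------------
# sweep gain


class TestSweepGain:
    def _traj(self, laps=30):
        t = np.arange(0.0, laps * 18.0, 0.02)
        return gt.AngularTrajectory(time=t, lab_angle_unwrapped=20.0 * t)

    def test_constant_gain_epoch(self):
        p = gt.GainProfile(epoch_laps=(0, 0, 30, 0), final_gain=1.5)
        s = Sweep(unit_id=0, start=15 * 360.0, end=15 * 360.0 + 60.0, spike_count=9)
        out = gt.assign_sweep_gain(s, self._traj(), p)
        assert out.g_p == pytest.approx(1.5)
        # landmark extent 60 deg at G=1.5 covers 40 lab degrees
        assert out.lab_extent == pytest.approx(40.0, abs=0.1)

    def test_epoch1_gain_is_one(self):
        p = gt.GainProfile(epoch_laps=(10, 10, 10, 0), final_gain=2.0)
        s = Sweep(unit_id=0, start=3 * 360.0, end=3 * 360.0 + 50.0, spike_count=9)
        out = gt.assign_sweep_gain(s, self._traj(), p)
        assert out.g_p == pytest.approx(1.0)
        assert out.lab_extent == pytest.approx(50.0, abs=0.05)

    def test_ramp_crossing_averages_endpoints(self):
        # gain ramps 1 -> 1.2 over laps 10-20; a sweep whose lab-frame
        # endpoints see gains g1 and g2 gets g_p = (g1+g2)/2
        p = gt.GainProfile(epoch_laps=(10, 10, 10, 0), final_gain=1.2)
        start = gt.lab_to_frame(self._traj(), p).angle_unwrapped
        traj = self._traj()
        # pick the sweep's frame angles from the transformed trajectory
        i0 = np.searchsorted(traj.lab_angle_unwrapped, 15 * 360.0)
        i1 = np.searchsorted(traj.lab_angle_unwrapped, 15 * 360.0 + 40.0)
        s = Sweep(unit_id=0, start=start[i0], end=start[i1], spike_count=9)
        out = gt.assign_sweep_gain(s, traj, p)
        g1 = gt.gain_at(p, traj.lab_angle_unwrapped[i0])
        g2 = gt.gain_at(p, traj.lab_angle_unwrapped[i1])
        assert out.g_p == pytest.approx((g1 + g2) / 2, abs=1e-3)
        assert out.g_p == pytest.approx(1.1, abs=0.01)


class TestGainBin:
    def _field_with_gains(self, gains):
        sweeps = []
        for k, g in enumerate(gains):
            s = make_sweep(180.0, lap=k)
            s.g_p = g
            s.lab_start = k * 360.0
            s.lab_end = k * 360.0 + 30.0
            sweeps.append(s)
        return gt.PlaceField(field_id=0, unit_id=0, sweeps=sweeps)

    def test_lowest_bin(self):
        f = self._field_with_gains([1.0, 0.8, 0.5])
        assert gt.field_gain_bin(f) == 0  # 0 - 0.6 bin

    def test_unity_bin(self):
        f = self._field_with_gains([1.0, 1.0, 1.0])
        edges = gt.detection.DEFAULT_GAIN_BIN_EDGES
        b = gt.field_gain_bin(f)
        assert edges[b] < 1.0 <= edges[b + 1] or edges[b] <= 1.0 < edges[b + 1]

    def test_uses_last_sweep_not_max(self):
        # gain rose to 1.6 mid-session then the field's last sweep was at 1.0
        f = self._field_with_gains([1.0, 1.6, 1.0])
        edges = gt.detection.DEFAULT_GAIN_BIN_EDGES
        b = gt.field_gain_bin(f)
        assert edges[b] <= 1.0 < edges[b + 1]

    def test_overflow_warns(self):
        f = self._field_with_gains([2.5])
        with pytest.warns(UserWarning):
            assert gt.field_gain_bin(f) == len(gt.detection.DEFAULT_GAIN_BIN_EDGES) - 1


# ---------------------------------------------------------------------------
# estimator surface


class TestEstimators:
    def test_sweep_detector_sklearn_surface(self):
        rng = np.random.default_rng(8)
        spikes = np.sort(
            np.concatenate([k * 360 + rng.normal(180, 9, 25) for k in range(8)])
        )
        det = gt.SweepDetector(peak_fraction=0.10)
        assert det.get_params()["kde_bandwidth"] == 8.0
        det.fit(spikes)
        assert len(det.sweeps_) == 8
        labels = gt.PlaceFieldClusterer().fit_predict(det.sweeps_)
        assert set(labels) == {0}

    def test_clusterer_marks_deleted_sweeps(self):
        sweeps = [make_sweep(180.0, lap=k) for k in range(10)]
        sweeps.append(make_sweep(300.0, lap=5))
        labels = gt.PlaceFieldClusterer().fit_predict(sweeps)
        assert labels[-1] == -1
        assert np.all(labels[:-1] == 0)
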