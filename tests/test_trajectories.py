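"""Trajectory I/O, gap handling and displacement extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import smtk
from smtk.trajectories import Trajectory, TrajectorySet, extract_jumps

from conftest import make_track_csv


def make_ts(tracks, dt=0.0044477):
    trajs = [Trajectory(i, f, x, y, dt) for i, (f, x, y) in enumerate(tracks)]
    return TrajectorySet(trajs, frame_interval=dt)


class TestReadTrajectories:
    def test_single_track_identity(self, tmp_path):
        path = make_track_csv(tmp_path, [(0, 0, 0.0, 0.0), (0, 1, 0.1, 0.0), (0, 2, 0.2, 0.0)])
        ts = smtk.read_trajectories(path)
        assert len(ts) == 1
        assert len(ts.trajectories[0]) == 3

    def test_one_frame_gap_kept_as_single_track(self, tmp_path):
        path = make_track_csv(tmp_path, [(0, 0, 0.0, 0.0), (0, 2, 0.1, 0.0)])
        ts = smtk.read_trajectories(path, max_gap=1)
        assert len(ts) == 1
        assert list(ts.trajectories[0].frames) == [0, 2]

    def test_long_gap_splits_track(self, tmp_path):
        path = make_track_csv(tmp_path, [(0, 0, 0.0, 0.0), (0, 3, 0.1, 0.0)])
        ts = smtk.read_trajectories(path, max_gap=1)
        assert len(ts) == 2
        assert all(len(t) == 1 for t in ts)

    def test_non_monotone_frames_rejected(self, tmp_path):
        path = make_track_csv(tmp_path, [(0, 1, 0.0, 0.0), (0, 0, 0.1, 0.0)])
        with pytest.raises(ValueError, match="strictly increasing"):
            smtk.read_trajectories(path)

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("track_id,frame,x_um,y_um\n0,0,0.0,0.0\n0,1,oops,0.0\n")
        with pytest.raises(ValueError, match="line 3"):
            smtk.read_trajectories(path)

    def test_round_trip_is_lossless(self, tmp_path, rng):
        tracks = []
        for _ in range(20):
            n = rng.integers(2, 12)
            tracks.append((np.arange(n), rng.normal(size=n), rng.normal(size=n)))
        ts = make_ts(tracks)
        path = tmp_path / "rt.csv"
        smtk.write_trajectories(ts, path)
        ts2 = smtk.read_trajectories(path)
        assert len(ts2) == len(ts)
        for a, b in zip(ts, ts2):
            assert np.array_equal(a.frames, b.frames)
            assert np.array_equal(a.x, b.x)  # bit-exact
            assert np.array_equal(a.y, b.y)


class TestExtractJumps:
    def test_eight_point_track_jump_counts(self):
        # 8 localizations -> 7 jumps at lag 1, 6 at lag 2, ... 1 at lag 7
        ts = make_ts([(np.arange(8), np.arange(8) * 0.1, np.zeros(8))])
        jd = extract_jumps(ts)
        assert jd.counts == {k: 8 - k for k in range(1, 8)}

    def test_single_jump_length(self):
        ts = make_ts([(np.array([0, 1]), np.array([0.0, 0.1]), np.zeros(2))])
        jd = extract_jumps(ts)
        assert jd.displacements[1] == pytest.approx([0.1])

    def test_truncation_at_eight_localizations(self, rng):
        f = np.arange(20)
        x, y = rng.normal(size=20), rng.normal(size=20)
        long = make_ts([(f, x, y)])
        short = make_ts([(f[:8], x[:8], y[:8])])
        a, b = extract_jumps(long), extract_jumps(short)
        for k in range(1, 8):
            assert np.array_equal(np.sort(a.displacements[k]), np.sort(b.displacements[k]))

    def test_gap_spanning_jump_lands_in_true_lag(self):
        ts = make_ts([(np.array([0, 2]), np.array([0.0, 0.3]), np.zeros(2))])
        jd = extract_jumps(ts)
        assert len(jd.displacements[1]) == 0
        assert jd.displacements[2] == pytest.approx([0.3])

    def test_permutation_invariance(self, rng):
        tracks = [
            (np.arange(n), rng.normal(size=n), rng.normal(size=n))
            for n in rng.integers(2, 10, size=15)
        ]
        a = extract_jumps(make_ts(tracks))
        b = extract_jumps(make_ts(tracks[::-1]))
        for k in range(1, 8):
            assert np.array_equal(np.sort(a.displacements[k]), np.sort(b.displacements[k]))

    @settings(deadline=None, max_examples=25)
    @given(st.integers(min_value=2, max_value=8), st.integers(min_value=0, max_value=10_000))
    def test_jump_count_matches_brute_force(self, length, seed):
        """All-pairs enumeration oracle on a random gapless track."""
        r = np.random.default_rng(seed)
        f = np.arange(length)
        x, y = r.normal(size=length), r.normal(size=length)
        jd = extract_jumps(make_ts([(f, x, y)]))
        expected = {}
        for i in range(length):
            for j in range(i + 1, length):
                expected.setdefault(j - i, []).append(np.hypot(x[j] - x[i], y[j] - y[i]))
        for k in range(1, 8):
            assert np.allclose(
                np.sort(jd.displacements[k]), np.sort(expected.get(k, []))
            )

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            extract_jumps(TrajectorySet([]))


class TestDriftCorrect:
    def make_static_with_drift(self, drift_per_frame, n_frames=200, n_particles=30, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.uniform(0, 10, (n_particles, 2))
        tracks = []
        for i in range(n_particles):
            f = np.arange(n_frames)
            x = base[i, 0] + drift_per_frame[0] * f + rng.normal(0, 0.005, n_frames)
            y = base[i, 1] + drift_per_frame[1] * f + rng.normal(0, 0.005, n_frames)
            tracks.append((f, x, y))
        return make_ts(tracks)

    def test_constant_drift_removed(self):
        ts = self.make_static_with_drift((0.010, 0.0))
        out = smtk.drift_correct(ts, bin_frames=20)
        for t in out:
            assert np.ptp(t.x) < 0.1  # 200 frames x 10 nm = 2 um before correction

    def test_zero_drift_is_identity_up_to_noise(self):
        ts = self.make_static_with_drift((0.0, 0.0))
        out = smtk.drift_correct(ts, bin_frames=20)
        for a, b in zip(ts, out):
            assert np.allclose(a.x, b.x, atol=0.02)

    def test_linear_xy_drift_residual_small(self):
        ts = self.make_static_with_drift((0.008, -0.005), n_frames=1000)
        out = smtk.drift_correct(ts, bin_frames=50)
        injected = np.hypot(0.008, 0.005) * 1000
        residual = max(max(np.ptp(t.x), np.ptp(t.y)) for t in out)
        assert residual < 0.1 * injected
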