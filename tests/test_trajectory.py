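"""Cleaning, gap handling and reach segmentation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import reachkin as rk
from reachkin.exceptions import SegmentValidationError
from reachkin.synthetic import min_jerk_reach
from reachkin.trajectory import interpolate_gaps, smooth_series

from _oracles import threshold_crossing_segments


class TestPreprocess:
    def test_constant_trajectory_unchanged(self):
        traj = rk.Trajectory3D(np.full((50, 3), 4.2), fs=100.0)
        out = rk.preprocess_trajectory(traj)
        np.testing.assert_allclose(out.xyz, traj.xyz, atol=1e-12)

    def test_single_gap_in_linear_motion_interpolated_exactly(self):
        t = np.arange(40, dtype=float)
        xyz = np.column_stack([2.0 * t, -0.5 * t, 0.1 * t])
        xyz[17] = np.nan
        out = rk.preprocess_trajectory(rk.Trajectory3D(xyz, fs=100.0))
        np.testing.assert_allclose(out.xyz[17], [34.0, -8.5, 1.7], atol=1e-9)

    def test_gap_length_threshold(self):
        v = np.arange(30, dtype=float)
        v[5:15] = np.nan  # 10-frame gap > max_gap: stays missing
        out = interpolate_gaps(v, max_gap=5)
        assert np.isnan(out[5:15]).all()
        w = np.arange(30, dtype=float)
        w[5:9] = np.nan  # 4-frame gap <= max_gap: filled on the line
        np.testing.assert_allclose(interpolate_gaps(w, max_gap=5), np.arange(30.0))

    def test_short_run_left_unsmoothed_with_warning(self):
        v = np.full(5, np.nan)
        v[1:4] = [1.0, 2.0, 1.0]
        with pytest.warns(UserWarning, match="unsmoothed"):
            out = smooth_series(v, window=7, order=3)
        np.testing.assert_allclose(out[1:4], [1.0, 2.0, 1.0])

    def test_likelihood_mask_applied_to_2d_track(self):
        data = pd.DataFrame(
            {
                "palm_u": np.linspace(0, 99, 100),
                "palm_v": np.linspace(0, 49.5, 100),
                "palm_likelihood": np.where(np.arange(100) == 50, 0.1, 0.95),
            }
        )
        track = rk.Keypoint2DTrack(data=data, fs=100.0)
        out = rk.preprocess(track, likelihood_min=0.6, max_gap=5)
        # masked frame sits on the line, so interpolation restores it
        assert out.data.loc[50, "palm_u"] == pytest.approx(50.0, abs=1e-9)

    def test_smoothing_reduces_noise(self):
        """Savitzky-Golay smoothing must beat the raw noisy series
        against the noiseless minimum-jerk truth, seed by seed."""
        wins = 0
        for seed in range(50):
            r = np.random.default_rng(seed)
            truth = min_jerk_reach(10.0, 0.3, 100.0, target=(10, 0, 0)).xyz
            noisy = truth + r.normal(0, 0.05, truth.shape)
            sm = rk.preprocess_trajectory(rk.Trajectory3D(noisy, fs=100.0)).xyz
            rmse_pre = np.sqrt(np.mean((noisy - truth) ** 2))
            rmse_post = np.sqrt(np.mean((sm - truth) ** 2))
            wins += rmse_post < rmse_pre
        assert wins == 50


def _session_palm(seed=0, noise=0.0, n_reaches=5):
    cfg = rk.SceneConfig(seed=seed, noise_mm=noise, noise_px=0.0)
    ses = rk.generate_session(cfg, n_reaches=n_reaches)
    return ses, rk.preprocess_trajectory(ses.trajectories["palm"])


class TestSegmentReaches:
    def test_flat_trajectory_yields_nothing(self):
        xyz = np.tile([-7.0, 1.0, 0.5], (300, 1))
        assert rk.segment_reaches(rk.Trajectory3D(xyz, fs=100.0)) == []

    def test_all_nan_trajectory_yields_nothing(self):
        traj = rk.Trajectory3D(np.full((100, 3), np.nan), fs=100.0)
        assert rk.segment_reaches(traj) == []

    def test_clean_session_reach_count_and_apex(self):
        ses, palm = _session_palm(seed=11, noise=0.0, n_reaches=5)
        segs = rk.segment_reaches(palm)
        assert len(segs) == 5
        for s, t in zip(segs, ses.truth):
            assert abs(s.apex_frame - t.apex_frame) <= 2

    def test_hysteresis_splits_on_single_subthreshold_frame(self):
        """Two peaks separated by one frame below the hysteresis level
        must come out as two segments; bounds cross-checked against a
        brute-force scan of all threshold crossings."""
        base = -7.0
        n = 120
        x = np.full(n, base)
        bump = 7.0 * np.sin(np.linspace(0, np.pi, 25)) ** 2
        x[20:45] += bump
        x[46:71] += bump  # frame 45 stays at baseline: below threshold
        xyz = np.column_stack([x, np.zeros(n), np.zeros(n)])
        segs = rk.segment_reaches(
            rk.Trajectory3D(xyz, fs=100.0), baseline=base, min_duration=5
        )
        assert len(segs) == 2
        for seg in segs:
            prom = x[seg.apex_frame] - base
            runs = threshold_crossing_segments(x, base + 0.25 * prom)
            assert (seg.start, seg.end) in runs

    def test_time_translation_shifts_segments(self):
        ses, palm = _session_palm(seed=3, noise=0.0, n_reaches=3)
        k = 37
        base = palm.xyz[:5].mean(axis=0)
        shifted = rk.Trajectory3D(
            np.vstack([np.tile(base, (k, 1)), palm.xyz]), fs=palm.fs
        )
        a = rk.segment_reaches(palm, baseline=-7.0)
        b = rk.segment_reaches(shifted, baseline=-7.0)
        assert len(a) == len(b)
        for sa, sb in zip(a, b):
            assert sb.start - sa.start == k
            assert sb.end - sa.end == k
            assert sb.apex_frame - sa.apex_frame == k

    def test_counts_match_truth_across_seeds_at_default_settings(self):
        for seed in range(20):
            ses, palm = _session_palm(seed=seed, noise=0.1, n_reaches=6)
            assert len(rk.segment_reaches(palm)) == len(ses.truth)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(0, 10_000))
    def test_segments_sorted_disjoint_in_bounds(self, seed):
        """On arbitrary smooth random walks segments never overlap and
        never exceed the trajectory bounds."""
        r = np.random.default_rng(seed)
        steps = r.normal(0, 0.8, size=(400, 3))
        xyz = np.cumsum(steps, axis=0)
        if seed % 3 == 0:
            xyz[r.integers(0, 400, size=30)] = np.nan
        segs = rk.segment_reaches(rk.Trajectory3D(xyz, fs=100.0), min_duration=2)
        prev_end = 0
        for s in segs:
            assert prev_end <= s.start < s.end <= 400
            assert s.start <= s.apex_frame < s.end
            prev_end = s.end


class TestManualSegments:
    def test_valid_spans_load(self, tmp_path, clean_palm):
        path = tmp_path / "spans.csv"
        pd.DataFrame({"start_frame": [10, 60], "end_frame": [50, 90]}).to_csv(
            path, index=False
        )
        segs = rk.load_manual_segments(path, clean_palm)
        assert [(s.start, s.end) for s in segs] == [(10, 50), (60, 90)]
        assert all(s.source == "manual" for s in segs)

    def test_out_of_range_span_rejected(self, tmp_path):
        traj = rk.Trajectory3D(np.zeros((100, 3)), fs=100.0)
        path = tmp_path / "spans.csv"
        pd.DataFrame({"start_frame": [90], "end_frame": [110]}).to_csv(path, index=False)
        with pytest.raises(SegmentValidationError) as exc:
            rk.load_manual_segments(path, traj)
        assert (90, 110) in exc.value.offenders

    def test_overlapping_spans_rejected(self, tmp_path):
        traj = rk.Trajectory3D(np.zeros((100, 3)), fs=100.0)
        path = tmp_path / "spans.csv"
        pd.DataFrame({"start_frame": [10, 30], "end_frame": [40, 60]}).to_csv(
            path, index=False
        )
        with pytest.raises(SegmentValidationError):
            rk.load_manual_segments(path, traj)

    def test_truth_spans_give_same_scalars_as_direct_segments(self, tmp_path):
        """Ingesting ground-truth windows through the manual-span file
        must be indistinguishable from constructing the segments in
        memory (and the apexes must agree with the generator's)."""
        ses, palm = _session_palm(seed=2, noise=0.0, n_reaches=4)
        path = tmp_path / "spans.csv"
        pd.DataFrame(
            {
                "start_frame": [t.start for t in ses.truth],
                "end_frame": [t.end for t in ses.truth],
            }
        ).to_csv(path, index=False)
        loaded = rk.load_manual_segments(path, palm)
        direct = [
            rk.ReachSegment(t.start, t.end, t.apex_frame, "manual") for t in ses.truth
        ]
        for seg_l, seg_d in zip(loaded, direct):
            assert abs(seg_l.apex_frame - seg_d.apex_frame) <= 2
            a = rk.compute_scalars(seg_l, palm)
            b = rk.compute_scalars(seg_d, palm)
            assert a.duration_s == b.duration_s
            assert a.vmax_mm_s == pytest.approx(b.vmax_mm_s, rel=1e-9)
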