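"""Trace extraction, dF/F0 normalization, pooling, classification and
compartment mode."""

import numpy as np
import pytest

from wormtrace.io import ProjectedMovie, max_project
from wormtrace.segmentation import postprocess_masks
from wormtrace.synthetic import simulate_movie
from wormtrace.tracking import track_movie
from wormtrace.traces import (ClassifierThresholds, CompartmentROIs, RawTrace,
                              classify_response, compartment_traces,
                              compute_background_series, extract_trace,
                              normalize_trace, pool_traces, summarize_calls,
                              traces_to_frame)


def gt_pipeline(movie, gt):
    """Segmentation from ground-truth masks, tracked, with background."""
    proj = max_project(movie)
    segs = [postprocess_masks(gt.masks["left"][t] | gt.masks["right"][t],
                              proj.data[t].astype(float), frame=t)
            for t in range(movie.n_frames)]
    res = track_movie(segs)
    assert not res.failed
    bg = compute_background_series(proj, segs)
    return proj, segs, res, bg


def raw_from_values(values, background=None, onset=20, identity="n",
                    interval=2.0, gap=None):
    values = np.asarray(values, dtype=float)
    T = len(values)
    return RawTrace(
        identity=identity, values=values,
        background=(np.zeros(T) if background is None
                    else np.asarray(background, dtype=float)),
        gap=(np.zeros(T, dtype=bool) if gap is None else np.asarray(gap)),
        frame_interval_s=interval, stimulus_onset_frame=onset,
        stimulus_duration_frames=max(1, T - onset - 5),
    )


class TestExtraction:
    def test_matches_masked_mean_exactly(self, noiseless_movie):
        movie, gt = noiseless_movie
        proj, segs, res, bg = gt_pipeline(movie, gt)
        for tr in res.tracks:
            raw = extract_trace(proj, tr, segs, background=bg)
            for t in (0, 25, 50):
                expect = proj.data[t][gt.masks[tr.identity][t]].astype(float).mean()
                assert raw.values[t] == pytest.approx(expect, rel=1e-12)

    def test_background_matches_outside_median(self, noiseless_movie):
        from scipy import ndimage

        movie, gt = noiseless_movie
        proj, segs, res, bg = gt_pipeline(movie, gt)
        t = 0
        occupied = segs[t].label_image > 0
        pool = ~ndimage.binary_dilation(occupied, iterations=3)
        assert bg[t] == pytest.approx(np.median(proj.data[t][pool]), rel=1e-12)

    def test_gap_interpolation_midpoint(self):
        from wormtrace.traces import _interpolate_gaps

        v = np.array([10.0, np.nan, 14.0])
        g = np.array([False, True, False])
        out, gout = _interpolate_gaps(v, g, max_gap=3)
        assert out[1] == pytest.approx(12.0)
        assert not gout.any()

    def test_gap_run_linear_ramp(self):
        from wormtrace.traces import _interpolate_gaps

        v = np.array([0.0, np.nan, np.nan, np.nan, 8.0])
        g = np.array([False, True, True, True, False])
        out, _ = _interpolate_gaps(v, g, max_gap=5)
        np.testing.assert_allclose(out, [0, 2, 4, 6, 8])

    def test_long_gap_stays_nan(self):
        from wormtrace.traces import _interpolate_gaps

        v = np.array([1.0] + [np.nan] * 4 + [1.0])
        g = np.array([False] + [True] * 4 + [False])
        out, gout = _interpolate_gaps(v, g, max_gap=3)
        assert np.isnan(out[1:5]).all() and gout[1:5].all()

    def test_border_gap_stays_nan(self):
        from wormtrace.traces import _interpolate_gaps

        v = np.array([np.nan, 5.0, 5.0])
        g = np.array([True, False, False])
        out, gout = _interpolate_gaps(v, g, max_gap=3)
        assert np.isnan(out[0]) and gout[0]

    def test_terminated_track_rejected(self, noiseless_movie):
        movie, gt = noiseless_movie
        proj, segs, res, bg = gt_pipeline(movie, gt)
        tr = res.tracks[0]
        tr.terminated = True
        with pytest.raises(ValueError, match="terminated"):
            extract_trace(proj, tr, segs, background=bg)
        tr.terminated = False


class TestNormalize:
    def test_constant_trace_zero_dff(self):
        raw = raw_from_values(np.full(60, 250.0))
        norm = normalize_trace(raw, subtract_background=False)
        assert norm.F0 == pytest.approx(250.0)
        assert np.allclose(norm.dff, 0.0)
        assert norm.baseline_sigma == 0.0

    def test_doubling_gives_dff_one(self):
        v = np.full(60, 100.0)
        v[30:] = 200.0
        norm = normalize_trace(raw_from_values(v), subtract_background=False)
        assert np.allclose(norm.dff[30:], 1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(100, 200, 60)
        n1 = normalize_trace(raw_from_values(v), subtract_background=False)
        n2 = normalize_trace(raw_from_values(3 * v), subtract_background=False)
        np.testing.assert_allclose(n1.dff, n2.dff, rtol=1e-12)

    def test_background_subtraction_changes_f0(self):
        v = np.full(60, 300.0)
        raw = raw_from_values(v, background=np.full(60, 100.0))
        assert normalize_trace(raw).F0 == pytest.approx(200.0)
        assert normalize_trace(raw, subtract_background=False).F0 == \
            pytest.approx(300.0)

    def test_too_few_baseline_frames_rejected(self):
        raw = raw_from_values(np.full(60, 100.0),
                              gap=np.r_[np.ones(17, bool), np.zeros(43, bool)])
        with pytest.raises(ValueError, match="baseline"):
            normalize_trace(raw, subtract_background=False)

    def test_nonpositive_f0_rejected(self):
        raw = raw_from_values(np.full(60, 50.0),
                              background=np.full(60, 80.0))
        with pytest.raises(ValueError, match="F0"):
            normalize_trace(raw)

    def test_amplitude_recovery_from_ground_truth_masks(self, noisy_movie):
        """With ground-truth masks and background subtraction, the peak
        dF/F0 recovers the simulated amplitude A within 10%."""
        from conftest import small_scene
        from wormtrace.synthetic import transient_kernel

        movie, gt = noisy_movie
        cfg = small_scene(seed=5)  # same config the fixture used
        proj, segs, res, bg = gt_pipeline(movie, gt)
        for tr in res.tracks:
            raw = extract_trace(proj, tr, segs, background=bg)
            norm = normalize_trace(raw)
            spec = next(s for s in cfg.neurons if s.neuron_id == tr.identity)
            k_grid = max(
                transient_kernel(f * movie.frame_interval_s,
                                 spec.tau_rise_s, spec.tau_decay_s)
                for f in range(1, movie.n_frames - movie.stimulus_onset_frame))
            expected_peak = spec.amplitude_A * k_grid
            onset = movie.stimulus_onset_frame
            peak = np.nanmax(norm.dff[onset:])
            assert abs(peak - expected_peak) / expected_peak <= 0.10


class TestPooling:
    def _norm(self, dff, onset=20):
        raw = raw_from_values(100.0 * (1 + np.asarray(dff)), onset=onset)
        return normalize_trace(raw, subtract_background=False)

    def test_identical_traces_zero_sd(self):
        dff = np.r_[np.zeros(20), np.linspace(0, 1, 40)]
        pooled = pool_traces([self._norm(dff) for _ in range(4)])
        assert np.allclose(pooled.sd, 0.0)
        sel = pooled.offsets >= 0
        np.testing.assert_allclose(pooled.mean[sel], dff[20:][sel[sel]],
                                   atol=1e-12)

    def test_mean_equals_recomputation(self):
        rng = np.random.default_rng(1)
        traces = [self._norm(rng.normal(0, 0.1, 60)) for _ in range(5)]
        pooled = pool_traces(traces)
        stack = np.stack([tr.dff for tr in traces])
        for i, off in enumerate(pooled.offsets):
            frame = off + 20
            assert pooled.mean[i] == pytest.approx(stack[:, frame].mean())
            assert pooled.sd[i] == pytest.approx(stack[:, frame].std(ddof=1))
            assert pooled.n[i] == 5

    def test_offset_alignment_differing_onsets(self):
        a = self._norm(np.r_[np.zeros(10), np.ones(30)], onset=10)
        b = self._norm(np.r_[np.zeros(30), np.ones(30)], onset=30)
        pooled = pool_traces([a, b])
        # both traces step to dff=1 exactly at their own onset
        sel = (pooled.offsets >= 0) & (pooled.offsets < 20)
        assert np.allclose(pooled.mean[sel], 1.0)
        assert np.allclose(pooled.sd[sel], 0.0)

    def test_min_n_drops_sparse_offsets(self):
        a = self._norm(np.zeros(60), onset=20)
        b = self._norm(np.zeros(30), onset=20)
        pooled = pool_traces([a, b], min_n=2)
        assert pooled.offsets.max() == 9  # only overlap survives
        assert (pooled.n >= 2).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pool_traces([])


class TestClassification:
    def _norm_with_peak(self, peak, onset=20, noise_sd=0.0, seed=0):
        rng = np.random.default_rng(seed)
        dff = rng.normal(0, noise_sd, 80)
        dff[onset + 5] += peak
        raw = raw_from_values(100.0 * (1 + dff), onset=onset)
        return normalize_trace(raw, subtract_background=False)

    def test_three_classes(self):
        assert classify_response(self._norm_with_peak(1.2)).response_class == "high"
        assert classify_response(self._norm_with_peak(0.5)).response_class == "moderate"
        assert classify_response(self._norm_with_peak(0.05)).response_class == "absent"

    def test_boundaries(self):
        th = ClassifierThresholds()
        assert classify_response(self._norm_with_peak(th.theta_high),
                                 th).response_class == "high"
        assert classify_response(self._norm_with_peak(th.theta_abs),
                                 th).response_class == "moderate"

    def test_noise_floor_scales_with_sigma(self):
        # a 0.3 peak passes on a quiet baseline but not on a noisy one
        quiet = self._norm_with_peak(0.3, noise_sd=0.01)
        assert classify_response(quiet).response_class == "moderate"
        loud = self._norm_with_peak(0.3, noise_sd=0.2, seed=3)
        call = classify_response(loud)
        assert call.thresholds.k_sigma * loud.baseline_sigma > 0.3

    def test_monotonicity(self):
        order = {"absent": 0, "moderate": 1, "high": 2}
        prev = -1
        for peak in (0.0, 0.1, 0.3, 0.6, 0.9, 1.5):
            cls = classify_response(self._norm_with_peak(peak)).response_class
            assert order[cls] >= prev
            prev = order[cls]

    def test_peak_within_lag_window_only(self):
        th = ClassifierThresholds(lag_allow_frames=2)
        dff = np.zeros(100)
        onset, dur = 20, 10
        dff[onset + dur + 20] = 2.0  # far outside the allowed lag
        raw = raw_from_values(100 * (1 + dff), onset=onset)
        raw.stimulus_duration_frames = dur
        norm = normalize_trace(raw, subtract_background=False)
        assert classify_response(norm, th).response_class == "absent"

    def test_all_gap_window_unclassifiable(self):
        norm = self._norm_with_peak(1.0)
        norm.gap[norm.stimulus_onset_frame:] = True
        call = classify_response(norm)
        assert call.unclassifiable

    def test_summarize_fractions_sum_to_one(self):
        calls = [classify_response(self._norm_with_peak(p))
                 for p in (1.2, 1.0, 0.5, 0.05)]
        df = summarize_calls(calls, ["a", "a", "a", "a"])
        row = df.iloc[0]
        assert row["n"] == 4
        assert row["frac_high"] + row["frac_moderate"] + row["frac_absent"] \
            == pytest.approx(1.0)
        assert row["n_high"] == 2 and row["n_moderate"] == 1

    def test_summarize_excludes_unclassifiable(self):
        good = classify_response(self._norm_with_peak(1.2))
        bad = classify_response(self._norm_with_peak(1.2))
        bad.unclassifiable = True
        df = summarize_calls([good, bad])
        assert df.iloc[0]["n"] == 1 and df.iloc[0]["n_unclassifiable"] == 1


class TestCompartments:
    def test_rois_measured_independently(self):
        T, H, W = 50, 40, 40
        data = np.full((T, H, W), 100.0)
        onset = 10
        # anterior ROI brightens 2x after light onset, others stay flat
        data[onset:, 5:10, 5:10] = 200.0
        rois = CompartmentROIs(
            anterior_neurite=[(5, 5), (5, 9), (9, 9), (9, 5)],
            posterior_neurite=[(25, 5), (25, 9), (29, 9), (29, 5)],
            soma=[(5, 25), (5, 29), (9, 29), (9, 25)],
        )
        out = compartment_traces(data, rois, light_onset_frame=onset)
        assert set(out) == {"anterior_neurite", "posterior_neurite", "soma"}
        assert out["anterior_neurite"].dff[onset:].mean() == pytest.approx(1.0)
        assert np.allclose(out["posterior_neurite"].dff, 0.0)
        assert np.allclose(out["soma"].dff, 0.0)
        assert out["anterior_neurite"].frame_interval_s == 0.1

    def test_background_subtraction_mode(self):
        T, H, W = 30, 40, 40
        data = np.full((T, H, W), 50.0)
        data[:, 5:10, 5:10] = 150.0
        data[:, 25:30, 5:10] = 150.0
        data[:, 5:10, 25:30] = 150.0
        rois = CompartmentROIs(
            anterior_neurite=[(5, 5), (5, 9), (9, 9), (9, 5)],
            posterior_neurite=[(25, 5), (25, 9), (29, 9), (29, 5)],
            soma=[(5, 25), (5, 29), (9, 29), (9, 25)],
        )
        out = compartment_traces(data, rois, light_onset_frame=10,
                                 subtract_background=True)
        assert out["anterior_neurite"].F0 == pytest.approx(100.0)

    def test_bad_stream_shape(self):
        rois = CompartmentROIs([(0, 0), (0, 2), (2, 2)],
                               [(4, 0), (4, 2), (6, 2)],
                               [(0, 4), (0, 6), (2, 6)])
        with pytest.raises(ValueError):
            compartment_traces(np.zeros((10, 10)), rois, 2)


class TestFrameExport:
    def test_round_trip_columns(self, noiseless_movie, tmp_path):
        from wormtrace.io import read_traces, write_traces

        movie, gt = noiseless_movie
        proj, segs, res, bg = gt_pipeline(movie, gt)
        raws = [extract_trace(proj, tr, segs, background=bg)
                for tr in res.tracks]
        norms = [normalize_trace(r) for r in raws]
        df = traces_to_frame(raws, norms)
        assert len(df) == 2 * movie.n_frames
        write_traces(df, tmp_path / "t.csv")
        back = read_traces(tmp_path / "t.csv")
        np.testing.assert_allclose(back["dff"], df["dff"], rtol=1e-6)
        assert set(back["neuron_id"]) == {"left", "right"}
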