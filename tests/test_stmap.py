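import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from tip.io import VideoStack
from tip.metrics import peak_frequency
from tip.stmap import (StMapError, build_st_map, enhance_frames,
                       extract_profiles, median_filter_2x2,
                       minimal_amplitude_projection, otsu_threshold_exact,
                       resample_curve_with_normals, st_map_from_video)


class TestEnhanceFrames:
    def test_constant_frame_passthrough(self):
        video = VideoStack(np.full((2, 32, 32), 0.4), 10.0)
        out = enhance_frames(video)
        np.testing.assert_allclose(out.frames, 0.4)

    def test_expands_low_contrast_and_stays_bounded(self):
        yy, xx = np.mgrid[0:64, 0:64]
        grating = 0.5 + 0.02 * np.sin(xx / 3.0)
        video = VideoStack(grating[None], 10.0)
        out = enhance_frames(video)
        assert np.ptp(out.frames) >= np.ptp(video.frames)
        assert out.frames.min() >= 0.0 and out.frames.max() <= 1.0


class TestMinimalAmplitudeProjection:
    def test_examples_and_bound(self):
        frames = np.array([[[1.0, 2.0], [0.0, 3.0]], [[0.0, 4.0], [2.0, 1.0]]])
        np.testing.assert_array_equal(minimal_amplitude_projection(frames),
                                      [[0.0, 2.0], [0.0, 1.0]])
        single = frames[:1]
        np.testing.assert_array_equal(minimal_amplitude_projection(single),
                                      single[0])
        assert np.all(minimal_amplitude_projection(frames) <= frames)


class TestResampleCurve:
    def test_straight_segment_normals(self):
        curve = resample_curve_with_normals(np.array([[0.0, 5.0], [20.0, 5.0]]), 10)
        np.testing.assert_allclose(curve.normals, [[0.0, 1.0]] * len(curve), atol=1e-12)
        assert curve.spacing <= 1.5

    def test_circle_normals_radial(self):
        theta = np.linspace(0.0, np.pi, 80)
        pts = np.stack([50 + 30 * np.cos(theta), 50 + 30 * np.sin(theta)], axis=1)
        curve = resample_curve_with_normals(pts, 10)
        radial = (curve.points - np.array([50.0, 50.0]))
        radial /= np.linalg.norm(radial, axis=1, keepdims=True)
        cosang = np.abs(np.sum(curve.normals * radial, axis=1))
        assert np.degrees(np.arccos(np.clip(cosang, 0, 1))).max() < 2.0

    def test_duplicates_dropped_single_point_rejected(self):
        curve = resample_curve_with_normals(
            np.array([[0.0, 0.0], [0.0, 0.0], [3.0, 4.0]]), 5)
        assert len(curve) >= 2
        with pytest.raises(StMapError):
            resample_curve_with_normals(np.array([[1.0, 1.0], [1.0, 1.0]]), 5)

    def test_normals_unit_and_orthogonal(self):
        pts = np.stack([np.linspace(0, 40, 30),
                        5 * np.sin(np.linspace(0, 3, 30))], axis=1)
        curve = resample_curve_with_normals(pts, 8)
        np.testing.assert_allclose(np.linalg.norm(curve.normals, axis=1), 1.0,
                                   atol=1e-9)
        tang = np.gradient(curve.points, axis=0)
        tang /= np.linalg.norm(tang, axis=1, keepdims=True)
        assert np.abs(np.sum(curve.normals * tang, axis=1)).max() < 1e-6


class TestExtractProfiles:
    def test_dark_tube_minimum_at_center(self):
        yy, xx = np.mgrid[0:40, 0:60].astype(float)
        frame = 0.9 - 0.6 * np.exp(-((yy - 20.0) ** 2) / 8.0)
        video = VideoStack(frame[None], 10.0)
        curve = resample_curve_with_normals(
            np.array([[10.0, 20.0], [50.0, 20.0]]), 16)
        P = extract_profiles(video, curve)
        assert P.shape == (len(curve), 17, 1)
        centers = np.argmin(P[:, :, 0], axis=1)
        assert np.all(np.abs(centers - 8) <= 1)

    def test_uniform_image_flat_profiles(self):
        video = VideoStack(np.full((2, 30, 30), 0.7), 10.0)
        curve = resample_curve_with_normals(
            np.array([[10.0, 15.0], [20.0, 15.0]]), 8)
        P = extract_profiles(video, curve)
        np.testing.assert_allclose(P, 0.7, atol=1e-7)


class TestOtsu:
    def test_two_delta_histogram_threshold_between_modes(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([np.full(300, 0.2), np.full(200, 0.8)])
        thr = otsu_threshold_exact(vals)
        assert 0.2 < thr < 0.8

    @staticmethod
    def icv_scan(vals):
        """Exhaustive inter-class-variance scan over a 256-bin histogram.

        Returns (thresholds, icv values) for every split point.
        """
        hist, edges = np.histogram(vals, bins=256)
        mids = 0.5 * (edges[:-1] + edges[1:])
        w = hist.astype(float)
        thr, icv = [], []
        for k in range(1, 256):
            w0, w1 = w[:k].sum(), w[k:].sum()
            if w0 == 0 or w1 == 0:
                continue
            m0 = (w[:k] * mids[:k]).sum() / w0
            m1 = (w[k:] * mids[k:]).sum() / w1
            thr.append(mids[k - 1])
            icv.append(w0 * w1 * (m0 - m1) ** 2)
        return np.array(thr), np.array(icv)

    def test_matches_exhaustive_scan(self):
        """Otsu attains the maximal inter-class variance of an exhaustive
        256-bin scan; with overlapping modes the maximizer is unique and
        the thresholds agree to one bin."""
        rng = np.random.default_rng(1)
        vals = np.concatenate([rng.normal(0.35, 0.1, 400),
                               rng.normal(0.7, 0.1, 250)]).clip(0, 1)
        thr = otsu_threshold_exact(vals)
        cand, icv = self.icv_scan(vals)
        k = int(np.argmin(np.abs(cand - thr)))
        assert icv[k] >= icv.max() * (1.0 - 1e-9)
        assert thr == pytest.approx(cand[int(np.argmax(icv))],
                                    abs=2 * (cand[1] - cand[0]))

    def test_attains_scan_maximum_with_separated_modes(self):
        """With an empty gap between modes the inter-class variance is flat
        over the gap; the chosen threshold still attains the maximum."""
        rng = np.random.default_rng(2)
        vals = np.concatenate([rng.normal(0.3, 0.05, 400),
                               rng.normal(0.75, 0.05, 250)]).clip(0, 1)
        thr = otsu_threshold_exact(vals)
        cand, icv = self.icv_scan(vals)
        k = int(np.argmin(np.abs(cand - thr)))
        assert icv[k] >= icv.max() * (1.0 - 1e-9)


class TestMedianFilter2x2:
    def test_constant_unchanged(self):
        np.testing.assert_array_equal(median_filter_2x2(np.full((5, 7), 3.0)),
                                      np.full((5, 7), 3.0))

    @settings(max_examples=30, deadline=None)
    @given(hnp.arrays(np.float64, (6, 8), elements=st.floats(0, 1)))
    def test_matches_sort_oracle_and_range(self, S):
        """Each output equals the mean of the two middle values of its
        (edge-replicated) 2x2 window; the value range never widens."""
        out = median_filter_2x2(S)
        pad = np.pad(S, ((1, 0), (1, 0)), mode="edge")
        for i in range(S.shape[0]):
            for j in range(S.shape[1]):
                win = sorted(pad[i:i + 2, j:j + 2].ravel())
                assert out[i, j] == pytest.approx(0.5 * (win[1] + win[2]))
        assert out.min() >= S.min() - 1e-12 and out.max() <= S.max() + 1e-12


class TestBuildStMap:
    def test_shape_contract(self, static_segmentation_video):
        video, truth, scene = static_segmentation_video
        m = st_map_from_video(video, truth.centerline_px, 40.0)
        n_curve = m.provenance["n_curve_points"]
        assert m.values.shape == (n_curve, video.n_frames)
        assert m.values.min() >= 0.0

    def test_constant_video_constant_map(self):
        video = VideoStack(np.full((6, 40, 40), 0.5), 10.0)
        m = st_map_from_video(video, np.array([[5.0, 20.0], [35.0, 20.0]]), 10.0,
                              enhance=False)
        np.testing.assert_allclose(m.values, m.values[0, 0])

    def test_segmentation_row_periodic_at_f(self, static_segmentation_video):
        """A contraction-site row of the ST map has its dominant frequency
        at the generator frequency within one spectral bin."""
        video, truth, scene = static_segmentation_video
        m = st_map_from_video(video, truth.centerline_px, 40.0)
        site_row = int(round(truth.site_arclengths_mm[0] / scene.pixel_pitch))
        from tip.metrics import CrossSectionSeries

        res = peak_frequency(CrossSectionSeries(m.values[site_row], m.frame_rate))
        assert res.peak_frequency == pytest.approx(truth.contraction_frequency,
                                                   abs=res.bin_width)

    def test_peristalsis_band_slope_matches_wave_speed(
            self, static_peristalsis_video):
        """The traveling dark band's slope in the ST map equals the wave
        speed within 20%."""
        video, truth, scene = static_peristalsis_video
        m = st_map_from_video(video, truth.centerline_px, 40.0)
        # trough position (row of minimal absorbance-masked signal) per frame
        rows = np.argmin(m.values + 1e3 * (m.values == 0), axis=0).astype(float)
        t = np.arange(m.n_frames) / m.frame_rate
        period_px = m.n_positions
        fit = np.polyfit(t, np.unwrap(rows, period=period_px), 1)
        speed_mm_s = abs(fit[0]) * scene.pixel_pitch
        assert speed_mm_s == pytest.approx(0.25, rel=0.2)


class TestEndToEndAutocorrelation:
    def test_pattern_autocorrelation_peak_location(
            self, static_peristalsis_video, static_segmentation_video):
        """Peristalsis ST maps have directional (off-time-axis) structure;
        segmentation maps do not (spectral form of the autocorrelation
        criterion)."""
        from tip.metrics import spectral_asymmetry

        for bundle, is_peri in ((static_peristalsis_video, True),
                                (static_segmentation_video, False)):
            video, truth, scene = bundle
            m = st_map_from_video(video, truth.centerline_px, 40.0)
            asym = abs(spectral_asymmetry(m.values))
            assert (asym > 0.3) == is_peri
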