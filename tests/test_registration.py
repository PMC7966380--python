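import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage as ndi

from conftest import angle_diff_deg
from tip.io import VideoStack
from tip.registration import (RegistrationError, RigidPose, SilhouetteError,
                              SilhouetteMask, compute_moments, convex_hull_mask,
                              extract_silhouette, pose_from_mask,
                              pose_from_moments, register_frame, register_video)


def make_mask(arr):
    arr = np.asarray(arr, bool)
    return SilhouetteMask(arr, int(arr.sum()), 0.5)


class TestExtractSilhouette:
    def synthetic_frame(self):
        """Hard-edged analogue of the imaging scene: bright disk (20% FOV),
        mouse blob at 0.5 inside it (6%), dark background 0.1."""
        frame = np.full((100, 100), 0.1)
        yy, xx = np.mgrid[0:100, 0:100]
        disk = (xx - 50) ** 2 + (yy - 50) ** 2 <= 25 ** 2
        frame[disk] = 0.9
        blob = ((xx - 50) / 20.0) ** 2 + ((yy - 50) / 10.0) ** 2 <= 1.0
        frame[blob] = 0.5
        return frame, blob

    def test_recovers_mouse_blob(self):
        frame, blob = self.synthetic_frame()
        sil = extract_silhouette(frame)
        # the speckle-suppressing 3x3 opening trims the blob's 1-px tips
        expected = ndi.binary_opening(blob, np.ones((3, 3)))
        np.testing.assert_array_equal(sil.mask, expected)
        # oracle: at the stopping threshold the blob is the second-largest
        # dark component by direct labeling of the opened complement
        labels, n = ndi.label(
            ndi.binary_opening(frame < sil.source_threshold, np.ones((3, 3))),
            np.ones((3, 3)))
        sizes = np.bincount(labels.ravel())[1:]
        assert sil.area_px == sorted(sizes)[-2]

    def test_recovers_exact_blob_without_opening(self):
        frame, blob = self.synthetic_frame()
        sil = extract_silhouette(frame, denoise_opening=False, refine_margin=0.0)
        np.testing.assert_array_equal(sil.mask, blob)

    def test_uniform_frame_has_no_silhouette(self):
        with pytest.raises(SilhouetteError):
            extract_silhouette(np.ones((50, 50)))

    def test_terminates_at_area_fraction(self):
        """A blob exactly at the area criterion is accepted at the first
        qualifying threshold."""
        frame = np.full((100, 100), 0.1)
        frame[:, :40] = 0.9                      # bright half
        frame[10:35, 10:30] = 0.5               # 500 px = 5% exactly
        sil = extract_silhouette(frame, area_fraction=0.05)
        assert sil.area_px / frame.size >= 0.05
        assert sil.mask[20, 20]


class TestConvexHull:
    def test_identity_on_rectangle(self):
        arr = np.zeros((30, 30), bool)
        arr[5:20, 8:25] = True
        hull = convex_hull_mask(make_mask(arr))
        np.testing.assert_array_equal(hull.mask, arr)

    def test_idempotent_on_disk(self):
        yy, xx = np.mgrid[0:41, 0:41]
        disk = make_mask((xx - 20) ** 2 + (yy - 20) ** 2 <= 15 ** 2)
        hull = convex_hull_mask(disk)
        np.testing.assert_array_equal(hull.mask, disk.mask)
        hull2 = convex_hull_mask(hull)
        np.testing.assert_array_equal(hull2.mask, hull.mask)

    def test_l_shape_filled(self):
        """An L-mask hulls to a strict superset; the hull contains every
        midpoint of set-pixel pairs (convexity, rasterization aside)."""
        arr = np.zeros((40, 40), bool)
        arr[5:35, 5:12] = True
        arr[28:35, 5:35] = True
        hull = convex_hull_mask(make_mask(arr))
        assert hull.area_px > arr.sum()
        assert np.all(hull.mask[arr])
        ys, xs = np.nonzero(hull.mask)
        rng = np.random.default_rng(0)
        pick = rng.integers(0, ys.size, size=(200, 2))
        mid_y = ((ys[pick[:, 0]] + ys[pick[:, 1]]) / 2).round().astype(int)
        mid_x = ((xs[pick[:, 0]] + xs[pick[:, 1]]) / 2).round().astype(int)
        assert hull.mask[mid_y, mid_x].all()

    def test_single_pixel(self):
        arr = np.zeros((9, 9), bool)
        arr[4, 4] = True
        hull = convex_hull_mask(make_mask(arr))
        np.testing.assert_array_equal(hull.mask, arr)


class TestMoments:
    def test_3x3_square(self):
        arr = np.zeros((7, 7), bool)
        arr[2:5, 2:5] = True
        m = compute_moments(make_mask(arr))
        assert m.mu_xx == pytest.approx(2.0 / 3.0)
        assert m.mu_yy == pytest.approx(2.0 / 3.0)
        assert m.mu_xy == pytest.approx(0.0)
        assert m.centroid == (3.0, 3.0)

    def test_horizontal_row(self):
        arr = np.zeros((5, 9), bool)
        arr[2, 2:7] = True
        m = compute_moments(make_mask(arr))
        assert m.mu_xx == pytest.approx(2.0)
        assert m.mu_yy == 0.0
        assert m.mu_xy == 0.0

    def test_matches_coordinate_covariance_oracle(self):
        """Moment covariance equals the two-pass coordinate covariance."""
        rng = np.random.default_rng(4)
        arr = ndi.binary_dilation(rng.random((30, 30)) > 0.8, iterations=2)
        m = compute_moments(make_mask(arr))
        ys, xs = np.nonzero(arr)
        oracle = np.cov(np.stack([xs, ys]), bias=True)
        np.testing.assert_allclose(m.cov, oracle, atol=1e-9)

    def test_empty_mask_errors(self):
        with pytest.raises(RegistrationError):
            compute_moments(np.zeros((5, 5), bool))


class TestPoseFromMoments:
    def test_axis_aligned_rows(self):
        arr = np.zeros((9, 9), bool)
        arr[4, 1:8] = True
        assert pose_from_moments(compute_moments(make_mask(arr))).theta == 0.0
        assert pose_from_moments(compute_moments(make_mask(arr.T))).theta == 90.0

    def test_rotated_ellipse_matches_closed_form(self):
        """Eigenvector angle agrees with atan2(2 mu_xy, mu_xx - mu_yy)/2
        and with the rendered orientation within 1 degree."""
        yy, xx = np.mgrid[0:101, 0:101]
        a = np.radians(30.0)
        u = (xx - 50) * np.cos(a) + (yy - 50) * np.sin(a)
        v = -(xx - 50) * np.sin(a) + (yy - 50) * np.cos(a)
        mask = make_mask((u / 35.0) ** 2 + (v / 12.0) ** 2 <= 1.0)
        m = compute_moments(mask)
        pose = pose_from_moments(m)
        closed = np.degrees(0.5 * np.arctan2(2 * m.mu_xy, m.mu_xx - m.mu_yy)) % 180
        assert angle_diff_deg(pose.theta, 30.0) < 1.0
        assert angle_diff_deg(pose.theta, closed) < 1e-6

    def test_isotropic_flagged_degenerate(self):
        yy, xx = np.mgrid[0:21, 0:21]
        disk = make_mask((xx - 10) ** 2 + (yy - 10) ** 2 <= 8 ** 2)
        pose = pose_from_moments(compute_moments(disk))
        assert pose.degenerate and pose.theta == 0.0

    @settings(max_examples=20, deadline=None)
    @given(st.floats(5.0, 175.0))
    def test_rotation_equivariance(self, alpha):
        """Rotating an elongated mask by alpha rotates its principal axis
        by alpha (within 1 degree for masks of a few hundred pixels)."""
        yy, xx = np.mgrid[0:121, 0:121]
        a = np.radians(alpha)
        u = (xx - 60) * np.cos(a) + (yy - 60) * np.sin(a)
        v = -(xx - 60) * np.sin(a) + (yy - 60) * np.cos(a)
        mask = (u / 40.0) ** 2 + (v / 14.0) ** 2 <= 1.0
        theta = pose_from_mask(mask).theta
        assert angle_diff_deg(theta, alpha) < 1.0

    def test_eigenvalues_translation_invariant(self):
        arr = np.zeros((60, 60), bool)
        arr[10:20, 10:35] = True
        ev1 = np.linalg.eigvalsh(compute_moments(make_mask(arr)).cov)
        ev2 = np.linalg.eigvalsh(compute_moments(make_mask(np.roll(arr, (17, 9), (0, 1)))).cov)
        np.testing.assert_allclose(ev1, ev2, atol=1e-12)


class TestRegisterFrame:
    def test_upright_pose_is_identity(self):
        rng = np.random.default_rng(1)
        frame = rng.random((40, 40))
        pose = RigidPose(90.0, (19.5, 19.5))
        out, tr = register_frame(frame, pose, pose)
        assert np.abs(out - frame).max() < 1e-6
        np.testing.assert_allclose(tr.matrix, np.eye(2), atol=1e-12)

    def test_transform_maps_centroid_to_anchor(self, moving_video):
        video, truth, scene = moving_video
        reg = register_video(video)
        anchor_reg = reg.transforms[0].apply_to_points(
            np.array(reg.poses[0].centroid))[0]
        for pose, tr in zip(reg.poses, reg.transforms):
            mapped = tr.apply_to_points(np.array(pose.centroid))[0]
            assert np.linalg.norm(mapped - anchor_reg) < 0.5

    def test_known_pose_silhouette_overlap(self, moving_video):
        """Frames under scripted rigid motion register onto the anchor
        silhouette with high Jaccard overlap."""
        video, truth, scene = moving_video
        reg = register_video(video)
        masks = [extract_silhouette(f).mask for f in reg.video.frames]
        ref = masks[0]
        for m in masks[1:]:
            jac = (m & ref).sum() / (m | ref).sum()
            assert jac >= 0.97

    def test_pose_recovery_accuracy(self, moving_video):
        """Noise-free rigid motion: angle within 1 degree, centroid within
        1 px of ground truth for every frame."""
        video, truth, scene = moving_video
        reg = register_video(video)
        for i, pose in enumerate(reg.poses):
            assert angle_diff_deg(pose.theta, truth.angles_deg[i]) < 1.0
            assert np.linalg.norm(np.array(pose.centroid)
                                  - truth.centroids_px[i]) < 1.0

    def test_registration_idempotent(self, moving_video):
        """Re-registering an already registered frame changes it only by
        interpolation noise."""
        video, truth, scene = moving_video
        reg = register_video(video)
        frame = reg.video.frames[3]
        pose = pose_from_mask(extract_silhouette(frame).mask)
        out, tr = register_frame(frame, pose, pose)
        interior = out[20:-20, 20:-20]
        assert np.abs(interior - frame[20:-20, 20:-20]).max() < 0.05
        assert abs(tr.angle_deg) < 1.0


class TestRegisterVideo:
    def test_single_frame_rejected(self):
        video = VideoStack(np.zeros((1, 10, 10)), 10.0)
        with pytest.raises(RegistrationError):
            register_video(video)

    def test_bent_frames_flagged(self):
        """Frames whose hull is nearly isotropic (bent body surrogate) are
        flagged for the similarity-based fallback."""
        frame = np.full((100, 100), 0.08)
        yy, xx = np.mgrid[0:100, 0:100]
        frame[(xx - 50) ** 2 + (yy - 50) ** 2 <= 40 ** 2] = 0.9
        blob = (xx - 50) ** 2 + (yy - 50) ** 2 <= 15 ** 2   # round "mouse"
        frame[blob] = 0.45
        video = VideoStack(np.stack([frame, frame]), 10.0)
        reg = register_video(video, eccentricity_threshold=0.8)
        assert reg.flags["bent"] == [0, 1]
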