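"""Silhouette extraction and moment-based rigid frame registration.

The mouse body silhouette is found by lowering a binary threshold from the
top of the normalized intensity range until, in the complemented image, the
second-largest connected component (the mouse; the largest is the
poorly-illuminated region outside the illumination disk) reaches a set
fraction of the sensor area.  The convex hull of that silhouette
generalizes the animal shape; its second-order central moments give the
body's principal axis.  Each frame is rotated by (90 - theta) so the body is
upright, then translated so the silhouette centroid lands on the anchor
(first-frame) centroid.  After registration the intestinal region is
aligned across frames up to residual non-rigid deformation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import convex_hull_image

from .io import VideoStack

_EIGHT_CONN = np.ones((3, 3), dtype=int)


class SilhouetteError(ValueError):
    """No silhouette satisfying the area criterion could be extracted."""


class RegistrationError(ValueError):
    pass


# --------------------------------------------------------------------------
# domain types


@dataclass
class SilhouetteMask:
    mask: np.ndarray          # bool (H, W), one connected component
    area_px: int
    source_threshold: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, bool)
        if self.area_px != int(self.mask.sum()) or self.area_px <= 0:
            raise RegistrationError("area_px must equal the set-pixel count (> 0)")


@dataclass
class MomentSet:
    """Per-pixel normalized second-order central moments of a binary mask."""

    n_pixels: int
    centroid: tuple[float, float]     # (x_bar, y_bar)
    mu_xx: float
    mu_yy: float
    mu_xy: float

    @property
    def cov(self) -> np.ndarray:
        return np.array([[self.mu_xx, self.mu_xy], [self.mu_xy, self.mu_yy]])


@dataclass
class RigidPose:
    """Major-axis angle (deg, in [0, 180)) and silhouette centroid (px)."""

    theta: float
    centroid: tuple[float, float]
    degenerate: bool = False


@dataclass
class RigidTransform:
    """Rotation by ``angle_deg`` about ``center`` followed by translation.

    ``matrix`` is the 2x2 rotation built from (90 - theta); ``shift_matrix``
    is the 2x3 affine appending the translation.  Applying the transform to
    the source frame's centroid yields the registered anchor centroid.
    """

    angle_deg: float                  # 90 - theta
    center: tuple[float, float]
    translation: tuple[float, float]  # (t_x, t_y) px
    flipped: bool = False

    @property
    def matrix(self) -> np.ndarray:
        a = math.radians(self.angle_deg)
        return np.array([[math.cos(a), -math.sin(a)],
                         [math.sin(a), math.cos(a)]])

    @property
    def shift_matrix(self) -> np.ndarray:
        return np.array([[1.0, 0.0, self.translation[0]],
                         [0.0, 1.0, self.translation[1]]])

    def apply_to_points(self, points: np.ndarray) -> np.ndarray:
        """Map (n, 2) (x, y) points from source-frame to registered coords."""
        pts = np.atleast_2d(np.asarray(points, float))
        c = np.asarray(self.center, float)
        return (self.matrix @ (pts - c).T).T + c + np.asarray(self.translation)


# --------------------------------------------------------------------------
# operations


def _binarize_complement(frame: np.ndarray, tau: float, opening: bool) -> np.ndarray:
    comp = frame < tau                # complement of (frame >= tau)
    if opening and comp.any():
        # 3x3 opening suppresses sensor-noise speckle in the complement
        comp = ndi.binary_opening(comp, structure=_EIGHT_CONN)
    return comp


def extract_silhouette(frame: np.ndarray, area_fraction: float = 0.05,
                       threshold_step: float = 0.005,
                       denoise_opening: bool = True,
                       refine_margin: float = 0.05) -> SilhouetteMask:
    """Iterative-threshold extraction of the mouse silhouette.

    Starting from threshold 1.0 and stepping down by ``threshold_step``,
    the frame is binarized (pixel >= tau), complemented, and labeled
    (8-connectivity).  The loop stops at the first tau where the
    second-largest complement component (the largest being the
    poorly-illuminated region) occupies at least ``area_fraction`` of the
    sensor area; that component is the mouse.

    Because the stopping tau sits immediately below the illumination
    level — in the shallow tail of the body-to-illumination intensity
    transition, where sensor noise dominates the gradient — the selected
    component is re-extracted at ``tau - refine_margin``, keeping the
    piece that overlaps the stopping-threshold component.  This moves the
    mask boundary onto the steep part of the edge without changing the
    stopping criterion.  Set ``refine_margin=0`` for the bare iteration.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise RegistrationError("frame must be 2D")
    total = frame.size
    best_ratio = 0.0
    n_steps = int(math.ceil(1.0 / threshold_step))
    for k in range(n_steps):
        tau = 1.0 - k * threshold_step
        if tau <= 0:
            break
        comp = _binarize_complement(frame, tau, denoise_opening)
        if not comp.any():
            continue
        labels, n = ndi.label(comp, structure=_EIGHT_CONN)
        if n < 2:
            continue
        sizes = np.bincount(labels.ravel())[1:]
        order = np.argsort(sizes)[::-1]
        second = int(sizes[order[1]])
        ratio = second / total
        best_ratio = max(best_ratio, ratio)
        if ratio >= area_fraction:
            mask = labels == (order[1] + 1)
            if refine_margin > 0:
                comp_r = _binarize_complement(frame, tau - refine_margin,
                                              denoise_opening)
                lab_r, n_r = ndi.label(comp_r, structure=_EIGHT_CONN)
                if n_r:
                    overlap = np.bincount(lab_r[mask].ravel(), minlength=n_r + 1)[1:]
                    if overlap.max() > 0:
                        mask = lab_r == (int(np.argmax(overlap)) + 1)
            return SilhouetteMask(mask, int(mask.sum()), tau)
    raise SilhouetteError(
        f"no silhouette reached area fraction {area_fraction:.3f} "
        f"(best ratio {best_ratio:.4f})")


def convex_hull_mask(sil: SilhouetteMask) -> SilhouetteMask:
    """Filled convex hull of a silhouette (superset of the input)."""
    if sil.area_px == 0:
        raise RegistrationError("empty mask has no convex hull")
    if sil.area_px == 1:
        return SilhouetteMask(sil.mask.copy(), 1, sil.source_threshold)
    # pixel-center coordinates keep hulling exactly idempotent
    hull = convex_hull_image(sil.mask, offset_coordinates=False)
    return SilhouetteMask(hull, int(hull.sum()), sil.source_threshold)


def compute_moments(sil: SilhouetteMask | np.ndarray) -> MomentSet:
    """Centroid and per-pixel normalized second-order central moments.

    For a binary mask the intensity function is identically 1 inside, so
    mu'_xx = sum (x - x_bar)^2 / N etc., assembling the 2x2 coordinate
    covariance matrix of the set pixels.
    """
    mask = sil.mask if isinstance(sil, SilhouetteMask) else np.asarray(sil, bool)
    ys, xs = np.nonzero(mask)
    n = xs.size
    if n == 0:
        raise RegistrationError("cannot compute moments of an empty mask")
    xbar = xs.mean()
    ybar = ys.mean()
    dx = xs - xbar
    dy = ys - ybar
    return MomentSet(n_pixels=n, centroid=(float(xbar), float(ybar)),
                     mu_xx=float(dx @ dx / n), mu_yy=float(dy @ dy / n),
                     mu_xy=float(dx @ dy / n))


def pose_from_moments(m: MomentSet, isotropy_tol: float = 1e-9) -> RigidPose:
    """Principal-axis angle from the moment covariance eigenvectors.

    theta is the angle of the eigenvector with the larger eigenvalue,
    measured from the +x (horizontal) axis and mapped into [0, 180).  An
    isotropic covariance (equal eigenvalues) has no defined major axis;
    theta = 0 is returned with the degenerate flag set.
    """
    evals, evecs = np.linalg.eigh(m.cov)
    if evals[1] - evals[0] <= isotropy_tol * max(evals[1], 1.0):
        return RigidPose(0.0, m.centroid, degenerate=True)
    v = evecs[:, int(np.argmax(evals))]
    theta = math.degrees(math.atan2(v[1], v[0])) % 180.0
    return RigidPose(float(theta), m.centroid)


def pose_from_mask(mask: np.ndarray | SilhouetteMask) -> RigidPose:
    """Convenience: hull -> moments -> pose for a silhouette mask."""
    sil = mask if isinstance(mask, SilhouetteMask) else SilhouetteMask(
        np.asarray(mask, bool), int(np.asarray(mask, bool).sum()), 0.0)
    return pose_from_moments(compute_moments(convex_hull_mask(sil)))


def _rot2(deg: float) -> np.ndarray:
    a = math.radians(deg)
    return np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])


def rotate_points(points: np.ndarray, deg: float, center) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, float))
    c = np.asarray(center, float)
    return (_rot2(deg) @ (pts - c).T).T + c


def _affine_rigid(frame: np.ndarray, deg: float, center, shift_xy, order: int = 1
                  ) -> np.ndarray:
    """Rotate about ``center`` then translate by ``shift_xy`` in one resample.

    Output pixel p maps from input R(-deg) (p - c - t) + c; out-of-frame
    pixels fill with 0.
    """
    c = np.asarray(center, float)
    t = np.asarray(shift_xy, float)
    rot_inv = _rot2(-deg)
    # scipy works in (row, col) = (y, x); reorder the (x, y) matrix
    m_yx = np.array([[rot_inv[1, 1], rot_inv[1, 0]],
                     [rot_inv[0, 1], rot_inv[0, 0]]])
    c_yx = c[::-1]
    t_yx = t[::-1]
    offset = c_yx - m_yx @ (c_yx + t_yx)
    return ndi.affine_transform(frame, m_yx, offset=offset, order=order,
                                mode="constant", cval=0.0,
                                output=np.float32 if frame.dtype == np.float32 else None)


def register_frame(frame: np.ndarray, pose: RigidPose, anchor: RigidPose,
                   center=None, order: int = 1
                   ) -> tuple[np.ndarray, RigidTransform]:
    """Rotate a frame upright and shift its centroid onto the anchor's.

    The frame is rotated by (90 - theta) about the image center with
    bilinear interpolation, after which the (rotated) silhouette centroid
    is translated onto the rotated anchor centroid.  Degenerate poses
    return the frame untransformed with an identity transform.
    """
    frame = np.asarray(frame)
    h, w = frame.shape
    if center is None:
        center = ((w - 1) / 2.0, (h - 1) / 2.0)
    if pose.degenerate:
        return frame.copy(), RigidTransform(0.0, tuple(center), (0.0, 0.0))
    phi = 90.0 - pose.theta
    phi_a = 90.0 - anchor.theta
    c_rot = rotate_points(pose.centroid, phi, center)[0]
    a_rot = rotate_points(anchor.centroid, phi_a, center)[0]
    t = a_rot - c_rot
    out = _affine_rigid(frame, phi, center, t, order=order)
    return out, RigidTransform(phi, tuple(center), (float(t[0]), float(t[1])))


@dataclass
class RegistrationResult:
    video: VideoStack
    transforms: list
    poses: list
    flags: dict = field(default_factory=dict)
    roi: tuple | None = None


def register_video(video: VideoStack, area_fraction: float = 0.05,
                   threshold_step: float = 0.005, roi: tuple | None = None,
                   eccentricity_threshold: float = 0.8,
                   on_missing: str = "interpolate") -> RegistrationResult:
    """Register every frame of a video to the first-frame anchor pose.

    The anchor is the convex-hull centroid and major-axis angle of frame 1.
    Frames whose silhouette cannot be extracted get a pose interpolated
    from neighbors (``on_missing='interpolate'``) or abort the run
    (``'abort'``).  Frames whose hull eccentricity falls below
    ``eccentricity_threshold`` (severely bent body) are flagged for
    similarity-based processing; they are still rigidly registered.
    An optional rectangular ROI (x, y, w, h) is cropped uniformly.
    """
    if video.n_frames < 2:
        raise RegistrationError("need at least 2 frames to register")
    n = video.n_frames
    thetas = np.full(n, np.nan)
    cents = np.full((n, 2), np.nan)
    missing, bent, degenerate = [], [], []
    for i in range(n):
        try:
            sil = extract_silhouette(video.frames[i], area_fraction, threshold_step)
        except SilhouetteError:
            if on_missing == "abort":
                raise
            missing.append(i)
            continue
        m = compute_moments(convex_hull_mask(sil))
        pose = pose_from_moments(m)
        if pose.degenerate:
            degenerate.append(i)
        evals = np.linalg.eigvalsh(m.cov)
        if evals[1] > 0:
            ecc = math.sqrt(max(0.0, 1.0 - evals[0] / evals[1]))
            if ecc < eccentricity_threshold:
                bent.append(i)
        thetas[i] = pose.theta
        cents[i] = pose.centroid
    if missing:
        good = np.flatnonzero(~np.isnan(thetas))
        if good.size == 0:
            raise SilhouetteError("no frame yielded a silhouette")
        idx = np.arange(n)
        thetas = np.interp(idx, good, thetas[good])
        cents[:, 0] = np.interp(idx, good, cents[good, 0])
        cents[:, 1] = np.interp(idx, good, cents[good, 1])

    # unwrap the 180-degree axis ambiguity so the body does not flip
    # head-to-tail between consecutive frames
    for i in range(1, n):
        d = thetas[i] - thetas[i - 1]
        if d > 90.0:
            thetas[i] -= 180.0
        elif d < -90.0:
            thetas[i] += 180.0

    anchor = RigidPose(float(thetas[0]), tuple(cents[0]))
    h, w = video.frame_shape
    center = ((w - 1) / 2.0, (h - 1) / 2.0)
    out = np.empty_like(video.frames)
    transforms = []
    poses = []
    for i in range(n):
        pose = RigidPose(float(thetas[i]), tuple(cents[i]),
                         degenerate=i in degenerate)
        reg, tr = register_frame(video.frames[i], pose, anchor, center=center)
        out[i] = reg
        transforms.append(tr)
        poses.append(pose)
    if roi is not None:
        x, y, rw, rh = roi
        out = out[:, y:y + rh, x:x + rw]
    reg_video = VideoStack(out, video.frame_rate, video.pixel_pitch,
                           meta={**video.meta, "registered": True})
    return RegistrationResult(reg_video, transforms, poses,
                              flags={"missing": missing, "bent": bent,
                                     "degenerate": degenerate},
                              roi=roi)
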