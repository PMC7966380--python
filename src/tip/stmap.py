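"""Spatial-temporal (kymograph) mapping along an intestine centerline.

Pipeline: registered frames are contrast-enhanced with CLAHE; a minimal
amplitude projection (per-pixel minimum over frames) gives a static image
on which the user draws the intestine centerline; the curve is arc-length
resampled with unit normals of fixed length; cross-sectional profiles are
sampled along every normal in every frame; per intestine position the
offset-by-time profile map is Otsu-thresholded (low-amplitude signal
removed) and averaged over offsets, and the per-position rows are stacked
into the position-by-time map, finally smoothed with a 2x2 median filter.

Maps are stored as contrast-agent absorbance (1 - intensity), so
contractions — less absorber in the cross-section — appear as low values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import exposure
from skimage.filters import threshold_otsu

from .io import VideoStack


class StMapError(ValueError):
    pass


@dataclass
class CenterlineCurve:
    """Ordered subpixel intestine path with fixed-length unit normals."""

    points: np.ndarray          # (n, 2) xy px
    normals: np.ndarray         # (n, 2) unit vectors
    normal_length: float        # px, full cross-section span
    spacing: float              # px between consecutive points

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def arclengths(self) -> np.ndarray:
        return np.arange(len(self)) * self.spacing


@dataclass
class SpatioTemporalMap:
    """positions x time matrix of averaged cross-section absorbance.

    Rows are intestine positions, columns are time points.
    """

    values: np.ndarray          # (n_positions, n_frames), >= 0
    frame_rate: float
    position_spacing: float = 1.0   # px
    otsu_threshold: float | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def n_positions(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def time_spacing(self) -> float:
        return 1.0 / self.frame_rate


# --------------------------------------------------------------------------
# frame preparation


def enhance_frames(video: VideoStack, clip_limit: float = 0.01,
                   tiles: int = 8) -> VideoStack:
    """Per-frame CLAHE (contrast-limited adaptive histogram equalization)."""
    h, w = video.frame_shape
    kernel = (max(1, h // tiles), max(1, w // tiles))
    out = np.empty_like(video.frames, dtype=np.float32)
    for i, frame in enumerate(video.frames):
        if np.ptp(frame) == 0:       # constant frame: nothing to equalize
            out[i] = frame
            continue
        out[i] = exposure.equalize_adapthist(
            np.clip(frame, 0.0, 1.0), kernel_size=kernel, clip_limit=clip_limit)
    return VideoStack(out, video.frame_rate, video.pixel_pitch,
                      meta={**video.meta, "clahe": clip_limit})


def minimal_amplitude_projection(frames: np.ndarray | VideoStack) -> np.ndarray:
    """Per-pixel minimum across frames (temporal MAP)."""
    arr = frames.frames if isinstance(frames, VideoStack) else np.asarray(frames)
    if arr.shape[0] < 1:
        raise StMapError("need at least one frame")
    return arr.min(axis=0)


# --------------------------------------------------------------------------
# centerline geometry


def resample_curve_with_normals(raw_points: np.ndarray, normal_length: float,
                                spacing: float = 1.0) -> CenterlineCurve:
    """Arc-length resample a drawn curve and attach unit normals.

    Consecutive duplicate points are dropped; tangents come from central
    differences and normals are the tangents rotated by +90 degrees
    ((tx, ty) -> (-ty, tx)).  All normals share the same ``normal_length``.
    """
    pts = np.atleast_2d(np.asarray(raw_points, float))
    keep = np.ones(len(pts), bool)
    keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-12
    pts = pts[keep]
    if len(pts) < 2:
        raise StMapError("need at least 2 distinct centerline points")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n = max(2, int(round(total / spacing)) + 1)
    s_new = np.linspace(0.0, total, n)
    res = np.stack([np.interp(s_new, s, pts[:, 0]),
                    np.interp(s_new, s, pts[:, 1])], axis=1)
    tang = np.gradient(res, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    normals = np.stack([-tang[:, 1], tang[:, 0]], axis=1)
    return CenterlineCurve(res, normals, float(normal_length),
                           float(total / (n - 1)))


# --------------------------------------------------------------------------
# profile extraction and map assembly


def extract_profiles(video: VideoStack | np.ndarray, curve: CenterlineCurve
                     ) -> np.ndarray:
    """Bilinear cross-section sampling: P[position, offset, time].

    Each normal is sampled at unit spacing over [-L/2, +L/2] (L + 1
    samples).  Samples falling outside the frame are taken as 0.
    """
    frames = video.frames if isinstance(video, VideoStack) else np.asarray(video)
    L = int(round(curve.normal_length))
    offsets = np.arange(L + 1, dtype=float) - L / 2.0
    # coords: (n_pos, n_off, 2)
    coords = curve.points[:, None, :] + curve.normals[:, None, :] * offsets[None, :, None]
    ys = coords[..., 1].ravel()
    xs = coords[..., 0].ravel()
    n_pos, n_off = coords.shape[:2]
    n_t = frames.shape[0]
    P = np.empty((n_pos, n_off, n_t), dtype=np.float32)
    for t in range(n_t):
        P[:, :, t] = ndi.map_coordinates(
            frames[t], [ys, xs], order=1, mode="constant", cval=0.0
        ).reshape(n_pos, n_off)
    return P


def otsu_threshold_exact(values: np.ndarray, nbins: int = 256) -> float:
    """Otsu's threshold via skimage (inter-class-variance maximization)."""
    return float(threshold_otsu(np.asarray(values).ravel(), nbins=nbins))


def median_filter_2x2(S: np.ndarray) -> np.ndarray:
    """2x2 median smoothing: mean of the two middle values per window.

    The window for output (i, j) covers rows {i-1, i} and columns
    {j-1, j} of the edge-replicated input, so the output keeps the input
    shape.  Constant images pass through unchanged and the value range
    never widens.
    """
    S = np.asarray(S, float)
    pad = np.pad(S, ((1, 0), (1, 0)), mode="edge")
    stack = np.stack([pad[:-1, :-1], pad[:-1, 1:], pad[1:, :-1], pad[1:, 1:]])
    stack.sort(axis=0)
    return 0.5 * (stack[1] + stack[2])


def build_st_map(P: np.ndarray, frame_rate: float, invert: bool = True,
                 position_spacing: float = 1.0,
                 provenance: dict | None = None) -> SpatioTemporalMap:
    """Assemble the position-by-time map from the profile stack.

    With ``invert=True`` (default) the signal is contrast-agent absorbance
    (1 - intensity), so relaxations (wide absorber-filled cross-sections)
    are high and contractions are low.  A single Otsu threshold computed
    over the whole profile stack removes low-amplitude signal before the
    offset-average; the stacked map is smoothed with the 2x2 median filter.
    """
    P = np.asarray(P)
    if P.size == 0:
        raise StMapError("empty profile stack")
    A = 1.0 - P if invert else P.astype(float)
    if np.ptp(A) == 0:
        thr = float(A.flat[0])
        S = A.mean(axis=1)
    else:
        thr = otsu_threshold_exact(A)
        A = np.where(A >= thr, A, 0.0)
        S = A.mean(axis=1)
    S = median_filter_2x2(S)
    return SpatioTemporalMap(S, frame_rate, position_spacing, thr,
                             provenance=provenance or {})


def st_map_from_video(video: VideoStack, raw_curve: np.ndarray,
                      normal_length: float, enhance: bool = True,
                      clip_limit: float = 0.01) -> SpatioTemporalMap:
    """Convenience wrapper: CLAHE -> resample curve -> profiles -> map."""
    vid = enhance_frames(video, clip_limit=clip_limit) if enhance else video
    curve = resample_curve_with_normals(raw_curve, normal_length)
    P = extract_profiles(vid, curve)
    return build_st_map(P, video.frame_rate,
                        provenance={"normal_length": normal_length,
                                    "n_curve_points": len(curve)})
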