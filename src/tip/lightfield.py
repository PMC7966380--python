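"""Light-field decoding, shift-and-add refocusing, and depth mapping.

A microlens array samples the 4D light field: the raw sensor mosaic holds,
under each lenslet, a pitch-by-pitch block of angular samples.  Decoding
rearranges the mosaic into sub-aperture images indexed by angle (u, v).
Shift-and-add refocusing shifts each sub-aperture image proportionally to
its angular offset (the slope, calibrated in slope units per mm of depth)
and averages: structures at the corresponding depth come into focus.
Stacking refocused slices over depths gives the focal stack; the per-pixel
depth of best focus (maximal local contrast) gives the depth index map.
No deconvolution is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .stmap import (CenterlineCurve, SpatioTemporalMap, build_st_map,
                    extract_profiles)


class LightFieldError(ValueError):
    pass


@dataclass
class LensletGrid:
    """Axis-aligned square lenslet geometry and depth calibration.

    ``pitch`` is both the lenslet pitch in sensor pixels and the angular
    sample count per axis (the samples fill the lenslet footprint).
    ``slope_per_mm`` maps depth (mm) to the refocusing slope (spatial
    shift, in lenslet units, per unit angular offset).
    """

    pitch: int
    n_y: int
    n_x: int
    slope_per_mm: float = 0.35
    offset: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.pitch <= 0:
            raise LightFieldError("pitch must be positive")
        if self.pitch < 3:
            raise LightFieldError("need at least 3 angular samples per axis")


@dataclass
class LightField:
    """4D array [u, v, y, x]: angular sample (u, v), lenslet position (y, x)."""

    array: np.ndarray
    grid: LensletGrid

    def __post_init__(self) -> None:
        p = self.grid.pitch
        if self.array.shape[:2] != (p, p):
            raise LightFieldError(
                f"angular axes {self.array.shape[:2]} do not match pitch {p}")

    def sub_aperture(self, u: int, v: int) -> np.ndarray:
        return self.array[u, v]


@dataclass
class FocalStack:
    slices: np.ndarray          # (n_depths, H, W)
    depths: np.ndarray          # mm, strictly monotonic
    slopes: np.ndarray = None

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, float)
        d = np.diff(self.depths)
        if d.size and not (np.all(d > 0) or np.all(d < 0)):
            raise LightFieldError("depth axis must be strictly monotonic")


@dataclass
class DepthIndexMap:
    depth_mm: np.ndarray        # per-pixel best-focus depth
    confidence: np.ndarray      # sharpness peak-to-mean ratio
    mask: np.ndarray            # True where confidence is sufficient
    degenerate: bool = False


# --------------------------------------------------------------------------
# decode / encode


def decode_lightfield(raw: np.ndarray, grid: LensletGrid) -> LightField:
    """Resample a raw lenslet mosaic into the 4D [u, v, y, x] array."""
    raw = np.asarray(raw)
    oy, ox = grid.offset
    raw = raw[oy:, ox:]
    p = grid.pitch
    want = (grid.n_y * p, grid.n_x * p)
    if raw.shape != want:
        est = (raw.shape[0] / grid.n_y, raw.shape[1] / grid.n_x)
        raise LightFieldError(
            f"mosaic shape {raw.shape} does not match grid {want}; "
            f"measured pitch estimate {est}")
    lf = raw.reshape(grid.n_y, p, grid.n_x, p).transpose(1, 3, 0, 2)
    return LightField(np.ascontiguousarray(lf), grid)


def encode_mosaic(lf: LightField) -> np.ndarray:
    """Inverse of :func:`decode_lightfield` (exact round trip)."""
    p = lf.grid.pitch
    return lf.array.transpose(2, 0, 3, 1).reshape(lf.grid.n_y * p, lf.grid.n_x * p)


# --------------------------------------------------------------------------
# refocusing


def refocus(lf: LightField, slope: float) -> np.ndarray:
    """Shift-and-add refocused image at one slope.

    Each sub-aperture image is shifted by ``-slope * (u - u0, v - v0)``
    with subpixel (bilinear) interpolation and the shifted images are
    averaged.  At slope 0 this is exactly the plain sub-aperture mean.
    """
    p = lf.grid.pitch
    u0 = (p - 1) / 2.0
    h, w = lf.array.shape[2:]
    if abs(slope) * u0 >= min(h, w):
        raise LightFieldError(
            f"slope {slope} shifts beyond the {h}x{w} spatial extent")
    if slope == 0:
        return lf.array.mean(axis=(0, 1))
    acc = np.zeros((h, w))
    for u in range(p):
        for v in range(p):
            sh = (-slope * (u - u0), -slope * (v - u0))
            acc += ndi.shift(lf.array[u, v], sh, order=1, mode="nearest")
    return acc / (p * p)


def focal_stack(lf: LightField, depths) -> FocalStack:
    """Refocus at each depth (depth -> slope via the grid calibration)."""
    depths = np.asarray(depths, float)
    slopes = depths * lf.grid.slope_per_mm
    slices = np.stack([refocus(lf, s) for s in slopes])
    return FocalStack(slices, depths, slopes)


# --------------------------------------------------------------------------
# depth indexing


def _local_variance(img: np.ndarray, window: int) -> np.ndarray:
    mean = ndi.uniform_filter(img, window)
    mean2 = ndi.uniform_filter(img * img, window)
    return np.clip(mean2 - mean * mean, 0.0, None)


def depth_index_map(stack: FocalStack, window: int = 5,
                    confidence_threshold: float = 1.5) -> DepthIndexMap:
    """Per-pixel best-focus depth by maximal local contrast.

    The sharpness functional is the local variance of the slice in a
    ``window`` x ``window`` neighborhood; the depth index is the argmax
    over slices.  Confidence is the functional's peak-to-mean ratio over
    depth; pixels below ``confidence_threshold`` (featureless background)
    are masked out.  A single-slice stack is degenerate: a constant map
    with zero confidence.
    """
    n_d = stack.slices.shape[0]
    if n_d < 2:
        depth = np.full(stack.slices.shape[1:], stack.depths[0])
        conf = np.zeros_like(depth)
        return DepthIndexMap(depth, conf, np.zeros_like(depth, bool),
                             degenerate=True)
    sharp = np.stack([_local_variance(s, window) for s in stack.slices])
    best = np.argmax(sharp, axis=0)
    depth = stack.depths[best]
    peak = sharp.max(axis=0)
    mean = sharp.mean(axis=0)
    conf = np.where(mean > 0, peak / np.where(mean > 0, mean, 1.0), 0.0)
    return DepthIndexMap(depth, conf, conf >= confidence_threshold)


# --------------------------------------------------------------------------
# lateral / axial kymographs from volume sequences


def axial_st_map(volumes: np.ndarray, curve: CenterlineCurve,
                 frame_rate: float, reference_slice: int,
                 invert: bool = True
                 ) -> tuple[SpatioTemporalMap, SpatioTemporalMap]:
    """Lateral and axial ST maps of one intestine from focal-stack videos.

    ``volumes`` is (T, D, H, W).  The lateral map runs the standard
    in-plane profile pipeline on the best-focus slice
    (``reference_slice``); the axial map samples each centerline point
    along the depth axis instead of along the in-plane normal — over the
    same span (``curve.normal_length`` samples, centered on the reference
    slice) — and is reduced identically (threshold, offset-average,
    median smoothing), so the two maps are directly comparable.
    """
    vols = np.asarray(volumes)
    if vols.ndim != 4:
        raise LightFieldError("volumes must be (T, D, H, W)")
    n_t, n_d, h, w = vols.shape
    if not 0 <= reference_slice < n_d:
        raise LightFieldError(f"reference slice {reference_slice} outside 0..{n_d - 1}")
    xs = curve.points[:, 0]
    ys = curve.points[:, 1]
    if xs.min() < 0 or xs.max() > w - 1 or ys.min() < 0 or ys.max() > h - 1:
        raise LightFieldError("curve lies outside the reference slice")

    P_lat = extract_profiles(vols[:, reference_slice], curve)
    lateral = build_st_map(P_lat, frame_rate, invert=invert,
                           provenance={"direction": "lateral",
                                       "reference_slice": reference_slice})

    n_pos = len(curve)
    L = int(round(curve.normal_length))
    offsets = np.arange(L + 1, dtype=float) - L / 2.0 + reference_slice
    P_ax = np.empty((n_pos, L + 1, n_t), dtype=np.float32)
    dd = np.repeat(offsets, n_pos)
    yy = np.tile(ys, L + 1)
    xx = np.tile(xs, L + 1)
    for t in range(n_t):
        samples = ndi.map_coordinates(vols[t], [dd, yy, xx], order=1,
                                      mode="constant", cval=0.0)
        P_ax[:, :, t] = samples.reshape(L + 1, n_pos).T
    axial = build_st_map(P_ax, frame_rate, invert=invert,
                         provenance={"direction": "axial",
                                     "reference_slice": reference_slice})
    return lateral, axial


def minimal_amplitude_projection_axial(stack: FocalStack) -> np.ndarray:
    """Per-pixel minimum across depth slices (axial MAP)."""
    return stack.slices.min(axis=0)
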