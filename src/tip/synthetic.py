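"""Synthetic transillumination scenes with known ground truth.

Every downstream stage of the pipeline (registration, kymograph mapping,
frequency analysis, light-field refocusing) is exercised on scenes rendered
here.  The forward model emulates transillumination imaging of a mouse
abdomen: a bright illumination disk on a dark background, a mouse-body
silhouette of intermediate intensity occupying a few percent of the field
of view, and a dark tube-shaped intestine whose local diameter follows
either a peristaltic traveling wave or a segmentation (Cannon-type)
standing-contraction rhythm.  Absorption follows Beer–Lambert through the
chord of a circular tube cross-section; the absorption coefficient default
gives ~80% attenuation through a resting 4 mm intestine.  Depth-dependent
scattering is modeled as Gaussian blur, sensor noise as additive Gaussian
clipped to [0, 1].

The rigid body pose (orientation angle and centroid) is applied
analytically per frame — pixel coordinates are inverse-transformed into the
canonical mouse frame before the scene function is evaluated — so ground
truth poses are exact and no interpolation artifacts enter the rendering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .io import VideoStack

#: Beer–Lambert absorption coefficient (1/mm): exp(-MU_TUBE * 4 mm) = 0.2,
#: i.e. ~80% attenuation through a resting-diameter intestine.
MU_TUBE = math.log(5.0) / 4.0


class SceneError(ValueError):
    """Raised when a scene configuration cannot be rendered."""


# --------------------------------------------------------------------------
# configuration


@dataclass
class SceneConfig:
    """Static imaging-scene parameters.

    Intensity levels are normalized to [0, 1] and must satisfy
    ``background_level < mouse_level < illum_level`` so silhouette
    extraction by descending threshold behaves as in the real system.
    """

    image_size: tuple[int, int] = (200, 200)  # (H, W) px
    pixel_pitch: float = 0.2                  # mm/px
    frame_rate: float = 15.0                  # Hz
    duration: float = 60.0                    # s
    illumination_center: tuple[float, float] | None = None  # (x, y) px
    illumination_radius: float = 80.0         # px
    background_level: float = 0.08
    mouse_level: float = 0.45
    illum_level: float = 0.9
    mouse_semi_axes: tuple[float, float] = (45.0, 18.0)  # (a, b) px
    blur_sigma: float = 1.2                   # px, scattering blur
    noise_sigma: float = 0.02
    mu_tube: float = MU_TUBE                  # 1/mm
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.background_level < self.mouse_level < self.illum_level <= 1.0):
            raise SceneError("require 0 <= background < mouse < illum <= 1")
        if self.frame_rate <= 0:
            raise SceneError("frame_rate must be positive")
        if self.noise_sigma < 0:
            raise SceneError("noise_sigma must be >= 0")

    @property
    def center(self) -> np.ndarray:
        h, w = self.image_size
        return np.array([(w - 1) / 2.0, (h - 1) / 2.0])


@dataclass
class MotilityConfig:
    """Motor-pattern parameters of the simulated intestine.

    The resting diameter defaults to the 4 mm average of the mouse small
    intestine; during contraction the local diameter falls to
    ``contracted_fraction`` (default 25%) of resting.
    """

    resting_diameter: float = 4.0       # mm
    contracted_fraction: float = 0.25
    pattern: str = "segmentation"       # peristalsis | segmentation | mixed
    contraction_frequency: float = 0.5  # Hz
    wave_speed: float = 0.25            # mm/s (peristalsis)
    site_spacing: float = 6.0           # mm (segmentation)
    bump_width: float = 2.0             # mm, half-width of raised-cosine bump
    centerline_points: np.ndarray | None = None  # (n, 2) mm, canonical frame

    def __post_init__(self) -> None:
        if not 0.0 < self.contracted_fraction < 1.0:
            raise SceneError("contracted_fraction must be in (0, 1)")
        if self.contraction_frequency <= 0:
            raise SceneError("contraction_frequency must be positive")
        if self.resting_diameter <= 0:
            raise SceneError("resting_diameter must be positive")
        if self.pattern not in ("peristalsis", "segmentation", "mixed"):
            raise SceneError(f"unknown pattern {self.pattern!r}")


@dataclass
class MotionConfig:
    """Scripted rigid motion of the mouse body.

    ``pose_schedule`` is a list of ``(time_s, angle_deg, (cx, cy))`` knots;
    centroid ``None`` means the image center.  Between knots the pose is
    either held or linearly interpolated.
    """

    pose_schedule: list = field(default_factory=lambda: [(0.0, 0.0, None)])
    interpolation: str = "hold"  # hold | linear

    def __post_init__(self) -> None:
        times = [t for t, _, _ in self.pose_schedule]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise SceneError("pose_schedule times must be strictly increasing")
        if self.interpolation not in ("hold", "linear"):
            raise SceneError(f"unknown interpolation {self.interpolation!r}")

    def poses_at(self, times: np.ndarray, default_center: np.ndarray):
        """Per-frame (angle_deg, centroid) resolved from the schedule."""
        knots_t = np.array([t for t, _, _ in self.pose_schedule], float)
        knots_a = np.array([a for _, a, _ in self.pose_schedule], float)
        knots_c = np.array(
            [default_center if c is None else np.asarray(c, float)
             for _, _, c in self.pose_schedule])
        if self.interpolation == "linear":
            ang = np.interp(times, knots_t, knots_a)
            cx = np.interp(times, knots_t, knots_c[:, 0])
            cy = np.interp(times, knots_t, knots_c[:, 1])
        else:
            idx = np.clip(np.searchsorted(knots_t, times, side="right") - 1, 0, None)
            ang = knots_a[idx]
            cx = knots_c[idx, 0]
            cy = knots_c[idx, 1]
        return ang, np.stack([cx, cy], axis=1)


@dataclass
class GroundTruth:
    """Known scene state returned alongside every rendered video."""

    angles_deg: np.ndarray            # (T,) rigid-pose angle per frame
    centroids_px: np.ndarray          # (T, 2) rigid-pose centroid per frame
    times: np.ndarray                 # (T,) s
    arclengths_mm: np.ndarray         # (n_s,)
    diameter_mm: np.ndarray           # (n_s, T) field d(s, t)
    centerline_px: np.ndarray         # (n_s, 2) canonical (unrotated) coords
    site_arclengths_mm: np.ndarray    # contraction sites (segmentation)
    contraction_frequency: float
    contracted_fraction: float
    resting_diameter: float

    def centerline_in_frame(self, frame_index: int, scene_center: np.ndarray) -> np.ndarray:
        """Canonical centerline mapped into frame ``i`` world coordinates."""
        a = math.radians(self.angles_deg[frame_index])
        rot = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
        rel = self.centerline_px - scene_center[None, :]
        return (rot @ rel.T).T + self.centroids_px[frame_index][None, :]


# --------------------------------------------------------------------------
# motor-pattern model


def _bump(x: np.ndarray, width: float) -> np.ndarray:
    """Raised-cosine contraction bump: 1 at center, 0 beyond |x| = width."""
    out = np.zeros_like(x, dtype=float)
    inside = np.abs(x) <= width
    out[inside] = 0.5 * (1.0 + np.cos(np.pi * x[inside] / width))
    return out


def segmentation_sites(length_mm: float, spacing: float) -> np.ndarray:
    """Contraction-site arclengths: evenly spaced, half-spacing inset ends."""
    return np.arange(spacing / 2.0, length_mm, spacing)


def diameter_field(motility: MotilityConfig, s_mm: np.ndarray,
                   t_s: np.ndarray, length_mm: float | None = None
                   ) -> np.ndarray:
    """Local intestine diameter d(s, t) in mm, shape (n_s, n_t).

    Peristalsis: a contraction bump travels at ``wave_speed`` and wraps at
    the centerline length.  Segmentation: fixed sites alternate between
    the flanking pair (contracted during the first half-cycle) and the
    in-between site (contracted during the second half-cycle), completing
    one cycle per ``1 / contraction_frequency``; the temporal envelope is
    sinusoidal so each site oscillates at the contraction frequency.

    ``length_mm`` is the centerline length defining the wave wrap and the
    site layout; it defaults to the extent of ``s_mm``.
    """
    s = np.asarray(s_mm, float)
    t = np.asarray(t_s, float)
    d0 = motility.resting_diameter
    dc = motility.contracted_fraction * d0
    if length_mm is None:
        length_mm = float(s.max() - s.min()) if s.size > 1 else motility.bump_width
    length = float(length_mm)
    envs = []
    if motility.pattern in ("peristalsis", "mixed"):
        # wave position modulo centerline length, recentered to [-L/2, L/2)
        x = (s[:, None] - motility.wave_speed * t[None, :]
             + length / 2.0) % length - length / 2.0
        envs.append(_bump(x, motility.bump_width))
    if motility.pattern in ("segmentation", "mixed"):
        # arclengths are absolute: sites are laid out from s = 0
        sites = segmentation_sites(length, motility.site_spacing)
        w = 2.0 * np.pi * motility.contraction_frequency * t
        env = np.zeros((s.size, t.size))
        for k, sk in enumerate(sites):
            phase = 0.5 * (1.0 + np.cos(w)) if k % 2 == 0 else 0.5 * (1.0 - np.cos(w))
            env += _bump(s - sk, motility.bump_width)[:, None] * phase[None, :]
        envs.append(np.clip(env, 0.0, 1.0))
    env = np.maximum.reduce(envs)
    return d0 - (d0 - dc) * env


def default_centerline_mm(half_extent: float = 7.0, amplitude: float = 1.0,
                          n: int = 60) -> np.ndarray:
    """Gentle sinusoidal intestine path in canonical mm coordinates."""
    x = np.linspace(-half_extent, half_extent, n)
    y = amplitude * np.sin(np.pi * x / half_extent)
    return np.stack([x, y], axis=1)


# --------------------------------------------------------------------------
# video rendering


def _resample_polyline(points: np.ndarray, spacing: float):
    """Arc-length resample a polyline; returns (points, arclengths)."""
    pts = np.asarray(points, float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n = max(2, int(round(total / spacing)) + 1)
    s_new = np.linspace(0.0, total, n)
    out = np.stack([np.interp(s_new, s, pts[:, 0]), np.interp(s_new, s, pts[:, 1])], axis=1)
    return out, s_new


def render_motility_video(scene: SceneConfig, motility: MotilityConfig,
                          motion: MotionConfig | None = None
                          ) -> tuple[VideoStack, GroundTruth]:
    """Render a transillumination motility video with exact ground truth.

    Each frame is the illumination disk times the mouse silhouette, with
    tube attenuation ``exp(-mu * chord)`` where the chord is the light path
    through a circular tube of local diameter ``d(s, t)``, followed by
    scattering blur and clipped additive Gaussian noise.  The rigid pose is
    applied analytically, so the returned :class:`GroundTruth` poses are
    exact.
    """
    motion = motion or MotionConfig()
    n_frames = int(round(scene.duration * scene.frame_rate))
    if n_frames < 2:
        raise SceneError("duration * frame_rate must give at least 2 frames")

    h, w = scene.image_size
    center = scene.center
    illum_c = (np.asarray(scene.illumination_center, float)
               if scene.illumination_center is not None else center)

    cl_mm = (motility.centerline_points if motility.centerline_points is not None
             else default_centerline_mm())
    cl_px = center[None, :] + np.asarray(cl_mm, float) / scene.pixel_pitch
    # dense canonical centerline for per-pixel nearest-point queries
    dense_px, dense_s_px = _resample_polyline(cl_px, 0.5)
    dense_s_mm = dense_s_px * scene.pixel_pitch
    tube_r_px = 0.5 * motility.resting_diameter / scene.pixel_pitch

    reach = np.linalg.norm(dense_px - illum_c[None, :], axis=1).max() + tube_r_px
    if reach > scene.illumination_radius:
        raise SceneError(
            f"centerline (+tube radius) extends {reach:.1f}px from the illumination "
            f"center, beyond the {scene.illumination_radius:.1f}px disk")
    if (dense_px.min() < 0 or dense_px[:, 0].max() >= w or dense_px[:, 1].max() >= h):
        raise SceneError("centerline lies outside the frame")

    times = np.arange(n_frames) / scene.frame_rate
    angles, centroids = motion.poses_at(times, center)
    diam = diameter_field(motility, dense_s_mm, times,
                          length_mm=float(dense_s_mm[-1]))  # (n_s, T)

    tree = cKDTree(dense_px)
    a, b = scene.mouse_semi_axes
    rng = np.random.default_rng(scene.rng_seed)

    yy, xx = np.mgrid[0:h, 0:w]
    coords = np.stack([xx.ravel(), yy.ravel()], axis=1).astype(float)

    frames = np.empty((n_frames, h, w), dtype=np.float32)
    for i in range(n_frames):
        ar = math.radians(angles[i])
        rot_inv = np.array([[math.cos(ar), math.sin(ar)],
                            [-math.sin(ar), math.cos(ar)]])
        canon = (rot_inv @ (coords - centroids[i][None, :]).T).T + center[None, :]
        cx = canon[:, 0] - center[0]
        cy = canon[:, 1] - center[1]
        img = np.full(h * w, scene.background_level)
        in_disk = (canon[:, 0] - illum_c[0]) ** 2 + (canon[:, 1] - illum_c[1]) ** 2 \
            <= scene.illumination_radius ** 2
        img[in_disk] = scene.illum_level
        in_mouse = (cx / a) ** 2 + (cy / b) ** 2 <= 1.0
        img[in_mouse & in_disk] = scene.mouse_level
        # tube attenuation inside the mouse only
        sel = np.flatnonzero(in_mouse)
        if sel.size:
            dist_px, idx = tree.query(canon[sel])
            d_here = diam[idx, i]
            r_mm = dist_px * scene.pixel_pitch
            half = 0.5 * d_here
            inside = r_mm < half
            chord = np.zeros_like(r_mm)
            chord[inside] = 2.0 * np.sqrt(half[inside] ** 2 - r_mm[inside] ** 2)
            img[sel[inside]] *= np.exp(-scene.mu_tube * chord[inside])
        frame = img.reshape(h, w)
        if scene.blur_sigma > 0:
            frame = ndi.gaussian_filter(frame, scene.blur_sigma)
        if scene.noise_sigma > 0:
            frame = frame + rng.normal(0.0, scene.noise_sigma, frame.shape)
        frames[i] = np.clip(frame, 0.0, 1.0)

    video = VideoStack(frames, scene.frame_rate, scene.pixel_pitch,
                       meta={"pattern": motility.pattern,
                             "contraction_frequency": motility.contraction_frequency,
                             "rng_seed": scene.rng_seed})
    truth = GroundTruth(
        angles_deg=angles, centroids_px=centroids, times=times,
        arclengths_mm=dense_s_mm, diameter_mm=diam, centerline_px=dense_px,
        site_arclengths_mm=segmentation_sites(
            float(dense_s_mm[-1]), motility.site_spacing),
        contraction_frequency=motility.contraction_frequency,
        contracted_fraction=motility.contracted_fraction,
        resting_diameter=motility.resting_diameter)
    return video, truth


# --------------------------------------------------------------------------
# phantom rendering (resolution / depth validation)


@dataclass
class PhantomResult:
    image: np.ndarray           # (H, W)
    cross_section: np.ndarray   # column profile through the tube center
    row_px: np.ndarray          # row coordinate of the profile samples
    sigma_px: float             # applied scattering blur
    mode: str


def render_tube_phantom(tube_diameter: float, depth_above: float = 0.0,
                        depth_below: float = 0.0, mode: str = "fixed_t1",
                        pixel_pitch: float = 0.2,
                        image_size: tuple[int, int] = (160, 160),
                        illum_level: float = 0.9, mu: float = MU_TUBE,
                        agar_mu: float = 0.05,
                        blur_per_mm: float = 0.25) -> PhantomResult:
    """Straight dark tube under depth-dependent scattering blur.

    The tube runs horizontally through the image center.  Scattering on the
    camera side (below the tube) blurs the shadow: blur sigma grows as
    ``blur_per_mm * depth_below`` mm.  Scattering above the tube only
    attenuates the (already diffuse) illumination, so it rescales intensity
    globally without changing the profile shape — mirroring the two phantom
    modes: ``fixed_t1`` varies the below-tube thickness, ``fixed_t2``
    varies the above-tube thickness.
    """
    if tube_diameter <= 0:
        raise SceneError("tube_diameter must be positive")
    if depth_above < 0 or depth_below < 0:
        raise SceneError("depths must be >= 0")
    if mode not in ("fixed_t1", "fixed_t2"):
        raise SceneError(f"unknown phantom mode {mode!r}")
    h, w = image_size
    y = np.arange(h, dtype=float)
    r_mm = np.abs(y - (h - 1) / 2.0) * pixel_pitch
    half = tube_diameter / 2.0
    chord = np.zeros_like(r_mm)
    inside = r_mm < half
    chord[inside] = 2.0 * np.sqrt(half ** 2 - r_mm[inside] ** 2)
    scale = illum_level * math.exp(-agar_mu * (depth_above + depth_below))
    column = scale * np.exp(-mu * chord)
    image = np.tile(column[:, None], (1, w))
    sigma_px = blur_per_mm * depth_below / pixel_pitch
    if sigma_px > 0:
        image = ndi.gaussian_filter(image, sigma_px)
    return PhantomResult(image=image, cross_section=image[:, w // 2].copy(),
                         row_px=y, sigma_px=sigma_px, mode=mode)


# --------------------------------------------------------------------------
# light-field rendering (pinhole-array forward model)


def render_lightfield(sources, grid, amplitude: float = 1.0):
    """Render point sources into a 4D light field ``[u, v, y, x]``.

    A source at lenslet coordinates (sy, sx) and depth z contributes to the
    angular sample (u, v) at spatial position shifted by
    ``slope(z) * (u - u0, v - v0)`` with ``slope(z) = slope_per_mm * z``:
    an in-focus source (z = 0) maps to one lenslet across all angular
    samples; an off-focus source spreads over multiple lenslets, more so
    with |z|.  Sources use bilinear splatting, so a source at integer
    lenslet coordinates and depth 0 occupies exactly one spatial bin.

    Parameters
    ----------
    sources : list of (y_lenslet, x_lenslet, z_mm) or
        (y_lenslet, x_lenslet, z_mm, weight)
    grid : LensletGrid
    """
    from .lightfield import LightField  # local import to avoid a cycle

    p = grid.pitch
    u0 = (p - 1) / 2.0
    lf = np.zeros((p, p, grid.n_y, grid.n_x))
    for src in sources:
        sy, sx, z = src[:3]
        wgt = amplitude * (src[3] if len(src) > 3 else 1.0)
        slope = grid.slope_per_mm * z
        if abs(slope) * u0 > max(grid.n_y, grid.n_x):
            raise SceneError(f"depth {z} mm shifts beyond the lenslet grid")
        for u in range(p):
            for v in range(p):
                yy = sy + slope * (u - u0)
                xx = sx + slope * (v - u0)
                _splat_bilinear(lf[u, v], yy, xx, wgt)
    return LightField(lf, grid)


def _splat_bilinear(img: np.ndarray, y: float, x: float, w: float) -> None:
    y0, x0 = int(np.floor(y)), int(np.floor(x))
    fy, fx = y - y0, x - x0
    for dy, wy in ((0, 1 - fy), (1, fy)):
        for dx, wx in ((0, 1 - fx), (1, fx)):
            yy, xx = y0 + dy, x0 + dx
            if 0 <= yy < img.shape[0] and 0 <= xx < img.shape[1] and wy * wx > 0:
                img[yy, xx] += w * wy * wx


def tube_sources(y_lenslet: float, z_mm: float, x_range: tuple[float, float],
                 n: int = 25) -> list:
    """A row of point sources emulating a straight tube/hair at one depth."""
    xs = np.linspace(x_range[0], x_range[1], n)
    return [(y_lenslet, float(x), z_mm) for x in xs]


# --------------------------------------------------------------------------
# volumetric tube sequences (for lateral vs axial kymographs)


def render_tube_volume_sequence(n_frames: int = 60, frame_rate: float = 5.0,
                                shape: tuple[int, int, int] = (21, 41, 60),
                                tube_y: float | None = None,
                                tube_depth: float | None = None,
                                sigma_lateral: float = 4.0,
                                sigma_axial: float = 4.0,
                                mod_lateral: float = 0.5,
                                mod_axial: float = 0.5,
                                frequency: float = 0.5,
                                absorbance: float = 0.8):
    """Time series of 3D volumes of a contracting tube along x.

    The tube cross-section is a Gaussian absorbance profile in (y, depth);
    its lateral (y) and axial (depth) widths oscillate at ``frequency``
    with independent modulation depths, so isotropic versus anisotropic
    contraction can be staged for lateral/axial kymograph comparisons.

    Returns (volumes with shape (T, D, H, W), truth dict).
    """
    d, h, w = shape
    y0 = tube_y if tube_y is not None else (h - 1) / 2.0
    z0 = tube_depth if tube_depth is not None else (d - 1) / 2.0
    t = np.arange(n_frames) / frame_rate
    osc = 0.5 * (1.0 + np.cos(2.0 * np.pi * frequency * t))
    sy = sigma_lateral * (1.0 - mod_lateral * osc)
    sz = sigma_axial * (1.0 - mod_axial * osc)
    zz, yy = np.mgrid[0:d, 0:h].astype(float)
    vols = np.empty((n_frames, d, h, w), dtype=np.float32)
    for i in range(n_frames):
        cross = absorbance * np.exp(-((yy - y0) ** 2 / (2 * sy[i] ** 2)
                                      + (zz - z0) ** 2 / (2 * sz[i] ** 2)))
        vols[i] = (1.0 - cross)[:, :, None]
    truth = {"frequency": frequency, "tube_y": y0, "tube_depth": z0,
             "sigma_lateral": sy, "sigma_axial": sz, "times": t}
    return vols, truth
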