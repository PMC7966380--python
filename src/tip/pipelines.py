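"""End-to-end recovery pipelines on the stated synthetic worlds.

These functions wire the stages together exactly as a user would for the
two in-vivo-like scenarios — a free-moving recording that needs rigid
registration, and a motion-free (anesthetized-like) recording — plus the
phantom diameter-ratio measurement.  They are used by the command-line
``run`` stage, the acceptance tests and the acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import cross_section_series, peak_frequency
from .registration import RegistrationResult, register_video
from .stmap import SpatioTemporalMap, st_map_from_video
from .synthetic import (GroundTruth, MotilityConfig, MotionConfig, SceneConfig,
                        render_motility_video, render_tube_phantom)


#: Scripted free-moving pose drift: slow rotation and centroid wander,
#: linearly interpolated, angles kept away from the 0/180 wrap.
FREE_MOVING_SCHEDULE = [
    (0.0, 60.0, (95.0, 100.0)),
    (20.0, 110.0, (105.0, 96.0)),
    (40.0, 70.0, (98.0, 104.0)),
    (60.0, 95.0, (92.0, 100.0)),
]


@dataclass
class FrequencyRecovery:
    recovered_hz: float
    true_hz: float
    bin_width_hz: float
    n_frames: int
    st_map: SpatioTemporalMap
    truth: GroundTruth
    registration: RegistrationResult | None = None


def _site_rows(truth: GroundTruth, scene: SceneConfig,
               half_width: int = 4) -> tuple[int, int]:
    """Row range of the ST map covering the first contraction site."""
    row = int(round(truth.site_arclengths_mm[0] / scene.pixel_pitch))
    return (row - half_width, row + half_width + 1)


def recover_frequency_free_moving(frequency_hz: float = 0.772,
                                  seed: int = 42,
                                  duration: float = 60.0,
                                  noise_sigma: float = 0.02,
                                  normal_length: float = 40.0
                                  ) -> FrequencyRecovery:
    """Full free-moving pipeline: render -> register -> ST map -> peak.

    A segmentation recording at ``frequency_hz`` under scripted rigid
    motion is registered frame-by-frame; the centerline (placed on the
    first frame) is mapped through the first frame's registration
    transform, and the contraction frequency is read from the spectral
    peak at the first contraction site.
    """
    scene = SceneConfig(duration=duration, frame_rate=15.0,
                        noise_sigma=noise_sigma, rng_seed=seed)
    motility = MotilityConfig(pattern="segmentation",
                              contraction_frequency=frequency_hz)
    motion = MotionConfig(pose_schedule=FREE_MOVING_SCHEDULE,
                          interpolation="linear")
    video, truth = render_motility_video(scene, motility, motion)
    reg = register_video(video)
    curve_frame0 = truth.centerline_in_frame(0, scene.center)
    curve_reg = reg.transforms[0].apply_to_points(curve_frame0)
    st_map = st_map_from_video(reg.video, curve_reg, normal_length)
    series = cross_section_series(st_map, _site_rows(truth, scene))
    res = peak_frequency(series)
    return FrequencyRecovery(res.peak_frequency, frequency_hz, res.bin_width,
                             video.n_frames, st_map, truth, reg)


def recover_frequency_anesthetized(frequency_hz: float = 0.380,
                                   seed: int = 43,
                                   duration: float = 60.0,
                                   noise_sigma: float = 0.02,
                                   normal_length: float = 40.0
                                   ) -> FrequencyRecovery:
    """Motion-free pipeline (no registration needed): ST map -> peak."""
    scene = SceneConfig(duration=duration, frame_rate=15.0,
                        noise_sigma=noise_sigma, rng_seed=seed)
    motility = MotilityConfig(pattern="segmentation",
                              contraction_frequency=frequency_hz)
    video, truth = render_motility_video(scene, motility)
    st_map = st_map_from_video(video, truth.centerline_px, normal_length)
    series = cross_section_series(st_map, _site_rows(truth, scene))
    res = peak_frequency(series)
    return FrequencyRecovery(res.peak_frequency, frequency_hz, res.bin_width,
                             video.n_frames, st_map, truth)


def measure_diameter_ratio(resting_mm: float = 4.0,
                           contracted_fraction: float = 0.25,
                           pixel_pitch: float = 0.2,
                           blur_depth_mm: float = 1.0) -> dict:
    """FWHM-based contracted/resting diameter ratio on noiseless phantoms.

    Renders straight-tube phantoms at the resting diameter and at the
    generator's contracted diameter under mild scattering blur and
    measures the cross-section FWHM ratio.  Returns the ratio both as a
    fraction and in percent.
    """
    from .metrics import diameter_change

    rest = render_tube_phantom(resting_mm, depth_above=4.0,
                               depth_below=blur_depth_mm,
                               pixel_pitch=pixel_pitch)
    cont = render_tube_phantom(resting_mm * contracted_fraction,
                               depth_above=4.0, depth_below=blur_depth_mm,
                               pixel_pitch=pixel_pitch)
    dc = diameter_change(rest.cross_section, cont.cross_section)
    return {"ratio": dc.ratio, "change": dc.change,
            "ratio_percent": 100.0 * dc.ratio,
            "n_samples": rest.cross_section.size}
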