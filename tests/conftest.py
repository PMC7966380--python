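"""Shared fixtures: small synthetic scenes rendered once per session."""

from __future__ import annotations

import numpy as np
import pytest

from tip.synthetic import (MotilityConfig, MotionConfig, SceneConfig,
                           render_motility_video)


@pytest.fixture(scope="session")
def small_scene_kwargs():
    """Compact scene parameters keeping unit-test renders fast."""
    return dict(image_size=(160, 160), illumination_radius=65.0,
                mouse_semi_axes=(40.0, 16.0))


@pytest.fixture(scope="session")
def static_segmentation_video(small_scene_kwargs):
    """20 s motion-free segmentation recording at 10 Hz, 0.5 Hz rhythm."""
    scene = SceneConfig(duration=20.0, frame_rate=10.0, noise_sigma=0.01,
                        rng_seed=7, **small_scene_kwargs)
    motility = MotilityConfig(pattern="segmentation", contraction_frequency=0.5)
    video, truth = render_motility_video(scene, motility)
    return video, truth, scene


@pytest.fixture(scope="session")
def static_peristalsis_video(small_scene_kwargs):
    """20 s motion-free peristalsis recording, wave speed 0.25 mm/s."""
    scene = SceneConfig(duration=20.0, frame_rate=10.0, noise_sigma=0.01,
                        rng_seed=8, **small_scene_kwargs)
    motility = MotilityConfig(pattern="peristalsis", contraction_frequency=0.5,
                              wave_speed=0.25)
    video, truth = render_motility_video(scene, motility)
    return video, truth, scene


@pytest.fixture(scope="session")
def moving_video(small_scene_kwargs):
    """Noise-free video under scripted rigid motion (rotation + drift)."""
    scene = SceneConfig(duration=1.2, frame_rate=10.0, noise_sigma=0.0,
                        rng_seed=5, **small_scene_kwargs)
    motility = MotilityConfig()
    motion = MotionConfig(
        pose_schedule=[(0.0, 50.0, (75.0, 82.0)), (1.2, 120.0, (85.0, 78.0))],
        interpolation="linear")
    video, truth = render_motility_video(scene, motility, motion)
    return video, truth, scene


def angle_diff_deg(a: float, b: float) -> float:
    """Absolute angular difference modulo the 180-degree axis ambiguity."""
    return abs((a - b + 90.0) % 180.0 - 90.0)
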