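"""Dual-color acquisition demultiplexing and channel overlay.

Two spectrally separated contrast agents are imaged with alternating
illumination wavelengths, the camera triggered so each frame holds exactly
one wavelength.  Demultiplexing routes frames by their wavelength label
into two stacks whose effective frame rate is the acquisition rate times
the channel's frame fraction; the per-channel stacks then run through the
standard registration/kymograph pipeline unchanged.  Overlays map each
channel's absorbance to a distinct color plane so overlapping intestine
sections remain distinguishable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import VideoStack


class MulticolorError(ValueError):
    pass


@dataclass
class AcquisitionSchedule:
    """Per-frame wavelength labels and the acquisition frame rate (Hz)."""

    labels: list
    frame_rate: float

    def __post_init__(self) -> None:
        uniq = sorted(set(self.labels), key=str)
        if len(uniq) != 2:
            raise MulticolorError(f"schedule must use exactly 2 labels, got {uniq}")
        self.channels = uniq

    @classmethod
    def alternating(cls, n_frames: int, labels=(808, 980),
                    frame_rate: float = 2.0) -> "AcquisitionSchedule":
        """Strictly alternating ABAB... schedule (dual-color default 2 Hz)."""
        return cls([labels[i % 2] for i in range(n_frames)], frame_rate)


def demultiplex(video: VideoStack, schedule: AcquisitionSchedule
                ) -> tuple[VideoStack, VideoStack]:
    """Route frames by wavelength label into two per-channel stacks.

    Every input frame lands in exactly one channel; each channel's frame
    rate is the acquisition rate scaled by its share of frames, and the
    original acquisition timestamps are kept in the metadata.  An empty
    channel is returned empty and flagged.
    """
    if len(schedule.labels) != video.n_frames:
        raise MulticolorError(
            f"schedule length {len(schedule.labels)} != {video.n_frames} frames")
    labels = np.asarray(schedule.labels)
    out = []
    for ch in schedule.channels:
        idx = np.flatnonzero(labels == ch)
        frames = video.frames[idx]
        rate = schedule.frame_rate * idx.size / video.n_frames
        meta = {**video.meta, "wavelength": ch,
                "source_indices": idx.tolist(),
                "timestamps_s": (idx / schedule.frame_rate).tolist(),
                "empty": idx.size == 0}
        if idx.size == 0:
            frames = np.empty((0,) + video.frame_shape, dtype=video.frames.dtype)
            rate = schedule.frame_rate
        out.append(VideoStack(frames, rate, video.pixel_pitch, meta))
    return out[0], out[1]


def interleave(ch1: VideoStack, ch2: VideoStack,
               schedule: AcquisitionSchedule) -> VideoStack:
    """Inverse of :func:`demultiplex`: restore the acquisition order."""
    labels = np.asarray(schedule.labels)
    n = labels.size
    shape = ch1.frame_shape if ch1.n_frames else ch2.frame_shape
    frames = np.empty((n,) + shape, dtype=(ch1.frames if ch1.n_frames else ch2.frames).dtype)
    for ch, stack in zip(schedule.channels, (ch1, ch2)):
        frames[labels == ch] = stack.frames
    return VideoStack(frames, schedule.frame_rate, ch1.pixel_pitch)


def overlay_channels(ch1_frame: np.ndarray, ch2_frame: np.ndarray | None,
                     colors=((1.0, 0.0, 0.0), (0.0, 1.0, 0.0))) -> np.ndarray:
    """RGB composite of two per-wavelength frames.

    Each channel's absorbance (1 - intensity) is normalized to its own
    maximum and painted into a fixed color plane (channel 1 first); where
    both agents absorb, both colors are present.
    """
    f1 = np.asarray(ch1_frame, float)
    planes = [(f1, colors[0])]
    if ch2_frame is not None and np.asarray(ch2_frame).size:
        f2 = np.asarray(ch2_frame, float)
        if f2.shape != f1.shape:
            raise MulticolorError(f"shape mismatch: {f1.shape} vs {f2.shape}")
        planes.append((f2, colors[1]))
    rgb = np.zeros(f1.shape + (3,))
    for frame, color in planes:
        absorb = 1.0 - np.clip(frame, 0.0, 1.0)
        peak = absorb.max()
        if peak > 0:
            absorb = absorb / peak
        rgb += absorb[..., None] * np.asarray(color)[None, None, :]
    return np.clip(rgb, 0.0, 1.0)


def pair_nearest_frames(ch1: VideoStack, ch2: VideoStack) -> list[tuple[int, int]]:
    """Pair each channel-1 frame with the nearest-in-time channel-2 frame."""
    t1 = np.asarray(ch1.meta.get("timestamps_s", ch1.times()))
    t2 = np.asarray(ch2.meta.get("timestamps_s", ch2.times()))
    if t2.size == 0:
        return [(i, -1) for i in range(t1.size)]
    return [(i, int(np.argmin(np.abs(t2 - t)))) for i, t in enumerate(t1)]
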