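"""Behavior-aware processing of long-duration recordings.

A free-moving mouse changes posture over a long session; the intestine
profile changes with it, so one centerline cannot serve the whole
recording.  Frames are compared to a running reference by Pearson
correlation (on downsampled frames); a similarity drop marks a behavior
change, the recording is split into epochs, a per-epoch ST map is computed
with its own centerline, and the maps are stitched column-wise into the
long-duration map.  A recording with no pose change yields a single epoch
whose stitched result equals the plain ST map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import downscale_local_mean

from .io import VideoStack
from .stmap import SpatioTemporalMap


class LongRecError(ValueError):
    pass


@dataclass
class SimilarityTrace:
    values: np.ndarray            # in [-1, 1], one per frame
    boundaries: list              # frame indices starting each epoch
    flagged: list = field(default_factory=list)   # zero-variance frames

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        b = list(self.boundaries)
        if b != sorted(set(b)) or (b and (b[0] < 0 or b[-1] >= self.values.size)):
            raise LongRecError("boundaries must be strictly increasing frame indices")


def _pearson(a: np.ndarray, b: np.ndarray) -> tuple[float, bool]:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0, True
    return float(a @ b / (na * nb)), False


def frame_similarity(video: VideoStack, drop_threshold: float = 0.8,
                     downsample: int = 4) -> SimilarityTrace:
    """Per-frame Pearson correlation with the current epoch's reference.

    The reference is the first frame of the epoch; when similarity falls
    below ``drop_threshold`` a new epoch starts and the reference resets to
    that frame.  Frames are block-averaged ``downsample`` -fold first.
    Zero-variance frames get similarity 0 and are flagged.
    """
    if video.n_frames < 2:
        raise LongRecError("need at least 2 frames")
    ds = np.stack([downscale_local_mean(f, (downsample, downsample))
                   for f in video.frames])
    n = ds.shape[0]
    values = np.empty(n)
    boundaries = [0]
    flagged = []
    ref = ds[0]
    values[0] = 1.0
    for i in range(1, n):
        r, bad = _pearson(ds[i], ref)
        if bad:
            flagged.append(i)
        values[i] = r
        if r < drop_threshold:
            boundaries.append(i)
            ref = ds[i]
    return SimilarityTrace(values, boundaries, flagged)


def segment_behaviors(trace: SimilarityTrace, drop_threshold: float = 0.8,
                      min_epoch_frames: int = 1) -> list[tuple[int, int]]:
    """Epoch (start, end) spans from a similarity trace.

    A new epoch starts at every recorded boundary (similarity drop below
    threshold); epochs shorter than ``min_epoch_frames`` are merged
    forward into the next epoch (the last one merges backward).
    """
    n = trace.values.size
    starts = [b for b in trace.boundaries
              if b == 0 or trace.values[b] < drop_threshold]
    if not starts or starts[0] != 0:
        starts = [0] + starts
    spans = [(s, e) for s, e in zip(starts, starts[1:] + [n])]
    merged: list[tuple[int, int]] = []
    pending_start = None
    for s, e in spans:
        start = pending_start if pending_start is not None else s
        if e - start < min_epoch_frames:
            pending_start = start
            continue
        merged.append((start, e))
        pending_start = None
    if pending_start is not None:
        if merged:
            s0, _ = merged.pop()
            merged.append((s0, n))
        else:
            merged.append((pending_start, n))
    return merged


def stitch_st_maps(per_epoch_maps: list[SpatioTemporalMap],
                   resample_rows: bool = False) -> SpatioTemporalMap:
    """Column-wise concatenation of per-epoch ST maps in epoch order.

    Row counts must match (same intestine length) unless ``resample_rows``
    lets shorter maps be linearly resampled to the first map's rows.
    Epoch boundaries are recorded in the provenance.
    """
    if not per_epoch_maps:
        raise LongRecError("no maps to stitch")
    n_rows = per_epoch_maps[0].n_positions
    blocks = []
    for m in per_epoch_maps:
        v = m.values
        if v.shape[0] != n_rows:
            if not resample_rows:
                raise LongRecError(
                    f"row mismatch: {v.shape[0]} vs {n_rows}; enable resample_rows")
            old = np.linspace(0.0, 1.0, v.shape[0])
            new = np.linspace(0.0, 1.0, n_rows)
            v = np.stack([np.interp(new, old, v[:, j]) for j in range(v.shape[1])],
                         axis=1)
        blocks.append(v)
    boundaries = np.cumsum([0] + [b.shape[1] for b in blocks])[:-1]
    first = per_epoch_maps[0]
    return SpatioTemporalMap(
        np.concatenate(blocks, axis=1), first.frame_rate,
        first.position_spacing, first.otsu_threshold,
        provenance={"epoch_boundaries": boundaries.tolist(),
                    "n_epochs": len(blocks)})
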