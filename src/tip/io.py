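"""Video, centerline and configuration I/O.

All pixel data is handled internally as floating point in ``[0, 1]``.
Integer inputs are normalized by their dtype range at ingest; geometry is
kept in pixels with an optional ``pixel_pitch`` (mm/px) for physical-unit
reporting.  Coordinate convention throughout the package: origin at the
top-left corner, ``x`` = column index, ``y`` = row index.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


class VideoError(ValueError):
    """Raised for unreadable or inconsistent video input."""


@dataclass
class VideoStack:
    """Ordered grayscale frames with acquisition metadata.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Normalized intensities in ``[0, 1]``.
    frame_rate : float
        Acquisition rate in Hz.
    pixel_pitch : float, optional
        Physical pixel size in mm/px.
    """

    frames: np.ndarray
    frame_rate: float
    pixel_pitch: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise VideoError(f"frames must be (T, H, W), got shape {self.frames.shape}")
        if self.frame_rate is not None and self.frame_rate <= 0:
            raise VideoError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, i):
        return self.frames[i]

    def times(self) -> np.ndarray:
        """Frame timestamps in seconds."""
        return np.arange(self.n_frames) / self.frame_rate


def normalize_frames(raw: np.ndarray) -> np.ndarray:
    """Scale integer images by their dtype range; pass floats through.

    8-bit and 16-bit encodings of the same proportional data normalize to
    identical values (up to quantization).
    """
    raw = np.asarray(raw)
    if np.issubdtype(raw.dtype, np.integer):
        info = np.iinfo(raw.dtype)
        return raw.astype(np.float32) / float(info.max)
    out = raw.astype(np.float32, copy=False)
    return out


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def read_video(path: str | Path, frame_rate: float | None = None,
               pixel_pitch: float | None = None) -> VideoStack:
    """Read a multi-page TIFF (or AVI) into a normalized :class:`VideoStack`.

    Frame rate is taken from the JSON sidecar written by :func:`write_video`
    unless given explicitly; with neither present an error is raised.
    """
    path = Path(path)
    meta: dict = {}
    side = _sidecar_path(path)
    if side.exists():
        meta = json.loads(side.read_text())
    if path.suffix.lower() in (".tif", ".tiff"):
        try:
            raw = tifffile.imread(path)
        except Exception as exc:  # pragma: no cover - depends on corrupt input
            raise VideoError(f"cannot read TIFF {path}: {exc}") from exc
    elif path.suffix.lower() == ".avi":
        import imageio.v3 as iio

        raw = np.asarray(iio.imread(path))
        if raw.ndim == 4:  # RGB: collapse to gray
            raw = raw.mean(axis=-1)
    else:
        raise VideoError(f"unsupported video format: {path.suffix}")
    if raw.ndim == 2:
        raw = raw[None]
    if raw.ndim != 3:
        raise VideoError(f"expected single-channel pages in {path}, got shape {raw.shape}")
    fr = frame_rate if frame_rate is not None else meta.get("frame_rate")
    if fr is None:
        raise VideoError(
            f"no frame rate for {path}: pass frame_rate= or provide a JSON sidecar")
    pp = pixel_pitch if pixel_pitch is not None else meta.get("pixel_pitch")
    return VideoStack(normalize_frames(raw), float(fr), pp, meta)


def write_video(path: str | Path, video: VideoStack) -> Path:
    """Write a :class:`VideoStack` as 16-bit multi-page TIFF plus JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.clip(video.frames, 0.0, 1.0)
    tifffile.imwrite(path, (data * 65535.0 + 0.5).astype(np.uint16),
                     photometric="minisblack")
    meta = {k: v for k, v in video.meta.items() if _jsonable(v)}
    meta["frame_rate"] = video.frame_rate
    if video.pixel_pitch is not None:
        meta["pixel_pitch"] = video.pixel_pitch
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def read_centerline_csv(path: str | Path) -> np.ndarray:
    """Read an ordered centerline as an (n, 2) array of (x, y) pixels."""
    df = pd.read_csv(path)
    cols = [c for c in ("x_px", "y_px") if c in df.columns]
    if len(cols) == 2:
        return df[cols].to_numpy(float)
    return df.iloc[:, :2].to_numpy(float)


def write_centerline_csv(path: str | Path, points: np.ndarray) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pts = np.asarray(points, float)
    pd.DataFrame({"x_px": pts[:, 0], "y_px": pts[:, 1]}).to_csv(path, index=False)
    return path


@dataclass
class RunConfig:
    """Resolved parameters for a pipeline run; JSON round-trippable."""

    stages: list = field(default_factory=list)
    input_path: str | None = None
    output_dir: str = "tip_out"
    rng_seed: int = 0
    log_level: str = "INFO"
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def read(cls, path: str | Path) -> "RunConfig":
        return cls.from_json(Path(path).read_text())
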