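"""Reading and writing video stacks and pipeline artifacts.

The interchange format for video is a directory of zero-padded 8-bit
grayscale PNG frames plus a JSON sidecar holding frame count and pixel
pitch.  Intensities are floats in [0, 1] in memory (dark silhouettes below
the bright background) and are scaled by 255 on disk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

SIDECAR_NAME = "video.json"


@dataclass
class VideoStack:
    """An ordered grayscale frame sequence.

    Parameters
    ----------
    frames : ndarray of shape (n_frames, height, width)
        Float intensities in [0, 1].
    pixel_pitch_um : float
        Physical size of one pixel in micrometres.
    video_id : str
        Identifier used to derive per-video RNG streams and output names.
    """

    frames: np.ndarray
    pixel_pitch_um: float = 35.0
    video_id: str = "video"
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, height, width) array")


def as_frames(video) -> np.ndarray:
    """Accept a VideoStack or a bare (T, H, W) array; return the array."""
    if isinstance(video, VideoStack):
        return video.frames
    arr = np.asarray(video, dtype=np.float64)
    if arr.ndim != 3:
        raise ValueError("expected a VideoStack or (n_frames, height, width) array")
    return arr


def to_uint8(img: np.ndarray) -> np.ndarray:
    return np.clip(np.round(np.asarray(img, dtype=np.float64) * 255.0), 0, 255).astype(np.uint8)


def from_uint8(img: np.ndarray) -> np.ndarray:
    return np.asarray(img, dtype=np.float64) / 255.0


def write_video(video: VideoStack, out_dir: str | Path) -> Path:
    """Write a PNG frame sequence plus JSON sidecar; return the directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(video.frames):
        iio.imwrite(out_dir / f"frame_{i:05d}.png", to_uint8(frame))
    sidecar = {
        "video_id": video.video_id,
        "n_frames": int(video.n_frames),
        "pixel_pitch_um": float(video.pixel_pitch_um),
        **video.meta,
    }
    (out_dir / SIDECAR_NAME).write_text(json.dumps(sidecar, indent=2))
    return out_dir


def read_video(path: str | Path) -> VideoStack:
    """Read a video from a PNG-sequence directory (or a video file).

    Video-file input (AVI/MP4) requires an imageio ffmpeg plugin; when none
    is available a clear error points at the PNG-sequence format.
    """
    path = Path(path)
    if path.is_dir():
        frame_files = sorted(p for p in path.glob("*.png"))
        if not frame_files:
            raise FileNotFoundError(f"no PNG frames found in {path}")
        frames = np.stack([from_uint8(_read_gray(p)) for p in frame_files])
        meta: dict = {}
        sidecar = path / SIDECAR_NAME
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        return VideoStack(
            frames,
            pixel_pitch_um=float(meta.get("pixel_pitch_um", 35.0)),
            video_id=str(meta.get("video_id", path.name)),
            meta={k: v for k, v in meta.items()
                  if k not in {"video_id", "n_frames", "pixel_pitch_um"}},
        )
    try:
        raw = iio.imread(path)  # needs a codec plugin for AVI/MP4
    except Exception as exc:  # pragma: no cover - depends on plugins present
        raise RuntimeError(
            f"cannot decode {path}: no suitable imageio plugin; convert the "
            "video to a directory of PNG frames (the native format)"
        ) from exc
    arr = np.asarray(raw)
    if arr.ndim == 4:  # (T, H, W, C) -> luminance
        arr = arr.mean(axis=-1)
    return VideoStack(from_uint8(arr), video_id=path.stem)


def _read_gray(path: Path) -> np.ndarray:
    img = iio.imread(path)
    if img.ndim == 3:
        img = img.mean(axis=-1)
    return img


def write_image(path: str | Path, img: np.ndarray) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, to_uint8(img))


def read_image(path: str | Path) -> np.ndarray:
    return from_uint8(_read_gray(Path(path)))
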