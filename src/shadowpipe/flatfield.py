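"""Flat-field illumination correction for shadowgraph video.

Per pixel, corrected = (raw - offset) * gain with
gain = avg / calibration, where avg is the pixel's temporal mean and the
calibration value is the mean of a percentile window (default the sorted
ranks in (0.80, 0.90]) of the pixel's temporal intensity distribution.
With offset 0 this reduces to corrected = raw * avg / calibration.

For video whose background oscillates (independently drifting layers,
camera vibration), correcting in short segments — default 10 frames — keeps
the calibration frame local in time and suppresses the shading the
whole-video correction leaves behind.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import VideoStack, as_frames

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = (0.80, 0.90)
DEFAULT_SEGMENT_LENGTH = 10


@dataclass
class FlatfieldModel:
    """Fitted per-pixel correction for one video (or one segment)."""

    avg_frame: np.ndarray
    calibration_frame: np.ndarray
    offset: float | np.ndarray = 0.0
    percentile_window: tuple[float, float] = DEFAULT_WINDOW
    segment_length: int | None = DEFAULT_SEGMENT_LENGTH

    @property
    def gain_frame(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(
                self.calibration_frame > 0,
                self.avg_frame / self.calibration_frame,
                1.0,
            )


def calibration_frame(video, window: tuple[float, float] = DEFAULT_WINDOW) -> np.ndarray:
    """Per-pixel mean of a sorted-rank window of the temporal values.

    For T frames the window (lo, hi] selects 1-based ranks
    ceil(lo*T)+1 ... ceil(hi*T) of each pixel's ascending sort; e.g. a pixel
    seeing 1..100 over 100 frames with window (0.8, 0.9) yields the mean of
    ranks 81..90.  The window (0, 1) degenerates to the temporal mean.
    """
    frames = as_frames(video)
    lo, hi = window
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError("window must satisfy 0 <= lo < hi <= 1")
    T = frames.shape[0]
    i0 = int(np.ceil(lo * T))  # 0-based start = 1-based rank ceil(lo*T)+1
    i1 = int(np.ceil(hi * T))
    if i1 <= i0:
        raise ValueError(
            f"window {window} selects no samples over {T} frame(s); "
            "widen the window or use whole-video correction"
        )
    srt = np.sort(frames, axis=0)
    return srt[i0:i1].mean(axis=0)


def fit_flatfield(video, window=DEFAULT_WINDOW, offset=0.0) -> FlatfieldModel:
    frames = as_frames(video)
    return FlatfieldModel(
        avg_frame=frames.mean(axis=0),
        calibration_frame=calibration_frame(frames, window),
        offset=offset,
        percentile_window=tuple(window),
        segment_length=None,
    )


def _correct_block(frames: np.ndarray, window, offset, uniform_background) -> np.ndarray:
    model = fit_flatfield(frames, window, offset)
    calib = model.calibration_frame
    dead = calib <= 0.0
    if dead.any():
        logger.warning(
            "flatfield: %d dead-dark pixel(s) passed through uncorrected",
            int(dead.sum()),
        )
    if uniform_background:
        # brightness target is the scalar mean: background is driven to a
        # single level, flattening static illumination gradients
        with np.errstate(divide="ignore", invalid="ignore"):
            gain = np.where(dead, 1.0, model.avg_frame.mean() / calib)
    else:
        gain = model.gain_frame
    out = (frames - offset) * gain
    out[:, dead] = frames[:, dead]
    return np.clip(out, 0.0, 1.0)


def flatfield_correct(
    video,
    offset: float | np.ndarray = 0.0,
    segment_length: int | None = DEFAULT_SEGMENT_LENGTH,
    window: tuple[float, float] = DEFAULT_WINDOW,
    uniform_background: bool = False,
):
    """Apply the gain/offset correction, optionally in temporal segments.

    segment_length None (or >= n_frames) corrects the whole video with one
    calibration frame; otherwise each segment gets its own average and
    calibration frames.  A trailing remainder shorter than segment_length is
    merged into the previous segment, avoiding degenerate one-frame
    calibration.  Zero calibration pixels are passed through uncorrected
    with a logged warning.  Output is clipped to [0, 1].

    With the default per-pixel gain (temporal mean over calibration), a
    perfectly static video is a fixed point: the correction acts on
    temporal deviations only.  uniform_background=True instead targets the
    scalar mean brightness — every background pixel is driven toward one
    level, which also flattens *static* illumination gradients.
    """
    frames = as_frames(video)
    T = frames.shape[0]
    if segment_length is None or segment_length >= T:
        bounds = [(0, T)]
    else:
        if segment_length < 2:
            raise ValueError("segment_length must be >= 2")
        starts = list(range(0, T, segment_length))
        bounds = [(s, min(s + segment_length, T)) for s in starts]
        if len(bounds) > 1 and bounds[-1][1] - bounds[-1][0] < segment_length:
            last = bounds.pop()
            prev = bounds.pop()
            bounds.append((prev[0], last[1]))
    out = np.empty_like(frames)
    for s, e in bounds:
        out[s:e] = _correct_block(frames[s:e], window, offset,
                                  uniform_background)
    if isinstance(video, VideoStack):
        return VideoStack(out, pixel_pitch_um=video.pixel_pitch_um,
                          video_id=video.video_id, meta=dict(video.meta))
    return out
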