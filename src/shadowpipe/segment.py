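"""Six-step ROI segmentation for flat-fielded shadowgraph video.

Order of operations, applied per video: (1) Otsu binarization per frame
with dark-on polarity (silhouettes are darker than the background);
(2) temporal frequency masking — pixels that are foreground in more than a
set fraction of frames are static artifacts (scratches, bubbles) and are
switched off everywhere; (3) minimum-area filtering; (4) dilation with an
exact Euclidean disc, rejoining fragments of translucent organisms;
(5) optional second area filter; (6) connected-component region detection,
with crops cut from the flat-fielded grayscale at each bounding box.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import remove_small_objects

from .io import as_frames

logger = logging.getLogger(__name__)


@dataclass
class SegmentationParams:
    """Tunable segmentation thresholds.

    max_freq 0.8 suppresses static artifacts while keeping anything that
    moves; min_area_px is typically set between 15 and 50 px depending on
    the particle sizes of interest; dilation uses a disc of radius 5 px.
    """

    max_freq: float = 0.8
    min_area_px: int = 15
    dilation_radius: int = 5
    post_dilation_min_area_px: int | None = None
    connectivity: int = 8  # 4 or 8

    def validate(self) -> None:
        if not 0.0 < self.max_freq <= 1.0:
            raise ValueError("max_freq must be in (0, 1]")
        if self.min_area_px < 1:
            raise ValueError("min_area_px must be >= 1")
        if self.dilation_radius < 0:
            raise ValueError("dilation_radius must be >= 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class ROIRecord:
    """One detected region: the atom passed on to classification."""

    video_id: str
    frame_index: int
    roi_id: int
    bbox: tuple[int, int, int, int]  # (r0, c0, height, width), half-open
    area_px: int  # component area after dilation
    crop: np.ndarray  # grayscale cut from the flat-fielded frame
    original_size: tuple[int, int]  # (height, width) kept for the size input


def _skimage_connectivity(connectivity: int) -> int:
    return 1 if connectivity == 4 else 2


def binarize_otsu(frame: np.ndarray) -> np.ndarray:
    """Dark-on Otsu threshold: pixels strictly below the threshold become 1."""
    frame = np.asarray(frame, dtype=np.float64)
    if frame.min() == frame.max():
        logger.warning("binarize_otsu: constant frame, no foreground")
        return np.zeros_like(frame, dtype=bool)
    t = threshold_otsu(frame)
    return frame < t


def pixel_frequency(stack) -> np.ndarray:
    """Fraction of frames in which each pixel is foreground."""
    arr = np.asarray(as_frames(stack), dtype=np.float64)
    return arr.mean(axis=0)


def mask_frequent(stack, max_freq: float = 0.8) -> np.ndarray:
    """Switch off, in every frame, pixels whose frequency exceeds max_freq.

    'Exceeds' is strict: a pixel at exactly max_freq is untouched.
    """
    if not 0.0 < max_freq <= 1.0:
        raise ValueError("max_freq must be in (0, 1]")
    arr = np.asarray(as_frames(stack)).astype(bool)
    noisy = pixel_frequency(arr) > max_freq
    out = arr.copy()
    out[:, noisy] = False
    return out


def remove_small(frame: np.ndarray, min_area_px: int, connectivity: int = 8) -> np.ndarray:
    """Drop connected components strictly smaller than min_area_px."""
    if min_area_px < 1:
        raise ValueError("min_area_px must be >= 1")
    frame = np.asarray(frame).astype(bool)
    # max_size removes components with area <= value; "smaller than
    # min_area_px" is strict, so components of exactly min_area_px survive
    return remove_small_objects(
        frame, max_size=min_area_px - 1,
        connectivity=_skimage_connectivity(connectivity),
    )


def disc_footprint(radius: int) -> np.ndarray:
    """Exact Euclidean disc {(dy, dx): dy^2 + dx^2 <= radius^2}."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    return yy**2 + xx**2 <= radius**2


def dilate_disc(frame: np.ndarray, radius: int) -> np.ndarray:
    """Morphological dilation with the exact Euclidean disc; radius 0 is identity."""
    frame = np.asarray(frame).astype(bool)
    if radius == 0:
        return frame.copy()
    return ndimage.binary_dilation(frame, structure=disc_footprint(radius))


def detect_regions(frame: np.ndarray, connectivity: int = 8):
    """Connected components as (bbox, area) records, ordered by bbox origin.

    bbox is the tight half-open box (r0, c0, height, width).
    """
    frame = np.asarray(frame).astype(bool)
    labeled = cc_label(frame, connectivity=_skimage_connectivity(connectivity))
    regions = []
    for rp in regionprops(labeled):
        r0, c0, r1, c1 = rp.bbox
        regions.append(((int(r0), int(c0), int(r1 - r0), int(c1 - c0)), int(rp.area)))
    regions.sort(key=lambda reg: (reg[0][0], reg[0][1]))
    return regions


def binarize_video(video, per_frame: bool = True) -> np.ndarray:
    """Otsu-binarize every frame (default) or with one global threshold."""
    frames = as_frames(video)
    if per_frame:
        return np.stack([binarize_otsu(f) for f in frames])
    if frames.min() == frames.max():
        logger.warning("binarize_video: constant video, no foreground")
        return np.zeros(frames.shape, dtype=bool)
    t = threshold_otsu(frames.ravel())
    return frames < t


def segment_video(video, params: SegmentationParams | None = None,
                  flatfielded=None) -> list[ROIRecord]:
    """Run the full six-step chain; crops are cut from the flat-fielded video.

    `video` is binarized and masked; `flatfielded` (defaults to `video`)
    supplies the grayscale crops.  Both must be aligned frame-for-frame.
    """
    params = params or SegmentationParams()
    params.validate()
    frames = as_frames(video)
    gray = frames if flatfielded is None else as_frames(flatfielded)
    if gray.shape[0] != frames.shape[0]:
        raise ValueError("video and flatfielded frame counts differ")
    video_id = getattr(video, "video_id", "video")

    binary = binarize_video(frames)
    binary = mask_frequent(binary, params.max_freq)

    rois: list[ROIRecord] = []
    for fi in range(frames.shape[0]):
        bf = remove_small(binary[fi], params.min_area_px, params.connectivity)
        bf = dilate_disc(bf, params.dilation_radius)
        if params.post_dilation_min_area_px:
            bf = remove_small(bf, params.post_dilation_min_area_px,
                              params.connectivity)
        for roi_id, (bbox, area) in enumerate(detect_regions(bf, params.connectivity)):
            r0, c0, h, w = bbox
            crop = gray[fi, r0:r0 + h, c0:c0 + w].copy()
            rois.append(
                ROIRecord(
                    video_id=video_id,
                    frame_index=fi,
                    roi_id=roi_id,
                    bbox=bbox,
                    area_px=area,
                    crop=crop,
                    original_size=(h, w),
                )
            )
    return rois


def rois_to_frame(rois: list[ROIRecord]):
    """Bounding-box table matching the CSV interchange format."""
    import pandas as pd

    return pd.DataFrame(
        {
            "video_id": [r.video_id for r in rois],
            "frame_index": [r.frame_index for r in rois],
            "roi_id": [r.roi_id for r in rois],
            "r0": [r.bbox[0] for r in rois],
            "c0": [r.bbox[1] for r in rois],
            "height": [r.bbox[2] for r in rois],
            "width": [r.bbox[3] for r in rois],
            "area_px": [r.area_px for r in rois],
        }
    )


def write_rois(rois: list[ROIRecord], out_dir, csv_name: str = "rois.csv"):
    """Write crops as PNGs plus the bounding-box CSV; returns the CSV path."""
    from pathlib import Path

    from .io import write_image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for r in rois:
        write_image(
            out_dir / f"{r.video_id}_{r.frame_index:05d}_{r.roi_id:03d}.png",
            r.crop,
        )
    csv_path = out_dir / csv_name
    rois_to_frame(rois).to_csv(csv_path, index=False)
    return csv_path
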