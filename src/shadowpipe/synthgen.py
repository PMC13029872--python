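"""Synthetic shadowgraph scene generator with exact ground truth.

Emulates the imaging conditions of an in situ shadowgraph profiler: a
bright, near-uniform background modulated by a multiplicative illumination
gradient; dark organism silhouettes of distinct morphologies drifting
through the frame; static dark artifacts (lens scratches, trapped bubbles);
a slowly oscillating background layer (water density gradients / camera
vibration); additive sensor noise; and partially translucent silhouettes
whose binarized masks fragment into gaps.

Every rendered object carries an exact per-frame ground-truth mask and
bounding box, so segmentation recall and artifact rejection are measurable
without field data.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datasetprep import ImageRecord, LabeledImageSet
from .io import VideoStack

MORPHOLOGIES = ("vermiform", "copepod_like", "gelatinous_blob", "chain", "round_blob")


@dataclass
class ObjectSpec:
    """One moving silhouette.

    trajectory holds per-frame (row, col) centers; if shorter than the
    video, the object is only present for frames
    [start_frame, start_frame + len(trajectory)).
    """

    class_label: str
    morphology: str
    length_px: float
    darkness: float = 0.6  # intensity drop relative to local background
    translucency_gap_fraction: float = 0.0
    trajectory: np.ndarray | None = None  # (k, 2) float centers
    start_frame: int = 0
    rotation: float = 0.0  # degrees, CCW

    def validate(self, n_frames: int) -> None:
        if self.morphology not in MORPHOLOGIES:
            raise ValueError(f"unknown morphology {self.morphology!r}")
        if self.length_px < 3:
            raise ValueError("length_px must be >= 3")
        if not 0.0 <= self.darkness <= 1.0:
            raise ValueError("darkness must be in [0, 1]")
        if not 0.0 <= self.translucency_gap_fraction < 1.0:
            raise ValueError("translucency_gap_fraction must be in [0, 1)")
        if self.trajectory is not None:
            traj = np.asarray(self.trajectory, dtype=np.float64)
            if traj.ndim != 2 or traj.shape[1] != 2:
                raise ValueError("trajectory must be a (k, 2) array of centers")
            if self.start_frame + len(traj) > n_frames:
                raise ValueError("trajectory extends past the last frame")


@dataclass
class SceneSpec:
    """Full description of one synthetic video."""

    frame_height: int = 256
    frame_width: int = 256
    n_frames: int = 20
    background_level: float = 0.9
    illumination: dict = field(default_factory=lambda: {"kind": "flat"})
    artifacts: list = field(default_factory=list)
    oscillation: dict = field(
        default_factory=lambda: {"amplitude_px": 0.0, "period_frames": 20,
                                 "strength": 0.0}
    )
    objects: list = field(default_factory=list)
    noise_sigma: float = 0.0
    seed: int = 0
    video_id: str = "synthetic"
    pixel_pitch_um: float = 35.0

    def validate(self) -> None:
        if self.frame_height < 32 or self.frame_width < 32:
            raise ValueError("frame dimensions must be at least 32x32")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not 0.0 < self.background_level <= 1.0:
            raise ValueError("background_level must be in (0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for obj in self.objects:
            obj.validate(self.n_frames)


@dataclass
class GroundTruth:
    """Exact per-frame object records plus per-object original sizes.

    per_frame[i] is a list of dicts with keys
    class_label, bbox (r0, c0, height, width), mask (bool crop), area_px,
    object_index; boxes are 0-based half-open.
    """

    per_frame: list
    objects: list  # dicts: class_label, length_px, morphology

    def records(self) -> pd.DataFrame:
        rows = []
        for fi, regs in enumerate(self.per_frame):
            for reg in regs:
                r0, c0, h, w = reg["bbox"]
                rows.append(
                    {
                        "frame_index": fi,
                        "class_label": reg["class_label"],
                        "r0": r0,
                        "c0": c0,
                        "height": h,
                        "width": w,
                        "area_px": reg["area_px"],
                    }
                )
        return pd.DataFrame(
            rows,
            columns=["frame_index", "class_label", "r0", "c0", "height",
                     "width", "area_px"],
        )

    def to_csv(self, path: str | Path) -> None:
        self.records().to_csv(path, index=False)


def _rng_for(seed: int, video_id: str) -> np.random.Generator:
    # one stream per (seed, video_id) so batch generation is order-independent
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(video_id.encode())])
    )


def _silhouette_mask(
    morphology: str,
    length_px: float,
    rotation_deg: float,
    gap_fraction: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render one silhouette as a boolean stamp.

    Shapes are evaluated analytically in a rotated object frame (u along the
    body axis, v across), so rotation introduces no interpolation.  All
    proportions scale with length, keeping the silhouette shape
    scale-invariant (the point of the size-dimorphic pair).
    """
    L = float(length_px)
    half = int(np.ceil(L / 2)) + 2
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1].astype(np.float64)
    th = np.deg2rad(rotation_deg)
    # inverse rotation of canvas coords into the object frame
    u = np.cos(th) * xx + np.sin(th) * yy
    v = -np.sin(th) * xx + np.cos(th) * yy

    if morphology == "round_blob":
        mask = u**2 + v**2 <= (L / 2) ** 2
    elif morphology == "gelatinous_blob":
        a, b = L / 2, 0.35 * L
        mask = (np.abs(u / a) ** 1.5 + np.abs(v / b) ** 1.5) <= 1.0
    elif morphology == "vermiform":
        amp, cycles = 0.08 * L, 1.5
        thick = max(1.2, 0.06 * L)
        spine = amp * np.sin(2 * np.pi * cycles * u / L)
        mask = (np.abs(u) <= L / 2) & (np.abs(v - spine) <= thick)
    elif morphology == "copepod_like":
        a, b = 0.35 * L, 0.18 * L
        body = ((u - 0.1 * L) / a) ** 2 + (v / b) ** 2 <= 1.0
        tail = (u >= -0.5 * L) & (u <= -0.2 * L) & (np.abs(v) <= max(1.0, 0.04 * L))
        mask = body | tail
    elif morphology == "chain":
        r = 0.11 * L
        centers = np.linspace(-0.375 * L, 0.375 * L, 4)
        mask = np.zeros_like(u, dtype=bool)
        for cu in centers:
            mask |= (u - cu) ** 2 + v**2 <= r**2
        mask &= np.abs(u) <= L / 2 + r
    else:
        raise ValueError(f"unknown morphology {morphology!r}")

    if gap_fraction > 0.0 and mask.any():
        mask = _apply_gaps(mask, u, L, gap_fraction, rng)
    return mask


def _apply_gaps(
    mask: np.ndarray, u: np.ndarray, length: float, fraction: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Zero the silhouette on random interior runs along the body axis."""
    n_gaps = max(1, int(round(fraction * 3)))
    total = fraction * length
    widths = np.full(n_gaps, total / n_gaps)
    # interior positions only: keep the endpoints of the body intact
    positions = rng.uniform(-0.3 * length, 0.3 * length, size=n_gaps)
    out = mask.copy()
    for pos, w in zip(positions, widths):
        out &= ~((u >= pos - w / 2) & (u <= pos + w / 2))
    return out


def _illumination_field(spec: SceneSpec) -> np.ndarray:
    h, w = spec.frame_height, spec.frame_width
    ill = spec.illumination or {"kind": "flat"}
    kind = ill.get("kind", "flat")
    if kind == "flat":
        return np.ones((h, w))
    if kind == "linear":
        lo = float(ill.get("lo", 0.6))
        hi = float(ill.get("hi", 1.0))
        axis = ill.get("axis", "col")
        ramp = np.linspace(lo, hi, w if axis == "col" else h)
        return np.tile(ramp, (h, 1)) if axis == "col" else np.tile(ramp[:, None], (1, w))
    if kind == "radial":
        amp = float(ill.get("amplitude", 0.3))
        yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
        r = np.hypot(yy - (h - 1) / 2, xx - (w - 1) / 2)
        return 1.0 - amp * (r / r.max()) ** 2
    raise ValueError(f"unknown illumination kind {kind!r}")


def _artifact_mask(spec: SceneSpec) -> np.ndarray:
    """Static dark shapes (scratches / bubbles), identical in every frame."""
    h, w = spec.frame_height, spec.frame_width
    mask = np.zeros((h, w), dtype=np.float64)
    for art in spec.artifacts:
        kind = art.get("kind", "disk")
        darkness = float(art.get("darkness", 0.5))
        r0, c0 = art["center"]
        if kind == "disk":
            rad = float(art.get("radius", 6))
            yy, xx = np.mgrid[0:h, 0:w]
            m = (yy - r0) ** 2 + (xx - c0) ** 2 <= rad**2
        elif kind == "scratch":
            ln = int(art.get("length", 40))
            wd = int(art.get("width", 2))
            m = np.zeros((h, w), dtype=bool)
            rr = slice(max(0, r0 - wd // 2), min(h, r0 + (wd + 1) // 2))
            cc = slice(max(0, c0 - ln // 2), min(w, c0 + (ln + 1) // 2))
            m[rr, cc] = True
        else:
            raise ValueError(f"unknown artifact kind {kind!r}")
        mask = np.maximum(mask, m.astype(np.float64) * darkness)
    return mask


def _oscillation_layer(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray | None:
    """A smooth dark layer drifting sinusoidally across columns.

    Mimics the independently moving background layers seen in field video;
    amplitude_px is the drift amplitude, strength the intensity dip.
    """
    osc = spec.oscillation or {}
    strength = float(osc.get("strength", 0.0))
    if strength <= 0.0:
        return None
    h, w = spec.frame_height, spec.frame_width
    n_bumps = int(osc.get("n_bumps", 3))
    sigma = float(osc.get("bump_sigma", w / 8))
    centers = rng.uniform(0, w, size=n_bumps)
    base = np.zeros(w)
    cols = np.arange(w, dtype=np.float64)
    for c in centers:
        # wrap-around so drifting the layer never runs off the frame
        d = np.minimum(np.abs(cols - c), w - np.abs(cols - c))
        base += np.exp(-0.5 * (d / sigma) ** 2)
    base = strength * base / max(base.max(), 1e-12)
    return np.tile(base, (h, 1))


def generate_video(spec: SceneSpec) -> tuple[VideoStack, GroundTruth]:
    """Render a scene into a VideoStack with exact GroundTruth.

    Deterministic given spec.seed (and video_id).  Background =
    background_level x illumination gradient, minus the oscillating layer
    and static artifacts, plus additive Gaussian noise; objects darken their
    silhouette pixels.  Intensities clipped to [0, 1].
    """
    spec.validate()
    rng = _rng_for(spec.seed, spec.video_id)
    h, w = spec.frame_height, spec.frame_width
    illum = _illumination_field(spec)
    artifacts = _artifact_mask(spec)
    osc = _oscillation_layer(spec, rng)

    # pre-render object stamps and trajectories
    stamps, trajs = [], []
    for obj in spec.objects:
        stamp = _silhouette_mask(
            obj.morphology, obj.length_px, obj.rotation,
            obj.translucency_gap_fraction, rng,
        )
        if obj.trajectory is not None:
            traj = np.asarray(obj.trajectory, dtype=np.float64)
            start = obj.start_frame
        else:
            # straight crossing at constant speed, random entry edge
            row = rng.uniform(0.2 * h, 0.8 * h)
            c_start, c_end = -obj.length_px, w + obj.length_px
            if rng.random() < 0.5:
                c_start, c_end = c_end, c_start
            cols = np.linspace(c_start, c_end, spec.n_frames)
            rows = np.full(spec.n_frames, row)
            traj = np.stack([rows, cols], axis=1)
            start = 0
        stamps.append(stamp)
        trajs.append((start, traj))

    frames = np.empty((spec.n_frames, h, w), dtype=np.float64)
    per_frame: list = [[] for _ in range(spec.n_frames)]
    for t in range(spec.n_frames):
        frame = spec.background_level * illum.copy()
        if osc is not None:
            amp = float(spec.oscillation.get("amplitude_px", 0.0))
            period = float(spec.oscillation.get("period_frames", 20))
            shift = amp * np.sin(2 * np.pi * t / period)
            k = int(np.round(shift))
            frame -= np.roll(osc, k, axis=1)
        frame -= artifacts
        for oi, (obj, stamp, (start, traj)) in enumerate(zip(spec.objects, stamps, trajs)):
            if not (start <= t < start + len(traj)):
                continue
            rec = _render_stamp(frame, stamp, traj[t - start], obj.darkness)
            if rec is not None:
                rec["class_label"] = obj.class_label
                rec["object_index"] = oi
                per_frame[t].append(rec)
        if spec.noise_sigma > 0:
            frame = frame + rng.normal(0.0, spec.noise_sigma, size=frame.shape)
        frames[t] = np.clip(frame, 0.0, 1.0)

    # deterministic record order per frame, matching detect_regions
    for t in range(spec.n_frames):
        per_frame[t].sort(key=lambda r: (r["bbox"][0], r["bbox"][1]))

    video = VideoStack(frames, pixel_pitch_um=spec.pixel_pitch_um,
                       video_id=spec.video_id)
    gt = GroundTruth(
        per_frame=per_frame,
        objects=[
            {"class_label": o.class_label, "length_px": o.length_px,
             "morphology": o.morphology}
            for o in spec.objects
        ],
    )
    return video, gt


def _render_stamp(frame, stamp, center, darkness):
    """Darken stamp pixels around an (row, col) center; return the GT record."""
    h, w = frame.shape
    sh, sw = stamp.shape
    r0 = int(np.round(center[0])) - sh // 2
    c0 = int(np.round(center[1])) - sw // 2
    rr0, cc0 = max(r0, 0), max(c0, 0)
    rr1, cc1 = min(r0 + sh, h), min(c0 + sw, w)
    if rr1 <= rr0 or cc1 <= cc0:
        return None
    sub = stamp[rr0 - r0:rr1 - r0, cc0 - c0:cc1 - c0]
    if not sub.any():
        return None
    frame[rr0:rr1, cc0:cc1][sub] -= darkness
    rows = np.any(sub, axis=1).nonzero()[0]
    cols = np.any(sub, axis=0).nonzero()[0]
    tr0, tr1 = rr0 + rows[0], rr0 + rows[-1] + 1
    tc0, tc1 = cc0 + cols[0], cc0 + cols[-1] + 1
    tight = sub[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
    return {
        "bbox": (int(tr0), int(tc0), int(tr1 - tr0), int(tc1 - tc0)),
        "mask": tight.copy(),
        "area_px": int(sub.sum()),
    }


def generate_labeled_dataset(
    class_specs: dict, seed: int = 0, background_level: float = 0.92,
) -> LabeledImageSet:
    """Render a class-per-label image set with known original sizes.

    class_specs maps label -> dict with keys
    morphology, length_mean, length_sd, n (and optional darkness,
    gap_fraction).  Each image is one silhouette on a canvas whose side
    scales with the drawn length, so original_size carries the organism-size
    signal exactly as a real ROI crop would.
    """
    records = []
    for label in sorted(class_specs):
        cs = class_specs[label]
        morph = cs["morphology"]
        if morph not in MORPHOLOGIES:
            raise ValueError(f"unknown morphology {morph!r} for class {label!r}")
        n = int(cs["n"])
        if n < 1:
            raise ValueError(f"class {label!r} needs n >= 1")
        rng = np.random.default_rng(
            np.random.SeedSequence([int(seed), zlib.crc32(label.encode())])
        )
        for i in range(n):
            length = max(3.0, rng.normal(cs["length_mean"], cs.get("length_sd", 0.0)))
            rot = rng.uniform(0, 360)
            stamp = _silhouette_mask(
                morph, length, rot, cs.get("gap_fraction", 0.0), rng
            )
            rows = np.any(stamp, axis=1).nonzero()[0]
            cols = np.any(stamp, axis=0).nonzero()[0]
            tight = stamp[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
            # padding scales with the organism so the canvas framing is
            # size-invariant: after resizing, framing betrays nothing
            pad = max(2, int(round(0.1 * length)))
            img = np.full(
                (tight.shape[0] + 2 * pad, tight.shape[1] + 2 * pad),
                background_level,
            )
            darkness = cs.get("darkness", float(rng.uniform(0.5, 0.8)))
            img[pad:-pad, pad:-pad][tight] -= darkness
            img = np.clip(img, 0.0, 1.0)
            records.append(
                ImageRecord(
                    image=img,
                    label=label,
                    original_size=(img.shape[0], img.shape[1]),
                    name=f"{label}_{i:05d}.png",
                    provenance="synthetic",
                )
            )
    return LabeledImageSet(records)


def size_dimorphic_pair_specs(
    n_per_class: int = 60,
    small=("small_bodied", 30.0, 2.0),
    large=("large_bodied", 120.0, 8.0),
    morphology: str = "vermiform",
) -> dict:
    """Two classes identical in silhouette shape, disjoint in length.

    Emulates the chaetognath-vs-larvacean confusion: after resizing to a
    common square the classes are indistinguishable by shape, but their
    stored original sizes separate them with no overlap at +/-3 sd.
    """
    out = {}
    for name, mean, sd in (small, large):
        out[name] = {
            "morphology": morphology,
            "length_mean": mean,
            "length_sd": sd,
            "n": n_per_class,
        }
    return out
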