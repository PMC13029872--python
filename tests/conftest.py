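"""Shared fixtures and independent brute-force oracles."""

from collections import deque

import numpy as np
import pytest

from shadowpipe.synthgen import ObjectSpec, SceneSpec, generate_video


# --- independent oracles --------------------------------------------------


def flood_fill_components(frame, connectivity=8):
    """BFS connected components of a binary frame.

    Returns a list of sets of (r, c) pixel coordinates; the independent
    oracle for region detection and minimum-area filtering.
    """
    frame = np.asarray(frame).astype(bool)
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(frame, dtype=bool)
    comps = []
    h, w = frame.shape
    for r in range(h):
        for c in range(w):
            if frame[r, c] and not seen[r, c]:
                comp = set()
                q = deque([(r, c)])
                seen[r, c] = True
                while q:
                    y, x = q.popleft()
                    comp.add((y, x))
                    for dy, dx in nbrs:
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and frame[ny, nx] \
                                and not seen[ny, nx]:
                            seen[ny, nx] = True
                            q.append((ny, nx))
                comps.append(comp)
    return comps


def exhaustive_otsu(frame, n_bins=256):
    """Threshold maximizing between-class variance by exhaustive search."""
    hist, edges = np.histogram(np.asarray(frame).ravel(), bins=n_bins,
                               range=(0.0, 1.0))
    centers = (edges[:-1] + edges[1:]) / 2
    total = hist.sum()
    best_t, best_var = centers[0], -1.0
    for k in range(1, n_bins):
        w0 = hist[:k].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[:k] * centers[:k]).sum() / w0
        mu1 = (hist[k:] * centers[k:]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_t = var, centers[k]
    return best_t


def disc_offsets(radius):
    """Integer offsets with dy^2 + dx^2 <= radius^2, by direct enumeration."""
    return {
        (dy, dx)
        for dy in range(-radius, radius + 1)
        for dx in range(-radius, radius + 1)
        if dy * dy + dx * dx <= radius * radius
    }


# --- fixtures -------------------------------------------------------------


@pytest.fixture(scope="session")
def crossing_scene():
    """One moving silhouette plus one static artifact, clean regime."""
    traj = np.stack([np.full(12, 60.0), np.linspace(20, 100, 12)], axis=1)
    spec = SceneSpec(
        frame_height=128,
        frame_width=128,
        n_frames=12,
        background_level=0.9,
        artifacts=[{"kind": "disk", "center": (100, 100), "radius": 6,
                    "darkness": 0.6}],
        objects=[ObjectSpec("Crustacean", "copepod_like", 36, darkness=0.6,
                            trajectory=traj)],
        seed=3,
        video_id="crossing",
    )
    video, gt = generate_video(spec)
    return spec, video, gt


@pytest.fixture(scope="session")
def dimorphic_dataset():
    """Standardized size-dimorphic pair with a train/val/test split."""
    from shadowpipe.datasetprep import split_dataset, standardize_dataset
    from shadowpipe.synthgen import generate_labeled_dataset, size_dimorphic_pair_specs

    specs = size_dimorphic_pair_specs(n_per_class=60)
    ds = generate_labeled_dataset(specs, seed=11)
    ds = standardize_dataset(ds, target_px=48)
    return split_dataset(ds, seed=5)
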