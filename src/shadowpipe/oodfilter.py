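"""Gradient-histogram pre-filter for out-of-distribution camera aberrations.

Many camera aberrations (flat glare regions, smooth density gradients) have
a distinct spike in their gradient-magnitude histogram: most of the image's
gradient mass collapses into one bin.  The spike score is that maximum bin
mass fraction — 1.0 for a constant image, small for textured organism
crops.  Images scoring above a threshold are flagged before they can reach
the classifier.  The statistic is an interpretable stand-in exported with
every score so users can recalibrate the threshold per instrument; the
filter is imperfect by design and some OOD images will pass it.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

DEFAULT_N_BINS = 64
DEFAULT_THRESHOLD = 0.5


def gradient_spike_score(img: np.ndarray, n_bins: int = DEFAULT_N_BINS) -> float:
    """Max mass fraction in one bin of the gradient-magnitude histogram.

    Gradients by central differences; histogram over [0, max].  Invariant
    to intensity shifts and to transposition.  Score 1.0 iff all gradient
    magnitudes fall in a single bin (e.g. a constant image).
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2 or img.shape[0] < 3 or img.shape[1] < 3:
        raise ValueError("image must be 2-D grayscale, at least 3x3")
    gy, gx = np.gradient(img)
    mag = np.hypot(gy, gx).ravel()
    top = mag.max()
    if top == 0.0:
        return 1.0
    counts, _ = np.histogram(mag, bins=n_bins, range=(0.0, top))
    return float(counts.max() / counts.sum())


def filter_ood(images, score_threshold: float = DEFAULT_THRESHOLD,
               n_bins: int = DEFAULT_N_BINS):
    """Partition images into (kept, flagged) by strict score > threshold."""
    if not 0.0 < score_threshold <= 1.0:
        raise ValueError("score_threshold must be in (0, 1]")
    kept, flagged = [], []
    for img in images:
        if gradient_spike_score(img, n_bins) > score_threshold:
            flagged.append(img)
        else:
            kept.append(img)
    return kept, flagged


class GradientSpikeFilter(BaseEstimator):
    """Sklearn-style wrapper: predict(X) -> boolean flags (True = OOD).

    Stateless aside from its parameters; fit exists for pipeline
    compatibility.
    """

    def __init__(self, score_threshold: float = DEFAULT_THRESHOLD,
                 n_bins: int = DEFAULT_N_BINS):
        self.score_threshold = score_threshold
        self.n_bins = n_bins

    def fit(self, X, y=None):
        if not 0.0 < self.score_threshold <= 1.0:
            raise ValueError("score_threshold must be in (0, 1]")
        self.n_features_in_ = len(X) if hasattr(X, "__len__") else None
        return self

    def score_samples(self, X):
        return np.array([gradient_spike_score(img, self.n_bins) for img in X])

    def predict(self, X):
        return self.score_samples(X) > self.score_threshold
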