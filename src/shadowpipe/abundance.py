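"""Volume-normalized abundance estimation with bootstrap intervals.

Per-class ROI counts from each video clip are divided by the water volume
sampled during the clip (pump flow rate x duration, 18 L/s x 30 s = 540 L
at the instrument defaults) to give abundances in organisms per liter.
Series across clips are trimmed of single-pass 3-standard-deviation
outliers, then a percentile bootstrap of the mean gives per-class 95%
confidence intervals.  One detection counts once; organisms spanning
several frames are not deduplicated, so absolute abundances are somewhat
overinflated while relative trends remain valid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LITERS_PER_CUBIC_INCH = 0.016387064


@dataclass
class InstrumentGeometry:
    """Shadowgraph imager geometry and flow characteristics."""

    pixel_pitch_um: float = 35.0
    frame_width_px: int = 2440
    frame_height_px: int = 2048
    min_resolvable_px: int = 10  # pixels needed to represent an object
    frame_volume_L: float = 0.74  # liters imaged per frame
    flow_rate_L_per_s: float = 18.0

    def validate(self) -> None:
        vals = (self.pixel_pitch_um, self.frame_width_px, self.frame_height_px,
                self.min_resolvable_px, self.frame_volume_L,
                self.flow_rate_L_per_s)
        if any(v <= 0 for v in vals):
            raise ValueError("all geometry fields must be positive")


def size_bounds(geom: InstrumentGeometry | None = None) -> tuple[float, float]:
    """(min, max) resolvable object size in micrometres.

    Lower bound: minimum representable pixel count times pixel pitch
    (10 px x 35 um = 350 um at defaults); upper bound: the longer frame
    dimension times pixel pitch (2440 px -> 85,400 um = 85.4 mm).
    """
    geom = geom or InstrumentGeometry()
    geom.validate()
    lo = geom.min_resolvable_px * geom.pixel_pitch_um
    hi = max(geom.frame_width_px, geom.frame_height_px) * geom.pixel_pitch_um
    return float(lo), float(hi)


def cubic_inches_to_liters(v_in3: float) -> float:
    if v_in3 < 0:
        raise ValueError("volume must be >= 0")
    return v_in3 * LITERS_PER_CUBIC_INCH


def volume_sampled(flow_rate_L_per_s: float, duration_s: float) -> float:
    """Water volume pumped past the imager during one clip, in liters."""
    if flow_rate_L_per_s <= 0 or duration_s <= 0:
        raise ValueError("flow rate and duration must be positive")
    return flow_rate_L_per_s * duration_s


def abundances(counts: pd.DataFrame, volume_L: float) -> pd.DataFrame:
    """Per-(video, class) counts -> organisms per liter.

    counts needs columns video_id, class_label, count (extra columns such
    as a timestamp pass through).
    """
    if volume_L <= 0:
        raise ValueError("volume must be positive")
    out = counts.copy()
    out["volume_L"] = volume_L
    out["org_per_L"] = out["count"] / volume_L
    return out


def remove_outliers(series, k_sd: float = 3.0):
    """Single-pass trim at k standard deviations from the mean.

    Mean and SD come from the full series once (no re-iteration); a
    degenerate SD of 0 removes nothing.  Returns (kept, removed) index
    partitions of the input.
    """
    x = np.asarray(series, dtype=np.float64)
    if x.size < 2:
        raise ValueError("series must have at least 2 points")
    mu = x.mean()
    sd = x.std(ddof=1)
    if sd == 0.0:
        return x.copy(), np.array([], dtype=np.float64)
    keep = np.abs(x - mu) <= k_sd * sd
    return x[keep], x[~keep]


def bootstrap_ci(series, B: int = 1000, level: float = 0.95,
                 seed: int = 0) -> tuple[float, float]:
    """Percentile bootstrap CI for the mean.

    B resamples with replacement; the interval is the empirical
    (alpha/2, 1 - alpha/2) quantiles of the resampled means.  Deterministic
    given the seed.  (The BCa variant some reference tools default to is
    intentionally not the default here; percentile is simpler and exactly
    reproducible.)
    """
    x = np.asarray(series, dtype=np.float64)
    if x.size < 2:
        raise ValueError("series must have at least 2 points")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if B < 100:
        warnings.warn("B < 100 gives unstable quantiles", stacklevel=2)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(B, x.size))
    means = x[idx].mean(axis=1)
    alpha = 1.0 - level
    lo, hi = np.quantile(means, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def summarize_abundances(
    table: pd.DataFrame,
    k_sd: float = 3.0,
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-class mean abundance with trimmed bootstrap CI.

    table needs columns class_label and org_per_L (one row per video).
    """
    rows = []
    for label, grp in table.groupby("class_label", sort=True):
        x = grp["org_per_L"].to_numpy(dtype=np.float64)
        if x.size >= 2:
            kept, removed = remove_outliers(x, k_sd)
            lo, hi = bootstrap_ci(kept, B=B, level=level, seed=seed)
        else:
            kept, removed = x, np.array([])
            lo = hi = float(x.mean())
        rows.append(
            {
                "class_label": label,
                "n_videos": int(x.size),
                "n_kept": int(kept.size),
                "n_outliers": int(removed.size),
                "mean_org_per_L": float(kept.mean()),
                "ci_lo": lo,
                "ci_hi": hi,
            }
        )
    return pd.DataFrame(rows)


def plot_abundance_series(table: pd.DataFrame, path=None):
    """Abundance vs. video index, colored by time order, one panel per class."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    classes = sorted(table["class_label"].unique())
    fig, axes = plt.subplots(len(classes), 1, sharex=True,
                             figsize=(7, 2.2 * max(len(classes), 1)))
    axes = np.atleast_1d(axes)
    for ax, label in zip(axes, classes):
        grp = table[table["class_label"] == label]
        order = np.arange(len(grp))
        sc = ax.scatter(order, grp["org_per_L"], c=order, cmap="viridis", s=14)
        ax.set_ylabel(f"{label}\n(org/L)")
    axes[-1].set_xlabel("video (time order)")
    fig.colorbar(sc, ax=axes, label="time order")
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
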