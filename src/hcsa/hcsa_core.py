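"""Hemoglobin-contrast computation and Otsu classification of Hb blush.

Whole blood absorbs green light far more strongly than red, so on a two- or
three-channel frame the difference (weak-absorption channel minus
strong-absorption channel) is large wherever hemoglobin is present.  The
per-series min-max normalized difference is the *contrast image*; Otsu's
criterion splits its values into hemoglobin-containing pixels (the "Hb
blush") and everything else.  The threshold search is implemented here from
first principles — it is the classification primitive the whole pipeline
rests on — and every call can be checked against an exhaustive search over
the candidate bin edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ConfigError,
    DegenerateContrastError,
    DegenerateInputError,
    ShapeMismatchError,
)
from .geometry import RoiMask
from .io_formats import ImageSeries, RunConfig


@dataclass
class ContrastStack:
    """Per-frame scalar hemoglobin-contrast images in [0, 1].

    Higher values mean more hemoglobin.  ``norm_min``/``norm_max`` record the
    raw-difference range used for the series-global normalization.
    """

    frames: np.ndarray
    norm_min: float
    norm_max: float

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class ThresholdResult:
    """An Otsu threshold on contrast values.

    The classification rule is ``value > threshold`` => hemoglobin-containing.
    """

    threshold: float
    between_class_variance: float
    n_bins: int
    histogram_range: tuple[float, float]


@dataclass
class BlushMeasurement:
    """Hb-classified pixel count within the ventricle ROI of one frame."""

    frame_index: int
    blush_px: int
    roi_area_px: int

    def __post_init__(self) -> None:
        if not 0 <= self.blush_px <= self.roi_area_px:
            raise ValueError("blush_px must lie in [0, roi_area_px]")


def compute_hb_contrast(series: ImageSeries, config: RunConfig) -> ContrastStack:
    """Build the hemoglobin-contrast stack for a series.

    channel_difference mode subtracts the strongly absorbed channel from the
    weakly absorbed one and min-max normalizes the difference over the whole
    series, so contrast values are comparable across frames.
    single_channel_inverted mode (for grayscale data where blood is dark)
    normalizes the single channel and inverts it.
    """
    if config.contrast_mode == "channel_difference":
        if series.n_channels < 2:
            raise ConfigError(
                "channel_difference mode needs a multi-channel series; "
                "use contrast_mode=single_channel_inverted for grayscale data"
            )
        for role in ("weak", "strong"):
            if role not in config.channel_roles:
                raise ConfigError(f"channel_roles lacks the {role!r} channel")
        weak = series.channel(config.channel_roles["weak"]).astype(np.float64)
        strong = series.channel(config.channel_roles["strong"]).astype(np.float64)
        raw = weak - strong
    else:
        raw = series.channel(0).astype(np.float64)
    lo, hi = float(raw.min()), float(raw.max())
    if hi == lo:
        raise DegenerateContrastError(
            "series has zero dynamic range; cannot form a contrast image"
        )
    norm = (raw - lo) / (hi - lo)
    if config.contrast_mode == "single_channel_inverted":
        norm = 1.0 - norm
    return ContrastStack(frames=norm, norm_min=lo, norm_max=hi)


def between_class_variance(
    hist: np.ndarray, centers: np.ndarray
) -> np.ndarray:
    """Otsu criterion w0*w1*(mu0-mu1)^2 at every interior bin edge.

    Returns an array of length ``len(hist) - 1``; entry k is the criterion
    for the split {bins <= k} vs {bins > k}.  Splits with an empty class
    score 0.
    """
    w = hist.astype(np.float64) / hist.sum()
    omega0 = np.cumsum(w)[:-1]
    omega1 = 1.0 - omega0
    cummu = np.cumsum(w * centers)
    mu_total = cummu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = cummu[:-1] / omega0
        mu1 = (mu_total - cummu[:-1]) / omega1
        crit = omega0 * omega1 * (mu0 - mu1) ** 2
    crit[(omega0 <= 0) | (omega1 <= 0)] = 0.0
    return crit


def otsu_threshold(values, n_bins: int = 256) -> ThresholdResult:
    """Otsu's method over an equal-width histogram of the observed range.

    Values are binned into ``n_bins`` bins spanning [min, max]; the
    candidate thresholds are the interior bin edges, and the returned edge
    maximizes the between-class variance, ties broken toward the lowest
    threshold (so borderline pixels count as blood).
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size < 2:
        raise DegenerateInputError("need >= 2 values to threshold")
    if n_bins < 2:
        raise ConfigError("n_bins must be >= 2")
    lo, hi = float(v.min()), float(v.max())
    if lo == hi:
        raise DegenerateInputError("all values identical; no threshold exists")
    hist, edges = np.histogram(v, bins=n_bins, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2.0
    crit = between_class_variance(hist, centers)
    k = int(np.argmax(crit))  # first maximum == lowest qualifying edge
    return ThresholdResult(
        threshold=float(edges[k + 1]),
        between_class_variance=float(crit[k]),
        n_bins=int(n_bins),
        histogram_range=(lo, hi),
    )


def classify_hb(values, threshold: ThresholdResult | float) -> np.ndarray:
    """Boolean hemoglobin classification: contrast strictly above threshold."""
    t = threshold.threshold if isinstance(threshold, ThresholdResult) else threshold
    return np.asarray(values) > t


def measure_blush(
    contrast_frame: np.ndarray,
    roi_mask: RoiMask,
    threshold: ThresholdResult | float,
) -> BlushMeasurement:
    """Count Hb-classified pixels inside the ventricle ROI of one frame."""
    frame = np.asarray(contrast_frame)
    if frame.shape != roi_mask.mask.shape:
        raise ShapeMismatchError(
            f"contrast frame {frame.shape} vs ROI mask {roi_mask.mask.shape}"
        )
    blush = int(np.count_nonzero(classify_hb(frame, threshold) & roi_mask.mask))
    return BlushMeasurement(
        frame_index=roi_mask.frame_index,
        blush_px=blush,
        roi_area_px=roi_mask.area_px,
    )
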