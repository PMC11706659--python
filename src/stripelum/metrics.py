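"""Per-fish luminance metrics: ROI extraction, stripe peaks, Weber contrast.

The striped trunk of a calibrated image yields a bimodal histogram of
luminance values: the lower peak is the dark-stripe luminance ``L_min``, the
higher the light-stripe luminance ``L_max``.  Stripe contrast is the Weber
contrast

    C_W = (L_max - L_min) / L_min,

the relative luminance difference between light and dark stripes.  Mean
luminance is taken on the long-wave (red) channel — the channel a fish
luminance mechanism is thought to draw on — while the peak histogram uses the
combined greyscale (unweighted channel mean); both channels are configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .calibration import CalibratedImage, batch_scale

__all__ = [
    "RoiSample",
    "StripeMetrics",
    "HistogramConfig",
    "UnimodalHistogramError",
    "apply_roi",
    "mean_luminance",
    "stripe_peaks",
    "weber_contrast",
    "measure_batch",
]

logger = logging.getLogger(__name__)


class UnimodalHistogramError(ValueError):
    """The ROI histogram shows fewer than two qualifying peaks."""


@dataclass(frozen=True)
class RoiSample:
    """In-ROI luminance values for one fish.

    ``longwave`` holds the long-wave-channel values used for mean luminance;
    ``grey`` the combined-greyscale values used for the peak histogram.  For
    single-channel images the two coincide.
    """

    longwave: np.ndarray
    grey: np.ndarray

    def __post_init__(self):
        if self.longwave.size == 0:
            raise ValueError("empty ROI sample")

    @property
    def n_pixels(self) -> int:
        return int(self.longwave.size)


@dataclass(frozen=True)
class StripeMetrics:
    """One fish's luminance metrics plus its design labels."""

    fish_id: str
    mean_luminance: float
    l_min: float | None
    l_max: float | None
    weber: float | None
    n_pixels: int
    arena: str | None = None
    stimulus: str | None = None
    session: str | None = None
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class HistogramConfig:
    """Histogram and peak-detection settings for stripe-peak extraction.

    256 bins over [0, 100] with a 3-bin moving-average smooth and a 10-bin
    minimum peak separation; peak values are reported as bin centres, the
    read-off a histogram maximum gives.
    """

    bins: int = 256
    value_range: tuple[float, float] = (0.0, 100.0)
    smoothing_window: int = 3
    min_separation: int = 10
    channel: str = "grey"  # "grey" (combined) or "longwave"

    def __post_init__(self):
        if self.bins < 16:
            raise ValueError("need at least 16 histogram bins")
        if self.min_separation < 1:
            raise ValueError("minimum peak separation must be >= 1 bin")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing window must be a positive odd width")
        if self.channel not in ("grey", "longwave"):
            raise ValueError("channel must be 'grey' or 'longwave'")


def apply_roi(
    cal: CalibratedImage,
    mask: np.ndarray,
    *,
    longwave_channel: int = 0,
) -> RoiSample:
    """Extract the in-ROI luminance sample from a calibrated image.

    ``mask`` must match the image's spatial shape and contain at least one
    True pixel.  The combined-greyscale value of a pixel is the unweighted
    mean of its channel luminances.
    """
    mask = np.asarray(mask, dtype=bool)
    spatial = cal.luminance.shape[:2]
    if mask.shape != spatial:
        raise ValueError(
            f"mask shape {mask.shape} does not match image shape {spatial}"
        )
    if not mask.any():
        raise ValueError("ROI mask is empty")
    longwave = cal.channel(longwave_channel)[mask].astype(float)
    if cal.luminance.ndim == 2:
        grey = longwave
    else:
        grey = cal.luminance[mask].mean(axis=1)
    return RoiSample(longwave=longwave, grey=grey)


def mean_luminance(sample: RoiSample) -> float:
    """Arithmetic mean of the long-wave-channel ROI values."""
    return float(sample.longwave.mean())


def _histogram(values: np.ndarray, cfg: HistogramConfig):
    counts, edges = np.histogram(values, bins=cfg.bins, range=cfg.value_range)
    centres = (edges[:-1] + edges[1:]) / 2.0
    if cfg.smoothing_window > 1:
        kernel = np.ones(cfg.smoothing_window) / cfg.smoothing_window
        counts = np.convolve(counts.astype(float), kernel, mode="same")
    return counts.astype(float), centres


def stripe_peaks(
    sample: RoiSample, cfg: HistogramConfig = HistogramConfig()
) -> tuple[float, float]:
    """Locate the two stripe peaks of the ROI luminance histogram.

    Builds a histogram per ``cfg``, smooths it, finds local maxima at least
    ``cfg.min_separation`` bins apart, and returns the bin-centre values of
    the two highest as ``(L_min, L_max)``.  Ties between equal-height
    candidates are broken toward the pair with the largest separation, then
    toward the lower bin index.

    Raises
    ------
    UnimodalHistogramError
        If fewer than two qualifying peaks exist (e.g. a constant or fully
        blended sample); the caller may fall back to mean luminance only.
    """
    values = sample.grey if cfg.channel == "grey" else sample.longwave
    counts, centres = _histogram(values, cfg)
    # Pad so maxima at the histogram edges qualify as peaks.
    padded = np.concatenate(([-np.inf], counts, [-np.inf]))
    idx, _ = find_peaks(padded, distance=cfg.min_separation)
    idx -= 1
    if len(idx) < 2:
        raise UnimodalHistogramError(
            f"found {len(idx)} qualifying peak(s); need 2"
        )
    heights = counts[idx]
    # Heights of the two retained peaks, smallest admissible pair first.
    order = np.argsort(-heights, kind="stable")
    top = heights[order[1]]
    # Candidates tied with the second-highest height (plus everything above).
    contenders = idx[heights >= top - 1e-12]
    c_heights = counts[contenders]
    best: tuple | None = None
    for i in range(len(contenders)):
        for j in range(i + 1, len(contenders)):
            pair_height = c_heights[i] + c_heights[j]
            sep = contenders[j] - contenders[i]
            key = (pair_height, sep, -contenders[i])
            if best is None or key > best[0]:
                best = (key, contenders[i], contenders[j])
    _, lo, hi = best
    return float(centres[lo]), float(centres[hi])


def weber_contrast(l_max: float, l_min: float) -> float:
    """Weber contrast ``(L_max - L_min) / L_min`` of the stripe pair."""
    if l_min <= 0:
        raise ValueError("L_min must be positive")
    if l_max < l_min:
        raise ValueError("L_max below L_min: peaks mislabelled")
    return (l_max - l_min) / l_min


def measure_fish(
    cal: CalibratedImage,
    mask: np.ndarray,
    cfg: HistogramConfig = HistogramConfig(),
    *,
    fish_id: str = "",
    labels: dict | None = None,
) -> StripeMetrics:
    """All stripe metrics for one fish; unimodal histograms are flagged."""
    sample = apply_roi(cal, mask)
    mean = mean_luminance(sample)
    labels = labels or {}
    flags: tuple[str, ...] = ()
    try:
        l_min, l_max = stripe_peaks(sample, cfg)
        cw = weber_contrast(l_max, l_min)
    except UnimodalHistogramError:
        l_min = l_max = cw = None
        flags = ("unimodal_histogram",)
    return StripeMetrics(
        fish_id=fish_id,
        mean_luminance=mean,
        l_min=l_min,
        l_max=l_max,
        weber=cw,
        n_pixels=sample.n_pixels,
        arena=labels.get("arena"),
        stimulus=labels.get("stimulus"),
        session=labels.get("session"),
        flags=flags,
    )


def measure_batch(
    items: list[dict],
    cfg: HistogramConfig = HistogramConfig(),
    *,
    outlier_threshold: float = 0.25,
) -> pd.DataFrame:
    """Measure a batch of fish, attaching batch scale and outlier flags.

    Each item is a dict with keys ``fish_id``, ``image``
    (:class:`CalibratedImage`), ``mask`` and optional label keys (``arena``,
    ``stimulus``, ``session``).  Items whose image or mask is missing (None)
    or that raise during measurement become per-row error records and the
    batch continues.  Returns one row per item with the metric columns, the
    batch scale and flags.
    """
    scales = [
        it["image"].px_per_mm
        for it in items
        if it.get("image") is not None and it["image"].px_per_mm
    ]
    batch = None
    scale_flags: dict[int, bool] = {}
    if scales:
        batch, flagged = batch_scale(scales, outlier_threshold=outlier_threshold)
        k = 0
        for i, it in enumerate(items):
            if it.get("image") is not None and it["image"].px_per_mm:
                scale_flags[i] = flagged[k]
                k += 1

    rows = []
    failures = 0
    for i, it in enumerate(items):
        fish_id = it.get("fish_id", f"row{i}")
        base = {
            "fish_id": fish_id,
            "session": it.get("session"),
            "arena": it.get("arena"),
            "stimulus": it.get("stimulus"),
            "mean_lum": np.nan,
            "l_min": np.nan,
            "l_max": np.nan,
            "cw": np.nan,
            "n_pixels": 0,
            "scale_px_per_mm": batch,
            "flags": "",
        }
        if it.get("image") is None or it.get("mask") is None:
            failures += 1
            base["flags"] = "missing_input"
            rows.append(base)
            continue
        try:
            m = measure_fish(
                it["image"], it["mask"], cfg, fish_id=fish_id, labels=it
            )
        except Exception as exc:  # per-row failure; batch continues
            failures += 1
            base["flags"] = f"error:{exc}"
            rows.append(base)
            continue
        flags = list(m.flags)
        if scale_flags.get(i):
            flags.append("scale_outlier")
        base.update(
            mean_lum=m.mean_luminance,
            l_min=np.nan if m.l_min is None else m.l_min,
            l_max=np.nan if m.l_max is None else m.l_max,
            cw=np.nan if m.weber is None else m.weber,
            n_pixels=m.n_pixels,
            flags=";".join(flags),
        )
        rows.append(base)
    if failures:
        logger.warning("measure_batch: %d of %d rows failed", failures, len(items))
    return pd.DataFrame(rows)
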