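"""Grey-standard luminance calibration and spatial scale management.

A photograph is converted to a standardized linear luminance image by
anchoring it to an in-frame grey standard of known reflectance: per channel,

    L(p) = pixel(p) / mean(standard pixels) * 100 * R_s,

so that the standard itself reads ``100 * R_s`` (18 for an 18%-reflectance
standard) on a 0-100 luminance scale.  The scaling is linear with no gamma;
an optional inverse-sRGB step linearises gamma-encoded inputs first.  Any
multiplicative factor common to the scene and the standard (illumination
gain, exposure, ISO) cancels exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .synthetic import srgb_decode

__all__ = [
    "StandardMeasurement",
    "CalibratedImage",
    "SaturatedStandardError",
    "measure_standard",
    "calibrate",
    "compute_scale",
    "batch_scale",
    "rect_mask",
]


class SaturatedStandardError(ValueError):
    """The grey-standard region contains too many ceiling-valued pixels."""


def _sensor_ceiling(image: np.ndarray) -> float:
    if image.dtype == np.uint8:
        return 255.0
    if image.dtype == np.uint16:
        return 65535.0
    return float("inf")  # float input: no meaningful hardware ceiling


def rect_mask(shape: tuple[int, int], rect: tuple[int, int, int, int]) -> np.ndarray:
    """Boolean mask for an (x, y, width, height) pixel rectangle."""
    x, y, w, h = rect
    if w <= 0 or h <= 0 or x < 0 or y < 0 or y + h > shape[0] or x + w > shape[1]:
        raise ValueError("rectangle falls outside the image")
    mask = np.zeros(shape, dtype=bool)
    mask[y : y + h, x : x + w] = True
    return mask


@dataclass(frozen=True)
class StandardMeasurement:
    """Mean pixel value of the grey-standard region, per channel."""

    mean: np.ndarray  # shape (channels,)
    reflectance: float = 0.18
    region: object = None  # mask or rectangle used
    known_length_mm: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "mean", np.atleast_1d(np.asarray(self.mean, float)))
        if not (0 < self.reflectance < 1):
            raise ValueError("standard reflectance must lie in (0, 1)")
        if np.any(self.mean <= 0):
            raise ValueError("standard mean pixel value must be positive")


@dataclass(frozen=True)
class CalibratedImage:
    """Linear luminance image on the 0-100 scale anchored to the grey standard.

    ``luminance`` has shape (H, W) for single-channel input or (H, W, C);
    values are >= 0 and the standard region averages ``100 * R_s``.
    """

    luminance: np.ndarray
    px_per_mm: float | None = None
    standard: StandardMeasurement | None = None
    source: str | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return 1 if self.luminance.ndim == 2 else self.luminance.shape[2]

    def channel(self, index: int) -> np.ndarray:
        if self.luminance.ndim == 2:
            if index != 0:
                raise IndexError("single-channel image")
            return self.luminance
        return self.luminance[..., index]


def measure_standard(
    image: np.ndarray,
    standard_region: np.ndarray | tuple[int, int, int, int],
    *,
    reflectance: float = 0.18,
    max_saturated_fraction: float = 0.0,
    known_length_mm: float | None = None,
) -> StandardMeasurement:
    """Measure the grey standard: per-channel arithmetic mean of its pixels.

    ``standard_region`` is a boolean mask of the image's spatial shape or an
    (x, y, w, h) rectangle.  Raises :class:`SaturatedStandardError` when the
    fraction of ceiling-valued pixels in the region exceeds
    ``max_saturated_fraction`` (default: none allowed), since a clipped
    standard no longer encodes the illumination.
    """
    image = np.asarray(image)
    spatial = image.shape[:2]
    if isinstance(standard_region, tuple):
        mask = rect_mask(spatial, standard_region)
    else:
        mask = np.asarray(standard_region, dtype=bool)
        if mask.shape != spatial:
            raise ValueError("standard mask shape does not match the image")
    if not mask.any():
        raise ValueError("standard region is empty")

    values = image[mask]  # (n,) or (n, C)
    ceiling = _sensor_ceiling(image)
    saturated = float(np.mean(np.any(np.atleast_2d(values.T).T >= ceiling, axis=-1)))
    if np.isfinite(ceiling) and saturated > max_saturated_fraction:
        raise SaturatedStandardError(
            f"{saturated:.1%} of standard pixels saturated "
            f"(allowed {max_saturated_fraction:.1%})"
        )
    mean = values.mean(axis=0)
    return StandardMeasurement(
        mean=mean,
        reflectance=reflectance,
        region=standard_region,
        known_length_mm=known_length_mm,
    )


def calibrate(
    image: np.ndarray,
    std: StandardMeasurement,
    *,
    px_per_mm: float | None = None,
    decode_srgb: bool = False,
    source: str | None = None,
) -> CalibratedImage:
    """Anchor an image to its grey standard, yielding 0-100 luminance.

    Per channel, ``L = pixel / std_mean * 100 * R_s``; the standard maps to
    luminance ``100 * R_s`` by construction.  With ``decode_srgb`` the image
    and the measured standard mean are passed through the inverse sRGB curve
    first (both normalised by the sensor ceiling), recovering the linear
    regime the calibration assumes.
    """
    arr = np.asarray(image, dtype=float)
    std_mean = std.mean.copy()
    if decode_srgb:
        ceiling = _sensor_ceiling(np.asarray(image))
        if not np.isfinite(ceiling):
            raise ValueError("sRGB decoding needs integer input with a known ceiling")
        arr = srgb_decode(arr / ceiling) * ceiling
        std_mean = srgb_decode(std_mean / ceiling) * ceiling
    if np.any(std_mean <= 0):
        raise ValueError("standard mean must be positive in every channel")

    scale = 100.0 * std.reflectance
    if arr.ndim == 2:
        lum = arr / float(std_mean[0]) * scale
    else:
        if std_mean.size == 1:
            std_mean = np.repeat(std_mean, arr.shape[2])
        if std_mean.size != arr.shape[2]:
            raise ValueError("one standard mean required per channel")
        lum = arr / std_mean[None, None, :] * scale
    return CalibratedImage(
        luminance=lum,
        px_per_mm=px_per_mm,
        standard=std,
        source=source,
        provenance={"decode_srgb": decode_srgb},
    )


def compute_scale(pixel_extent: float, known_length_mm: float) -> float:
    """Spatial scale in px/mm from a reference object of known length.

    ``pixel_extent`` is the object's extent in pixels (e.g. the width of the
    grey standard); ``known_length_mm`` its physical length.
    """
    if known_length_mm <= 0:
        raise ValueError("known length must be positive")
    if pixel_extent <= 0:
        raise ValueError("pixel extent must be positive")
    return pixel_extent / known_length_mm


def batch_scale(
    scales: Sequence[float], *, outlier_threshold: float = 0.25
) -> tuple[float, list[bool]]:
    """Batch analysis scale and per-image outlier flags.

    The batch is analysed at the *minimum* scale of its images, so no image
    is ever up-scaled.  An image is flagged as a scale outlier when its scale
    deviates from the batch median by more than ``outlier_threshold``
    (relative); flagged images should be excluded by the caller — the rule is
    reported, never silently applied.
    """
    scales = list(scales)
    if not scales:
        raise ValueError("empty batch")
    if any(s <= 0 for s in scales):
        raise ValueError("scales must be positive")
    median = float(np.median(scales))
    flags = [abs(s - median) / median > outlier_threshold for s in scales]
    return min(scales), flags
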