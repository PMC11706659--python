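"""Synthetic fish images and per-fish metric tables with known ground truth.

The image generator emulates a lateral "photo booth" photograph of a striped
fish: an elliptical body bearing alternating horizontal stripes of two
reflectance classes, an in-frame grey standard patch of known reflectance,
a multiplicative illumination gain and additive sensor noise.  The sensor is
linear: a surface of reflectance ``r`` photographed under gain ``g`` yields a
pixel value ``g * r * D`` (plus noise), where ``D`` is a fixed dynamic-range
constant.  Because downstream calibration divides by the grey-standard mean,
the calibrated luminance of that surface is ``100 * r`` on the 0-100 scale.

The table generator draws per-fish metric rows (mean luminance, dark- and
light-stripe peak luminances, Weber contrast) from a Gaussian linear model
with arena/stimulus/session effects, with the stripe-luminance pair drawn
bivariate-correlated and the Weber contrast derived from it, never sampled
independently of its definition.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "DYNAMIC_RANGE",
    "SENSOR_CEILING",
    "SyntheticImageSpec",
    "SyntheticGroundTruth",
    "EffectSpec",
    "generate_fish_image",
    "generate_metric_table",
    "srgb_encode",
    "srgb_decode",
]

#: Linear sensor response of a perfect reflector (r = 1) at unit gain.
DYNAMIC_RANGE = 26000.0

#: 16-bit sensor ceiling; noise is truncated here and at 0.
SENSOR_CEILING = 65535.0


def srgb_encode(linear: np.ndarray) -> np.ndarray:
    """Apply the sRGB transfer curve to values in [0, 1]."""
    linear = np.asarray(linear, dtype=float)
    return np.where(
        linear <= 0.0031308,
        12.92 * linear,
        1.055 * np.clip(linear, 0, None) ** (1 / 2.4) - 0.055,
    )


def srgb_decode(encoded: np.ndarray) -> np.ndarray:
    """Invert the sRGB transfer curve back to linear values in [0, 1]."""
    encoded = np.asarray(encoded, dtype=float)
    return np.where(
        encoded <= 0.04045,
        encoded / 12.92,
        ((np.clip(encoded, 0, None) + 0.055) / 1.055) ** 2.4,
    )


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Geometry, reflectances and sensor settings for one synthetic photograph.

    Lengths are millimetres unless stated; the body ellipse centre is in
    pixel coordinates (x, y, origin top-left).  ``stripe_count`` counts full
    dark+light cycles of length ``stripe_period_mm``; the striped band is
    centred on the body and must fit within the ellipse's minor axis.
    """

    shape: tuple[int, int] = (240, 320)  # (height, width) px
    px_per_mm: float = 8.0
    body_centre: tuple[float, float] = (200.0, 130.0)  # (x, y) px
    body_semi_axes_mm: tuple[float, float] = (14.0, 5.0)  # (a along x, b along y)
    stripe_count: int = 5
    stripe_period_mm: float = 2.0
    r_dark: float = 0.09
    r_light: float = 0.27
    standard_reflectance: float = 0.18
    standard_rect: tuple[int, int, int, int] = (12, 12, 64, 32)  # x, y, w, h px
    standard_length_mm: float = 8.0  # physical width of the standard patch
    background_reflectance: float = 0.5
    gain: float = 1.0
    noise_sd: float = 260.0  # pixel units; 260 px = 1 luminance unit at g = 1
    apply_srgb_gamma: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.r_dark < self.r_light <= 1):
            raise ValueError("require 0 < r_dark < r_light <= 1")
        if not (0 < self.standard_reflectance < 1):
            raise ValueError("standard reflectance must lie in (0, 1)")
        if self.gain <= 0:
            raise ValueError("illumination gain must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise s.d. must be non-negative")
        if self.stripe_count < 1 or self.stripe_period_mm <= 0:
            raise ValueError("need at least one stripe cycle of positive period")
        if self.stripe_count * self.stripe_period_mm > 2 * self.body_semi_axes_mm[1]:
            raise ValueError("stripe period x count exceeds the body's minor axis")
        x, y, w, h = self.standard_rect
        hgt, wid = self.shape
        if w <= 0 or h <= 0 or x < 0 or y < 0 or x + w > wid or y + h > hgt:
            raise ValueError("standard rectangle falls outside the image")


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """True quantities behind one generated image, on the calibrated scale."""

    l_dark: float  # true dark-stripe luminance (100 * r_dark)
    l_light: float  # true light-stripe luminance (100 * r_light)
    mean_luminance: float  # area-weighted over the ROI
    weber_contrast: float  # (l_light - l_dark) / l_dark
    roi_mask: np.ndarray  # bool (H, W), True on the striped body
    n_dark: int
    n_light: int
    saturated_fraction: float
    seed: int


def _body_mask(spec: SyntheticImageSpec) -> np.ndarray:
    h, w = spec.shape
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = spec.body_centre
    a = spec.body_semi_axes_mm[0] * spec.px_per_mm
    b = spec.body_semi_axes_mm[1] * spec.px_per_mm
    return ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0


def generate_fish_image(
    spec: SyntheticImageSpec,
) -> tuple[np.ndarray, SyntheticGroundTruth]:
    """Render a synthetic photograph and its ground truth.

    Returns a ``uint16`` image of shape ``spec.shape`` and the
    :class:`SyntheticGroundTruth` describing it.  Fully reproducible from
    ``spec.seed``.

    Raises
    ------
    ValueError
        If the spec violates its invariants or the standard patch overlaps
        the fish body.
    """
    spec.validate()
    body = _body_mask(spec)

    x, y, w, h = spec.standard_rect
    std = np.zeros(spec.shape, dtype=bool)
    std[y : y + h, x : x + w] = True
    if (std & body).any():
        raise ValueError("standard patch overlaps the fish body")

    # Horizontal stripes: band index advances with the row coordinate.
    hgt, wid = spec.shape
    yy = np.arange(hgt, dtype=float)[:, None]
    half_period_px = spec.stripe_period_mm * spec.px_per_mm / 2.0
    band_top = spec.body_centre[1] - spec.stripe_count * half_period_px
    band = np.floor((yy - band_top) / half_period_px).astype(int)
    dark_rows = (band % 2 == 0) & np.ones((1, wid), dtype=bool)

    reflectance = np.full(spec.shape, spec.background_reflectance)
    reflectance[body & dark_rows] = spec.r_dark
    reflectance[body & ~dark_rows] = spec.r_light
    reflectance[std] = spec.standard_reflectance

    rng = np.random.default_rng(spec.seed)
    signal = spec.gain * reflectance * DYNAMIC_RANGE
    if spec.noise_sd > 0:
        signal = signal + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    if spec.apply_srgb_gamma:
        signal = srgb_encode(np.clip(signal, 0, SENSOR_CEILING) / SENSOR_CEILING)
        signal = signal * SENSOR_CEILING
    saturated = float(np.mean(signal >= SENSOR_CEILING))
    image = np.clip(np.round(signal), 0, SENSOR_CEILING).astype(np.uint16)

    n_dark = int((body & dark_rows).sum())
    n_light = int((body & ~dark_rows).sum())
    l_dark = 100.0 * spec.r_dark
    l_light = 100.0 * spec.r_light
    mean_lum = (n_dark * l_dark + n_light * l_light) / (n_dark + n_light)
    truth = SyntheticGroundTruth(
        l_dark=l_dark,
        l_light=l_light,
        mean_luminance=mean_lum,
        weber_contrast=(l_light - l_dark) / l_dark,
        roi_mask=body,
        n_dark=n_dark,
        n_light=n_light,
        saturated_fraction=saturated,
        seed=spec.seed,
    )
    return image, truth


# ---------------------------------------------------------------------------
# Metric tables


@dataclass(frozen=True)
class EffectSpec:
    """Gaussian-linear-model design behind a per-fish metric table.

    The linear predictor for fish *i* is
    ``mu_i = grand_mean + arena_effect * 1[arena = white]
    + stimulus_effects[stim_i] + session_effects[session_i]``.
    Mean luminance is drawn ``N(mu_i, residual_sd^2)``; the stripe pair is
    drawn bivariate normal centred at ``mu_i -/+ stripe_separation / 2`` with
    common s.d. ``residual_sd`` and correlation ``rho``; Weber contrast is
    derived from the pair.  The default design mirrors a 2 x 3 factorial with
    11 fish per cell tested over 11 sessions.
    """

    grand_mean: float = 18.0
    arena_effect: float = 6.0
    stimulus_effects: dict[str, float] = field(
        default_factory=lambda: {"control": 0.0, "predatory": 0.0, "social": 0.0}
    )
    session_effects: dict[str, float] = field(
        default_factory=lambda: {str(i): 0.0 for i in range(1, 12)}
    )
    residual_sd: float = 1.5
    rho: float = 0.53
    group_sizes: int | dict[tuple[str, str], int] = 11
    stripe_separation: float = 18.0

    def validate(self) -> None:
        if self.residual_sd <= 0:
            raise ValueError("residual s.d. must be positive")
        if abs(self.rho) > 1:
            raise ValueError("|rho| must not exceed 1")
        for n in self.cell_sizes().values():
            if n < 1:
                raise ValueError("group sizes must be >= 1")

    def cells(self) -> list[tuple[str, str]]:
        return list(itertools.product(("black", "white"), self.stimulus_effects))

    def cell_sizes(self) -> dict[tuple[str, str], int]:
        if isinstance(self.group_sizes, int):
            return {cell: self.group_sizes for cell in self.cells()}
        return {cell: self.group_sizes.get(cell, 0) for cell in self.cells()}


def generate_metric_table(design: EffectSpec, seed: int) -> pd.DataFrame:
    """Draw one per-fish metric table from the design's Gaussian linear model.

    Returns a frame with columns ``fish_id, session, arena, stimulus,
    mean_lum, l_min, l_max, cw``, one row per fish, reproducible from
    ``seed``.  Sessions are assigned cyclically across fish so each session
    spans the treatment cells, as in a randomised block design.
    """
    design.validate()
    rng = np.random.default_rng(seed)
    sessions = list(design.session_effects)

    rows: list[dict] = []
    sizes = design.cell_sizes()
    order: list[tuple[str, str]] = []
    # Interleave cells so consecutive fish (and hence sessions) mix treatments.
    counters = dict(sizes)
    while any(v > 0 for v in counters.values()):
        for cell in design.cells():
            if counters[cell] > 0:
                order.append(cell)
                counters[cell] -= 1

    sd = design.residual_sd
    cov = sd**2 * np.array([[1.0, design.rho], [design.rho, 1.0]])
    for i, (arena, stim) in enumerate(order):
        session = sessions[i // max(1, len(order) // len(sessions)) % len(sessions)]
        mu = (
            design.grand_mean
            + (design.arena_effect if arena == "white" else 0.0)
            + design.stimulus_effects[stim]
            + design.session_effects[session]
        )
        mean_lum = rng.normal(mu, sd)
        half = design.stripe_separation / 2.0
        l_min, l_max = rng.multivariate_normal([mu - half, mu + half], cov)
        rows.append(
            {
                "fish_id": f"fish{i + 1:03d}",
                "session": session,
                "arena": arena,
                "stimulus": stim,
                "mean_lum": mean_lum,
                "l_min": l_min,
                "l_max": l_max,
                "cw": (l_max - l_min) / l_min,
            }
        )
    return pd.DataFrame(rows)


def exp2_like_spec(**overrides) -> EffectSpec:
    """The default two-arena, three-stimulus design with one cell of 10 fish.

    Mirrors a 66-fish factorial in which one fish is excluded, leaving 65
    analysable rows (10 in one cell, 11 elsewhere).
    """
    sizes = {
        cell: 11 for cell in itertools.product(("black", "white"),
                                               ("control", "predatory", "social"))
    }
    sizes[("black", "social")] = 10
    base = EffectSpec(group_sizes=sizes)
    return replace(base, **overrides) if overrides else base
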