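"""Colorimetric image-change metric: sRGB -> CIELAB and per-pixel Delta-E 1976.

The whole-image change score used throughout the package is the arithmetic
mean of per-pixel Delta-E 1976 values between an original and a manipulated
image, optionally log-transformed (base 10 by default).  The conversion
assumes sRGB input, D65 white point and the 2-degree standard observer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LabImage",
    "DeltaESummary",
    "srgb_to_lab",
    "delta_e76",
    "log_delta_e",
]

# sRGB (linear) -> XYZ, D65 white, 2-degree observer.
_RGB2XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
# Reference white = matrix row sums, so (255,255,255) maps exactly to L*=100.
_WHITE = _RGB2XYZ.sum(axis=1)

_DELTA = 6.0 / 29.0


@dataclass(frozen=True)
class LabImage:
    """CIELAB rasters; ``L`` in [0, 100] for in-gamut sRGB input."""

    L: np.ndarray
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        if not (self.L.shape == self.a.shape == self.b.shape):
            raise ValueError("L, a, b rasters must share dimensions")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.L.shape


@dataclass(frozen=True)
class DeltaESummary:
    """Per-pixel Delta-E 1976 raster and its whole-image aggregates.

    ``mean`` is the image's Delta-E score (average over *all* pixels, not
    only the manipulated region); ``per_region`` holds the mean Delta-E
    within each grid cell when a grid was supplied.
    """

    per_pixel: np.ndarray
    mean: float
    log_mean: float
    per_region: dict[int, float] = field(default_factory=dict)


def _f_lab(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return np.where(t > _DELTA**3, np.cbrt(t), t / (3 * _DELTA**2) + 4.0 / 29.0)


def srgb_to_lab(image: np.ndarray) -> LabImage:
    """Convert an 8-bit sRGB image (H, W, 3) to CIELAB.

    Decoding follows the standard two-part sRGB gamma, a linear-RGB -> XYZ
    matrix for D65, and the CIE L*a*b* forward transform against the D65
    reference white.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError(f"expected a 3-channel image, got shape {image.shape}")
    srgb = image.astype(float) / 255.0
    linear = np.where(srgb <= 0.04045, srgb / 12.92, ((srgb + 0.055) / 1.055) ** 2.4)
    xyz = linear @ _RGB2XYZ.T
    fxyz = _f_lab(xyz / _WHITE)
    fx, fy, fz = fxyz[..., 0], fxyz[..., 1], fxyz[..., 2]
    return LabImage(L=116.0 * fy - 16.0, a=500.0 * (fx - fy), b=200.0 * (fy - fz))


def delta_e76(
    lab_a: LabImage,
    lab_b: LabImage,
    grid=None,
    log_base: float = 10.0,
) -> DeltaESummary:
    """Per-pixel Delta-E 1976 between two CIELAB images plus aggregates.

    ``per_pixel[i, j] = sqrt(dL^2 + da^2 + db^2)``; ``mean`` averages over
    every pixel.  If ``grid`` (a :class:`photoforge.gridchance.Grid`) is
    given, mean Delta-E is also reported per grid region.  ``log_mean`` is
    NaN when the images are identical (zero mean has no logarithm).
    """
    if lab_a.shape != lab_b.shape:
        raise ValueError(f"shape mismatch: {lab_a.shape} vs {lab_b.shape}")
    per_pixel = np.sqrt(
        (lab_a.L - lab_b.L) ** 2 + (lab_a.a - lab_b.a) ** 2 + (lab_a.b - lab_b.b) ** 2
    )
    mean = float(per_pixel.mean())
    log_mean = log_delta_e(mean, base=log_base) if mean > 0 else float("nan")
    per_region: dict[int, float] = {}
    if grid is not None:
        labels = grid.region_map()
        if labels.shape != per_pixel.shape:
            raise ValueError("grid dimensions do not match the images")
        for idx in range(grid.n_regions):
            per_region[idx] = float(per_pixel[labels == idx].mean())
    return DeltaESummary(per_pixel=per_pixel, mean=mean, log_mean=log_mean, per_region=per_region)


def log_delta_e(mean: float, base: float = 10.0) -> float:
    """Logarithm of a positive mean Delta-E score (default base 10)."""
    if mean <= 0:
        raise ValueError("log Delta-E undefined for a non-positive mean (unmanipulated pair?)")
    return math.log(mean, base)
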