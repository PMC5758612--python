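"""Gabor triplet stimuli for lateral-masking experiments.

A lateral-masking display consists of a low-contrast Gabor target flanked
by two high-contrast Gabors placed symmetrically along a global axis.
Flankers either share the target's carrier orientation (*collinear*) or
are rotated by 90 deg (*orthogonal*, the baseline that controls for
spatial uncertainty).  Target-to-flanker separation is expressed in
multiples of the carrier wavelength lambda (1 deg at 1 cycle/deg).

Luminance images are held as continuous cd/m^2 arrays; quantization to the
display's bit depth happens only on export.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .exceptions import GeometryError, ParameterError

__all__ = [
    "DisplayGeometry",
    "StimulusConfig",
    "StimulusImage",
    "render_gabor",
    "render_triplet",
    "michelson_contrast",
]

OrientationCondition = Literal["collinear", "orthogonal"]
GlobalAxis = Literal["vertical", "horizontal"]

#: Angle (deg) of the Gabor carrier bars for each global stimulus axis.
#: 0 deg = vertical bars; collinear flankers are displaced along the bars.
_AXIS_ORIENTATION_DEG = {"vertical": 0.0, "horizontal": 90.0}


@dataclass(frozen=True)
class DisplayGeometry:
    """Pixel raster and photometry of the display.

    Defaults describe a 1024 x 768 CRT at 47.6 cd/m^2 mean luminance with
    a pixel pitch of 2.14 arcmin, i.e. the viewing geometry under which
    1 cycle/deg corresponds to ~28 px per carrier cycle.
    """

    width_px: int = 1024
    height_px: int = 768
    arcmin_per_pixel: float = 2.14
    mean_luminance: float = 47.6
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ParameterError("display dimensions must be positive")
        if self.arcmin_per_pixel <= 0:
            raise ParameterError("arcmin_per_pixel must be positive")
        if self.mean_luminance <= 0:
            raise ParameterError("mean_luminance must be positive")
        if self.bit_depth < 1:
            raise ParameterError("bit_depth must be >= 1")

    @property
    def deg_per_pixel(self) -> float:
        return self.arcmin_per_pixel / 60.0

    @property
    def center(self) -> tuple[float, float]:
        """(row, col) of the raster center; a pixel center for odd sizes."""
        return ((self.height_px - 1) / 2.0, (self.width_px - 1) / 2.0)

    def deg_to_px(self, deg: float) -> int:
        """Convert a visual angle to an integer pixel offset.

        Offsets are computed in degrees and rounded to the nearest pixel,
        so the placement error never exceeds half a pixel.
        """
        return int(round(deg / self.deg_per_pixel))


@dataclass(frozen=True)
class StimulusConfig:
    """Full description of one lateral-masking trial display.

    ``gabor_sigma`` defaults to half the carrier wavelength, a common
    choice that keeps the three patches essentially non-overlapping even
    at the smallest (3 lambda) separation.  The carrier phase defaults to
    0 (even-symmetric cosine phase).
    """

    separation_lambda: float
    orientation_condition: OrientationCondition
    target_contrast: float
    flanker_contrast: float = 0.8
    spatial_frequency: float = 1.0
    global_axis: GlobalAxis = "vertical"
    gabor_sigma: float | None = None
    phase: float = 0.0
    geometry: DisplayGeometry = field(default_factory=DisplayGeometry)

    def __post_init__(self) -> None:
        if self.spatial_frequency <= 0:
            raise ParameterError("spatial_frequency must be positive")
        if self.separation_lambda <= 0:
            raise ParameterError(
                "separation_lambda must be positive (flankers must not "
                "coincide with the target)"
            )
        for name in ("target_contrast", "flanker_contrast"):
            c = getattr(self, name)
            if not 0 < c <= 1:
                raise ParameterError(f"{name} must lie in (0, 1], got {c}")
        if self.orientation_condition not in ("collinear", "orthogonal"):
            raise ParameterError(
                f"unknown orientation_condition {self.orientation_condition!r}"
            )
        if self.global_axis not in _AXIS_ORIENTATION_DEG:
            raise ParameterError(f"unknown global_axis {self.global_axis!r}")
        if self.gabor_sigma is not None and self.gabor_sigma <= 0:
            raise ParameterError("gabor_sigma must be positive")

    @property
    def wavelength_lambda(self) -> float:
        """Carrier wavelength in deg (the lambda of the separations)."""
        return 1.0 / self.spatial_frequency

    @property
    def sigma(self) -> float:
        """Effective Gaussian envelope SD in deg (default lambda / 2)."""
        return self.gabor_sigma if self.gabor_sigma is not None else self.wavelength_lambda / 2.0


@dataclass
class StimulusImage:
    """A rendered luminance image plus element bookkeeping.

    ``element_centers`` lists (row, col) pixel coordinates in the order
    flanker-above (or left), target, flanker-below (or right); for a lone
    patch it holds a single entry.
    """

    luminance: np.ndarray
    element_centers: list[tuple[float, float]]
    geometry: DisplayGeometry

    def quantized(self, bit_depth: int | None = None) -> np.ndarray:
        """Quantize luminance to integer display levels.

        Mean luminance maps to the middle of the range; 0 and twice the
        mean map to the bottom and top levels.
        """
        bd = self.geometry.bit_depth if bit_depth is None else bit_depth
        levels = 2**bd - 1
        scaled = self.luminance / (2.0 * self.geometry.mean_luminance)
        return np.clip(np.round(scaled * levels), 0, levels).astype(np.uint16)

    def to_grayscale(self) -> np.ndarray:
        """8-bit grayscale with mean luminance at mid-gray."""
        return self.quantized(bit_depth=8).astype(np.uint8)

    def save_png(self, path) -> None:
        from PIL import Image

        Image.fromarray(self.to_grayscale(), mode="L").save(path)

    def to_text(self, fmt: str = "%.6g") -> str:
        """Plain-text matrix (rows of space-separated cd/m^2 values)."""
        return "\n".join(
            " ".join(fmt % v for v in row) for row in self.luminance
        )

    def patch_region(self, index: int, half_width_px: int) -> np.ndarray:
        """Square luminance window around one element center."""
        r, c = self.element_centers[index]
        r, c = int(round(r)), int(round(c))
        return self.luminance[
            max(r - half_width_px, 0) : r + half_width_px + 1,
            max(c - half_width_px, 0) : c + half_width_px + 1,
        ]


def michelson_contrast(region: np.ndarray, mean_luminance: float) -> float:
    """Michelson contrast of the carrier underlying a windowed grating.

    For a Gabor the Gaussian window attenuates the carrier away from the
    envelope peak, so the raw (max-min)/(max+min) of the patch
    underestimates the carrier contrast.  The carrier contrast is instead
    recovered from the peak luminance excursion about the background:
    ``max |L - L_mean| / L_mean``, which equals the nominal Michelson
    contrast of the generating grating whenever the grid samples the
    envelope peak.
    """
    region = np.asarray(region, dtype=float)
    return float(np.max(np.abs(region - mean_luminance)) / mean_luminance)


def _gabor_modulation(
    contrast: float,
    sf: float,
    orientation_deg: float,
    sigma: float,
    phase: float,
    geometry: DisplayGeometry,
    center: tuple[float, float],
) -> np.ndarray:
    """Dimensionless modulation c * envelope * carrier on the full raster."""
    rows = np.arange(geometry.height_px, dtype=float)[:, None]
    cols = np.arange(geometry.width_px, dtype=float)[None, :]
    dpp = geometry.deg_per_pixel
    y = (rows - center[0]) * dpp
    x = (cols - center[1]) * dpp
    theta = math.radians(orientation_deg)
    # u runs perpendicular to the carrier bars: theta = 0 -> vertical bars,
    # modulation along x.
    u = x * math.cos(theta) + y * math.sin(theta)
    envelope = np.exp(-(x**2 + y**2) / (2.0 * sigma**2))
    carrier = np.cos(2.0 * math.pi * sf * u + phase)
    return contrast * envelope * carrier


def render_gabor(
    contrast: float,
    sf: float = 1.0,
    orientation: float = 0.0,
    sigma: float = 0.5,
    phase: float = 0.0,
    geometry: DisplayGeometry | None = None,
    center: tuple[float, float] | None = None,
) -> StimulusImage:
    """Render a single Gabor patch on a uniform mean-luminance field.

    L(x, y) = L_mean * (1 + c * exp(-(x^2+y^2)/(2 sigma^2))
                          * cos(2 pi f u + phase))

    where u is the spatial coordinate perpendicular to the carrier bars
    and ``orientation`` is the bar angle in deg (0 = vertical bars).
    A contrast of 0 is allowed and yields a uniform field.
    """
    geometry = geometry or DisplayGeometry()
    if not 0 <= contrast <= 1:
        raise ParameterError(f"contrast must lie in [0, 1], got {contrast}")
    if sf <= 0 or sigma <= 0:
        raise ParameterError("sf and sigma must be positive")
    center = geometry.center if center is None else center
    modulation = (
        _gabor_modulation(contrast, sf, orientation, sigma, phase, geometry, center)
        if contrast > 0
        else np.zeros((geometry.height_px, geometry.width_px))
    )
    luminance = geometry.mean_luminance * (1.0 + modulation)
    return StimulusImage(luminance, [center], geometry)


def render_triplet(config: StimulusConfig) -> StimulusImage:
    """Render the three-Gabor lateral-masking display.

    The target sits at the display center; the flankers at
    +/- separation_lambda * lambda along the global axis.  Modulations
    superpose additively on the shared mean-luminance pedestal (at the
    default sigma the overlap between neighbouring envelopes is
    negligible even at 3 lambda).
    """
    geom = config.geometry
    target_theta = _AXIS_ORIENTATION_DEG[config.global_axis]
    flank_theta = target_theta + (
        0.0 if config.orientation_condition == "collinear" else 90.0
    )
    offset_deg = config.separation_lambda * config.wavelength_lambda
    offset_px = geom.deg_to_px(offset_deg)

    cr, cc = geom.center
    if config.global_axis == "vertical":
        centers = [(cr - offset_px, cc), (cr, cc), (cr + offset_px, cc)]
    else:
        centers = [(cr, cc - offset_px), (cr, cc), (cr, cc + offset_px)]
    for r, c in (centers[0], centers[2]):
        if not (0 <= r < geom.height_px and 0 <= c < geom.width_px):
            raise GeometryError(
                f"flanker center at separation {config.separation_lambda} "
                f"lambda ({offset_px} px) falls outside the "
                f"{geom.width_px}x{geom.height_px} raster"
            )

    modulation = np.zeros((geom.height_px, geom.width_px))
    for i, ctr in enumerate(centers):
        is_target = i == 1
        modulation += _gabor_modulation(
            config.target_contrast if is_target else config.flanker_contrast,
            config.spatial_frequency,
            target_theta if is_target else flank_theta,
            config.sigma,
            config.phase,
            geom,
            ctr,
        )
    luminance = geom.mean_luminance * (1.0 + modulation)
    return StimulusImage(luminance, centers, geom)
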