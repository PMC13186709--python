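"""Apical:basal localization-efficiency metric for injected embryos.

Fixed-size regions of interest (ROIs; default area 7.391 µm², the mean
footprint of apically localized RNA at a microtubule organizing centre)
are centred on the brightest apical fluorescence, duplicated at a basal
position by a vertical translation, and averaged.  After subtracting the
mean intensity of a background region distant from the injection site,
localization efficiency is the ratio of apical to basal mean intensity.
Row 0 of the image is the apical-most edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .io import IntensityImage

FracRange = tuple[float, float]


@dataclass(frozen=True)
class RoiSpec:
    """ROI geometry and placement parameters.

    Band positions are fractions of image height because the anatomy
    ("apical region", "just above the yolk") has no fixed pixel
    definition; ``basal_offset_um`` overrides the fractional offset when
    given.
    """

    area_um2: float = 7.391
    n_rois: int = 4
    shape: str = "disc"  # or "square"
    basal_offset_um: Optional[float] = None  # default: 30% of image height
    basal_offset_frac: float = 0.30
    apical_band: FracRange = (0.0, 0.15)  # row fractions, apical edge = 0
    background_region: tuple[FracRange, FracRange] = ((0.80, 0.95), (0.10, 0.90))

    def __post_init__(self) -> None:
        if self.area_um2 <= 0:
            raise ValueError("area_um2 must be positive")
        if self.n_rois < 1:
            raise ValueError("n_rois must be >= 1")
        if self.shape not in ("disc", "square"):
            raise ValueError(f"unknown ROI shape {self.shape!r}")

    def radius_px(self, pixel_size: float) -> float:
        """Half-extent of the ROI in pixels (disc radius or half-side)."""
        if self.shape == "disc":
            return float(np.sqrt(self.area_um2 / np.pi) / pixel_size)
        return float(np.sqrt(self.area_um2) / 2.0 / pixel_size)


@dataclass(frozen=True)
class LocalizationResult:
    apical_mean: float
    basal_mean: float
    background_mean: float
    ratio: float
    roi_centers: tuple[tuple[int, int], ...]
    basal_centers: tuple[tuple[int, int], ...]

    def to_dict(self) -> dict:
        return {
            "apical_mean": self.apical_mean,
            "basal_mean": self.basal_mean,
            "background_mean": self.background_mean,
            "ratio": self.ratio,
            "roi_centers": [list(c) for c in self.roi_centers],
            "basal_centers": [list(c) for c in self.basal_centers],
        }


def _roi_mask(shape: tuple[int, int], center: tuple[int, int], radius: float, kind: str) -> np.ndarray:
    rr, cc = np.ogrid[0 : shape[0], 0 : shape[1]]
    r0, c0 = center
    if kind == "disc":
        return (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
    return (np.abs(rr - r0) <= radius) & (np.abs(cc - c0) <= radius)


def place_apical_rois(
    image: IntensityImage,
    apical_band: Optional[FracRange] = None,
    spec: Optional[RoiSpec] = None,
) -> list[tuple[int, int]]:
    """Greedy placement of non-overlapping ROIs on the brightest apical spots.

    The image is Gaussian-smoothed (σ = ROI radius / 2), the global
    maximum within the apical band is taken, its ROI footprint excluded,
    and the step repeated ``n_rois`` times.  Ties break deterministically
    in row-major order (numpy argmax).
    """
    spec = spec or RoiSpec()
    band = apical_band if apical_band is not None else spec.apical_band
    h, w = image.pixels.shape
    radius = spec.radius_px(image.pixel_size)
    r_lo = max(int(band[0] * h), int(np.ceil(radius)))
    r_hi = min(int(band[1] * h), h - int(np.ceil(radius)))
    if r_hi <= r_lo:
        raise ValueError(f"apical band {band} too small for ROI radius {radius:.1f} px")
    smoothed = ndimage.gaussian_filter(image.pixels.astype(float), sigma=radius / 2.0)
    score = np.full((h, w), -np.inf)
    c_lo, c_hi = int(np.ceil(radius)), w - int(np.ceil(radius))
    score[r_lo:r_hi, c_lo:c_hi] = smoothed[r_lo:r_hi, c_lo:c_hi]
    centers: list[tuple[int, int]] = []
    for _ in range(spec.n_rois):
        if not np.isfinite(score).any():
            raise ValueError(f"band cannot hold {spec.n_rois} non-overlapping ROIs")
        idx = int(np.argmax(score))
        center = (idx // w, idx % w)
        centers.append(center)
        # exclude a footprint so the next ROI cannot overlap this one
        score[_roi_mask((h, w), center, 2.0 * radius, "disc")] = -np.inf
    return centers


def _mean_intensity(pixels: np.ndarray, mask: np.ndarray) -> float:
    values = pixels[mask]
    if np.issubdtype(pixels.dtype, np.integer):
        sat = np.iinfo(pixels.dtype).max
        n_sat = int((values == sat).sum())
        if n_sat:
            warnings.warn(f"excluding {n_sat} saturated pixel(s) from ROI mean")
            values = values[values != sat]
    if values.size == 0:
        raise ValueError("ROI contains no usable pixels")
    return float(values.mean())


def localization_efficiency(
    image: IntensityImage,
    spec: Optional[RoiSpec] = None,
    apical_centers: Optional[Sequence[tuple[int, int]]] = None,
) -> LocalizationResult:
    """Background-corrected apical:basal intensity ratio.

    Apical ROIs are placed automatically (or supplied, e.g. from manual
    annotation); basal ROIs are the same centres translated vertically
    by the basal offset.  ROI means are averaged per compartment, the
    background mean subtracted from both, and the ratio returned.
    Saturated pixels are excluded from all means with a warning.
    """
    spec = spec or RoiSpec()
    h, w = image.pixels.shape
    radius = spec.radius_px(image.pixel_size)
    if apical_centers is None:
        apical_centers = place_apical_rois(image, spec=spec)
    apical_centers = [tuple(c) for c in apical_centers]
    if spec.basal_offset_um is not None:
        offset_px = int(round(spec.basal_offset_um / image.pixel_size))
    else:
        offset_px = int(round(spec.basal_offset_frac * h))
    basal_centers = [(r + offset_px, c) for r, c in apical_centers]
    for r, c in basal_centers:
        if not (radius <= r < h - radius):
            raise ValueError(f"basal ROI at row {r} falls outside the image")
    apical_mean = float(
        np.mean([_mean_intensity(image.pixels, _roi_mask((h, w), c, radius, spec.shape))
                 for c in apical_centers])
    )
    basal_mean = float(
        np.mean([_mean_intensity(image.pixels, _roi_mask((h, w), c, radius, spec.shape))
                 for c in basal_centers])
    )
    (rf0, rf1), (cf0, cf1) = spec.background_region
    bg_mask = np.zeros((h, w), dtype=bool)
    bg_mask[int(rf0 * h) : int(rf1 * h), int(cf0 * w) : int(cf1 * w)] = True
    background_mean = _mean_intensity(image.pixels, bg_mask)
    denom = basal_mean - background_mean
    if denom <= 0:
        raise ValueError(
            "non-positive denominator: basal mean "
            f"{basal_mean:.3f} <= background mean {background_mean:.3f}; "
            "check basal offset and background region placement"
        )
    ratio = (apical_mean - background_mean) / denom
    return LocalizationResult(
        apical_mean=apical_mean,
        basal_mean=basal_mean,
        background_mean=background_mean,
        ratio=ratio,
        roi_centers=tuple(apical_centers),
        basal_centers=tuple(basal_centers),
    )
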