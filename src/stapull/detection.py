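"""Diffraction-limited spot calling and the single-color intensity threshold.

Detection follows the SD-threshold semantics used for the pulldown images:
the projected image is Gaussian-smoothed, thresholded at ``mean + k·SD``
(both computed over unmasked pixels of the smoothed image, k = 5 by default),
and 8-connected components above threshold become candidate puncta.
Components smaller than the optical resolution limit are rejected as noise.

The single-color (SiMPull-style) analysis infers aggregates from brightness
alone: a threshold of 3 SD above the mean peak signal of non-coincident
(single-molecule) species is subtracted from the image before re-detection,
so only multi-label puncta survive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging import Image2D

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class DetectionParams:
    k_sd: float = 5.0
    smooth_sigma_px: float = 1.0
    min_diameter_px: float = 2.0  # resolution-limit exclusion
    max_area_px: float | None = None
    robust: bool = False  # median/MAD stand-in for mean/SD

    def __post_init__(self) -> None:
        if not self.k_sd > 0:
            raise ValueError("k_sd must be positive")
        if self.min_diameter_px < 0:
            raise ValueError("min_diameter_px must be >= 0")


@dataclass
class Spot:
    x: float  # continuous, pixel centers at integers
    y: float
    integrated_intensity: float  # background-subtracted sum over component
    peak_pixel: float  # maximum raw pixel value in component
    area_px: int
    on_border: bool = False


@dataclass
class SpotSet:
    spots: list[Spot]
    image_shape: tuple[int, int]
    pixel_size_um: float
    channel: str = ""
    fov: str = ""

    def __len__(self) -> int:
        return len(self.spots)

    @property
    def area_um2(self) -> float:
        return self.image_shape[0] * self.image_shape[1] * self.pixel_size_um**2

    def coordinates(self) -> np.ndarray:
        if not self.spots:
            return np.empty((0, 2))
        return np.array([[s.x, s.y] for s in self.spots])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fov": self.fov,
                "channel": self.channel,
                "x": [s.x for s in self.spots],
                "y": [s.y for s in self.spots],
                "area": [s.area_px for s in self.spots],
                "integrated_intensity": [s.integrated_intensity for s in self.spots],
                "peak_pixel": [s.peak_pixel for s in self.spots],
                "border_flag": [s.on_border for s in self.spots],
            }
        )


def detect_spots(
    img: Image2D, params: DetectionParams | None = None, channel: str = "", fov: str = ""
) -> SpotSet:
    """Detect diffraction-limited puncta above ``mean + k_sd·SD``.

    Centroids are intensity-weighted over background-subtracted raw pixels of
    each component; the background estimate is the mean of the unmasked raw
    image. Components touching the image border (or masked pixels) are kept
    but flagged so intensity statistics can exclude them. Spots are returned
    in deterministic row-major order of their centroids.
    """
    params = params or DetectionParams()
    mask = img.mask if img.mask is not None else np.ones(img.shape, dtype=bool)
    if mask.sum() < img.pixels.size / 2:
        raise ValueError("more than half the image is masked; refusing to detect")

    smoothed = ndimage.gaussian_filter(img.pixels, params.smooth_sigma_px)
    vals = smoothed[mask]
    if params.robust:
        center = float(np.median(vals))
        spread = float(np.median(np.abs(vals - center)) * 1.4826)
    else:
        center = float(vals.mean())
        spread = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    threshold = center + params.k_sd * spread

    above = (smoothed > threshold) & mask
    labels, n = ndimage.label(above, structure=_EIGHT)
    background = float(img.pixels[mask].mean())

    spots: list[Spot] = []
    if n:
        objects = ndimage.find_objects(labels)
        for lab, sl in enumerate(objects, start=1):
            comp = labels[sl] == lab
            area = int(comp.sum())
            eq_diam = 2.0 * np.sqrt(area / np.pi)
            if eq_diam < params.min_diameter_px:
                continue
            if params.max_area_px is not None and area > params.max_area_px:
                continue
            raw = img.pixels[sl]
            w = np.clip(raw - background, 0, None) * comp
            yy, xx = np.mgrid[sl[0].start : sl[0].stop, sl[1].start : sl[1].stop]
            wsum = w.sum()
            if wsum > 0:
                cx = float((w * xx).sum() / wsum)
                cy = float((w * yy).sum() / wsum)
            else:
                cx = float(xx[comp].mean())
                cy = float(yy[comp].mean())
            on_border = (
                sl[0].start == 0
                or sl[1].start == 0
                or sl[0].stop == img.shape[0]
                or sl[1].stop == img.shape[1]
            )
            if not on_border and img.mask is not None:
                # adjacency to masked pixels also flags the spot
                ex = (
                    slice(sl[0].start - 1, sl[0].stop + 1),
                    slice(sl[1].start - 1, sl[1].stop + 1),
                )
                grown = ndimage.binary_dilation(labels[ex] == lab, structure=_EIGHT)
                if np.any(grown & ~mask[ex]):
                    on_border = True
            spots.append(
                Spot(
                    x=cx,
                    y=cy,
                    integrated_intensity=float(wsum),
                    peak_pixel=float(raw[comp].max()),
                    area_px=area,
                    on_border=on_border,
                )
            )
    spots.sort(key=lambda s: (s.y, s.x))
    return SpotSet(spots, img.shape, img.pixel_size_um, channel=channel, fov=fov)


def simpull_threshold_value(noncoincident: list[Spot], k_sd: float = 3.0) -> float:
    """Aggregate-calling threshold: mean + 3·SD of single-molecule peak signal.

    ``noncoincident`` are spots identified as single-color (non-coincident)
    species; their peak pixel values define the single-molecule brightness
    distribution. Sample (n-1) SD.
    """
    if len(noncoincident) < 2:
        raise ValueError("need at least 2 noncoincident spots")
    peaks = np.array([s.peak_pixel for s in noncoincident], dtype=float)
    return float(peaks.mean() + k_sd * peaks.std(ddof=1))


def detect_simpull(
    img: Image2D,
    threshold: float,
    params: DetectionParams | None = None,
    channel: str = "",
    fov: str = "",
) -> SpotSet:
    """Single-color aggregate detection by threshold subtraction.

    The threshold value is subtracted from every pixel (clipped at zero) to
    suppress signal consistent with single molecules, then ordinary spot
    detection runs on the remainder.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    sub = Image2D(
        np.clip(img.pixels - threshold, 0, None), img.pixel_size_um, mask=img.mask
    )
    return detect_spots(sub, params, channel=channel, fov=fov)
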