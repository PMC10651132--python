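"""TIRF dual-view image I/O, channel splitting, registration and projection.

The assay images surface-captured protein on an emission-split ("dual-view")
camera: the two spectral channels occupy the two halves of each frame. This
module loads stacks, crops the halves apart, registers the channels from bead
fiducial images acquired in the same session, and reduces stacks to 2-D
projections for spot detection.

Coordinate convention (fixed so the 2-px coincidence radius is reproducible):
pixel indices are 0-based, ``x`` is the column and ``y`` the row, and
continuous centroid coordinates place pixel centers at integer positions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage
from skimage.registration import phase_cross_correlation
from skimage.transform import warp_polar


@dataclass
class ImageStack:
    """A multi-frame single-channel acquisition in camera counts."""

    frames: np.ndarray  # (n_frames, rows, cols)
    pixel_size_um: float
    frame_rate_hz: float = 20.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (frame, row, col) array with >=1 frame")
        if np.any(self.frames < 0):
            raise ValueError("intensities must be non-negative")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class Image2D:
    """A single 2-D image; ``mask`` marks pixels valid for statistics."""

    pixels: np.ndarray
    pixel_size_um: float
    mask: np.ndarray | None = None  # True = valid; None = all valid

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be 2-D")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("intensities must be finite")
        if self.mask is not None and self.mask.shape != self.pixels.shape:
            raise ValueError("mask shape must match pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def area_um2(self) -> float:
        return self.pixels.size * self.pixel_size_um**2

    def valid_pixels(self) -> np.ndarray:
        if self.mask is None:
            return self.pixels.ravel()
        return self.pixels[self.mask]


@dataclass
class DualViewLayout:
    """How the two spectral channels tile the camera frame.

    ``split_axis`` is the orientation of the dividing line: ``"vertical"``
    means left/right halves (columns are split), ``"horizontal"`` means
    top/bottom halves.  ``long_wavelength_half`` records which spatial half
    ("first" = left/top) carries the long-wavelength emission.
    """

    split_axis: str = "vertical"
    long_wavelength_half: str = "second"

    def __post_init__(self) -> None:
        if self.split_axis not in ("vertical", "horizontal"):
            raise ValueError("split_axis must be 'vertical' or 'horizontal'")
        if self.long_wavelength_half not in ("first", "second"):
            raise ValueError("long_wavelength_half must be 'first' or 'second'")


@dataclass
class RegistrationTransform:
    """Maps channel-B coordinates onto channel-A coordinates.

    ``(x_a, y_a) = scale * R(rotation_deg) @ (x_b, y_b) + (dx_px, dy_px)``
    with the rotation about the image center. Translation-only transforms
    have rotation_deg = 0, scale = 1.
    """

    dx_px: float
    dy_px: float
    rotation_deg: float = 0.0
    scale: float = 1.0
    residual_px: float | None = None  # mean fiducial residual after applying

    def apply_to_points(self, xy: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        cy = (shape[0] - 1) / 2.0
        cx = (shape[1] - 1) / 2.0
        th = np.deg2rad(self.rotation_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        centered = xy - [cx, cy]
        out = (self.scale * centered @ rot.T) + [cx, cy]
        out += [self.dx_px, self.dy_px]
        return out

    def inverse(self) -> "RegistrationTransform":
        # Exact inverse for translation-only; for similarity the center-relative
        # form inverts as scale->1/scale, rotation->-rotation, shift rotated back.
        th = np.deg2rad(-self.rotation_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        d = -(rot @ np.array([self.dx_px, self.dy_px])) / self.scale
        return RegistrationTransform(d[0], d[1], -self.rotation_deg, 1.0 / self.scale)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "dx_px": self.dx_px,
                    "dy_px": self.dy_px,
                    "rotation_deg": self.rotation_deg,
                    "scale": self.scale,
                    "residual_px": self.residual_px,
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RegistrationTransform":
        return cls(**json.loads(Path(path).read_text()))


def load_stack(
    path: str | Path,
    pixel_size_um: float = 0.1,
    frame_rate_hz: float = 20.0,
) -> ImageStack:
    """Load a single- or multi-page TIFF as an :class:`ImageStack`.

    Metadata absent from the file (pixel size, frame rate) is supplied by the
    caller's configuration.
    """
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3 or arr.shape[0] < 1:
        raise ValueError(f"{path}: expected a 2-D or 3-D TIFF, got shape {arr.shape}")
    return ImageStack(arr.astype(float), pixel_size_um, frame_rate_hz)


def save_stack(path: str | Path, stack: ImageStack) -> None:
    tifffile.imwrite(str(path), stack.frames.astype(np.float32))


def split_dual_view(
    stack: ImageStack, layout: DualViewLayout
) -> tuple[ImageStack, ImageStack]:
    """Crop the dual-view frame into its two equal channel halves.

    Returns the halves in spatial order (left/right or top/bottom);
    ``layout.long_wavelength_half`` says which one is the red channel.
    Concatenating the returned frames along the split axis reproduces the
    input exactly.
    """
    axis = 2 if layout.split_axis == "vertical" else 1
    n = stack.frames.shape[axis]
    if n % 2:
        raise ValueError(f"frame size {n} along split axis is odd; cannot halve")
    first, second = np.split(stack.frames, 2, axis=axis)
    return (
        ImageStack(first.copy(), stack.pixel_size_um, stack.frame_rate_hz),
        ImageStack(second.copy(), stack.pixel_size_um, stack.frame_rate_hz),
    )


def max_project(stack: ImageStack) -> Image2D:
    """Per-pixel maximum over frames (noise reduction before spot calling)."""
    return Image2D(stack.frames.max(axis=0), stack.pixel_size_um)


def mean_project(stack: ImageStack) -> Image2D:
    """Per-pixel mean over frames."""
    return Image2D(stack.frames.mean(axis=0), stack.pixel_size_um)


def _detect_fiducials(img: Image2D, min_separation_px: int = 5) -> np.ndarray:
    """Local-maximum bead candidates (x, y) above a robust threshold."""
    sm = ndimage.gaussian_filter(img.pixels, 1.0)
    med = np.median(sm)
    mad = np.median(np.abs(sm - med)) * 1.4826 + 1e-12
    thr = med + 5 * mad
    maxf = ndimage.maximum_filter(sm, size=2 * min_separation_px + 1)
    peaks = np.argwhere((sm == maxf) & (sm > thr))
    if len(peaks) == 0:
        return np.empty((0, 2))
    # refine each peak with an iterated intensity-weighted centroid; the
    # window recenters between passes so truncation bias averages out
    half = 4
    out = []
    for r, c in peaks:
        cx, cy = float(c), float(r)
        for _ in range(3):
            r0 = max(int(round(cy)) - half, 0)
            r1 = min(int(round(cy)) + half + 1, sm.shape[0])
            c0 = max(int(round(cx)) - half, 0)
            c1 = min(int(round(cx)) + half + 1, sm.shape[1])
            w = np.clip(img.pixels[r0:r1, c0:c1] - med, 0, None)
            if w.sum() <= 0:
                break
            yy, xx = np.mgrid[r0:r1, c0:c1]
            cx = float((w * xx).sum() / w.sum())
            cy = float((w * yy).sum() / w.sum())
        out.append((cx, cy))
    return np.array(out)


def _match_points(a: np.ndarray, b: np.ndarray, radius: float) -> np.ndarray:
    """Greedy nearest pairing; returns displacement vectors b->a."""
    if len(a) == 0 or len(b) == 0:
        return np.empty((0, 2))
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    pairs = []
    used_a: set[int] = set()
    used_b: set[int] = set()
    for i, j in sorted(
        ((i, j) for i in range(len(a)) for j in range(len(b)) if d[i, j] <= radius),
        key=lambda ij: d[ij[0], ij[1]],
    ):
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append(a[i] - b[j])
    return np.array(pairs) if pairs else np.empty((0, 2))


def estimate_registration(
    beads_a: Image2D,
    beads_b: Image2D,
    mode: str = "translation",
    upsample_factor: int = 100,
) -> RegistrationTransform:
    """Estimate the channel-B -> channel-A transform from bead fiducials.

    Translation is recovered by phase cross-correlation with sub-pixel peak
    interpolation. In ``mode="similarity"`` rotation and isotropic scale are
    first estimated from the log-polar magnitude spectra, channel B is
    resampled accordingly, and the residual translation is then estimated.

    The returned transform carries the mean residual displacement of matched
    beads after registration (``residual_px``), or None when fewer than three
    bead pairs could be matched.
    """
    if beads_a.shape != beads_b.shape:
        raise ValueError("bead images must share a shape")
    a = beads_a.pixels
    b = beads_b.pixels
    rotation = 0.0
    scale = 1.0
    if mode == "similarity":
        rotation, scale = _estimate_rotation_scale(a, b)
        t = RegistrationTransform(0.0, 0.0, rotation, scale)
        b = _resample(Image2D(b, beads_b.pixel_size_um), t).pixels
    elif mode != "translation":
        raise ValueError("mode must be 'translation' or 'similarity'")
    shift, error, _ = phase_cross_correlation(
        a, b, upsample_factor=upsample_factor, normalization=None
    )
    if not np.all(np.isfinite(shift)):
        raise ValueError("degenerate correlation peak")
    transform = RegistrationTransform(
        dx_px=float(shift[1]), dy_px=float(shift[0]), rotation_deg=rotation, scale=scale
    )
    pa = _detect_fiducials(beads_a)
    pb = _detect_fiducials(beads_b)
    if len(pa) == 0 and len(pb) == 0:
        raise ValueError("no detectable fiducials in either bead image")
    if len(pa) >= 3 and len(pb) >= 3:
        pb_reg = transform.apply_to_points(pb, beads_a.shape)
        disp = _match_points(pa, pb_reg, radius=3.0)
        if len(disp) >= 3:
            transform.residual_px = float(np.linalg.norm(disp, axis=1).mean())
    return transform


def _estimate_rotation_scale(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Rotation/scale via phase correlation of log-polar FFT magnitudes."""
    wa = np.abs(np.fft.fftshift(np.fft.fft2(a - a.mean())))
    wb = np.abs(np.fft.fftshift(np.fft.fft2(b - b.mean())))
    radius = min(a.shape) // 2
    pa = warp_polar(wa, radius=radius, scaling="log", output_shape=(360, radius))
    pb = warp_polar(wb, radius=radius, scaling="log", output_shape=(360, radius))
    shift, _, _ = phase_cross_correlation(pa, pb, upsample_factor=20, normalization=None)
    rotation = -shift[0]  # degrees; spectra rotate with the image
    if rotation > 90:
        rotation -= 180
    elif rotation < -90:
        rotation += 180
    klog = radius / np.log(radius)
    scale = float(np.exp(shift[1] / klog))
    return float(rotation), scale


def _resample(img: Image2D, t: RegistrationTransform) -> Image2D:
    """Resample ``img`` from channel-B space into channel-A space (bilinear)."""
    cy = (img.shape[0] - 1) / 2.0
    cx = (img.shape[1] - 1) / 2.0
    th = np.deg2rad(t.rotation_deg)
    # inverse map: for each output (A) pixel, sample the B pixel it came from
    rot = np.array([[np.cos(th), np.sin(th)], [-np.sin(th), np.cos(th)]]) / t.scale
    yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    pts = np.stack([xx.ravel() - t.dx_px - cx, yy.ravel() - t.dy_px - cy])
    src = rot @ pts
    src_x = src[0] + cx
    src_y = src[1] + cy
    out = ndimage.map_coordinates(
        img.pixels, [src_y, src_x], order=1, mode="constant", cval=0.0
    ).reshape(img.shape)
    inside = (
        (src_x >= 0)
        & (src_x <= img.shape[1] - 1)
        & (src_y >= 0)
        & (src_y <= img.shape[0] - 1)
    ).reshape(img.shape)
    if img.mask is not None:
        src_mask = ndimage.map_coordinates(
            img.mask.astype(float), [src_y, src_x], order=0, mode="constant", cval=0.0
        ).reshape(img.shape)
        inside &= src_mask > 0.5
    return Image2D(out, img.pixel_size_um, mask=inside)


def apply_registration(
    img: Image2D, t: RegistrationTransform, fill_value: float = 0.0
) -> Image2D:
    """Resample a channel-B image onto the channel-A pixel grid.

    Out-of-frame pixels receive ``fill_value`` and are masked out of
    downstream image statistics.
    """
    if not all(
        np.isfinite(v) for v in (t.dx_px, t.dy_px, t.rotation_deg, t.scale)
    ):
        raise ValueError("transform parameters must be finite")
    out = _resample(img, t)
    out.pixels[~out.mask] = fill_value
    return out
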