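"""Image I/O and the single-parameter simplified MSRCR enhancer.

The enhancer implements the one-knob variant of multi-scale retinex with
color restoration popularised by the GIMP retinex plug-in.  For each RGB
channel it computes the mean ``Mean`` and the population standard deviation
``Var`` of the channel intensities, derives stretch bounds

    Min = Mean - Dyn * Var
    Max = Mean + Dyn * Var

and linearly maps every pixel by ``(Value - Min) / (Max - Min) * 255``,
clipping to [0, 255].  ``Dyn`` is the single tuning parameter: small values
stretch aggressively (saturating tails), large values stretch gently.

``Var`` is deliberately the standard deviation, not the variance: this
matches the GIMP "Dyn" slider semantics, and with the variance the bounds
would be absurd for any natural image (sigma^2 > 100 would put Min far
below zero at Dyn = 1).

An optional multi-scale retinex pre-filter (equal-weight log-ratio against
Gaussian surrounds) can be applied before the stretch; it is off by default
in the library so that the stretch alone is the reference behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError
from scipy.ndimage import gaussian_filter

__all__ = [
    "ImageRGB",
    "ChannelStats",
    "RetinexParams",
    "DimensionError",
    "ImageReadError",
    "read_image",
    "write_image",
    "channel_stats",
    "msrcr_enhance",
    "msr_prefilter",
    "quantize",
]

#: Minimum height/width accepted for metric-bearing images.
MIN_SIZE = 8

#: Default Gaussian surround scales (sigma, pixels) for the MSR pre-filter.
DEFAULT_MSR_SCALES = (16.0, 80.0, 240.0)


class DimensionError(ValueError):
    """Image dimensions violate a minimum-size or block-size requirement."""


class ImageReadError(IOError):
    """File could not be decoded as an 8-bit raster image."""


def quantize(pixels: np.ndarray) -> np.ndarray:
    """Clip to [0, 255] and round half away from zero to integer values.

    Returns a float64 array holding exact integers; 8-bit conversion is a
    plain cast afterwards.  For non-negative values round-half-away equals
    ``floor(x + 0.5)``.
    """
    clipped = np.clip(np.asarray(pixels, dtype=np.float64), 0.0, 255.0)
    return np.floor(clipped + 0.5)


@dataclass
class ImageRGB:
    """8-bit-range RGB raster; float64 in memory, [0, 255] by invariant.

    Pixels may hold fractional values mid-pipeline (e.g. the pre-filter
    response); quantisation to integers happens at enhancement output and
    at file-write time.
    """

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"ImageRGB requires an HxWx3 array, got shape {self.pixels.shape}"
            )
        if self.pixels.min() < 0.0 or self.pixels.max() > 255.0:
            raise ValueError("ImageRGB intensities must lie in [0, 255]")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def to_uint8(self) -> np.ndarray:
        return quantize(self.pixels).astype(np.uint8)

    def copy(self, source_id: str | None = None) -> "ImageRGB":
        return ImageRGB(
            self.pixels.copy(),
            self.source_id if source_id is None else source_id,
        )


@dataclass(frozen=True)
class ChannelStats:
    """Per-channel mean, dispersion and derived stretch bounds.

    ``var`` is the population standard deviation of the channel (see module
    docstring); bounds satisfy ``max_bound - min_bound == 2 * dyn * var``.
    """

    mean: np.ndarray
    var: np.ndarray
    min_bound: np.ndarray
    max_bound: np.ndarray


@dataclass(frozen=True)
class RetinexParams:
    """Configuration of the simplified MSRCR enhancer.

    dyn:           stretch parameter, > 0 (dimensionless).
    msr_prefilter: apply the multi-scale log-ratio pre-filter first.
    msr_scales:    Gaussian surround sigmas (pixels) for the pre-filter.
    """

    dyn: float = 2.0
    msr_prefilter: bool = False
    msr_scales: tuple[float, ...] = field(default=DEFAULT_MSR_SCALES)

    def __post_init__(self) -> None:
        if not self.dyn > 0:
            raise ValueError(f"dyn must be > 0, got {self.dyn}")
        if self.msr_prefilter and len(self.msr_scales) == 0:
            raise ValueError("msr_prefilter requires at least one scale")
        if any(s <= 0 for s in self.msr_scales):
            raise ValueError("msr_scales must all be > 0")


def read_image(path: str | Path) -> ImageRGB:
    """Read a PNG/JPEG/TIFF file into an :class:`ImageRGB`.

    Grayscale inputs are replicated to three channels; alpha is dropped.
    Raises :class:`ImageReadError` for unreadable files and
    :class:`DimensionError` for images smaller than 8x8.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            rgb = im.convert("RGB")
            arr = np.asarray(rgb, dtype=np.float64)
    except (UnidentifiedImageError, OSError) as exc:
        raise ImageReadError(f"cannot decode image file {path}: {exc}") from exc
    if arr.shape[0] < MIN_SIZE or arr.shape[1] < MIN_SIZE:
        raise DimensionError(
            f"image {path} is {arr.shape[1]}x{arr.shape[0]}; "
            f"minimum is {MIN_SIZE}x{MIN_SIZE}"
        )
    return ImageRGB(arr, source_id=path.stem)


def write_image(img: ImageRGB, path: str | Path) -> None:
    """Write the quantised image as 8-bit RGB; format from the suffix."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(img.to_uint8(), mode="RGB").save(path)


def channel_stats(img: ImageRGB, dyn: float) -> ChannelStats:
    """Per-channel mean, population standard deviation and stretch bounds."""
    if not dyn > 0:
        raise ValueError(f"dyn must be > 0, got {dyn}")
    flat = img.pixels.reshape(-1, 3)
    mean = flat.mean(axis=0)
    std = flat.std(axis=0)  # population (ddof=0)
    return ChannelStats(
        mean=mean,
        var=std,
        min_bound=mean - dyn * std,
        max_bound=mean + dyn * std,
    )


def msr_prefilter(
    img: ImageRGB, scales: tuple[float, ...] = DEFAULT_MSR_SCALES
) -> ImageRGB:
    """Multi-scale retinex log-ratio pre-filter.

    Per channel: the equal-weight average over scales of
    ``log(ch + 1) - log(G_sigma(ch) + 1)`` with a reflective-boundary
    separable Gaussian surround, then a per-channel linear rescale to
    [0, 255].  A constant response (e.g. a constant input) maps to
    mid-gray 127.5.
    """
    if len(scales) == 0:
        raise ValueError("scales must be non-empty")
    if any(s <= 0 for s in scales):
        raise ValueError("scales must all be > 0")
    out = np.empty_like(img.pixels)
    for c in range(3):
        ch = img.pixels[:, :, c]
        log_ch = np.log(ch + 1.0)
        acc = np.zeros_like(ch)
        for s in scales:
            surround = gaussian_filter(ch, sigma=s, mode="reflect")
            acc += log_ch - np.log(surround + 1.0)
        resp = acc / len(scales)
        lo, hi = resp.min(), resp.max()
        if hi - lo == 0.0:
            out[:, :, c] = 127.5
        else:
            out[:, :, c] = (resp - lo) / (hi - lo) * 255.0
    return ImageRGB(out, source_id=img.source_id)


def msrcr_enhance(img: ImageRGB, params: RetinexParams) -> ImageRGB:
    """Simplified MSRCR: optional MSR pre-filter, then the Dyn stretch.

    Channel statistics are computed on the floating-point (possibly
    pre-filtered) channel.  A degenerate channel (zero dispersion) is
    passed through unchanged apart from quantisation.  Output pixels are
    integer-valued after clip-and-round.
    """
    work = msr_prefilter(img, params.msr_scales) if params.msr_prefilter else img
    stats = channel_stats(work, params.dyn)
    out = np.empty_like(work.pixels)
    for c in range(3):
        ch = work.pixels[:, :, c]
        lo, hi = stats.min_bound[c], stats.max_bound[c]
        if hi - lo == 0.0:
            out[:, :, c] = ch
        else:
            out[:, :, c] = (ch - lo) / (hi - lo) * 255.0
    return ImageRGB(quantize(out), source_id=img.source_id)
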