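"""Underwater Image Quality Measure (UIQM) and its three components.

UIQM is a weighted sum of a colorfulness term (UICM), a sharpness term
(UISM) and a contrast term (UIConM):

    UIQM = c1 * UICM + c2 * UISM + c3 * UIConM

with the published weights c1 = 0.0282, c2 = 0.2953, c3 = 3.5753.  It is
the standard no-reference score for judging underwater enhancement, and is
the selection criterion of the Dyn-sweep dataset builder in this package.

Component definitions, briefly:

* UICM - opponent color channels RG = R - G and YB = (R + G)/2 - B;
  asymmetric alpha-trimmed mean mu and the mean squared deviation sigma^2
  of all pixels about that trimmed mean, combined as
  -0.0268 * sqrt(muRG^2 + muYB^2) + 0.1586 * sqrt(s2RG + s2YB).
* UISM - per channel, Sobel gradient magnitude multiplied elementwise by
  the channel, then the EME log-contrast over non-overlapping blocks,
  (2/K) * sum ln(max/min); channels combined with luma weights
  0.299 / 0.587 / 0.114.
* UIConM - logAMEE of the intensity (unweighted channel mean) over
  non-overlapping blocks using parameterised logarithmic image processing
  (PLIP) arithmetic: r = plip_sub(max, min) / plip_add(max, min) per
  block, combined as (-1/K) * sum r * ln(r) so that the measure is
  non-negative and grows with local contrast.  Degenerate blocks
  (max == min) contribute zero.

All block measures discard partial edge tiles.  Every constant is carried
in :class:`MetricConfig` so scores are comparable only within one config.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imaging import DimensionError, ImageRGB

__all__ = ["MetricConfig", "UIQMScore", "uicm", "uism", "uiconm", "uiqm"]

# Published UICM combination constants.
UICM_MU_COEF = -0.0268
UICM_SIGMA_COEF = 0.1586

# Luma weights for combining per-channel EME in UISM.
UISM_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class MetricConfig:
    """All tunable constants of the UIQM computation.

    c1, c2, c3:  composite weights (dimensionless).
    alpha_trim:  trim fraction per tail for the UICM statistics, [0, 0.5).
    block:       block edge length (pixels) for UISM/UIConM, >= 2.
    plip_gamma:  PLIP arithmetic constant for UIConM.
    eps:         stabiliser inside log ratios.
    """

    c1: float = 0.0282
    c2: float = 0.2953
    c3: float = 3.5753
    alpha_trim: float = 0.1
    block: int = 8
    plip_gamma: float = 1026.0
    eps: float = 1e-7

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha_trim < 0.5):
            raise ValueError(f"alpha_trim must be in [0, 0.5), got {self.alpha_trim}")
        if self.block < 2:
            raise ValueError(f"block must be >= 2, got {self.block}")
        if self.plip_gamma <= 0 or self.eps <= 0:
            raise ValueError("plip_gamma and eps must be > 0")

    def to_dict(self) -> dict:
        return {
            "c1": self.c1,
            "c2": self.c2,
            "c3": self.c3,
            "alpha_trim": self.alpha_trim,
            "block": self.block,
            "plip_gamma": self.plip_gamma,
            "eps": self.eps,
        }


@dataclass(frozen=True)
class UIQMScore:
    uicm: float
    uism: float
    uiconm: float
    total: float


def _trimmed_stats(values: np.ndarray, alpha: float) -> tuple[float, float]:
    """Alpha-trimmed mean and mean squared deviation about it.

    The trim count per tail is ceil(alpha * N); the squared deviation is
    averaged over all N values, not just the retained ones.
    """
    flat = np.sort(values.ravel())
    n = flat.size
    t = int(np.ceil(alpha * n))
    kept = flat[t : n - t] if n - 2 * t > 0 else flat
    mu = float(kept.mean())
    sigma2 = float(np.mean((values - mu) ** 2))
    return mu, sigma2


def uicm(img: ImageRGB, cfg: MetricConfig = MetricConfig()) -> float:
    """Colorfulness from trimmed statistics of the opponent channels."""
    r = img.pixels[:, :, 0]
    g = img.pixels[:, :, 1]
    b = img.pixels[:, :, 2]
    rg = r - g
    yb = (r + g) / 2.0 - b
    mu_rg, s2_rg = _trimmed_stats(rg, cfg.alpha_trim)
    mu_yb, s2_yb = _trimmed_stats(yb, cfg.alpha_trim)
    return UICM_MU_COEF * float(np.hypot(mu_rg, mu_yb)) + UICM_SIGMA_COEF * float(
        np.sqrt(s2_rg + s2_yb)
    )


def _check_block(img: ImageRGB, block: int) -> None:
    if img.height < block or img.width < block:
        raise DimensionError(
            f"image {img.width}x{img.height} smaller than block {block}"
        )


def _block_minmax(channel: np.ndarray, block: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-tile max and min over non-overlapping blocks; partial tiles dropped."""
    h, w = channel.shape
    nh, nw = h // block, w // block
    tiles = channel[: nh * block, : nw * block].reshape(nh, block, nw, block)
    return tiles.max(axis=(1, 3)), tiles.min(axis=(1, 3))


def _eme(channel: np.ndarray, block: int, eps: float) -> float:
    """EME log-contrast: (2/K) * sum ln((max+eps)/(min+eps)) over tiles."""
    mx, mn = _block_minmax(channel, block)
    k = mx.size
    return float(2.0 / k * np.sum(np.log((mx + eps) / (mn + eps))))


def uism(img: ImageRGB, cfg: MetricConfig = MetricConfig()) -> float:
    """Sharpness: luma-weighted EME of Sobel-edge-enhanced channels."""
    _check_block(img, cfg.block)
    total = 0.0
    for c, w in enumerate(UISM_WEIGHTS):
        ch = img.pixels[:, :, c]
        gx = ndimage.sobel(ch, axis=0, mode="reflect")
        gy = ndimage.sobel(ch, axis=1, mode="reflect")
        mag = np.hypot(gx, gy)
        total += w * _eme(mag * ch, cfg.block, cfg.eps)
    return total


def plip_sub(a: np.ndarray, b: np.ndarray, gamma: float) -> np.ndarray:
    """PLIP subtraction: gamma * (a - b) / (gamma - b)."""
    return gamma * (a - b) / (gamma - b)


def plip_add(a: np.ndarray, b: np.ndarray, gamma: float) -> np.ndarray:
    """PLIP addition: a + b - a*b/gamma."""
    return a + b - a * b / gamma


def uiconm(img: ImageRGB, cfg: MetricConfig = MetricConfig()) -> float:
    """Contrast: blockwise logAMEE of the intensity image with PLIP ops."""
    _check_block(img, cfg.block)
    intensity = img.pixels.mean(axis=2)
    mx, mn = _block_minmax(intensity, cfg.block)
    k = mx.size
    sub = plip_sub(mx, mn, cfg.plip_gamma)
    add = plip_add(mx, mn, cfg.plip_gamma)
    # degenerate tiles (max == min) get r = 1 so r * ln r is exactly 0
    ratio = np.ones_like(sub)
    np.divide(sub, add + cfg.eps, out=ratio, where=mx > mn)
    return float(-np.sum(ratio * np.log(ratio)) / k)


def uiqm(img: ImageRGB, cfg: MetricConfig = MetricConfig()) -> UIQMScore:
    """All three components and the weighted composite."""
    c_uicm = uicm(img, cfg)
    c_uism = uism(img, cfg)
    c_uiconm = uiconm(img, cfg)
    total = cfg.c1 * c_uicm + cfg.c2 * c_uism + cfg.c3 * c_uiconm
    return UIQMScore(uicm=c_uicm, uism=c_uism, uiconm=c_uiconm, total=total)
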