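"""Synthetic seafloor scenes and parametric underwater degradation.

Real ROV footage of cold-seep habitats suffers a characteristic set of
defects: strong red-channel attenuation giving a blue-green cast, veiling
haze from backscatter, non-uniform lamp illumination (vignetting), and
sensor noise in dim frames.  This module generates clean synthetic scenes
(gradients + random geometric "fauna" + band-limited texture) and applies a
parametric degradation

    out = clip((1 - v) * blur(img * attenuation) * vignette + v * veil + noise)

so that the whole enhancement pipeline, the quality metric and the GAN can
be exercised end to end without any external imagery.  Five built-in
presets stand in for distinct camera/lighting "working conditions"; they
are declared stand-ins, not radiative-transfer calibrations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .imaging import DimensionError, ImageRGB, quantize, write_image

__all__ = [
    "DegradationParams",
    "PRESETS",
    "make_scene",
    "degrade_underwater",
    "make_fixture_set",
]

MIN_SCENE = 32


@dataclass(frozen=True)
class DegradationParams:
    """Parametric underwater degradation.

    attenuation:      per-channel multiplicative transmission in (0, 1];
                      underwater, red is attenuated hardest so its factor
                      is the smallest by default.
    veiling_color:    backscatter veil RGB, [0, 255] each.
    veiling_strength: veil mixing weight v in [0, 1].
    vignette_strength:radial illumination falloff in [0, 1].
    vignette_offset:  lamp offset (dy, dx) as a fraction of H/W.
    blur_sigma:       Gaussian blur (pixels) of the attenuated scene
                      radiance — the high-frequency loss of turbid water.
    noise_sigma:      additive Gaussian noise sigma, intensity units.
    seed:             RNG seed for the noise field.
    """

    attenuation: tuple[float, float, float] = (0.35, 0.70, 0.95)
    veiling_color: tuple[float, float, float] = (18.0, 64.0, 110.0)
    veiling_strength: float = 0.25
    vignette_strength: float = 0.3
    vignette_offset: tuple[float, float] = (0.0, 0.0)
    blur_sigma: float = 0.8
    noise_sigma: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not 0 < a for a in self.attenuation):
            raise ValueError("attenuation factors must be > 0")
        if any(not 0 <= c <= 255 for c in self.veiling_color):
            raise ValueError("veiling_color must be in [0, 255]")
        if not 0 <= self.veiling_strength <= 1:
            raise ValueError("veiling_strength must be in [0, 1]")
        if not 0 <= self.vignette_strength <= 1:
            raise ValueError("vignette_strength must be in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")

    def is_identity(self) -> bool:
        return (
            self.attenuation == (1.0, 1.0, 1.0)
            and self.veiling_strength == 0.0
            and self.vignette_strength == 0.0
            and self.blur_sigma == 0.0
            and self.noise_sigma == 0.0
        )


#: Five working-condition presets: blue cast, green cast, dark vignette
#: (off-centre lamp), hazy water column, and a noisy low-light camera.
PRESETS: dict[str, DegradationParams] = {
    "blue_cast": DegradationParams(
        attenuation=(0.30, 0.65, 0.95),
        veiling_color=(18.0, 60.0, 110.0),
        veiling_strength=0.25,
        vignette_strength=0.25,
        blur_sigma=0.8,
        noise_sigma=3.0,
    ),
    "green_cast": DegradationParams(
        attenuation=(0.35, 0.90, 0.60),
        veiling_color=(25.0, 95.0, 70.0),
        veiling_strength=0.25,
        vignette_strength=0.20,
        blur_sigma=0.8,
        noise_sigma=3.0,
    ),
    "dark_vignette": DegradationParams(
        attenuation=(0.50, 0.70, 0.80),
        veiling_color=(10.0, 30.0, 50.0),
        veiling_strength=0.12,
        vignette_strength=0.75,
        vignette_offset=(0.15, 0.10),
        blur_sigma=0.8,
        noise_sigma=4.0,
    ),
    "hazy": DegradationParams(
        attenuation=(0.55, 0.80, 0.90),
        veiling_color=(120.0, 160.0, 180.0),
        veiling_strength=0.55,
        vignette_strength=0.10,
        blur_sigma=1.5,
        noise_sigma=2.0,
    ),
    "noisy": DegradationParams(
        attenuation=(0.45, 0.70, 0.85),
        veiling_color=(20.0, 60.0, 90.0),
        veiling_strength=0.20,
        vignette_strength=0.30,
        blur_sigma=1.0,
        noise_sigma=8.0,
    ),
}


def make_scene(seed: int, size: tuple[int, int] = (64, 64)) -> ImageRGB:
    """Deterministic synthetic seafloor scene.

    Composites per-channel oriented gradients, random rectangles and
    ellipses (object stand-ins) and band-limited texture, then stretches
    every channel to the full [0, 255] range.
    """
    h, w = size
    if h < MIN_SCENE or w < MIN_SCENE:
        raise DimensionError(f"scene size {w}x{h} below minimum {MIN_SCENE}")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    yy /= h - 1
    xx /= w - 1
    img = np.empty((h, w, 3), dtype=np.float64)
    for c in range(3):
        theta = rng.uniform(0, 2 * np.pi)
        ramp = np.cos(theta) * xx + np.sin(theta) * yy
        lo, hi = sorted(rng.uniform(0, 255, size=2))
        img[:, :, c] = lo + (ramp - ramp.min()) / max(np.ptp(ramp), 1e-9) * (hi - lo)

    # objects: rectangles and ellipses in random colors
    n_obj = rng.integers(5, 9)
    for _ in range(n_obj):
        color = rng.uniform(0, 255, size=3)
        cy, cx = rng.uniform(0.1, 0.9) * h, rng.uniform(0.1, 0.9) * w
        ry, rx = rng.uniform(0.05, 0.25) * h, rng.uniform(0.05, 0.25) * w
        if rng.random() < 0.5:
            mask = (np.abs(yy * (h - 1) - cy) < ry) & (np.abs(xx * (w - 1) - cx) < rx)
        else:
            mask = ((yy * (h - 1) - cy) / ry) ** 2 + (
                (xx * (w - 1) - cx) / rx
            ) ** 2 < 1.0
        img[mask] = color

    # band-limited texture: smoothed white noise
    texture = gaussian_filter(rng.normal(0.0, 1.0, size=(h, w)), sigma=1.5)
    img += 25.0 * texture[:, :, None]

    # full dynamic range per channel
    for c in range(3):
        ch = img[:, :, c]
        img[:, :, c] = (ch - ch.min()) / max(np.ptp(ch), 1e-9) * 255.0
    return ImageRGB(quantize(img), source_id=f"scene_{seed:06d}")


def _vignette_mask(
    h: int, w: int, strength: float, offset: tuple[float, float]
) -> np.ndarray:
    """Radial falloff 1 - strength * (r / r_max)^2, centered + offset."""
    cy = (h - 1) / 2.0 + offset[0] * h
    cx = (w - 1) / 2.0 + offset[1] * w
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    r2 = (yy - cy) ** 2 + (xx - cx) ** 2
    r2max = max(r2.max(), 1e-9)
    return 1.0 - strength * (r2 / r2max)


def degrade_underwater(img: ImageRGB, p: DegradationParams) -> ImageRGB:
    """Apply the parametric underwater degradation model.

    The identity configuration reproduces the input exactly.  Noise is
    drawn from ``default_rng(p.seed)``, so the map is deterministic.
    """
    if p.is_identity():
        return img.copy()
    v = p.veiling_strength
    atten = np.asarray(p.attenuation, dtype=np.float64)
    veil = np.asarray(p.veiling_color, dtype=np.float64)
    mask = _vignette_mask(img.height, img.width, p.vignette_strength, p.vignette_offset)
    radiance = img.pixels * atten
    if p.blur_sigma > 0:
        radiance = gaussian_filter(radiance, sigma=(p.blur_sigma, p.blur_sigma, 0))
    out = (1.0 - v) * radiance * mask[:, :, None] + v * veil
    if p.noise_sigma > 0:
        rng = np.random.default_rng(p.seed)
        out = out + rng.normal(0.0, p.noise_sigma, size=out.shape)
    return ImageRGB(quantize(out), source_id=img.source_id)


def make_fixture_set(
    n: int,
    seed: int,
    out_dir: str | Path | None = None,
    conditions: int = 5,
    size: tuple[int, int] = (64, 64),
) -> dict:
    """Generate ``n`` clean/degraded pairs cycling through presets.

    Image ``i`` uses scene seed derived from (seed, i) and the preset
    ``i % conditions``.  When ``out_dir`` is given, writes
    ``clean/<id>.png`` and ``degraded/<id>.png`` plus ``fixtures.json``;
    always returns the listing with the in-memory pairs omitted from the
    JSON form.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if conditions < 1:
        raise ValueError("conditions must be >= 1")
    preset_names = list(PRESETS)[:conditions]
    if len(preset_names) < conditions:
        preset_names += [
            preset_names[i % len(preset_names)]
            for i in range(conditions - len(preset_names))
        ]
    ss = np.random.SeedSequence(seed)
    scene_seeds = ss.generate_state(2 * n).astype(np.int64) % (2**31)
    entries = []
    pairs = []
    for i in range(n):
        name = preset_names[i % conditions]
        base = PRESETS[name]
        p = DegradationParams(
            attenuation=base.attenuation,
            veiling_color=base.veiling_color,
            veiling_strength=base.veiling_strength,
            vignette_strength=base.vignette_strength,
            vignette_offset=base.vignette_offset,
            noise_sigma=base.noise_sigma,
            seed=int(scene_seeds[2 * i + 1]),
        )
        clean = make_scene(int(scene_seeds[2 * i]), size=size)
        clean = ImageRGB(clean.pixels, source_id=f"fix_{i:03d}")
        degraded = degrade_underwater(clean, p)
        pairs.append((clean, degraded))
        entries.append(
            {"id": clean.source_id, "condition": name, "scene_seed": int(scene_seeds[2 * i])}
        )
    listing = {"n": n, "seed": seed, "conditions": conditions, "images": entries}
    if out_dir is not None:
        out_dir = Path(out_dir)
        for clean, degraded in pairs:
            write_image(clean, out_dir / "clean" / f"{clean.source_id}.png")
            write_image(degraded, out_dir / "degraded" / f"{degraded.source_id}.png")
        (out_dir / "fixtures.json").write_text(
            json.dumps(listing, indent=2, sort_keys=True) + "\n"
        )
    listing["pairs"] = pairs
    return listing
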