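"""Metric-guided Dyn sweep and unpaired-dataset assembly.

The core procedure: enhance every input image with the simplified MSRCR at
each Dyn on a grid (default 0.4 to 6.0, step 0.2), score each candidate
with UIQM, keep the per-image argmax, and assemble the originals (domain A,
the degraded style) and the best enhancements (domain B, the clear style)
into an unpaired training dataset with a seeded 80/20 train/validation
split.  A per-Dyn report of UIQM mean and population variance across the
image set mirrors the usual way such sweeps are summarised.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .imaging import ImageRGB, RetinexParams, msrcr_enhance, write_image
from .uiqm import MetricConfig, uiqm

__all__ = [
    "SweepResult",
    "DatasetManifest",
    "DynReport",
    "default_grid",
    "sweep",
    "build_dataset",
    "dyn_report",
]

logger = logging.getLogger(__name__)

GRID_START = 0.4
GRID_STOP = 6.0
GRID_STEP = 0.2


def default_grid() -> list[float]:
    """The standard Dyn grid: 0.4, 0.6, ..., 6.0 (29 values, ascending)."""
    n = int(round((GRID_STOP - GRID_START) / GRID_STEP)) + 1
    return [round(GRID_START + k * GRID_STEP, 1) for k in range(n)]


@dataclass(frozen=True)
class SweepResult:
    """Outcome of scoring one image across the Dyn grid.

    ``best_dyn`` is the grid value at the FIRST index attaining the
    maximum score — at a tie the mildest enhancement wins.
    """

    source_id: str
    grid: tuple[float, ...]
    scores: tuple[float, ...]
    best_dyn: float
    best_score: float


def sweep(
    img: ImageRGB,
    grid: list[float] | None = None,
    retinex: RetinexParams = RetinexParams(),
    metric: MetricConfig = MetricConfig(),
) -> SweepResult:
    """Enhance at every Dyn in the grid, score with UIQM, take the argmax."""
    grid = default_grid() if grid is None else list(grid)
    if len(grid) == 0:
        raise ValueError("grid must be non-empty")
    scores = []
    for dyn in grid:
        params = RetinexParams(
            dyn=dyn,
            msr_prefilter=retinex.msr_prefilter,
            msr_scales=retinex.msr_scales,
        )
        scores.append(uiqm(msrcr_enhance(img, params), metric).total)
    best_idx = int(np.argmax(scores))  # argmax returns the first maximum
    return SweepResult(
        source_id=img.source_id,
        grid=tuple(grid),
        scores=tuple(scores),
        best_dyn=grid[best_idx],
        best_score=scores[best_idx],
    )


@dataclass
class DatasetManifest:
    """Self-describing record of an unpaired two-domain dataset.

    Domain A holds the original (degraded-style) images, domain B the
    best-Dyn enhancements.  The two domains are unpaired by contract: no
    pairing index is stored, and each domain is shuffled with its own
    seed-derived stream.
    """

    domain_a: list[str]
    domain_b: list[dict]
    train_a: list[str]
    val_a: list[str]
    train_b: list[str]
    val_b: list[str]
    split_fraction: float
    seed: int
    grid: list[float]
    metric_config: dict
    out_dir: str = ""

    def to_json(self) -> str:
        payload = {
            "domain_a": self.domain_a,
            "domain_b": self.domain_b,
            "train_a": self.train_a,
            "val_a": self.val_a,
            "train_b": self.train_b,
            "val_b": self.val_b,
            "split_fraction": self.split_fraction,
            "seed": self.seed,
            "grid": self.grid,
            "metric_config": self.metric_config,
        }
        return json.dumps(payload, indent=2, sort_keys=True) + "\n"

    @classmethod
    def from_json(cls, text: str, out_dir: str = "") -> "DatasetManifest":
        d = json.loads(text)
        return cls(out_dir=out_dir, **d)

    @classmethod
    def load(cls, path: str | Path) -> "DatasetManifest":
        path = Path(path)
        return cls.from_json(path.read_text(), out_dir=str(path.parent))


def _split(ids: list[str], fraction: float, rng: np.random.Generator):
    """Seeded shuffle then round-half-up train-size split."""
    order = list(rng.permutation(len(ids)))
    shuffled = [ids[i] for i in order]
    n_train = int(np.floor(fraction * len(ids) + 0.5))
    return shuffled[:n_train], shuffled[n_train:]


def build_dataset(
    images: list[ImageRGB],
    grid: list[float] | None = None,
    retinex: RetinexParams = RetinexParams(),
    metric: MetricConfig = MetricConfig(),
    split_fraction: float = 0.8,
    seed: int = 0,
    out_dir: str | Path = "dataset",
) -> DatasetManifest:
    """Sweep every image, write both domains to disk, split, and record.

    Writes PNGs (lossless regardless of the input codec) under
    ``trainA/ valA/ trainB/ valB`` and a ``manifest.json`` that reproduces
    byte-identically for the same inputs and seed.
    """
    if len(images) == 0:
        raise ValueError("images must be non-empty")
    if not 0.0 < split_fraction < 1.0:
        raise ValueError(f"split_fraction must be in (0, 1), got {split_fraction}")
    ids = [img.source_id for img in images]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate source_id in input images")
    grid = default_grid() if grid is None else list(grid)
    out_dir = Path(out_dir)

    best: dict[str, tuple[ImageRGB, SweepResult]] = {}
    for img in images:
        res = sweep(img, grid, retinex, metric)
        params = RetinexParams(
            dyn=res.best_dyn,
            msr_prefilter=retinex.msr_prefilter,
            msr_scales=retinex.msr_scales,
        )
        best[img.source_id] = (msrcr_enhance(img, params), res)

    rng_a, rng_b = (
        np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(2)
    )
    train_a, val_a = _split(ids, split_fraction, rng_a)
    train_b, val_b = _split(ids, split_fraction, rng_b)
    if min(len(val_a), len(val_b)) == 0:
        logger.warning(
            "validation split is empty (n=%d, split=%.2f)", len(ids), split_fraction
        )

    by_id = {img.source_id: img for img in images}
    for name, subset in (("trainA", train_a), ("valA", val_a)):
        for sid in subset:
            write_image(by_id[sid], out_dir / name / f"{sid}.png")
    for name, subset in (("trainB", train_b), ("valB", val_b)):
        for sid in subset:
            write_image(best[sid][0], out_dir / name / f"{sid}.png")

    manifest = DatasetManifest(
        domain_a=ids,
        domain_b=[
            {"id": sid, "best_dyn": best[sid][1].best_dyn} for sid in ids
        ],
        train_a=train_a,
        val_a=val_a,
        train_b=train_b,
        val_b=val_b,
        split_fraction=split_fraction,
        seed=seed,
        grid=[float(g) for g in grid],
        metric_config=metric.to_dict(),
        out_dir=str(out_dir),
    )
    try:
        (out_dir / "manifest.json").write_text(manifest.to_json())
    except OSError as exc:
        raise IOError(f"cannot write manifest under {out_dir}: {exc}") from exc
    return manifest


@dataclass
class DynReport:
    """Per-Dyn summary: mean and population variance of UIQM across images.

    Rows: the original (unenhanced) images, one row per fixed grid value,
    and a "best value chosen" row built from each image's sweep maximum.
    """

    rows: list[tuple[str, float, float]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["label", "mean", "variance"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")


def dyn_report(
    images: list[ImageRGB],
    grid: list[float] | None = None,
    retinex: RetinexParams = RetinexParams(),
    metric: MetricConfig = MetricConfig(),
) -> DynReport:
    """Tabulate UIQM mean/variance per Dyn plus original and best rows."""
    if len(images) == 0:
        raise ValueError("images must be non-empty")
    grid = default_grid() if grid is None else list(grid)
    results = [sweep(img, grid, retinex, metric) for img in images]
    originals = np.array([uiqm(img, metric).total for img in images])
    per_dyn = np.array([res.scores for res in results])  # (n_images, n_grid)
    bests = np.array([res.best_score for res in results])

    rows: list[tuple[str, float, float]] = [
        ("original", float(originals.mean()), float(originals.var()))
    ]
    for j, dyn in enumerate(grid):
        col = per_dyn[:, j]
        rows.append((f"dyn-{dyn:g}", float(col.mean()), float(col.var())))
    rows.append(("best value chosen", float(bests.mean()), float(bests.var())))
    return DynReport(rows=rows)
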