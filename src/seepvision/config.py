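"""Pipeline configuration: loading, validation, and the end-to-end driver.

A :class:`PipelineConfig` describes the whole workflow — simulate (or load)
inputs, sweep-and-build the unpaired dataset, train the CycleGAN, run
inference, and write the per-Dyn report.  Unknown keys are rejected;
validation errors are aggregated and reported together (pydantic).  Every
run directory receives the fully resolved configuration so the run can be
reproduced from it alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import cyclegan as cg
from .dataset import build_dataset, default_grid, dyn_report
from .imaging import ImageRGB, RetinexParams, read_image, write_image
from .synthetic import make_fixture_set
from .uiqm import MetricConfig

__all__ = ["PipelineConfig", "load_config", "run_pipeline", "parse_grid"]

logger = logging.getLogger(__name__)


def parse_grid(spec: str) -> list[float]:
    """Parse ``start:stop:step`` into an inclusive ascending grid."""
    try:
        start, stop, step = (float(x) for x in spec.split(":"))
    except ValueError as exc:
        raise ValueError(f"grid spec must be start:stop:step, got {spec!r}") from exc
    if step <= 0 or stop < start:
        raise ValueError(f"invalid grid spec {spec!r}")
    n = int(round((stop - start) / step)) + 1
    decimals = max(len(p.partition(".")[2]) for p in spec.split(":"))
    return [round(start + k * step, max(decimals, 1)) for k in range(n)]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class RetinexSection(_Section):
    dyn: float = Field(default=2.0, gt=0)
    msr_prefilter: bool = False
    msr_scales: list[float] = Field(default=[16.0, 80.0, 240.0])

    def to_params(self, dyn: float | None = None) -> RetinexParams:
        return RetinexParams(
            dyn=self.dyn if dyn is None else dyn,
            msr_prefilter=self.msr_prefilter,
            msr_scales=tuple(self.msr_scales),
        )


class MetricSection(_Section):
    c1: float = 0.0282
    c2: float = 0.2953
    c3: float = 3.5753
    alpha_trim: float = Field(default=0.1, ge=0, lt=0.5)
    block: int = Field(default=8, ge=2)
    plip_gamma: float = Field(default=1026.0, gt=0)
    eps: float = Field(default=1e-7, gt=0)

    def to_config(self) -> MetricConfig:
        return MetricConfig(**self.model_dump())


class GanSection(_Section):
    """Training profile; defaults are the CPU toy scale.

    The full-scale published protocol (512 px, 6 blocks, 64 channels,
    350 epochs, batch 1) is available as ``GANConfig()`` in the library
    and is GPU-scale.
    """

    image_size: int = Field(default=64, ge=8)
    n_res_blocks: int = Field(default=2, ge=1)
    base_channels: int = Field(default=16, ge=1)
    lambda_cyc: float = Field(default=10.0, ge=0)
    lr: float = Field(default=2e-4, gt=0)
    epochs: int = Field(default=30, ge=1)
    batch_size: int = Field(default=2, ge=1)
    checkpoint_every: int = Field(default=10, ge=1)
    identity_weight: float = Field(default=0.0, ge=0)

    def to_config(self, seed: int) -> cg.GANConfig:
        return cg.GANConfig(seed=seed, **self.model_dump())


class SimulateSection(_Section):
    n: int = Field(default=20, ge=1)
    conditions: int = Field(default=5, ge=1)
    size: int = Field(default=64, ge=32)


class PipelineConfig(_Section):
    in_dir: str | None = None
    out_dir: str = "runs/run"
    grid: str = "0.4:6.0:0.2"
    split_fraction: float = Field(default=0.8, gt=0, lt=1)
    seed: int = 0
    log_level: str = "INFO"
    retinex: RetinexSection = RetinexSection()
    metric: MetricSection = MetricSection()
    gan: GanSection = GanSection()
    simulate: SimulateSection = SimulateSection()

    def grid_values(self) -> list[float]:
        return parse_grid(self.grid)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=True)


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML/JSON config file; ``None`` or an empty file = defaults."""
    if path is None:
        return PipelineConfig()
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        return PipelineConfig()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        return PipelineConfig()
    cfg = PipelineConfig.model_validate(data)
    cfg.grid_values()  # fail early on a malformed grid spec
    return cfg


def _stage_seeds(seed: int, n: int = 4) -> list[int]:
    """Fan one global seed out into independent per-stage seeds (< 2^31)."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def run_pipeline(cfg: PipelineConfig, skip: set[str] = frozenset()) -> dict:
    """Run simulate -> build-dataset -> train -> infer -> report.

    Returns a dict of artifact paths.  Stages listed in ``skip`` reuse
    artifacts already present in the run directory.
    """
    run_dir = Path(cfg.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "resolved_config.yaml").write_text(cfg.to_yaml())
    seeds = _stage_seeds(cfg.seed)
    artifacts: dict[str, str] = {"config": str(run_dir / "resolved_config.yaml")}

    # stage 1: inputs (simulate or load)
    if cfg.in_dir is not None:
        in_dir = Path(cfg.in_dir)
        if not in_dir.is_dir():
            raise IOError(f"input directory {in_dir} does not exist")
        paths = sorted(
            p
            for p in in_dir.iterdir()
            if p.suffix.lower() in {".png", ".jpg", ".jpeg", ".tif", ".tiff"}
        )
        if not paths:
            raise IOError(f"no images found in {in_dir}")
        images = [read_image(p) for p in paths]
    else:
        fix_dir = run_dir / "fixtures"
        if "simulate" not in skip or not fix_dir.exists():
            listing = make_fixture_set(
                cfg.simulate.n,
                seeds[0],
                out_dir=fix_dir,
                conditions=cfg.simulate.conditions,
                size=(cfg.simulate.size, cfg.simulate.size),
            )
            images = [degraded for _, degraded in listing["pairs"]]
        else:
            images = [read_image(p) for p in sorted((fix_dir / "degraded").glob("*.png"))]
        artifacts["fixtures"] = str(fix_dir)

    grid = cfg.grid_values()
    retinex = cfg.retinex.to_params()
    metric = cfg.metric.to_config()

    # stage 2: metric-guided dataset
    ds_dir = run_dir / "dataset"
    logger.info("building dataset over %d images, %d grid values", len(images), len(grid))
    manifest = build_dataset(
        images,
        grid=grid,
        retinex=retinex,
        metric=metric,
        split_fraction=cfg.split_fraction,
        seed=seeds[1],
        out_dir=ds_dir,
    )
    artifacts["manifest"] = str(ds_dir / "manifest.json")

    # stage 3: CycleGAN training
    train_dir = run_dir / "train"
    if "train" not in skip:
        gan_cfg = cfg.gan.to_config(seed=seeds[2])
        logger.info("training CycleGAN for %d epochs", gan_cfg.epochs)
        cg.train(gan_cfg, manifest, train_dir)
    artifacts["loss_log"] = str(train_dir / "loss_log.csv")
    artifacts["checkpoint"] = str(train_dir / "ckpt_last.npz")

    # stage 4: inference on the validation split of the degraded domain
    enh_dir = run_dir / "enhanced"
    val_ids = manifest.val_a if manifest.val_a else manifest.train_a[:2]
    sub = "valA" if manifest.val_a else "trainA"
    gan_cfg_loaded, G, _, _ = cg.load_checkpoint(train_dir / "ckpt_last.npz")
    for sid in val_ids:
        img = read_image(Path(manifest.out_dir) / sub / f"{sid}.png")
        out = cg.tensor_to_image(
            G(cg.Tensor(cg.image_to_tensor(img, gan_cfg_loaded.image_size)[None])).data[0],
            out_size=(img.height, img.width),
            source_id=sid,
        )
        write_image(out, enh_dir / f"{sid}.png")
    artifacts["enhanced"] = str(enh_dir)

    # stage 5: per-Dyn report
    report = dyn_report(images, grid=grid, retinex=retinex, metric=metric)
    report.to_csv(run_dir / "report.csv")
    artifacts["report"] = str(run_dir / "report.csv")
    return artifacts
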