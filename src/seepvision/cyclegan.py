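"""Compact CycleGAN for unpaired underwater image translation.

Two generators map between the degraded domain (A, distribution m) and the
clear domain (B, distribution n): G enhances (A -> B) and F degrades
(B -> A).  Two patch-level discriminators DM and DN score realness of the
translated images.  Training minimises least-squares adversarial terms
plus a cycle-consistency penalty

    L_cyc(G, F) = E_m ||F(G(m)) - m||_1 + E_n ||G(F(n)) - n||_1
    L(G, F, DM, DN) = L_GAN(G, DN) + L_GAN(F, DM) + lambda * L_cyc

solved as the usual minimax over generators and discriminators.  The
generators are encoder / residual-bottleneck / decoder ResNets (six
residual blocks at full scale); the decoder uses nearest-upsample +
convolution rather than transposed convolution to avoid checkerboard
artifacts.  Full-scale defaults (512 x 512, 350 epochs) reproduce the
published training configuration; the toy profile trains in minutes on one
CPU and is what the test suite exercises.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .dataset import DatasetManifest
from .imaging import ImageRGB, read_image
from .nn import Adam, Conv2d, Module, Sequential, Tensor

__all__ = [
    "GANConfig",
    "TrainState",
    "NumericalError",
    "Generator",
    "PatchDiscriminator",
    "build_models",
    "cycle_loss",
    "adversarial_losses",
    "full_objective",
    "train",
    "save_checkpoint",
    "load_checkpoint",
    "enhance",
    "degrade",
    "image_to_tensor",
    "tensor_to_image",
]


class NumericalError(RuntimeError):
    """A model or loss produced non-finite values."""


@dataclass(frozen=True)
class GANConfig:
    """Architecture and training hyperparameters.

    image_size must be divisible by 4 (two stride-2 encoder stages);
    lambda_cyc weighs cycle consistency against the adversarial terms
    (10 is the canonical choice).  The default configuration is the
    full-scale 512 x 512 / 350-epoch protocol; use :meth:`toy` for a
    CPU-scale profile.
    """

    image_size: int = 512
    n_res_blocks: int = 6
    base_channels: int = 64
    lambda_cyc: float = 10.0
    lr: float = 2e-4
    epochs: int = 350
    batch_size: int = 1
    seed: int = 0
    device: str = "cpu"
    checkpoint_every: int = 10
    identity_weight: float = 0.0

    def __post_init__(self) -> None:
        if self.image_size % 4 != 0 or self.image_size < 8:
            raise ValueError("image_size must be a multiple of 4 and >= 8")
        if self.n_res_blocks < 1:
            raise ValueError("n_res_blocks must be >= 1")
        if self.lambda_cyc < 0 or self.lr <= 0:
            raise ValueError("lambda_cyc must be >= 0 and lr > 0")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")

    @classmethod
    def toy(cls, **overrides) -> "GANConfig":
        """CPU-scale profile: 64 px, 2 residual blocks, 16 channels."""
        base = dict(
            image_size=64,
            n_res_blocks=2,
            base_channels=16,
            batch_size=2,
            epochs=30,
            checkpoint_every=10,
        )
        base.update(overrides)
        return cls(**base)


# --------------------------------------------------------------------------
# models


class ResBlock(Module):
    def __init__(self, channels: int, rng: np.random.Generator):
        self.conv1 = Conv2d(channels, channels, 3, pad=1, rng=rng)
        self.conv2 = Conv2d(channels, channels, 3, pad=1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        y = self.conv1(x).instance_norm().relu()
        y = self.conv2(y).instance_norm()
        return x + y


class Generator(Module):
    """Encoder / residual bottleneck / decoder with tanh output in [-1, 1]."""

    def __init__(self, cfg: GANConfig, rng: np.random.Generator):
        bc = cfg.base_channels
        self.enc1 = Conv2d(3, bc, 7, pad=3, rng=rng)
        self.enc2 = Conv2d(bc, 2 * bc, 3, stride=2, pad=1, rng=rng)
        self.enc3 = Conv2d(2 * bc, 4 * bc, 3, stride=2, pad=1, rng=rng)
        self.blocks = [ResBlock(4 * bc, rng) for _ in range(cfg.n_res_blocks)]
        self.dec1 = Conv2d(4 * bc, 2 * bc, 3, pad=1, rng=rng)
        self.dec2 = Conv2d(2 * bc, bc, 3, pad=1, rng=rng)
        self.out = Conv2d(bc, 3, 7, pad=3, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        y = self.enc1(x).instance_norm().relu()
        y = self.enc2(y).instance_norm().relu()
        y = self.enc3(y).instance_norm().relu()
        for block in self.blocks:
            y = block(y)
        y = self.dec1(y.upsample2x()).instance_norm().relu()
        y = self.dec2(y.upsample2x()).instance_norm().relu()
        return self.out(y).tanh()


class PatchDiscriminator(Module):
    """PatchGAN: a score map over overlapping receptive fields."""

    def __init__(self, cfg: GANConfig, rng: np.random.Generator):
        bc = cfg.base_channels
        self.c1 = Conv2d(3, bc, 4, stride=2, pad=1, rng=rng)
        self.c2 = Conv2d(bc, 2 * bc, 4, stride=2, pad=1, rng=rng)
        self.c3 = Conv2d(2 * bc, 4 * bc, 4, stride=2, pad=1, rng=rng)
        self.c4 = Conv2d(4 * bc, 1, 4, pad=1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        y = self.c1(x).leaky_relu(0.2)
        y = self.c2(y).instance_norm().leaky_relu(0.2)
        y = self.c3(y).instance_norm().leaky_relu(0.2)
        return self.c4(y)


def build_models(
    cfg: GANConfig,
) -> tuple[Generator, Generator, PatchDiscriminator, PatchDiscriminator]:
    """Seeded construction of (G, F, DM, DN).

    G: A -> B (enhance), F: B -> A (degrade); DM judges domain A, DN
    judges domain B.  Same config and seed give identical initial weights.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(4)]
    return (
        Generator(cfg, rngs[0]),
        Generator(cfg, rngs[1]),
        PatchDiscriminator(cfg, rngs[2]),
        PatchDiscriminator(cfg, rngs[3]),
    )


def res_block_param_count(base_channels: int) -> int:
    """Closed-form parameter count of one residual block."""
    c = 4 * base_channels
    per_conv = c * c * 3 * 3 + c
    return 2 * per_conv


# --------------------------------------------------------------------------
# tensor <-> image plumbing


def image_to_tensor(img: ImageRGB, size: int) -> np.ndarray:
    """Bilinear-resize to (size, size) and map [0, 255] -> [-1, 1], CHW."""
    pil = Image.fromarray(img.to_uint8(), mode="RGB")
    resized = np.asarray(
        pil.resize((size, size), resample=Image.BILINEAR), dtype=np.float32
    )
    return (resized / 127.5 - 1.0).transpose(2, 0, 1)


def tensor_to_image(
    chw: np.ndarray, out_size: tuple[int, int] | None = None, source_id: str = ""
) -> ImageRGB:
    """Map [-1, 1] CHW back to an 8-bit image, optionally resized to (H, W)."""
    arr = np.clip((chw.transpose(1, 2, 0) + 1.0) * 127.5, 0.0, 255.0)
    img = Image.fromarray(arr.astype(np.uint8), mode="RGB")
    if out_size is not None:
        img = img.resize((out_size[1], out_size[0]), resample=Image.BILINEAR)
    return ImageRGB(np.asarray(img, dtype=np.float64), source_id=source_id)


def _check_batch(batch: Tensor) -> None:
    if batch.data.ndim != 4 or batch.data.shape[1] != 3:
        raise ValueError(f"expected NCHW 3-channel batch, got {batch.data.shape}")
    if batch.data.shape[0] == 0:
        raise ValueError("batch must be non-empty")


# --------------------------------------------------------------------------
# losses


def _l1(a: Tensor, b: Tensor) -> Tensor:
    return (a - b).abs().mean()


def _mse_to(x: Tensor, target: float) -> Tensor:
    return (x - target).square().mean()


def cycle_loss(G: Module, F: Module, batch_m: Tensor, batch_n: Tensor) -> Tensor:
    """Two-term L1 cycle-consistency loss.

    ||F(G(m)) - m||_1 + ||G(F(n)) - n||_1, each averaged over batch and
    pixels; zero exactly when both reconstructions are exact.
    """
    _check_batch(batch_m)
    _check_batch(batch_n)
    if batch_m.data.shape[1:] != batch_n.data.shape[1:]:
        raise ValueError(
            f"domain shape mismatch {batch_m.data.shape} vs {batch_n.data.shape}"
        )
    return _l1(F(G(batch_m)), batch_m) + _l1(G(F(batch_n)), batch_n)


def adversarial_losses(
    G: Module,
    F: Module,
    DM: Module,
    DN: Module,
    batch_m: Tensor,
    batch_n: Tensor,
) -> tuple[Tensor, Tensor, Tensor, Tensor]:
    """Least-squares GAN terms; returns (g_adv, d_total, fake_n, fake_m).

    Generator side pushes D(fake) toward 1; discriminator side pushes
    D(real) toward 1 and D(fake) toward 0 with the usual 1/2 weighting.
    Fakes are detached for the discriminator terms.
    """
    fake_n = G(batch_m)
    fake_m = F(batch_n)
    g_adv = _mse_to(DN(fake_n), 1.0) + _mse_to(DM(fake_m), 1.0)
    d_total = 0.5 * (
        _mse_to(DN(batch_n), 1.0) + _mse_to(DN(fake_n.detach()), 0.0)
    ) + 0.5 * (_mse_to(DM(batch_m), 1.0) + _mse_to(DM(fake_m.detach()), 0.0))
    return g_adv, d_total, fake_n, fake_m


def full_objective(
    G: Module,
    F: Module,
    DM: Module,
    DN: Module,
    batch_m: Tensor,
    batch_n: Tensor,
    lambda_cyc: float,
) -> tuple[float, float]:
    """Evaluate the full objective: (g_total, d_total) as floats.

    g_total = adversarial generator terms + lambda_cyc * cycle loss.
    Raises :class:`NumericalError` on non-finite values.
    """
    g_adv, d_total, _, _ = adversarial_losses(G, F, DM, DN, batch_m, batch_n)
    cyc = cycle_loss(G, F, batch_m, batch_n)
    g_total = g_adv.item() + lambda_cyc * cyc.item()
    d_val = d_total.item()
    if not (np.isfinite(g_total) and np.isfinite(d_val)):
        raise NumericalError(
            f"non-finite objective: g_total={g_total}, d_total={d_val}"
        )
    return g_total, d_val


# --------------------------------------------------------------------------
# training


@dataclass
class TrainState:
    epoch: int
    g_loss: float
    d_loss: float
    cycle: float
    history: list[dict] = field(default_factory=list)


def _load_domain(manifest: DatasetManifest, ids: list[str], sub: str, size: int):
    root = Path(manifest.out_dir)
    arrays = []
    for sid in ids:
        img = read_image(root / sub / f"{sid}.png")
        arrays.append(image_to_tensor(img, size))
    return np.stack(arrays) if arrays else np.zeros((0, 3, size, size), np.float32)


def train(
    cfg: GANConfig,
    manifest: DatasetManifest,
    out_dir: str | Path,
    stop_after: int | None = None,
) -> TrainState:
    """Alternating least-squares GAN training on unpaired domains.

    Each epoch draws independent seeded shuffles of the two train splits,
    steps the generators (adversarial + lambda * cycle) and then the
    discriminators on detached fakes.  Writes ``loss_log.csv`` (epoch,
    g_loss, d_loss, cycle) and periodic + final checkpoints under
    ``out_dir``.  The epoch shuffles are derived from (seed, epoch), so a
    resumed run reproduces an uninterrupted one exactly; ``stop_after``
    ends the run early (simulating interruption) after that epoch's
    checkpoint.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if len(manifest.train_a) == 0 or len(manifest.train_b) == 0:
        raise ValueError("both training domains must be non-empty")
    data_a = _load_domain(manifest, manifest.train_a, "trainA", cfg.image_size)
    data_b = _load_domain(manifest, manifest.train_b, "trainB", cfg.image_size)

    G, F, DM, DN = build_models(cfg)
    opt_g = Adam(G.parameters() + F.parameters(), lr=cfg.lr)
    opt_d = Adam(DM.parameters() + DN.parameters(), lr=cfg.lr)
    start_epoch = 0

    resume = out_dir / "ckpt_last.npz"
    if resume.exists():
        start_epoch = _restore(resume, cfg, G, F, DM, DN, opt_g, opt_d)

    log_path = out_dir / "loss_log.csv"
    history: list[dict] = []
    if start_epoch > 0 and log_path.exists():
        with open(log_path) as fh:
            history = [
                {k: float(v) for k, v in row.items()}
                for row in csv.DictReader(fh)
                if int(float(row["epoch"])) <= start_epoch
            ]

    state = TrainState(epoch=start_epoch, g_loss=np.nan, d_loss=np.nan, cycle=np.nan)
    for epoch in range(start_epoch + 1, cfg.epochs + 1):
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, epoch)))
        idx_a = rng.permutation(len(data_a))
        idx_b = rng.permutation(len(data_b))
        n_steps = min(len(data_a), len(data_b)) // cfg.batch_size
        if n_steps == 0:
            raise ValueError("not enough images for a single batch")
        # linear LR decay over the second half of training
        half = cfg.epochs / 2.0
        lr_scale = 1.0 if epoch <= half else max(
            0.0, (cfg.epochs - epoch) / max(cfg.epochs - half, 1.0)
        )
        g_sum = d_sum = c_sum = 0.0
        for step in range(n_steps):
            sl = slice(step * cfg.batch_size, (step + 1) * cfg.batch_size)
            bm = Tensor(data_a[idx_a[sl]])
            bn = Tensor(data_b[idx_b[sl]])

            # generator step (discriminators frozen by not stepping them)
            fake_n = G(bm)
            fake_m = F(bn)
            g_adv = _mse_to(DN(fake_n), 1.0) + _mse_to(DM(fake_m), 1.0)
            cyc = _l1(F(fake_n), bm) + _l1(G(fake_m), bn)
            g_total = g_adv + cfg.lambda_cyc * cyc
            if cfg.identity_weight > 0:
                g_total = g_total + cfg.identity_weight * (
                    _l1(G(bn), bn) + _l1(F(bm), bm)
                )
            if not np.isfinite(g_total.item()):
                raise NumericalError(
                    f"non-finite generator loss at epoch {epoch} step {step}"
                )
            fake_n_data, fake_m_data = fake_n.data.copy(), fake_m.data.copy()
            G.zero_grad(); F.zero_grad(); DM.zero_grad(); DN.zero_grad()
            g_total.backward()
            opt_g.step(lr_scale)

            # discriminator step on detached fakes
            d_total = 0.5 * (
                _mse_to(DN(bn.detach()), 1.0) + _mse_to(DN(Tensor(fake_n_data)), 0.0)
            ) + 0.5 * (
                _mse_to(DM(bm.detach()), 1.0) + _mse_to(DM(Tensor(fake_m_data)), 0.0)
            )
            if not np.isfinite(d_total.item()):
                raise NumericalError(
                    f"non-finite discriminator loss at epoch {epoch} step {step}"
                )
            DM.zero_grad(); DN.zero_grad()
            d_total.backward()
            opt_d.step(lr_scale)

            g_sum += g_total.item()
            d_sum += d_total.item()
            c_sum += cyc.item()

        state = TrainState(
            epoch=epoch,
            g_loss=g_sum / n_steps,
            d_loss=d_sum / n_steps,
            cycle=c_sum / n_steps,
        )
        history.append(
            {
                "epoch": float(epoch),
                "g_loss": state.g_loss,
                "d_loss": state.d_loss,
                "cycle": state.cycle,
            }
        )
        _write_log(log_path, history)
        if (
            epoch % cfg.checkpoint_every == 0
            or epoch == cfg.epochs
            or epoch == stop_after
        ):
            save_checkpoint(
                out_dir / "ckpt_last.npz", cfg, G, F, DM, DN, opt_g, opt_d, epoch
            )
        if stop_after is not None and epoch >= stop_after:
            break
    state.history = history
    if not (out_dir / "ckpt_last.npz").exists():
        save_checkpoint(
            out_dir / "ckpt_last.npz", cfg, G, F, DM, DN, opt_g, opt_d, state.epoch
        )
    return state


def _write_log(path: Path, history: list[dict]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["epoch", "g_loss", "d_loss", "cycle"])
        writer.writeheader()
        for row in history:
            writer.writerow({k: f"{row[k]:.8g}" for k in writer.fieldnames})


# --------------------------------------------------------------------------
# checkpoints and inference

CKPT_VERSION = 1


def save_checkpoint(path, cfg, G, F, DM, DN, opt_g=None, opt_d=None, epoch=0) -> None:
    """Serialise config, all model parameters and optimiser state to npz."""
    arrays = {}
    meta = {"version": CKPT_VERSION, "epoch": int(epoch), "config": asdict(cfg)}
    for name, model in (("G", G), ("F", F), ("DM", DM), ("DN", DN)):
        for i, arr in enumerate(model.state_arrays()):
            arrays[f"{name}_{i:03d}"] = arr
    for name, opt in (("optg", opt_g), ("optd", opt_d)):
        if opt is not None:
            for i, arr in enumerate(opt.state_arrays()):
                arrays[f"{name}_{i:03d}"] = arr
    arrays["meta"] = np.frombuffer(
        json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def _read_meta(npz) -> dict:
    return json.loads(bytes(npz["meta"].tobytes()).decode())


def load_checkpoint(path) -> tuple[GANConfig, Generator, Generator, int]:
    """Rebuild (cfg, G, F, epoch) from a checkpoint for inference."""
    with np.load(path) as npz:
        meta = _read_meta(npz)
        if meta.get("version") != CKPT_VERSION:
            raise ValueError(
                f"incompatible checkpoint version {meta.get('version')} "
                f"(expected {CKPT_VERSION})"
            )
        cfg = GANConfig(**meta["config"])
        G, F, _, _ = build_models(cfg)
        _load_model(npz, "G", G)
        _load_model(npz, "F", F)
        return cfg, G, F, int(meta["epoch"])


def _load_model(npz, prefix: str, model: Module) -> None:
    keys = sorted(k for k in npz.files if k.startswith(prefix + "_"))
    model.load_state_arrays([npz[k] for k in keys])


def _restore(path, cfg, G, F, DM, DN, opt_g, opt_d) -> int:
    with np.load(path) as npz:
        meta = _read_meta(npz)
        if meta.get("version") != CKPT_VERSION:
            raise ValueError("incompatible checkpoint version")
        saved, current = dict(meta["config"]), asdict(cfg)
        # training may be extended on resume; everything else must match
        for key in ("epochs", "checkpoint_every"):
            saved.pop(key, None)
            current.pop(key, None)
        if saved != current:
            raise ValueError("checkpoint config does not match training config")
        for name, model in (("G", G), ("F", F), ("DM", DM), ("DN", DN)):
            _load_model(npz, name, model)
        for name, opt in (("optg", opt_g), ("optd", opt_d)):
            keys = sorted(k for k in npz.files if k.startswith(name + "_"))
            opt.load_state_arrays([npz[k] for k in keys])
        return int(meta["epoch"])


def _infer(img: ImageRGB, model: Module, size: int) -> ImageRGB:
    x = Tensor(image_to_tensor(img, size)[None])
    y = model(x).data[0]
    return tensor_to_image(y, out_size=(img.height, img.width), source_id=img.source_id)


def enhance(img: ImageRGB, ckpt_path) -> ImageRGB:
    """Run the enhancing generator G (degraded -> clear) from a checkpoint."""
    cfg, G, _, _ = load_checkpoint(ckpt_path)
    return _infer(img, G, cfg.image_size)


def degrade(img: ImageRGB, ckpt_path) -> ImageRGB:
    """Run the degrading generator F (clear -> degraded) from a checkpoint."""
    cfg, _, F, _ = load_checkpoint(ckpt_path)
    return _infer(img, F, cfg.image_size)
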