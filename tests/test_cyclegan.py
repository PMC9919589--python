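"""Unit tests for the CycleGAN models, losses, training and inference."""

import numpy as np
import pytest

from seepvision import cyclegan as cg
from seepvision.dataset import build_dataset
from seepvision.nn import Module, Tensor
from seepvision.synthetic import PRESETS, degrade_underwater, make_scene


class Identity(Module):
    def forward(self, x):
        return x


class Shift(Module):
    def __init__(self, delta):
        self.delta = delta

    def forward(self, x):
        return x + self.delta


class OracleDiscriminator(Module):
    """Outputs exactly 1 for the memorised real batch and 0 otherwise."""

    def __init__(self, real: np.ndarray):
        self.real = real.copy()

    def forward(self, x):
        val = 1.0 if np.array_equal(x.data, self.real) else 0.0
        return Tensor(np.full((x.data.shape[0], 1, 1, 1), val, dtype=np.float32))


@pytest.fixture(scope="module")
def toy_cfg():
    return cg.GANConfig.toy(epochs=2, seed=11)


@pytest.fixture(scope="module")
def batches():
    rng = np.random.default_rng(0)
    bm = Tensor(rng.uniform(-1, 1, size=(2, 3, 32, 32)).astype(np.float32))
    bn = Tensor(rng.uniform(-1, 1, size=(2, 3, 32, 32)).astype(np.float32))
    return bm, bn


class TestModels:
    def test_generator_shape_contract(self, toy_cfg, batches):
        G, F, DM, DN = cg.build_models(toy_cfg)
        bm, _ = batches
        out = G(bm)
        assert out.data.shape == bm.data.shape
        assert np.all(np.abs(out.data) <= 1.0)

    def test_discriminator_emits_score_map(self, toy_cfg, batches):
        _, _, DM, _ = cg.build_models(toy_cfg)
        out = DM(batches[0])
        assert out.data.ndim == 4 and out.data.shape[1] == 1
        assert out.data.shape[2] > 1 and out.data.shape[3] > 1

    def test_seeded_init_reproducible(self, toy_cfg):
        G1, F1, _, _ = cg.build_models(toy_cfg)
        G2, F2, _, _ = cg.build_models(toy_cfg)
        for a, b in zip(G1.state_arrays(), G2.state_arrays()):
            assert np.array_equal(a, b)
        # G and F are distinct initialisations
        assert not all(
            np.array_equal(a, b) for a, b in zip(G1.state_arrays(), F1.state_arrays())
        )

    def test_res_block_parameter_counting(self):
        cfg2 = cg.GANConfig.toy(n_res_blocks=2)
        cfg6 = cg.GANConfig.toy(n_res_blocks=6)
        g2, _, _, _ = cg.build_models(cfg2)
        g6, _, _, _ = cg.build_models(cfg6)
        diff = g6.n_parameters() - g2.n_parameters()
        assert diff == 4 * cg.res_block_param_count(cfg2.base_channels)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            cg.GANConfig(image_size=30)
        with pytest.raises(ValueError):
            cg.GANConfig(n_res_blocks=0)


class TestLosses:
    def test_cycle_loss_zero_for_identity(self, batches):
        bm, bn = batches
        assert cg.cycle_loss(Identity(), Identity(), bm, bn).item() == 0.0

    def test_cycle_loss_hand_l1(self, batches):
        bm, bn = batches
        # G shifts by +0.5, F is identity: both reconstructions are off by
        # exactly 0.5 everywhere, so the two L1 terms sum to 1.0
        val = cg.cycle_loss(Shift(0.5), Identity(), bm, bn).item()
        assert np.isclose(val, 1.0, atol=1e-6)
        # G = +0.5 and F = -0.5 are mutual inverses: exact reconstruction
        assert np.isclose(
            cg.cycle_loss(Shift(0.5), Shift(-0.5), bm, bn).item(), 0.0, atol=1e-6
        )

    def test_cycle_loss_symmetry(self, toy_cfg, batches):
        G, F, _, _ = cg.build_models(toy_cfg)
        bm, bn = batches
        a = cg.cycle_loss(G, F, bm, bn).item()
        b = cg.cycle_loss(F, G, bn, bm).item()
        assert np.isclose(a, b, rtol=1e-6)

    def test_full_objective_lambda_zero(self, toy_cfg, batches):
        G, F, DM, DN = cg.build_models(toy_cfg)
        bm, bn = batches
        g0, _ = cg.full_objective(G, F, DM, DN, bm, bn, 0.0)
        g_adv, _, _, _ = cg.adversarial_losses(G, F, DM, DN, bm, bn)
        assert np.isclose(g0, g_adv.item(), rtol=1e-6)

    @pytest.mark.parametrize("lam", [1.0, 10.0])
    def test_full_objective_linear_in_lambda(self, toy_cfg, batches, lam):
        G, F, DM, DN = cg.build_models(toy_cfg)
        bm, bn = batches
        g0, _ = cg.full_objective(G, F, DM, DN, bm, bn, 0.0)
        gl, _ = cg.full_objective(G, F, DM, DN, bm, bn, lam)
        cyc = cg.cycle_loss(G, F, bm, bn).item()
        assert np.isclose(gl - g0, lam * cyc, rtol=1e-4)

    def test_perfect_discriminator_zero_loss(self, batches):
        bm, bn = batches
        DM = OracleDiscriminator(bm.data)
        DN = OracleDiscriminator(bn.data)
        _, d_total, _, _ = cg.adversarial_losses(
            Shift(0.1), Shift(-0.1), DM, DN, bm, bn
        )
        assert d_total.item() == 0.0

    def test_shape_mismatch_rejected(self, batches):
        bm, _ = batches
        bad = Tensor(np.zeros((2, 3, 16, 16), dtype=np.float32))
        with pytest.raises(ValueError):
            cg.cycle_loss(Identity(), Identity(), bm, bad)


@pytest.fixture(scope="module")
def tiny_manifest(tmp_path_factory):
    root = tmp_path_factory.mktemp("gan_ds")
    scenes = [make_scene(400 + i, (64, 64)) for i in range(5)]
    presets = list(PRESETS.values())
    degraded = [
        degrade_underwater(s, presets[i % len(presets)]) for i, s in enumerate(scenes)
    ]
    return build_dataset(degraded, grid=[1.0, 2.0], seed=5, out_dir=root)


class TestTraining:
    def test_short_training_runs_and_logs(self, tiny_manifest, tmp_path):
        cfg = cg.GANConfig.toy(epochs=2, seed=21, checkpoint_every=1)
        state = cg.train(cfg, tiny_manifest, tmp_path / "run")
        assert state.epoch == 2
        assert len(state.history) == 2
        assert (tmp_path / "run/loss_log.csv").exists()
        assert (tmp_path / "run/ckpt_last.npz").exists()
        assert np.isfinite([state.g_loss, state.d_loss, state.cycle]).all()

    def test_resume_reproduces_uninterrupted_run(self, tiny_manifest, tmp_path):
        cfg3 = cg.GANConfig.toy(epochs=3, seed=33, checkpoint_every=1)
        full = cg.train(cfg3, tiny_manifest, tmp_path / "full")
        cg.train(cfg3, tiny_manifest, tmp_path / "resumed", stop_after=2)
        resumed = cg.train(cfg3, tiny_manifest, tmp_path / "resumed")
        a = full.history[-1]
        b = resumed.history[-1]
        assert a["epoch"] == b["epoch"] == 3
        for key in ("g_loss", "d_loss", "cycle"):
            assert np.isclose(a[key], b[key], atol=1e-5), key

    def test_empty_domain_rejected(self, tiny_manifest, tmp_path):
        import copy

        man = copy.deepcopy(tiny_manifest)
        man.train_b = []
        cfg = cg.GANConfig.toy(epochs=1)
        with pytest.raises(ValueError):
            cg.train(cfg, man, tmp_path / "run")

    def test_nonfinite_weight_aborts(self, tiny_manifest, tmp_path, monkeypatch):
        cfg = cg.GANConfig.toy(epochs=1, seed=2)

        real_build = cg.build_models

        def poisoned(c):
            G, F, DM, DN = real_build(c)
            G.enc1.weight.data[0, 0, 0, 0] = np.nan
            return G, F, DM, DN

        monkeypatch.setattr(cg, "build_models", poisoned)
        with pytest.raises(cg.NumericalError):
            cg.train(cfg, tiny_manifest, tmp_path / "run")


@pytest.fixture(scope="module")
def ckpt(tiny_manifest, tmp_path_factory):
    out = tmp_path_factory.mktemp("infer_run")
    cfg = cg.GANConfig.toy(epochs=1, seed=9)
    cg.train(cfg, tiny_manifest, out)
    return out / "ckpt_last.npz"


class TestInference:
    def test_output_dims_match_input(self, ckpt):
        img = make_scene(900, (48, 80))
        out = cg.enhance(img, ckpt)
        assert (out.height, out.width) == (48, 80)
        assert out.pixels.min() >= 0 and out.pixels.max() <= 255

    def test_inference_deterministic(self, ckpt):
        img = make_scene(901, (64, 64))
        a = cg.enhance(img, ckpt)
        b = cg.enhance(img, ckpt)
        assert np.array_equal(a.pixels, b.pixels)
        d1 = cg.degrade(img, ckpt)
        assert not np.array_equal(a.pixels, d1.pixels)

    def test_incompatible_checkpoint_rejected(self, ckpt, tmp_path):
        import json

        with np.load(ckpt) as npz:
            arrays = {k: npz[k] for k in npz.files}
        meta = json.loads(bytes(arrays["meta"].tobytes()).decode())
        meta["version"] = 999
        arrays["meta"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8
        )
        bad = tmp_path / "bad.npz"
        np.savez(bad, **arrays)
        with pytest.raises(ValueError, match="version"):
            cg.load_checkpoint(bad)
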