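"""Model construction, losses, training bookkeeping and prediction."""

import numpy as np
import pytest

from trichoseg.annot import SparseMask
from trichoseg.nn import seed_init
from trichoseg.nn import tensor as T
from trichoseg.nn.tensor import Tensor
from trichoseg.segnet import (
    DECODERS,
    ENCODERS,
    ModelConfig,
    build_model,
    compute_loss,
    load_checkpoint,
    predict_mask,
    predict_proba,
    save_checkpoint,
    train,
)
from trichoseg.segnet.decoders import build_decoder
from trichoseg.segnet.encoders import build_encoder
from trichoseg.segnet.losses import loss_fn
from trichoseg.synthleaf import SyntheticSpec, generate_image

PAPER_ENCODERS = ["vgg19bn", "resnet18", "resnet50", "se_resnet50", "regnetx064", "effnet_b5"]
ALL_DECODERS = ["unet", "unetpp", "deeplabv3", "linknet", "manet"]


class TestBuildModel:
    def test_tiny_unet_contract(self):
        model = build_model(ModelConfig(encoder="tiny", decoder="unet", seed=0))
        x = np.random.default_rng(0).normal(size=(1, 64, 64, 3)).astype(np.float32)
        out = model(Tensor(x))
        assert out.shape == (1, 64, 64, 1)
        assert 0.0 <= out.data.min() and out.data.max() <= 1.0

    def test_registry_covers_published_grid(self):
        assert set(PAPER_ENCODERS) <= set(ENCODERS)
        assert set(ALL_DECODERS) == set(DECODERS)

    def test_all_thirty_pairs_constructible(self):
        # the full 6 x 5 grid: construction only (no forward pass)
        for ename in PAPER_ENCODERS:
            for dname in ALL_DECODERS:
                with seed_init(0):
                    enc = build_encoder(ename)
                    dec = build_decoder(dname, enc.out_channels)
                assert len(enc.out_channels) == 5
                assert dec.parameters()

    def test_unknown_decoder_lists_names(self):
        with pytest.raises(KeyError, match="segformer"):
            ModelConfig(decoder="segformer")

    def test_unknown_encoder_lists_names(self):
        with pytest.raises(KeyError, match="registered"):
            ModelConfig(encoder="vit")

    def test_pretrained_rejected_offline(self):
        with pytest.raises(NotImplementedError, match="offline"):
            build_model(ModelConfig(encoder="vgg19bn", pretrained=True))

    def test_same_seed_same_weights(self):
        a = build_model(ModelConfig(seed=5))
        b = build_model(ModelConfig(seed=5))
        for (na, pa), (nb, pb) in zip(a.named_parameters(), b.named_parameters()):
            assert na == nb
            np.testing.assert_array_equal(pa.data, pb.data)


@pytest.mark.slow
class TestGridForwardBackward:
    """Every registered (encoder, decoder) pair runs one training step on a
    64x64 batch without shape errors (~20 s total on one core)."""

    @pytest.mark.parametrize("ename", PAPER_ENCODERS)
    def test_encoder_with_all_decoders(self, ename):
        x = np.random.default_rng(0).normal(size=(1, 64, 64, 3)).astype(np.float32)
        y = (np.random.default_rng(1).random((1, 64, 64, 1)) < 0.02).astype(np.float32)
        for dname in ALL_DECODERS:
            with seed_init(0):
                enc = build_encoder(ename)
                dec = build_decoder(dname, enc.out_channels)
            out = T.sigmoid(dec(enc(Tensor(x))))
            assert out.shape == (1, 64, 64, 1), (ename, dname)
            loss = loss_fn("dice")(out, y)
            loss.backward()
            assert all(
                p.grad is not None and np.isfinite(p.grad).all()
                for p in enc.parameters()
            )


class TestComputeLoss:
    def test_perfect_binary_dice_jaccard_zero(self):
        g = np.random.default_rng(1).integers(0, 2, (16, 16)).astype(np.float32)
        assert compute_loss(g, g, "dice") == pytest.approx(0.0, abs=1e-6)
        assert compute_loss(g, g, "jaccard") == pytest.approx(0.0, abs=1e-6)

    def test_bce_at_half_is_ln2(self):
        p = np.full((16, 16), 0.5, dtype=np.float32)
        g = np.zeros((16, 16), dtype=np.float32)
        assert compute_loss(p, g, "bce") == pytest.approx(np.log(2), abs=1e-7)

    def test_focal_zero_on_empty(self):
        z = np.zeros((8, 8), dtype=np.float32)
        assert compute_loss(z, z, "focal") == pytest.approx(0.0, abs=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            compute_loss(np.full((4, 4), 1.5, np.float32), np.zeros((4, 4)), "bce")

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            compute_loss(np.zeros((4, 4), np.float32), np.zeros((5, 5)), "dice")

    def test_unknown_loss(self):
        with pytest.raises(KeyError, match="tversky"):
            loss_fn("tversky")

    def test_dice_jaccard_relation(self):
        # J = D / (2 - D) for the overlap coefficients, within epsilon effects
        rng = np.random.default_rng(7)
        for _ in range(20):
            p = (rng.random((48, 48)) < 0.3).astype(np.float32)
            g = (rng.random((48, 48)) < 0.3).astype(np.float32)
            dice_coeff = 1.0 - compute_loss(p, g, "dice")
            jac_coeff = 1.0 - compute_loss(p, g, "jaccard")
            assert jac_coeff == pytest.approx(dice_coeff / (2 - dice_coeff), abs=5e-3)


def tiny_records(n, seed, hair_count=12.0, size=64):
    spec = SyntheticSpec(image_size=(size, size), hair_count=(hair_count, 0),
                         hair_length_px=(18, 4))
    return [generate_image(spec, seed + i, image_id=f"r{i}.png") for i in range(n)]


class TestTrain:
    def test_single_epoch_bookkeeping(self):
        cfg = ModelConfig(recipe="RS64", epochs=1, batch_size=2, seed=0)
        report = train(cfg, tiny_records(4, 0), tiny_records(2, 100))
        assert report.epochs_run == 1
        assert set(report.history[0]) == {"epoch", "loss", "val_iou", "val_f1"}
        assert report.best_epoch == 0

    def test_empty_train_set_rejected(self):
        cfg = ModelConfig(recipe="RS64", epochs=1)
        with pytest.raises(ValueError, match="empty"):
            train(cfg, [], tiny_records(2, 0))

    def test_training_improves(self):
        cfg = ModelConfig(recipe="RS64+RF", epochs=6, batch_size=4, seed=1)
        report = train(cfg, tiny_records(16, 0), tiny_records(4, 500))
        assert report.history[-1]["val_iou"] >= report.history[0]["val_iou"] - 1e-9
        assert report.best_val_iou > 0.1

    def test_metrics_csv(self, tmp_path):
        cfg = ModelConfig(recipe="RS64", epochs=2, batch_size=2, seed=0)
        train(cfg, tiny_records(4, 0), tiny_records(2, 100),
              metrics_path=tmp_path / "m.csv")
        lines = (tmp_path / "m.csv").read_text().strip().splitlines()
        assert lines[0] == "epoch,loss,val_iou,val_f1"
        assert len(lines) == 3

    def test_rerun_identical(self):
        cfg = ModelConfig(recipe="RS64", epochs=2, batch_size=2, seed=4)
        a = train(cfg, tiny_records(6, 0), tiny_records(2, 100))
        b = train(cfg, tiny_records(6, 0), tiny_records(2, 100))
        assert a.best_val_iou == b.best_val_iou  # numpy backend: bit-identical


class TestPredictMask:
    def test_threshold_semantics(self):
        cfg = ModelConfig(seed=0)
        model = build_model(cfg)

        class Const:
            cfg = model.cfg

            def __init__(self, value):
                self.value = value

            def eval(self):
                return self

            def __call__(self, t):
                n, h, w, _ = t.data.shape
                return Tensor(np.full((n, h, w, 1), self.value, np.float32))

        img = np.zeros((64, 64, 3), dtype=np.uint8)
        assert predict_mask(Const(0.0), img).n_foreground == 0
        assert predict_mask(Const(0.9), img, threshold=1.0 - 1e-9).n_foreground == 0
        assert predict_mask(Const(0.9), img, threshold=0.5).n_foreground == 64 * 64

    def test_non_image_rejected(self):
        model = build_model(ModelConfig(seed=0))
        with pytest.raises(ValueError, match="HxWx3"):
            predict_proba(model, np.zeros((64, 64), dtype=np.uint8))

    def test_returns_sparse(self):
        model = build_model(ModelConfig(seed=0))
        img = np.zeros((64, 64, 3), dtype=np.uint8)
        assert isinstance(predict_mask(model, img), SparseMask)

    def test_pads_odd_sizes(self):
        model = build_model(ModelConfig(seed=0))
        prob = predict_proba(model, np.zeros((70, 50, 3), dtype=np.uint8))
        assert prob.shape == (70, 50)


class TestCheckpoint:
    def test_round_trip(self, tmp_path):
        cfg = ModelConfig(recipe="RS64", epochs=1, batch_size=2, seed=2)
        report = train(cfg, tiny_records(4, 0), tiny_records(2, 100))
        save_checkpoint(report.model, tmp_path / "ckpt.npz")
        loaded = load_checkpoint(tmp_path / "ckpt.npz")
        assert loaded.cfg == cfg
        img = tiny_records(1, 999)[0].pixels
        np.testing.assert_array_equal(
            predict_proba(loaded, img), predict_proba(report.model, img)
        )

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="ckpt"):
            load_checkpoint(tmp_path / "ckpt.npz")
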