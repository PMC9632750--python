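import numpy as np
import pytest

from dermofuse.backbones.tiny import TinyBackbone, tiny_backbone
from dermofuse.fusion import (ConvDimSpec, FusionConfig, FusionModel,
                              build_branch, build_fusion_conv_reduce,
                              build_fusion_dense_concat,
                              build_fusion_zero_pad, conv_output_dims,
                              fuse_parallel, load_model, save_model)

INPUT_SHAPE = (56, 76, 3)
MISMATCHED = [(12, 17, 8), (12, 17, 6), (14, 19, 8)]


def specs(maps=MISMATCHED):
    return [tiny_backbone(i, m, name=f"b{i}") for i, m in enumerate(maps)]


def batch(n=2, shape=INPUT_SHAPE, seed=0):
    return np.random.default_rng(seed).random((n,) + shape,
                                              dtype=np.float32)


class TestConvOutputDims:
    def test_fourteen_nineteen_reduces_to_twelve_seventeen(self):
        done = conv_output_dims(ConvDimSpec(w_in=19, h_in=14, f=3, p=0, s=1))
        assert (done.h_out, done.w_out) == (12, 17)

    @pytest.mark.parametrize("h,w", [(1, 1), (7, 3), (450, 600)])
    def test_one_by_one_filter_is_identity(self, h, w):
        done = conv_output_dims(ConvDimSpec(w_in=w, h_in=h, f=1, p=0, s=1))
        assert (done.h_out, done.w_out) == (h, w)

    def test_padded_five_by_five_preserves_28(self):
        done = conv_output_dims(ConvDimSpec(w_in=28, h_in=28, f=5, p=2, s=1))
        assert (done.h_out, done.w_out) == (28, 28)

    def test_non_integral_stride_is_an_error(self):
        with pytest.raises(ValueError, match="divisible"):
            conv_output_dims(ConvDimSpec(w_in=10, h_in=10, f=3, p=0, s=2))


class TestFuseParallel:
    def test_mean_of_identical_maps_is_identity(self, rng):
        m = rng.random((2, 3, 4))
        np.testing.assert_allclose(fuse_parallel([m, m, m], "mean"), m)

    def test_max_never_below_mean(self, rng):
        maps = [rng.random((3, 3, 2)) for _ in range(4)]
        assert (fuse_parallel(maps, "max")
                >= fuse_parallel(maps, "mean") - 1e-12).all()

    def test_two_map_enumeration(self):
        a = np.array([[1.0, 2.0], [3.0, 4.0]])[..., None]
        b = np.array([[4.0, 1.0], [0.0, 8.0]])[..., None]
        np.testing.assert_array_equal(
            fuse_parallel([a, b], "sum")[..., 0], [[5, 3], [3, 12]])
        np.testing.assert_array_equal(
            fuse_parallel([a, b], "mean")[..., 0], [[2.5, 1.5], [1.5, 6]])
        np.testing.assert_array_equal(
            fuse_parallel([a, b], "max")[..., 0], [[4, 2], [3, 8]])

    def test_shape_mismatch_is_a_hard_error(self, rng):
        with pytest.raises(ValueError, match="identical"):
            fuse_parallel([rng.random((2, 2, 1)), rng.random((2, 3, 1))],
                          "sum")


class TestTinyBackbone:
    @pytest.mark.parametrize("out_map", MISMATCHED)
    def test_emits_requested_geometry(self, rng, out_map):
        bb = TinyBackbone(INPUT_SHAPE, out_map, rng=rng)
        from dermofuse.nn.autodiff import Var
        out = bb(Var(batch(1)))
        assert out.shape == (1,) + out_map

    def test_target_larger_than_input_rejected(self, rng):
        with pytest.raises(ValueError):
            TinyBackbone((8, 8, 3), (12, 17, 4), rng=rng)


class TestFusionBuilders:
    def test_conv_reduce_accepts_mismatched_maps(self):
        cfg = FusionConfig(strategy="conv_reduce", backbones=specs(),
                           n_classes=7, cbam_reduction=2,
                           branch_dense_units=16)
        model = build_fusion_conv_reduce(cfg, INPUT_SHAPE)
        res = model.forward(batch())
        assert res.logits.shape == (2, 7)
        np.testing.assert_allclose(res.probs.sum(axis=1), 1.0, atol=1e-6)

    def test_zero_pad_accepts_mismatched_maps(self):
        cfg = FusionConfig(strategy="zero_pad", backbones=specs(),
                           n_classes=7, cbam_reduction=2,
                           branch_dense_units=16)
        model = build_fusion_zero_pad(cfg, INPUT_SHAPE)
        res = model.forward(batch())
        assert res.logits.shape == (2, 7)
        # padded concat map keeps the larger spatial dims
        assert res.branch_maps["merged"].shape[1:3] == (14, 19)

    def test_dense_concat_exposes_four_outputs(self):
        cfg = FusionConfig(strategy="dense_concat", backbones=specs(),
                           n_classes=7, cbam_reduction=2,
                           branch_dense_units=16)
        model = build_fusion_dense_concat(cfg, INPUT_SHAPE)
        assert model.n_outputs == 4
        res = model.forward(batch())
        assert len(res.aux_logits) == 3
        np.testing.assert_allclose(res.probs.sum(axis=1), 1.0, atol=1e-6)
        for p in res.aux_probs:
            np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    @pytest.mark.parametrize("mode", ["sum", "mean", "max"])
    def test_parallel_modes_require_and_accept_identical_maps(self, mode):
        same = [(12, 17, 8)] * 3
        cfg = FusionConfig(strategy=mode, backbones=specs(same), n_classes=4,
                           cbam_reduction=2, branch_dense_units=16)
        model = FusionModel(cfg, INPUT_SHAPE)
        assert model.forward(batch()).logits.shape == (2, 4)
        with pytest.raises(ValueError, match="identical"):
            FusionModel(FusionConfig(strategy=mode, backbones=specs(),
                                     n_classes=4, cbam_reduction=2),
                        INPUT_SHAPE)

    def test_conv_reduce_unreconcilable_dims_suggest_zero_pad(self):
        maps = [(12, 17, 4), (18, 23, 4)]  # needs a 7x7, not 3x3, reduction
        cfg = FusionConfig(strategy="conv_reduce", backbones=specs(maps),
                           n_classes=3, cbam_reduction=2)
        with pytest.raises(ValueError, match="zero_pad"):
            FusionModel(cfg, INPUT_SHAPE)

    def test_zero_pad_odd_difference_is_an_error(self):
        maps = [(13, 18, 4), (14, 19, 4)]
        cfg = FusionConfig(strategy="zero_pad", backbones=specs(maps),
                           n_classes=3, cbam_reduction=2)
        with pytest.raises(ValueError, match="ring"):
            FusionModel(cfg, INPUT_SHAPE)

    def test_fewer_than_two_backbones_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            FusionConfig(strategy="dense_concat", backbones=specs()[:1],
                         n_classes=3)

    def test_per_branch_cbam_toggles(self):
        cfg = FusionConfig(strategy="dense_concat", backbones=specs(),
                           n_classes=3, use_cbam=[True, False, True],
                           cbam_reduction=2, branch_dense_units=8)
        model = FusionModel(cfg, INPUT_SHAPE)
        assert model.branches[0].cbam is not None
        assert model.branches[1].cbam is None
        assert model.branches[2].cbam is not None

    def test_build_branch_backbone_then_attention(self):
        cfg = FusionConfig(strategy="dense_concat", backbones=specs(),
                           n_classes=3, cbam_reduction=2)
        branch = build_branch(cfg.backbones[0], cfg, INPUT_SHAPE)
        from dermofuse.nn.autodiff import Var
        fmap, att = branch(Var(batch(1)))
        assert fmap.shape == att.shape == (1, 12, 17, 8)


class TestFreezeAndSerialize:
    def make_model(self):
        cfg = FusionConfig(strategy="dense_concat", backbones=specs(),
                           n_classes=3, cbam_reduction=2,
                           branch_dense_units=8, seed=11)
        return FusionModel(cfg, INPUT_SHAPE)

    def test_backbone_and_head_params_partition(self):
        model = self.make_model()
        all_ids = {id(p) for p in model.params()}
        bb = {id(p) for p in model.backbone_params()}
        head = {id(p) for p in model.head_params()}
        assert bb | head == all_ids
        assert not bb & head

    def test_freeze_unfreeze(self):
        model = self.make_model()
        model.freeze_backbones()
        assert all(not p.trainable for p in model.backbone_params())
        assert all(p.trainable for p in model.head_params())
        model.unfreeze_all()
        assert all(p.trainable for p in model.params())

    def test_save_load_round_trip(self, tmp_path):
        model = self.make_model()
        x = batch()
        before = model.forward(x).probs
        save_model(model, tmp_path / "m.npz")
        loaded = load_model(tmp_path / "m.npz")
        np.testing.assert_allclose(loaded.forward(x).probs, before,
                                   atol=1e-7)
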