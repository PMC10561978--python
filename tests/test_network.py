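import time

import numpy as np
import pytest

import stomakit as sk
from stomakit.network import (AggregationNode, FeatureMap, HDAStage,
                              RotatedStomataNet, aggregation_node, ida_combine)
from stomakit.nn import ConvBNReLU, Tensor


def _feature(rng, c, h, w, stride=4):
    return FeatureMap(Tensor(rng.normal(size=(1, c, h, w)).astype(np.float32)),
                      stride)


class TestAggregationNode:
    def test_shape_contract(self, rng):
        node = AggregationNode(np.random.default_rng(0), [6, 6], 6)
        out = aggregation_node([_feature(rng, 6, 8, 8),
                                _feature(rng, 6, 8, 8)], node)
        assert out.values.data.shape == (1, 6, 8, 8)
        assert out.stride == 4

    def test_zero_weights_reduce_to_activated_residual(self, rng):
        node = AggregationNode(np.random.default_rng(0), [4, 4], 4)
        node.conv.weight.data[:] = 0.0
        node.conv.bias.data[:] = 0.0
        node.eval()  # identity normalization: running stats (0, 1)
        x1 = _feature(rng, 4, 6, 6)
        xn = _feature(rng, 4, 6, 6)
        out = node([x1.values, xn.values])
        assert np.allclose(out.data, np.maximum(xn.values.data, 0.0),
                           atol=1e-5)

    def test_three_inputs_accepted(self, rng):
        node = AggregationNode(np.random.default_rng(0), [4, 4, 4], 4)
        out = node([_feature(rng, 4, 6, 6).values for _ in range(3)])
        assert out.data.shape == (1, 4, 6, 6)

    def test_residual_channel_mismatch_rejected(self):
        with pytest.raises(ValueError):
            AggregationNode(np.random.default_rng(0), [4, 8], 4)


class TestIdaCombine:
    def test_single_feature_is_identity(self, rng):
        f = _feature(rng, 8, 16, 16)
        out = ida_combine([f])
        assert out is f  # bit-exact base case

    def test_two_features_fold_to_finer_stride(self, rng):
        init = np.random.default_rng(0)
        nodes = [AggregationNode(init, [8, 8], 8)]
        projs = [ConvBNReLU(init, 16, 8, 3)]
        shallow = _feature(rng, 8, 16, 16, stride=8)
        deep = _feature(rng, 16, 8, 8, stride=16)
        out = ida_combine([shallow, deep], nodes, projs)
        assert out.stride == 8
        assert out.values.data.shape == (1, 8, 16, 16)

    def test_three_features_match_hand_unrolled_fold(self, rng):
        from stomakit.nn import upsample_bilinear2x

        init = np.random.default_rng(0)
        nodes = [AggregationNode(init, [8, 8], 8),
                 AggregationNode(init, [4, 4], 4)]
        projs = [ConvBNReLU(init, 16, 8, 3), ConvBNReLU(init, 8, 4, 3)]
        for m in nodes + projs:
            m.eval()
        f1 = _feature(rng, 4, 16, 16, stride=4)
        f2 = _feature(rng, 8, 8, 8, stride=8)
        f3 = _feature(rng, 16, 4, 4, stride=16)
        out = ida_combine([f1, f2, f3], nodes, projs)
        # hand unroll: N2(up(N1(up(f3), f2)), f1)
        mid = nodes[0]([upsample_bilinear2x(projs[0](f3.values)), f2.values])
        want = nodes[1]([upsample_bilinear2x(projs[1](mid)), f1.values])
        assert np.allclose(out.values.data, want.data, atol=1e-6)
        assert out.stride == 4

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            ida_combine([])


class TestHDAStage:
    def test_depth_one_halves_resolution(self, rng):
        stage = HDAStage(np.random.default_rng(0), 4, 8, depth=1, stride=2)
        out = stage(_feature(rng, 4, 16, 16).values)
        assert out.data.shape == (1, 8, 8, 8)

    def test_depth_one_matches_unrolled_blocks(self, rng):
        stage = HDAStage(np.random.default_rng(0), 4, 8, depth=1, stride=2)
        stage.eval()
        x = _feature(rng, 4, 16, 16).values
        l1 = stage.block1(x)
        l2 = stage.block2(l1)
        want = stage.node([l1, l2])
        assert np.allclose(stage(x).data, want.data)

    def test_depth_two_has_three_way_aggregation(self, rng):
        stage = HDAStage(np.random.default_rng(0), 4, 8, depth=2, stride=2)
        assert len(stage.node.in_channels) == 3
        out = stage(_feature(rng, 4, 16, 16).values)
        assert out.data.shape == (1, 8, 8, 8)

    def test_outputs_finite_for_random_inputs(self, rng):
        stage = HDAStage(np.random.default_rng(0), 3, 6, depth=1, stride=2)
        stage.eval()
        for _ in range(100):
            x = Tensor(rng.normal(scale=3.0,
                                  size=(1, 3, 8, 8)).astype(np.float32))
            assert np.isfinite(stage(x).data).all()


class TestForward:
    def test_head_shapes_and_ranges(self, lite_model, rng):
        img = rng.integers(0, 255, (256, 256)).astype(np.uint8)
        heads = lite_model(img)
        for t in (heads.heatmap, heads.angle):
            assert t.data.shape[2:] == (64, 64)
        assert heads.size.data.shape == (1, 2, 64, 64)
        assert heads.offset.data.shape == (1, 2, 64, 64)
        assert 0 < heads.heatmap.data.min() and heads.heatmap.data.max() < 1
        assert 0 < heads.angle.data.min() and heads.angle.data.max() < 180
        assert heads.size.data.min() >= 0

    def test_forward_is_deterministic(self, lite_model, rng):
        img = rng.integers(0, 255, (128, 128)).astype(np.uint8)
        a = lite_model(img).heatmap.data
        b = lite_model(img).heatmap.data
        assert np.array_equal(a, b)

    def test_non_multiple_stride_input_is_padded(self, lite_model):
        heads = lite_model(np.zeros((100, 90), dtype=np.uint8))
        assert heads.input_hw == (100, 90)
        # padded to 112×96 → grid 28×24
        assert heads.heatmap.data.shape[2:] == (28, 24)

    def test_deformable_variant_same_shapes(self, rng):
        img = rng.integers(0, 255, (64, 64)).astype(np.uint8)
        plain = sk.RotatedStomataNet(sk.NetConfig(use_deformable=False), 0)(img)
        deform = sk.RotatedStomataNet(sk.NetConfig(use_deformable=True), 0)(img)
        assert plain.heatmap.data.shape == deform.heatmap.data.shape
        assert plain.size.data.shape == deform.size.data.shape

    def test_gradient_reaches_every_head(self, rng):
        from stomakit.targets import encode_targets
        from stomakit.training import DatasetItem, batch_losses

        model = sk.RotatedStomataNet(sk.NetConfig(), seed=1)
        sample = sk.generate_sample(sk.SynthConfig.test_scale(seed=2), 2)
        ann = sample.annotation_set("g")
        item = DatasetItem(sample.image, ann, encode_targets(ann, 4))
        heads = model(sample.image)
        loss, _ = batch_losses(heads, [item], sk.LossWeights())
        loss.backward()
        for head in (model.head_heatmap, model.head_size, model.head_offset,
                     model.head_angle):
            norms = [np.abs(p.grad).sum() for layer in head
                     for p in layer.parameters() if p.grad is not None]
            assert norms and sum(norms) > 0

    def test_lite_forward_under_one_second(self, lite_model):
        img = np.zeros((256, 256), dtype=np.uint8)
        lite_model(img)  # warm-up
        start = time.perf_counter()
        lite_model(img)
        assert time.perf_counter() - start < 1.0

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            sk.NetConfig(preset="resnet").resolved()
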