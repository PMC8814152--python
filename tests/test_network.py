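"""Two-branch network contracts and the Grad-CAM oracle."""

import numpy as np
import pytest

from jawdx.network import (Checkpoint, EncoderConfig, TwoBranchNet,
                           gradcam_response, gradcam_response_map)
from jawdx.nn import autograd as ag


@pytest.fixture(scope="module")
def net():
    return TwoBranchNet(EncoderConfig.tiny(), ("lesion", "healthy"),
                        np.random.default_rng(0))


@pytest.fixture(scope="module")
def images():
    rng = np.random.default_rng(1)
    return rng.random((2, 48, 96))


class TestEncode:
    def test_last_map_resolution(self, net, images):
        feats = net.encode(images)
        # total stride 8: 96x48 -> 12x6
        assert feats.last.shape == (2, 64, 6, 12)
        assert feats.last is feats.pyramid[-1]

    def test_spatial_dims_nonincreasing(self, net, images):
        feats = net.encode(images)
        dims = [p.shape[2] * p.shape[3] for p in feats.pyramid]
        assert all(a >= b for a, b in zip(dims, dims[1:]))

    def test_indivisible_dims_error_names_stride(self, net):
        with pytest.raises(ValueError, match="stride 8"):
            net.encode(np.zeros((1, 50, 90)))

    def test_inference_determinism(self, net, images):
        a = net.encode(images).last.data
        b = net.encode(images).last.data
        np.testing.assert_array_equal(a, b)


class TestClassify:
    def test_probs_sum_to_one(self, net, images):
        _, probs = net.classify(net.encode(images))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all()

    def test_softmax_closed_form(self):
        # logits (1, 0) -> probs (0.7311, 0.2689)
        logp = ag.log_softmax(ag.Tensor([[1.0, 0.0]]), axis=1)
        np.testing.assert_allclose(np.exp(logp.data),
                                   [[0.73106, 0.26894]], atol=1e-4)


class TestSegment:
    def test_output_shape_and_range(self, net, images):
        out = net.segment(net.encode(images))
        assert out.shape == (2, 1, 48, 96)
        assert out.data.min() >= 0.0 and out.data.max() <= 1.0

    def test_decoder_gradient_reaches_stem(self, net, images):
        feats = net.encode(images)
        loss = ag.ssum(net.segment(feats))
        grads = ag.backward(loss)
        g = grads.get(net.params["encoder.stem.w"])
        assert g is not None and np.abs(g).max() > 0

    def test_absent_decoder_raises(self, images):
        bare = TwoBranchNet(EncoderConfig.tiny(), ("lesion", "healthy"),
                            np.random.default_rng(0), with_decoder=False)
        with pytest.raises(ValueError):
            bare.segment(bare.encode(images))


class TestBranchSeparation:
    def test_heads_share_only_the_encoder(self, net):
        head = {k for k in net.params if k.startswith("head.")}
        dec = {k for k in net.params if k.startswith("decoder.")}
        enc = {k for k in net.params if k.startswith("encoder.")}
        assert head and dec and enc
        assert not head & dec
        assert head | dec | enc == set(net.params)


def brute_force_gradcam(feature_map, grads):
    """Loop over channels and pixels: alpha_c = mean grad; R = relu(sum)."""
    c, h, w = feature_map.shape
    r = np.zeros((h, w))
    for ci in range(c):
        alpha = 0.0
        for y in range(h):
            for x in range(w):
                alpha += grads[ci, y, x]
        alpha /= h * w
        for y in range(h):
            for x in range(w):
                r[y, x] += alpha * feature_map[ci, y, x]
    return np.maximum(r, 0.0)


class TestGradCam:
    def make_linear_graph(self, fmap, weights):
        """logit = sum_c w_c * sum(A_c): gradient d logit/dA_c = w_c."""
        from jawdx.network import EncoderFeatures
        last = ag.Tensor(fmap[None])
        pooled = ag.reshape(ag.ssum(last, axis=(2, 3)), (1, fmap.shape[0]))
        logits = ag.matmul(pooled, ag.Tensor(weights))
        return EncoderFeatures(pyramid=[last], last=last), logits

    def test_derived_two_channel_example(self):
        fmap = np.zeros((2, 2, 2))
        fmap[0] = [[1, 0], [0, 0]]
        fmap[1] = [[0, 1], [0, 0]]
        weights = np.array([[0.5], [-0.5]])  # grads 0.5 and -0.5 per channel
        feats, logits = self.make_linear_graph(fmap, weights)
        r = gradcam_response_map(feats, logits, 0)
        np.testing.assert_allclose(r.values[0], [[0.5, 0.0], [0.0, 0.0]],
                                   atol=1e-6)

    def test_single_channel_unit_gradient_rectifies_map(self):
        rng = np.random.default_rng(0)
        fmap = rng.normal(size=(1, 4, 4)).astype(np.float32)
        feats, logits = self.make_linear_graph(fmap, np.array([[1.0]]))
        r = gradcam_response_map(feats, logits, 0)
        np.testing.assert_allclose(r.values[0], np.maximum(fmap[0], 0.0),
                                   atol=1e-6)

    @pytest.mark.parametrize("channels", [1, 2, 4])
    def test_matches_brute_force_loop(self, channels):
        rng = np.random.default_rng(channels)
        fmap = rng.normal(size=(channels, 4, 4)).astype(np.float32)
        weights = rng.normal(size=(channels, 3)).astype(np.float32)
        feats, logits = self.make_linear_graph(fmap, weights)
        for target in range(3):
            r = gradcam_response_map(feats, logits, target)
            grads = np.repeat(
                weights[:, target][:, None, None], 16, axis=1
            ).reshape(channels, 4, 4)
            expected = brute_force_gradcam(fmap.astype(np.float64),
                                           grads.astype(np.float64))
            np.testing.assert_allclose(r.values[0], expected, atol=1e-6)

    def test_logit_independent_of_features_gives_zero_map(self):
        from jawdx.network import EncoderFeatures
        last = ag.Tensor(np.ones((1, 2, 3, 3)))
        probe = ag.Tensor(np.ones((1, 2)))
        logits = ag.matmul(probe, ag.Tensor(np.ones((2, 2))))
        feats = EncoderFeatures(pyramid=[last], last=last)
        with pytest.raises(ValueError, match="do not depend"):
            gradcam_response(feats, logits, 0)

    def test_inference_only_graph_raises(self):
        from jawdx.network import EncoderFeatures
        last = ag.Tensor(np.ones((1, 2, 3, 3)))
        logits = ag.Tensor(np.ones((1, 2)))  # leaf: no graph
        feats = EncoderFeatures(pyramid=[last], last=last)
        with pytest.raises(ValueError, match="gradient unavailable"):
            gradcam_response(feats, logits, 0)

    def test_second_order_flag_unsupported(self, net, images):
        feats = net.encode(images)
        logits, _ = net.classify(feats)
        with pytest.raises(NotImplementedError):
            gradcam_response(feats, logits, 0, detach_weights=False)

    def test_response_nonnegative_on_real_network(self, net, images):
        feats = net.encode(images)
        logits, _ = net.classify(feats)
        r = gradcam_response_map(feats, logits, [0, 1])
        assert (r.values >= 0).all()


class TestCheckpoint:
    def test_save_load_roundtrip(self, net, images, tmp_path):
        ckpt = Checkpoint(arrays=net.state_arrays(),
                          encoder_config=net.config, classes=net.classes,
                          with_decoder=True, meta={"mode": "binary"})
        path = ckpt.save(tmp_path / "model.npz")
        loaded = Checkpoint.load(path)
        net2 = loaded.build_network()
        a = net.encode(images).last.data
        b = net2.encode(images).last.data
        np.testing.assert_array_equal(a, b)

    def test_encoder_transfer_roundtrip(self, net):
        bare = TwoBranchNet(EncoderConfig.tiny(), ("lesion", "healthy"),
                            np.random.default_rng(9), with_decoder=False)
        bare.load_encoder_arrays(net.encoder_arrays())
        for k, v in net.encoder_arrays().items():
            got = bare.params[k].data if k in bare.params else bare.buffers[k]
            np.testing.assert_array_equal(got, v)

    def test_mismatched_encoder_arrays_rejected(self, net):
        arrays = net.encoder_arrays()
        arrays.pop(sorted(arrays)[0])
        bare = TwoBranchNet(EncoderConfig.tiny(), ("lesion", "healthy"),
                            np.random.default_rng(9), with_decoder=False)
        with pytest.raises(ValueError, match="missing"):
            bare.load_encoder_arrays(arrays)
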