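"""The two-branch model: shared residual encoder, classification head,
U-Net-style segmentation decoder, and Grad-CAM response extraction.

Both branches (and the contrastive pretraining network) share one
convolutional encoder.  The classification head is global average pooling
followed by a hidden fully-connected layer and a softmax over the class list;
the decoder upsamples the deepest feature map back to input resolution with
stage-wise skip connections and a terminal sigmoid.

Grad-CAM weights each channel of the deepest feature map by the spatial mean
of the class-score gradient, sums over channels, and rectifies; during
training the channel weights are treated as constants so that the
position-consistency loss backpropagates only through the feature map itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.optim import he_conv, he_linear

__all__ = ["EncoderConfig", "EncoderFeatures", "Prediction", "ResponseMap",
           "TwoBranchNet", "gradcam_response", "Checkpoint"]

BINARY_CLASSES = ("lesion", "healthy")
FIVE_CLASSES = ("DC", "PC", "AB", "KCOT", "healthy")


@dataclass(frozen=True)
class EncoderConfig:
    """Shape of the shared encoder and classification head.

    The stem halves resolution; each stage applies one residual block with
    its own stride.  ``head_hidden`` is the width of the fully-connected
    layer after pooling (2048 at full scale).
    """

    stem_channels: int = 8
    stage_channels: tuple = (16, 32, 48, 64)
    stage_strides: tuple = (2, 2, 1, 1)
    head_hidden: int = 64

    @property
    def total_stride(self) -> int:
        return 2 * int(np.prod(self.stage_strides))

    @staticmethod
    def tiny() -> "EncoderConfig":
        return EncoderConfig()

    @staticmethod
    def full() -> "EncoderConfig":
        # 2048-wide deepest stage feeding a 2048-unit head, stride 32
        return EncoderConfig(stem_channels=64,
                             stage_channels=(256, 512, 1024, 2048),
                             stage_strides=(2, 2, 2, 2), head_hidden=2048)

    def to_dict(self) -> dict:
        return {"stem_channels": self.stem_channels,
                "stage_channels": list(self.stage_channels),
                "stage_strides": list(self.stage_strides),
                "head_hidden": self.head_hidden}

    @staticmethod
    def from_dict(d: dict) -> "EncoderConfig":
        return EncoderConfig(stem_channels=d["stem_channels"],
                             stage_channels=tuple(d["stage_channels"]),
                             stage_strides=tuple(d["stage_strides"]),
                             head_hidden=d["head_hidden"])


@dataclass
class EncoderFeatures:
    """Per-stage feature pyramid; ``last`` is the deepest map (Grad-CAM)."""

    pyramid: list
    last: Tensor


@dataclass
class ResponseMap:
    """Rectified Grad-CAM response at last-stage resolution."""

    values: np.ndarray

    def __post_init__(self):
        if np.any(self.values < 0):
            raise ValueError("response map must be nonnegative")


@dataclass
class Prediction:
    probs: np.ndarray          # (n_classes,), sums to 1
    logits: np.ndarray
    mask: np.ndarray           # soft mask in [0,1], input resolution
    binary_mask: np.ndarray    # mask >= 0.5
    boxes: list                # (x0, y0, x1, y1, confidence)
    response: ResponseMap | None
    classes: tuple


def _init_encoder_params(rng, cfg: EncoderConfig):
    """Convolution kernels plus batch-norm parameters and statistics."""
    p, buf = {}, {}

    def bn(name, c):
        p[f"{name}.bn.g"] = Tensor(np.ones(c))
        p[f"{name}.bn.b"] = Tensor(np.zeros(c))
        buf[f"{name}.bn.mean"] = np.zeros(c, dtype=np.float32)
        buf[f"{name}.bn.var"] = np.ones(c, dtype=np.float32)

    p["encoder.stem.w"] = he_conv(rng, cfg.stem_channels, 1, 3, 3)
    bn("encoder.stem", cfg.stem_channels)
    cin = cfg.stem_channels
    for i, (cout, stride) in enumerate(zip(cfg.stage_channels,
                                           cfg.stage_strides)):
        pre = f"encoder.stage{i}"
        p[f"{pre}.conv1.w"] = he_conv(rng, cout, cin, 3, 3)
        bn(f"{pre}.conv1", cout)
        p[f"{pre}.conv2.w"] = he_conv(rng, cout, cout, 3, 3)
        bn(f"{pre}.conv2", cout)
        if cin != cout or stride != 1:
            p[f"{pre}.skip.w"] = he_conv(rng, cout, cin, 1, 1)
            bn(f"{pre}.skip", cout)
        cin = cout
    return p, buf


class TwoBranchNet:
    """Shared-encoder classification + segmentation network."""

    def __init__(self, encoder_config: EncoderConfig, classes,
                 rng: np.random.Generator, with_decoder: bool = True):
        self.config = encoder_config
        self.classes = tuple(classes)
        self.with_decoder = with_decoder
        cfg = encoder_config
        self.params, self.buffers = _init_encoder_params(rng, cfg)
        self._collect: dict | None = None
        c_last = cfg.stage_channels[-1]
        self.params["head.fc1.w"] = he_linear(rng, c_last, cfg.head_hidden)
        self.params["head.fc1.b"] = Tensor(np.zeros(cfg.head_hidden))
        self.params["head.fc2.w"] = he_linear(rng, cfg.head_hidden,
                                              len(self.classes))
        self.params["head.fc2.b"] = Tensor(np.zeros(len(self.classes)))
        if with_decoder:
            def bn(name, c):
                self.params[f"{name}.bn.g"] = Tensor(np.ones(c))
                self.params[f"{name}.bn.b"] = Tensor(np.zeros(c))
                self.buffers[f"{name}.bn.mean"] = np.zeros(c,
                                                           dtype=np.float32)
                self.buffers[f"{name}.bn.var"] = np.ones(c,
                                                         dtype=np.float32)

            skip_channels = [cfg.stem_channels] + list(cfg.stage_channels[:-1])
            d_ch = c_last
            for i, s_ch in enumerate(reversed(skip_channels)):
                self.params[f"decoder.block{i}.w"] = he_conv(
                    rng, s_ch, d_ch + s_ch, 3, 3)
                bn(f"decoder.block{i}", s_ch)
                d_ch = s_ch
            self.params["decoder.out1.w"] = he_conv(rng, 8, d_ch, 3, 3)
            bn("decoder.out1", 8)
            self.params["decoder.out2.w"] = he_conv(rng, 1, 8, 1, 1)
            self.params["decoder.out2.b"] = Tensor(np.zeros(1))

    # ------------------------------------------------------------------ #

    def _bn(self, x, name: str, training: bool) -> Tensor:
        g, b = self.params[f"{name}.bn.g"], self.params[f"{name}.bn.b"]
        if training:
            out, mean, var = ag.batchnorm_train(x, g, b)
            if self._collect is not None:
                self._collect.setdefault(name, []).append((mean, var))
            return out
        return ag.batchnorm_eval(x, g, b, self.buffers[f"{name}.bn.mean"],
                                 self.buffers[f"{name}.bn.var"])

    def recalibrate_stats(self, batches) -> None:
        """Set the inference batch-norm statistics to the average batch
        statistics of the current weights over ``batches`` of images.

        Running averages lag badly over the short training schedules this
        package uses, so inference statistics are recomputed exactly after
        each epoch instead of tracked by an exponential moving average.
        """
        self._collect = {}
        try:
            for images in batches:
                feats = self.encode(images, training=True)
                if self.with_decoder:
                    self.segment(feats, training=True)
        finally:
            collected, self._collect = self._collect, None
        for name, stats in collected.items():
            self.buffers[f"{name}.bn.mean"] = np.mean(
                [m for m, _ in stats], axis=0).astype(np.float32)
            self.buffers[f"{name}.bn.var"] = np.mean(
                [v for _, v in stats], axis=0).astype(np.float32)

    def encode(self, images, training: bool = False) -> EncoderFeatures:
        """Forward the encoder; ``images`` is (N, H, W) or a Tensor NCHW."""
        if not isinstance(images, Tensor):
            arr = np.asarray(images, dtype=np.float64)
            if arr.ndim == 2:
                arr = arr[None]
            images = Tensor(arr[:, None, :, :])
        n, c, h, w = images.shape
        stride = self.config.total_stride
        if h % stride or w % stride:
            raise ValueError(
                f"input {w}x{h} not divisible by the encoder's total "
                f"stride {stride}")
        p = self.params
        x = ag.relu(self._bn(ag.conv2d(images, p["encoder.stem.w"], None,
                                       stride=2, pad=1),
                             "encoder.stem", training))
        pyramid = [x]
        for i, s in enumerate(self.config.stage_strides):
            pre = f"encoder.stage{i}"
            y = ag.relu(self._bn(ag.conv2d(x, p[f"{pre}.conv1.w"], None,
                                           stride=s, pad=1),
                                 f"{pre}.conv1", training))
            y = self._bn(ag.conv2d(y, p[f"{pre}.conv2.w"], None,
                                   stride=1, pad=1), f"{pre}.conv2", training)
            if f"{pre}.skip.w" in p:
                shortcut = self._bn(ag.conv2d(x, p[f"{pre}.skip.w"], None,
                                              stride=s, pad=0),
                                    f"{pre}.skip", training)
            else:
                shortcut = x
            x = ag.relu(y + shortcut)
            pyramid.append(x)
        return EncoderFeatures(pyramid=pyramid, last=pyramid[-1])

    def classify(self, features: EncoderFeatures):
        """Pooled last map -> hidden FC -> class logits and softmax probs."""
        p = self.params
        pooled = ag.global_avg_pool(features.last)
        hidden = ag.relu(ag.add(ag.matmul(pooled, p["head.fc1.w"]),
                                p["head.fc1.b"]))
        logits = ag.add(ag.matmul(hidden, p["head.fc2.w"]), p["head.fc2.b"])
        log_probs = ag.log_softmax(logits, axis=1)
        return logits, np.exp(log_probs.data)

    def segment(self, features: EncoderFeatures,
                training: bool = False) -> Tensor:
        """Decode the pyramid to a soft mask (N, 1, H, W) in [0, 1]."""
        if not self.with_decoder:
            raise ValueError("this network was built without a decoder")
        p = self.params
        d = features.last
        for i, skip in enumerate(reversed(features.pyramid[:-1])):
            if d.shape[2] != skip.shape[2]:
                d = ag.upsample2(d)
            d = ag.relu(self._bn(ag.conv2d(ag.concat([d, skip], axis=1),
                                           p[f"decoder.block{i}.w"], None,
                                           stride=1, pad=1),
                                 f"decoder.block{i}", training))
        d = ag.upsample2(d)  # stem is at half input resolution
        d = ag.relu(self._bn(ag.conv2d(d, p["decoder.out1.w"], None,
                                       stride=1, pad=1),
                             "decoder.out1", training))
        d = ag.conv2d(d, p["decoder.out2.w"], p["decoder.out2.b"],
                      stride=1, pad=0)
        return ag.sigmoid(d)

    # ------------------------------------------------------------------ #

    def encoder_arrays(self) -> dict:
        """Encoder weights plus batch-norm statistics, by name."""
        out = {k: v.data.copy() for k, v in self.params.items()
               if k.startswith("encoder.")}
        out.update({k: v.copy() for k, v in self.buffers.items()
                    if k.startswith("encoder.")})
        return out

    def load_encoder_arrays(self, arrays: dict) -> None:
        own = {k for k in self.params if k.startswith("encoder.")} |             {k for k in self.buffers if k.startswith("encoder.")}
        if set(arrays) != own:
            missing = sorted(own - set(arrays))
            unexpected = sorted(set(arrays) - own)
            raise ValueError(f"encoder weight mismatch: missing={missing}, "
                             f"unexpected={unexpected}")
        for k, v in arrays.items():
            target = (self.params[k].data if k in self.params
                      else self.buffers[k])
            if target.shape != v.shape:
                raise ValueError(f"shape mismatch for {k}: "
                                 f"{target.shape} vs {v.shape}")
            if k in self.params:
                self.params[k].data = v.astype(np.float32).copy()
            else:
                self.buffers[k] = v.astype(np.float32).copy()

    def state_arrays(self) -> dict:
        out = {k: v.data.copy() for k, v in self.params.items()}
        out.update({k: v.copy() for k, v in self.buffers.items()})
        return out

    def load_state_arrays(self, arrays: dict) -> None:
        if set(arrays) != set(self.params) | set(self.buffers):
            raise ValueError("parameter name mismatch when loading state")
        for k, v in arrays.items():
            if k in self.params:
                self.params[k].data = v.astype(np.float32).copy()
            else:
                self.buffers[k] = v.astype(np.float32).copy()


def gradcam_response(features: EncoderFeatures, logits: Tensor,
                     target_class, detach_weights: bool = True,
                     rows=None) -> Tensor:
    """Grad-CAM response tensor for the requested class(es).

    ``target_class`` is an int or an (N,) integer array.  Channel weights are
    the spatial means of d(logit[target]) / d(last feature map); the response
    is the rectified channel-weighted sum, shape (N, h, w), connected to the
    graph through the feature map (the weights are detached constants).

    ``rows`` optionally restricts the output to a subset of batch rows (the
    position-consistency loss only applies to lesion samples).
    """
    if not detach_weights:
        raise NotImplementedError(
            "full second-order backpropagation through the Grad-CAM weights "
            "is not supported by the numpy tape; use detach_weights=True")
    if not logits.parents:
        raise ValueError("gradient unavailable: logits are not connected to "
                         "the feature map (inference-only graph)")
    n, k = logits.shape
    targets = np.broadcast_to(np.asarray(target_class, dtype=np.intp), (n,))
    if np.any(targets < 0) or np.any(targets >= k):
        raise ValueError(f"target class out of range for {k} classes")
    onehot = np.zeros((n, k))
    onehot[np.arange(n), targets] = 1.0
    score = ag.ssum(ag.mul(logits, onehot))
    grads = ag.backward(score)
    g = grads.get(features.last)
    if g is None:
        raise ValueError("gradient unavailable: the logits do not depend on "
                         "the last feature map")
    alpha = g.mean(axis=(2, 3), keepdims=True)  # (N, C, 1, 1) constants
    fmap = features.last if rows is None else ag.take_rows(features.last, rows)
    if rows is not None:
        alpha = alpha[np.asarray(rows, dtype=np.intp)]
    weighted = ag.ssum(ag.mul(fmap, alpha), axis=1)
    return ag.relu(weighted)


def gradcam_response_map(features: EncoderFeatures, logits: Tensor,
                         target_class, detach_weights: bool = True
                         ) -> ResponseMap:
    """Convenience wrapper returning a plain :class:`ResponseMap` array."""
    r = gradcam_response(features, logits, target_class,
                        detach_weights=detach_weights)
    return ResponseMap(values=r.data)


@dataclass
class Checkpoint:
    """Weights + architecture + class list, stored as npz with a JSON header."""

    arrays: dict
    encoder_config: EncoderConfig
    classes: tuple
    with_decoder: bool
    meta: dict = field(default_factory=dict)

    def save(self, path) -> Path:
        path = Path(path)
        header = json.dumps({
            "encoder_config": self.encoder_config.to_dict(),
            "classes": list(self.classes),
            "with_decoder": self.with_decoder,
            "meta": self.meta,
        })
        if path.suffix != ".npz":
            path = path.with_suffix(path.suffix + ".npz")
        np.savez(path, __header__=np.frombuffer(header.encode(), dtype=np.uint8),
                 **self.arrays)
        return path

    @staticmethod
    def load(path) -> "Checkpoint":
        with np.load(path) as z:
            header = json.loads(bytes(z["__header__"]).decode())
            arrays = {k: z[k] for k in z.files if k != "__header__"}
        return Checkpoint(
            arrays=arrays,
            encoder_config=EncoderConfig.from_dict(header["encoder_config"]),
            classes=tuple(header["classes"]),
            with_decoder=header["with_decoder"],
            meta=header["meta"])

    def build_network(self) -> TwoBranchNet:
        net = TwoBranchNet(self.encoder_config, self.classes,
                           np.random.default_rng(0),
                           with_decoder=self.with_decoder)
        net.load_state_arrays(self.arrays)
        return net

    def parameter_count(self) -> int:
        return int(sum(a.size for a in self.arrays.values()))
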