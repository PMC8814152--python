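"""Momentum-contrast self-supervised pretraining of the shared encoder.

Healthy panoramic frames are abundant and unannotated; the encoder is
pretrained on them alone.  Each image yields two stochastically augmented
views; a query encoder + 2-layer projection head embeds one view, a momentum
(key) encoder embeds the other, and the InfoNCE loss contrasts the positive
pair against a FIFO queue of past key embeddings.  After training, the
encoder weights (projection head stripped) initialise the two-branch network.

Augmentations are a grayscale-appropriate recipe: random resized crop,
horizontal flip, brightness/contrast jitter, and Gaussian blur.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import resize

from .network import EncoderConfig, TwoBranchNet
from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.optim import SGD, he_linear

__all__ = ["PretrainConfig", "ContrastState", "momentum_update", "info_nce",
           "random_view", "pretrain_encoder", "pooled_embeddings"]


@dataclass
class PretrainConfig:
    encoder: EncoderConfig = field(default_factory=EncoderConfig.tiny)
    epochs: int = 10
    batch_size: int = 16
    queue_size: int = 64           # 65536 at full scale
    momentum: float = 0.9          # 0.999 at full scale; the key encoder
                                   # must track the query within ~100 steps
    temperature: float = 0.2
    lr: float = 0.1
    proj_dim: int = 32
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.momentum <= 1.0:
            raise ValueError("momentum must be in [0, 1]")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class ContrastState:
    """Query/key parameter sets plus the negative-key queue."""

    query_params: dict            # name -> Tensor (trained)
    key_params: dict              # name -> ndarray (momentum copy)
    queue: np.ndarray             # (dim, queue_size), unit-norm columns
    queue_ids: np.ndarray         # source-image index per queue column
    ptr: int
    momentum: float
    temperature: float


def momentum_update(query_params, key_params, m: float) -> dict:
    """Exponential-moving-average update: key' = m*key + (1-m)*query."""
    q_arrays = {k: (v.data if isinstance(v, Tensor) else np.asarray(v))
                for k, v in query_params.items()}
    k_arrays = {k: (v.data if isinstance(v, Tensor) else np.asarray(v))
                for k, v in key_params.items()}
    if set(q_arrays) != set(k_arrays):
        raise ValueError("query/key parameter structures do not match")
    out = {}
    for name, kv in k_arrays.items():
        qv = q_arrays[name]
        if kv.shape != qv.shape:
            raise ValueError(f"shape mismatch for {name}")
        out[name] = m * kv + (1.0 - m) * qv
    return out


def info_nce(query_emb, positive_emb, queue, tau: float) -> float:
    """InfoNCE: softmax cross-entropy over [q.k+, q.queue] against index 0.

    ``query_emb``/``positive_emb`` are (N, dim) unit-norm embeddings; the
    queue holds negatives as (dim, K) unit-norm columns.
    """
    q = np.asarray(query_emb, dtype=np.float64)
    k = np.asarray(positive_emb, dtype=np.float64)
    if q.ndim == 1:
        q, k = q[None], k[None]
    if np.any(np.linalg.norm(q, axis=1) < 1e-8) or \
       np.any(np.linalg.norm(k, axis=1) < 1e-8):
        raise ValueError("zero-norm embedding")
    queue = np.asarray(queue, dtype=np.float64)
    if queue.size == 0:
        raise ValueError("queue must be nonempty")
    l_pos = (q * k).sum(axis=1, keepdims=True)
    l_neg = q @ queue
    logits = np.concatenate([l_pos, l_neg], axis=1) / tau
    z = logits - logits.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1))
    return float(np.mean(lse - z[:, 0]))


def random_view(image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One stochastic augmented view of a grayscale image.

    Panoramic radiographs are acquired in a standardised geometry, so the
    crop range is mild compared with natural-image recipes, and the
    intensity jitter is gentle: radiolucency (local darkness) is diagnostic
    in this domain and should not be trained away entirely.
    """
    h, w = image.shape
    s = rng.uniform(0.85, 1.0)
    ch, cw = max(2, int(round(h * s))), max(2, int(round(w * s)))
    y0 = int(rng.integers(0, h - ch + 1))
    x0 = int(rng.integers(0, w - cw + 1))
    view = image[y0:y0 + ch, x0:x0 + cw]
    if view.shape != (h, w):
        view = resize(view, (h, w), order=1, anti_aliasing=False,
                      preserve_range=True)
    else:
        view = view.copy()
    if rng.random() < 0.5:
        view = view[:, ::-1]
    view = view * rng.uniform(0.95, 1.05) + rng.uniform(-0.03, 0.03)
    if rng.random() < 0.3:
        view = gaussian_filter(view, sigma=float(rng.uniform(0.2, 0.6)))
    return np.clip(view, 0.0, 1.0)


def _build_proj(rng, c_last: int, proj_dim: int) -> dict:
    return {"proj.fc1.w": he_linear(rng, c_last, c_last),
            "proj.fc1.b": Tensor(np.zeros(c_last)),
            "proj.fc2.w": he_linear(rng, c_last, proj_dim),
            "proj.fc2.b": Tensor(np.zeros(proj_dim))}


def _embed(net: TwoBranchNet, proj: dict, images: np.ndarray) -> Tensor:
    feats = net.encode(images, training=True)
    pooled = ag.global_avg_pool(feats.last)
    h = ag.relu(ag.add(ag.matmul(pooled, proj["proj.fc1.w"]),
                       proj["proj.fc1.b"]))
    z = ag.add(ag.matmul(h, proj["proj.fc2.w"]), proj["proj.fc2.b"])
    return ag.l2_normalize(z, axis=1)


def pretrain_encoder(samples, config: PretrainConfig):
    """Train the encoder on healthy samples; returns (encoder arrays, history).

    ``samples`` must all be healthy (lesions have annotations and belong to
    the supervised stage); a lesion sample raises.  History is one dict per
    epoch with the mean InfoNCE loss.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("no samples for pretraining")
    for s in samples:
        if s.category != "healthy":
            raise ValueError(f"pretraining is healthy-only by design; got a "
                             f"{s.category!r} sample ({s.id!r})")
    rng = np.random.default_rng(config.seed)
    net = TwoBranchNet(config.encoder, ("lesion", "healthy"), rng,
                       with_decoder=False)
    c_last = config.encoder.stage_channels[-1]
    proj = _build_proj(rng, c_last, config.proj_dim)
    query_params = {**{k: v for k, v in net.params.items()
                       if k.startswith("encoder.")}, **proj}
    key_params = {k: v.data.copy() for k, v in query_params.items()}

    # queue warm-start: key-encoder embeddings of augmented views, so the
    # contrastive task is realistic from the very first step
    warm = np.empty((0, config.proj_dim))
    warm_ids = []
    while warm.shape[0] < config.queue_size:
        take = min(config.batch_size, config.queue_size - warm.shape[0])
        srcs = [(warm.shape[0] + j) % len(samples) for j in range(take)]
        views = np.stack([random_view(samples[i].image, rng) for i in srcs])
        warm = np.concatenate([warm, _embed(net, proj, views).data], axis=0)
        warm_ids.extend(srcs)
    queue = np.ascontiguousarray(warm.T)
    state = ContrastState(query_params=query_params, key_params=key_params,
                          queue=queue, queue_ids=np.asarray(warm_ids),
                          ptr=0, momentum=config.momentum,
                          temperature=config.temperature)
    opt = SGD(query_params, lr=config.lr, momentum=0.9)

    key_net = TwoBranchNet(config.encoder, ("lesion", "healthy"),
                           np.random.default_rng(0), with_decoder=False)
    history = []
    n = len(samples)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            if len(idx) < 2:
                continue
            v1 = np.stack([random_view(samples[i].image, rng) for i in idx])
            v2 = np.stack([random_view(samples[i].image, rng) for i in idx])
            q = _embed(net, proj, v1)
            # key branch: momentum encoder, no gradient needed
            for name, arr in state.key_params.items():
                if name.startswith("encoder."):
                    key_net.params[name].data = arr
            key_proj = {name: Tensor(arr) for name, arr in
                        state.key_params.items() if name.startswith("proj.")}
            k = _embed(key_net, key_proj, v2).data

            l_pos = ag.ssum(ag.mul(q, k), axis=1, keepdims=True)
            l_neg = ag.matmul(q, Tensor(state.queue))
            # a queue key from the query's own image is a false negative at
            # this dataset size; exclude it from the softmax
            same = (state.queue_ids[None, :] == idx[:, None])
            l_neg = ag.add(l_neg, -1e9 * same)
            logits = ag.scale(ag.concat([l_pos, l_neg], axis=1),
                              1.0 / state.temperature)
            logp = ag.log_softmax(logits, axis=1)
            loss = ag.scale(ag.ssum(reshape_col0(logp)), -1.0 / len(idx))
            grads = ag.backward(loss)
            opt.step(grads)
            losses.append(float(loss.data))

            state.key_params = momentum_update(
                state.query_params, state.key_params, state.momentum)
            # FIFO enqueue of the new keys
            for row, src in zip(k, idx):
                state.queue[:, state.ptr] = row
                state.queue_ids[state.ptr] = src
                state.ptr = (state.ptr + 1) % config.queue_size
        history.append({"epoch": epoch, "loss": float(np.mean(losses))})
    # inference batch-norm statistics on clean (un-augmented) images
    net.recalibrate_stats(
        np.stack([s.image for s in samples[i:i + config.batch_size]])
        for i in range(0, n, config.batch_size))
    return net.encoder_arrays(), history


def reshape_col0(t: Tensor) -> Tensor:
    """First column of a 2-D tensor as (N,)."""
    n, k = t.shape
    sel = np.zeros((k, 1))
    sel[0, 0] = 1.0
    return ag.reshape(ag.matmul(t, Tensor(sel)), (n,))


def pooled_embeddings(encoder_arrays, encoder_config: EncoderConfig,
                      images, init_seed: int = 0) -> np.ndarray:
    """Global-average-pooled last-stage features for a stack of images
    (used by linear probes of representation quality).  ``init_seed``
    controls the random initialisation used when no weights are given."""
    net = TwoBranchNet(encoder_config, ("lesion", "healthy"),
                       np.random.default_rng(init_seed), with_decoder=False)
    if encoder_arrays is not None:
        net.load_encoder_arrays(encoder_arrays)
    feats = net.encode(np.stack([np.asarray(im) for im in images]))
    return feats.last.data.mean(axis=(2, 3))
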