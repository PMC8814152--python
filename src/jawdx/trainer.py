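"""Joint training of the two-branch network and single-image inference.

Training follows the two-stage recipe: the encoder may be initialised from
healthy-only contrastive pretraining, then both branches are trained jointly
with the weighted sum of the cross-entropy, mask-MSE and Grad-CAM
position-consistency losses.  The shared encoder and classification head use
the classification learning rate; the segmentation decoder its own (the
full-scale rates are 1e-3 and 1e-2).  Ablation flags remove the pretrained
initialisation, the segmentation branch (and its loss), or the consistency
constraint — the three rows of the ablation comparison.

Lesion samples are augmented on the fly (flip, cut-and-paste onto a healthy
frame, or one of the 20 patch-covered variants); a fully patch-covered lesion
is relabeled healthy, so the constraint and the mask loss see its emptied
mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import augment as aug
from .data import LesionSizeStats, survey_lesion_sizes
from .evaluate import bbox_from_mask
from .losses import dilate_mask, mask_to_feature_res
from .network import (BINARY_CLASSES, FIVE_CLASSES, Checkpoint,
                      EncoderConfig, Prediction, ResponseMap, TwoBranchNet,
                      gradcam_response)
from .nn import autograd as ag
from .nn.optim import SGD, Adam

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "TrainResult", "train_two_branch", "predict",
           "response_mass_fraction"]


@dataclass
class TrainConfig:
    mode: str = "five_class"            # or "binary"
    epochs: int = 60
    batch_size: int = 16
    lr_classification: float = 1e-3
    lr_segmentation: float = 1e-2
    weights: tuple = (1.0, 1.0, 1.0)    # (w_ce, w_mse, w_con); CE:MSE is 1:1
    optimizer: str = "sgd"              # "sgd" (momentum 0.9) or "adam"
    dilation_range: tuple = (6, 12)     # disk radius, inclusive
    seed: int = 0
    encoder: EncoderConfig = field(default_factory=EncoderConfig.full)
    no_pretrain: bool = False
    no_segment: bool = False
    no_constraint: bool = False
    healthy_train_count: int = 500
    patience: int | None = 10           # early stopping on validation loss
    mse_per_pixel: bool = False
    class_weighting: bool = False
    use_all_lesions: bool = False
    augment_lesions: bool = True

    def __post_init__(self):
        if self.mode not in ("five_class", "binary"):
            raise ValueError("mode must be 'five_class' or 'binary'")
        if self.lr_classification <= 0 or self.lr_segmentation <= 0:
            raise ValueError("learning rates must be positive")

    @property
    def classes(self) -> tuple:
        return FIVE_CLASSES if self.mode == "five_class" else BINARY_CLASSES

    @staticmethod
    def tiny(seed: int = 0, **overrides) -> "TrainConfig":
        """Desk-scale profile: 96x48 inputs, small encoder, 10 epochs.

        The full-scale SGD learning rates belong to the full-scale network;
        the tiny profile uses Adam (short small-batch schedules stall
        seed-dependently under plain SGD here) with a faster decoder rate,
        and per-pixel mask MSE for stable decoder steps at low resolution.
        The dilation radius range scales the full-scale 6..12 px (at 512x256)
        down by the ~5x resolution factor.
        """
        cfg = TrainConfig(mode="binary", epochs=8, batch_size=16,
                          lr_classification=2e-3, lr_segmentation=5e-3,
                          optimizer="adam", dilation_range=(1, 3), seed=seed,
                          encoder=EncoderConfig.tiny(),
                          healthy_train_count=132, patience=None,
                          mse_per_pixel=True)
        return replace(cfg, **overrides) if overrides else cfg


@dataclass
class TrainResult:
    checkpoint: Checkpoint
    history: list
    best_val_accuracy: float
    best_val_loss: float


def _label_index(category: str, classes: tuple) -> int:
    if category in classes:
        return classes.index(category)
    if "lesion" in classes and category != "healthy":
        return classes.index("lesion")
    raise ValueError(f"category {category!r} not representable in {classes}")


def _augment_sample(sample, healthy_pool, stats: LesionSizeStats,
                    patch_config, rng):
    out = sample
    if sample.category != "healthy" and stats is not None:
        op = rng.integers(0, 3)
        if op == 1 and healthy_pool:
            partner = healthy_pool[int(rng.integers(0, len(healthy_pool)))]
            out = aug.cut_and_paste(out, partner, rng)
        elif op == 2:
            variants = aug.patch_cover(out, stats, patch_config, rng)
            if variants:
                out = variants[int(rng.integers(0, len(variants)))]
    if rng.random() < 0.5:
        out = aug.horizontal_flip(out)
    return out


def _forward_losses(net: TwoBranchNet, batch, config: TrainConfig,
                    rng, want_constraint: bool):
    """Build the loss graph for one batch; returns (total, parts dict)."""
    classes = config.classes
    images = np.stack([s.image for s in batch])
    labels = np.array([_label_index(s.category, classes) for s in batch])
    n = len(batch)
    feats = net.encode(images, training=True)
    logits, probs = net.classify(feats)

    onehot = np.zeros((n, len(classes)))
    onehot[np.arange(n), labels] = 1.0
    logp = ag.log_softmax(logits, axis=1)
    if config.class_weighting:
        counts = np.maximum(onehot.sum(axis=0), 1.0)
        w = (onehot * (n / (len(classes) * counts))).sum(axis=1)
    else:
        w = np.ones(n)
    ce = ag.scale(ag.ssum(ag.mul(logp, onehot * (-w[:, None] / w.sum()))), 1.0)

    parts = {"ce": float(ce.data)}
    total = ag.scale(ce, config.weights[0])

    if not config.no_segment:
        masks = np.stack([s.mask.astype(np.float64) for s in batch])
        pred = ag.reshape(net.segment(feats, training=True), masks.shape)
        diff = ag.sub(pred, masks)
        denom = n * (masks[0].size if config.mse_per_pixel else 1)
        mse = ag.scale(ag.ssum(ag.square(diff)), 1.0 / denom)
        parts["mse"] = float(mse.data)
        total = ag.add(total, ag.scale(mse, config.weights[1]))
    else:
        parts["mse"] = 0.0

    lesion_rows = np.array([i for i, s in enumerate(batch)
                            if s.category != "healthy" and s.mask.any()],
                           dtype=np.intp)
    if want_constraint and config.weights[2] != 0 and len(lesion_rows):
        fh, fw = feats.last.shape[2], feats.last.shape[3]
        d_lo, d_hi = config.dilation_range
        weights_arr = []
        for i in lesion_rows:
            d = int(rng.integers(d_lo, d_hi + 1))
            dil = dilate_mask(batch[i].mask, d).values
            md = mask_to_feature_res(dil, (fh, fw)).astype(np.float64)
            weights_arr.append(1.0 - 2.0 * md)
        r = gradcam_response(feats, logits, labels, rows=lesion_rows)
        con = ag.scale(ag.ssum(ag.mul(r, np.stack(weights_arr))),
                       1.0 / len(lesion_rows))
        parts["constrain"] = float(con.data)
        total = ag.add(total, ag.scale(con, config.weights[2]))
    else:
        parts["constrain"] = 0.0
    parts["probs"] = probs
    parts["labels"] = labels
    return total, parts


def _validate(net: TwoBranchNet, val_samples, config: TrainConfig):
    classes = config.classes
    correct, losses = 0, []
    for start in range(0, len(val_samples), config.batch_size):
        batch = val_samples[start:start + config.batch_size]
        images = np.stack([s.image for s in batch])
        labels = np.array([_label_index(s.category, classes) for s in batch])
        feats = net.encode(images)
        logits, probs = net.classify(feats)
        pred = probs.argmax(axis=1)
        correct += int((pred == labels).sum())
        logp = np.log(np.clip(probs[np.arange(len(batch)), labels],
                              1e-12, None))
        loss = -logp.mean()
        if not config.no_segment:
            masks = np.stack([s.mask.astype(np.float64) for s in batch])
            seg = net.segment(feats).data.reshape(masks.shape)
            denom = masks[0].size if config.mse_per_pixel else 1
            loss += ((seg - masks) ** 2).sum(axis=(1, 2)).mean() / denom
        losses.append(float(loss))
    return 100.0 * correct / len(val_samples), float(np.mean(losses))


def train_two_branch(samples, encoder_arrays, config: TrainConfig
                     ) -> TrainResult:
    """Train the two-branch network; returns the best-validation checkpoint.

    ``samples`` carry split tags; training uses the lesion ``train`` split
    plus ``healthy_train_count`` healthy frames drawn (in id order) from the
    pretraining pool, and validation uses the ``val`` split.
    ``encoder_arrays`` are pretrained encoder weights or None.
    """
    samples = list(samples)
    lesion_splits = (None if config.use_all_lesions else "train")
    lesions = [s for s in samples if s.category != "healthy"
               and (lesion_splits is None or s.split == lesion_splits)]
    healthy_pool = sorted((s for s in samples
                           if s.category == "healthy" and
                           s.split == "pretrain"), key=lambda s: s.id)
    healthy_train = healthy_pool[:config.healthy_train_count]
    train_set = lesions + healthy_train
    val_set = [s for s in samples if s.split == "val"]
    if not train_set:
        raise ValueError("empty training split")
    if not val_set:
        raise ValueError("empty validation split")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    net = TwoBranchNet(config.encoder, config.classes, rng,
                       with_decoder=not config.no_segment)
    if encoder_arrays is not None and not config.no_pretrain:
        net.load_encoder_arrays(encoder_arrays)

    stats = None
    patch_config = None
    if config.augment_lesions and lesions:
        stats = survey_lesion_sizes(lesions, all_splits=True)
        h, w = train_set[0].image.shape
        patch_config = aug.AugmentConfig(crop_box=(0, 0, w, h),
                                         target_size=(w, h))

    if config.optimizer == "adam":
        opt = Adam(net.params, lr=config.lr_classification,
                   lr_overrides={"decoder.": config.lr_segmentation})
    else:
        opt = SGD(net.params, lr=config.lr_classification, momentum=0.9,
                  lr_overrides={"decoder.": config.lr_segmentation})
    want_constraint = not config.no_constraint

    history = []
    best = {"loss": np.inf, "acc": 0.0, "arrays": net.state_arrays(),
            "epoch": -1}
    stall = 0
    for epoch in range(config.epochs):
        order = rng.permutation(len(train_set))
        epoch_parts = {"ce": [], "mse": [], "constrain": []}
        for start in range(0, len(train_set), config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = [train_set[i] for i in idx]
            if config.augment_lesions and stats is not None:
                batch = [_augment_sample(s, healthy_train, stats,
                                         patch_config, rng) for s in batch]
            total, parts = _forward_losses(net, batch, config, rng,
                                           want_constraint)
            grads = ag.backward(total)
            opt.step(grads)
            for k in epoch_parts:
                epoch_parts[k].append(parts[k])
        # exact inference statistics for the current weights
        net.recalibrate_stats(
            np.stack([s.image for s in train_set[i:i + config.batch_size]])
            for i in range(0, len(train_set), config.batch_size))
        val_acc, val_loss = _validate(net, val_set, config)
        record = {"epoch": epoch,
                  **{k: float(np.mean(v)) for k, v in epoch_parts.items()},
                  "val_accuracy": val_acc, "val_loss": val_loss}
        history.append(record)
        logger.info("epoch %d: ce=%.4f mse=%.4f con=%.4f val_acc=%.2f",
                    epoch, record["ce"], record["mse"], record["constrain"],
                    val_acc)
        if val_loss < best["loss"]:
            best = {"loss": val_loss, "acc": val_acc,
                    "arrays": net.state_arrays(), "epoch": epoch}
            stall = 0
        else:
            stall += 1
            if config.patience is not None and stall >= config.patience:
                break
    checkpoint = Checkpoint(
        arrays=best["arrays"], encoder_config=config.encoder,
        classes=config.classes, with_decoder=not config.no_segment,
        meta={"mode": config.mode, "best_epoch": best["epoch"],
              "best_val_accuracy": best["acc"],
              "pretrained": bool(encoder_arrays is not None
                                 and not config.no_pretrain)})
    return TrainResult(checkpoint=checkpoint, history=history,
                       best_val_accuracy=best["acc"],
                       best_val_loss=best["loss"])


def predict(checkpoint: Checkpoint, image: np.ndarray,
            min_area: int = 20, with_response: bool = True) -> Prediction:
    """Classify and segment one preprocessed image.

    Returns class probabilities, the soft and thresholded masks, mask-derived
    detection boxes, and the Grad-CAM response for the predicted class.  A
    healthy prediction still yields a (possibly empty) binary mask.
    """
    net = checkpoint.build_network()
    image = np.asarray(image, dtype=np.float64)
    feats = net.encode(image[None])
    logits, probs = net.classify(feats)
    if net.with_decoder:
        soft = net.segment(feats).data[0, 0]
    else:
        soft = np.zeros_like(image)
    binary = (soft >= 0.5).astype(np.uint8)
    boxes = bbox_from_mask(binary, soft_mask=soft, min_area=min_area)
    response = None
    if with_response:
        target = int(np.argmax(probs[0]))
        r = gradcam_response(feats, logits, target)
        response = ResponseMap(values=r.data[0])
    return Prediction(probs=probs[0], logits=logits.data[0], mask=soft,
                      binary_mask=binary, boxes=boxes, response=response,
                      classes=net.classes)


def response_mass_fraction(checkpoint: Checkpoint, lesion_samples,
                           dilation_radius: int = 2) -> float:
    """Mean fraction of Grad-CAM response mass inside the dilated
    ground-truth mask over lesion samples (the concentration measure used to
    judge the position-consistency constraint)."""
    net = checkpoint.build_network()
    fractions = []
    for s in lesion_samples:
        feats = net.encode(s.image[None])
        logits, probs = net.classify(feats)
        target = int(np.argmax(probs[0]))
        r = gradcam_response(feats, logits, target).data[0]
        total = r.sum()
        if total <= 0:
            continue
        dil = dilate_mask(s.mask, dilation_radius).values
        md = mask_to_feature_res(dil, r.shape)
        fractions.append(float((r * md).sum() / total))
    if not fractions:
        raise ValueError("no lesion sample produced nonzero response mass")
    return float(np.mean(fractions))
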