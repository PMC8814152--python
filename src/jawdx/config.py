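"""Run configuration and the end-to-end pipeline.

A run config is a nested mapping with sections ``phantom``, ``augment``,
``pretrain``, ``train`` and ``evaluate`` plus a global ``seed`` and a
``profile`` (``tiny`` or ``full``).  Unknown keys are rejected by name.  Each
stage derives its own seed from the global seed and the stage name, so a
stage can be skipped (outputs already on disk) without disturbing the
randomness of later stages.

Pipeline order: generate phantoms -> survey lesion sizes -> contrastive
pretraining on healthy frames -> joint two-branch training -> evaluation on
the held-out test split.
"""

from __future__ import annotations

import copy
import csv
import json
import zlib
from pathlib import Path

import numpy as np
import yaml

from . import data as dio
from .augment import AugmentConfig, central_crop_box, crop_and_resize
from .evaluate import MetricsReport, evaluate_model
from .network import Checkpoint, EncoderConfig
from .phantoms import PhantomSpec, generate_phantom_dataset
from .pretrain import PretrainConfig, pretrain_encoder
from .trainer import TrainConfig, predict, train_two_branch

__all__ = ["default_config", "load_config", "validate_config",
           "run_pipeline", "stage_seed"]

_PROFILES = {
    "tiny": {
        "phantom": {"image_height": 48, "image_width": 96,
                    "class_counts": {"DC": 25, "PC": 25, "AB": 25,
                                     "KCOT": 25},
                    "healthy_splits": [132, 16, 16],
                    "lesion_size_range": [6, 12], "noise_sd": 0.03},
        "augment": {"crop_frac_w": 0.8, "crop_frac_h": 0.9,
                    "target_width": 96, "target_height": 48,
                    "patches_per_sample": 20, "patch_fill": 0.5,
                    "max_placement_tries": 50},
        "pretrain": {"epochs": 10, "batch_size": 16, "queue_size": 64,
                     "momentum": 0.9, "temperature": 0.2, "lr": 0.1,
                     "proj_dim": 32},
        "train": {"mode": "five_class", "epochs": 28, "batch_size": 16,
                  "optimizer": "adam",
                  "lr_classification": 2e-3, "lr_segmentation": 5e-3,
                  "w_ce": 1.0, "w_mse": 1.0, "w_con": 1.0,
                  "dilation_min": 1, "dilation_max": 3,
                  "healthy_train_count": 132, "patience": None,
                  "mse_per_pixel": True, "no_pretrain": False,
                  "no_segment": False, "no_constraint": False},
        "evaluate": {"min_area": 4, "iou_threshold": 0.5},
        "encoder": "tiny",
    },
    "full": {
        "phantom": {"image_height": 512, "image_width": 1024,
                    "class_counts": {"DC": 356, "PC": 292, "AB": 94,
                                     "KCOT": 130},
                    "healthy_splits": [9500, 300, 200],
                    "lesion_size_range": [40, 120], "noise_sd": 0.03},
        "augment": {"crop_frac_w": 0.8, "crop_frac_h": 0.9,
                    "target_width": 512, "target_height": 256,
                    "patches_per_sample": 20, "patch_fill": 0.5,
                    "max_placement_tries": 50},
        "pretrain": {"epochs": 100, "batch_size": 16, "queue_size": 65536,
                     "momentum": 0.999, "temperature": 0.2, "lr": 0.03,
                     "proj_dim": 128},
        "train": {"mode": "five_class", "epochs": 100, "batch_size": 16,
                  "optimizer": "sgd",
                  "lr_classification": 1e-3, "lr_segmentation": 1e-2,
                  "w_ce": 1.0, "w_mse": 1.0, "w_con": 1.0,
                  "dilation_min": 6, "dilation_max": 12,
                  "healthy_train_count": 500, "patience": 10,
                  "mse_per_pixel": False, "no_pretrain": False,
                  "no_segment": False, "no_constraint": False},
        "evaluate": {"min_area": 20, "iou_threshold": 0.5},
        "encoder": "full",
    },
}


def default_config(profile: str = "tiny", seed: int = 0) -> dict:
    if profile not in _PROFILES:
        raise ValueError(f"unknown profile {profile!r}")
    cfg = copy.deepcopy(_PROFILES[profile])
    cfg["profile"] = profile
    cfg["seed"] = int(seed)
    return cfg


def validate_config(cfg: dict) -> dict:
    """Reject unknown keys anywhere in the nested config, by name."""
    template = default_config(cfg.get("profile", "tiny"),
                              cfg.get("seed", 0))

    def check(node, tmpl, path):
        for key, value in node.items():
            if key not in tmpl:
                where = ".".join(path + [str(key)]) if path else str(key)
                raise ValueError(f"unknown config key {where!r}")
            if isinstance(tmpl[key], dict) and key != "class_counts":
                if not isinstance(value, dict):
                    raise ValueError(f"section {key!r} must be a mapping")
                check(value, tmpl[key], path + [key])

    check(cfg, template, [])
    merged = copy.deepcopy(template)
    for key, value in cfg.items():
        if isinstance(value, dict) and key != "class_counts":
            merged[key].update(value)
        else:
            merged[key] = value
    return merged


def load_config(path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    ss = np.random.SeedSequence([int(global_seed),
                                 zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _phantom_spec(cfg: dict) -> PhantomSpec:
    p = cfg["phantom"]
    return PhantomSpec(image_height=p["image_height"],
                       image_width=p["image_width"],
                       class_counts=dict(p["class_counts"]),
                       healthy_splits=tuple(p["healthy_splits"]),
                       lesion_size_range=tuple(p["lesion_size_range"]),
                       noise_sd=p["noise_sd"],
                       seed=stage_seed(cfg["seed"], "phantom"))


def _encoder_config(cfg: dict) -> EncoderConfig:
    return (EncoderConfig.tiny() if cfg["encoder"] == "tiny"
            else EncoderConfig.full())


def _train_config(cfg: dict) -> TrainConfig:
    t = cfg["train"]
    return TrainConfig(mode=t["mode"], epochs=t["epochs"],
                       batch_size=t["batch_size"],
                       optimizer=t["optimizer"],
                       lr_classification=t["lr_classification"],
                       lr_segmentation=t["lr_segmentation"],
                       weights=(t["w_ce"], t["w_mse"], t["w_con"]),
                       dilation_range=(t["dilation_min"], t["dilation_max"]),
                       seed=stage_seed(cfg["seed"], "train"),
                       encoder=_encoder_config(cfg),
                       no_pretrain=t["no_pretrain"],
                       no_segment=t["no_segment"],
                       no_constraint=t["no_constraint"],
                       healthy_train_count=t["healthy_train_count"],
                       patience=t["patience"],
                       mse_per_pixel=t["mse_per_pixel"])


def _preprocess(samples, cfg: dict):
    a = cfg["augment"]
    out = []
    for s in samples:
        h, w = s.image.shape
        box = central_crop_box(h, w, a["crop_frac_w"], a["crop_frac_h"])
        ac = AugmentConfig(crop_box=box,
                           target_size=(a["target_width"],
                                        a["target_height"]),
                           patches_per_sample=a["patches_per_sample"],
                           patch_fill=a["patch_fill"],
                           max_placement_tries=a["max_placement_tries"])
        out.append(crop_and_resize(s, ac))
    return out


def run_pipeline(cfg: dict, out_dir, force: bool = False) -> MetricsReport:
    """Execute every stage in order; stages whose outputs already exist are
    skipped unless ``force``.  Returns the final metrics report."""
    cfg = validate_config(cfg)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "resolved_config.json", "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True)

    # -- stage: phantom generation -------------------------------------- #
    data_dir = out_dir / "data"
    manifest_path = data_dir / "manifest.csv"
    if force or not manifest_path.exists():
        generate_phantom_dataset(_phantom_spec(cfg), data_dir)
    manifest = dio.load_manifest(manifest_path)

    # -- stage: lesion size survey -------------------------------------- #
    survey_path = out_dir / "lesion_sizes.json"
    stats = dio.survey_from_manifest(manifest, split="train")
    with open(survey_path, "w") as fh:
        json.dump(stats.__dict__, fh)

    # -- stage: contrastive pretraining on healthy frames ---------------- #
    encoder_path = out_dir / "pretrained_encoder.npz"
    train_cfg = _train_config(cfg)
    if train_cfg.no_pretrain:
        encoder_arrays = None
    elif not force and encoder_path.exists():
        with np.load(encoder_path) as z:
            encoder_arrays = {k: z[k] for k in z.files}
    else:
        p = cfg["pretrain"]
        healthy = _preprocess(
            dio.load_samples(manifest, splits="pretrain",
                             categories="healthy"), cfg)
        pc = PretrainConfig(encoder=_encoder_config(cfg), epochs=p["epochs"],
                            batch_size=p["batch_size"],
                            queue_size=p["queue_size"],
                            momentum=p["momentum"],
                            temperature=p["temperature"], lr=p["lr"],
                            proj_dim=p["proj_dim"],
                            seed=stage_seed(cfg["seed"], "pretrain"))
        encoder_arrays, history = pretrain_encoder(healthy, pc)
        np.savez(encoder_path, **encoder_arrays)
        with open(out_dir / "pretrain_loss.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["epoch", "loss"])
            writer.writeheader()
            writer.writerows(history)

    # -- stage: joint two-branch training -------------------------------- #
    checkpoint_path = out_dir / "checkpoint.npz"
    if not force and checkpoint_path.exists():
        checkpoint = Checkpoint.load(checkpoint_path)
    else:
        train_samples = _preprocess(
            dio.load_samples(manifest, splits=("train", "val", "pretrain")),
            cfg)
        result = train_two_branch(train_samples, encoder_arrays, train_cfg)
        checkpoint = result.checkpoint
        checkpoint.save(checkpoint_path)
        if result.history:
            with open(out_dir / "train_log.csv", "w", newline="") as fh:
                writer = csv.DictWriter(fh,
                                        fieldnames=list(result.history[0]))
                writer.writeheader()
                writer.writerows(result.history)

    # -- stage: evaluation on the test split ------------------------------ #
    e = cfg["evaluate"]
    test_samples = _preprocess(dio.load_samples(manifest, splits="test"), cfg)
    report = evaluate_model(
        lambda image: predict(checkpoint, image, min_area=e["min_area"]),
        test_samples, checkpoint.classes, min_area=e["min_area"],
        iou_threshold=e["iou_threshold"], mode=cfg["train"]["mode"])
    with open(out_dir / "metrics.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
    return report
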