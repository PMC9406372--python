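"""Configuration-driven end-to-end experiment runner.

A YAML config describes the whole pipeline (simulate -> balance -> split ->
train [-> adapt] -> evaluate); :func:`run_experiment` executes it and writes
every artifact (manifest, checkpoints, history CSVs, metrics JSON, run log)
into one output directory.  Re-running the same config reproduces all
metrics because every random draw is seeded from the config.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import coral as coral_mod
from . import datasets as ds
from . import evalmetrics as em
from . import imagesim, nets
from .ensemble import ensemble_predict
from .errors import ConfigError
from .types import BethesdaClass, SOURCE_STYLE, TARGET_STYLE

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "image_size": 32,
    "dataset": {"counts": {"NILM": 40, "LSIL": 24, "HSIL": 24, "SCC": 24},
                "target_counts": None},
    "augmentation": {"max_rotation": 25.0, "allow_flips": True},
    "split": [0.65, 0.15, 0.20],
    "model": "cnn",
    "ensemble_size": 3,
    "training": {"epochs": 2, "learning_rate": 1e-3, "batch_size": 16},
    "coral": {"lambda": 0.0},
}

_VALID_MODELS = ("cnn", "ae_cnn", "transfer_stub", "ensemble")


def resolve_config(raw: dict) -> dict:
    """Merge a user config over defaults and validate the schema."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, val in (raw or {}).items():
        if key not in cfg and key != "out_dir":
            raise ConfigError(f"unknown config key {key!r}")
        if isinstance(val, dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    if cfg["model"] not in _VALID_MODELS:
        raise ConfigError(f"model must be one of {_VALID_MODELS}")
    if abs(sum(cfg["split"]) - 1.0) > 1e-9:
        raise ConfigError("split fractions must sum to 1")
    for name in cfg["dataset"]["counts"]:
        BethesdaClass.from_string(name)
    if cfg["image_size"] < 16:
        raise ConfigError("image_size must be >= 16")
    if cfg["training"]["epochs"] < 0:
        raise ConfigError("epochs must be non-negative")
    lam = cfg["coral"]["lambda"]
    if lam != "auto" and float(lam) < 0:
        raise ConfigError("coral lambda must be non-negative or 'auto'")
    return cfg


def _counts_map(d: dict) -> dict:
    return {BethesdaClass.from_string(k): int(v) for k, v in d.items()}


def _build_model(cfg: dict, seed: int):
    size = cfg["image_size"]
    kind = cfg["model"]
    if kind in ("cnn", "ensemble"):
        spec = nets.small_cnn_spec(size)
        return spec, nets.build_from_spec(spec, seed=seed)
    if kind == "transfer_stub":
        backbone = nets.make_stub_backbone((size, size, 3), feature_dim=32,
                                           seed=seed)
        return None, nets.adapt_transfer_head(backbone, 4, "head_only",
                                              seed=seed + 1)
    raise ConfigError(f"unsupported model {kind!r}")  # pragma: no cover


def run_experiment(config: dict | str | Path, out_dir: Optional[str] = None) -> Path:
    """Run the configured pipeline; returns the artifact directory."""
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = resolve_config(config)
    out = Path(out_dir or cfg.get("out_dir") or "experiment_out")
    out.mkdir(parents=True, exist_ok=True)

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    root = logging.getLogger("cytocoral")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run(cfg, out)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(cfg: dict, out: Path) -> Path:
    seed = int(cfg["seed"])
    size = int(cfg["image_size"])
    logger.info("resolved config: %s", json.dumps(cfg, sort_keys=True))
    (out / "config.resolved.yaml").write_text(yaml.safe_dump(cfg))

    # simulate
    data = ds.Dataset(imagesim.synth_dataset(
        _counts_map(cfg["dataset"]["counts"]), SOURCE_STYLE, seed, size=size))
    logger.info("simulated %d source images", len(data))

    # balance + split
    policy = ds.AugmentationPolicy(
        max_rotation=float(cfg["augmentation"]["max_rotation"]),
        allow_flips=bool(cfg["augmentation"]["allow_flips"]))
    data = ds.balance_classes(data, policy, seed=seed + 1)
    assignment = ds.stratified_split(data, tuple(cfg["split"]), seed=seed + 2)
    data = ds.apply_split(data, assignment)
    manifest = ds.save_dataset(data, out / "dataset")
    logger.info("balanced to %d images; split %s; manifest %s",
                len(data), assignment.counts(), manifest)

    Xtr, ytr = data.subset("train").arrays()
    Xva, yva = data.subset("val").arrays()
    Xte, yte = data.subset("test").arrays()
    tcfg = nets.TrainingConfig(
        epochs=int(cfg["training"]["epochs"]),
        learning_rate=float(cfg["training"]["learning_rate"]),
        batch_size=int(cfg["training"]["batch_size"]), seed=seed + 3)

    target_X = None
    if cfg["dataset"]["target_counts"]:
        tgt = ds.Dataset(imagesim.synth_dataset(
            _counts_map(cfg["dataset"]["target_counts"]), TARGET_STYLE,
            seed + 10, size=size))
        target_X, target_y = tgt.arrays()
        logger.info("simulated %d target images", len(tgt))

    metrics: dict = {"config_model": cfg["model"]}
    kind = cfg["model"]

    if kind == "ensemble":
        members = []
        for k in range(int(cfg["ensemble_size"])):
            spec, m = _build_model(cfg, seed + 100 + k)
            m, hist = nets.train_classifier(m, (Xtr, ytr), (Xva, yva),
                                            tcfg.with_seed(seed + 200 + k))
            nets.save_history(out / f"history_member{k}.csv", hist)
            nets.save_checkpoint(out / f"member{k}.npz", spec, m)
            members.append(m)
        preds = ensemble_predict(members, Xte)
    elif kind == "ae_cnn":
        ae_spec = nets.small_autoencoder_spec(size)
        ae, encoder, _ = nets.build_autoencoder(
            ae_spec, nets.SMALL_ENCODER_DEPTH, seed=seed + 100)
        ae, ae_hist = nets.train_autoencoder(
            ae, Xtr, nets.TrainingConfig(epochs=max(1, tcfg.epochs),
                                         learning_rate=1e-3,
                                         batch_size=tcfg.batch_size,
                                         loss="mse", seed=seed + 300))
        nets.save_history(out / "history_ae.csv", ae_hist)
        Ftr = nets.encode_dataset(encoder, Xtr)
        Fva = nets.encode_dataset(encoder, Xva)
        Fte = nets.encode_dataset(encoder, Xte)
        clf_spec = nets.small_ae_classifier_spec(Ftr.shape[1:])
        clf = nets.build_from_spec(clf_spec, seed=seed + 101)
        clf, hist = nets.train_classifier(clf, (Ftr, ytr), (Fva, yva), tcfg)
        nets.save_history(out / "history.csv", hist)
        nets.save_checkpoint(out / "checkpoint.npz", clf_spec, clf)
        nets.save_checkpoint(out / "autoencoder.npz", ae_spec, ae)
        preds = clf.predict(Fte).argmax(axis=1)
        metrics["scores"] = clf.predict(Fte)
    else:
        spec, model = _build_model(cfg, seed + 100)
        lam = cfg["coral"]["lambda"]
        if target_X is not None and lam not in (0, 0.0):
            ccfg = coral_mod.CoralConfig(lam=lam if lam == "auto" else float(lam))
            if lam == "auto":
                best, grid = coral_mod.tune_lambda(
                    lambda: _build_model(cfg, seed + 100)[1], (Xtr, ytr),
                    (Xva, yva), target_X, ccfg, tcfg)
                logger.info("tuned lambda=%g from grid results %s", best, grid)
                ccfg = coral_mod.CoralConfig(lam=best)
            model, hist = coral_mod.adapt_train(model, (Xtr, ytr), (Xva, yva),
                                                target_X, ccfg, tcfg)
        else:
            model, hist = nets.train_classifier(model, (Xtr, ytr), (Xva, yva),
                                                tcfg)
        nets.save_history(out / "history.csv", hist)
        if spec is not None:
            nets.save_checkpoint(out / "checkpoint.npz", spec, model)
        preds = model.predict(Xte).argmax(axis=1)
        metrics["scores"] = model.predict(Xte)
        if target_X is not None:
            tpred = model.predict(target_X).argmax(axis=1)
            tcm = em.confusion_matrix(target_y, tpred)
            metrics["target"] = em.classification_report(tcm).as_dict()

    cm = em.confusion_matrix(yte, preds)
    report = em.classification_report(cm)
    metrics["test"] = report.as_dict()
    metrics["test"]["confusion_matrix"] = cm.tolist()
    if "scores" in metrics:
        try:
            metrics["test"]["auc"] = em.roc_auc(yte, metrics.pop("scores"))["auc"]
        except Exception:
            metrics.pop("scores", None)
    (out / "metrics.json").write_text(
        json.dumps(metrics, indent=2, default=float))
    logger.info("test accuracy %.4f", report.accuracy)
    return out
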