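"""End-to-end pipeline: simulate/load -> preprocess -> split -> augment ->
train -> evaluate -> explain, driven by one YAML-serializable config.

Every run directory is self-describing: the manifest JSON records the
config, seeds, per-stage counts and the final metrics, so all non-
floating-point artifacts are reproducible bit-exactly from it.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, balance, dataio, styletransfer
from .backbones.tiny import tiny_backbone
from .dataio import DatasetSplits, LabeledDataset
from .evaluation import evaluate_predictions
from .fusion import FusionConfig, FusionModel, save_model
from .interpretability import (SaliencyTarget, grad_cam, grad_cam_pp,
                               saliency_overlay)
from .synthetic import SyntheticSpec, generate_dataset, scaled_counts
from .training import TrainConfig, two_phase_train

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from / dumpable to YAML."""

    # data source: a directory + metadata CSV, or a synthetic spec
    image_dir: str | None = None
    metadata: str | None = None
    synthetic_scale: float | None = 0.02
    synthetic_seed: int = 0
    synthetic_classes: list[str] | None = None  # subset, None = all seven
    classes: list[str] = field(
        default_factory=lambda: list(dataio.HAM10000_CLASSES))
    # preprocessing
    target_h: int = 32
    target_w: int = 32
    # split
    split_ratio: tuple[int, int, int] = (3, 1, 1)
    split_seed: int = 0
    # imbalance strategy: none | rotation | style | pixel | class_weight
    strategy: str = "style"
    majority_class: str = "nv"
    augment_seed: int = 0
    stylizer: str = "statistical"
    # model
    model_strategy: str = "dense_concat"
    feature_maps: list[tuple[int, int, int]] | None = None
    use_cbam: bool = True
    branch_dense_units: int = 32
    cbam_reduction: int = 2
    backbone_width: int = 8
    model_seed: int = 0
    # training
    phase1_epochs: int = 2
    phase2_epochs: int = 20
    batch_size: int = 16
    lr_phase1: float = 1e-3
    lr_phase2: float = 1e-3
    train_seed: int = 0
    # interpretability
    explain_method: str = "gradcampp"
    # output
    out_dir: str = "runs/latest"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _augment(train: LabeledDataset, cfg: PipelineConfig):
    """Apply the configured imbalance treatment to the training split."""
    plan_dict = None
    class_weight_map = None
    if cfg.strategy in ("rotation", "style", "pixel"):
        train = balance.augment_rotations(train, cfg.majority_class)
    if cfg.strategy == "style":
        plan = balance.compute_allocation(train.counts, cfg.majority_class)
        backend = styletransfer.get_backend(cfg.stylizer)
        train = styletransfer.execute_plan(train, plan, backend,
                                          seed=cfg.augment_seed)
        plan_dict = plan.to_dict()
    elif cfg.strategy == "pixel":
        train = balance.perturbation_upsample(train, cfg.majority_class,
                                              seed=cfg.augment_seed)
    elif cfg.strategy == "class_weight":
        class_weight_map = balance.class_weights(train.counts)
    elif cfg.strategy not in ("none", "rotation"):
        raise ValueError(f"unknown imbalance strategy {cfg.strategy!r}")
    return train, plan_dict, class_weight_map


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk).

    Any stage failure raises :class:`PipelineError` naming the stage; the
    partial manifest collected so far is persisted first.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "dermofuse_version": __version__,
        "python": platform.python_version(),
        "config": asdict(cfg),
        "stages": {},
    }

    def persist():
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    def stage(name):
        def deco(fn):
            try:
                result = fn()
            except Exception as exc:
                manifest["stages"][name] = {"status": "failed", "error": str(exc)}
                persist()
                raise PipelineError(name, exc) from exc
            manifest["stages"][name] = {"status": "ok", **(result or {})}
            persist()
        return deco

    state: dict = {}

    @stage("prepare")
    def _prepare():
        if cfg.image_dir is not None and cfg.metadata is not None:
            ds = dataio.load_dataset(cfg.image_dir, cfg.metadata,
                                     tuple(cfg.classes))
        elif cfg.synthetic_scale is not None:
            counts = scaled_counts(cfg.synthetic_scale)
            if cfg.synthetic_classes is not None:
                counts = {c: counts[c] for c in cfg.synthetic_classes}
            spec = SyntheticSpec(class_counts=counts,
                                 image_size=(cfg.target_h, cfg.target_w),
                                 seed=cfg.synthetic_seed)
            ds = generate_dataset(spec)
        else:
            raise ValueError("config names neither an image dir nor a "
                             "synthetic scale")
        ds = dataio.preprocess_dataset(ds, cfg.target_h, cfg.target_w)
        splits = dataio.stratified_split(ds, tuple(cfg.split_ratio),
                                         seed=cfg.split_seed)
        dataio.write_manifest(splits, out / "splits.csv")
        state["splits"] = splits
        return {"counts": ds.counts,
                "split_sizes": [len(p) for p in splits]}

    @stage("augment")
    def _augment_stage():
        splits: DatasetSplits = state["splits"]
        train, plan_dict, cw = _augment(splits.train, cfg)
        state["train"] = train
        state["class_weight_map"] = cw
        if plan_dict is not None:
            with open(out / "augmentation_plan.json", "w") as fh:
                json.dump(plan_dict, fh, indent=2)
        rows = [{"image_id": r.id, "label": r.label,
                 "provenance": r.provenance.value, "source_id": r.source_id}
                for r in train.records]
        pd.DataFrame(rows).to_csv(out / "augmentation_manifest.csv",
                                  index=False)
        return {"strategy": cfg.strategy, "train_counts": train.counts,
                "plan": plan_dict,
                "class_weights": cw}

    @stage("train")
    def _train():
        splits: DatasetSplits = state["splits"]
        train: LabeledDataset = state["train"]
        x_train, y_train = train.to_arrays()
        x_valid, y_valid = splits.valid.to_arrays()
        input_shape = x_train.shape[1:]
        maps = cfg.feature_maps
        if maps is None:
            mh = max(1, -(-cfg.target_h // 8))
            mw = max(1, -(-cfg.target_w // 8))
            maps = [(mh, mw, 8), (mh, mw, 6), (mh, mw, 8)]
        specs = [tiny_backbone(cfg.model_seed + i, tuple(m),
                               width=cfg.backbone_width, name=f"branch{i}")
                 for i, m in enumerate(maps)]
        fcfg = FusionConfig(strategy=cfg.model_strategy, backbones=specs,
                            n_classes=len(train.classes),
                            use_cbam=cfg.use_cbam,
                            branch_dense_units=cfg.branch_dense_units,
                            cbam_reduction=cfg.cbam_reduction,
                            seed=cfg.model_seed)
        model = FusionModel(fcfg, input_shape)
        cw = state.get("class_weight_map")
        weights = None
        if cw is not None:
            index = {c: i for i, c in enumerate(train.classes)}
            weights = {index[k]: v for k, v in cw.items()}
        tcfg = TrainConfig(phase1_epochs=cfg.phase1_epochs,
                           phase2_epochs=cfg.phase2_epochs,
                           batch_size=cfg.batch_size,
                           lr_phase1=cfg.lr_phase1, lr_phase2=cfg.lr_phase2,
                           class_weights=weights, seed=cfg.train_seed)
        history = two_phase_train(model, x_train, y_train,
                                  x_valid, y_valid, tcfg)
        state["model"] = model
        save_model(model, out / "model.npz")
        pd.DataFrame({k: history[k] for k in
                      ("phase", "epoch", "train_loss", "train_acc",
                       "valid_acc")}).to_csv(out / "history.csv", index=False)
        with open(out / "model_summary.txt", "w") as fh:
            fh.write(model.summary() + "\n")
        return {"n_outputs": model.n_outputs,
                "final_train_acc": history["train_acc"][-1],
                "final_valid_acc": history["valid_acc"][-1]}

    @stage("evaluate")
    def _evaluate():
        splits: DatasetSplits = state["splits"]
        model: FusionModel = state["model"]
        x_test, y_test = splits.test.to_arrays()
        classes = splits.test.classes
        present = [c for c in classes]
        scores = model.predict_proba(x_test)
        y_true = np.array([classes[i] for i in y_test])
        y_pred = np.array([classes[i] for i in scores.argmax(axis=1)])
        report = evaluate_predictions(y_true, y_pred, scores, tuple(present))
        state["report"] = report
        with open(out / "metrics.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)
        report.per_class.to_csv(out / "metrics_per_class.csv")
        return {"overall_accuracy": report.overall_accuracy,
                "weighted": report.weighted}

    @stage("explain")
    def _explain():
        splits: DatasetSplits = state["splits"]
        model: FusionModel = state["model"]
        if len(splits.test) == 0:
            return {"skipped": "empty test split"}
        rec = splits.test.records[0]
        probs = model.predict_proba(rec.pixels[None])[0]
        cls_idx = int(probs.argmax())
        fn = grad_cam_pp if cfg.explain_method == "gradcampp" else grad_cam
        branch = model.branches[0].name
        smap = fn(model, rec.pixels, SaliencyTarget(branch, cls_idx))
        np.savetxt(out / "saliency.txt", smap.heatmap, fmt="%.6f")
        overlay = saliency_overlay(rec.pixels, smap)
        from PIL import Image
        Image.fromarray((overlay * 255).astype(np.uint8)).save(
            out / "saliency_overlay.png")
        return {"image_id": rec.id, "branch": branch,
                "class_index": cls_idx, "all_zero": smap.all_zero}

    persist()
    return manifest
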