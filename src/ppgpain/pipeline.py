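"""End-to-end orchestration: signal -> beats -> PPI -> features -> screening
-> classifiers -> subject-wise cross-validated evaluation.

The stages and their defaults mirror the reference processing chain (8 Hz /
0.5 Hz Butterworth filters, 111/667 ms moving-average windows, threshold
offset 0.02, 5-min windows at 1-min steps, +/- 2.5 MAD outlier screen, 50-bag
ensembles, 6-fold subject-wise CV for 2 classes and 5-fold for 4).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import beatdetect, ensemble, evaluate, features, models, postfeat, ppi, synth
from .features import FEATURE_NAMES, META_COLUMNS, WindowSpec
from .preprocess import PPGRecord, preprocess_record
from .study import nrs_to_four_class

__all__ = ["PipelineConfig", "features_for_record", "cohort_features",
           "label_rows", "run_cv", "run_pipeline"]


@dataclass
class SynthBlock:
    n_subjects: int = 20
    duration_s: float = 840.0
    noise_sd: float = 0.02
    ectopic_rate_per_min: float = 0.5
    mode: str = "two_class"  # or "four_class"


@dataclass
class FilterBlock:
    lowpass_hz: float = 8.0
    highpass_hz: float = 0.5
    order: int = 2


@dataclass
class ThresholdBlock:
    w1_ms: float = 111.0
    w2_ms: float = 667.0
    beta: float = 0.02


@dataclass
class WindowBlock:
    window_s: float = 300.0
    step_s: float = 60.0


@dataclass
class ScreeningBlock:
    alpha: float = 0.05
    mode: str = "two_class"


@dataclass
class ModelBlock:
    kind: str = "dbn"  # dbn | mlpnn | svm
    hidden: tuple[int, ...] = (6, 6)
    epochs_pretrain: int = 20
    epochs_finetune: int = 800
    batch_size: int = 104
    learning_rate: float = 0.08
    momentum: float = 0.9
    weight_decay: float = 0.00029
    svm_gamma: float = 0.05
    svm_C: float = 1.0


@dataclass
class EnsembleBlock:
    n_bags: int = 50


@dataclass
class CVBlock:
    k: int = 6
    max_folds: int | None = None  # run only the first folds when set
    auc_bootstrap: int = 300


@dataclass
class PipelineConfig:
    """All pipeline parameters with reference defaults."""

    synth: SynthBlock = field(default_factory=SynthBlock)
    filters: FilterBlock = field(default_factory=FilterBlock)
    thresholds: ThresholdBlock = field(default_factory=ThresholdBlock)
    window: WindowBlock = field(default_factory=WindowBlock)
    mad_k: float = 2.5
    screening: ScreeningBlock = field(default_factory=ScreeningBlock)
    model: ModelBlock = field(default_factory=ModelBlock)
    ensemble: EnsembleBlock = field(default_factory=EnsembleBlock)
    cv: CVBlock = field(default_factory=CVBlock)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, blob: dict) -> "PipelineConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in blob:
                continue
            v = blob[f.name]
            if dataclasses.is_dataclass(f.type) or f.name in (
                "synth", "filters", "thresholds", "window", "screening",
                "model", "ensemble", "cv",
            ):
                sub_cls = {
                    "synth": SynthBlock, "filters": FilterBlock,
                    "thresholds": ThresholdBlock, "window": WindowBlock,
                    "screening": ScreeningBlock, "model": ModelBlock,
                    "ensemble": EnsembleBlock, "cv": CVBlock,
                }[f.name]
                sub = sub_cls(**v)
                if f.name == "model" and isinstance(sub.hidden, list):
                    sub.hidden = tuple(sub.hidden)
                kwargs[f.name] = sub
            else:
                kwargs[f.name] = v
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def features_for_record(
    record: PPGRecord, config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Run filtering, beat detection, PPI correction and feature extraction."""
    cfg = config or PipelineConfig()
    filtered = preprocess_record(record, cfg.filters.lowpass_hz,
                                 cfg.filters.highpass_hz, cfg.filters.order)
    params = beatdetect.ThresholdParams(cfg.thresholds.w1_ms, cfg.thresholds.w2_ms,
                                        cfg.thresholds.beta)
    beats = beatdetect.detect_beats(filtered, params)
    if beats.n_beats < 2:
        warnings.warn(f"record {record.subject_id}/{record.period}: "
                      f"{beats.n_beats} beats detected; no features")
        return pd.DataFrame(columns=list(FEATURE_NAMES) + list(META_COLUMNS))
    series = ppi.correct_ppi(beats)
    spec = WindowSpec(cfg.window.window_s, cfg.window.step_s)
    return features.extract_features(record, filtered, beats, series, spec)


def cohort_features(records, config: PipelineConfig | None = None) -> pd.DataFrame:
    frames = [features_for_record(
        r.record if isinstance(r, synth.SynthRecord) else r, config)
        for r in records]
    return pd.concat(frames, ignore_index=True)


def label_rows(matrix: pd.DataFrame, mode: str = "two_class") -> pd.Series:
    """Class label per feature row from the period/NRS metadata."""
    if mode == "two_class":
        return matrix["period"].map(
            {"preoperative": "N", "postoperative": "P"}).rename("label")
    if mode == "four_class":
        return pd.Series(
            np.where(matrix["period"] == "preoperative", "none",
                     [nrs_to_four_class(int(v)) for v in matrix["nrs"]]),
            index=matrix.index, name="label")
    raise ValueError(f"unknown labelling mode {mode!r}")


def _net_config(block: ModelBlock, n_features: int, n_classes: int,
                seed: int) -> models.NetConfig:
    return models.NetConfig(
        layer_sizes=(n_features, *block.hidden, n_classes),
        lr_weights=block.learning_rate, lr_vbias=block.learning_rate,
        lr_hbias=block.learning_rate, batch_size=block.batch_size,
        momentum=block.momentum, weight_decay=block.weight_decay,
        epochs_pretrain=block.epochs_pretrain,
        epochs_finetune=block.epochs_finetune, seed=seed)


def _trainer_for(cfg: PipelineConfig, n_features: int, n_classes: int, seed: int):
    if cfg.model.kind == "svm":
        return models.make_trainer(
            "svm", models.SVMConfig(gamma=cfg.model.svm_gamma, C=cfg.model.svm_C))
    return models.make_trainer(
        cfg.model.kind, _net_config(cfg.model, n_features, n_classes, seed))


def run_cv(
    matrix: pd.DataFrame,
    config: PipelineConfig | None = None,
    positive: object = "P",
) -> dict:
    """MAD screen, feature screening, normalization and subject-wise k-fold CV.

    Evaluates the single model, the full bag and the hill-climbing-selected
    bag per fold; windows are the evaluation unit. Returns a report dict with
    per-fold and mean accuracies, confusion counts and AUC statistics
    (bootstrap over the selective model's test scores).
    """
    cfg = config or PipelineConfig()
    mode = cfg.screening.mode
    matrix, mad_report = postfeat.mad_filter(matrix, k=cfg.mad_k)
    labels = label_rows(matrix, mode)
    retained, screen_report = postfeat.screen_features(
        matrix, labels, mode=mode, alpha=cfg.screening.alpha)
    if not retained:
        raise ValueError("screening retained no features")

    subjects = sorted(matrix["subject_id"].unique())
    plan = evaluate.subject_kfold(subjects, cfg.cv.k, seed=cfg.seed)
    n_classes = labels.nunique()

    folds_out = []
    folds = plan.folds if cfg.cv.max_folds is None else plan.folds[:cfg.cv.max_folds]
    for f_idx, fold in enumerate(folds):
        roles = {
            "train": matrix["subject_id"].isin(fold.train),
            "validation": matrix["subject_id"].isin(fold.validation),
            "test": matrix["subject_id"].isin(fold.test),
        }
        tr, va, te = (matrix.loc[roles[r]] for r in ("train", "validation", "test"))
        tr_n, va_n, te_n = postfeat.minmax_fit_apply(
            tr, va, te, feature_names=tuple(retained))
        Xtr, ytr = tr_n[retained].to_numpy(float), labels[tr.index].to_numpy()
        Xva, yva = va_n[retained].to_numpy(float), labels[va.index].to_numpy()
        Xte, yte = te_n[retained].to_numpy(float), labels[te.index].to_numpy()

        fold_seed = cfg.seed * 1000 + f_idx
        trainer = _trainer_for(cfg, len(retained), n_classes, fold_seed)
        single = trainer(Xtr, ytr, fold_seed)
        bag = ensemble.bag_train(trainer, Xtr, ytr,
                                 n_bags=cfg.ensemble.n_bags, seed=fold_seed)
        single_val_acc = float(np.mean(single.predict(Xva) == yva))
        ensemble.hc_select(bag, Xva, yva)

        out = {"fold": f_idx, "n_test_rows": int(len(yte)),
               "single_val_accuracy": 100.0 * single_val_acc}
        sel_val_preds = bag.predict(Xva)
        out["selective_val_accuracy"] = 100.0 * float(np.mean(sel_val_preds == yva))
        out["n_selected"] = len(bag.selected)

        for variant, predict_fn, score_fn in (
            ("single", single.predict, single.predict_scores),
            ("bagging", _all_bag_predict(bag), _all_bag_scores(bag)),
            ("selective", bag.predict, bag.predict_scores),
        ):
            y_pred = predict_fn(Xte)
            rep = evaluate.confusion_and_accuracy(yte, y_pred, positive=positive)
            out[variant] = rep.to_dict()
            if n_classes == 2:
                classes = sorted(pd.unique(labels))
                pos_col = classes.index(positive)
                scores = score_fn(Xte)[:, pos_col]
                _, auc = evaluate.roc_auc(scores, yte, positive=positive)
                out[variant]["auc"] = auc
                if variant == "selective" and cfg.cv.auc_bootstrap > 1:
                    samples = evaluate.bootstrap_auc(
                        scores, yte, n_boot=cfg.cv.auc_bootstrap, seed=fold_seed,
                        positive=positive)
                    out[variant]["auc_stats"] = evaluate.auc_vs_half_ttest(samples)
        folds_out.append(out)

    report = {
        "mode": mode,
        "model_kind": cfg.model.kind,
        "n_rows": int(len(matrix)),
        "n_rows_removed_by_mad": int(mad_report["row"].nunique()) if len(mad_report) else 0,
        "retained_features": retained,
        "folds": folds_out,
    }
    for variant in ("single", "bagging", "selective"):
        report[f"{variant}_accuracy_mean"] = float(
            np.mean([f[variant]["accuracy"] for f in folds_out]))
        if all("auc" in f[variant] for f in folds_out):
            report[f"{variant}_auc_mean"] = float(
                np.mean([f[variant]["auc"] for f in folds_out]))
    report["screening"] = screen_report.to_dict(orient="records")
    return report


def _all_bag_predict(bag: ensemble.EnsembleModel):
    def fn(X):
        saved, bag.selected = bag.selected, None
        try:
            return bag.predict(X)
        finally:
            bag.selected = saved
    return fn


def _all_bag_scores(bag: ensemble.EnsembleModel):
    def fn(X):
        saved, bag.selected = bag.selected, None
        try:
            return bag.predict_scores(X)
        finally:
            bag.selected = saved
    return fn


def run_pipeline(
    config: PipelineConfig | None = None,
    outdir: str | Path = "ppgpain_run",
    records=None,
    force: bool = False,
) -> dict:
    """Run the full pipeline, caching stage outputs under ``outdir``.

    Without ``records`` a synthetic cohort is generated per the config. A
    cached ``features.csv`` (same resolved config) is reused unless ``force``.
    Writes features.csv, screening_report.csv, eval_report.json and the
    resolved config as config.yaml.
    """
    cfg = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")

    feat_path = outdir / "features.csv"
    if feat_path.exists() and not force and records is None:
        matrix = pd.read_csv(feat_path)
    else:
        if records is None:
            specs = (synth.DEFAULT_TWO_CLASS_SPECS if cfg.synth.mode == "two_class"
                     else synth.DEFAULT_FOUR_CLASS_SPECS)
            base = synth.SynthConfig(duration_s=cfg.synth.duration_s,
                                     noise_sd=cfg.synth.noise_sd,
                                     ectopic_rate_per_min=cfg.synth.ectopic_rate_per_min)
            records = synth.generate_cohort(cfg.synth.n_subjects, specs,
                                            seed=cfg.seed, base_config=base)
        matrix = cohort_features(records, cfg)
        matrix.to_csv(feat_path, index=False)

    report = run_cv(matrix, cfg)
    pd.DataFrame(report.pop("screening")).to_csv(
        outdir / "screening_report.csv", index=False)
    with open(outdir / "eval_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
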