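"""Experiment orchestration: classification studies and the XAI pipeline.

Four classification experiments mirror the study design:

1. severity staging on insole-style force windows (4 classes);
2. 5-class walking-manner classification across all subjects
   (normal gait vs four dual tasks);
3. the same 5 classes within each subject separately;
4. binary normal-vs-dual-task classification per task group under four
   split regimes (test on 1 / 2 / 4 held-out subjects / random 70-10-20).

``run_xai_pipeline`` chains relevance maps, MoRF/random perturbation
curves, model and method selection, spatial averaging, cycle segmentation
and per-class gait-event histograms into one report.

All functions are deterministic under their seed and return plain dict
reports (JSON-serializable apart from embedded numpy arrays); pass
``out_dir`` to also write JSON/CSV artifacts.
"""
from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import grf_io
from .data import GaitDataset
from .graph import LSTMClassifier, TrainedModel, TrainingConfig, build_architecture, train
from .interpret import (
    LEFT_FOOT_CHANNELS, assign_relevance_events, event_histogram, segment_cycles,
    spatial_average,
)
from .lrp import explain_batch, make_ruleset
from .metrics import confusion, scores
from .perturb import morf_curve, select_model, select_xai_method, tile_regions
from .phase import GaitPhaseModel
from .synthetic import (
    COGNITIVE_PLY_SIZES, GeneratorConfig, generate_cognitive_dataset, generate_pd_dataset,
)

logger = logging.getLogger("gaitxai")

__all__ = [
    "ExperimentConfig", "prepare_pd_dataset", "prepare_cognitive_dataset",
    "run_experiment_1", "run_experiment_2", "run_experiment_3",
    "run_experiment_4", "run_xai_pipeline", "per_class_event_analysis",
    "cognitive_reference_channels",
]


@dataclass
class ExperimentConfig:
    """Settings shared by the experiment runners."""

    experiment: int = 1
    architectures: List[str] = field(default_factory=lambda: ["parallel"])
    arch_hyperparams: Dict = field(default_factory=dict)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    generator: Optional[GeneratorConfig] = None
    split_fractions: Tuple[float, float, float] = (0.6, 0.2, 0.2)
    split_mode: str = "window"
    rules: List[str] = field(default_factory=lambda: ["lrp_spf"])
    n_steps: int = 30
    region_shape: Tuple[int, int] = (7, 7)
    #: replacement-noise (mean, sd); the low default sd effectively
    #: deletes the region's signal rather than injecting structure
    morf_noise: Tuple[float, float] = (0.0, 0.001)
    early_window: int = 15
    include_baselines: bool = False
    include_lstm: bool = False
    seed: int = 0
    out_dir: Optional[str] = None

    def __post_init__(self):
        if self.experiment == 4 and self.split_mode == "window":
            # experiment 4 is defined by leave-subjects-out transfer
            self.split_mode = "subject"

    def hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# data preparation

def easy_pd_config(n_subjects: int = 10, trials: int = 20, seed: int = 0) -> GeneratorConfig:
    """Easy-regime study conditions for the end-to-end validation runs.

    Subject-level nuisance is switched off (single body-weight factor,
    common mean cadence) so the planted event signatures are the only
    class information; see the methods note for why this matters for the
    event-recovery check.
    """
    return GeneratorConfig.pd(
        n_subjects=n_subjects,
        trials_per_subject_per_class=trials,
        subject_weight_scale_range=(1.0, 1.0),
        subject_cadence_sd=0.0,
        seed=seed,
    )


def run_easy_pd_study(
    seed: int = 0,
    n_subjects: int = 10,
    trials: int = 20,
    epochs: int = 30,
    arch: str = "parallel",
    arch_hyperparams: Optional[Dict] = None,
) -> Tuple[GaitDataset, TrainedModel]:
    """Generate the easy-regime severity dataset and train the CNN on it.

    The shared entry point for the end-to-end validation runs: ~800
    windows (10 subjects x 4 classes x 20 windows), a small parallel CNN
    (filter counts halved, 32-unit dense head), 30 epochs of Adam at
    batch 50 in single precision — sizes at which the easy-regime
    problem is comfortably learnable in a few minutes on one CPU.
    """
    dataset = prepare_pd_dataset(easy_pd_config(n_subjects, trials), seed=seed)
    hp = {"scale": 0.5, "dense_width": 32}
    hp.update(arch_hyperparams or {})
    graph = build_architecture(arch, (dataset.window_len, dataset.n_channels),
                               len(dataset.classes), hp)
    model = train(graph, dataset,
                  TrainingConfig(epochs=epochs, batch_size=50, seed=seed,
                                 dtype="float32"))
    return dataset, model


def prepare_pd_dataset(
    config: Optional[GeneratorConfig] = None,
    seed: int = 0,
    fractions: Tuple[float, float, float] = (0.6, 0.2, 0.2),
    split_mode: str = "window",
) -> GaitDataset:
    """Generate, standardize and split a synthetic severity dataset."""
    config = config or GeneratorConfig.pd(n_subjects=10, trials_per_subject_per_class=20)
    ds = generate_pd_dataset(config, seed=seed)
    ds, _ = grf_io.standardize(ds)
    ds = grf_io.split(ds, fractions, seed=seed, mode=split_mode)
    logger.info("pd dataset: %s samples of %sx%s", len(ds), ds.window_len, ds.n_channels)
    return ds


def prepare_cognitive_dataset(
    config: Optional[GeneratorConfig] = None,
    seed: int = 0,
    fractions: Tuple[float, float, float] = (0.6, 0.2, 0.2),
    split_mode: str = "window",
    test_subjects: Optional[Sequence[str]] = None,
) -> GaitDataset:
    """Generate, standardize and split a synthetic dual-task dataset."""
    config = config or GeneratorConfig.cognitive()
    ds = generate_cognitive_dataset(config, seed=seed)
    ds, _ = grf_io.standardize(ds)
    ds = grf_io.split(ds, fractions, seed=seed, mode=split_mode, test_subjects=test_subjects)
    return ds


# ---------------------------------------------------------------------------
# shared helpers

def _fit_cnn(name: str, dataset: GaitDataset, cfg: ExperimentConfig) -> TrainedModel:
    graph = build_architecture(
        name, (dataset.window_len, dataset.n_channels), len(dataset.classes),
        cfg.arch_hyperparams,
    )
    return train(graph, dataset, cfg.training)


def _evaluate(model, dataset: GaitDataset, split: str = "test") -> Dict:
    sub = dataset.split_subset(split)
    y_pred = model.predict(sub.values)
    cm = confusion(sub.labels.tolist(), y_pred.tolist(), dataset.classes)
    sc = scores(cm)
    return {"confusion": cm.counts.tolist(), "classes": list(map(str, dataset.classes)),
            "macro_f1": sc["macro"]["f1"], "accuracy": sc["accuracy"],
            "per_class": {str(k): v for k, v in sc["per_class"].items()}}


def _baseline_models(cfg: ExperimentConfig, n_train: int):
    from sklearn.gaussian_process import GaussianProcessClassifier
    from sklearn.linear_model import SGDClassifier
    from sklearn.neighbors import KNeighborsClassifier

    out = {
        "sgd": SGDClassifier(loss="log_loss", random_state=cfg.seed),
        "knn": KNeighborsClassifier(n_neighbors=5, metric="euclidean"),
    }
    if n_train <= 2000:  # GPC is cubic; keep it to small problems
        out["gpc"] = GaussianProcessClassifier(random_state=cfg.seed)
    return out


def _fit_baselines(dataset: GaitDataset, cfg: ExperimentConfig) -> Dict[str, Dict]:
    tr = dataset.split_subset("train")
    te = dataset.split_subset("test")
    Xtr = tr.values.reshape(len(tr), -1)
    Xte = te.values.reshape(len(te), -1)
    ytr = tr.labels.astype(str)
    reports = {}
    for name, clf in _baseline_models(cfg, len(tr)).items():
        if name == "gpc" and len(tr) > 500:
            rng = np.random.default_rng(cfg.seed)
            idx = rng.choice(len(tr), 500, replace=False)
            clf.fit(Xtr[idx], ytr[idx])
        else:
            clf.fit(Xtr, ytr)
        y_pred = clf.predict(Xte)
        cm = confusion(te.labels.astype(str).tolist(), y_pred.tolist(),
                       [str(c) for c in dataset.classes])
        reports[name] = {"macro_f1": scores(cm)["macro"]["f1"],
                         "accuracy": scores(cm)["accuracy"]}
    return reports


def _write_report(report: Dict, cfg: ExperimentConfig, stem: str) -> None:
    if cfg.out_dir is None:
        return
    os.makedirs(cfg.out_dir, exist_ok=True)
    path = os.path.join(cfg.out_dir, f"{stem}.json")
    with open(path, "w") as f:
        json.dump(report, f, indent=2, default=_jsonable)


def _jsonable(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    return str(o)


# ---------------------------------------------------------------------------
# experiments

def run_experiment_1(cfg: ExperimentConfig, dataset: Optional[GaitDataset] = None) -> Dict:
    """Severity staging: train CNNs (and baselines) on 4-class force windows."""
    if dataset is None:
        gen = cfg.generator or GeneratorConfig.pd(n_subjects=10, trials_per_subject_per_class=20)
        if gen.scenario != "pd":
            raise ValueError("experiment 1 requires pd-scenario data")
        dataset = prepare_pd_dataset(gen, cfg.seed, cfg.split_fractions, cfg.split_mode)
    if any(l is None for l in dataset.labels):
        raise ValueError("dataset has unlabeled samples; severity labels required")
    report = {"experiment": 1, "config_hash": cfg.hash(), "seed": cfg.seed,
              "dataset_tag": dataset.dataset_tag, "models": {}}
    models = {}
    for arch in cfg.architectures:
        model = _fit_cnn(arch, dataset, cfg)
        models[arch] = model
        report["models"][arch] = _evaluate(model, dataset)
        logger.info("experiment 1 %s macro-F1 %.3f", arch, report["models"][arch]["macro_f1"])
    if cfg.include_lstm:
        lstm = LSTMClassifier(n_units=32, time_stride=5).fit(dataset, cfg.training)
        te = dataset.split_subset("test")
        cm = confusion(te.labels.tolist(), lstm.predict(te.values).tolist(), dataset.classes)
        report["models"]["lstm"] = {"macro_f1": scores(cm)["macro"]["f1"],
                                    "accuracy": scores(cm)["accuracy"]}
    if cfg.include_baselines:
        report["models"].update(_fit_baselines(dataset, cfg))
    report["_trained"] = models
    _write_report({k: v for k, v in report.items() if k != "_trained"}, cfg, "experiment1")
    return report


def run_experiment_2(cfg: ExperimentConfig, dataset: Optional[GaitDataset] = None) -> Dict:
    """5-class walking-manner classification across all subjects.

    The report separates the normal-gait true-positive rate from the four
    dual-task rates (the headline contrast: normal gait is predicted far
    better than the subject-varying dual tasks).
    """
    if dataset is None:
        dataset = prepare_cognitive_dataset(cfg.generator, cfg.seed, cfg.split_fractions,
                                            cfg.split_mode)
    arch = cfg.architectures[0]
    model = _fit_cnn(arch, dataset, cfg)
    ev = _evaluate(model, dataset)
    tp_rates = {str(c): ev["per_class"][str(c)]["recall"] for c in dataset.classes}
    report = {
        "experiment": 2, "config_hash": cfg.hash(), "seed": cfg.seed,
        "model": arch, "evaluation": ev,
        "normal_tp_rate": tp_rates[str(dataset.classes[0])],
        "dual_task_tp_rates": {k: v for k, v in tp_rates.items()
                               if k != str(dataset.classes[0])},
        "_trained": {arch: model},
    }
    _write_report({k: v for k, v in report.items() if k != "_trained"}, cfg, "experiment2")
    return report


def run_experiment_3(cfg: ExperimentConfig, dataset: Optional[GaitDataset] = None) -> Dict:
    """Per-subject 5-class classification; one report row per subject."""
    if dataset is None:
        dataset = prepare_cognitive_dataset(cfg.generator, cfg.seed, cfg.split_fractions,
                                            "window")
    rows = {}
    arch = cfg.architectures[0]
    for subject in sorted(set(map(str, dataset.subject_ids))):
        sub = dataset.subset(np.array([str(s) == subject for s in dataset.subject_ids]))
        counts = {c: int(np.sum(sub.labels == c)) for c in sub.classes}
        if min(counts.values()) < 2:
            logger.warning("subject %s skipped: insufficient per-class samples %s",
                           subject, counts)
            continue
        sub = grf_io.split(sub, cfg.split_fractions, seed=cfg.seed, mode="window")
        model = _fit_cnn(arch, sub, cfg)
        rows[subject] = _evaluate(model, sub)["macro_f1"]
    report = {"experiment": 3, "config_hash": cfg.hash(), "seed": cfg.seed,
              "model": arch, "per_subject_f1": rows}
    _write_report(report, cfg, "experiment3")
    return report


def run_experiment_4(cfg: ExperimentConfig, dataset: Optional[GaitDataset] = None) -> Dict:
    """Binary normal-vs-dual-task classification per group and split regime.

    For each dual-task class the samples of the normal class and that
    class form one data group; each group is evaluated under testing on 1,
    2 and 4 held-out subjects plus a random 70/10/20 split, giving the
    4 x 4 F1 grid.
    """
    if dataset is None:
        dataset = prepare_cognitive_dataset(cfg.generator, cfg.seed, (0.7, 0.1, 0.2),
                                            "window")
    normal = dataset.classes[0]
    subjects = sorted(set(map(str, dataset.subject_ids)))
    rng = np.random.default_rng(cfg.seed)
    arch = cfg.architectures[0]
    grid: Dict[str, Dict[str, float]] = {}
    for dual in dataset.classes[1:]:
        mask = np.array([l in (normal, dual) for l in dataset.labels])
        pair = dataset.subset(mask)
        pair.classes = [normal, dual]
        row: Dict[str, float] = {}
        for regime, n_test in [("1 subject", 1), ("2 subjects", 2), ("4 subjects", 4)]:
            held = list(rng.choice(subjects, n_test, replace=False))
            split_ds = grf_io.split(pair, (0.85, 0.15, 0.0), seed=cfg.seed,
                                    test_subjects=held)
            model = _fit_cnn(arch, split_ds, cfg)
            row[regime] = _evaluate(model, split_ds)["macro_f1"]
        random_ds = grf_io.split(pair, (0.7, 0.1, 0.2), seed=cfg.seed, mode="window")
        model = _fit_cnn(arch, random_ds, cfg)
        row["all subjects"] = _evaluate(model, random_ds)["macro_f1"]
        grid[str(dual)] = row
    report = {"experiment": 4, "config_hash": cfg.hash(), "seed": cfg.seed,
              "model": arch, "f1_grid": grid}
    _write_report(report, cfg, "experiment4")
    return report


# ---------------------------------------------------------------------------
# interpretation pipeline

def cognitive_reference_channels(half_width: float = 0.09) -> List[int]:
    """Channels of the lengthwise optical ply dominated by the left foot.

    Used as the reference-foot proxy for cycle segmentation on 116-channel
    windows (the insole layout exposes the left foot directly; the floor
    sensor does not).
    """
    pos = np.linspace(0.0, 1.0, COGNITIVE_PLY_SIZES[0])
    return [int(i) for i in np.nonzero(np.abs(pos - 0.38) < half_width)[0]]


def per_class_event_analysis(
    model: TrainedModel,
    dataset: GaitDataset,
    rule: str = "deep_taylor",
    phase_model: Optional[GaitPhaseModel] = None,
    segmentation_channels: Optional[Sequence[int]] = None,
    split: str = "test",
    top_k: int = 1,
    max_per_class: Optional[int] = None,
) -> Dict:
    """Assign each true-positive test window's top relevance peak to an event.

    For every class: restrict to true-positive predictions, explain them
    toward their class, spatially average the relevance, segment cycles on
    the reference-foot signal SA, and label the strongest relevance peak
    per window with its gait event. Returns per-class assignments,
    normalized event histograms and the modal event.
    """
    phase_model = phase_model or GaitPhaseModel()
    sub = dataset.split_subset(split) if split else dataset
    if segmentation_channels is None:
        segmentation_channels = (
            LEFT_FOOT_CHANNELS if sub.n_channels == 18 else cognitive_reference_channels()
        )
    y_pred = model.predict(sub.values)
    assignments: Dict[object, List] = {}
    for cls in dataset.classes:
        tp = np.array([p == l == cls for p, l in zip(y_pred, sub.labels)])
        idx = np.nonzero(tp)[0]
        if max_per_class is not None:
            idx = idx[:max_per_class]
        if idx.size == 0:
            continue
        rmap = explain_batch(model, sub.values[idx], cls, rule)
        per_window = []
        for j, i in enumerate(idx):
            sig_sa = spatial_average(sub.values[i], "signal", segmentation_channels)
            seg = segment_cycles(sig_sa, sub.sample_rate)
            rel_sa = spatial_average(rmap.scores[j], "relevance")
            per_window.append(assign_relevance_events(rel_sa, seg, phase_model, top_k))
        assignments[cls] = per_window
    hist = event_histogram(assignments)
    modal = {cls: max(h, key=h.get) for cls, h in hist.items()}
    return {"assignments": assignments, "histograms": hist, "modal_events": modal,
            "rule": rule}


def run_xai_pipeline(
    cfg: ExperimentConfig,
    models: Dict[str, TrainedModel],
    dataset: GaitDataset,
    n_random_seeds: int = 3,
) -> Dict:
    """Relevance maps, perturbation curves, selections and event report.

    ``models`` maps architecture name -> trained model. The best model is
    chosen by the steepest early MoRF decay (using the first configured
    rule); the best rule is chosen for that model against the random-
    removal baseline; the event analysis runs with the winning pair.
    """
    te = dataset.split_subset("test")
    grid = tile_regions((dataset.window_len, dataset.n_channels), cfg.region_shape)
    labels = te.labels.tolist()
    pred_map: Dict[str, np.ndarray] = {}

    def maps_for(model, rule):
        out = np.zeros_like(te.values)
        y_pred = model.predict(te.values)
        for cls in dataset.classes:
            idx = np.nonzero(y_pred == cls)[0]
            if idx.size:
                out[idx] = explain_batch(model, te.values[idx], cls, rule).scores
        return out

    primary_rule = cfg.rules[0]
    model_curves = []
    for name, model in models.items():
        maps = maps_for(model, primary_rule)
        res = morf_curve(model, te.values, labels, maps, grid, cfg.n_steps,
                         "morf", noise=cfg.morf_noise, seed=cfg.seed)
        model_curves.append(((name, model), res))
    (best_name, best_model) = select_model(model_curves, cfg.early_window)
    report = {
        "config_hash": cfg.hash(), "seed": cfg.seed,
        "model_curves": {n: r.step_accuracies.tolist() for (n, _), r in model_curves},
        "selected_model": best_name,
    }

    rand_curves = [
        morf_curve(best_model, te.values, labels, None, grid, cfg.n_steps,
                   "random", noise=cfg.morf_noise, seed=cfg.seed + 1000 + i)
        for i in range(n_random_seeds)
    ]
    rand_mean = np.mean([r.step_accuracies for r in rand_curves], axis=0)
    baseline = rand_curves[0]
    method_curves = {}
    for rule in cfg.rules:
        maps = maps_for(best_model, rule)
        method_curves[rule] = morf_curve(best_model, te.values, labels, maps, grid,
                                         cfg.n_steps, "morf", noise=cfg.morf_noise,
                                         seed=cfg.seed)
    best_rule = select_xai_method(method_curves, baseline, cfg.early_window)
    report.update({
        "method_curves": {k: v.step_accuracies.tolist() for k, v in method_curves.items()},
        "random_curve_mean": rand_mean.tolist(),
        "selected_method": best_rule,
    })

    events = per_class_event_analysis(best_model, dataset, best_rule)
    report["event_histograms"] = {str(k): v for k, v in events["histograms"].items()}
    report["modal_events"] = {str(k): v for k, v in events["modal_events"].items()}
    _write_report(report, cfg, "xai_pipeline")
    return report
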