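"""End-to-end experiment orchestration: load/generate -> binarize -> segment
-> split -> train -> evaluate, plus the window/overlap sweeps and k-fold CV.

Every experiment is described by an :class:`ExperimentConfig` (YAML-backed)
whose defaults are the published protocol: window 4032 / overlap 6,
threshold-5 binarization, 80/20 split, Adam with learning rate 0.001,
batch 32, 5 epochs.  One independent binary model is trained per requested
label.  All randomness derives from the config seed, so a rerun of the same
config writes byte-identical metric tables.

The train/test split operates at the trial level by default: with heavily
overlapping windows, segment-level splitting leaks near-duplicate windows
of one trial into both partitions, so the leakage mode is recorded
prominently in every result header.
"""

from __future__ import annotations

import dataclasses
import io
import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dataio, evaluation, recnet, segmentation, synthetic
from .errors import ValidationError

logger = logging.getLogger(__name__)

DEAP_LABELS = ("arousal", "valence", "dominance", "liking")


@dataclass(frozen=True)
class ExperimentConfig:
    """A complete, reproducible experiment description."""

    # data source: a DEAP-layout path (file or directory of participants),
    # or None to generate synthetically with the given overrides
    data_path: str | None = None
    synthetic: Mapping = field(default_factory=dict)
    labels: tuple[str, ...] = DEAP_LABELS
    threshold: float = 5.0
    window_size: int = 4032
    overlap_param: int = 6
    seg_mode: str = "tile"
    seg_cap: int | None = None
    model: str = "proposed"
    decimation: int = 1
    input_scale: float = 1.0 / 15.0
    train_fraction: float = 0.8
    split_unit: str = "trial"
    stratify: bool = False
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 5
    seed: int = 0
    deterministic_mode: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))

    # -- derived specs -------------------------------------------------------

    def segmentation_spec(self) -> segmentation.SegmentationSpec:
        return segmentation.SegmentationSpec(
            window_size=self.window_size, overlap_param=self.overlap_param,
            mode=self.seg_mode, cap=self.seg_cap)

    def split_spec(self) -> dataio.SplitSpec:
        return dataio.SplitSpec(
            train_fraction=self.train_fraction, unit=self.split_unit,
            seed=self.seed, stratify=self.stratify)

    def train_config(self) -> recnet.TrainConfig:
        return recnet.TrainConfig(
            learning_rate=self.learning_rate, batch_size=self.batch_size,
            epochs=self.epochs, seed=self.seed,
            deterministic_mode=self.deterministic_mode)

    def to_yaml(self, path=None) -> str:
        d = dataclasses.asdict(self)
        d["labels"] = list(d["labels"])
        d["synthetic"] = dict(d["synthetic"])
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "ExperimentConfig":
        text = Path(source).read_text() if not isinstance(source, io.IOBase) else source.read()
        d = yaml.safe_load(text) or {}
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def resolve_dataset(config: ExperimentConfig) -> dataio.Dataset:
    """Load the configured data path, or generate the synthetic dataset."""
    if config.data_path is not None:
        path = Path(config.data_path)
        if path.is_dir() and not (path / "data.csv").exists():
            files = sorted(p for p in path.iterdir()
                           if p.suffix in (".h5", ".hdf5", ".npz") or p.is_dir())
            files = [p for p in files if p.name != "generator_spec.yaml"]
            if not files:
                raise ValidationError(f"no participant files under {path}")
            trials: list[dataio.Trial] = []
            for f in files:
                trials.extend(dataio.load_deap_participant(f).trials)
            return dataio.Dataset(trials=tuple(trials), label_schema="deap")
        return dataio.load_deap_participant(path)
    overrides = dict(config.synthetic)
    overrides.setdefault("seed", config.seed)
    return synthetic.generate(synthetic.SyntheticSpec(**overrides))


@dataclass
class LabelResult:
    """Evaluation bundle for one binary label task."""

    label: str
    metrics: dict[str, float]
    cm: evaluation.ConfusionMatrix
    roc: list[evaluation.RocPoint]
    history: dict[str, list[float]]
    n_train: int
    n_test: int


@dataclass
class ExperimentResult:
    """All per-label results plus the resolved config and a run log."""

    config: ExperimentConfig
    per_label: dict[str, LabelResult]
    log: list[str]

    def metrics_table(self) -> pd.DataFrame:
        """Label x metric table (the per-model block of a comparison table)."""
        rows = [{"label": lab, **res.metrics} for lab, res in self.per_label.items()]
        return pd.DataFrame(rows, columns=["label", *evaluation.METRIC_NAMES])

    def write(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.config.to_yaml(out / "config.yaml")
        self.metrics_table().to_csv(out / "metrics.csv", index=False, float_format="%.6f")
        for lab, res in self.per_label.items():
            res.cm.as_table().to_csv(out / f"confusion_{lab}.csv")
            evaluation.roc_points_frame(res.roc).to_csv(
                out / f"roc_{lab}.csv", index=False, float_format="%.6f")
            pd.DataFrame(res.history).to_csv(
                out / f"history_{lab}.csv", index=False, float_format="%.6f")
        (out / "run_log.txt").write_text("\n".join(self.log) + "\n")
        return out


def _segment_labels(segments: Sequence[segmentation.Segment], label: str,
                    labeling: dataio.BinaryLabeling) -> np.ndarray:
    return np.asarray([labeling(s.ratings[label]) for s in segments])


def run_experiment(config: ExperimentConfig,
                   dataset: dataio.Dataset | None = None) -> ExperimentResult:
    """Execute the full pipeline for every requested label.

    ``dataset`` short-circuits data resolution (used by sweeps and CV to
    avoid regenerating); otherwise the config's source is resolved.
    """
    log: list[str] = []
    log.append("=== experiment run ===")
    log.append(f"seed: {config.seed}  deterministic_mode: {config.deterministic_mode}")
    log.append(f"SPLIT UNIT: {config.split_unit.upper()}-LEVEL "
               + ("(no cross-partition trial contamination)"
                  if config.split_unit == "trial"
                  else "(WARNING: overlapping segments may leak across partitions)"))
    if dataset is None:
        dataset = resolve_dataset(config)
    schema_labels = dataset.label_names
    for lab in config.labels:
        if lab not in schema_labels:
            raise ValidationError(
                f"label {lab!r} not in the dataset schema {sorted(schema_labels)}")
    labeling = dataio.BinaryLabeling(config.threshold)
    seg_spec = config.segmentation_spec()
    segments = segmentation.segment_dataset(dataset, seg_spec)
    log.append(f"dataset: {len(dataset)} trials -> {len(segments)} segments "
               f"(N={seg_spec.window_size}, O={seg_spec.overlap_param}, "
               f"mode={seg_spec.mode}{f', cap={seg_spec.cap}' if seg_spec.cap else ''})")

    per_label: dict[str, LabelResult] = {}
    for lab in config.labels:
        seg_y = _segment_labels(segments, lab, labeling)
        train_segs, test_segs = dataio.split(
            segments, config.split_spec(),
            labels=seg_y if config.stratify else None)
        X_train = recnet.as_sequence_batch(train_segs, decimation=config.decimation,
                                           scale=config.input_scale)
        X_test = recnet.as_sequence_batch(test_segs, decimation=config.decimation,
                                          scale=config.input_scale)
        y_train = _segment_labels(train_segs, lab, labeling)
        y_test = _segment_labels(test_segs, lab, labeling)
        spec = recnet.model_spec(config.model, X_train.shape[2], X_train.shape[1], 2)
        model, history = recnet.train(spec, X_train, y_train, config.train_config())
        proba = model.predict_proba(X_test)
        y_pred = proba.argmax(axis=1)
        cm = evaluation.confusion(y_test, y_pred)
        res = LabelResult(
            label=lab,
            metrics=evaluation.metrics_record(cm),
            cm=cm,
            roc=evaluation.roc_curve(y_test, proba[:, 1])
            if len(set(y_test.tolist())) == 2 else [],
            history=history,
            n_train=len(train_segs),
            n_test=len(test_segs),
        )
        per_label[lab] = res
        log.append(f"[{lab}] train {res.n_train} / test {res.n_test} segments; "
                   + "  ".join(f"{k}={v:.4f}" for k, v in res.metrics.items()))
    return ExperimentResult(config=config, per_label=per_label, log=log)


def _sweep_eval_fn(config: ExperimentConfig):
    """Adapt run_experiment into the (dataset, spec) -> metrics contract."""
    def eval_fn(dataset, spec: segmentation.SegmentationSpec):
        cfg = dataclasses.replace(
            config, window_size=spec.window_size, overlap_param=spec.overlap_param,
            seg_mode=spec.mode, seg_cap=spec.cap)
        result = run_experiment(cfg, dataset=dataset)
        return {lab: res.metrics for lab, res in result.per_label.items()}
    return eval_fn


def run_window_sweep(config: ExperimentConfig, candidate_ns: Sequence[int],
                     dataset: dataio.Dataset | None = None) -> segmentation.SearchResult:
    """Phase-1 sweep: train/evaluate at each window size, overlap fixed."""
    if dataset is None:
        dataset = resolve_dataset(config)
    return segmentation.phase1_window_search(
        dataset, candidate_ns, config.overlap_param, _sweep_eval_fn(config),
        mode=config.seg_mode, cap=config.seg_cap)


def run_overlap_sweep(config: ExperimentConfig, candidate_os: Sequence[int],
                      dataset: dataio.Dataset | None = None) -> segmentation.SearchResult:
    """Phase-2 sweep: train/evaluate at each overlap, window size fixed."""
    if dataset is None:
        dataset = resolve_dataset(config)
    return segmentation.phase2_overlap_search(
        dataset, config.window_size, candidate_os, _sweep_eval_fn(config),
        mode=config.seg_mode, cap=config.seg_cap)


def run_cv(config: ExperimentConfig, k: int = 5,
           dataset: dataio.Dataset | None = None) -> evaluation.CVReport:
    """k-fold cross-validation at the trial level.

    Trials are partitioned into k folds; each fold's trials are segmented
    and evaluated against models trained on the other k-1 folds, one model
    per label, reusing the experiment's segmentation/training settings.
    """
    if dataset is None:
        dataset = resolve_dataset(config)
    labeling = dataio.BinaryLabeling(config.threshold)
    seg_spec = config.segmentation_spec()
    train_cfg = config.train_config()

    def evaluate_fold(train_trials, test_trials):
        seg_tr = segmentation.segment_dataset(train_trials, seg_spec)
        seg_te = segmentation.segment_dataset(test_trials, seg_spec)
        X_tr = recnet.as_sequence_batch(seg_tr, decimation=config.decimation,
                                        scale=config.input_scale)
        X_te = recnet.as_sequence_batch(seg_te, decimation=config.decimation,
                                        scale=config.input_scale)
        out = {}
        for lab in config.labels:
            y_tr = _segment_labels(seg_tr, lab, labeling)
            y_te = _segment_labels(seg_te, lab, labeling)
            spec = recnet.model_spec(config.model, X_tr.shape[2], X_tr.shape[1], 2)
            model, _ = recnet.train(spec, X_tr, y_tr, train_cfg)
            cm = evaluation.confusion(y_te, model.predict(X_te))
            out[lab] = evaluation.metrics_record(cm)
        return out

    return evaluation.cross_validate(list(dataset), k, evaluate_fold, seed=config.seed)
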