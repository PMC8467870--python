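"""End-to-end orchestration: records -> features -> sub-models -> stack.

The full detector is: filter each record, cut 30-s segments, compute the
29x8 band-power matrix and the 1x42 expert vector per segment, train the
four sub-models (waveform CNN, band-power RNN, expert-feature forest,
pre-merged CNN+RNN), then fit the logistic meta-classifier on stacked
sub-model probabilities and threshold at 0.5.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .config import GdConfig, RunConfig, TrainConfig
from .evaluation import EvalReport, auroc, evaluate, record_folds, train_test_record_split
from .expert import expert_matrix
from .preprocess import apply_filter, design_filter, segment_dataset
from .spectral import band_matrices, compute_dpss
from .stacking import MetaCoefs, fit_meta, predict_meta, stack_probabilities
from .submodels import (
    CnnClassifier,
    ForestClassifier,
    PreMergeClassifier,
    RnnClassifier,
)
from .synthetic import generate_dataset

__all__ = ["FeatureSet", "extract_features", "prepare_synthetic_features",
           "StackedDetector", "run_study"]

SUBMODEL_NAMES = ("cnn", "rnn", "forest", "premerge")


@dataclass
class FeatureSet:
    """Per-segment inputs for every sub-model, plus labels and provenance."""

    waveforms: np.ndarray  # (n, 6000) filtered segments
    band: np.ndarray  # (n, 29, 8) band-power matrices
    expert: np.ndarray  # (n, 42) expert vectors
    labels: np.ndarray  # (n,) Boolean segment labels
    record_ids: np.ndarray  # (n,) source-record identifiers

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, idx) -> "FeatureSet":
        return FeatureSet(
            waveforms=self.waveforms[idx],
            band=self.band[idx],
            expert=self.expert[idx],
            labels=self.labels[idx],
            record_ids=self.record_ids[idx],
        )


def extract_features(segments, config: RunConfig | None = None) -> FeatureSet:
    """Band-power and expert features for a list of (filtered) segments."""
    config = config or RunConfig()
    sp = config.spectral
    tapers = compute_dpss(sp.frame_length, sp.n_tapers, sp.time_bandwidth)
    band = band_matrices(segments, tapers, sp)
    expert = expert_matrix(segments, band)
    return FeatureSet(
        waveforms=np.stack([s.x for s in segments]),
        band=band,
        expert=expert,
        labels=np.array([s.label for s in segments], dtype=np.int8),
        record_ids=np.array([s.source_record for s in segments]),
    )


def prepare_synthetic_features(
    config: RunConfig, n_records: int, record_duration: float | None = None
) -> FeatureSet:
    """Generate, filter, segment and featurize a synthetic dataset.

    Synthetic records are stationary from the first sample (there is no
    montage settling or lights-on artifact to trim), so no edge discard is
    applied here; the hour-long discard remains the default for real
    overnight records.
    """
    synth = config.synth
    if record_duration is not None:
        synth = dataclasses.replace(synth, record_duration=record_duration)
    records = generate_dataset(synth, n_records)
    coefs = design_filter(config.filter, synth.sampling_rate)
    filtered = [apply_filter(r, coefs) for r in records]
    seg_cfg = dataclasses.replace(config.segmentation, discard_edges_seconds=0.0)
    segments = segment_dataset(filtered, seg_cfg)
    return extract_features(segments, config)


def _inputs_for(name: str, fs: FeatureSet):
    if name == "cnn":
        return (fs.waveforms,)
    if name == "rnn":
        return (fs.band,)
    if name == "forest":
        return (fs.expert,)
    if name == "premerge":
        return (fs.waveforms, fs.band)
    raise KeyError(name)


@dataclass
class StackedDetector:
    """The four sub-models plus the logistic meta-classifier."""

    config: RunConfig = field(default_factory=RunConfig)
    train_overrides: dict[str, TrainConfig] = field(default_factory=dict)

    def _train_cfg(self, name: str) -> TrainConfig:
        if name in self.train_overrides:
            return self.train_overrides[name]
        return dataclasses.replace(self.config.train, seed=self.config.train.seed)

    def _new_submodels(self, seed_offset: int = 0) -> dict:
        base = self.config.seed + seed_offset
        forest_cfg = dataclasses.replace(self.config.forest, seed=base + 3)
        return {
            "cnn": CnnClassifier(seed=base + 1),
            "rnn": RnnClassifier(seed=base + 2),
            "forest": ForestClassifier(forest_cfg),
        }

    def _fit_submodels(self, models: dict, fs: FeatureSet, seed_offset: int = 0) -> dict:
        for name in ("cnn", "rnn", "forest"):
            cfg = dataclasses.replace(self._train_cfg(name),
                                      seed=self.config.seed + seed_offset + 10)
            models[name].fit(*_inputs_for(name, fs), fs.labels, config=cfg)
        models["premerge"] = PreMergeClassifier(
            models["cnn"], models["rnn"], seed=self.config.seed + seed_offset + 4
        )
        cfg = dataclasses.replace(self._train_cfg("premerge"),
                                  seed=self.config.seed + seed_offset + 11)
        models["premerge"].fit(fs.waveforms, fs.band, fs.labels, config=cfg)
        return models

    def _predict_pairs(self, models: dict, fs: FeatureSet) -> list[np.ndarray]:
        return [models[name].predict_proba(*_inputs_for(name, fs))
                for name in SUBMODEL_NAMES]

    def fit(self, fs: FeatureSet) -> "StackedDetector":
        """Train sub-models and the meta-classifier per the stack protocol."""
        protocol = self.config.stack.protocol
        if protocol == "oof":
            # Final sub-models train on everything; the meta-classifier sees
            # out-of-fold predictions so it never reads in-sample confidence.
            folds = record_folds(fs.record_ids, self.config.stack.n_folds,
                                 seed=self.config.seed)
            P_meta = np.zeros((len(fs), 8))
            for f in range(self.config.stack.n_folds):
                hold = np.flatnonzero(folds == f)
                rest = np.flatnonzero(folds != f)
                fold_models = self._fit_submodels(
                    self._new_submodels(seed_offset=100 * (f + 1)),
                    fs.subset(rest), seed_offset=100 * (f + 1),
                )
                pairs = self._predict_pairs(fold_models, fs.subset(hold))
                P_meta[hold] = np.column_stack(pairs)
            y_meta = fs.labels
            self.models = self._fit_submodels(self._new_submodels(), fs)
        elif protocol == "holdout":
            # Blending: a dedicated stacking split the sub-models never saw.
            stack_frac = self.config.stack.holdout_fraction
            fit_mask, stack_mask = train_test_record_split(
                fs.record_ids, test_fraction=stack_frac, seed=self.config.seed + 7
            )
            fit_fs, stack_fs = fs.subset(fit_mask), fs.subset(stack_mask)
            self.models = self._fit_submodels(self._new_submodels(), fit_fs)
            P_meta = np.column_stack(self._predict_pairs(self.models, stack_fs))
            y_meta = stack_fs.labels
        elif protocol == "naive":
            self.models = self._fit_submodels(self._new_submodels(), fs)
            P_meta = np.column_stack(self._predict_pairs(self.models, fs))
            y_meta = fs.labels
        else:
            raise ValueError(f"unknown stacking protocol {protocol!r}")

        P = stack_probabilities([P_meta[:, 2 * i : 2 * i + 2] for i in range(4)])
        if self.config.stack.drop_redundant:
            keep = [0, 2, 4, 6, 8]  # intercept + the arousal column of each pair
            P = P[:, keep]
        self._keep_cols = P.shape[1]
        self.meta: MetaCoefs = fit_meta(P, y_meta, self.config.stack.gd)
        return self

    def meta_inputs(self, fs: FeatureSet) -> np.ndarray:
        pairs = self._predict_pairs(self.models, fs)
        P = stack_probabilities(pairs)
        if self.config.stack.drop_redundant:
            P = P[:, [0, 2, 4, 6, 8]]
        return P

    def predict(self, fs: FeatureSet):
        """(labels, meta probability, per-sub-model probability pairs)."""
        pairs = self._predict_pairs(self.models, fs)
        P = stack_probabilities(pairs)
        if self.config.stack.drop_redundant:
            P = P[:, [0, 2, 4, 6, 8]]
        labels, h = predict_meta(P, self.meta)
        return labels, h, dict(zip(SUBMODEL_NAMES, pairs))


def reference_study(seed: int = 1) -> dict:
    """The default synthetic evaluation study at its canonical scale.

    34 half-hour records (~2,040 segments at ~40% arousal prevalence), a 20%
    record-level held-out test split, blending (holdout) stacking, and
    reduced epoch budgets per sub-model — the CNN converges on this task in
    a handful of epochs, so longer schedules only add cost.
    """
    cfg = RunConfig(seed=seed)
    cfg.stack = dataclasses.replace(
        cfg.stack, protocol="holdout", gd=GdConfig(tol=1e-6, max_iter=20_000)
    )
    overrides = {
        "cnn": TrainConfig(max_epochs=6, patience=3, seed=seed),
        "rnn": TrainConfig(max_epochs=20, patience=5, seed=seed),
        "forest": TrainConfig(seed=seed),
        "premerge": TrainConfig(max_epochs=3, patience=3, seed=seed),
    }
    return run_study(cfg, n_records=34, record_duration=1800.0,
                     train_overrides=overrides)


def run_study(
    config: RunConfig,
    n_records: int = 34,
    record_duration: float = 1800.0,
    train_overrides: dict[str, TrainConfig] | None = None,
) -> dict:
    """Train and evaluate the full detector on a synthetic study.

    Records are split at the record level (default 20% held out); every
    sub-model and the stacked meta-classifier are scored on the held-out
    segments.  Returns a dict with the feature-set sizes, per-sub-model
    AUROCs, and the meta-classifier's full metric report.
    """
    fs = prepare_synthetic_features(config, n_records, record_duration)
    train_mask, test_mask = train_test_record_split(
        fs.record_ids, config.evaluation.test_fraction, seed=config.seed
    )
    train_fs, test_fs = fs.subset(train_mask), fs.subset(test_mask)
    det = StackedDetector(config=config, train_overrides=train_overrides or {})
    det.fit(train_fs)
    pred, h, pairs = det.predict(test_fs)
    sub_auroc = {
        name: auroc(test_fs.labels, pairs[name][:, 1]) for name in SUBMODEL_NAMES
    }
    report: EvalReport = evaluate(test_fs.labels, pred, scores=h)
    return {
        "n_segments": len(fs),
        "n_train": len(train_fs),
        "n_test": len(test_fs),
        "prevalence": float(fs.labels.mean()),
        "submodel_auroc": sub_auroc,
        "meta_report": report,
        "detector": det,
        "test_features": test_fs,
    }
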