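"""End-to-end pipeline: synthesis/ingest -> features -> processing -> models.

The run directory produced by :func:`run_pipeline` contains feature CSVs,
the selection report, saved normalization parameters, model bundles, one
evaluation JSON per model for both the validation set and the blinded test
set, confusion CSVs, and a manifest recording every seed, threshold, and
row/column count, sufficient to reproduce the run bit-for-bit.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import audio_io, features, models, preprocess, synth
from .audio_io import AudioValidationError, Waveform
from .evaluate import evaluate as evaluate_predictions

logger = logging.getLogger(__name__)

DEFAULT_MODELS = ("svm_linear", "neural_net", "knn", "decision_tree",
                  "naive_bayes_kernel", "random_forest")


@dataclass
class RunConfig:
    """Serializable description of one full pipeline run."""

    input_dir: str | None = None          # directory of labeled WAVs, or None
    synth_counts: Mapping[str, int] = field(
        default_factory=lambda: {"heart": 120, "lung": 81, "bowel": 123})
    snr_db: float = 20.0
    segment_seconds: float = audio_io.DEFAULT_SEGMENT_SECONDS
    target_rate: float = audio_io.DEFAULT_RATE
    holdout_per_class: int = 20
    smote_k: int = preprocess.SMOTE_K_DEFAULT
    selection_thresholds: Mapping[str, float] = field(default_factory=dict)
    train_frac: float = 0.70
    model_kinds: Sequence[str] = DEFAULT_MODELS
    seed: int = 0
    order: str = "paper"                  # "paper" | "sound-practice"
    output_dir: str = "runs/latest"

    def __post_init__(self) -> None:
        if self.order not in ("paper", "sound-practice"):
            raise AudioValidationError(
                f"order must be 'paper' or 'sound-practice', got {self.order!r}")
        for kind in self.model_kinds:
            models.ModelSpec(kind=kind)  # validates early

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["synth_counts"] = dict(self.synth_counts)
        payload["selection_thresholds"] = dict(self.selection_thresholds)
        payload["model_kinds"] = list(self.model_kinds)
        Path(path).write_text(json.dumps(payload, indent=1))


def _load_audio(config: RunConfig) -> list[Waveform]:
    """Waveforms from a labeled WAV directory, or the synthetic generator.

    WAV layout: ``<input_dir>/<class>/<name>.wav`` with class in
    {heart, lung, bowel, noise}.
    """
    if config.input_dir is None:
        return synth.make_dataset(
            dict(config.synth_counts), seed=config.seed,
            duration=config.segment_seconds, rate=config.target_rate,
            snr_db=config.snr_db)
    root = Path(config.input_dir)
    waveforms: list[Waveform] = []
    for class_dir in sorted(root.iterdir()):
        if not class_dir.is_dir() or class_dir.name not in audio_io.CLASS_LABELS:
            continue
        for wav_path in sorted(class_dir.glob("*.wav")):
            w = audio_io.read_wav(wav_path)
            waveforms.append(Waveform(samples=w.samples, rate=w.rate,
                                      label=class_dir.name,
                                      source_id=str(wav_path)))
    if not waveforms:
        raise AudioValidationError(f"no labeled WAV files under {root}")
    return waveforms


def prepare_segments(config: RunConfig) -> list[Waveform]:
    """Resample to the target rate and slice into analysis segments."""
    segments: list[Waveform] = []
    for w in _load_audio(config):
        w = audio_io.resample(w, config.target_rate)
        segments.extend(audio_io.segment(w, config.segment_seconds))
    logger.info("prepared %d segments", len(segments))
    return segments


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full run and return the populated output directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": json.loads(json.dumps(asdict(config), default=str)),
                      "counts": {}}

    segments = prepare_segments(config)
    matrix = features.build_matrix(segments)
    matrix.to_csv(out / "features_full.csv")
    manifest["counts"]["segments"] = len(matrix)

    test, pool = preprocess.carve_holdout(
        matrix, n_per_class=config.holdout_per_class, seed=config.seed)
    manifest["counts"]["test"] = len(test)
    manifest["counts"]["pool"] = len(pool)
    logger.info("holdout: %d test, %d pool (%s)", len(test), len(pool),
                pool.class_counts())

    if config.order == "paper":
        balanced = preprocess.smote(pool, k=config.smote_k, seed=config.seed)
        manifest["counts"]["post_smote"] = len(balanced)
        norm = preprocess.fit_normalize(balanced)
        normalized = preprocess.apply_normalize(balanced, norm)
        report, reduced = preprocess.select_features(
            normalized, thresholds=dict(config.selection_thresholds),
            seed=config.seed)
        train_set, val_set = preprocess.split(
            reduced, train_frac=config.train_frac, seed=config.seed)
    else:  # sound-practice: split first, fit everything on train only
        train_raw, val_raw = preprocess.split(
            pool, train_frac=config.train_frac, seed=config.seed)
        train_bal = preprocess.smote(train_raw, k=config.smote_k, seed=config.seed)
        manifest["counts"]["post_smote"] = len(train_bal)
        norm = preprocess.fit_normalize(train_bal)
        train_set = preprocess.apply_normalize(train_bal, norm)
        report, train_set = preprocess.select_features(
            train_set, thresholds=dict(config.selection_thresholds),
            seed=config.seed)
        val_norm = preprocess.apply_normalize(val_raw, norm)
        val_set = features.FeatureMatrix(
            X=val_norm.X[report.kept].copy(), labels=val_norm.labels,
            sources=list(val_norm.sources))
    manifest["counts"]["train"] = len(train_set)
    manifest["counts"]["validation"] = len(val_set)
    manifest["order"] = config.order
    logger.info("train %d rows, validation %d rows, %d selected features",
                len(train_set), len(val_set), len(report.kept))

    norm.to_json(out / "normalization.json")
    report.to_json(out / "selection_report.json")
    train_set.to_csv(out / "train.csv")
    val_set.to_csv(out / "validation.csv")

    # the blinded test set is transformed with the saved parameters only
    test_norm = preprocess.apply_normalize(test, norm)
    test_set = features.FeatureMatrix(
        X=test_norm.X[report.kept].copy(), labels=test_norm.labels,
        sources=list(test_norm.sources))
    test_set.to_csv(out / "test.csv")

    classes = sorted(np.unique(matrix.labels))
    results: dict[str, dict] = {}
    for kind in config.model_kinds:
        spec = models.ModelSpec(kind=kind, seed=config.seed)
        t0 = time.perf_counter()
        model = models.train(spec, train_set)
        train_s = time.perf_counter() - t0
        model.save(out / f"model_{spec.kind}.pkl")
        for split_name, split_set in (("validation", val_set), ("test", test_set)):
            t1 = time.perf_counter()
            predicted = models.predict(model, split_set)
            predict_s = time.perf_counter() - t1
            rep = evaluate_predictions(
                split_set.labels, predicted, classes=classes,
                train_seconds=train_s, predict_seconds=predict_s)
            rep.to_json(out / f"eval_{spec.kind}_{split_name}.json")
            rep.confusion_matrix.to_csv(
                out / f"confusion_{spec.kind}_{split_name}.csv")
            results.setdefault(spec.kind, {})[split_name] = rep.summary
            logger.info("%s/%s: %s", spec.kind, split_name,
                        {k: round(v, 4) for k, v in rep.summary.items()})
    manifest["results"] = results
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
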