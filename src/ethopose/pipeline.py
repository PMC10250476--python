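"""End-to-end pipeline: normalize -> label -> window -> classify -> report.

A :class:`PipelineConfig` (optionally loaded from YAML) fully determines a
run; together with the classifier seed it makes every numeric output
reproducible.  The resolved configuration and package version are embedded
in the run's metadata file so an output directory is self-describing.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .classify import ClassifierConfig, fit, load_model, predict_proba, save_model
from .evaluate import cv5_nonshuffled
from .features import make_windows, select_features, feature_matrix, windows_from_labeled
from .io import read_labels, read_pose_csv
from .labeling import apply_labels, validate
from .normalize import normalize_track
from .postprocess import TupleThreshold, apply_tuple_thresholds, argmax_prediction
from .report import make_ethogram, overlay_manifest

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, serializable to/from YAML."""

    track: str
    out_dir: str
    mode: str = "train"  # "train" or "predict"
    labels: str | None = None
    model: str | None = None
    window_size: int = 16
    min_likelihood: float = 0.6
    n_estimators: int = 20
    seed: int = 0
    middle_neck_mode: str = "difference"
    fps: float | None = None
    tuple_thresholds: list[tuple[str, str, float]] = field(default_factory=list)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("train", "predict"):
            raise ValueError("mode must be 'train' or 'predict'")
        if self.mode == "train" and not self.labels:
            raise ValueError("labeling stage: train mode requires a labels file")
        if self.mode == "predict" and not self.model:
            raise ValueError("classify stage: predict mode requires a model file")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage(name: str):
    def decorator(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapped

    return decorator


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and write all artifacts to ``out_dir``.

    Train mode fits and cross-validates a model on the labeled track and
    reports on the last fold; predict mode applies a stored model to an
    (unlabeled) track.  Both modes emit predictions, an ethogram (CSV +
    plot) and, when the frame rate is known, an SRT overlay manifest.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}

    track = _stage("io")(read_pose_csv)(config.track)
    if config.fps:
        track.fps = config.fps
    norm, state = _stage("normalize")(normalize_track)(track, config.middle_neck_mode)
    if state.n_degenerate:
        logger.warning("%d frames had a degenerate middle-neck vector", state.n_degenerate)
    selection = _stage("features")(select_features)(track, config.min_likelihood)
    logger.info("excluded parts: %s", selection.excluded_parts or "none")

    tuples = [TupleThreshold(*t) for t in config.tuple_thresholds]

    if config.mode == "train":
        labels = _stage("labeling")(read_labels)(config.labels)
        report = validate(labels, track)
        (out / "label_report.txt").write_text(report.summary() + "\n", encoding="utf-8")
        labeled = _stage("labeling")(apply_labels)(labels, norm)
        dataset = _stage("features")(windows_from_labeled)(
            norm, labeled, selection, config.window_size
        )
        clf_config = ClassifierConfig(
            n_estimators=config.n_estimators, random_seed=config.seed
        )
        eval_report = _stage("evaluate")(cv5_nonshuffled)(dataset, clf_config)
        eval_report.save(out / "evaluation")
        model = _stage("classify")(fit)(
            dataset, clf_config, tuple(selection.feature_names)
        )
        save_model(model, out / "model.joblib")
        proba = _stage("classify")(predict_proba)(model, dataset)
        artifacts.update(model=model, eval_report=eval_report, dataset=dataset)
    else:
        model = _stage("classify")(load_model)(config.model)
        feats = feature_matrix(norm, selection)
        import numpy as np

        dataset = _stage("features")(make_windows)(
            feats, np.arange(norm.n_frames), model.spec.window_size
        )
        proba = _stage("classify")(predict_proba)(model, dataset)
        artifacts.update(model=model, dataset=dataset)

    preds = _stage("postprocess")(argmax_prediction)(proba)
    if tuples:
        preds = _stage("postprocess")(apply_tuple_thresholds)(preds, proba, tuples)
    etho = _stage("report")(make_ethogram)(
        preds, out / "ethogram.csv", out / "ethogram.png"
    )
    fps = track.fps
    if fps:
        _stage("report")(overlay_manifest)(preds, fps, out / "overlay.srt")

    meta = {"config": config.to_dict(), "version": __version__}
    (out / "run_metadata.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True), encoding="utf-8"
    )
    artifacts.update(predictions=preds, probabilities=proba, ethogram=etho)
    return artifacts
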