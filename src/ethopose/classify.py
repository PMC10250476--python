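"""Imbalance-aware window classification behind a pluggable backend contract.

The shipped backend is a random forest: the number of features considered
per split is the square root of the input-vector length, and every model is
trained with *balanced class weights*, where class ``c`` receives weight

    w_c = total_observations / (n_classes * observations_c)

i.e. inversely proportional to class frequency, so rare behaviors are not
drowned out by the dominant ones.  These weights are computed here
explicitly (:func:`class_weights`) and handed to the backend, which keeps
the weighting auditable and backend-independent.

Backends implement ``fit(X, y, class_weight, seed)`` / ``predict_proba(X)``
so that other architectures (e.g. convolutional time-series networks) can
plug into the same pipeline without changes; only the random forest is
bundled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Protocol

import joblib
import numpy as np
import sklearn
from sklearn.ensemble import RandomForestClassifier

from .features import WindowDataset, WindowSpec

#: Hyperparameter grid for tree-count validation curves.
ESTIMATOR_GRID = tuple(range(1, 101))


def class_weights(class_counts: Mapping[str, int]) -> dict[str, float]:
    """Balanced per-class weights, inversely proportional to class frequency.

    ``w_c = total / (n_classes * count_c)``; the weighted counts sum back to
    the total number of observations.
    """
    if not class_counts:
        raise ValueError("class_counts must be non-empty")
    for name, count in class_counts.items():
        if count <= 0:
            raise ValueError(f"class {name!r} has non-positive count {count}")
    total = sum(class_counts.values())
    k = len(class_counts)
    return {name: total / (k * count) for name, count in class_counts.items()}


@dataclass(frozen=True)
class ClassifierConfig:
    """Training configuration shared by all backends."""

    n_estimators: int = 20
    max_features_rule: str = "sqrt"
    class_weighting: str = "balanced"
    random_seed: int = 0
    backend: str = "random_forest"
    backend_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        if self.max_features_rule != "sqrt":
            raise ValueError("only the sqrt max-features rule is supported")
        if self.class_weighting not in ("balanced", "none"):
            raise ValueError("class_weighting must be 'balanced' or 'none'")

    def replace(self, **kwargs) -> "ClassifierConfig":
        from dataclasses import replace

        return replace(self, **kwargs)


class Backend(Protocol):
    """Contract a classifier backend must satisfy."""

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        class_weight: Mapping[str, float] | None,
        seed: int,
    ) -> None: ...

    def predict_proba(self, X: np.ndarray) -> np.ndarray: ...

    @property
    def classes_(self) -> np.ndarray: ...


class RandomForestBackend:
    """Random-forest backend (scikit-learn) with sqrt max-features."""

    def __init__(self, n_estimators: int = 20, **params) -> None:
        self.n_estimators = n_estimators
        self.params = params
        self._model: RandomForestClassifier | None = None

    def fit(self, X, y, class_weight, seed) -> None:
        self._model = RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_features="sqrt",
            class_weight=dict(class_weight) if class_weight else None,
            random_state=seed,
            n_jobs=1,
            **self.params,
        )
        self._model.fit(X, y)

    def predict_proba(self, X) -> np.ndarray:
        if self._model is None:
            raise RuntimeError("backend is not fitted")
        return self._model.predict_proba(X)

    @property
    def classes_(self) -> np.ndarray:
        if self._model is None:
            raise RuntimeError("backend is not fitted")
        return self._model.classes_

    def effective_params(self) -> dict:
        assert self._model is not None
        return self._model.get_params()


BACKENDS = {"random_forest": RandomForestBackend}


@dataclass
class FittedModel:
    """A trained backend plus the metadata needed to reapply it."""

    backend: Backend
    classes: tuple[str, ...]
    spec: WindowSpec
    config: ClassifierConfig
    feature_names: tuple[str, ...] | None = None
    metadata: dict = field(default_factory=dict)


@dataclass
class ProbabilityTrack:
    """Per-anchor-frame class probability vectors (each row sums to 1)."""

    classes: tuple[str, ...]
    probs: np.ndarray
    frame_indices: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        if self.probs.ndim != 2 or self.probs.shape[1] != len(self.classes):
            raise ValueError(
                f"probs must have shape (n, {len(self.classes)}); got {self.probs.shape}"
            )
        if len(self.frame_indices) != len(self.probs):
            raise ValueError("frame_indices length must match probs")
        if len(self.probs) and (
            np.any(self.probs < 0)
            or np.any(self.probs > 1)
            or not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9)
        ):
            raise ValueError("each probability vector must lie in [0,1] and sum to 1")

    def __len__(self) -> int:
        return len(self.probs)

    def class_index(self, name: str) -> int:
        try:
            return self.classes.index(name)
        except ValueError:
            raise KeyError(f"unknown class {name!r}; model classes: {self.classes}")


def fit(
    dataset: WindowDataset,
    config: ClassifierConfig | None = None,
    feature_names: tuple[str, ...] | None = None,
) -> FittedModel:
    """Train a backend on a labeled window dataset.

    Requires at least two classes.  With ``class_weighting="balanced"`` the
    per-class weights from :func:`class_weights` are applied.  A fixed
    ``random_seed`` makes refits bit-reproducible.
    """
    config = config or ClassifierConfig()
    if dataset.labels is None:
        raise ValueError("fit requires a labeled dataset")
    labels = dataset.labels.astype(str)
    names, counts = np.unique(labels, return_counts=True)
    if len(names) < 2:
        raise ValueError(f"need >= 2 classes to fit, got {list(names)}")

    weights = None
    if config.class_weighting == "balanced":
        weights = class_weights({str(n): int(c) for n, c in zip(names, counts)})

    backend_cls = BACKENDS.get(config.backend)
    if backend_cls is None:
        raise ValueError(f"unknown backend {config.backend!r}; have {sorted(BACKENDS)}")
    backend = backend_cls(n_estimators=config.n_estimators, **config.backend_params)
    backend.fit(dataset.vectors, labels, weights, config.random_seed)

    metadata = {
        "sklearn_version": sklearn.__version__,
        "n_training_windows": len(dataset),
        "class_counts": {str(n): int(c) for n, c in zip(names, counts)},
        "class_weights": weights,
    }
    if isinstance(backend, RandomForestBackend):
        metadata["backend_params"] = backend.effective_params()
    return FittedModel(
        backend=backend,
        classes=tuple(str(c) for c in backend.classes_),
        spec=dataset.spec,
        config=config,
        feature_names=feature_names,
        metadata=metadata,
    )


def predict_proba(model: FittedModel, dataset: WindowDataset) -> ProbabilityTrack:
    """Apply a fitted model; one probability vector per window anchor frame."""
    expected = model.spec.vector_length
    actual = dataset.vectors.shape[1]
    if actual != expected:
        raise ValueError(
            f"window vector length mismatch: model expects {expected} "
            f"({model.spec.n_features} features x {model.spec.window_size} frames), "
            f"dataset has {actual}"
        )
    probs = model.backend.predict_proba(dataset.vectors)
    return ProbabilityTrack(model.classes, probs, dataset.anchor_frames)


def save_model(model: FittedModel, path: str | Path) -> None:
    """Persist a fitted model (with its metadata) to *path*."""
    joblib.dump(model, Path(path))


def load_model(path: str | Path) -> FittedModel:
    """Load a model previously stored with :func:`save_model`."""
    model = joblib.load(Path(path))
    if not isinstance(model, FittedModel):
        raise TypeError(f"{path} does not contain a FittedModel")
    return model
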