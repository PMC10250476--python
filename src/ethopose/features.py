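"""Feature selection by tracking stability and sliding-window segmentation.

Classifier inputs are the raw x/y coordinates of the *reliably tracked*
body parts: a part whose mean likelihood falls below a cutoff (default 0.6)
is dropped entirely — in practice this removes the beak, which is
frequently occluded by the bird itself.

Windows are cut with a sliding window of step 1 and flattened frame-major,
so the input-vector length is ``n_features * window_size``.  In training
mode a window must lie fully inside a single contiguous run of equal-label
frames: windows never straddle a label boundary or a frame-index gap left
by unlabeled-frame removal, since a mixed-label window has no coherent
supervision target.  Each window is attributed to its *last* frame (causal
convention), which keeps downstream ethograms aligned with what was
observable at prediction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import PoseTrack
from .labeling import LabeledFrames

DEFAULT_MIN_MEAN_LIKELIHOOD = 0.6


@dataclass(frozen=True)
class WindowSpec:
    """Shape of the sliding-window segmentation."""

    window_size: int
    n_features: int
    step: int = 1

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError(f"window_size must be >= 1, got {self.window_size}")
        if self.step != 1:
            raise ValueError("only step size 1 is supported")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")

    @property
    def vector_length(self) -> int:
        return self.n_features * self.window_size


@dataclass
class WindowDataset:
    """Flattened sliding-window feature vectors plus labels and anchors."""

    vectors: np.ndarray
    labels: np.ndarray | None
    anchor_frames: np.ndarray
    spec: WindowSpec

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors)
        self.anchor_frames = np.asarray(self.anchor_frames, dtype=int)
        if self.vectors.ndim != 2 or self.vectors.shape[1] != self.spec.vector_length:
            raise ValueError(
                f"vectors must have shape (n, {self.spec.vector_length}); "
                f"got {self.vectors.shape}"
            )
        if len(self.anchor_frames) != len(self.vectors):
            raise ValueError("anchor_frames length must match vectors")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if len(self.labels) != len(self.vectors):
                raise ValueError("labels length must match vectors")

    def __len__(self) -> int:
        return len(self.vectors)

    def subset(self, indices: np.ndarray) -> "WindowDataset":
        labels = None if self.labels is None else self.labels[indices]
        return WindowDataset(
            self.vectors[indices], labels, self.anchor_frames[indices], self.spec
        )


@dataclass
class FeatureSelection:
    """Outcome of likelihood-based part selection."""

    selected_parts: list[str]
    excluded_parts: list[str]
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.feature_names:
            self.feature_names = [
                f"{part} {axis}" for part in self.selected_parts for axis in ("x", "y")
            ]

    @property
    def n_features(self) -> int:
        return 2 * len(self.selected_parts)


def select_features(
    track: PoseTrack, min_mean_likelihood: float = DEFAULT_MIN_MEAN_LIKELIHOOD
) -> FeatureSelection:
    """Keep x/y of every part whose mean likelihood reaches the cutoff.

    Parts are kept in track order.  Raises if the cutoff excludes every
    part, since no features would remain.
    """
    mean_lik = track.likelihood.mean(axis=0)
    selected = [p for p, m in zip(track.parts, mean_lik) if m >= min_mean_likelihood]
    excluded = [p for p, m in zip(track.parts, mean_lik) if m < min_mean_likelihood]
    if not selected:
        raise ValueError(
            f"min_mean_likelihood={min_mean_likelihood} excludes all "
            f"{track.n_parts} parts (max mean likelihood {mean_lik.max():.3f})"
        )
    return FeatureSelection(selected, excluded)


def feature_matrix(track: PoseTrack, selection: FeatureSelection) -> np.ndarray:
    """Per-frame feature matrix ``(n_frames, n_features)`` for selected parts."""
    idx = [track.parts.index(p) for p in selection.selected_parts]
    return track.coords[:, idx, :].reshape(track.n_frames, -1)


def _contiguous_runs(
    frame_indices: np.ndarray, labels: np.ndarray | None
) -> list[tuple[int, int]]:
    """Half-open [start, stop) runs of contiguous frames (and equal labels)."""
    n = len(frame_indices)
    if n == 0:
        return []
    breaks = np.zeros(n - 1, dtype=bool) if n > 1 else np.zeros(0, dtype=bool)
    if n > 1:
        breaks |= np.diff(frame_indices) != 1
        if labels is not None:
            breaks |= labels[1:] != labels[:-1]
    starts = np.concatenate([[0], np.nonzero(breaks)[0] + 1])
    stops = np.concatenate([np.nonzero(breaks)[0] + 1, [n]])
    return list(zip(starts.tolist(), stops.tolist()))


def make_windows(
    features: np.ndarray,
    frame_indices: np.ndarray,
    window_size: int,
    labels: np.ndarray | None = None,
    dtype=np.float32,
) -> WindowDataset:
    """Cut step-1 sliding windows and flatten them frame-major.

    Parameters
    ----------
    features:
        ``(n_frames, n_features)`` per-frame feature matrix (already
        restricted to the retained frames).
    frame_indices:
        Original frame index of each row; gaps break window runs.
    window_size:
        Frames per window; a run of length ``n`` yields ``max(0, n - w + 1)``
        windows.
    labels:
        Per-frame labels for training mode.  If given, windows are cut only
        inside equal-label runs and each window carries the run's label.
        If omitted (inference mode), windows are cut over every contiguous
        position.
    """
    features = np.asarray(features)
    frame_indices = np.asarray(frame_indices, dtype=int)
    if features.ndim != 2:
        raise ValueError("features must be a 2-D (n_frames, n_features) array")
    if len(frame_indices) != len(features):
        raise ValueError("frame_indices length must match features")
    spec = WindowSpec(window_size=window_size, n_features=features.shape[1])
    w = window_size

    vec_chunks: list[np.ndarray] = []
    label_chunks: list[np.ndarray] = []
    anchor_chunks: list[np.ndarray] = []
    lab = None if labels is None else np.asarray(labels, dtype=object)
    for start, stop in _contiguous_runs(frame_indices, lab):
        run_len = stop - start
        if run_len < w:
            continue
        block = features[start:stop]
        windows = np.lib.stride_tricks.sliding_window_view(block, (w, block.shape[1]))
        vec_chunks.append(windows.reshape(run_len - w + 1, w * block.shape[1]))
        anchor_chunks.append(frame_indices[start + w - 1 : stop])
        if lab is not None:
            label_chunks.append(lab[start + w - 1 : stop])

    if vec_chunks:
        vectors = np.concatenate(vec_chunks).astype(dtype)
        anchors = np.concatenate(anchor_chunks)
        out_labels = np.concatenate(label_chunks) if lab is not None else None
    else:
        vectors = np.empty((0, spec.vector_length), dtype=dtype)
        anchors = np.empty(0, dtype=int)
        out_labels = np.empty(0, dtype=object) if lab is not None else None
    return WindowDataset(vectors, out_labels, anchors, spec)


def unflatten_window(vector: np.ndarray, spec: WindowSpec) -> np.ndarray:
    """Inverse of the frame-major flattening: ``(window_size, n_features)``."""
    vector = np.asarray(vector)
    if vector.shape != (spec.vector_length,):
        raise ValueError(f"expected vector of length {spec.vector_length}")
    return vector.reshape(spec.window_size, spec.n_features)


def windows_from_labeled(
    track: PoseTrack,
    labeled: LabeledFrames,
    selection: FeatureSelection,
    window_size: int,
) -> WindowDataset:
    """Convenience: feature matrix + labeled frames -> training WindowDataset."""
    feats = feature_matrix(track, selection)[labeled.frame_indices]
    return make_windows(feats, labeled.frame_indices, window_size, labeled.labels)
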