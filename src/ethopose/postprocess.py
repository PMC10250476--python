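"""From class probabilities to behavior predictions.

The baseline rule takes, per frame, the class of maximal probability (ties
broken deterministically in favor of the first class in model order).  On
top of that, *tuple thresholds* let a user trade recall for precision for
individual behavior pairs in a multi-class model: a rule
``(fallback, target, threshold)`` reassigns a frame predicted as *target*
to *fallback* whenever the fallback class's own probability reaches the
threshold.  With e.g. ``(standing, head_shake, 0.2)``, a head-shake call is
only kept when the model puts less than 20% probability on standing —
fewer, more confident head-shake predictions (precision up, recall down).

Rules are applied in list order with at most one reassignment per frame
(the first matching tuple wins), so the outcome is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import ProbabilityTrack


@dataclass(frozen=True)
class TupleThreshold:
    """A pairwise reassignment rule (fallback, target, threshold)."""

    fallback: str
    target: str
    threshold: float

    def __post_init__(self) -> None:
        if self.fallback == self.target:
            raise ValueError("fallback and target must differ")
        if not (0.0 <= self.threshold <= 1.0):
            raise ValueError(f"threshold must lie in [0, 1], got {self.threshold}")


@dataclass
class PredictionTrack:
    """Per-anchor-frame behavior predictions."""

    frame_indices: np.ndarray
    behaviors: np.ndarray
    probabilities: np.ndarray
    reassigned: np.ndarray
    tied: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        self.behaviors = np.asarray(self.behaviors, dtype=object)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        self.reassigned = np.asarray(self.reassigned, dtype=bool)
        self.tied = np.asarray(self.tied, dtype=bool)
        n = len(self.frame_indices)
        for name in ("behaviors", "probabilities", "reassigned", "tied"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length must match frame_indices")
        unknown = set(self.behaviors.astype(str)) - set(self.classes)
        if unknown:
            raise ValueError(f"behaviors outside the class set: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.frame_indices)


def argmax_prediction(probs: ProbabilityTrack) -> PredictionTrack:
    """Pick, per frame, the most probable class.

    Exact ties go to the first class in model order and are flagged in
    ``tied`` so a user can audit them.
    """
    if len(probs) == 0:
        empty = np.empty(0)
        return PredictionTrack(
            np.empty(0, dtype=int), np.empty(0, dtype=object), empty,
            np.zeros(0, dtype=bool), np.zeros(0, dtype=bool), probs.classes,
        )
    winners = np.argmax(probs.probs, axis=1)
    winning_p = probs.probs[np.arange(len(probs)), winners]
    tied = (probs.probs == winning_p[:, None]).sum(axis=1) > 1
    behaviors = np.asarray([probs.classes[i] for i in winners], dtype=object)
    return PredictionTrack(
        frame_indices=probs.frame_indices.copy(),
        behaviors=behaviors,
        probabilities=winning_p,
        reassigned=np.zeros(len(probs), dtype=bool),
        tied=tied,
        classes=probs.classes,
    )


def apply_tuple_thresholds(
    preds: PredictionTrack,
    probs: ProbabilityTrack,
    tuples: list[TupleThreshold],
) -> PredictionTrack:
    """Apply pairwise reassignment rules to argmax predictions.

    For each frame whose current prediction equals a rule's target and
    whose fallback probability is at least the rule's threshold, the
    prediction becomes the fallback and the frame is flagged
    ``reassigned``.  Rules are tried in list order; a frame is reassigned
    at most once.  The inputs are not modified.
    """
    if len(preds) != len(probs):
        raise ValueError("prediction and probability tracks must align")
    for rule in tuples:
        for name in (rule.fallback, rule.target):
            if name not in probs.classes:
                raise KeyError(
                    f"tuple threshold references unknown class {name!r}; "
                    f"model classes: {probs.classes}"
                )
    behaviors = preds.behaviors.copy()
    probabilities = preds.probabilities.copy()
    reassigned = preds.reassigned.copy()
    for rule in tuples:
        i_fallback = probs.class_index(rule.fallback)
        mask = (
            ~reassigned
            & (behaviors.astype(str) == rule.target)
            & (probs.probs[:, i_fallback] >= rule.threshold)
        )
        behaviors[mask] = rule.fallback
        probabilities[mask] = probs.probs[mask, i_fallback]
        reassigned |= mask
    return PredictionTrack(
        frame_indices=preds.frame_indices.copy(),
        behaviors=behaviors,
        probabilities=probabilities,
        reassigned=reassigned,
        tied=preds.tied.copy(),
        classes=preds.classes,
    )


def read_tuple_thresholds(path) -> list[TupleThreshold]:
    """Read ordered rules from a CSV with columns fallback,target,threshold."""
    import pandas as pd

    df = pd.read_csv(path)
    missing = {"fallback", "target", "threshold"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        TupleThreshold(str(r.fallback), str(r.target), float(r.threshold))
        for r in df.itertuples(index=False)
    ]
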