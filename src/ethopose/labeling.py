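"""Label integrity checking and per-frame label application.

Manual behavior annotation arrives as frame-range time slices.  Before any
training, the slices are validated against the pose track and the behavior
vocabulary: names must match the vocabulary exactly (after trimming
surrounding whitespace and lower-casing — anything else, e.g. a trailing
space or a capitalization change, is reported), slices must not overlap
(behaviors are mutually exclusive under a single-observer protocol, so an
overlap indicates an annotation bug rather than a tie to break), and no
slice may extend past the end of the track.

:func:`apply_labels` then produces the per-frame training view: every frame
covered by a slice carries that slice's behavior, frames outside all slices
are removed, and original frame indices are retained for traceability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import LabelSet, LabelValidationError, PoseTrack


def canonical_name(name: str) -> str:
    """Canonical form used for vocabulary matching: stripped and lower-cased."""
    return name.strip().lower()


@dataclass
class ValidationReport:
    """Findings from checking a LabelSet against a track and vocabulary."""

    unknown_names: list[str] = field(default_factory=list)
    inconsistent_names: list[tuple[str, str]] = field(default_factory=list)
    overlaps: list[tuple[int, int]] = field(default_factory=list)
    out_of_range: list[int] = field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return not (
            self.unknown_names
            or self.inconsistent_names
            or self.overlaps
            or self.out_of_range
        )

    def summary(self) -> str:
        if self.is_valid:
            return "labels valid: no findings"
        lines = []
        for raw, expected in self.inconsistent_names:
            lines.append(f"inconsistent name: {raw!r} (vocabulary has {expected!r})")
        for name in self.unknown_names:
            lines.append(f"unknown behavior name: {name!r}")
        for i, j in self.overlaps:
            lines.append(f"slices {i} and {j} overlap")
        for i in self.out_of_range:
            lines.append(f"slice {i} extends past the end of the track")
        return "\n".join(lines)


@dataclass
class LabeledFrames:
    """Per-frame labels with unlabeled frames removed.

    ``frame_indices`` keeps the original (pre-removal) frame numbers, so
    downstream windows and predictions stay traceable to the video.
    """

    frame_indices: np.ndarray
    labels: np.ndarray
    class_counts: dict[str, int]

    def __post_init__(self) -> None:
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.frame_indices) != len(self.labels):
            raise ValueError("frame_indices and labels must have equal length")
        if sum(self.class_counts.values()) != len(self.labels):
            raise ValueError("class_counts must sum to the number of retained frames")

    @property
    def n_frames(self) -> int:
        return len(self.frame_indices)


def validate(
    labels: LabelSet, track: PoseTrack, vocabulary: set[str] | None = None
) -> ValidationReport:
    """Check *labels* against *track* and *vocabulary*; returns all findings.

    An empty report (``report.is_valid``) is the precondition for
    :func:`apply_labels`.
    """
    vocab = vocabulary if vocabulary is not None else labels.vocabulary
    by_canonical = {canonical_name(v): v for v in vocab}
    report = ValidationReport()

    for s in labels.slices:
        if s.behavior in vocab:
            continue
        canon = canonical_name(s.behavior)
        if canon in by_canonical:
            report.inconsistent_names.append((s.behavior, by_canonical[canon]))
        else:
            report.unknown_names.append(s.behavior)

    order = sorted(range(len(labels.slices)), key=lambda i: labels.slices[i].start_frame)
    for a, b in zip(order, order[1:]):
        if labels.slices[a].end_frame >= labels.slices[b].start_frame:
            report.overlaps.append(tuple(sorted((a, b))))

    for i, s in enumerate(labels.slices):
        if s.end_frame >= track.n_frames:
            report.out_of_range.append(i)

    return report


def apply_labels(labels: LabelSet, track: PoseTrack) -> LabeledFrames:
    """Expand validated slices to per-frame labels, dropping unlabeled frames.

    Raises :class:`LabelValidationError` carrying the validation report if
    the labels do not pass :func:`validate`.
    """
    report = validate(labels, track)
    if not report.is_valid:
        raise LabelValidationError(
            "labels failed validation:\n" + report.summary()
        )

    per_frame = np.full(track.n_frames, None, dtype=object)
    for s in labels.slices:
        per_frame[s.start_frame : s.end_frame + 1] = s.behavior

    keep = np.array([lab is not None for lab in per_frame])
    frame_indices = np.nonzero(keep)[0]
    kept = per_frame[keep]
    names, counts = np.unique(kept.astype(str), return_counts=True)
    class_counts = {str(n): int(c) for n, c in zip(names, counts)}
    return LabeledFrames(frame_indices, kept, class_counts)
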