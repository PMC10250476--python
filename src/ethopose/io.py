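"""Readers and writers for pose tracks and behavior label tables.

Pose tracks use the DeepLabCut CSV dialect: three header rows
(``scorer`` / ``bodyparts`` / ``coords``), one row per video frame, and
per body part an ``x``, ``y`` and ``likelihood`` column triple.  The
``likelihood`` is the tracker's per-point confidence in [0, 1].  Behavior
labels are frame-range tables with columns ``start_frame``, ``end_frame``
(both 0-based, inclusive) and ``behavior``.

This module also carries two small bookkeeping helpers used when planning
recordings: the expected frame count of a session and the per-frame size of
a keypoint representation relative to raw video.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Parts that egocentric normalization requires (see :mod:`ethopose.normalize`).
REQUIRED_PARTS = ("body", "left neck", "right neck")

_HEADER_ROWS = ("scorer", "bodyparts", "coords")


class PoseFormatError(ValueError):
    """Raised when a pose CSV does not follow the expected dialect."""


class LabelValidationError(ValueError):
    """Raised when a label table violates its invariants."""


@dataclass(frozen=True)
class BodyPartSet:
    """Ordered, unique set of tracked body-part names."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.names:
            raise ValueError("BodyPartSet must contain at least one part")
        if len(set(self.names)) != len(self.names):
            raise ValueError("body-part names must be unique")
        object.__setattr__(self, "names", tuple(self.names))

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def index(self, name: str) -> int:
        """Index of *name*, matching case-insensitively on stripped names."""
        wanted = name.strip().lower()
        for i, n in enumerate(self.names):
            if n.strip().lower() == wanted:
                return i
        raise KeyError(f"body part {name!r} not present in {self.names}")

    def has(self, name: str) -> bool:
        try:
            self.index(name)
        except KeyError:
            return False
        return True


@dataclass
class PoseTrack:
    """A multivariate keypoint time series.

    Attributes
    ----------
    parts:
        The tracked body parts, in column order.
    coords:
        Array of shape ``(n_frames, n_parts, 2)`` holding x, y in pixels.
    likelihood:
        Array of shape ``(n_frames, n_parts)`` with tracker confidence
        values in [0, 1].
    fps:
        Recording frame rate in frames per second, if known.
    """

    parts: BodyPartSet
    coords: np.ndarray
    likelihood: np.ndarray
    fps: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.likelihood = np.asarray(self.likelihood, dtype=float)
        n_parts = len(self.parts)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (n_parts, 2):
            raise ValueError(
                f"coords must have shape (n_frames, {n_parts}, 2); "
                f"got {self.coords.shape}"
            )
        if self.likelihood.shape != self.coords.shape[:2]:
            raise ValueError(
                f"likelihood must have shape {self.coords.shape[:2]}; "
                f"got {self.likelihood.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        if np.any(self.likelihood < 0) or np.any(self.likelihood > 1):
            raise ValueError("likelihood values must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_parts(self) -> int:
        return len(self.parts)

    def copy(self) -> "PoseTrack":
        return PoseTrack(self.parts, self.coords.copy(), self.likelihood.copy(), self.fps)


@dataclass(frozen=True)
class TimeSlice:
    """A frame range [start_frame, end_frame] (inclusive) carrying one behavior."""

    start_frame: int
    end_frame: int
    behavior: str

    def __post_init__(self) -> None:
        if self.start_frame < 0:
            raise LabelValidationError(f"start_frame must be >= 0, got {self.start_frame}")
        if self.start_frame > self.end_frame:
            raise LabelValidationError(
                f"start_frame {self.start_frame} > end_frame {self.end_frame}"
            )

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


@dataclass
class LabelSet:
    """A collection of behavior time slices plus the admissible vocabulary."""

    slices: list[TimeSlice]
    vocabulary: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.vocabulary:
            self.vocabulary = {s.behavior for s in self.slices}

    @property
    def n_labeled_frames(self) -> int:
        return sum(s.n_frames for s in self.slices)


# ---------------------------------------------------------------------------
# pose CSV I/O


def read_pose_csv(path: str | Path) -> PoseTrack:
    """Read a pose track from a DeepLabCut-dialect CSV file.

    The file must carry the three DLC header rows; a missing ``likelihood``
    column per part is tolerated (filled with 1.0 and logged) to support
    hand-made fixtures.
    """
    path = Path(path)
    df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    _check_header(df, path)

    parts: list[str] = []
    for part in df.columns.get_level_values(1):
        if part not in parts:
            parts.append(part)

    per_part = {p: [c.lower() for c in df[df.columns[0][0]][p].columns] for p in parts}
    has_likelihood = all(cols[:3] == ["x", "y", "likelihood"] for cols in per_part.values())
    xy_only = all(cols == ["x", "y"] for cols in per_part.values())
    if not has_likelihood and not xy_only:
        bad = next(p for p, c in per_part.items() if c[:3] != ["x", "y", "likelihood"])
        raise PoseFormatError(
            f"{path}: coords header row must cycle x, y, likelihood per part; "
            f"part {bad!r} has columns {per_part[bad]}"
        )
    if xy_only:
        logger.warning("%s: no likelihood columns; filling with 1.0", path)

    values = _to_float(df, path, parts, 3 if has_likelihood else 2)
    n_frames = values.shape[0]
    stride = 3 if has_likelihood else 2
    cube = values.reshape(n_frames, len(parts), stride)
    coords = cube[:, :, :2]
    likelihood = cube[:, :, 2] if has_likelihood else np.ones((n_frames, len(parts)))
    return PoseTrack(BodyPartSet(tuple(parts)), coords, likelihood)


def _check_header(df: pd.DataFrame, path: Path) -> None:
    if df.columns.nlevels != 3:
        raise PoseFormatError(
            f"{path}: expected three header rows (scorer/bodyparts/coords), "
            f"found {df.columns.nlevels}"
        )
    index_names = tuple((n or "").lower() for n in df.columns.names)
    for i, expected in enumerate(_HEADER_ROWS):
        if index_names[i] not in (expected, ""):
            raise PoseFormatError(
                f"{path}: header row {i + 1} should be labelled {expected!r}, "
                f"found {df.columns.names[i]!r}"
            )
    scorers = set(df.columns.get_level_values(0))
    if len(scorers) != 1:
        raise PoseFormatError(f"{path}: expected a single scorer, found {sorted(scorers)}")


def _to_float(df: pd.DataFrame, path: Path, parts: list[str], stride: int) -> np.ndarray:
    try:
        return df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        arr = df.to_numpy()
        for i in range(arr.shape[0]):
            for j in range(arr.shape[1]):
                try:
                    float(arr[i, j])
                except (TypeError, ValueError):
                    raise PoseFormatError(
                        f"{path}: non-numeric cell {arr[i, j]!r} at frame "
                        f"{df.index[i]}, part {parts[j // stride]!r}"
                    ) from None
        raise  # pragma: no cover - unreachable


def write_pose_csv(track: PoseTrack, path: str | Path, scorer: str = "ethopose") -> None:
    """Write *track* as a DeepLabCut-dialect CSV readable by :func:`read_pose_csv`.

    Values are serialized with six decimal places, so a round trip preserves
    coordinates and likelihoods to 1e-6.
    """
    path = Path(path)
    columns = pd.MultiIndex.from_tuples(
        [(scorer, part, coord) for part in track.parts for coord in ("x", "y", "likelihood")],
        names=list(_HEADER_ROWS),
    )
    n = track.n_frames
    data = np.empty((n, 3 * track.n_parts))
    data[:, 0::3] = track.coords[:, :, 0]
    data[:, 1::3] = track.coords[:, :, 1]
    data[:, 2::3] = track.likelihood
    frame = pd.DataFrame(data, columns=columns, index=pd.RangeIndex(n))
    frame.to_csv(path, float_format="%.6f", encoding="utf-8")


def read_pose_hdf(path: str | Path) -> PoseTrack:
    """Read a pose track from a DeepLabCut HDF5 file (pandas HDFStore layout)."""
    df = pd.read_hdf(Path(path))
    parts: list[str] = []
    for part in df.columns.get_level_values("bodyparts"):
        if part not in parts:
            parts.append(part)
    n = len(df)
    coords = np.empty((n, len(parts), 2))
    likelihood = np.ones((n, len(parts)))
    scorer = df.columns.get_level_values(0)[0]
    for j, part in enumerate(parts):
        sub = df[scorer][part]
        coords[:, j, 0] = sub["x"].to_numpy(dtype=float)
        coords[:, j, 1] = sub["y"].to_numpy(dtype=float)
        if "likelihood" in sub.columns:
            likelihood[:, j] = sub["likelihood"].to_numpy(dtype=float)
    return PoseTrack(BodyPartSet(tuple(parts)), coords, likelihood)


# ---------------------------------------------------------------------------
# label table I/O


def read_labels(path: str | Path, vocabulary: Iterable[str] | None = None) -> LabelSet:
    """Read a frame-range label table (columns start_frame, end_frame, behavior)."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"start_frame", "end_frame", "behavior"}
    missing = required - set(df.columns)
    if missing:
        raise LabelValidationError(f"{path}: missing columns {sorted(missing)}")
    slices = []
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        start, end = int(row.start_frame), int(row.end_frame)
        if start > end:
            raise LabelValidationError(
                f"{path} line {row_number}: start_frame {start} > end_frame {end}"
            )
        slices.append(TimeSlice(start, end, str(row.behavior)))
    return LabelSet(slices, set(vocabulary) if vocabulary is not None else set())


def write_labels(labels: LabelSet, path: str | Path) -> None:
    """Write a LabelSet as a start_frame,end_frame,behavior CSV."""
    df = pd.DataFrame(
        {
            "start_frame": [s.start_frame for s in labels.slices],
            "end_frame": [s.end_frame for s in labels.slices],
            "behavior": [s.behavior for s in labels.slices],
        }
    )
    df.to_csv(Path(path), index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# recording arithmetic


def expected_frame_count(duration_s: float, fps: float) -> int:
    """Number of frames a recording of *duration_s* seconds yields at *fps*.

    For example a 10-minute session at 119.88 frames/s gives
    ``round(600 * 119.88) = 71928`` frames.
    """
    if duration_s <= 0 or fps <= 0:
        raise ValueError("duration_s and fps must be positive")
    return int(round(duration_s * fps))


def reduced_bits_per_frame(n_parts: int, coords_per_part: int, bit_depth: int) -> int:
    """Per-frame size, in bits, of a keypoint representation of a video frame.

    Tracking reduces each frame to ``n_parts * coords_per_part`` numbers of
    *bit_depth* bits each — e.g. 10 parts x 2 coordinates x 32 bit = 640 bit,
    versus megabits for the raw decompressed frame.
    """
    for name, v in (("n_parts", n_parts), ("coords_per_part", coords_per_part),
                    ("bit_depth", bit_depth)):
        if not isinstance(v, (int, np.integer)) or v <= 0:
            raise ValueError(f"{name} must be a positive integer, got {v!r}")
    return int(n_parts) * int(coords_per_part) * int(bit_depth)
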