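"""Ethograms and overlay manifests for human quality control.

An ethogram is the classical time-resolved behavior catalogue: one row per
behavior class, filled where that behavior is predicted.  It is emitted as
a CSV (losslessly re-readable) and as a plot.  For checking predictions
against the original footage, an SRT subtitle file is produced that maps
each maximal run of constant prediction to a timed text cue — any ordinary
video player can overlay it, which keeps codecs and rendering out of this
package.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

from .postprocess import PredictionTrack

matplotlib.use("Agg", force=False)


@dataclass
class Ethogram:
    """Frame-indexed predicted behaviors, ready for plotting and export."""

    frame_indices: np.ndarray
    behaviors: np.ndarray
    probabilities: np.ndarray
    reassigned: np.ndarray
    class_order: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": self.frame_indices,
                "behavior": self.behaviors.astype(str),
                "probability": self.probabilities,
                "reassigned": self.reassigned.astype(bool),
            }
        )


def make_ethogram(
    preds: PredictionTrack,
    csv_path: str | Path | None = None,
    plot_path: str | Path | None = None,
    class_order: tuple[str, ...] | None = None,
) -> Ethogram:
    """Build an ethogram from predictions; optionally write CSV and plot."""
    if len(preds) == 0:
        raise ValueError("cannot build an ethogram from empty predictions")
    order = tuple(class_order) if class_order is not None else preds.classes
    etho = Ethogram(
        frame_indices=preds.frame_indices.copy(),
        behaviors=preds.behaviors.copy(),
        probabilities=preds.probabilities.copy(),
        reassigned=preds.reassigned.copy(),
        class_order=order,
    )
    if csv_path is not None:
        etho.to_frame().to_csv(Path(csv_path), index=False, encoding="utf-8")
    if plot_path is not None:
        _plot_ethogram(etho, Path(plot_path))
    return etho


def _plot_ethogram(etho: Ethogram, path: Path) -> None:
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 0.5 * len(etho.class_order) + 1.5))
    for row, behavior in enumerate(etho.class_order):
        mask = etho.behaviors.astype(str) == behavior
        if mask.any():
            ax.plot(
                etho.frame_indices[mask],
                np.full(mask.sum(), row),
                marker="|",
                linestyle="none",
                markersize=12,
            )
    ax.set_yticks(range(len(etho.class_order)))
    ax.set_yticklabels(etho.class_order)
    ax.set_xlabel("frame")
    ax.set_title("Ethogram of predicted behaviors")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def read_ethogram_csv(path: str | Path) -> pd.DataFrame:
    """Re-read an ethogram CSV written by :func:`make_ethogram`."""
    return pd.read_csv(Path(path))


def _srt_timestamp(seconds: float) -> str:
    ms = int(round(seconds * 1000))
    h, rem = divmod(ms, 3_600_000)
    m, rem = divmod(rem, 60_000)
    s, ms = divmod(rem, 1000)
    return f"{h:02d}:{m:02d}:{s:02d},{ms:03d}"


def overlay_manifest(
    preds: PredictionTrack, fps: float, path: str | Path | None = None
) -> str:
    """SRT subtitle text with one cue per run of constant prediction.

    Cue ``k`` spans from the first frame of the run to one frame past its
    last frame, converted to time with *fps*; the cue text is the behavior
    name (suffixed with ``*`` where the prediction was reassigned by a
    tuple threshold).  Consecutive cues therefore partition the predicted
    span exactly.
    """
    if not fps or fps <= 0:
        raise ValueError("a positive fps is required to build an overlay manifest")
    cues: list[tuple[int, int, str]] = []
    if len(preds):
        frames = preds.frame_indices
        labels = preds.behaviors.astype(str)
        marks = np.char.add(labels.astype(str),
                            np.where(preds.reassigned, " *", ""))
        start = 0
        for i in range(1, len(preds) + 1):
            boundary = (
                i == len(preds)
                or marks[i] != marks[start]
                or frames[i] != frames[i - 1] + 1
            )
            if boundary:
                cues.append((int(frames[start]), int(frames[i - 1]), marks[start]))
                start = i
    lines = []
    for k, (first, last, text) in enumerate(cues, start=1):
        lines.append(str(k))
        lines.append(
            f"{_srt_timestamp(first / fps)} --> {_srt_timestamp((last + 1) / fps)}"
        )
        lines.append(text)
        lines.append("")
    srt = "\n".join(lines)
    if path is not None:
        Path(path).write_text(srt, encoding="utf-8")
    return srt
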