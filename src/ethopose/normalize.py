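"""Egocentric normalization of pose tracks.

Tracked coordinates are absolute pixel positions; behavior is easier to
classify in a body-centered frame.  Each frame is normalized independently:

1. the body point is translated into the origin (every part is shifted by
   the displacement vector ``s = (-x_body, -y_body)``);
2. a synthetic *middle neck* vector is formed from the two neck points
   (by default their difference, left minus right);
3. the signed angle of that vector, measured from the positive y-axis as
   ``degrees(arctan2(v_x, v_y))``, is taken as the normalization rotation;
4. the counter-clockwise rotation matrix for that angle is applied to all
   parts, which maps the middle-neck vector onto the non-negative y-axis.

The result is invariant under rigid motion of the animal in the image:
global position and heading are removed, relative geometry (all pairwise
inter-part distances) is preserved exactly.  Frames with a degenerate
(zero) middle-neck vector are assigned a rotation of 0° and flagged, never
dropped, so frame alignment with label tables is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import PoseTrack

__all__ = [
    "NormalizationState",
    "displacement_vector",
    "translate_frame",
    "middle_neck",
    "rotation_angle",
    "rotation_matrix",
    "apply_rotation",
    "normalize_track",
]


@dataclass
class NormalizationState:
    """Per-frame record of the normalization applied to a track.

    Attributes
    ----------
    displacement:
        ``(n_frames, 2)`` translation applied to each frame (pixels).
    middle_neck:
        ``(n_frames, 2)`` middle-neck vector on the translated coordinates.
    rotation_deg:
        ``(n_frames,)`` rotation applied, degrees in (-180, 180].
    degenerate:
        ``(n_frames,)`` boolean; True where the middle-neck vector was zero
        and the rotation defaulted to 0°.
    """

    displacement: np.ndarray
    middle_neck: np.ndarray
    rotation_deg: np.ndarray
    degenerate: np.ndarray

    @property
    def n_degenerate(self) -> int:
        return int(self.degenerate.sum())

    def rotation_matrices(self) -> np.ndarray:
        """The ``(n_frames, 2, 2)`` rotation matrices actually applied."""
        theta = np.radians(self.rotation_deg)
        c, s = np.cos(theta), np.sin(theta)
        return np.stack(
            [np.stack([c, -s], axis=-1), np.stack([s, c], axis=-1)], axis=-2
        )


def displacement_vector(frame: np.ndarray, body_index: int) -> np.ndarray:
    """Translation that moves the body point of a single frame to the origin."""
    return -np.asarray(frame, dtype=float)[body_index]


def translate_frame(frame: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Shift every part of a single ``(n_parts, 2)`` frame by the vector *s*."""
    s = np.asarray(s, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("translation vector must be finite")
    return np.asarray(frame, dtype=float) + s


def middle_neck(
    frame: np.ndarray,
    left_index: int,
    right_index: int,
    mode: str = "difference",
) -> np.ndarray:
    """Synthetic middle-neck vector of a single (already translated) frame.

    ``mode="difference"`` (default) returns left neck minus right neck;
    ``mode="midpoint"`` returns their midpoint.
    """
    frame = np.asarray(frame, dtype=float)
    if mode == "difference":
        return frame[left_index] - frame[right_index]
    if mode == "midpoint":
        return (frame[left_index] + frame[right_index]) / 2.0
    raise ValueError(f"unknown middle-neck mode {mode!r}")


def rotation_angle(v: np.ndarray) -> float:
    """Signed angle of *v* from the positive y-axis, in degrees (-180, 180]."""
    v = np.asarray(v, dtype=float)
    deg = float(np.degrees(np.arctan2(v[0], v[1])))
    return 180.0 if deg <= -180.0 else deg


def rotation_matrix(angle_deg: float) -> np.ndarray:
    """Counter-clockwise 2x2 rotation matrix for *angle_deg* degrees."""
    theta = np.radians(angle_deg)
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def apply_rotation(frame: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate every part of a single ``(n_parts, 2)`` frame counter-clockwise."""
    return np.asarray(frame, dtype=float) @ rotation_matrix(angle_deg).T


def normalize_track(
    track: PoseTrack, middle_neck_mode: str = "difference"
) -> tuple[PoseTrack, NormalizationState]:
    """Normalize every frame of *track* into the egocentric body frame.

    Returns the normalized track (likelihoods passed through unchanged) and
    the per-frame :class:`NormalizationState`.  After normalization every
    frame has the body at the origin and the middle-neck vector on the
    non-negative y-axis (x-component zero to numerical precision).
    """
    parts = track.parts
    try:
        i_body = parts.index("body")
        i_left = parts.index("left neck")
        i_right = parts.index("right neck")
    except KeyError as exc:
        raise ValueError(f"normalization requires part {exc.args[0]}") from exc

    coords = track.coords
    displacement = -coords[:, i_body, :]
    translated = coords + displacement[:, None, :]

    if middle_neck_mode == "difference":
        v = translated[:, i_left, :] - translated[:, i_right, :]
    elif middle_neck_mode == "midpoint":
        v = (translated[:, i_left, :] + translated[:, i_right, :]) / 2.0
    else:
        raise ValueError(f"unknown middle-neck mode {middle_neck_mode!r}")

    degenerate = (v[:, 0] == 0.0) & (v[:, 1] == 0.0)
    rotation_deg = np.degrees(np.arctan2(v[:, 0], v[:, 1]))
    rotation_deg[degenerate] = 0.0
    rotation_deg[rotation_deg <= -180.0] = 180.0

    state = NormalizationState(displacement, v, rotation_deg, degenerate)
    rotated = np.einsum("nij,npj->npi", state.rotation_matrices(), translated)
    out = PoseTrack(parts, rotated, track.likelihood.copy(), track.fps)
    return out, state
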