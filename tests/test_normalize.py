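import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from conftest import make_track
from ethopose.normalize import (
    apply_rotation,
    displacement_vector,
    middle_neck,
    normalize_track,
    rotation_angle,
    rotation_matrix,
    translate_frame,
)

finite_frames = arrays(
    float,
    (10, 2),
    elements=st.floats(-1e4, 1e4, allow_nan=False, allow_infinity=False),
)


class TestFrameOperations:
    @pytest.mark.parametrize(
        "body,expected",
        [((3, 4), (-3, -4)), ((0, 0), (0, 0)), ((-2.5, 7), (2.5, -7))],
    )
    def test_displacement_is_negated_body(self, body, expected):
        frame = np.array([[1.0, 1.0], list(body)])
        np.testing.assert_allclose(displacement_vector(frame, 1), expected)

    def test_translate_shifts_every_part(self):
        frame = np.array([[5.0, 5.0], [1.0, 2.0]])
        out = translate_frame(frame, (-3.0, -4.0))
        np.testing.assert_allclose(out, [[2.0, 1.0], [-2.0, -2.0]])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(frame=finite_frames, sx=st.floats(-100, 100), sy=st.floats(-100, 100))
    def test_translation_preserves_pairwise_distances(self, frame, sx, sy):
        out = translate_frame(frame, (sx, sy))
        d0 = np.linalg.norm(frame[:, None] - frame[None, :], axis=-1)
        d1 = np.linalg.norm(out[:, None] - out[None, :], axis=-1)
        np.testing.assert_allclose(d0, d1, atol=1e-9)

    @pytest.mark.parametrize(
        "left,right,expected",
        [((2, 3), (1, 1), (1, 2)), ((5, 5), (5, 5), (0, 0)), ((0, 1), (0, -1), (0, 2))],
    )
    def test_middle_neck_difference(self, left, right, expected):
        frame = np.array([list(left), list(right)])
        np.testing.assert_allclose(middle_neck(frame, 0, 1), expected)

    def test_middle_neck_midpoint_mode(self):
        frame = np.array([[2.0, 4.0], [4.0, 0.0]])
        np.testing.assert_allclose(middle_neck(frame, 0, 1, "midpoint"), (3.0, 2.0))


class TestRotation:
    @pytest.mark.parametrize(
        "v,expected_deg",
        [
            ((0, 1), 0.0),
            ((1, 0), 90.0),
            ((1, 1), 45.0),
            ((-1, 0), -90.0),
            ((0, -1), 180.0),
        ],
    )
    def test_angle_measured_from_positive_y_axis(self, v, expected_deg):
        assert rotation_angle(np.array(v, dtype=float)) == pytest.approx(expected_deg)

    def test_angle_range_excludes_minus_180(self):
        assert rotation_angle(np.array([-0.0, -1.0])) == 180.0

    def test_rotation_matrix_is_special_orthogonal(self):
        for deg in (-170.0, -45.0, 0.0, 30.0, 179.0):
            r = rotation_matrix(deg)
            np.testing.assert_allclose(r @ r.T, np.eye(2), atol=1e-12)
            assert np.linalg.det(r) == pytest.approx(1.0)

    def test_quarter_turn_maps_x_axis_to_y_axis(self):
        out = apply_rotation(np.array([[1.0, 0.0]]), 90.0)
        np.testing.assert_allclose(out, [[0.0, 1.0]], atol=1e-12)

    def test_zero_rotation_is_identity(self):
        frame = np.array([[3.0, -2.0], [0.5, 8.0]])
        np.testing.assert_allclose(apply_rotation(frame, 0.0), frame)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(frame=finite_frames, deg=st.floats(-180, 180))
    def test_rotation_preserves_norms(self, frame, deg):
        out = apply_rotation(frame, deg)
        np.testing.assert_allclose(
            np.linalg.norm(out, axis=1), np.linalg.norm(frame, axis=1), atol=1e-6
        )


class TestNormalizeTrack:
    def test_output_contract(self, random_track):
        norm, state = normalize_track(random_track)
        i_body = norm.parts.index("body")
        i_left = norm.parts.index("left neck")
        i_right = norm.parts.index("right neck")
        np.testing.assert_allclose(norm.coords[:, i_body], 0.0, atol=1e-9)
        v = norm.coords[:, i_left] - norm.coords[:, i_right]
        np.testing.assert_allclose(v[:, 0], 0.0, atol=1e-6)
        assert np.all(v[:, 1] >= -1e-9)
        np.testing.assert_allclose(norm.likelihood, random_track.likelihood)
        assert state.n_degenerate == 0

    def test_idempotence(self, random_track):
        once, _ = normalize_track(random_track)
        twice, state = normalize_track(once)
        np.testing.assert_allclose(twice.coords, once.coords, atol=1e-6)
        np.testing.assert_allclose(state.rotation_deg, 0.0, atol=1e-6)

    def test_rigid_motion_invariance(self, random_track, rng):
        base, _ = normalize_track(random_track)
        theta = np.radians(37.0)
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        moved = make_track(
            random_track.coords @ rot.T + np.array([50.0, -20.0]),
            random_track.parts,
            random_track.likelihood,
        )
        out, _ = normalize_track(moved)
        np.testing.assert_allclose(out.coords, base.coords, atol=1e-6)

    def test_pairwise_distances_preserved(self, random_track):
        norm, _ = normalize_track(random_track)
        d0 = np.linalg.norm(
            random_track.coords[:, :, None] - random_track.coords[:, None], axis=-1
        )
        d1 = np.linalg.norm(norm.coords[:, :, None] - norm.coords[:, None], axis=-1)
        np.testing.assert_allclose(d0, d1, atol=1e-9)

    def test_degenerate_frames_flagged_not_dropped(self, parts, rng):
        coords = rng.uniform(0, 10, size=(3, len(parts), 2))
        coords[1] = np.zeros((len(parts), 2))  # necks coincide in frame 1
        track = make_track(coords, parts)
        norm, state = normalize_track(track)
        assert norm.n_frames == 3
        assert state.n_degenerate == 1
        assert state.rotation_deg[1] == 0.0

    def test_missing_required_part_is_an_error(self, rng):
        from ethopose.io import BodyPartSet

        parts = BodyPartSet(("head", "tail"))
        track = make_track(rng.uniform(size=(5, 2, 2)), parts)
        with pytest.raises(ValueError, match="body"):
            normalize_track(track)

    def test_midpoint_mode_aligns_neck_midpoint(self, random_track):
        norm, _ = normalize_track(random_track, middle_neck_mode="midpoint")
        i_left = norm.parts.index("left neck")
        i_right = norm.parts.index("right neck")
        mid = (norm.coords[:, i_left] + norm.coords[:, i_right]) / 2
        np.testing.assert_allclose(mid[:, 0], 0.0, atol=1e-6)
        assert np.all(mid[:, 1] >= -1e-9)
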