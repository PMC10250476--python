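import numpy as np
import pytest

from ethopose.labeling import validate
from ethopose.normalize import normalize_track
from ethopose.simulate import (
    BEHAVIORS,
    DEFAULT_PROFILE,
    DEFAULT_TEMPLATE,
    BehaviorScript,
    SimConfig,
    generate,
    make_benchmark,
)


class TestScript:
    def test_unknown_behavior_rejected(self):
        with pytest.raises(ValueError, match="flying"):
            BehaviorScript([("flying", 10)])

    def test_non_positive_duration_rejected(self):
        with pytest.raises(ValueError):
            BehaviorScript([("standing", 0)])


class TestGenerate:
    def test_zero_noise_standing_is_static_template(self):
        config = SimConfig(noise_sd=0.0, seed=5)
        track, labels = generate(BehaviorScript([("standing", 50)]), config)
        assert track.n_frames == 50
        np.testing.assert_array_equal(track.coords, np.broadcast_to(
            track.coords[0], track.coords.shape))
        center = np.array([config.canvas[0] / 2, config.canvas[1] / 2])
        for j, part in enumerate(track.parts):
            np.testing.assert_allclose(
                track.coords[0, j], center + np.array(DEFAULT_TEMPLATE[part])
            )

    def test_determinism_under_seed(self):
        script = BehaviorScript([(b, 30) for b in BEHAVIORS])
        a_track, a_labels = generate(script, SimConfig(seed=11))
        b_track, b_labels = generate(script, SimConfig(seed=11))
        np.testing.assert_array_equal(a_track.coords, b_track.coords)
        np.testing.assert_array_equal(a_track.likelihood, b_track.likelihood)
        assert a_labels.slices == b_labels.slices

    def test_different_seeds_differ(self):
        script = BehaviorScript([("standing", 30)])
        a, _ = generate(script, SimConfig(seed=1))
        b, _ = generate(script, SimConfig(seed=2))
        assert not np.array_equal(a.coords, b.coords)

    def test_bookkeeping_of_slices_and_counts(self):
        script = BehaviorScript([(b, 200) for b in BEHAVIORS])
        track, labels = generate(script, SimConfig(seed=0))
        assert track.n_frames == 1400
        assert len(labels.slices) == 7
        assert all(s.n_frames == 200 for s in labels.slices)
        # slices tile the track exactly
        starts = [s.start_frame for s in labels.slices]
        ends = [s.end_frame for s in labels.slices]
        assert starts[0] == 0 and ends[-1] == 1399
        assert all(starts[i + 1] == ends[i] + 1 for i in range(6))

    def test_beak_occlusion_drops_likelihood_below_half(self):
        track, _ = generate(
            BehaviorScript([("standing", 500)]), SimConfig(seed=3)
        )
        beak = track.parts.index("beak")
        occluded = track.likelihood[:, beak] < 0.5
        assert 0.3 < occluded.mean() < 0.9
        assert np.all(track.likelihood[occluded, beak] < 0.5)
        others = np.delete(track.likelihood, beak, axis=1)
        assert others.mean() > 0.9

    def test_normalized_walking_keeps_non_head_parts_static_at_zero_noise(self):
        config = SimConfig(noise_sd=0.0, seed=9)
        track, _ = generate(BehaviorScript([("walking", 80)]), config)
        norm, _ = normalize_track(track)
        moving = {"head", "beak"}
        for j, part in enumerate(norm.parts):
            spread = np.ptp(norm.coords[:, j, :], axis=0).max()
            if part in moving:
                assert spread > 1.0  # head-bob survives normalization
            else:
                assert spread < 1e-6  # translation removed exactly

    def test_shakes_oscillate_faster_than_standing_drifts(self):
        config = SimConfig(seed=4)
        shake, _ = generate(BehaviorScript([("head_shake", 400)]), config)
        stand, _ = generate(BehaviorScript([("standing", 400)]), config)
        head = shake.parts.index("head")

        def lag5_autocorr(track):
            # the neck line is rotated onto +y, so the lateral head motion
            # ends up in the normalized y coordinate
            norm, _ = normalize_track(track)
            y = norm.coords[:, head, 1]
            y = y - y.mean()
            return np.corrcoef(y[:-5], y[5:])[0, 1]

        # half a shake period apart -> anticorrelated; drift -> correlated
        assert lag5_autocorr(shake) < -0.2
        assert lag5_autocorr(stand) > 0.2


class TestBenchmark:
    def test_profile_shares_and_validation(self):
        track, labels = make_benchmark(SimConfig(seed=2), total_frames=20_000)
        assert track.n_frames == 20_000
        report = validate(labels, track)
        assert report.is_valid
        counts: dict[str, int] = {}
        for s in labels.slices:
            counts[s.behavior] = counts.get(s.behavior, 0) + s.n_frames
        assert sum(counts.values()) == 20_000
        for rare in ("head_shake", "tail_shake"):
            assert counts[rare] / 20_000 < 0.05
        assert counts["standing"] == max(counts.values())

    def test_uniform_profile_gives_near_equal_counts(self):
        profile = {b: 1.0 for b in BEHAVIORS}
        _, labels = make_benchmark(
            SimConfig(seed=2), profile=profile, total_frames=7_000, round_frames=700
        )
        counts: dict[str, int] = {}
        for s in labels.slices:
            counts[s.behavior] = counts.get(s.behavior, 0) + s.n_frames
        assert max(counts.values()) - min(counts.values()) <= 700 / len(BEHAVIORS)

    def test_zero_share_rejected(self):
        profile = dict(DEFAULT_PROFILE)
        profile["walking"] = 0.0
        with pytest.raises(ValueError, match="walking"):
            make_benchmark(SimConfig(seed=0), profile=profile, total_frames=1000)

    def test_incomplete_profile_rejected(self):
        with pytest.raises(ValueError, match="behaviors"):
            make_benchmark(SimConfig(seed=0), profile={"standing": 1.0})

    def test_every_behavior_present_in_every_fifth(self):
        _, labels = make_benchmark(SimConfig(seed=1), total_frames=20_000)
        for block in range(5):
            lo, hi = block * 4_000, (block + 1) * 4_000
            present = {
                s.behavior
                for s in labels.slices
                if s.start_frame < hi and s.end_frame >= lo
            }
            assert present == set(BEHAVIORS)
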