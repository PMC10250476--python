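"""Synthetic labeled pose tracks for a seven-behavior pigeon ethogram.

The generator emits multivariate keypoint time series in the same shape as
markerless-tracking output (10 body parts, x/y pixels plus a per-point
likelihood) together with exactly matching frame-range labels, so every
pipeline stage can be exercised without any recorded video.

The body plan is a bilaterally symmetric 10-point silhouette (head, beak,
left/right neck, body, left/right wing up/down points, tail) placed on a
1280x960 canvas.  Behaviors are deliberately simple harmonic or linear
motions — the simulator's job is to carry the *statistical* structure of
the problem (static posture classes vs. fast oscillatory classes, common
vs. rare behaviors, a noisily tracked and often-occluded beak), not
anatomical realism:

- ``standing``   template plus tracking jitter, with a slow idle drift of
                 the head and tail (an autoregressive wander much slower
                 than a shake cycle, its amplitude tied to the jitter
                 scale so that zero-noise tracks are exactly static);
- ``walking``    global translation with heading wander, plus the
                 characteristic head-bobbing of pigeon locomotion (without
                 it, per-frame egocentric normalization would cancel the
                 translation and leave walking indistinguishable from
                 standing);
- ``eating``     head and beak lowered toward the feeder with periodic
                 dipping;
- ``head_shake`` fast lateral sinusoidal head/beak oscillation;
- ``tail_shake`` fast lateral sinusoidal tail oscillation;
- ``preening``   head/beak excursion to a wing point, alternating contact
                 episodes;
- ``fluffing``   wing points displaced outward with amplified ruffling
                 jitter.

The shake amplitude (10 px) is deliberately of the same order as the
*effective* lateral keypoint noise after egocentric normalization — direct
jitter (default 3 px, typical tracking error) plus the heading noise that
jittered neck points inject through the rotation step (the neck baseline
is 60 px, so 3 px jitter per neck point means roughly 4 degrees of heading
noise, i.e. several pixels of lateral smear at head radius).  A *single*
frame of a shake is therefore ambiguous against standing while a 16-frame
window sees the full oscillation — the property that makes window size
matter for the dynamic behaviors.  The slow standing drift completes that
mechanism: the *marginal* per-frame distribution of the head position is
nearly the same in standing and head-shake bouts, so only the temporal
pattern inside a window separates them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import BodyPartSet, LabelSet, PoseTrack, TimeSlice

BEHAVIORS = (
    "eating",
    "standing",
    "walking",
    "head_shake",
    "tail_shake",
    "preening",
    "fluffing",
)

#: Body-frame template offsets (pixels, y pointing "up" along the spine).
DEFAULT_TEMPLATE: dict[str, tuple[float, float]] = {
    "head": (0.0, 90.0),
    "beak": (0.0, 120.0),
    "left neck": (-30.0, 60.0),
    "right neck": (30.0, 60.0),
    "body": (0.0, 0.0),
    "left wing up": (-45.0, 30.0),
    "left wing down": (-45.0, -30.0),
    "right wing up": (45.0, 30.0),
    "right wing down": (45.0, -30.0),
    "tail": (0.0, -80.0),
}

_WING_PARTS = ("left wing up", "left wing down", "right wing up", "right wing down")

#: Class shares mimicking the natural skew of the behaviors: mostly
#: standing/eating/walking, shakes rare (< 5% of frames each).
DEFAULT_PROFILE: dict[str, float] = {
    "standing": 0.30,
    "eating": 0.25,
    "walking": 0.20,
    "preening": 0.10,
    "fluffing": 0.07,
    "head_shake": 0.04,
    "tail_shake": 0.04,
}


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters.

    ``noise_sd`` is the i.i.d. Gaussian jitter per keypoint in pixels;
    ``oscillation_period`` the head/tail-shake period in frames;
    ``walk_speed`` the translation speed in pixels/frame; and
    ``occlusion_rate`` the fraction of frames on which the beak is occluded
    (likelihood dropped well below 0.5 and position glitched).
    """

    fps: float = 119.88
    noise_sd: float = 3.0
    oscillation_period: float = 10.0
    walk_speed: float = 2.0
    occlusion_rate: float = 0.6
    seed: int = 0
    canvas: tuple[float, float] = (1280.0, 960.0)
    template: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TEMPLATE)
    )
    shake_amplitude: float = 10.0
    head_bob_amplitude: float = 12.0
    head_bob_period: float = 15.0
    eating_dip_period: float = 40.0
    preening_contact_frames: int = 20
    fluff_scale: float = 1.6
    turn_sd: float = 0.02
    idle_drift_scale: float = 2.5  # standing head/tail drift sd, x noise_sd
    idle_drift_rho: float = 0.98  # AR(1) coefficient of the idle drift

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (0.0 <= self.occlusion_rate <= 1.0):
            raise ValueError("occlusion_rate must lie in [0, 1]")


@dataclass
class BehaviorScript:
    """Ordered (behavior, duration-in-frames) segments to synthesize."""

    segments: list[tuple[str, int]]

    def __post_init__(self) -> None:
        for behavior, duration in self.segments:
            if behavior not in BEHAVIORS:
                raise ValueError(
                    f"unknown behavior {behavior!r}; known: {BEHAVIORS}"
                )
            if duration < 1:
                raise ValueError(f"segment durations must be >= 1, got {duration}")

    @property
    def n_frames(self) -> int:
        return sum(d for _, d in self.segments)


def _ar1_drift(duration: int, config: SimConfig, rng) -> np.ndarray:
    """Slow stationary AR(1) wander; exactly zero when noise_sd is zero."""
    sd = config.idle_drift_scale * config.noise_sd
    if sd == 0.0:
        return np.zeros(duration)
    rho = config.idle_drift_rho
    innovation_sd = sd * np.sqrt(1.0 - rho**2)
    drift = np.empty(duration)
    drift[0] = rng.normal(0.0, sd)
    shocks = rng.normal(0.0, innovation_sd, size=duration)
    for i in range(1, duration):
        drift[i] = rho * drift[i - 1] + shocks[i]
    return drift


def _segment_offsets(
    behavior: str, duration: int, config: SimConfig, parts: list[str], rng
) -> np.ndarray:
    """Body-frame offsets ``(duration, n_parts, 2)`` for one segment."""
    base = np.array([config.template[p] for p in parts])
    offsets = np.tile(base, (duration, 1, 1))
    t = np.arange(duration, dtype=float)
    idx = {p: i for i, p in enumerate(parts)}

    if behavior == "standing":
        head_drift = _ar1_drift(duration, config, rng)
        tail_drift = _ar1_drift(duration, config, rng)
        offsets[:, idx["head"], 0] += head_drift
        offsets[:, idx["beak"], 0] += head_drift
        offsets[:, idx["tail"], 0] += tail_drift
    elif behavior == "walking":
        bob = config.head_bob_amplitude * np.sin(
            2 * np.pi * t / config.head_bob_period
        )
        offsets[:, idx["head"], 1] += bob
        offsets[:, idx["beak"], 1] += bob
    elif behavior == "eating":
        dip = 0.5 * (1 + np.sin(2 * np.pi * t / config.eating_dip_period))
        head_y = 25.0 + 20.0 * dip
        offsets[:, idx["head"], 1] = head_y
        offsets[:, idx["beak"], 1] = head_y - 25.0
    elif behavior == "head_shake":
        wave = config.shake_amplitude * np.sin(
            2 * np.pi * t / config.oscillation_period
        )
        offsets[:, idx["head"], 0] += wave
        offsets[:, idx["beak"], 0] += 1.3 * wave
    elif behavior == "tail_shake":
        offsets[:, idx["tail"], 0] += config.shake_amplitude * np.sin(
            2 * np.pi * t / config.oscillation_period
        )
    elif behavior == "preening":
        contact = (t // config.preening_contact_frames) % 2 == 0
        offsets[:, idx["head"], :] = np.where(
            contact[:, None], [-38.0, -18.0], [-20.0, 30.0]
        )
        offsets[:, idx["beak"], :] = np.where(
            contact[:, None], [-46.0, -28.0], [-26.0, 12.0]
        )
    elif behavior == "fluffing":
        for p in _WING_PARTS:
            offsets[:, idx[p], 0] *= config.fluff_scale
            offsets[:, idx[p], :] += rng.normal(
                0.0, 1.5 * config.noise_sd, size=(duration, 2)
            )
    else:  # pragma: no cover - guarded by BehaviorScript
        raise ValueError(f"unknown behavior {behavior!r}")
    return offsets


def generate(script: BehaviorScript, config: SimConfig) -> tuple[PoseTrack, LabelSet]:
    """Synthesize a pose track plus exactly mirroring frame-range labels.

    Fully deterministic for a given script and config (seed included).
    """
    rng = np.random.default_rng(config.seed)
    parts = list(config.template)
    n_parts = len(parts)
    n_total = script.n_frames
    width, height = config.canvas
    margin = 160.0

    coords = np.empty((n_total, n_parts, 2))
    likelihood = np.empty((n_total, n_parts))
    slices: list[TimeSlice] = []

    pos = np.array([width / 2.0, height / 2.0])
    heading = 0.0
    cursor = 0
    for behavior, duration in script.segments:
        offsets = _segment_offsets(behavior, duration, config, parts, rng)

        headings = np.full(duration, heading)
        positions = np.tile(pos, (duration, 1))
        if behavior == "walking":
            turns = rng.normal(0.0, config.turn_sd, size=duration)
            p = pos.copy()
            h = heading
            for i in range(duration):
                h += turns[i]
                step = config.walk_speed * np.array([np.cos(h), np.sin(h)])
                nxt = p + step
                if not (margin <= nxt[0] <= width - margin):
                    h = np.pi - h
                if not (margin <= nxt[1] <= height - margin):
                    h = -h
                p = p + config.walk_speed * np.array([np.cos(h), np.sin(h)])
                headings[i] = h
                positions[i] = p
            pos, heading = p, h

        c, s = np.cos(headings), np.sin(headings)
        rot = np.stack(
            [np.stack([c, -s], axis=-1), np.stack([s, c], axis=-1)], axis=-2
        )
        world = positions[:, None, :] + np.einsum("nij,npj->npi", rot, offsets)
        world += rng.normal(0.0, config.noise_sd, size=world.shape)

        lik = np.clip(rng.normal(0.95, 0.02, size=(duration, n_parts)), 0.0, 1.0)
        beak = parts.index("beak")
        occluded = rng.random(duration) < config.occlusion_rate
        lik[occluded, beak] = rng.uniform(0.05, 0.35, size=int(occluded.sum()))
        world[occluded, beak, :] += rng.normal(
            0.0, 8.0 * config.noise_sd, size=(int(occluded.sum()), 2)
        )

        coords[cursor : cursor + duration] = world
        likelihood[cursor : cursor + duration] = lik
        slices.append(TimeSlice(cursor, cursor + duration - 1, behavior))
        cursor += duration

    track = PoseTrack(BodyPartSet(tuple(parts)), coords, likelihood, fps=config.fps)
    return track, LabelSet(slices, set(BEHAVIORS))


def make_benchmark(
    config: SimConfig | None = None,
    profile: dict[str, float] | None = None,
    total_frames: int = 50_000,
    round_frames: int = 2_000,
) -> tuple[PoseTrack, LabelSet]:
    """A long interleaved benchmark track with realistic class imbalance.

    The track is built from shuffled "rounds" of ``round_frames`` frames,
    each containing one bout per behavior with duration proportional to its
    profile share, so every behavior occurs throughout the recording (and
    therefore inside every contiguous cross-validation block).
    """
    config = config or SimConfig()
    profile = dict(profile) if profile is not None else dict(DEFAULT_PROFILE)
    if set(profile) != set(BEHAVIORS):
        raise ValueError(f"profile must cover exactly the behaviors {BEHAVIORS}")
    for behavior, share in profile.items():
        if share <= 0:
            raise ValueError(f"behavior {behavior!r} has non-positive share {share}")
    total_share = sum(profile.values())

    durations = {
        b: max(1, int(round(round_frames * share / total_share)))
        for b, share in profile.items()
    }
    # absorb rounding drift into the largest class
    drift = round_frames - sum(durations.values())
    durations[max(durations, key=durations.get)] += drift

    order_rng = np.random.default_rng(np.random.SeedSequence((config.seed, 90571)))
    segments: list[tuple[str, int]] = []
    produced = 0
    while produced < total_frames:
        for b in order_rng.permutation(list(profile)):
            if produced >= total_frames:
                break
            d = min(durations[str(b)], total_frames - produced)
            segments.append((str(b), d))
            produced += d
    return generate(BehaviorScript(segments), config)
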