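"""Synthetic multi-actor activity corpora with ground-truth event classes.

Emulates the statistical structure of a naturalistic activity corpus at
desk scale: each activity is a script of 6-7 events drawn from a shared
pool of event classes, performed by an actor in some environment.  Each
event class has its own short-run dynamics — a stable linear recurrence
pulling the motion features toward a class-specific attractor — so a
sequence predictor can learn class-distinct structure, and class changes
produce feature jumps a segmentation model can discover.

The scene-vector block layout mirrors the modeled corpus: a continuous
motion block driven by the class dynamics, a semantic block that is
piecewise-constant within an event, two sparse object-change flags that
spike at event onsets, and one slowly varying luminance dimension.
Simulated raters perturb the true boundaries with jitter, misses and
Poisson false alarms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .datamodel import (
    DEFAULT_BLOCK_LAYOUT,
    DEFAULT_DT,
    Activity,
    Corpus,
    RaterSegmentation,
    block_slices,
)


@dataclass
class EventClass:
    """One event class: stable linear dynamics toward an attractor."""

    id: int
    transition: np.ndarray      # (M, M) motion-block recurrence, spectral radius < 1
    motion_offset: np.ndarray   # (M,) attractor of the motion block
    semantic_vector: np.ndarray  # (S,) piecewise-constant semantic signature
    emission_noise_sd: float = 0.1

    def __post_init__(self):
        rad = max(abs(np.linalg.eigvals(self.transition)))
        if rad >= 1.0:
            raise ValueError(f"unstable dynamics: spectral radius {rad:.3f} >= 1")


@dataclass
class Script:
    """Ordered event-class ids with a per-event duration range (timesteps)."""

    event_ids: list[int]
    duration_range: tuple[int, int] = (10, 20)

    def __post_init__(self):
        if not (6 <= len(self.event_ids) <= 7):
            raise ValueError("scripts have 6 to 7 events")
        if self.duration_range[0] < 3:
            raise ValueError("event durations must be >= 3 timesteps")


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic corpus generator.

    ``separation`` scales the pairwise distances between class attractors
    (in feature units); class structure is easy to recover when it is
    large relative to ``noise_sd``.  Actor offsets add a per-actor style
    shift so the same event class looks slightly different across actors.
    """

    n_classes: int = 4
    D: int = 30
    block_layout: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_BLOCK_LAYOUT)
    )
    separation: float = 4.0
    noise_sd: float = 0.1
    n_actors: int = 3
    actor_offset_sd: float = 0.2
    n_train: int = 30
    n_validation: int = 6
    events_per_activity: tuple[int, int] = (6, 7)
    duration_range: tuple[int, int] = (10, 20)
    spectral_radius: float = 0.7
    dt: float = DEFAULT_DT
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if sum(self.block_layout.values()) != self.D:
            raise ValueError("block layout must sum to D")


def _stable_matrix(rng: np.random.Generator, M: int, radius: float) -> np.ndarray:
    A = rng.normal(size=(M, M)) / np.sqrt(M)
    rad = max(abs(np.linalg.eigvals(A)))
    return A * (radius / rad)


def make_classes(config: GeneratorConfig, rng: np.random.Generator) -> list[EventClass]:
    """Draw event classes with random stable dynamics.

    Attractor offsets are unit-scale Gaussian draws multiplied by
    ``separation``, so mean pairwise attractor distance scales linearly
    with it; ``separation=0`` collapses all offsets to zero.
    """
    M = config.block_layout["motion"]
    S = config.block_layout["semantic"]
    classes = []
    for cid in range(config.n_classes):
        classes.append(
            EventClass(
                id=cid,
                transition=_stable_matrix(rng, M, config.spectral_radius),
                motion_offset=rng.normal(size=M) / np.sqrt(M) * config.separation,
                semantic_vector=rng.normal(size=S) / np.sqrt(S) * config.separation,
                emission_noise_sd=config.noise_sd,
            )
        )
    return classes


def generate_activity(
    activity_id: str,
    script: Script,
    classes: Sequence[EventClass],
    actor_offset: np.ndarray,
    config: GeneratorConfig,
    rng: np.random.Generator,
    actor_id: Optional[str] = None,
    environment_id: Optional[str] = None,
) -> Activity:
    """Concatenate per-event trajectories into one labeled activity.

    Within each event the motion block evolves as
    ``x(t+1) = c + A (x(t) - c) + noise`` with the class's recurrence A
    and attractor ``c = motion_offset + actor_offset``; the semantic
    block sits at the class signature (plus noise), the object-change
    flags spike at event onsets, and the luminance dimension follows a
    slow AR(1).
    """
    by_id = {c.id: c for c in classes}
    sl = block_slices(config.block_layout)
    lo, hi = script.duration_range
    durations = [int(rng.integers(lo, hi + 1)) for _ in script.event_ids]
    T = sum(durations)
    scenes = np.zeros((T, config.D))
    labels = np.zeros(T, dtype=int)

    M = config.block_layout["motion"]
    x = rng.normal(size=M) * config.noise_sd  # initial motion state
    lum = 0.0
    t = 0
    for eid, dur in zip(script.event_ids, durations):
        cls = by_id[eid]
        c = cls.motion_offset + actor_offset
        for j in range(dur):
            x = c + cls.transition @ (x - c) + rng.normal(size=M) * cls.emission_noise_sd
            lum = 0.95 * lum + rng.normal() * 0.05
            scenes[t, sl["motion"]] = x
            scenes[t, sl["semantic"]] = (
                cls.semantic_vector
                + rng.normal(size=len(cls.semantic_vector)) * cls.emission_noise_sd
            )
            flags = np.zeros(config.block_layout["object_change"])
            if j == 0:
                flags[:] = 1.0
            scenes[t, sl["object_change"]] = (
                flags + rng.normal(size=len(flags)) * cls.emission_noise_sd
            )
            scenes[t, sl["luminance"]] = lum
            labels[t] = eid
            t += 1
    return Activity(
        id=activity_id,
        scenes=scenes,
        dt=config.dt,
        true_labels=labels,
        actor_id=actor_id,
        environment_id=environment_id,
    )


def _random_script(config: GeneratorConfig, rng: np.random.Generator) -> Script:
    n_events = int(rng.integers(config.events_per_activity[0],
                                config.events_per_activity[1] + 1))
    ids = []
    prev = -1
    for _ in range(n_events):
        choices = [c for c in range(config.n_classes) if c != prev]
        prev = int(rng.choice(choices))
        ids.append(prev)
    return Script(event_ids=ids, duration_range=config.duration_range)


def generate_corpus(config: GeneratorConfig) -> Corpus:
    """Generate a train/validation corpus with shared classes and actors.

    Scripts are drawn independently for train and validation activities
    (so no activity repeats), while event classes and actors are shared —
    validation therefore probes generalization to new instances of known
    event classes, the way similar events recur in everyday experience.
    Every class is guaranteed to appear in at least one training activity.
    """
    rng = np.random.default_rng(config.seed)
    classes = make_classes(config, rng)
    actor_offsets = {
        f"actor{i}": rng.normal(size=config.block_layout["motion"])
        * config.actor_offset_sd
        for i in range(config.n_actors)
    }
    actor_ids = sorted(actor_offsets)

    activities = []
    split = {}

    def gen(prefix, n, part):
        for i in range(n):
            aid = f"{prefix}{i:03d}"
            actor = actor_ids[int(rng.integers(len(actor_ids)))]
            act = generate_activity(
                aid, _random_script(config, rng), classes,
                actor_offsets[actor], config, rng,
                actor_id=actor, environment_id=f"env{int(rng.integers(3))}",
            )
            activities.append(act)
            split[aid] = part

    gen("train", config.n_train, "train")
    gen("val", config.n_validation, "validation")

    # every class must appear in >= 1 training activity
    seen = set()
    for a in activities:
        if split[a.id] == "train":
            seen.update(np.unique(a.true_labels).tolist())
    missing = [c for c in range(config.n_classes) if c not in seen]
    if missing and config.n_train > 0:
        first = activities[0]
        script = Script(
            event_ids=(missing * 7)[:6], duration_range=config.duration_range
        )
        patched = generate_activity(
            first.id, script, classes, actor_offsets[actor_ids[0]], config, rng,
            actor_id=actor_ids[0], environment_id="env0",
        )
        activities[0] = patched

    return Corpus(activities=activities, split=split,
                  block_layout=dict(config.block_layout))


def generate_curriculum_corpus(
    config: GeneratorConfig,
    class_pools: Sequence[Sequence[int]] = ((0, 1), (2, 3)),
    n_per_phase: int = 10,
    n_validation: int = 4,
) -> Corpus:
    """Sequential curriculum for interference probes.

    Training activities are blocked by phase: the first ``n_per_phase``
    activities draw their scripts only from ``class_pools[0]``, the next
    ``n_per_phase`` only from ``class_pools[1]``, and so on, in order.
    Validation activities all come from the first pool, so validation PE
    tracks how much later-phase learning disturbs earlier-phase knowledge.
    """
    rng = np.random.default_rng(config.seed)
    classes = make_classes(config, rng)
    actor_offsets = {
        f"actor{i}": rng.normal(size=config.block_layout["motion"])
        * config.actor_offset_sd
        for i in range(config.n_actors)
    }
    actor_ids = sorted(actor_offsets)

    def pool_script(pool) -> Script:
        n_events = int(rng.integers(config.events_per_activity[0],
                                    config.events_per_activity[1] + 1))
        ids, prev = [], -1
        for _ in range(n_events):
            choices = [c for c in pool if c != prev] or list(pool)
            prev = int(rng.choice(choices))
            ids.append(prev)
        return Script(event_ids=ids, duration_range=config.duration_range)

    activities, split = [], {}

    def gen(prefix, n, pool, part):
        for i in range(n):
            aid = f"{prefix}{i:03d}"
            actor = actor_ids[int(rng.integers(len(actor_ids)))]
            activities.append(
                generate_activity(
                    aid, pool_script(pool), classes, actor_offsets[actor],
                    config, rng, actor_id=actor, environment_id="env0",
                )
            )
            split[aid] = part

    for phase, pool in enumerate(class_pools):
        gen(f"phase{phase}_", n_per_phase, pool, "train")
    gen("val", n_validation, class_pools[0], "validation")
    return Corpus(activities=activities, split=split,
                  block_layout=dict(config.block_layout))


def true_boundary_times(activity: Activity) -> np.ndarray:
    """Seconds of ground-truth event-class changes within an activity."""
    lab = activity.true_labels
    if lab is None:
        raise ValueError("activity has no true labels")
    idx = np.flatnonzero(lab[1:] != lab[:-1]) + 1
    return idx * activity.dt


def simulate_raters(
    activity: Activity,
    n_raters: int = 30,
    jitter_sd_s: float = 0.5,
    miss_prob: float = 0.2,
    false_alarm_rate: float = 1.0,
    rng: Optional[np.random.Generator] = None,
    grain: str = "fine",
) -> list[RaterSegmentation]:
    """Simulate human raters marking boundaries for one activity.

    Each rater starts from the true boundaries, drops each independently
    with ``miss_prob``, jitters the rest by Gaussian noise (SD
    ``jitter_sd_s`` seconds), and adds Poisson false alarms at
    ``false_alarm_rate`` per minute, uniformly over the activity; times
    are clipped to the activity span.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    truth = true_boundary_times(activity)
    span = activity.duration_s
    raters = []
    for i in range(n_raters):
        keep = truth[rng.random(len(truth)) >= miss_prob]
        times = keep + rng.normal(size=len(keep)) * jitter_sd_s
        n_fa = rng.poisson(false_alarm_rate * span / 60.0)
        times = np.concatenate([times, rng.uniform(0, span, size=n_fa)])
        times = np.clip(times, 0.0, span)
        raters.append(
            RaterSegmentation(
                rater_id=f"rater{i:02d}",
                activity_id=activity.id,
                boundary_times=times,
                grain=grain,
            )
        )
    return raters
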