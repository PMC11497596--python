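"""Core domain types for activity streams and their segmentations.

An *activity* is a sequence of fixed-dimension scene vectors sampled every
``dt`` seconds (default 1/3 s).  Each scene vector summarizes mid-level
visual features of a moment of human activity: body-motion components,
object-semantic components, object appearance/disappearance flags and a
luminance-change component.  Activities optionally carry ground-truth
per-timestep event-class labels, and human (or simulated) raters provide
boundary times in seconds.

Conventions used throughout the package:

* all sequences are 0-indexed;
* timestep ``t`` covers the half-open interval ``[t*dt, (t+1)*dt)``, and
  boundary times in seconds are binned by ``floor(time/dt)`` clipped to
  ``[0, T-1]``;
* an *event boundary* is a transition of the active schema from one
  predictor network to another; hidden-state resets are transitions of the
  event model but are only counted as boundaries on request.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: Default block layout of a scene vector: named feature groups -> width.
DEFAULT_BLOCK_LAYOUT = {
    "motion": 14,
    "semantic": 13,
    "object_change": 2,
    "luminance": 1,
}

DEFAULT_DT = 1.0 / 3.0


def block_slices(layout: dict[str, int]) -> dict[str, slice]:
    """Map each named block to its index slice within a scene vector."""
    out = {}
    start = 0
    for name, width in layout.items():
        out[name] = slice(start, start + width)
        start += width
    return out


class DecisionKind(enum.Enum):
    KEEP = "keep"
    SWITCH = "switch"
    RESET = "reset"
    SPAWN = "spawn"


@dataclass(frozen=True)
class Decision:
    """Outcome of one schema-inference step."""

    kind: DecisionKind
    schema_id: int


@dataclass
class Activity:
    """One recorded activity: a (T, D) array of scene vectors.

    Parameters
    ----------
    id : str
        Unique activity identifier.
    scenes : ndarray, shape (T, D)
        One scene vector per timestep; T >= 2.
    dt : float
        Seconds per timestep.
    true_labels : sequence of int, optional
        Ground-truth event-class id per timestep (length T).
    actor_id, environment_id : str, optional
    """

    id: str
    scenes: np.ndarray
    dt: float = DEFAULT_DT
    true_labels: Optional[np.ndarray] = None
    actor_id: Optional[str] = None
    environment_id: Optional[str] = None

    def __post_init__(self):
        self.scenes = np.asarray(self.scenes, dtype=float)
        if self.true_labels is not None:
            self.true_labels = np.asarray(self.true_labels)

    @property
    def T(self) -> int:
        return self.scenes.shape[0]

    @property
    def D(self) -> int:
        return self.scenes.shape[1]

    @property
    def duration_s(self) -> float:
        return self.T * self.dt


@dataclass
class Corpus:
    """A set of activities with a train/validation split."""

    activities: list[Activity]
    split: dict[str, str]  # activity id -> "train" | "validation"
    block_layout: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_BLOCK_LAYOUT)
    )

    def by_id(self, activity_id: str) -> Activity:
        for a in self.activities:
            if a.id == activity_id:
                return a
        raise KeyError(activity_id)

    @property
    def train(self) -> list[Activity]:
        return [a for a in self.activities if self.split.get(a.id) == "train"]

    @property
    def validation(self) -> list[Activity]:
        return [a for a in self.activities if self.split.get(a.id) == "validation"]


@dataclass
class TraceRow:
    """Per-timestep record of the model's decision and prediction quality."""

    t: int
    active_schema: int
    decision: Decision
    pe: float
    unc: float = math.nan
    gate_fired: bool = True
    log_posterior_top3: Optional[list[tuple[int, float]]] = None


@dataclass
class EventTrace:
    """Full per-timestep trace for one activity."""

    activity_id: str
    rows: list[TraceRow] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def labels(self) -> np.ndarray:
        """Active schema id per timestep (the model's event labels)."""
        return np.array([r.active_schema for r in self.rows], dtype=int)

    @property
    def pes(self) -> np.ndarray:
        return np.array([r.pe for r in self.rows], dtype=float)

    @property
    def decisions(self) -> list[Decision]:
        return [r.decision for r in self.rows]

    def boundaries(self, count_resets: bool = False) -> np.ndarray:
        return labels_to_boundaries(self.labels, self.decisions, count_resets)


@dataclass
class HyperParams:
    """All tunable parameters of the architecture.

    stickiness (lambda) biases the prior toward keeping the active schema;
    concentration (alpha) is the prior mass on spawning a new schema;
    noise_scale (sigma) is the likelihood's isotropic Gaussian SD;
    gate_margin (m) is the additive threshold over the running-average
    gating signal; dropout_samples (S) is the MC sample count for the
    epistemic-uncertainty estimate.
    """

    stickiness: float = 1.0
    concentration: float = 0.5
    noise_scale: float = 0.5
    gate_margin: float = 0.0
    ema_decay: float = 0.9
    dropout_rate: float = 0.5
    dropout_samples: int = 32
    context_window: int = 3
    learning_rate: float = 0.005
    hidden_size: int = 16
    hidden_multiplier: int = 1
    max_schemas: Optional[int] = None
    seed: int = 0
    count_resets_as_boundaries: bool = False

    def __post_init__(self):
        if self.stickiness < 0:
            raise ValueError("stickiness must be >= 0")
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")
        if self.noise_scale <= 0:
            raise ValueError("noise_scale must be > 0")
        if not (0.0 < self.ema_decay < 1.0):
            raise ValueError("ema_decay must be in (0, 1)")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.dropout_samples < 2:
            raise ValueError("dropout_samples must be >= 2")
        if self.context_window < 1:
            raise ValueError("context_window must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.hidden_size < 1:
            raise ValueError("hidden_size must be >= 1")
        if self.hidden_multiplier not in (1, 2, 3):
            raise ValueError("hidden_multiplier must be 1, 2 or 3")

    def replace(self, **kw) -> "HyperParams":
        return dataclasses.replace(self, **kw)


@dataclass
class RaterSegmentation:
    """One rater's boundary times (seconds) for one activity."""

    rater_id: str
    activity_id: str
    boundary_times: np.ndarray
    grain: str = "fine"

    def __post_init__(self):
        self.boundary_times = np.sort(np.asarray(self.boundary_times, dtype=float))
        if self.grain not in ("fine", "coarse"):
            raise ValueError("grain must be 'fine' or 'coarse'")


@dataclass
class ValidationReport:
    ok: bool
    problems: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.ok


def validate_corpus(corpus: Corpus) -> ValidationReport:
    """Check corpus invariants.

    Verifies that all activities share one dimensionality, that every entry
    is finite (locating the offending (activity, timestep, dimension)),
    that label lengths match, that T >= 2, that the block layout sums to D
    and that the split is a disjoint cover of the activities.
    """
    if not corpus.activities:
        raise ValueError("empty corpus")
    problems: list[str] = []
    D = corpus.activities[0].D
    layout_total = sum(corpus.block_layout.values())
    if layout_total != D:
        problems.append(
            f"block layout sums to {layout_total} but scene dimension is {D}"
        )
    for a in corpus.activities:
        if a.D != D:
            problems.append(f"activity {a.id}: dimension {a.D} != {D}")
        if a.T < 2:
            problems.append(f"activity {a.id}: T={a.T} < 2")
        bad = np.argwhere(~np.isfinite(a.scenes))
        for t, d in bad[:10]:
            problems.append(f"activity {a.id}: non-finite entry at (t={t}, dim={d})")
        if a.true_labels is not None and len(a.true_labels) != a.T:
            problems.append(
                f"activity {a.id}: {len(a.true_labels)} labels for {a.T} timesteps"
            )
        if a.dt <= 0:
            problems.append(f"activity {a.id}: dt={a.dt} <= 0")
    ids = [a.id for a in corpus.activities]
    if len(set(ids)) != len(ids):
        problems.append("duplicate activity ids")
    for i in ids:
        if corpus.split.get(i) not in ("train", "validation"):
            problems.append(f"activity {i}: missing or invalid split assignment")
    for i in corpus.split:
        if i not in ids:
            problems.append(f"split references unknown activity {i}")
    return ValidationReport(ok=not problems, problems=problems)


def labels_to_boundaries(
    labels: Sequence,
    decisions: Optional[Sequence[Decision]] = None,
    count_resets: bool = False,
) -> np.ndarray:
    """Convert per-timestep event labels to a binary boundary indicator.

    ``indicator[t] = 1`` iff ``labels[t] != labels[t-1]`` (for t >= 1), or,
    when ``count_resets`` is set and a decision sequence is supplied, the
    decision at ``t`` re-initialized the active event model's hidden state.
    ``indicator[0]`` is always 0: the start of a sequence is not a boundary.
    """
    labels = list(labels)
    if len(labels) < 1:
        raise ValueError("labels must be nonempty")
    if decisions is not None and len(decisions) != len(labels):
        raise ValueError(
            f"decisions length {len(decisions)} != labels length {len(labels)}"
        )
    ind = np.zeros(len(labels), dtype=int)
    for t in range(1, len(labels)):
        if labels[t] != labels[t - 1]:
            ind[t] = 1
        elif (
            count_resets
            and decisions is not None
            and decisions[t].kind is DecisionKind.RESET
        ):
            ind[t] = 1
    return ind


def boundaries_to_times(boundaries: np.ndarray, dt: float) -> np.ndarray:
    """Timestep indicator -> boundary times in seconds (bin left edges)."""
    return np.flatnonzero(np.asarray(boundaries) != 0) * dt


def bin_time(time_s: float, dt: float, T: int) -> int:
    """Bin a boundary time (seconds) onto the timestep grid."""
    return int(min(max(math.floor(time_s / dt), 0), T - 1))
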