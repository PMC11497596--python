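"""Training and evaluation protocol.

Online, single-pass learning: activities are processed in order, each
watched exactly once, whole activity before the next.  After every 10
training activities (and at the end) the full validation set is run with
learning disabled and frozen weights, and per-checkpoint metrics are
recorded.  Simulations repeat the protocol with shuffled training orders
and distinct seeds; a grid search can match the model's boundary rate to
a target (e.g. the median human fine-grain boundary count per activity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import metrics, nets
from .datamodel import (
    Activity,
    Corpus,
    EventTrace,
    HyperParams,
    block_slices,
    validate_corpus,
)
from .inference import ModelState, run_activity
from .nets import SchemaLibrary, library_hash

logger = logging.getLogger(__name__)

CHECKPOINT_EVERY = 10


@dataclass
class Checkpoint:
    """Validation snapshot after ``n_trained`` training activities."""

    n_trained: int
    validation_pe: float
    per_activity_pe: dict[str, float]
    per_activity_boundaries: dict[str, int]
    schema_count: int
    traces: dict[str, EventTrace]

    @property
    def mean_boundaries(self) -> float:
        return float(np.mean(list(self.per_activity_boundaries.values())))


@dataclass
class SimulationResult:
    """Outcome of one seeded single-pass simulation."""

    variant: str
    hp: HyperParams
    train_order: list[str]
    checkpoints: list[Checkpoint]
    train_traces: list[EventTrace]
    spawn_log: list[tuple[int, int]]
    library: SchemaLibrary

    @property
    def final(self) -> Checkpoint:
        return self.checkpoints[-1]

    @property
    def first(self) -> Checkpoint:
        return self.checkpoints[0]


def _validation_pass(
    variant: str,
    library: SchemaLibrary,
    state: ModelState,
    validation: Sequence[Activity],
    hp: HyperParams,
    rng: np.random.Generator,
    n_trained: int,
) -> Checkpoint:
    """Evaluate all validation activities with learning disabled.

    Each activity runs on a fresh copy of the library with gate baselines
    and active schema restored from training, so validation activities
    are independent of each other and the training-time library is
    bit-identical before and after the pass.
    """
    traces: dict[str, EventTrace] = {}
    per_pe: dict[str, float] = {}
    per_b: dict[str, int] = {}
    for act in validation:
        lib_copy = library.copy()
        st = state.copy()
        trace = run_activity(variant, lib_copy, st, act, hp, rng, learn=False)
        traces[act.id] = trace
        pes = trace.pes
        per_pe[act.id] = float(np.mean(pes * pes))
        per_b[act.id] = int(
            trace.boundaries(hp.count_resets_as_boundaries).sum()
        )
    return Checkpoint(
        n_trained=n_trained,
        validation_pe=float(np.mean(list(per_pe.values()))),
        per_activity_pe=per_pe,
        per_activity_boundaries=per_b,
        schema_count=library.K,
        traces=traces,
    )


def train_online(
    corpus: Corpus,
    hp: HyperParams,
    variant: str = "sem2",
    train_order: Optional[Sequence[str]] = None,
    checkpoint_every: int = CHECKPOINT_EVERY,
) -> SimulationResult:
    """One single-pass simulation over the corpus's training split.

    ``train_order`` (activity ids) defaults to the corpus's stored order.
    Checkpoints are taken after activities ``checkpoint_every, 2x, ...``
    and after the final activity.  Errors raised while processing an
    activity are logged and the run continues with the next activity.
    """
    report = validate_corpus(corpus)
    if not report:
        raise ValueError("invalid corpus: " + "; ".join(report.problems[:5]))
    train_acts = corpus.train
    if not train_acts:
        raise ValueError("empty training split")
    if train_order is not None:
        by_id = {a.id: a for a in train_acts}
        train_acts = [by_id[i] for i in train_order]
    validation = corpus.validation

    D = train_acts[0].D
    H = hp.hidden_size * hp.hidden_multiplier
    library = SchemaLibrary.create(D, H, seed=hp.seed, max_schemas=hp.max_schemas)
    state = ModelState.fresh(hp)
    rng = np.random.default_rng(hp.seed)

    checkpoints: list[Checkpoint] = []
    train_traces: list[EventTrace] = []
    n = len(train_acts)
    for i, act in enumerate(train_acts):
        try:
            trace = run_activity(variant, library, state, act, hp, rng, learn=True)
            train_traces.append(trace)
        except Exception:
            logger.exception("activity %s failed; continuing", act.id)
            continue
        done = i + 1
        if validation and (done % checkpoint_every == 0 or done == n):
            pre_hash = library_hash(library)
            ckpt = _validation_pass(
                variant, library, state, validation, hp, rng, n_trained=done
            )
            assert library_hash(library) == pre_hash, "validation mutated weights"
            checkpoints.append(ckpt)
    return SimulationResult(
        variant=variant,
        hp=hp,
        train_order=[a.id for a in train_acts],
        checkpoints=checkpoints,
        train_traces=train_traces,
        spawn_log=list(library.spawn_log),
        library=library,
    )


def run_simulations(
    corpus: Corpus,
    hp: HyperParams,
    variant: str = "sem2",
    n_sims: int = 8,
    seeds: Optional[Sequence[int]] = None,
) -> list[SimulationResult]:
    """Repeat training with shuffled orders; one result per seed.

    Simulation i shuffles the training order with seed ``seeds[i]`` and
    uses the same seed for the model's own randomness, so the full result
    table is reproducible from the seed list.
    """
    if seeds is None:
        seeds = [hp.seed + i for i in range(n_sims)]
    if len(seeds) != n_sims:
        raise ValueError("need one seed per simulation")
    train_ids = [a.id for a in corpus.train]
    results = []
    for s in seeds:
        order_rng = np.random.default_rng(s)
        order = [train_ids[j] for j in order_rng.permutation(len(train_ids))]
        results.append(
            train_online(corpus, hp.replace(seed=int(s)), variant, train_order=order)
        )
    return results


@dataclass
class TuneSpec:
    """Grid search matching the model's boundary rate to a target.

    ``target`` is the desired mean number of boundaries per validation
    activity (typically the median human fine-grain count); the objective
    is ``|mean model boundaries - target|`` at the final checkpoint of a
    reduced-budget run over the first ``n_train_budget`` activities.
    """

    grid: list[HyperParams]
    target: float
    n_train_budget: Optional[int] = 10

    def __post_init__(self):
        if not self.grid:
            raise ValueError("empty grid")


def tune_boundary_rate(
    corpus: Corpus, spec: TuneSpec, variant: str = "sem2"
) -> tuple[HyperParams, list[float]]:
    """Evaluate each grid point and return the argmin hyperparameters.

    Ties are broken by grid order.  Also returns the per-point objective
    values for inspection.
    """
    train_ids = [a.id for a in corpus.train]
    budget = spec.n_train_budget or len(train_ids)
    order = train_ids[:budget]
    objectives = []
    for hp in spec.grid:
        res = train_online(corpus, hp, variant, train_order=order)
        objectives.append(abs(res.final.mean_boundaries - spec.target))
    best = int(np.argmin(objectives))
    return spec.grid[best], objectives


def ablate_inputs(corpus: Corpus, block: str) -> Corpus:
    """Zero out one named feature block in every scene vector.

    Returns a new corpus; all other entries (and all metadata) are
    untouched.  Raises KeyError for an unknown block.
    """
    if block not in corpus.block_layout:
        raise KeyError(f"unknown block {block!r}")
    sl = block_slices(corpus.block_layout)[block]
    new_acts = []
    for a in corpus.activities:
        scenes = a.scenes.copy()
        scenes[:, sl] = 0.0
        new_acts.append(
            Activity(
                id=a.id, scenes=scenes, dt=a.dt,
                true_labels=None if a.true_labels is None else a.true_labels.copy(),
                actor_id=a.actor_id, environment_id=a.environment_id,
            )
        )
    return Corpus(
        activities=new_acts, split=dict(corpus.split),
        block_layout=dict(corpus.block_layout),
    )


def generic_baseline(
    corpus: Corpus,
    hp: HyperParams,
    hidden_multiplier: int = 1,
    train_order: Optional[Sequence[str]] = None,
    checkpoint_every: int = CHECKPOINT_EVERY,
) -> SimulationResult:
    """Train only the generic network: no schema inference, no boundaries.

    A single predictor with ``hidden_size * hidden_multiplier`` hidden
    units sees the identical training stream as a full model would and
    takes one gradient step per timestep.  Checkpoints record validation
    PE per activity; since there is a single model, every decision is
    KEEP and no boundary is ever emitted.  Interference is probed by
    reading per-activity (hence per-class) validation PE across the
    checkpoints of a class-ordered curriculum.
    """
    from .datamodel import Decision, DecisionKind, TraceRow
    from .nets import context_window, predict, prediction_error, train_generic

    if hidden_multiplier not in (1, 2, 3):
        raise ValueError("hidden_multiplier must be 1, 2 or 3")
    report = validate_corpus(corpus)
    if not report:
        raise ValueError("invalid corpus: " + "; ".join(report.problems[:5]))
    train_acts = corpus.train
    if train_order is not None:
        by_id = {a.id: a for a in train_acts}
        train_acts = [by_id[i] for i in train_order]
    validation = corpus.validation
    D = train_acts[0].D
    library = SchemaLibrary.create(
        D, hp.hidden_size * hidden_multiplier, seed=hp.seed
    )

    def eval_activity(act: Activity) -> EventTrace:
        trace = EventTrace(activity_id=act.id)
        for t in range(act.T):
            ctx = context_window(act.scenes, t, hp.context_window)
            pe = prediction_error(predict(library.generic, ctx), act.scenes[t])
            trace.rows.append(
                TraceRow(t=t, active_schema=0,
                         decision=Decision(DecisionKind.KEEP, 0), pe=pe)
            )
        return trace

    checkpoints: list[Checkpoint] = []
    n = len(train_acts)
    for i, act in enumerate(train_acts):
        for t in range(act.T):
            ctx = context_window(act.scenes, t, hp.context_window)
            train_generic(library, ctx, act.scenes[t], hp.learning_rate)
            library.tick()
        done = i + 1
        if validation and (done % checkpoint_every == 0 or done == n):
            pre_hash = library_hash(library)
            traces = {a.id: eval_activity(a) for a in validation}
            assert library_hash(library) == pre_hash
            per_pe = {
                aid: float(np.mean(tr.pes * tr.pes)) for aid, tr in traces.items()
            }
            checkpoints.append(
                Checkpoint(
                    n_trained=done,
                    validation_pe=float(np.mean(list(per_pe.values()))),
                    per_activity_pe=per_pe,
                    per_activity_boundaries={aid: 0 for aid in traces},
                    schema_count=0,
                    traces=traces,
                )
            )
    return SimulationResult(
        variant=f"generic{hidden_multiplier}x",
        hp=hp,
        train_order=[a.id for a in train_acts],
        checkpoints=checkpoints,
        train_traces=[],
        spawn_log=[],
        library=library,
    )
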