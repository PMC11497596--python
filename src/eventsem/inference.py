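"""Approximate Bayesian schema inference and gating.

At each timestep the model holds one active schema.  When inference runs,
every candidate — each existing schema (KEEP for the active one, SWITCH
for the others), a RESET of the active schema's event model, and a SPAWN
of a fresh schema initialized from the generic network — predicts the
current scene from the same context window.  Prediction errors are
converted to isotropic-Gaussian log-likelihoods, combined with a sticky
uniform-process prior, and the maximum-a-posteriori candidate wins (local
MAP; no history is revisited).

The sticky uniform process assigns unnormalized prior weight ``1 +
stickiness`` to the active schema, ``1`` to every other existing schema
and to RESET, and ``concentration`` to SPAWN — unlike the sticky Chinese
restaurant process, large and small schemas get equal prior mass, which
avoids the rich-get-richer collapse onto a few schemas.

The two gated variants run this inference only when the active schema's
prediction error (pe variant) or MC-dropout prediction uncertainty (unc
variant) exceeds its exponential moving average by a margin; the ungated
model (sem2) runs it at every timestep.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import logsumexp

from .datamodel import Decision, DecisionKind, HyperParams, TraceRow
from . import nets
from .nets import SchemaLibrary, context_window

VARIANTS = ("sem2", "pe", "unc")


def sup_prior(
    K: int, active_index: int, stickiness: float, concentration: float
) -> np.ndarray:
    """Sticky uniform-process prior over K existing schemas + RESET + SPAWN.

    Returns a probability vector of length K+2 ordered as (existing
    schemas in index order, RESET, SPAWN).  Unnormalized weights: active
    schema ``1 + stickiness``, every other existing schema ``1``, RESET
    ``1``, SPAWN ``concentration``.
    """
    if K < 1:
        raise ValueError("need at least one existing schema")
    if not (0 <= active_index < K):
        raise ValueError("active_index out of range")
    if stickiness < 0:
        raise ValueError("stickiness must be >= 0")
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    w = np.ones(K + 2)
    w[active_index] += stickiness
    w[K + 1] = concentration
    return w / w.sum()


def log_likelihood(error: float, sigma: float, D: int) -> float:
    """Isotropic Gaussian log-density of a prediction error.

    ``-error^2 / (2 sigma^2) - (D/2) ln(2 pi sigma^2)``; monotonically
    decreasing in the error, maximized at zero.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if error < 0:
        raise ValueError("error must be >= 0")
    return -(error * error) / (2.0 * sigma * sigma) - 0.5 * D * math.log(
        2.0 * math.pi * sigma * sigma
    )


@dataclass
class Candidate:
    kind: DecisionKind
    schema_id: int  # for SPAWN, the id a new schema would get
    log_prior: float
    log_lik: float
    log_posterior: float = math.nan


@dataclass
class CandidateSet:
    """All candidates of one inference, in tie-break priority order.

    Order: KEEP (active schema), RESET, SWITCH candidates by ascending
    schema id, SPAWN.  ``log_posterior`` is normalized so the posterior
    sums to 1.
    """

    candidates: list[Candidate]

    def __post_init__(self):
        lp = np.array([c.log_prior + c.log_lik for c in self.candidates])
        norm = logsumexp(lp)
        for c, v in zip(self.candidates, lp - norm):
            c.log_posterior = float(v)

    @property
    def posterior(self) -> np.ndarray:
        return np.exp([c.log_posterior for c in self.candidates])

    def top(self, n: int = 3) -> list[tuple[int, float]]:
        ranked = sorted(
            self.candidates, key=lambda c: -c.log_posterior
        )[:n]
        return [(c.schema_id, c.log_posterior) for c in ranked]


def decide(cset: CandidateSet) -> Decision:
    """MAP decision with tie-break order KEEP > RESET > lowest-id SWITCH > SPAWN.

    Candidates are stored in exactly that priority order, so the first
    maximum wins ties.
    """
    best = max(range(len(cset.candidates)),
               key=lambda i: (cset.candidates[i].log_posterior, -i))
    c = cset.candidates[best]
    return Decision(c.kind, c.schema_id)


def infer_step(
    library: SchemaLibrary,
    active_id: int,
    context: np.ndarray,
    observed: np.ndarray,
    hp: HyperParams,
) -> tuple[Decision, CandidateSet]:
    """One full schema inference over all K+2 candidates.

    Every candidate predicts the observed scene from the same context
    window; RESET re-initializes the active event model's hidden state
    (under window-recomputed hidden states its prediction coincides with
    KEEP's), and SPAWN predicts with the generic network's current weights
    (the would-be initial weights of the new schema).
    """
    ids = library.ids
    K = len(ids)
    if K < 1:
        raise ValueError("inference requires at least one schema")
    active_index = ids.index(active_id)
    prior = sup_prior(K, active_index, hp.stickiness, hp.concentration)
    D = library.generic.D

    def ll(net):
        err = nets.prediction_error(nets.predict(net, context), observed)
        return log_likelihood(err, hp.noise_scale, D)

    ll_existing = {sid: ll(library.schemas[sid]) for sid in ids}
    # RESET: active schema with re-initialized hidden state; hidden states
    # are recomputed from the window, so the likelihood equals KEEP's.
    ll_reset = ll_existing[active_id]
    can_spawn = library.can_spawn()
    ll_spawn = ll(library.generic) if can_spawn else -math.inf

    cands = [
        Candidate(DecisionKind.KEEP, active_id,
                  math.log(prior[active_index]), ll_existing[active_id]),
        Candidate(DecisionKind.RESET, active_id,
                  math.log(prior[K]), ll_reset),
    ]
    for i, sid in enumerate(ids):
        if sid == active_id:
            continue
        cands.append(
            Candidate(DecisionKind.SWITCH, sid, math.log(prior[i]),
                      ll_existing[sid])
        )
    if can_spawn:
        cands.append(
            Candidate(DecisionKind.SPAWN, library._next_id,
                      math.log(prior[K + 1]), ll_spawn)
        )
    cset = CandidateSet(cands)
    return decide(cset), cset


@dataclass
class GateState:
    """Per-schema exponential moving average of the gating signal."""

    ema_decay: float
    margin: float
    means: dict[int, float] = field(default_factory=dict)

    def initialized(self, schema_id: int) -> bool:
        return schema_id in self.means

    def observe(self, schema_id: int, signal: float) -> None:
        """Fold a new signal into the schema's running mean.

        The mean is initialized at the first observed signal.
        """
        if schema_id not in self.means:
            self.means[schema_id] = float(signal)
        else:
            d = self.ema_decay
            self.means[schema_id] = d * self.means[schema_id] + (1 - d) * float(signal)

    def copy(self) -> "GateState":
        return GateState(self.ema_decay, self.margin, dict(self.means))


def gate(signal: float, state: GateState, schema_id: int) -> bool:
    """True iff the signal exceeds the schema's running mean by the margin.

    The gate is evaluated on the current timestep's signal *before* that
    signal is folded into the running mean.
    """
    if not state.initialized(schema_id):
        raise ValueError(f"gate state not initialized for schema {schema_id}")
    return signal > state.means[schema_id] + state.margin


@dataclass
class ModelState:
    """Mutable per-run state: the active schema id and the gate baselines."""

    active_id: Optional[int] = None
    gate: GateState = None  # type: ignore[assignment]

    @classmethod
    def fresh(cls, hp: HyperParams) -> "ModelState":
        return cls(active_id=None, gate=GateState(hp.ema_decay, hp.gate_margin))

    def copy(self) -> "ModelState":
        return ModelState(self.active_id, self.gate.copy())


def step(
    variant: str,
    library: SchemaLibrary,
    state: ModelState,
    context: np.ndarray,
    observed: np.ndarray,
    hp: HyperParams,
    rng: np.random.Generator,
    t: int = 0,
    learn: bool = True,
) -> TraceRow:
    """Process one scene vector: predict, gate, infer, (optionally) learn.

    sem2 runs the full inference at every timestep; the pe and unc
    variants evaluate the gate on the active schema's prediction error or
    MC-dropout uncertainty and run inference only when it fires, keeping
    the active schema otherwise.  After the decision, the chosen schema
    and the generic network each take one gradient step (when ``learn``),
    and the gate baseline is updated with the post-decision active
    schema's signal.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")

    def signal_for(schema) -> tuple[float, float]:
        pred = nets.predict(schema, context)
        pe = nets.prediction_error(pred, observed)
        unc = math.nan
        if variant == "unc":
            sample = nets.mc_predict(
                schema, context, hp.dropout_samples, hp.dropout_rate, rng
            )
            unc = nets.uncertainty(sample)
        return pe, unc

    # First timestep of a run: empty library forces a spawn.
    if library.K == 0:
        sid = nets.spawn(library)
        state.active_id = sid
        pe, unc = signal_for(library.schemas[sid])
        decision = Decision(DecisionKind.SPAWN, sid)
        cset = None
        gate_fired = True
        post_pe, post_unc = pe, unc
    else:
        active = state.active_id
        pe, unc = signal_for(library.schemas[active])
        signal = unc if variant == "unc" else pe
        if variant == "sem2":
            gate_fired = True
        else:
            gate_fired = gate(signal, state.gate, active)
        if gate_fired:
            decision, cset = infer_step(library, active, context, observed, hp)
        else:
            decision, cset = Decision(DecisionKind.KEEP, active), None
        if decision.kind is DecisionKind.SPAWN:
            sid = nets.spawn(library)
            decision = Decision(DecisionKind.SPAWN, sid)
        state.active_id = decision.schema_id
        if decision.schema_id == active:
            post_pe, post_unc = pe, unc
        else:
            post_pe, post_unc = signal_for(library.schemas[decision.schema_id])

    active = state.active_id
    # Gate baseline: signal of the post-decision active schema, computed
    # before any weight update.
    state.gate.observe(active, post_unc if variant == "unc" else post_pe)

    if learn:
        # Dropout-regularized SGD with masks drawn from a stream indexed
        # by (seed, global training step): training randomness is shared
        # across variants, so gating equivalences hold exactly.
        rng_train = np.random.default_rng((hp.seed, library._step))
        nets.update(
            library.schemas[active], context, observed, hp.learning_rate,
            dropout_rate=hp.dropout_rate, rng=rng_train,
        )
        nets.train_generic(
            library, context, observed, hp.learning_rate,
            dropout_rate=hp.dropout_rate, rng=rng_train,
        )
        library.touch(active)
        library.tick()

    return TraceRow(
        t=t,
        active_schema=active,
        decision=decision,
        pe=pe,
        unc=unc,
        gate_fired=gate_fired,
        log_posterior_top3=cset.top(3) if cset is not None else None,
    )


def run_activity(
    variant: str,
    library: SchemaLibrary,
    state: ModelState,
    activity,
    hp: HyperParams,
    rng: np.random.Generator,
    learn: bool = True,
):
    """Run one activity through the model, returning its EventTrace.

    The context window restarts (zero-padded) at the activity's first
    timestep; library state and gate baselines carry in as given.
    """
    from .datamodel import EventTrace

    trace = EventTrace(activity_id=activity.id)
    for t in range(activity.T):
        ctx = context_window(activity.scenes, t, hp.context_window)
        row = step(
            variant, library, state, ctx, activity.scenes[t], hp, rng,
            t=t, learn=learn,
        )
        trace.rows.append(row)
    return trace
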