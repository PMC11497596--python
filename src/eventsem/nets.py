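"""Recurrent event-schema predictors and the schema library.

Each event schema is the weight set of a small four-layer recurrent
predictor: a dense input layer with leaky-ReLU activation, a gated
recurrent unit (GRU) layer, a dense leaky-ReLU layer and a linear output
layer mapping back to scene-vector space.  The network consumes the window
of the ``k`` most recent scene vectors (zero-padded at sequence start) and
predicts the next scene vector.  Hidden states are recomputed from the
window at every query, so schemas carry no persistent recurrent state.

Epistemic uncertainty about a schema's weights is approximated by Monte
Carlo dropout: ``S`` stochastic forward passes, each with independent
Bernoulli dropout masks applied before every weight layer, yield a sample
of predictions whose total variance (trace of the sample covariance)
estimates the prediction uncertainty

    Uncertainty = 1/(S-1) * sum_s || v_s - mean(v) ||^2 .

Learning is plain stochastic gradient descent on squared prediction error,
with gradients computed by backpropagation through the unrolled window.
Training steps use the deterministic forward pass (dropout is reserved for
the uncertainty estimate), which keeps every schema update reproducible.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

logger = logging.getLogger(__name__)

_LEAK = 0.01  # leaky-ReLU negative slope
_CLIP_NORM = 5.0  # global gradient-norm clip for SGD stability

__all__ = [
    "SchemaNetwork",
    "SchemaLibrary",
    "PredictionSample",
    "context_window",
    "predict",
    "mc_predict",
    "uncertainty",
    "prediction_error",
    "update",
    "train_generic",
    "spawn",
    "weights_hash",
    "library_hash",
]


def _lrelu(x: np.ndarray) -> np.ndarray:
    return np.where(x >= 0, x, _LEAK * x)


def _dlrelu(x: np.ndarray) -> np.ndarray:
    return np.where(x >= 0, 1.0, _LEAK)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out))


#: parameter names in canonical order (used for hashing/serialization)
PARAM_NAMES = (
    "W_in", "b_in",
    "Wz", "Uz", "bz",
    "Wr", "Ur", "br",
    "Wn", "Un", "bn",
    "W_mid", "b_mid",
    "W_out", "b_out",
)


class SchemaNetwork:
    """Four-layer recurrent predictor (dense -> GRU -> dense -> linear).

    Parameters
    ----------
    D : int
        Scene-vector dimension (input and output size).
    H : int
        Hidden units per layer.
    seed : int
        Seed for weight initialization.
    """

    def __init__(self, D: int, H: int, seed: int = 0):
        self.D = int(D)
        self.H = int(H)
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {
            "W_in": _glorot(rng, D, H), "b_in": np.zeros(H),
            "Wz": _glorot(rng, H, H), "Uz": _glorot(rng, H, H), "bz": np.zeros(H),
            "Wr": _glorot(rng, H, H), "Ur": _glorot(rng, H, H), "br": np.zeros(H),
            "Wn": _glorot(rng, H, H), "Un": _glorot(rng, H, H), "bn": np.zeros(H),
            "W_mid": _glorot(rng, H, H), "b_mid": np.zeros(H),
            "W_out": _glorot(rng, H, D), "b_out": np.zeros(D),
        }

    # -- forward ---------------------------------------------------------

    def forward(
        self,
        X: np.ndarray,
        masks: Optional[dict[str, np.ndarray]] = None,
        cache: bool = False,
    ):
        """Run the network over a batch of context windows.

        Parameters
        ----------
        X : ndarray, shape (B, k, D)
            Batch of context windows (oldest scene first).
        masks : dict, optional
            Dropout masks ``{"m0": (B,D), "m1": (B,H), "m2": (B,H),
            "m3": (B,H)}`` applied multiplicatively before each weight
            layer; shared across the window's timesteps.
        cache : bool
            If True, also return the intermediates needed for backprop
            (only supported without dropout masks).

        Returns
        -------
        y : ndarray, shape (B, D), or (y, cache) when ``cache`` is True.
        """
        p = self.params
        B, k, D = X.shape
        if D != self.D:
            raise ValueError(f"context dimension {D} != network dimension {self.D}")
        h = np.zeros((B, self.H))
        steps = []
        m0 = masks["m0"] if masks else None
        m1 = masks["m1"] if masks else None
        for t in range(k):
            x0 = X[:, t] * m0 if m0 is not None else X[:, t]
            pre_in = x0 @ p["W_in"] + p["b_in"]
            a = _lrelu(pre_in)
            xg = a * m1 if m1 is not None else a
            z = _sigmoid(xg @ p["Wz"] + h @ p["Uz"] + p["bz"])
            r = _sigmoid(xg @ p["Wr"] + h @ p["Ur"] + p["br"])
            n = np.tanh(xg @ p["Wn"] + (r * h) @ p["Un"] + p["bn"])
            h_new = (1.0 - z) * n + z * h
            if cache:
                steps.append((x0, pre_in, xg, z, r, n, h))
            h = h_new
        hm = h * masks["m2"] if masks else h
        pre_mid = hm @ p["W_mid"] + p["b_mid"]
        mid = _lrelu(pre_mid)
        mm = mid * masks["m3"] if masks else mid
        y = mm @ p["W_out"] + p["b_out"]
        if cache:
            return y, {
                "steps": steps, "hm": hm, "pre_mid": pre_mid, "mm": mm,
                "masks": masks,
            }
        return y

    def backward(self, X: np.ndarray, dy: np.ndarray, cache_data: dict):
        """Gradients of a loss wrt all parameters, given dL/dy.

        ``X`` and ``cache_data`` must come from ``forward(..., cache=True)``.
        Returns a dict with the same keys as ``self.params``.
        """
        p = self.params
        g = {k: np.zeros_like(v) for k, v in p.items()}
        hm, pre_mid, mm = cache_data["hm"], cache_data["pre_mid"], cache_data["mm"]
        masks = cache_data["masks"]
        m1 = masks["m1"] if masks else None

        g["b_out"] += dy.sum(axis=0)
        g["W_out"] += mm.T @ dy
        dmid = dy @ p["W_out"].T
        if masks:
            dmid = dmid * masks["m3"]
        dpre_mid = dmid * _dlrelu(pre_mid)
        g["W_mid"] += hm.T @ dpre_mid
        g["b_mid"] += dpre_mid.sum(axis=0)
        dh = dpre_mid @ p["W_mid"].T
        if masks:
            dh = dh * masks["m2"]

        for x0, pre_in, xg, z, r, n, h_prev in reversed(cache_data["steps"]):
            dz = dh * (h_prev - n)
            dn = dh * (1.0 - z)
            dh_prev = dh * z

            dan = dn * (1.0 - n * n)
            dxg = dan @ p["Wn"].T
            drh = dan @ p["Un"].T
            dr = drh * h_prev
            dh_prev = dh_prev + drh * r
            g["Wn"] += xg.T @ dan
            g["Un"] += (r * h_prev).T @ dan
            g["bn"] += dan.sum(axis=0)

            daz = dz * z * (1.0 - z)
            dxg = dxg + daz @ p["Wz"].T
            dh_prev = dh_prev + daz @ p["Uz"].T
            g["Wz"] += xg.T @ daz
            g["Uz"] += h_prev.T @ daz
            g["bz"] += daz.sum(axis=0)

            dar = dr * r * (1.0 - r)
            dxg = dxg + dar @ p["Wr"].T
            dh_prev = dh_prev + dar @ p["Ur"].T
            g["Wr"] += xg.T @ dar
            g["Ur"] += h_prev.T @ dar
            g["br"] += dar.sum(axis=0)

            if m1 is not None:
                dxg = dxg * m1
            dpre_in = dxg * _dlrelu(pre_in)
            g["W_in"] += x0.T @ dpre_in
            g["b_in"] += dpre_in.sum(axis=0)
            dh = dh_prev
        return g

    def copy(self) -> "SchemaNetwork":
        new = SchemaNetwork.__new__(SchemaNetwork)
        new.D, new.H = self.D, self.H
        new.params = {k: v.copy() for k, v in self.params.items()}
        return new


@dataclass
class PredictionSample:
    """MC-dropout prediction sample: S stochastic predictions of one scene."""

    samples: np.ndarray  # (S, D)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] < 2:
            raise ValueError("need at least 2 prediction samples")

    @property
    def S(self) -> int:
        return self.samples.shape[0]

    @property
    def mean(self) -> np.ndarray:
        return self.samples.mean(axis=0)


def context_window(scenes: np.ndarray, t: int, k: int) -> np.ndarray:
    """Window of the k scenes preceding timestep ``t``, zero-padded left.

    The window used to predict ``scenes[t]`` is ``scenes[t-k:t]``; at the
    start of a sequence missing entries are zero vectors, so at ``t=0`` the
    window is all pads.
    """
    scenes = np.asarray(scenes, dtype=float)
    D = scenes.shape[1]
    win = np.zeros((k, D))
    lo = max(0, t - k)
    chunk = scenes[lo:t]
    if len(chunk):
        win[k - len(chunk):] = chunk
    return win


def predict(schema: SchemaNetwork, context: np.ndarray) -> np.ndarray:
    """Deterministic next-scene prediction from a (k, D) context window."""
    context = np.asarray(context, dtype=float)
    if context.ndim != 2:
        raise ValueError("context must be a (k, D) array")
    return schema.forward(context[None])[0]


def _draw_masks(
    rng: np.random.Generator, S: int, D: int, H: int, p: float
) -> dict[str, np.ndarray]:
    keep = 1.0 - p
    def mask(width):
        return rng.binomial(1, keep, size=(S, width)) / keep
    return {"m0": mask(D), "m1": mask(H), "m2": mask(H), "m3": mask(H)}


def mc_predict(
    schema: SchemaNetwork,
    context: np.ndarray,
    S: int,
    p: float,
    rng: np.random.Generator,
) -> PredictionSample:
    """S dropout-perturbed predictions of the next scene.

    Each sample uses independent Bernoulli(1-p) masks (inverse-scaled)
    before every weight layer; with ``p=0`` all samples equal the
    deterministic prediction.
    """
    if S < 2:
        raise ValueError("S must be >= 2")
    if not (0.0 <= p < 1.0):
        raise ValueError("dropout rate must be in [0, 1)")
    context = np.asarray(context, dtype=float)
    X = np.broadcast_to(context, (S,) + context.shape)
    if p == 0.0:
        y = schema.forward(context[None])[0]
        return PredictionSample(np.tile(y, (S, 1)))
    masks = _draw_masks(rng, S, schema.D, schema.H, p)
    return PredictionSample(schema.forward(np.ascontiguousarray(X), masks=masks))


def uncertainty(sample: PredictionSample) -> float:
    """Total variance of the MC prediction sample (trace of covariance)."""
    dev = sample.samples - sample.mean
    return float(np.sum(dev * dev) / (sample.S - 1))


def prediction_error(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Euclidean distance between prediction and observation."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError(
            f"shape mismatch: {predicted.shape} vs {observed.shape}"
        )
    return float(np.linalg.norm(predicted - observed))


def update(
    schema: SchemaNetwork,
    context: np.ndarray,
    observed: np.ndarray,
    learning_rate: float,
    dropout_rate: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """One SGD step on squared prediction error for this schema only.

    With a nonzero ``dropout_rate`` the step is dropout-regularized: one
    fresh mask set is drawn from ``rng`` and applied before every weight
    layer for both the forward pass and the gradient.  Returns the
    pre-step squared error (of the dropout-masked forward when masks are
    in play).  A non-finite gradient skips the step and logs a warning;
    no other network is touched.
    """
    context = np.asarray(context, dtype=float)
    observed = np.asarray(observed, dtype=float)
    masks = None
    if dropout_rate > 0.0:
        if rng is None:
            raise ValueError("dropout training requires an rng")
        masks = _draw_masks(rng, 1, schema.D, schema.H, dropout_rate)
    y, cache_data = schema.forward(context[None], masks=masks, cache=True)
    resid = y - observed[None]
    loss = float(np.sum(resid * resid))
    if learning_rate == 0.0:
        return loss
    grads = schema.backward(context[None], 2.0 * resid, cache_data)
    if not all(np.all(np.isfinite(g)) for g in grads.values()):
        logger.warning("non-finite gradient; update step skipped")
        return loss
    # clip the global gradient norm: recurrent nets occasionally produce
    # exploding gradients under plain SGD, especially with dropout masks
    gnorm = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
    scale = _CLIP_NORM / gnorm if gnorm > _CLIP_NORM else 1.0
    for name, g in grads.items():
        schema.params[name] -= learning_rate * scale * g
    return loss


@dataclass
class SchemaLibrary:
    """The generic always-learning predictor plus the spawned schemas.

    The generic network is trained on every timestep regardless of which
    schema is active; new schemas are spawned as copies of its current
    weights, so they start with the broad knowledge of feature
    co-occurrence and dynamics the generic has accumulated.
    """

    generic: SchemaNetwork
    schemas: dict[int, SchemaNetwork] = field(default_factory=dict)
    usage_counts: dict[int, int] = field(default_factory=dict)
    spawn_log: list[tuple[int, int]] = field(default_factory=list)  # (step, id)
    max_schemas: Optional[int] = None
    _next_id: int = 0
    _step: int = 0

    @classmethod
    def create(
        cls, D: int, H: int, seed: int = 0, max_schemas: Optional[int] = None
    ) -> "SchemaLibrary":
        return cls(generic=SchemaNetwork(D, H, seed=seed), max_schemas=max_schemas)

    @property
    def K(self) -> int:
        return len(self.schemas)

    @property
    def ids(self) -> list[int]:
        return sorted(self.schemas)

    def can_spawn(self) -> bool:
        return self.max_schemas is None or self.K < self.max_schemas

    def tick(self) -> None:
        """Advance the library's training-timestep counter."""
        self._step += 1

    def touch(self, schema_id: int) -> None:
        self.usage_counts[schema_id] = self.usage_counts.get(schema_id, 0) + 1

    def copy(self) -> "SchemaLibrary":
        return copy.deepcopy(self)


def train_generic(
    library: SchemaLibrary,
    context: np.ndarray,
    observed: np.ndarray,
    learning_rate: float,
    dropout_rate: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Gradient step for the generic network; schema networks untouched."""
    return update(library.generic, context, observed, learning_rate,
                  dropout_rate=dropout_rate, rng=rng)


def spawn(library: SchemaLibrary) -> int:
    """Append a new schema initialized from the generic network's weights.

    Returns the new schema id; ids are assigned in spawn order.  Raises
    RuntimeError when ``max_schemas`` has been reached.
    """
    if not library.can_spawn():
        logger.warning("max_schemas=%s reached; spawning disabled", library.max_schemas)
        raise RuntimeError("max_schemas reached")
    new_id = library._next_id
    library._next_id += 1
    library.schemas[new_id] = library.generic.copy()
    library.usage_counts.setdefault(new_id, 0)
    library.spawn_log.append((library._step, new_id))
    return new_id


# -- hashing & serialization ---------------------------------------------

def weights_hash(net: SchemaNetwork) -> str:
    """Stable hexadecimal digest of a network's weights."""
    h = hashlib.sha256()
    for name in PARAM_NAMES:
        h.update(np.ascontiguousarray(net.params[name]).tobytes())
    return h.hexdigest()


def library_hash(library: SchemaLibrary) -> str:
    """Digest covering the generic network and every schema, in id order."""
    h = hashlib.sha256()
    h.update(weights_hash(library.generic).encode())
    for sid in library.ids:
        h.update(str(sid).encode())
        h.update(weights_hash(library.schemas[sid]).encode())
    return h.hexdigest()


def save_library(library: SchemaLibrary, path: str) -> None:
    """Serialize the library to a single .npz archive (versioned manifest)."""
    manifest = {
        "format_version": 1,
        "D": library.generic.D,
        "H": library.generic.H,
        "ids": library.ids,
        "usage_counts": {str(k): v for k, v in library.usage_counts.items()},
        "spawn_log": library.spawn_log,
        "max_schemas": library.max_schemas,
        "next_id": library._next_id,
        "step": library._step,
    }
    arrays = {"manifest": np.frombuffer(json.dumps(manifest).encode(), dtype=np.uint8)}
    for name in PARAM_NAMES:
        arrays[f"generic/{name}"] = library.generic.params[name]
    for sid in library.ids:
        for name in PARAM_NAMES:
            arrays[f"schema{sid}/{name}"] = library.schemas[sid].params[name]
    np.savez(path, **arrays)


def load_library(path: str) -> SchemaLibrary:
    with np.load(path) as data:
        manifest = json.loads(bytes(data["manifest"]).decode())
        if manifest["format_version"] != 1:
            raise ValueError(f"unsupported format version {manifest['format_version']}")
        D, H = manifest["D"], manifest["H"]

        def load_net(prefix):
            net = SchemaNetwork.__new__(SchemaNetwork)
            net.D, net.H = D, H
            net.params = {n: data[f"{prefix}/{n}"].copy() for n in PARAM_NAMES}
            return net

        lib = SchemaLibrary(
            generic=load_net("generic"),
            schemas={sid: load_net(f"schema{sid}") for sid in manifest["ids"]},
            usage_counts={int(k): v for k, v in manifest["usage_counts"].items()},
            spawn_log=[tuple(x) for x in manifest["spawn_log"]],
            max_schemas=manifest["max_schemas"],
        )
        lib._next_id = manifest["next_id"]
        lib._step = manifest["step"]
    return lib
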