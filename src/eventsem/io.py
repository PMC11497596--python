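"""File formats: scene CSVs, rater CSVs, trace JSON-lines, config JSON.

All tabular data is plain CSV, configs and manifests are JSON, and
per-timestep traces are JSON-lines — language-agnostic formats that
round-trip losslessly for every declared field.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .datamodel import (
    Activity,
    Corpus,
    Decision,
    DecisionKind,
    EventTrace,
    HyperParams,
    RaterSegmentation,
    TraceRow,
)
from .synthetic import GeneratorConfig


# -- corpus ---------------------------------------------------------------

def save_corpus(corpus: Corpus, directory: str) -> None:
    """Write one scenes CSV (and labels CSV) per activity plus a manifest."""
    os.makedirs(directory, exist_ok=True)
    manifest = {"block_layout": corpus.block_layout, "activities": []}
    labels_rows = []
    for a in corpus.activities:
        cols = {f"f{i}": a.scenes[:, i] for i in range(a.D)}
        pd.DataFrame(cols).to_csv(
            os.path.join(directory, f"{a.id}_scenes.csv"), index=False
        )
        manifest["activities"].append(
            {
                "id": a.id,
                "dt": a.dt,
                "actor": a.actor_id,
                "environment": a.environment_id,
                "split": corpus.split[a.id],
                "has_labels": a.true_labels is not None,
            }
        )
        if a.true_labels is not None:
            for t, v in enumerate(a.true_labels):
                labels_rows.append({"activity_id": a.id, "t": t, "value": int(v)})
    if labels_rows:
        pd.DataFrame(labels_rows).to_csv(
            os.path.join(directory, "labels.csv"), index=False
        )
    with open(os.path.join(directory, "manifest.json"), "w") as f:
        json.dump(manifest, f, indent=2)


def load_corpus(directory: str) -> Corpus:
    with open(os.path.join(directory, "manifest.json")) as f:
        manifest = json.load(f)
    labels_path = os.path.join(directory, "labels.csv")
    labels_df = pd.read_csv(labels_path) if os.path.exists(labels_path) else None
    activities, split = [], {}
    for meta in manifest["activities"]:
        df = pd.read_csv(os.path.join(directory, f"{meta['id']}_scenes.csv"))
        scenes = df.to_numpy(dtype=float)
        true_labels = None
        if meta["has_labels"] and labels_df is not None:
            sub = labels_df[labels_df.activity_id == meta["id"]].sort_values("t")
            true_labels = sub["value"].to_numpy()
        activities.append(
            Activity(
                id=meta["id"], scenes=scenes, dt=meta["dt"],
                true_labels=true_labels, actor_id=meta["actor"],
                environment_id=meta["environment"],
            )
        )
        split[meta["id"]] = meta["split"]
    return Corpus(
        activities=activities, split=split,
        block_layout={k: int(v) for k, v in manifest["block_layout"].items()},
    )


# -- raters ---------------------------------------------------------------

def save_rater_csv(raters: list[RaterSegmentation], path: str) -> None:
    rows = [
        {
            "rater_id": r.rater_id, "activity_id": r.activity_id,
            "time_s": t, "grain": r.grain,
        }
        for r in raters for t in r.boundary_times
    ]
    pd.DataFrame(rows, columns=["rater_id", "activity_id", "time_s", "grain"]).to_csv(
        path, index=False
    )


def load_rater_csv(path: str) -> list[RaterSegmentation]:
    """Parse a rater CSV; malformed rows are rejected with line numbers."""
    df = pd.read_csv(path)
    required = {"rater_id", "activity_id", "time_s", "grain"}
    if not required.issubset(df.columns):
        raise ValueError(f"rater CSV missing columns {required - set(df.columns)}")
    bad = df.index[(df.time_s < 0) | ~np.isfinite(df.time_s)].tolist()
    if bad:
        # +2: header line plus 1-based numbering
        lines = ", ".join(str(i + 2) for i in bad[:10])
        raise ValueError(f"negative or non-finite time_s at line(s) {lines}")
    out = []
    for (rid, aid, grain), sub in df.groupby(
        ["rater_id", "activity_id", "grain"], sort=True
    ):
        out.append(
            RaterSegmentation(
                rater_id=str(rid), activity_id=str(aid),
                boundary_times=sub.time_s.to_numpy(), grain=str(grain),
            )
        )
    return out


# -- traces ---------------------------------------------------------------

def save_trace_jsonl(traces: list[EventTrace], path: str) -> None:
    with open(path, "w") as f:
        for trace in traces:
            for r in trace.rows:
                rec = {
                    "activity_id": trace.activity_id,
                    "t": r.t,
                    "schema": r.active_schema,
                    "decision": r.decision.kind.value,
                    "decision_schema": r.decision.schema_id,
                    "pe": r.pe,
                    "unc": None if math.isnan(r.unc) else r.unc,
                    "gate_fired": r.gate_fired,
                    "log_posterior_top3": r.log_posterior_top3,
                }
                f.write(json.dumps(rec) + "\n")


def load_trace_jsonl(path: str) -> list[EventTrace]:
    traces: dict[str, EventTrace] = {}
    with open(path) as f:
        for lineno, line in enumerate(f, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as e:
                raise ValueError(f"malformed trace row at line {lineno}: {e}") from e
            aid = rec["activity_id"]
            trace = traces.setdefault(aid, EventTrace(activity_id=aid))
            trace.rows.append(
                TraceRow(
                    t=rec["t"],
                    active_schema=rec["schema"],
                    decision=Decision(
                        DecisionKind(rec["decision"]), rec["decision_schema"]
                    ),
                    pe=rec["pe"],
                    unc=math.nan if rec["unc"] is None else rec["unc"],
                    gate_fired=rec["gate_fired"],
                    log_posterior_top3=(
                        None if rec["log_posterior_top3"] is None
                        else [tuple(x) for x in rec["log_posterior_top3"]]
                    ),
                )
            )
    return list(traces.values())


# -- experiment config ----------------------------------------------------

@dataclass
class ExperimentConfig:
    """A full experiment: corpus generation + model + simulation plan."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    hp: HyperParams = field(default_factory=HyperParams)
    variant: str = "unc"
    n_sims: int = 8
    out_dir: str = "results"
    seeds: Optional[list[int]] = None

    def to_dict(self) -> dict:
        d = {
            "generator": dataclasses.asdict(self.generator),
            "hp": dataclasses.asdict(self.hp),
            "variant": self.variant,
            "n_sims": self.n_sims,
            "out_dir": self.out_dir,
            "seeds": self.seeds,
        }
        d["generator"]["events_per_activity"] = list(
            self.generator.events_per_activity
        )
        d["generator"]["duration_range"] = list(self.generator.duration_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        gen = dict(d["generator"])
        gen["events_per_activity"] = tuple(gen["events_per_activity"])
        gen["duration_range"] = tuple(gen["duration_range"])
        return cls(
            generator=GeneratorConfig(**gen),
            hp=HyperParams(**d["hp"]),
            variant=d["variant"],
            n_sims=d["n_sims"],
            out_dir=d["out_dir"],
            seeds=d["seeds"],
        )

    def save(self, path: str) -> None:
        with open(path, "w") as f:
            json.dump(self.to_dict(), f, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path: str) -> "ExperimentConfig":
        with open(path) as f:
            return cls.from_dict(json.load(f))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()
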