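"""End-to-end experiment driver: corpus -> simulations -> metric tables."""

from __future__ import annotations

import json
import os
from typing import Optional

import numpy as np
import pandas as pd

from . import metrics, nets
from .datamodel import Corpus
from .io import ExperimentConfig, save_corpus, save_trace_jsonl
from .runner import SimulationResult, run_simulations
from .synthetic import generate_corpus, simulate_raters


def checkpoint_metrics(
    result: SimulationResult,
    corpus: Corpus,
    raters_by_activity: Optional[dict] = None,
    sim: int = 0,
) -> pd.DataFrame:
    """Tidy (simulation, checkpoint, metric, value) table for one run."""
    rows = []
    validation = corpus.validation
    for ckpt in result.checkpoints:
        def add(metric, value):
            rows.append(
                {
                    "simulation": sim,
                    "checkpoint": ckpt.n_trained,
                    "metric": metric,
                    "value": value,
                }
            )

        add("validation_pe", ckpt.validation_pe)
        add("mean_boundaries", ckpt.mean_boundaries)
        add("schema_count", ckpt.schema_count)
        traces = [ckpt.traces[a.id] for a in validation]
        model_labels, _ = metrics.concat_labels(traces)
        if all(a.true_labels is not None for a in validation):
            true_labels = np.concatenate([a.true_labels for a in validation])
            add("ami", metrics.adjusted_mutual_information(model_labels, true_labels))
            purity, coverage = metrics.purity_coverage(model_labels, true_labels)
            add("purity", purity)
            add("coverage", coverage)
        if raters_by_activity:
            spbs = []
            for a in validation:
                norm = metrics.normative_series(
                    raters_by_activity[a.id], a.T, a.dt
                )
                b = ckpt.traces[a.id].boundaries(
                    result.hp.count_resets_as_boundaries
                )
                try:
                    spbs.append(metrics.scaled_point_biserial(b, norm))
                except ValueError:
                    pass
            if spbs:
                add("scaled_point_biserial", float(np.mean(spbs)))
    return pd.DataFrame(rows)


def run_experiment(config: ExperimentConfig) -> str:
    """Run the configured experiment and write all artifacts.

    Creates the output directory, generates (and saves) the corpus and
    simulated raters, runs the simulations, writes the tidy metrics CSV,
    the final-checkpoint traces, the schema-library archives and a
    manifest carrying the config hash.  Returns the output directory.
    """
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    corpus = generate_corpus(config.generator)
    save_corpus(corpus, os.path.join(out, "corpus"))
    rater_rng = np.random.default_rng(config.generator.seed + 1)
    raters = {
        a.id: simulate_raters(a, rng=rater_rng) for a in corpus.validation
    }
    results = run_simulations(
        corpus, config.hp, config.variant, n_sims=config.n_sims, seeds=config.seeds
    )
    tables = []
    for i, res in enumerate(results):
        tables.append(checkpoint_metrics(res, corpus, raters, sim=i))
        save_trace_jsonl(
            list(res.final.traces.values()),
            os.path.join(out, f"traces_sim{i}.jsonl"),
        )
        nets.save_library(res.library, os.path.join(out, f"library_sim{i}.npz"))
    pd.concat(tables, ignore_index=True).to_csv(
        os.path.join(out, "metrics.csv"), index=False
    )
    config.save(os.path.join(out, "config.json"))
    manifest = {
        "config_hash": config.digest(),
        "n_sims": config.n_sims,
        "variant": config.variant,
        "complete": True,
    }
    with open(os.path.join(out, "manifest.json"), "w") as f:
        json.dump(manifest, f, indent=2)
    return out
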