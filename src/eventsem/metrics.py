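"""Evaluation statistics for segmentation and categorization.

Covers the validation prediction-error summary (mean over activities of
the mean squared Euclidean error per timestep), the normative boundary
series (proportion of raters marking a boundary in each timestep), the
scaled point-biserial segmentation agreement, adjusted mutual information
and purity/coverage for categorization agreement, boundary-interval
("flurry") statistics, schema spawn/reuse curves, and length-preserving
permutation nulls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import adjusted_mutual_info_score

from .datamodel import (
    Activity,
    DecisionKind,
    EventTrace,
    RaterSegmentation,
    bin_time,
    labels_to_boundaries,
)


def validation_pe(traces: Sequence[EventTrace], activities: Sequence[Activity]) -> float:
    """Mean over activities of the mean squared prediction error.

    Each trace row carries the Euclidean prediction error for its
    timestep; the per-activity summary is the mean of the squared errors
    over timesteps, and the corpus summary is the unweighted mean over
    activities (so every activity counts equally regardless of length).
    """
    by_id = {t.activity_id: t for t in traces}
    vals = []
    for a in activities:
        if a.id not in by_id:
            raise KeyError(f"missing trace for validation activity {a.id}")
        pes = by_id[a.id].pes
        vals.append(float(np.mean(pes * pes)))
    return float(np.mean(vals))


def normative_series(
    raters: Sequence[RaterSegmentation], T: int, dt: float
) -> np.ndarray:
    """Per-timestep proportion of raters with >= 1 boundary in that bin.

    Boundary times are binned by ``floor(time/dt)``; times outside the
    activity span are clipped into it.
    """
    if not raters:
        raise ValueError("need at least one rater")
    counts = np.zeros(T)
    for r in raters:
        bins = {bin_time(s, dt, T) for s in r.boundary_times}
        for b in bins:
            counts[b] += 1
    return counts / len(raters)


def point_biserial(boundaries: np.ndarray, normative: np.ndarray) -> float:
    """Pearson correlation of a binary boundary series with a continuous one."""
    b = np.asarray(boundaries, dtype=float)
    x = np.asarray(normative, dtype=float)
    if b.shape != x.shape:
        raise ValueError("length mismatch")
    bs, xs = b.std(), x.std()
    if bs == 0 or xs == 0:
        raise ValueError("point-biserial undefined for a constant series")
    return float(np.mean((b - b.mean()) * (x - x.mean())) / (bs * xs))


def scaled_point_biserial(boundaries: np.ndarray, normative: np.ndarray) -> float:
    """Point-biserial correlation rescaled by its attainable range.

    For a fixed boundary count B, the correlation is maximal when the B
    boundaries sit at the B largest normative values and minimal at the B
    smallest (it is monotone in the sum of normative values at boundary
    positions).  The scaled value ``(r - r_min) / (r_max - r_min)`` lies
    in [0, 1] and is comparable across segmenters with different B.

    Raises ValueError when undefined: no boundaries, all timesteps
    boundaries, or a constant normative series.
    """
    b = np.asarray(boundaries, dtype=int)
    x = np.asarray(normative, dtype=float)
    if b.shape != x.shape:
        raise ValueError("length mismatch")
    B = int(b.sum())
    if B == 0 or B == len(b):
        raise ValueError("scaled point-biserial undefined without both classes")
    order = np.argsort(x)
    b_min = np.zeros_like(b)
    b_min[order[:B]] = 1
    b_max = np.zeros_like(b)
    b_max[order[-B:]] = 1
    r = point_biserial(b, x)
    r_min = point_biserial(b_min, x)
    r_max = point_biserial(b_max, x)
    if r_max == r_min:
        raise ValueError("degenerate normative series: r_max == r_min")
    return (r - r_min) / (r_max - r_min)


def adjusted_mutual_information(labels_a: Sequence, labels_b: Sequence) -> float:
    """Chance-corrected agreement between two partitions of the timesteps.

    Adjusted mutual information with the permutation-model expected MI
    and max normalization; 1 for identical partitions, ~0 for independent
    ones, invariant to relabeling either partition.
    """
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("length mismatch")
    return float(adjusted_mutual_info_score(labels_a, labels_b, average_method="max"))


def purity_coverage(model_labels: Sequence, true_labels: Sequence) -> tuple[float, float]:
    """Complementary cluster-overlap scores.

    purity = (1/N) * sum over model clusters of their largest overlap with
    any true class (penalizes mixed model clusters); coverage = the same
    with the roles of the partitions swapped (penalizes fragmenting a true
    class across many model clusters).  A model partition that strictly
    refines the truth has purity 1 and coverage < 1.
    """
    m = np.asarray(model_labels)
    t = np.asarray(true_labels)
    if m.shape != t.shape:
        raise ValueError("length mismatch")
    N = len(m)
    mu, mi = np.unique(m, return_inverse=True)
    tu, ti = np.unique(t, return_inverse=True)
    cont = np.zeros((len(mu), len(tu)), dtype=int)
    np.add.at(cont, (mi, ti), 1)
    purity = cont.max(axis=1).sum() / N
    coverage = cont.max(axis=0).sum() / N
    return float(purity), float(coverage)


@dataclass
class PermutationNull:
    """Length-preserving permutations of a concatenated label sequence."""

    permutations: list[np.ndarray]
    offsets: list[int]
    rejected: int = 0
    metric_values: list[float] = field(default_factory=list)


def _runs(labels: np.ndarray) -> list[tuple[int, int]]:
    """Run-length encode: list of (label, length)."""
    labels = np.asarray(labels)
    out = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[i - 1]:
            out.append((labels[start], i - start))
            start = i
    return out


def gap_intervals(labels: np.ndarray, offsets: Sequence[int]) -> list[tuple[int, int]]:
    """Disallowed boundary zones at activity joins.

    For consecutive activities the interval runs from the onset of the
    last event of the earlier activity to the onset of the first event of
    the next (which is the activity's first timestep).  Permuted
    boundaries may not fall strictly inside these half-open intervals.
    """
    labels = np.asarray(labels)
    ivals = []
    for i in range(len(offsets) - 1):
        end = offsets[i + 1]  # exclusive end of activity i == start of next
        start = offsets[i]
        t = end - 1
        while t > start and labels[t] == labels[t - 1]:
            t -= 1
        ivals.append((t, end))
    return ivals


def permute_events(
    labels: np.ndarray,
    offsets: Sequence[int],
    rng: np.random.Generator,
    n: int,
    max_tries: int = 1000,
) -> PermutationNull:
    """Shuffle the order of label runs, preserving every run's length.

    ``labels`` is the concatenation of all activities' event labels and
    ``offsets`` the start index of each activity (first entry 0).  Each
    permutation reorders the runs uniformly at random, rejection-sampling
    until (a) no two same-label runs become adjacent (which would merge
    them and change the run-length multiset) and (b) no permuted boundary
    (run join) falls inside a gap interval between activities; after
    ``max_tries`` rejections the last draw is kept and counted in
    ``rejected``.
    """
    labels = np.asarray(labels)
    offsets = list(offsets)
    if not offsets or offsets[0] != 0:
        raise ValueError("offsets must start at 0")
    runs = _runs(labels)
    gaps = gap_intervals(labels, offsets)
    perms = []
    rejected = 0
    for _ in range(n):
        for attempt in range(max_tries):
            order = rng.permutation(len(runs))
            seq = np.concatenate(
                [np.full(runs[i][1], runs[i][0]) for i in order]
            )
            merged = any(
                runs[a][0] == runs[b][0] for a, b in zip(order, order[1:])
            )
            bpos = set(np.flatnonzero(seq[1:] != seq[:-1]) + 1)
            bad_gap = any(
                any(lo < p < hi for p in bpos) for lo, hi in gaps
            )
            if not merged and not bad_gap:
                break
        else:
            rejected += 1
        perms.append(seq)
    return PermutationNull(permutations=perms, offsets=offsets, rejected=rejected)


def split_by_offsets(seq: np.ndarray, offsets: Sequence[int]) -> list[np.ndarray]:
    """Split a concatenated sequence back into per-activity pieces."""
    bounds = list(offsets) + [len(seq)]
    return [seq[bounds[i]: bounds[i + 1]] for i in range(len(offsets))]


def permuted_boundaries(perm: np.ndarray, offsets: Sequence[int]) -> list[np.ndarray]:
    """Per-activity boundary indicators of a permuted label sequence."""
    return [labels_to_boundaries(p) for p in split_by_offsets(perm, offsets)]


def boundary_interval_stats(
    boundaries: np.ndarray, dt: float, threshold_s: float = 1.0
) -> tuple[np.ndarray, float]:
    """Inter-boundary intervals (seconds) and the share below a threshold.

    With fewer than two boundaries the interval list is empty and the
    fraction is NaN.  The comparison at the threshold is strict.
    """
    times = np.flatnonzero(np.asarray(boundaries) != 0) * dt
    if len(times) < 2:
        return np.array([]), math.nan
    intervals = np.diff(times)
    return intervals, float(np.mean(intervals < threshold_s))


def schema_usage_curves(
    spawn_log: Sequence[tuple[int, int]],
    traces: Sequence[EventTrace],
    activity_bins: Optional[Sequence[tuple[int, int]]] = None,
    n_bins: int = 3,
):
    """Spawn rate and schema-reuse rate per training-time bin.

    ``traces`` are the per-activity training traces in training order.
    Spawn rate is spawns per activity within the bin; reuse rate is the
    fraction of event-model transitions (SWITCH or SPAWN decisions) in the
    bin that reactivate a previously spawned schema (SWITCH) rather than
    spawning a new one.  Bins are (start, stop) activity-index ranges;
    by default the run is split into ``n_bins`` equal ranges.
    """
    if not traces:
        raise ValueError("no traces")
    n_act = len(traces)
    if activity_bins is None:
        edges = np.linspace(0, n_act, n_bins + 1).astype(int)
        activity_bins = [(edges[i], edges[i + 1]) for i in range(n_bins)]
    rows = []
    for lo, hi in activity_bins:
        spawns = switches = 0
        for i in range(lo, hi):
            for r in traces[i].rows:
                if r.decision.kind is DecisionKind.SPAWN:
                    spawns += 1
                elif r.decision.kind is DecisionKind.SWITCH:
                    switches += 1
        n = max(hi - lo, 1)
        transitions = spawns + switches
        rows.append({
            "bin": (lo, hi),
            "spawn_rate": spawns / n,
            "reuse_rate": switches / transitions if transitions else math.nan,
        })
    return rows


def concat_labels(traces: Sequence[EventTrace]) -> tuple[np.ndarray, list[int]]:
    """Concatenate per-activity model labels, returning activity offsets."""
    offsets, parts, pos = [], [], 0
    for t in traces:
        offsets.append(pos)
        lab = t.labels
        parts.append(lab)
        pos += len(lab)
    return np.concatenate(parts), offsets
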