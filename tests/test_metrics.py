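import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import hypergeom

from eventsem.datamodel import (
    Activity,
    Decision,
    DecisionKind,
    EventTrace,
    RaterSegmentation,
    TraceRow,
)
from eventsem.metrics import (
    adjusted_mutual_information,
    boundary_interval_stats,
    concat_labels,
    gap_intervals,
    normative_series,
    permute_events,
    permuted_boundaries,
    point_biserial,
    purity_coverage,
    scaled_point_biserial,
    schema_usage_curves,
    validation_pe,
)


def trace_with_pes(aid, pes, labels=None):
    t = EventTrace(activity_id=aid)
    for i, pe in enumerate(pes):
        lab = labels[i] if labels is not None else 0
        t.rows.append(
            TraceRow(t=i, active_schema=lab,
                     decision=Decision(DecisionKind.KEEP, lab), pe=pe)
        )
    return t


def activity(aid, T):
    return Activity(id=aid, scenes=np.zeros((T, 3)))


class TestValidationPE:
    def test_perfect_predictions_zero(self):
        tr = trace_with_pes("a", [0.0, 0.0])
        assert validation_pe([tr], [activity("a", 2)]) == 0.0

    def test_hand_values(self):
        tr = trace_with_pes("a", [3.0, 4.0])
        assert validation_pe([tr], [activity("a", 2)]) == pytest.approx(
            12.5, rel=1e-9
        )
        tr2 = trace_with_pes("b", [0.0, 0.0, 0.0])
        both = validation_pe([tr, tr2], [activity("a", 2), activity("b", 3)])
        assert both == pytest.approx(6.25, rel=1e-9)

    def test_activity_order_invariance(self):
        tr = trace_with_pes("a", [1.0, 2.0])
        tr2 = trace_with_pes("b", [3.0])
        acts = [activity("a", 2), activity("b", 1)]
        assert validation_pe([tr, tr2], acts) == validation_pe(
            [tr2, tr], acts[::-1]
        )

    def test_brute_force_double_loop(self, rng):
        pes = {"a": rng.uniform(0, 3, size=5), "b": rng.uniform(0, 3, size=7)}
        traces = [trace_with_pes(k, v) for k, v in pes.items()]
        acts = [activity("a", 5), activity("b", 7)]
        expected = np.mean([np.mean([e * e for e in v]) for v in pes.values()])
        assert validation_pe(traces, acts) == pytest.approx(expected, rel=1e-12)

    def test_missing_trace_raises(self):
        with pytest.raises(KeyError):
            validation_pe([], [activity("a", 2)])


class TestNormativeSeries:
    def test_single_rater_binning(self):
        r = RaterSegmentation("r", "a", [1.0])
        series = normative_series([r], T=6, dt=1 / 3)
        assert series[3] == 1.0 and series.sum() == 1.0

    def test_proportion(self):
        raters = [
            RaterSegmentation(f"r{i}", "a", [5 * 0.5] if i < 2 else [])
            for i in range(4)
        ]
        series = normative_series(raters, T=10, dt=0.5)
        assert series[5] == 0.5

    def test_identical_raters_binary(self):
        raters = [RaterSegmentation(f"r{i}", "a", [0.6, 2.1]) for i in range(7)]
        series = normative_series(raters, T=10, dt=0.5)
        assert set(np.unique(series)) <= {0.0, 1.0}

    def test_out_of_span_clipped(self):
        r = RaterSegmentation("r", "a", [99.0])
        series = normative_series([r], T=4, dt=0.5)
        assert series[3] == 1.0


class TestScaledPointBiserial:
    def test_optimal_placement_is_one(self):
        norm = np.array([0.9, 0.1, 0.5, 0.2])
        b = np.array([1, 0, 1, 0])  # the two largest normative values
        assert scaled_point_biserial(b, norm) == pytest.approx(1.0)

    def test_pessimal_placement_is_zero(self):
        norm = np.array([0.9, 0.1, 0.5, 0.2])
        b = np.array([0, 1, 0, 1])
        assert scaled_point_biserial(b, norm) == pytest.approx(0.0)

    def test_four_point_fixture(self):
        norm = np.array([0.9, 0.1, 0.5, 0.2])
        b = np.array([0, 0, 1, 0])
        assert scaled_point_biserial(b, norm) == pytest.approx(0.5)

    def test_linear_in_selected_value(self):
        """Brute force: single-boundary scaled value is linear in the
        normative value at the boundary position."""
        norm = np.array([0.9, 0.1, 0.5, 0.2])
        lo, hi = norm.min(), norm.max()
        for i in range(4):
            b = np.zeros(4, dtype=int)
            b[i] = 1
            expected = (norm[i] - lo) / (hi - lo)
            assert scaled_point_biserial(b, norm) == pytest.approx(expected)

    @given(st.data())
    def test_in_unit_interval(self, data):
        T = data.draw(st.integers(4, 30))
        norm = np.array(
            data.draw(
                st.lists(
                    st.floats(0, 1, allow_nan=False), min_size=T, max_size=T
                )
            )
        )
        B = data.draw(st.integers(1, T - 1))
        pos = data.draw(st.permutations(range(T)))[:B]
        b = np.zeros(T, dtype=int)
        b[list(pos)] = 1
        if len(np.unique(norm)) < 2:
            return
        val = scaled_point_biserial(b, norm)
        assert -1e-9 <= val <= 1 + 1e-9

    def test_undefined_cases_signaled(self):
        with pytest.raises(ValueError):
            scaled_point_biserial(np.zeros(4, dtype=int), np.arange(4.0))
        with pytest.raises(ValueError):
            scaled_point_biserial(np.array([1, 0, 0, 0]), np.ones(4))


def _ami_oracle(a, b):
    """Direct-formula AMI: hypergeometric expected MI, max normalization."""
    a, b = np.asarray(a), np.asarray(b)
    N = len(a)
    av, ai = np.unique(a, return_inverse=True)
    bv, bi = np.unique(b, return_inverse=True)
    cont = np.zeros((len(av), len(bv)))
    np.add.at(cont, (ai, bi), 1)
    arow, bcol = cont.sum(1), cont.sum(0)
    mi = 0.0
    for i in range(len(av)):
        for j in range(len(bv)):
            nij = cont[i, j]
            if nij:
                mi += nij / N * math.log(N * nij / (arow[i] * bcol[j]))
    emi = 0.0
    for ai_ in arow:
        for bj in bcol:
            lo = int(max(ai_ + bj - N, 1))
            hi = int(min(ai_, bj))
            for nij in range(lo, hi + 1):
                p = hypergeom.pmf(nij, N, ai_, bj)
                emi += p * nij / N * math.log(N * nij / (ai_ * bj))
    ha = -sum(x / N * math.log(x / N) for x in arow)
    hb = -sum(x / N * math.log(x / N) for x in bcol)
    denom = max(ha, hb) - emi
    return (mi - emi) / denom


class TestAMI:
    def test_identical_partitions(self):
        assert adjusted_mutual_information([0, 0, 1, 1], [5, 5, 9, 9]) == 1.0

    def test_relabel_invariance(self, rng):
        a = rng.integers(0, 3, size=40)
        b = rng.integers(0, 4, size=40)
        relab = np.array([7, 3, 11])[a]
        assert adjusted_mutual_information(a, b) == pytest.approx(
            adjusted_mutual_information(relab, b)
        )

    def test_symmetry(self, rng):
        a = rng.integers(0, 3, size=30)
        b = rng.integers(0, 3, size=30)
        assert adjusted_mutual_information(a, b) == pytest.approx(
            adjusted_mutual_information(b, a)
        )

    @pytest.mark.parametrize(
        "a,b",
        [
            ([0, 0, 1, 1], [0, 0, 1, 2]),
            ([0, 0, 1, 1, 2, 2], [0, 1, 1, 1, 2, 2]),
        ],
    )
    def test_matches_direct_formula_oracle(self, a, b):
        assert adjusted_mutual_information(a, b) == pytest.approx(
            _ami_oracle(a, b), rel=1e-6
        )


class TestPurityCoverage:
    def test_identical(self):
        assert purity_coverage([0, 0, 1], [4, 4, 5]) == (1.0, 1.0)

    def test_refinement(self):
        model = [0, 0, 1, 1, 2, 2]
        true = [0, 0, 0, 0, 1, 1]
        p, c = purity_coverage(model, true)
        assert p == 1.0 and c < 1.0

    def test_hand_fixture(self):
        model = ["A", "A", "B", "B", "C", "C"]
        true = ["x", "x", "x", "y", "y", "y"]
        p, c = purity_coverage(model, true)
        assert p == pytest.approx(5 / 6)
        assert c == pytest.approx(2 / 3)


class TestPermuteEvents:
    def test_single_run_identity(self, rng):
        labels = np.zeros(8, dtype=int)
        null = permute_events(labels, [0], rng, n=3)
        for p in null.permutations:
            assert np.array_equal(p, labels)

    @given(st.lists(st.integers(0, 2), min_size=2, max_size=30))
    def test_run_length_multiset_preserved(self, labels):
        labels = np.array(labels)
        rng = np.random.default_rng(0)
        null = permute_events(labels, [0], rng, n=3)

        def multiset(x):
            runs = []
            start = 0
            for i in range(1, len(x) + 1):
                if i == len(x) or x[i] != x[i - 1]:
                    runs.append(i - start)
                    start = i
            return sorted(runs)

        for p in null.permutations:
            assert multiset(p) == multiset(labels)

    def test_enumerated_orderings(self, rng):
        labels = np.array([0, 0, 1, 2, 2, 2])  # runs of lengths {2, 1, 3}
        valid = set()
        for order in itertools.permutations([(0, 2), (1, 1), (2, 3)]):
            valid.add(
                tuple(np.concatenate([np.full(n, v) for v, n in order]))
            )
        null = permute_events(labels, [0], rng, n=20)
        for p in null.permutations:
            assert tuple(p) in valid

    def test_gap_constraint_respected(self, rng):
        # two activities; gap = last run of act 0 through start of act 1
        labels = np.array([0, 0, 1, 1, 1, 2, 2, 3, 3])
        offsets = [0, 5]
        gaps = gap_intervals(labels, offsets)
        assert gaps == [(2, 5)]
        null = permute_events(labels, offsets, rng, n=30)
        assert null.rejected == 0
        for p in null.permutations:
            bpos = np.flatnonzero(p[1:] != p[:-1]) + 1
            assert not any(2 < b < 5 for b in bpos)

    def test_permuted_boundaries_split(self, rng):
        labels = np.array([0, 0, 1, 1, 2, 2])
        bnds = permuted_boundaries(labels, [0, 3])
        assert [b.tolist() for b in bnds] == [[0, 0, 1], [0, 1, 0]]


class TestBoundaryIntervals:
    def test_hand_fixture(self):
        b = np.zeros(31, dtype=int)
        b[[0, 1, 2, 30]] = 1
        intervals, frac = boundary_interval_stats(b, dt=1 / 3)
        assert np.allclose(intervals, [1 / 3, 1 / 3, 28 / 3])
        assert frac == pytest.approx(2 / 3)

    @pytest.mark.parametrize("b", [np.zeros(5, dtype=int), np.eye(5, dtype=int)[2]])
    def test_fewer_than_two_boundaries(self, b):
        intervals, frac = boundary_interval_stats(b, dt=1 / 3)
        assert len(intervals) == 0 and math.isnan(frac)

    def test_strict_threshold(self):
        b = np.zeros(10, dtype=int)
        b[[0, 3]] = 1  # exactly 1.0 s apart at dt=1/3
        _, frac = boundary_interval_stats(b, dt=1 / 3, threshold_s=1.0)
        assert frac == 0.0


class TestUsageCurves:
    def make_trace(self, kinds):
        t = EventTrace(activity_id="a")
        for i, (kind, sid) in enumerate(kinds):
            t.rows.append(
                TraceRow(t=i, active_schema=sid, decision=Decision(kind, sid),
                         pe=0.0)
            )
        return t

    def test_all_keep_no_spawns(self):
        K = DecisionKind.KEEP
        traces = [self.make_trace([(DecisionKind.SPAWN, 0), (K, 0), (K, 0)])]
        traces += [self.make_trace([(K, 0)] * 3) for _ in range(5)]
        rows = schema_usage_curves([(0, 0)], traces, n_bins=2)
        assert rows[1]["spawn_rate"] == 0.0

    def test_every_inference_spawns_reuse_zero(self):
        S = DecisionKind.SPAWN
        traces = [self.make_trace([(S, i) for i in range(4)])]
        rows = schema_usage_curves([(i, i) for i in range(4)], traces, n_bins=1)
        assert rows[0]["reuse_rate"] == 0.0

    def test_hand_counted_bins(self):
        S, W, K = DecisionKind.SPAWN, DecisionKind.SWITCH, DecisionKind.KEEP
        bin1 = self.make_trace([(S, 0), (S, 1), (K, 1)])
        bin2 = self.make_trace([(W, 0), (W, 1), (W, 0), (W, 1)])
        rows = schema_usage_curves(
            [(0, 0), (1, 1)], [bin1, bin2], activity_bins=[(0, 1), (1, 2)]
        )
        assert rows[0]["spawn_rate"] == 2.0
        assert rows[1]["reuse_rate"] == 1.0


def test_concat_labels_offsets():
    t1 = trace_with_pes("a", [0, 0, 0], labels=[1, 1, 2])
    t2 = trace_with_pes("b", [0, 0], labels=[2, 3])
    labels, offsets = concat_labels([t1, t2])
    assert labels.tolist() == [1, 1, 2, 2, 3]
    assert offsets == [0, 3]
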