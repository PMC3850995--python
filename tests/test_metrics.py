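"""Per-target metrics: top-L/n selection, accuracies, clustering, ROC, summaries."""

import math

import numpy as np
import pytest

from contactbench.metrics import (
    ClusterSet,
    SelectionSpec,
    cluster_accuracy,
    exact_accuracy,
    greedy_cluster,
    neighbourhood_accuracy,
    pooled_roc,
    select_top,
    summarize,
)
from contactbench.rr_io import PredictionSet, ScoredPair

from conftest import make_map, make_pair, random_instance


# ---------------------------------------------------------------- oracles
def oracle_neighbourhood(selected, truth_pairs, delta):
    hits = 0
    for p in selected:
        ok = False
        for (u, v) in truth_pairs:
            if abs(p.i - u) <= delta and abs(p.j - v) <= delta:
                ok = True
        if ok:
            hits += 1
    return hits / len(selected)


def oracle_greedy(selected, radius=8):
    reps = []
    for p in selected:
        keep = True
        for r in reps:
            if abs(p.i - r.i) <= radius and abs(p.j - r.j) <= radius:
                keep = False
                break
        if keep:
            reps.append(p)
    return reps


def oracle_auc(scored_labels):
    """Normalized Mann-Whitney pair count, ties counted one half."""
    pos = [s for s, l in scored_labels if l]
    neg = [s for s, l in scored_labels if not l]
    wins = sum(
        1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg
    )
    return wins / (len(pos) * len(neg))


# ---------------------------------------------------------------- selection
def _preds(pairs_scores, length=100):
    return PredictionSet(
        target_id="T1",
        predictor_id="m",
        pairs=tuple(make_pair(i, j, s) for (i, j), s in pairs_scores),
        length=length,
    )


class TestSelectTop:
    def test_count_rule_floor_l_over_n(self, rng):
        truth = make_map([(1, 40)], length=100)
        pairs = [((i, i + 30), 1 - i / 100) for i in range(1, 21)]
        sel = select_top(_preds(pairs), truth, SelectionSpec(10, "long"))
        assert len(sel) == 10
        assert [p.pair for p in sel] == [(i, i + 30) for i in range(1, 11)]

    def test_minimum_one_for_tiny_targets(self):
        # L = 7, n = 10: floor(0.7) = 0 is raised to a single prediction
        truth = make_map([], length=7)
        preds = PredictionSet("T1", "m", (make_pair(1, 7, 0.9),), length=7)
        sel = select_top(preds, truth, SelectionSpec(10, "short"))
        assert [p.pair for p in sel] == [(1, 7)]

    def test_invalid_divisor_rejected(self):
        with pytest.raises(ValueError):
            SelectionSpec(0, "long")

    def test_wrong_class_and_unobserved_pairs_excluded(self):
        truth = make_map([], length=100, observed=range(1, 60))
        pairs = [
            ((1, 40), 0.9),   # long, observed -> kept
            ((1, 13), 0.8),   # medium -> filtered by class
            ((30, 70), 0.7),  # position 70 unobserved -> dropped
        ]
        sel = select_top(_preds(pairs), truth, SelectionSpec(10, "long"))
        assert [p.pair for p in sel] == [(1, 40)]

    def test_ties_match_brute_force_stable_sort(self, rng):
        for _ in range(50):
            length = 60
            n = int(rng.integers(1, 40))
            seen = set()
            pairs = []
            while len(pairs) < n:
                i = int(rng.integers(1, length))
                j = int(rng.integers(i + 1, length + 1))
                if (i, j) in seen:
                    continue
                seen.add((i, j))
                pairs.append(((i, j), float(rng.choice([0.2, 0.5, 0.9]))))
            truth = make_map([], length=length)
            preds = _preds(pairs, length=length)
            divisor = int(rng.choice([1, 5, 10]))
            sel = select_top(preds, truth, SelectionSpec(divisor, "long"))
            eligible = [p for p in preds.pairs if p.j - p.i >= 24]
            full = sorted(eligible, key=lambda p: (-p.score, p.i, p.j))
            k = max(length // divisor, 1)
            assert list(sel) == full[:k]

    def test_smaller_divisor_selection_is_prefix_of_larger(self, rng):
        truth, selected = random_instance(rng, length=60)
        preds = PredictionSet("T1", "m", tuple(selected), length=60)
        sels = {
            d: select_top(preds, truth, SelectionSpec(d, "long")) for d in (10, 5, 1)
        }
        assert sels[5][: len(sels[10])] == sels[10]
        assert sels[1][: len(sels[5])] == sels[5]


class TestExactAccuracy:
    def test_ten_true_among_twenty_selected_is_half(self):
        truth = make_map([(i, i + 30) for i in range(1, 11)], length=100)
        selected = [make_pair(i, i + 30, 1 - i / 50) for i in range(1, 11)]
        selected += [make_pair(i, i + 40, 0.3 - i / 100) for i in range(1, 11)]
        rec = exact_accuracy(selected, truth)
        assert rec.value == 0.50
        assert (rec.numerator, rec.denominator) == (10, 20)

    def test_bounds(self):
        truth = make_map([(1, 40)], length=100)
        assert exact_accuracy([make_pair(1, 40, 0.9)], truth).value == 1.0
        assert exact_accuracy([make_pair(2, 50, 0.9)], truth).value == 0.0

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            exact_accuracy([], make_map([(1, 40)]))


class TestNeighbourhoodAccuracy:
    def test_offset_one_counts_at_delta_one(self):
        truth = make_map([(11, 41)], length=100)
        sel = [make_pair(10, 40, 0.9)]
        assert neighbourhood_accuracy(sel, truth, 1).value == 1.0
        assert neighbourhood_accuracy(sel, truth, 0).value == 0.0

    def test_delta_zero_equals_exact(self, rng):
        for _ in range(30):
            truth, selected = random_instance(rng)
            assert (
                neighbourhood_accuracy(selected, truth, 0).value
                == exact_accuracy(selected, truth).value
            )

    def test_matches_exhaustive_oracle_and_monotone_in_delta(self, rng):
        for _ in range(100):
            truth, selected = random_instance(rng)
            prev = -1.0
            for delta in (0, 1, 2, 3):
                got = neighbourhood_accuracy(selected, truth, delta).value
                assert got == oracle_neighbourhood(selected, truth.pairs, delta)
                assert got >= prev
                prev = got


class TestGreedyCluster:
    def test_single_prediction_is_one_representative(self):
        cs = greedy_cluster([make_pair(10, 50, 0.9)])
        assert cs.count == 1

    def test_nearby_pair_excluded(self):
        cs = greedy_cluster([make_pair(10, 50, 0.9), make_pair(12, 52, 0.8)])
        assert [p.pair for p in cs.representatives] == [(10, 50)]

    def test_pair_differing_on_one_axis_kept(self):
        cs = greedy_cluster([make_pair(10, 50, 0.9), make_pair(10, 60, 0.8)])
        assert cs.count == 2

    def test_matches_literal_scan_and_invariants(self, rng):
        for _ in range(100):
            _, selected = random_instance(rng)
            cs = greedy_cluster(selected)
            expected = oracle_greedy(selected)
            assert list(cs.representatives) == expected
            assert cs.count <= len(selected)
            # subsequence of the ranked input
            it = iter(selected)
            assert all(any(r is p for p in it) for r in cs.representatives)
            for a in range(cs.count):
                for b in range(a + 1, cs.count):
                    ra, rb = cs.representatives[a], cs.representatives[b]
                    assert abs(ra.i - rb.i) > 8 or abs(ra.j - rb.j) > 8

    def test_constructor_rejects_violating_representatives(self):
        with pytest.raises(ValueError):
            ClusterSet(representatives=(make_pair(10, 50, 0.9), make_pair(11, 51, 0.8)))


class TestClusterAccuracy:
    def test_equals_neighbourhood_accuracy_of_representatives(self, rng):
        for _ in range(50):
            truth, selected = random_instance(rng)
            cs = greedy_cluster(selected)
            rec = cluster_accuracy(cs, truth, delta=2)
            assert rec.value == neighbourhood_accuracy(
                cs.representatives, truth, 2
            ).value


class TestPooledRoc:
    def test_perfect_separation_gives_auc_one(self):
        items = [(0.9, True), (0.8, True), (0.2, False), (0.1, False)]
        assert pooled_roc(items).auc == 1.0

    def test_all_tied_scores_give_diagonal(self):
        items = [(0.5, True), (0.5, False), (0.5, True), (0.5, False)]
        curve = pooled_roc(items)
        assert set(zip(curve.fpr, curve.tpr)) == {(0.0, 0.0), (1.0, 1.0)}
        assert curve.auc == 0.5

    def test_single_label_class_rejected(self):
        with pytest.raises(ValueError):
            pooled_roc([(0.5, True), (0.9, True)])

    def test_matches_mann_whitney_pair_count(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 50))
            labels = rng.integers(0, 2, size=n).astype(bool)
            if labels.all() or not labels.any():
                continue
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
            items = list(zip(scores.tolist(), labels.tolist()))
            assert pooled_roc(items).auc == pytest.approx(oracle_auc(items), abs=1e-12)

    def test_invariant_under_strictly_increasing_transform(self, rng):
        n = 40
        labels = rng.integers(0, 2, size=n).astype(bool)
        labels[0], labels[1] = True, False
        scores = rng.uniform(0.0, 1.0, size=n)
        base = pooled_roc(list(zip(scores.tolist(), labels.tolist()))).auc
        squashed = pooled_roc(list(zip((scores ** 3).tolist(), labels.tolist()))).auc
        assert squashed == pytest.approx(base, abs=1e-12)


class TestSummarize:
    def test_zero_variance(self):
        from contactbench.metrics import MetricRecord, make_params
        recs = [
            MetricRecord(f"T{k}", "accuracy", make_params(delta=0), 4, 10)
            for k in range(3)
        ]
        s = summarize(recs)
        assert s.mean == pytest.approx(0.4)
        assert s.se == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_se(self):
        from contactbench.metrics import MetricRecord, make_params
        recs = [
            MetricRecord(f"T{k}", "accuracy", make_params(delta=0), n, 10)
            for k, n in enumerate([2, 4, 6])
        ]
        s = summarize(recs)
        assert s.mean == pytest.approx(0.4)
        assert s.se == pytest.approx(0.2 / math.sqrt(3))

    def test_single_target_has_undefined_se(self):
        from contactbench.metrics import MetricRecord, make_params
        s = summarize([MetricRecord("T0", "accuracy", make_params(delta=0), 5, 10)])
        assert s.mean == 0.5 and s.se is None and s.n_targets == 1

    def test_mixed_metrics_rejected(self):
        from contactbench.metrics import MetricRecord, make_params
        recs = [
            MetricRecord("T0", "accuracy", make_params(delta=0), 5, 10),
            MetricRecord("T1", "accuracy", make_params(delta=1), 5, 10),
        ]
        with pytest.raises(ValueError):
            summarize(recs)
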