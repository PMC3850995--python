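"""Evaluation metrics for ranked residue-residue contact predictions.

Implements the per-target metrics used to benchmark contact predictors:

* top-L/n selection — the floor(L/n) highest-scored pairs of a separation
  class, where L is the target length and n a small divisor (1, 5, 10);
* exact accuracy — fraction of selected pairs that are true contacts;
* neighbourhood accuracy — a selected pair counts as correct if a true
  contact lies within ±δ on both sequence indices, crediting predictions
  with less-than-residue-level precision;
* greedy clustering — scan the ranked selection and keep a pair as a
  cluster representative only if it differs by more than ``radius`` (8)
  positions on at least one index from every earlier representative; the
  representative count measures how many distinct interaction areas a
  predictor identifies, and representatives are scored at δ = 2;
* pooled ROC/AUC — pool each target's top-L (or L/n) selection across the
  dataset with exact true-contact labels and sweep decision thresholds;
* dataset summary — per-target mean with standard error from the sample
  variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

from .contact_map import SEP_CLASSES, ContactMap, classify_separation
from .rr_io import PredictionSet, ScoredPair

DEFAULT_CLUSTER_RADIUS = 8
DEFAULT_CLUSTER_DELTA = 2


@dataclass(frozen=True)
class SelectionSpec:
    """How many predictions to evaluate and of which separation class.

    The count rule is floor(L/divisor) with a minimum of 1, so tiny targets
    still contribute a denominator.
    """

    divisor: int
    sep_class: str

    def __post_init__(self) -> None:
        if self.divisor < 1:
            raise ValueError("divisor must be >= 1")
        if self.sep_class not in SEP_CLASSES:
            raise ValueError(f"sep_class must be one of {SEP_CLASSES}")

    def count(self, length: int) -> int:
        return max(length // self.divisor, 1)


@dataclass(frozen=True)
class MetricRecord:
    """One per-target metric value with its numerator/denominator and parameters."""

    target_id: str
    metric: str
    params: tuple[tuple[str, object], ...]
    numerator: int
    denominator: int

    def __post_init__(self) -> None:
        if self.denominator < 1:
            raise ValueError("denominator must be >= 1")
        if not 0 <= self.numerator <= self.denominator:
            raise ValueError("numerator out of range")

    @property
    def value(self) -> float:
        return self.numerator / self.denominator

    @property
    def key(self) -> tuple:
        """Metric identity (name + parameters), for grouping across targets."""
        return (self.metric, self.params)


def make_params(**kwargs: object) -> tuple[tuple[str, object], ...]:
    return tuple(sorted(kwargs.items()))


@dataclass(frozen=True)
class ClusterSet:
    """Greedy-scan cluster representatives of a ranked selection."""

    representatives: tuple[ScoredPair, ...]
    radius: int = DEFAULT_CLUSTER_RADIUS

    def __post_init__(self) -> None:
        reps = self.representatives
        for a in range(len(reps)):
            for b in range(a + 1, len(reps)):
                if (
                    abs(reps[a].i - reps[b].i) <= self.radius
                    and abs(reps[a].j - reps[b].j) <= self.radius
                ):
                    raise ValueError(
                        f"representatives {reps[a].pair} and {reps[b].pair} "
                        f"violate the exclusion radius {self.radius}"
                    )

    @property
    def count(self) -> int:
        return len(self.representatives)


@dataclass(frozen=True)
class RocCurve:
    """ROC points over decreasing decision thresholds, with trapezoidal AUC."""

    fpr: tuple[float, ...]
    tpr: tuple[float, ...]
    thresholds: tuple[float, ...]
    auc: float

    def __post_init__(self) -> None:
        f, t = np.asarray(self.fpr), np.asarray(self.tpr)
        if np.any(np.diff(f) < 0) or np.any(np.diff(t) < 0):
            raise ValueError("ROC points must be monotone")
        if not (f[0] == 0.0 and t[0] == 0.0 and f[-1] == 1.0 and t[-1] == 1.0):
            raise ValueError("ROC curve must be anchored at (0,0) and (1,1)")


@dataclass(frozen=True)
class DatasetSummary:
    """Mean and standard error of one metric over the targets of a dataset.

    SE = sample standard deviation (N-1 denominator) / sqrt(N); undefined
    (None) for a single target.
    """

    metric: str
    params: tuple[tuple[str, object], ...]
    n_targets: int
    mean: float
    se: Optional[float]


def select_top(
    predictions: PredictionSet,
    contact_map_context: ContactMap,
    spec: SelectionSpec,
) -> tuple[ScoredPair, ...]:
    """The top floor(L/divisor) predictions of the requested separation class.

    Pairs touching residues unobserved in the structure are excluded first,
    so predictors are not penalized for unresolved regions.  Sorting is by
    score descending with ties broken by (i, j) ascending, which makes the
    selection fully deterministic and makes top-L/10 a prefix of top-L/5.
    Fewer pairs than requested may be returned if the filtered list is short.
    """
    length = predictions.length or contact_map_context.length
    observed = contact_map_context.observed_positions()
    eligible = [
        p
        for p in predictions.pairs
        if classify_separation(p.i, p.j) == spec.sep_class
        and p.i in observed
        and p.j in observed
    ]
    eligible.sort(key=lambda p: (-p.score, p.i, p.j))
    return tuple(eligible[: spec.count(length)])


def exact_accuracy(
    selected: Sequence[ScoredPair],
    truth: ContactMap,
    params: Optional[tuple[tuple[str, object], ...]] = None,
) -> MetricRecord:
    """Fraction of the selected pairs that are true contacts.

    E.g. 10 true contacts among 20 considered predictions gives 0.50.
    """
    if not selected:
        raise ValueError("empty selection")
    true_pairs = truth.pairs
    hits = sum(1 for p in selected if p.pair in true_pairs)
    return MetricRecord(
        target_id=truth.target_id,
        metric="accuracy",
        params=params if params is not None else make_params(delta=0),
        numerator=hits,
        denominator=len(selected),
    )


def neighbourhood_accuracy(
    selected: Sequence[ScoredPair],
    truth: ContactMap,
    delta: int,
    params: Optional[tuple[tuple[str, object], ...]] = None,
) -> MetricRecord:
    """Accuracy allowing less-than-residue-level precision.

    A selected pair (x, y) is correct if some true contact (u, v), both
    normalized to first index < second, satisfies |x-u| <= δ and |y-v| <= δ.
    A single true contact may validate several predictions.  δ = 0 reduces
    to exact accuracy.
    """
    if not selected:
        raise ValueError("empty selection")
    if delta < 0:
        raise ValueError("delta must be >= 0")
    truth_arr = np.array(sorted(truth.pairs), dtype=int).reshape(-1, 2)
    hits = 0
    for p in selected:
        if truth_arr.size and bool(
            np.any(
                (np.abs(truth_arr[:, 0] - p.i) <= delta)
                & (np.abs(truth_arr[:, 1] - p.j) <= delta)
            )
        ):
            hits += 1
    return MetricRecord(
        target_id=truth.target_id,
        metric="accuracy",
        params=params if params is not None else make_params(delta=delta),
        numerator=hits,
        denominator=len(selected),
    )


def greedy_cluster(
    selected: Sequence[ScoredPair], radius: int = DEFAULT_CLUSTER_RADIUS
) -> ClusterSet:
    """Greedy scan of the ranked selection keeping well-separated representatives.

    The first pair always becomes a representative; a later pair (x, y) is
    added only if |x - xi| > radius or |y - yi| > radius for every existing
    representative (xi, yi).
    """
    if not selected:
        raise ValueError("empty selection")
    reps: list[ScoredPair] = []
    for p in selected:
        if all(
            abs(p.i - r.i) > radius or abs(p.j - r.j) > radius for r in reps
        ):
            reps.append(p)
    return ClusterSet(representatives=tuple(reps), radius=radius)


def cluster_accuracy(
    clusters: ClusterSet,
    truth: ContactMap,
    delta: int = DEFAULT_CLUSTER_DELTA,
    params: Optional[tuple[tuple[str, object], ...]] = None,
) -> MetricRecord:
    """Neighbourhood accuracy (default δ = 2) of the cluster representatives."""
    if clusters.count < 1:
        raise ValueError("empty representative list")
    rec = neighbourhood_accuracy(clusters.representatives, truth, delta)
    return MetricRecord(
        target_id=truth.target_id,
        metric="cluster_accuracy",
        params=params if params is not None else make_params(delta=delta, radius=clusters.radius),
        numerator=rec.numerator,
        denominator=rec.denominator,
    )


def pooled_roc(
    scored_labels: Iterable[tuple[float, bool]],
) -> RocCurve:
    """ROC curve and AUC over pooled per-target selections.

    Input is the pooled collection of (score, is-true-contact) items — each
    target contributes its top-L (or L/n) selection labelled with the exact
    contact definition.  The curve sweeps every distinct score as a decision
    threshold; AUC is the trapezoidal area.
    """
    items = list(scored_labels)
    scores = np.array([s for s, _ in items], dtype=float)
    labels = np.array([bool(l) for _, l in items], dtype=bool)
    if labels.size == 0 or labels.all() or not labels.any():
        raise ValueError("pooled set needs at least one positive and one negative")
    fpr, tpr, thresholds = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(
        fpr=tuple(float(x) for x in fpr),
        tpr=tuple(float(x) for x in tpr),
        thresholds=tuple(float(x) for x in thresholds),
        auc=auc,
    )


def summarize(per_target: Sequence[MetricRecord]) -> DatasetSummary:
    """Mean and standard error of one metric's per-target values."""
    if not per_target:
        raise ValueError("no records to summarize")
    keys = {r.key for r in per_target}
    if len(keys) > 1:
        raise ValueError(f"mixed metrics in summary: {keys}")
    values = np.array([r.value for r in per_target], dtype=float)
    n = len(values)
    mean = float(values.mean())
    se = float(values.std(ddof=1) / math.sqrt(n)) if n >= 2 else None
    rec = per_target[0]
    return DatasetSummary(
        metric=rec.metric, params=rec.params, n_targets=n, mean=mean, se=se
    )
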