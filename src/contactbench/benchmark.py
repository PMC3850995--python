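"""Dataset-level orchestration: evaluate predictors over targets, summarize.

The evaluation unit is the full protein — no per-domain splitting.  For each
predictor and target the configured grid of (separation class, L/n divisor,
δ) accuracies is computed, plus greedy-cluster accuracy and count per
(class, divisor).  Dataset summaries are per-target means with standard
errors; cluster counts are summed over targets; ROC/AUC is computed on the
pooled per-target selections.  Targets a method did not predict are excluded
from that method's averages (not scored as zero) and logged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from .contact_map import ContactMap, DEFAULT_CONTACT_THRESHOLD, SEP_LONG
from .metrics import (
    ClusterSet,
    DatasetSummary,
    MetricRecord,
    RocCurve,
    SelectionSpec,
    cluster_accuracy,
    exact_accuracy,
    greedy_cluster,
    make_params,
    neighbourhood_accuracy,
    pooled_roc,
    select_top,
    summarize,
)
from .rr_io import PredictionSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvaluationConfig:
    """The full parameter grid of one benchmark run."""

    divisors: tuple[int, ...] = (10, 5, 1)
    sep_classes: tuple[str, ...] = ("medium", "long")
    deltas: tuple[int, ...] = (0, 1, 2)
    cluster_radius: int = 8
    cluster_delta: int = 2
    contact_threshold: float = DEFAULT_CONTACT_THRESHOLD
    roc_divisor: int = 1
    roc_sep_class: str = SEP_LONG
    seed: int = 0

    @classmethod
    def from_file(cls, path: str) -> "EvaluationConfig":
        """Load from a YAML key-value file; unknown keys are an error."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("divisors", "sep_classes", "deltas"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class TargetEvaluation:
    records: list[MetricRecord]
    clusters: dict[tuple[str, int], ClusterSet]  # keyed by (sep_class, divisor)


@dataclass
class BenchmarkReport:
    """Per-method dataset summaries, cluster-count sums, AUCs and the
    per-target detail every summary row is derived from."""

    summaries: dict[str, list[DatasetSummary]]
    cluster_counts: dict[str, dict[tuple[str, int], int]]
    roc: dict[str, Optional[RocCurve]]
    detail: dict[str, list[MetricRecord]]
    coverage: dict[str, int]
    n_targets: int
    config: EvaluationConfig


def evaluate_target(
    predictions: PredictionSet,
    truth: ContactMap,
    config: EvaluationConfig,
) -> TargetEvaluation:
    """All configured metrics for one predictor on one target.

    A (class, divisor) cell with no evaluable predictions yields no records
    (absence, not zero).  Deterministic given the config.
    """
    if predictions.target_id and truth.target_id and predictions.target_id != truth.target_id:
        raise ValueError(
            f"target mismatch: predictions {predictions.target_id!r} "
            f"vs truth {truth.target_id!r}"
        )
    if predictions.length is not None and predictions.length != truth.length:
        raise ValueError("prediction and truth lengths disagree")

    records: list[MetricRecord] = []
    clusters: dict[tuple[str, int], ClusterSet] = {}
    for sep_class in config.sep_classes:
        for divisor in config.divisors:
            spec = SelectionSpec(divisor=divisor, sep_class=sep_class)
            selected = select_top(predictions, truth, spec)
            if not selected:
                logger.info(
                    "%s: no evaluable %s-range predictions for top-L/%d",
                    truth.target_id, sep_class, divisor,
                )
                continue
            for delta in config.deltas:
                params = make_params(
                    sep_class=sep_class, divisor=divisor, delta=delta
                )
                if delta == 0:
                    records.append(exact_accuracy(selected, truth, params=params))
                else:
                    records.append(
                        neighbourhood_accuracy(selected, truth, delta, params=params)
                    )
            cset = greedy_cluster(selected, radius=config.cluster_radius)
            clusters[(sep_class, divisor)] = cset
            records.append(
                cluster_accuracy(
                    cset,
                    truth,
                    delta=config.cluster_delta,
                    params=make_params(
                        sep_class=sep_class,
                        divisor=divisor,
                        delta=config.cluster_delta,
                        radius=config.cluster_radius,
                    ),
                )
            )
    return TargetEvaluation(records=records, clusters=clusters)


def evaluate_dataset(
    method_submissions: Mapping[str, Mapping[str, PredictionSet]],
    truths: Mapping[str, ContactMap],
    config: EvaluationConfig,
) -> BenchmarkReport:
    """Evaluate every method over every target it predicted."""
    if not method_submissions:
        raise ValueError("no methods to evaluate")
    summaries: dict[str, list[DatasetSummary]] = {}
    cluster_counts: dict[str, dict[tuple[str, int], int]] = {}
    rocs: dict[str, Optional[RocCurve]] = {}
    detail: dict[str, list[MetricRecord]] = {}
    coverage: dict[str, int] = {}
    any_overlap = False

    for method in sorted(method_submissions):
        submissions = method_submissions[method]
        target_ids = sorted(set(submissions) & set(truths))
        missing = sorted(set(truths) - set(submissions))
        if missing:
            logger.info(
                "method %s: no submission for %d/%d targets (%s...)",
                method, len(missing), len(truths), ", ".join(missing[:3]),
            )
        if not target_ids:
            continue
        any_overlap = True
        coverage[method] = len(target_ids)

        records: list[MetricRecord] = []
        counts: dict[tuple[str, int], int] = {}
        pooled: list[tuple[float, bool]] = []
        roc_spec = SelectionSpec(divisor=config.roc_divisor, sep_class=config.roc_sep_class)
        for tid in target_ids:
            truth = truths[tid]
            ev = evaluate_target(submissions[tid], truth, config)
            records.extend(ev.records)
            for key, cset in ev.clusters.items():
                counts[key] = counts.get(key, 0) + cset.count
            true_pairs = truth.pairs
            for p in select_top(submissions[tid], truth, roc_spec):
                pooled.append((p.score, p.pair in true_pairs))

        by_key: dict[tuple, list[MetricRecord]] = {}
        for rec in records:
            by_key.setdefault(rec.key, []).append(rec)
        summaries[method] = [summarize(group) for group in by_key.values()]
        cluster_counts[method] = counts
        detail[method] = records
        labels = {lab for _, lab in pooled}
        rocs[method] = pooled_roc(pooled) if labels == {True, False} else None

    if not any_overlap:
        raise ValueError("no target overlaps between submissions and truth maps")
    return BenchmarkReport(
        summaries=summaries,
        cluster_counts=cluster_counts,
        roc=rocs,
        detail=detail,
        coverage=coverage,
        n_targets=len(truths),
        config=config,
    )


def _params_dict(params: tuple[tuple[str, object], ...]) -> dict:
    return dict(params)


def _method_sort_key(report: BenchmarkReport):
    """Methods ordered by top-L/10 long-range exact accuracy, descending."""
    def key(method: str) -> tuple:
        best = 0.0
        for s in report.summaries.get(method, []):
            p = _params_dict(s.params)
            if (
                s.metric == "accuracy"
                and p.get("sep_class") == "long"
                and p.get("divisor") == 10
                and p.get("delta") == 0
            ):
                best = s.mean
        return (-best, method)
    return key


def _summary_rows(report: BenchmarkReport) -> pd.DataFrame:
    rows = []
    for method in sorted(report.summaries, key=_method_sort_key(report)):
        for s in report.summaries[method]:
            p = _params_dict(s.params)
            rows.append(
                {
                    "method": method,
                    "metric": s.metric,
                    "sep_class": p.get("sep_class"),
                    "divisor": p.get("divisor"),
                    "delta": p.get("delta"),
                    "n_targets": s.n_targets,
                    "mean": s.mean,
                    "se": s.se,
                }
            )
        for (sep_class, divisor), count in sorted(report.cluster_counts.get(method, {}).items()):
            rows.append(
                {
                    "method": method,
                    "metric": "cluster_count",
                    "sep_class": sep_class,
                    "divisor": divisor,
                    "delta": None,
                    "n_targets": report.coverage.get(method),
                    "mean": count,
                    "se": None,
                }
            )
        curve = report.roc.get(method)
        if curve is not None:
            rows.append(
                {
                    "method": method,
                    "metric": "auc",
                    "sep_class": report.config.roc_sep_class,
                    "divisor": report.config.roc_divisor,
                    "delta": None,
                    "n_targets": report.coverage.get(method),
                    "mean": curve.auc,
                    "se": None,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["method", "metric", "sep_class", "divisor", "delta", "n_targets", "mean", "se"],
    )


def render_report(report: BenchmarkReport, format: str = "tsv") -> str:
    """Serialize a benchmark report as tsv, markdown or json.

    The markdown layout mirrors benchmark summary tables: one row per method
    (sorted by top-L/10 long-range accuracy descending), one "mean (SE)"
    cell per class x divisor; floats rounded to 3 decimals.  JSON keeps full
    precision.
    """
    df = _summary_rows(report)
    if format == "tsv":
        return df.to_csv(sep="\t", index=False, float_format="%.17g")
    if format == "json":
        payload = {
            "n_targets": report.n_targets,
            "coverage": report.coverage,
            "rows": df.to_dict(orient="records"),
        }
        return json.dumps(payload, indent=2, default=float)
    if format == "markdown":
        return _render_markdown(report, df)
    raise ValueError(f"unknown format {format!r}")


def _render_markdown(report: BenchmarkReport, df: pd.DataFrame) -> str:
    methods = sorted(report.summaries, key=_method_sort_key(report))
    cols = [
        (sep_class, divisor)
        for sep_class in report.config.sep_classes
        for divisor in report.config.divisors
    ]
    header = "| Method | " + " | ".join(
        f"Acc. top L/{d} {c} (SE)" if d != 1 else f"Acc. top L {c} (SE)"
        for c, d in cols
    ) + " |"
    rule = "|" + "---|" * (len(cols) + 1)
    lines = [header, rule]
    acc = df[(df["metric"] == "accuracy") & (df["delta"] == 0)]
    for method in methods:
        cells = []
        for sep_class, divisor in cols:
            row = acc[
                (acc["method"] == method)
                & (acc["sep_class"] == sep_class)
                & (acc["divisor"] == divisor)
            ]
            if row.empty:
                cells.append("-")
            else:
                mean = row["mean"].iloc[0]
                se = row["se"].iloc[0]
                cells.append(
                    f"{mean:.3f} ({se:.3f})" if pd.notna(se) else f"{mean:.3f}"
                )
        lines.append(f"| {method} | " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"
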