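"""Confusion-matrix metrics at every scope, oMCC aggregation, and effect sizes.

Per cross-validation iteration the pipeline records TP/TN/FP/FN overall and
per compound / pathway.  Iteration-level MCC summarizes each test set;
"overall MCC" (oMCC) for an individual compound, pathway, or hierarchy level
is computed from a *single* confusion matrix obtained by summing counts
across all iterations (and, for a level, across its pathways) — per-entity
test slices are usually too small for a valid per-iteration MCC.

Metrics whose denominator vanishes are ``None`` ("undefined"), never 0: an
entity with no positive test entries carries no evidence either way.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class ConfusionCounts(NamedTuple):
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other):  # type: ignore[override]
        return ConfusionCounts(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )


@dataclass(frozen=True)
class MetricSet:
    mcc: float | None
    accuracy: float | None
    f1: float | None
    precision: float | None
    recall: float | None
    specificity: float | None


@dataclass
class CVResult:
    """Raw confusion tallies from a repeated-CV run.

    ``overall_counts`` has shape (n_iterations, 4); ``compound_counts`` and
    ``pathway_counts`` have shape (n_iterations, n_entities, 4).  Count
    columns are ordered (tp, tn, fp, fn).
    """

    compound_ids: list[str]
    pathway_ids: list[str]
    overall_counts: np.ndarray
    compound_counts: np.ndarray
    pathway_counts: np.ndarray
    levels: "LevelMapLike | None" = None
    seeds: list[int] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    @property
    def n_iterations(self) -> int:
        return self.overall_counts.shape[0]

    def iteration_counts(self, i: int) -> ConfusionCounts:
        return ConfusionCounts(*(int(v) for v in self.overall_counts[i]))


class LevelMapLike:
    """Protocol-ish alias: anything with .level dict and .display_level()."""


@dataclass(frozen=True)
class IterationSummary:
    mean_mcc: float
    median_mcc: float
    sd_mcc: float
    n_iterations: int


def confusion(labels, predictions) -> ConfusionCounts:
    """Count TP/TN/FP/FN for boolean label/prediction vectors."""
    y = np.asarray(labels, dtype=bool)
    p = np.asarray(predictions, dtype=bool)
    if y.shape != p.shape:
        raise ValueError(f"shape mismatch {y.shape} vs {p.shape}")
    return ConfusionCounts(
        tp=int(np.sum(y & p)),
        tn=int(np.sum(~y & ~p)),
        fp=int(np.sum(~y & p)),
        fn=int(np.sum(y & ~p)),
    )


def mcc(c: ConfusionCounts) -> float | None:
    """Matthews correlation coefficient; None when any marginal is zero."""
    tp, tn, fp, fn = int(c.tp), int(c.tn), int(c.fp), int(c.fn)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return None
    return (tp * tn - fp * fn) / math.sqrt(denom)


def _ratio(num: int, den: int) -> float | None:
    return num / den if den else None


def metric_set(c: ConfusionCounts) -> MetricSet:
    """Standard binary-classification metrics; zero denominators give None."""
    tp, tn, fp, fn = int(c.tp), int(c.tn), int(c.fp), int(c.fn)
    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricSet(
        mcc=mcc(c),
        accuracy=_ratio(tp + tn, tp + tn + fp + fn),
        f1=f1,
        precision=precision,
        recall=recall,
        specificity=_ratio(tn, tn + fp),
    )


def _sum_counts(block: np.ndarray) -> ConfusionCounts:
    total = np.asarray(block, dtype=np.int64).reshape(-1, 4).sum(axis=0)
    return ConfusionCounts(*(int(v) for v in total))


def overall_counts(cv: CVResult, scope: str, entity=None) -> ConfusionCounts:
    """Single summed confusion matrix for a dataset/compound/pathway/level scope."""
    if scope == "dataset":
        return _sum_counts(cv.overall_counts)
    if scope == "compound":
        i = cv.compound_ids.index(entity)
        return _sum_counts(cv.compound_counts[:, i, :])
    if scope == "pathway":
        i = cv.pathway_ids.index(entity)
        return _sum_counts(cv.pathway_counts[:, i, :])
    if scope == "level":
        if cv.levels is None:
            raise ValueError("CVResult carries no level map")
        if isinstance(entity, str):
            label = entity
        else:
            label = "L6+" if int(entity) >= 6 else f"L{entity}"
        idx = [
            i
            for i, p in enumerate(cv.pathway_ids)
            if cv.levels.display_level(p) == label
        ]
        if not idx:
            raise KeyError(f"no pathway with display level {label!r}")
        return _sum_counts(cv.pathway_counts[:, idx, :])
    raise ValueError(f"unknown scope {scope!r}")


def overall_metric(cv: CVResult, scope: str, entity=None) -> MetricSet:
    """Metric set on counts summed across iterations (the oMCC convention)."""
    return metric_set(overall_counts(cv, scope, entity))


def summarize_iterations(cv: CVResult) -> IterationSummary:
    """Mean / median / sample-SD of per-iteration overall MCC.

    Iterations with undefined MCC are excluded (logged).  SD uses ddof=1 and
    is reported as 0.0 when only one defined iteration remains.
    """
    values = [mcc(cv.iteration_counts(i)) for i in range(cv.n_iterations)]
    defined = [v for v in values if v is not None]
    if len(defined) < len(values):
        logger.info(
            "summarize_iterations: %d of %d iterations had undefined MCC",
            len(values) - len(defined),
            len(values),
        )
    if not defined:
        raise ValueError("no iteration produced a defined MCC")
    arr = np.asarray(defined, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return IterationSummary(
        mean_mcc=float(arr.mean()),
        median_mcc=float(np.median(arr)),
        sd_mcc=sd,
        n_iterations=len(defined),
    )


def cohens_d(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> float:
    """Cohen's d with pooled standard deviation."""
    pooled = math.sqrt(
        ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2)
    )
    return (mean_a - mean_b) / pooled


def relative_improvement(mean_new: float, mean_ref: float) -> float:
    """Percent improvement of ``mean_new`` over the reference mean."""
    return 100.0 * (mean_new - mean_ref) / mean_ref


def size_report(
    cv: CVResult,
    levels,
    compound_sizes: dict[str, int],
    pathway_sizes: dict[str, int],
) -> pd.DataFrame:
    """Join entity sizes with per-entity oMCC and hierarchy level labels.

    One row per compound and per pathway: (entity_id, kind, size, omcc,
    level).  Compounds have no hierarchy level (empty string); undefined
    oMCC is left as NaN.
    """
    rows = []
    for kind, ids in (("compound", cv.compound_ids), ("pathway", cv.pathway_ids)):
        sizes = compound_sizes if kind == "compound" else pathway_sizes
        for eid in ids:
            value = mcc(overall_counts(cv, kind, eid))
            rows.append(
                {
                    "entity_id": eid,
                    "kind": kind,
                    "size": sizes.get(eid),
                    "omcc": np.nan if value is None else value,
                    "level": levels.display_level(eid) if kind == "pathway" else "",
                }
            )
    return pd.DataFrame(rows, columns=["entity_id", "kind", "size", "omcc", "level"])


def metrics_to_row(ms: MetricSet) -> dict[str, object]:
    """Serialize a MetricSet for a report table; undefined values become 'undefined'."""
    return {
        name: ("undefined" if value is None else value)
        for name, value in vars(ms).items()
    }
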