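"""Scoring predictions against truth and dataset-level statistics.

Precision is the proportion of predicted ortholog pairs that are true,
recall the proportion of true pairs that are predicted.  Replicate runs are
aggregated by computing the metrics per replicate first and reporting the
mean with a Student-t 95% confidence interval of the mean (df = n - 1); a
pooled-counts mode is also available.

An empty prediction set has no defined precision; it is reported as a
flagged NA rather than silently coerced to 0 or 1, so degenerate methods do
not look artificially good or bad.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats as _st

from .evolver import SimulatedDataset
from .inference import AlignmentResult
from .truth import OrthologPairSet

__all__ = [
    "PRResult",
    "EvalSummary",
    "DatasetStats",
    "precision_recall",
    "pooled_precision_recall",
    "aggregate_replicates",
    "score_distance_correlation",
    "dataset_statistics",
]


@dataclass(frozen=True)
class PRResult:
    """Precision/recall of one prediction set against one truth set."""

    tp: int
    fp: int
    fn: int
    precision: Optional[float]  # None (flagged) when no pairs were predicted
    recall: float

    @property
    def undefined_precision(self) -> bool:
        return self.precision is None


def precision_recall(pred: OrthologPairSet, truth: OrthologPairSet) -> PRResult:
    """TP/FP/FN counting over unordered pair sets sharing one id namespace."""
    if len(truth) == 0:
        raise ValueError("truth set is empty; precision/recall are undefined")
    tp = len(pred.intersection(truth))
    fp = len(pred) - tp
    fn = len(truth) - tp
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    recall = tp / (tp + fn)
    return PRResult(tp=tp, fp=fp, fn=fn, precision=precision, recall=recall)


def pooled_precision_recall(results: Sequence[PRResult]) -> tuple[float, float]:
    """Micro-average: pool TP/FP/FN counts over replicates."""
    tp = sum(r.tp for r in results)
    fp = sum(r.fp for r in results)
    fn = sum(r.fn for r in results)
    if tp + fp == 0:
        raise ValueError("no predictions in any replicate")
    return tp / (tp + fp), tp / (tp + fn)


@dataclass(frozen=True)
class EvalSummary:
    """Mean precision/recall over replicates with 95% CI half-widths."""

    n_replicates: int
    precisions: tuple[float, ...]
    recalls: tuple[float, ...]
    mean_precision: float
    mean_recall: float
    ci_precision: float
    ci_recall: float


def _t_ci_halfwidth(values: np.ndarray) -> float:
    n = len(values)
    sd = values.std(ddof=1)
    if sd == 0:
        return 0.0
    t = _st.t.ppf(0.975, df=n - 1)
    return float(t * sd / math.sqrt(n))


def aggregate_replicates(
    per_replicate: Sequence[tuple[float, float]]
) -> EvalSummary:
    """Mean and t-based 95% CI of the mean in each dimension; needs n >= 2."""
    if len(per_replicate) < 2:
        raise ValueError("replicate aggregation needs at least 2 replicates")
    p = np.array([pr[0] for pr in per_replicate], dtype=float)
    r = np.array([pr[1] for pr in per_replicate], dtype=float)
    if np.isnan(p).any() or np.isnan(r).any():
        raise ValueError("replicate metrics contain NA values")
    return EvalSummary(
        n_replicates=len(per_replicate),
        precisions=tuple(p),
        recalls=tuple(r),
        mean_precision=float(p.mean()),
        mean_recall=float(r.mean()),
        ci_precision=_t_ci_halfwidth(p),
        ci_recall=_t_ci_halfwidth(r),
    )


def score_distance_correlation(results: Iterable[AlignmentResult]) -> float:
    """Pearson correlation of (normalised score, ML distance) over hits."""
    xs, ys = [], []
    for res in results:
        if res.distance is None:
            raise ValueError("distance missing; call estimate_distance first")
        x, y = res.normalized_score, res.distance.d_hat
        if math.isfinite(x) and math.isfinite(y):
            xs.append(x)
            ys.append(y)
    if len(xs) < 3:
        raise ValueError("need at least 3 finite (score, distance) pairs")
    x = np.asarray(xs)
    y = np.asarray(ys)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in score or distance")
    return float(_st.pearsonr(x, y).statistic)


@dataclass(frozen=True)
class DatasetStats:
    """Dataset-level descriptive statistics, percentages in [0, 100].

    ``gap_fraction`` is the mean over families of the per-family percentage
    of gap characters in the true alignment; ``gap_variance`` is the
    between-family variance of that percentage.  The duplication/LGT
    background is the percentage of extant genes with at least one such
    event on their root-to-leaf lineage.
    """

    gap_fraction: float
    gap_variance: float
    dup_background: float
    lgt_background: float
    x_fraction: float


def dataset_statistics(ds: SimulatedDataset) -> DatasetStats:
    gap_pcts = []
    for _, rows in ds.true_msas.values():
        cells = sum(len(r) for r in rows)
        if cells == 0:
            continue
        gaps = sum(r.count("-") for r in rows)
        gap_pcts.append(100.0 * gaps / cells)
    gap_arr = np.asarray(gap_pcts) if gap_pcts else np.zeros(0)
    genes = list(ds.all_genes())
    n = len(genes)
    dup_bg = 100.0 * sum(g.n_dup >= 1 for g in genes) / n if n else 0.0
    lgt_bg = 100.0 * sum(g.n_transfer >= 1 for g in genes) / n if n else 0.0
    total_chars = sum(len(g.sequence) for g in genes)
    n_x = sum(g.sequence.count("X") for g in genes)
    return DatasetStats(
        gap_fraction=float(gap_arr.mean()) if gap_arr.size else 0.0,
        gap_variance=float(gap_arr.var(ddof=1)) if gap_arr.size > 1 else 0.0,
        dup_background=dup_bg,
        lgt_background=lgt_bg,
        x_fraction=100.0 * n_x / total_chars if total_chars else 0.0,
    )
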