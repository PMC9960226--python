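"""Gene-level scoring and essential-gene benchmarking.

A dropout screen's quality is judged by how well it separates known
essential from known non-essential genes when entities are ranked by a
depletion score (lower = more depleted).  Implemented here:

* ROC-AUC with essential genes as positives (tie-corrected Mann-Whitney);
* dAUC — the difference between rank-prefix recovery AUCs of the
  essential and non-essential sets, which rewards rankings that pull
  essentials to the top *and* push non-essentials to the bottom;
* recall at a fixed false-discovery rate and FDR at fixed recall, from an
  exhaustive sweep of the rank threshold;
* export of activity-corrected pseudo-counts (initial count times FC or
  v) in the count-table layout consumed by MAGeCK and DrugZ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .activity_correct import GuideMetrics
from .library_io import GeneReference
from .read_classify import SampleCounts

ScoreMetric = Literal["fc", "v"]
Aggregation = Literal["median", "mean", "second_best"]


@dataclass(frozen=True)
class EntityScore:
    """A scored, labelled entity (guide or gene); lower = more depleted."""

    entity_id: str
    score: float
    level: str = "gene"  # "guide" | "gene"
    label: str = "other"  # "essential" | "nonessential" | "other"


@dataclass
class BenchResult:
    roc_auc: float
    auc_essential: float
    auc_nonessential: float
    dauc: float
    recall_at_fdr: dict[float, float] = field(default_factory=dict)
    fdr_at_recall: dict[float, float] = field(default_factory=dict)
    fpr: Optional[np.ndarray] = None
    tpr: Optional[np.ndarray] = None


def gene_scores(
    metrics: Sequence[GuideMetrics],
    reference: GeneReference,
    metric: ScoreMetric = "v",
    agg: Aggregation = "median",
    include_unreliable: bool = True,
) -> list[EntityScore]:
    """Aggregate guide metrics into one depletion score per gene.

    ``metric`` selects normalised fold change ("fc") or corrected
    viability ("v").  Aggregation over a gene's guides is the median by
    default; "second_best" takes the second-lowest value (robust to a
    single outlier guide), falling back to the minimum for single-guide
    genes.  Guides with undefined values are skipped; when
    ``include_unreliable`` is False, low-activity guides are also skipped
    unless a gene has no reliable guide at all (then all its defined
    guides are used).
    """
    if not metrics:
        raise ValueError("no guide metrics given")
    by_gene: dict[str, list[GuideMetrics]] = {}
    for m in metrics:
        if m.role != "targeting":
            continue
        by_gene.setdefault(m.gene, []).append(m)

    def value(m: GuideMetrics) -> float:
        return m.fc_norm if metric == "fc" else m.v

    out = []
    for gene, ms in sorted(by_gene.items()):
        defined = [m for m in ms if not math.isnan(value(m))]
        if metric == "v":
            defined = [m for m in defined if m.v_defined]
        if not defined:
            continue
        pool = defined
        if not include_unreliable:
            reliable = [m for m in defined if m.reliable]
            pool = reliable if reliable else defined
        vals = np.array(sorted(value(m) for m in pool))
        if agg == "median":
            score = float(np.median(vals))
        elif agg == "mean":
            score = float(vals.mean())
        elif agg == "second_best":
            score = float(vals[1] if len(vals) > 1 else vals[0])
        else:
            raise ValueError(f"unknown aggregation {agg!r}")
        out.append(EntityScore(gene, score, level="gene", label=reference.label(gene)))
    if not out:
        raise ValueError("no gene received a defined score")
    return out


def guide_scores(
    metrics: Sequence[GuideMetrics],
    reference: GeneReference,
    metric: ScoreMetric = "v",
) -> list[EntityScore]:
    """Guide-level scores carrying their gene's essentiality label."""
    def value(m: GuideMetrics) -> float:
        return m.fc_norm if metric == "fc" else m.v
    out = [
        EntityScore(m.guide_id, value(m), level="guide", label=reference.label(m.gene))
        for m in metrics
        if m.role == "targeting" and not math.isnan(value(m))
    ]
    if not out:
        raise ValueError("no guide received a defined score")
    return out


def _labeled_arrays(scores: Sequence[EntityScore]) -> tuple[np.ndarray, np.ndarray]:
    lab = [(s.score, s.label == "essential") for s in scores if s.label != "other"]
    if not lab:
        raise ValueError("no labeled entities")
    vals = np.array([v for v, _ in lab])
    is_ess = np.array([e for _, e in lab], dtype=bool)
    if is_ess.all() or not is_ess.any():
        raise ValueError("need both essential and nonessential labeled entities")
    return vals, is_ess


def compute_roc(scores: Sequence[EntityScore]) -> tuple[float, np.ndarray, np.ndarray]:
    """ROC-AUC for depleted-essential detection, with the full curve.

    Essential entities are the positives and a *lower* score ranks first,
    so scores are negated before the standard ROC computation.  The AUC
    equals the tie-corrected Mann-Whitney pair probability.
    """
    vals, is_ess = _labeled_arrays(scores)
    auc = float(roc_auc_score(is_ess, -vals))
    fpr, tpr, _ = roc_curve(is_ess, -vals)
    return auc, fpr, tpr


def roc_auc(scores: Sequence[EntityScore]) -> float:
    return compute_roc(scores)[0]


def dauc(scores: Sequence[EntityScore]) -> tuple[float, float, float]:
    """Rank-prefix recovery dAUC.

    All entities (labelled or not) are ranked ascending by score, ties
    broken by entity id for determinism.  For each prefix fraction
    t = k/N the recovery curve of a label set is the fraction of that set
    already seen in the top k; its AUC is the trapezoid area over
    t in [0, 1].  Returns ``(auc_essential, auc_nonessential, dauc)``
    with ``dauc = auc_essential - auc_nonessential``.
    """
    if not scores:
        raise ValueError("no scores given")
    order = sorted(scores, key=lambda s: (s.score, s.entity_id))
    n = len(order)
    n_ess = sum(1 for s in order if s.label == "essential")
    n_non = sum(1 for s in order if s.label == "nonessential")
    if n_ess == 0 or n_non == 0:
        raise ValueError("need both essential and nonessential labeled entities")
    cum_e = np.cumsum([s.label == "essential" for s in order]) / n_ess
    cum_n = np.cumsum([s.label == "nonessential" for s in order]) / n_non
    t = np.arange(n + 1) / n
    curve_e = np.concatenate([[0.0], cum_e])
    curve_n = np.concatenate([[0.0], cum_n])
    auc_e = float(np.trapezoid(curve_e, t))
    auc_n = float(np.trapezoid(curve_n, t))
    return auc_e, auc_n, auc_e - auc_n


def recall_fdr(
    scores: Sequence[EntityScore],
    fdr_levels: Sequence[float] = (0.2,),
    recall_levels: Sequence[float] = (0.95, 0.975, 0.98),
) -> tuple[dict[float, float], dict[float, float]]:
    """Recall at FDR caps and FDR at recall floors, by threshold sweep.

    Labeled entities are ranked ascending by score (ties by id); for each
    prefix k, TP and FP are the essential and non-essential counts within
    the top k, FDR(k) = FP/(TP+FP) and recall(k) = TP/n_essential.
    ``recall_at_fdr[q]`` is the best recall over thresholds with
    FDR <= q (0 if none); ``fdr_at_recall[r]`` the smallest FDR over
    thresholds with recall >= r (NaN if unreachable).
    """
    labeled = sorted(
        (s for s in scores if s.label != "other"),
        key=lambda s: (s.score, s.entity_id),
    )
    if not labeled:
        raise ValueError("no labeled entities")
    is_ess = np.array([s.label == "essential" for s in labeled], dtype=bool)
    if is_ess.all() or not is_ess.any():
        raise ValueError("need both essential and nonessential labeled entities")
    tp = np.cumsum(is_ess)
    fp = np.cumsum(~is_ess)
    fdr = fp / (tp + fp)
    recall = tp / is_ess.sum()
    recall_at = {
        float(q): float(recall[fdr <= q].max()) if (fdr <= q).any() else 0.0
        for q in fdr_levels
    }
    fdr_at = {
        float(r): float(fdr[recall >= r].min()) if (recall >= r).any() else math.nan
        for r in recall_levels
    }
    return recall_at, fdr_at


def benchmark(
    scores: Sequence[EntityScore],
    fdr_levels: Sequence[float] = (0.2,),
    recall_levels: Sequence[float] = (0.95, 0.975, 0.98),
) -> BenchResult:
    """All benchmark metrics for one ranking."""
    auc, fpr, tpr = compute_roc(scores)
    auc_e, auc_n, d = dauc(scores)
    recall_at, fdr_at = recall_fdr(scores, fdr_levels, recall_levels)
    return BenchResult(
        roc_auc=auc,
        auc_essential=auc_e,
        auc_nonessential=auc_n,
        dauc=d,
        recall_at_fdr=recall_at,
        fdr_at_recall=fdr_at,
        fpr=fpr,
        tpr=tpr,
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def export_pseudocounts(
    initial_counts: SampleCounts,
    metrics: Sequence[GuideMetrics],
    metric: ScoreMetric = "v",
    sample_name: Optional[str] = None,
    drop_missing: bool = True,
) -> pd.DataFrame:
    """Corrected count table for MAGeCK / DrugZ.

    Each guide's exported count is ``round(max(0, initial * metric))``
    with half-up rounding, in the MAGeCK layout (sgRNA, gene, one sample
    column).  Guides lacking a defined metric are dropped by default, or
    carried with their initial count when ``drop_missing=False``.
    """
    col = sample_name or f"{initial_counts.sample_id}_{metric}"
    rows = []
    for m in metrics:
        init = initial_counts.counts.get(m.guide_id)
        if init is None:
            continue
        val = m.fc_norm if metric == "fc" else m.v
        if math.isnan(val) or (metric == "v" and not m.v_defined):
            if drop_missing:
                continue
            count = init.n_total
        else:
            count = _round_half_up(max(0.0, init.n_total * val))
        rows.append((m.guide_id, m.gene, count))
    return pd.DataFrame(rows, columns=["sgRNA", "gene", col])


def write_count_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
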