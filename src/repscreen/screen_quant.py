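"""Per-guide frequencies, fold changes, observed indel rates and QC.

The raw dropout signal of a pooled viability screen is the fold change
(FC) of each guide's frequency between a reference sample (plasmid pool
or day 0) and the final timepoint.  In a self-reporting library the final
sample additionally yields an *observed* indel frequency — the edited
fraction of coupled reporter reads — which is the raw measure of each
guide's cutting activity.

QC follows screen practice for coupled libraries: guides that are nearly
absent from the reference sample (reads per thousand below a threshold,
default 0.1) behave erratically between replicates (genetic drift) and
are flagged out of all downstream fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .read_classify import SampleCounts

DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_MIN_RPT = 0.1


@dataclass(frozen=True)
class GuideQuant:
    """Per-guide quantification for one replicate.

    ``fc_raw = freq_final / freq_ref`` with a pseudocount applied to both
    counts; ``indel_obs = n_edited / n_coupled`` in the final sample (NaN
    when no coupled reads); ``rpt_ref`` is raw reads-per-thousand in the
    reference sample, the QC statistic.
    """

    guide_id: str
    freq_ref: float
    freq_final: float
    rpt_ref: float
    fc_raw: float
    indel_obs: float  # NaN when undefined (no coupled reads)
    qc_pass: bool = True


def compute_quant(
    ref: SampleCounts,
    final: SampleCounts,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[GuideQuant]:
    """Quantify every guide appearing in either sample.

    Frequencies are computed over library-assigned reads with
    ``pseudocount`` added to each guide's count in both samples, so
    dropouts of essential genes keep a finite positive fold change.
    Raises ``ValueError`` if either sample has zero total reads.
    """
    guides = sorted(set(ref.counts) | set(final.counts))
    n_ref = np.array([ref.counts[g].n_total if g in ref.counts else 0 for g in guides], dtype=float)
    n_fin = np.array([final.counts[g].n_total if g in final.counts else 0 for g in guides], dtype=float)
    tot_ref, tot_fin = n_ref.sum(), n_fin.sum()
    if tot_ref == 0:
        raise ValueError(f"sample {ref.sample_id!r} has zero total reads")
    if tot_fin == 0:
        raise ValueError(f"sample {final.sample_id!r} has zero total reads")

    freq_ref = (n_ref + pseudocount) / (n_ref + pseudocount).sum()
    freq_fin = (n_fin + pseudocount) / (n_fin + pseudocount).sum()
    rpt_ref = 1000.0 * n_ref / tot_ref

    out = []
    for i, g in enumerate(guides):
        gc = final.counts.get(g)
        if gc is not None and gc.n_coupled > 0:
            indel_obs = gc.n_edited / gc.n_coupled
        else:
            indel_obs = math.nan
        out.append(
            GuideQuant(
                guide_id=g,
                freq_ref=float(freq_ref[i]),
                freq_final=float(freq_fin[i]),
                rpt_ref=float(rpt_ref[i]),
                fc_raw=float(freq_fin[i] / freq_ref[i]),
                indel_obs=indel_obs,
            )
        )
    return out


def apply_qc(quants: Sequence[GuideQuant], min_rpt: float = DEFAULT_MIN_RPT) -> list[GuideQuant]:
    """Flag guides underrepresented in the reference sample.

    ``qc_pass = rpt_ref >= min_rpt``.  Flagged guides are carried through
    (so tables stay complete) but excluded from all downstream fits and
    scores.  Idempotent.
    """
    return [replace(q, qc_pass=q.rpt_ref >= min_rpt) for q in quants]


def average_replicates(replicates: Sequence[Sequence[GuideQuant]]) -> list[GuideQuant]:
    """Average fc_raw and indel_obs over replicates, guide by guide.

    NaN indel values are ignored in the mean; a guide passes QC only if it
    passes in every replicate.  Frequencies and rpt are averaged likewise.
    """
    if not replicates:
        raise ValueError("no replicates given")
    by_guide: dict[str, list[GuideQuant]] = {}
    for rep in replicates:
        for q in rep:
            by_guide.setdefault(q.guide_id, []).append(q)
    out = []
    for gid, qs in sorted(by_guide.items()):
        indels = [q.indel_obs for q in qs if not math.isnan(q.indel_obs)]
        out.append(
            GuideQuant(
                guide_id=gid,
                freq_ref=float(np.mean([q.freq_ref for q in qs])),
                freq_final=float(np.mean([q.freq_final for q in qs])),
                rpt_ref=float(np.mean([q.rpt_ref for q in qs])),
                fc_raw=float(np.mean([q.fc_raw for q in qs])),
                indel_obs=float(np.mean(indels)) if indels else math.nan,
                qc_pass=all(q.qc_pass for q in qs),
            )
        )
    return out


def replicate_concordance(
    a: Sequence[GuideQuant], b: Sequence[GuideQuant]
) -> dict[str, tuple[float, float]]:
    """Pearson r (with two-tailed p) between replicates.

    Computed over shared QC-passing guides, on log2 fold changes and on
    observed indel frequencies (guides with undefined indel are dropped
    from that comparison only).  Requires >= 3 shared guides.
    """
    a_by = {q.guide_id: q for q in a if q.qc_pass}
    b_by = {q.guide_id: q for q in b if q.qc_pass}
    shared = sorted(set(a_by) & set(b_by))
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared qc-passing guides (need >= 3)")
    lfc_a = np.log2([a_by[g].fc_raw for g in shared])
    lfc_b = np.log2([b_by[g].fc_raw for g in shared])
    r_fc, p_fc = stats.pearsonr(lfc_a, lfc_b)
    ind = [
        (a_by[g].indel_obs, b_by[g].indel_obs)
        for g in shared
        if not (math.isnan(a_by[g].indel_obs) or math.isnan(b_by[g].indel_obs))
    ]
    if len(ind) >= 3:
        ia, ib = np.array(ind).T
        if np.ptp(ia) == 0 or np.ptp(ib) == 0:
            r_in, p_in = math.nan, math.nan  # correlation undefined
        else:
            r_in, p_in = stats.pearsonr(ia, ib)
    else:
        r_in, p_in = math.nan, math.nan
    return {"log_fc": (float(r_fc), float(p_fc)), "indel_obs": (float(r_in), float(p_in))}


def moving_median(x: Sequence[float], y: Sequence[float], k: int = 20) -> np.ndarray:
    """Median of ``y`` over each point's ``k`` nearest neighbours in ``x``.

    Neighbourhoods are by absolute distance in ``x`` (self included), the
    smoother used for activity-vs-score diagnostic plots.  Returns an
    array aligned with the input.  Requires ``len(x) == len(y) >= k``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    n = len(x)
    if n < k:
        raise ValueError(f"need at least k={k} points, got {n}")
    if k < 1:
        raise ValueError("k must be >= 1")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    out_sorted = np.empty(n)
    # The k nearest x-neighbours of a point are contiguous in sorted order,
    # and the optimal window start is non-decreasing in i: one pass suffices.
    lo = 0
    for i in range(n):
        while lo + k <= i:  # window must contain point i
            lo += 1
        while lo + k < n and (xs[lo + k] - xs[i]) < (xs[i] - xs[lo]):
            lo += 1
        out_sorted[i] = np.median(ys[lo: lo + k])
    out = np.empty(n)
    out[order] = out_sorted
    return out


def quants_to_frame(quants: Sequence[GuideQuant]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (q.guide_id, q.fc_raw, q.indel_obs, q.rpt_ref, q.qc_pass)
            for q in quants
        ],
        columns=["guide_id", "fc_raw", "indel_obs", "rpt_ref", "qc_pass"],
    )


def write_quants(quants: Sequence[GuideQuant], path: str | Path) -> None:
    quants_to_frame(quants).to_csv(path, sep="\t", index=False)
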