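"""Paired-end read classification: guide counting and reporter indel calling.

Read 2 of each pair carries the sgRNA cassette (the spacer follows a fixed
anchor at the end of the U6 scaffold); read 1 carries the reporter amplicon.
Each pair is therefore classified along three axes:

* **guide assignment** — which library spacer the read-2 20-mer matches,
  within a configurable Hamming distance (ties are left unassigned);
* **coupling** — whether the reporter protospacer on read 1 belongs to the
  assigned guide (lentiviral template switching and PCR chimeras can swap
  reporters between cassettes, which would corrupt the indel signal);
* **edit status** — whether a coupled reporter carries an indel whose
  alignment footprint touches the window around the expected Cas9 cut site.

Substitution-only reads count as unedited so that sequencing error does not
inflate indel frequencies; indels far from the cut are likewise ignored.
Uncoupled reads stay in ``n_total`` but are excluded from both the indel
numerator and denominator.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from itertools import zip_longest
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import edlib
import numpy as np
import pandas as pd
from Bio import Align

from .library_io import GuideRecord, locate_protospacer

# End of the U6/scaffold sequence immediately 5' of the spacer on read 2
# (suffix of the hU6 promoter ending in the canonical "CACCG" cloning site).
DEFAULT_ANCHOR = "GGACGAAACACCG"

COUPLED = "coupled"
UNCOUPLED = "uncoupled"
INDETERMINATE = "indeterminate"
EDITED = "edited"
UNEDITED = "unedited"
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class ClassifyParams:
    """Tunable knobs of the read classifier.

    ``anchor`` is the fixed sequence immediately upstream of the spacer on
    read 2.  ``max_mismatch`` bounds the Hamming distance for spacer
    assignment (ties -> unassigned).  ``flank_mm`` bounds per-flank
    mismatches when locating the reporter's variable segment on read 1.
    ``window`` is the half-width, in nt around the cut site, within which
    an indel footprint counts as an edit.  ``min_mean_q`` optionally drops
    pairs whose mean base quality falls below the threshold (off by
    default).  Gap scores make a single indel cheaper than a run of
    substitutions, the standard convention for amplicon indel calling.
    """

    anchor: str = DEFAULT_ANCHOR
    anchor_mm: int = 1
    max_mismatch: int = 1
    flank_mm: int = 2
    window: int = 10
    flank_probe_len: int = 12
    min_mean_q: Optional[float] = None
    match_score: float = 1.0
    mismatch_score: float = -1.0
    gap_open: float = -6.0
    gap_extend: float = -0.25


@dataclass(frozen=True)
class ReadClass:
    """Classification of a single read pair."""

    guide_id: Optional[str]
    coupling: str = INDETERMINATE
    edit: str = UNCLASSIFIED

    def __post_init__(self) -> None:
        if self.guide_id is None and (
            self.coupling != INDETERMINATE or self.edit != UNCLASSIFIED
        ):
            raise ValueError("unassigned read must be indeterminate/unclassified")
        if self.edit in (EDITED, UNEDITED) and self.coupling != COUPLED:
            raise ValueError("edit status requires coupling == coupled")


@dataclass
class GuideCounts:
    n_total: int = 0
    n_coupled: int = 0
    n_edited: int = 0


@dataclass
class SampleCounts:
    """Per-guide read counts for one sample.

    ``n_total`` counts every read pair assigned to the guide, ``n_coupled``
    the subset whose reporter belongs to the same cassette, and ``n_edited``
    the coupled reads with a cut-site indel; ``0 <= n_edited <= n_coupled
    <= n_total`` holds per guide.
    """

    sample_id: str
    timepoint_days: float = 0.0
    counts: dict[str, GuideCounts] = field(default_factory=dict)

    def add(self, guide_id: str, coupling: str, edit: str) -> None:
        gc = self.counts.setdefault(guide_id, GuideCounts())
        gc.n_total += 1
        if coupling == COUPLED:
            gc.n_coupled += 1
            if edit == EDITED:
                gc.n_edited += 1

    def validate(self) -> None:
        for gid, gc in self.counts.items():
            if not (0 <= gc.n_edited <= gc.n_coupled <= gc.n_total):
                raise ValueError(f"count invariant violated for guide {gid!r}: {gc}")

    def total_reads(self) -> int:
        return sum(gc.n_total for gc in self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (gid, gc.n_total, gc.n_coupled, gc.n_edited)
            for gid, gc in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["guide_id", "n_total", "n_coupled", "n_edited"])


def write_counts(counts: SampleCounts, path: str | Path) -> None:
    counts.to_frame().to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path, sample_id: str | None = None, timepoint_days: float = 0.0) -> SampleCounts:
    df = pd.read_csv(path, sep="\t", dtype={"guide_id": str})
    sc = SampleCounts(sample_id=sample_id or Path(path).stem, timepoint_days=timepoint_days)
    for row in df.itertuples(index=False):
        sc.counts[str(row.guide_id)] = GuideCounts(
            n_total=int(row.n_total), n_coupled=int(row.n_coupled), n_edited=int(row.n_edited)
        )
    sc.validate()
    return sc


# ---------------------------------------------------------------------------
# guide assignment (read 2)
# ---------------------------------------------------------------------------

class _SpacerIndex:
    """Hamming lookup over equal-length spacer sets, vectorised with numpy."""

    def __init__(self, library: Sequence[GuideRecord]):
        self.exact: dict[str, str] = {}
        by_len: dict[int, list[tuple[str, str]]] = {}
        for rec in library:
            sp = rec.spacer.upper()
            if sp in self.exact:
                raise ValueError(f"duplicate spacer in library: {sp}")
            self.exact[sp] = rec.guide_id
            by_len.setdefault(len(sp), []).append((sp, rec.guide_id))
        self.by_len: dict[int, tuple[np.ndarray, list[str]]] = {}
        for length, pairs in by_len.items():
            mat = np.frombuffer(
                "".join(sp for sp, _ in pairs).encode(), dtype=np.uint8
            ).reshape(len(pairs), length)
            self.by_len[length] = (mat, [gid for _, gid in pairs])

    def lookup(self, seq_after_anchor: str, max_mismatch: int) -> Optional[str]:
        for length, (mat, gids) in self.by_len.items():
            probe = seq_after_anchor[:length].upper()
            if len(probe) < length:
                continue
            hit = self.exact.get(probe)
            if hit is not None:
                return hit
            if max_mismatch == 0:
                continue
            arr = np.frombuffer(probe.encode(), dtype=np.uint8)
            dists = (mat != arr).sum(axis=1)
            best = int(dists.min())
            if best <= max_mismatch:
                idx = np.flatnonzero(dists == best)
                if len(idx) == 1:
                    return gids[int(idx[0])]
                return None  # ambiguous tie
        return None


_INDEX_CACHE: dict[int, _SpacerIndex] = {}


def _spacer_index(library: Sequence[GuideRecord]) -> _SpacerIndex:
    key = id(library)
    idx = _INDEX_CACHE.get(key)
    if idx is None:
        _INDEX_CACHE.clear()  # keep at most one library resident
        idx = _INDEX_CACHE[key] = _SpacerIndex(library)
    return idx


def assign_guide(
    read2_seq: str,
    library: Sequence[GuideRecord],
    max_mismatch: int = 1,
    anchor: str = DEFAULT_ANCHOR,
    anchor_mm: int = 1,
) -> Optional[str]:
    """Assign a read-2 sequence to a library guide, or ``None``.

    The spacer is extracted immediately after the anchor, located exactly
    or within ``anchor_mm`` substitutions; the 20-mer is matched exactly,
    then within ``max_mismatch`` Hamming distance.  Ambiguous ties and
    anchor-less reads return ``None``.
    """
    read2 = read2_seq.upper()
    pos = read2.find(anchor.upper())
    if pos < 0 and anchor_mm > 0:
        pos = _hamming_search(read2, anchor.upper(), anchor_mm)
        if pos is None:
            pos = -1
    if pos < 0:
        return None
    return _spacer_index(library).lookup(read2[pos + len(anchor):], max_mismatch)


# ---------------------------------------------------------------------------
# reporter classification (read 1)
# ---------------------------------------------------------------------------

def _variable_segment(record: GuideRecord) -> tuple[int, int]:
    """Half-open interval of the reporter's guide-specific segment
    (protospacer plus the 3-nt PAM on the protospacer's strand)."""
    start, end, is_reverse = locate_protospacer(record)
    if is_reverse:
        return max(0, start - 3), end
    return start, min(len(record.reporter_seq), end + 3)


def _hamming_search(read: str, probe: str, max_mm: int, start: int = 0) -> Optional[int]:
    """Leftmost position >= start where probe matches read within max_mm
    substitutions; None if absent."""
    n, m = len(read), len(probe)
    if m == 0 or n - start < m:
        return None
    parr = np.frombuffer(probe.encode(), dtype=np.uint8)
    rarr = np.frombuffer(read.encode(), dtype=np.uint8)
    # windows is (n-m+1, m) strided view; fine for 100-150 nt reads
    windows = np.lib.stride_tricks.sliding_window_view(rarr, m)[start:]
    mm = (windows != parr).sum(axis=1)
    hits = np.flatnonzero(mm <= max_mm)
    return int(hits[0]) + start if len(hits) else None


def _make_aligner(params: ClassifyParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match_score
    aligner.mismatch_score = params.mismatch_score
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def _indel_footprints(alignment) -> list[tuple[int, int]]:
    """Reference-coordinate footprints of every gap in a global alignment.

    Deletions from the reference give ``(ref_start, ref_end)`` of the
    deleted run; insertions give a zero-length ``(pos, pos)`` at the
    insertion point.
    """
    blocks_ref, blocks_query = alignment.aligned
    footprints: list[tuple[int, int]] = []
    prev_r = prev_q = 0
    for (rs, re), (qs, qe) in zip(blocks_ref, blocks_query):
        if rs > prev_r:  # deletion in query relative to reference
            footprints.append((prev_r, rs))
        if qs > prev_q:  # insertion in query
            footprints.append((rs, rs))
        prev_r, prev_q = re, qe
    ref_len = len(alignment.target)
    query_len = len(alignment.query)
    if prev_r < ref_len:
        footprints.append((prev_r, ref_len))
    if prev_q < query_len:
        footprints.append((ref_len, ref_len))
    return footprints


def _footprint_in_window(fp: tuple[int, int], lo: int, hi: int) -> bool:
    """True if footprint [a, b) (or point (a, a)) touches [lo, hi]."""
    a, b = fp
    if a == b:  # insertion point
        return lo <= a <= hi
    return a <= hi and b > lo


def classify_reporter(
    read1_seq: str,
    record: GuideRecord,
    library: Sequence[GuideRecord],
    params: ClassifyParams = ClassifyParams(),
    _aligner: Optional[Align.PairwiseAligner] = None,
) -> ReadClass:
    """Classify the reporter read of a pair already assigned to ``record``.

    The fixed flanks bordering the reporter's guide-specific segment are
    located on the read within ``params.flank_mm`` mismatches each; failure
    leaves the edit status unclassified.  The between-flank region is then
    (1) checked for coupling — if it edit-aligns strictly closer to another
    guide's segment than to this guide's, the pair is a chimera — and
    (2) globally aligned to the expected segment with affine gap scores;
    any indel footprint intersecting ``cut_offset ± window`` marks the read
    edited, while substitution-only differences leave it unedited.
    """
    read1 = read1_seq.upper()
    vs, ve = _variable_segment(record)
    rep = record.reporter_seq
    left_probe = rep[max(0, vs - params.flank_probe_len): vs]
    right_probe = rep[ve: ve + params.flank_probe_len]
    if not left_probe or not right_probe:
        return ReadClass(record.guide_id, INDETERMINATE, UNCLASSIFIED)

    lpos = _hamming_search(read1, left_probe, params.flank_mm)
    if lpos is None:
        return ReadClass(record.guide_id, INDETERMINATE, UNCLASSIFIED)
    region_start = lpos + len(left_probe)
    rpos = _hamming_search(read1, right_probe, params.flank_mm, start=region_start)
    if rpos is None:
        return ReadClass(record.guide_id, INDETERMINATE, UNCLASSIFIED)
    region = read1[region_start:rpos]

    expected = rep[vs:ve]
    own_dist = edlib.align(region, expected, mode="NW", task="distance")["editDistance"]
    for other in library:
        if other.guide_id == record.guide_id:
            continue
        o_vs, o_ve = _variable_segment(other)
        o_seg = other.reporter_seq[o_vs:o_ve]
        if o_seg == expected:
            continue
        d = edlib.align(region, o_seg, mode="NW", task="distance")["editDistance"]
        if d < own_dist:
            return ReadClass(record.guide_id, UNCOUPLED, UNCLASSIFIED)

    if region == expected:
        return ReadClass(record.guide_id, COUPLED, UNEDITED)

    aligner = _aligner if _aligner is not None else _make_aligner(params)
    if not region:  # whole segment deleted
        footprints = [(0, len(expected))]
    else:
        footprints = _indel_footprints(aligner.align(expected, region)[0])
    cut = record.cut_offset - vs
    lo, hi = cut - params.window, cut + params.window
    edited = any(_footprint_in_window(fp, lo, hi) for fp in footprints)
    return ReadClass(record.guide_id, COUPLED, EDITED if edited else UNEDITED)


# ---------------------------------------------------------------------------
# FASTQ driving loop
# ---------------------------------------------------------------------------

def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _iter_fastq(handle) -> Iterator[tuple[str, str, str]]:
    """Yield (id, seq, qual) triplets from a FASTQ text handle."""
    while True:
        header = handle.readline()
        if not header:
            return
        seq = handle.readline().rstrip("\n")
        plus = handle.readline()
        qual = handle.readline().rstrip("\n")
        if not qual and not plus:
            raise ValueError("truncated FASTQ record")
        yield header.rstrip("\n").split()[0].lstrip("@"), seq, qual


def _mean_quality(qual: str) -> float:
    if not qual:
        return 0.0
    arr = np.frombuffer(qual.encode(), dtype=np.uint8)
    return float(arr.mean()) - 33.0


def count_sample(
    fastq_r1: str | Path,
    fastq_r2: str | Path,
    library: Sequence[GuideRecord],
    params: ClassifyParams = ClassifyParams(),
    sample_id: str = "sample",
    timepoint_days: float = 0.0,
) -> tuple[SampleCounts, dict]:
    """Count total / coupled / edited reads per guide from a FASTQ pair.

    Read 2 assigns the guide; read 1 classifies the reporter.  Returns the
    per-guide :class:`SampleCounts` (guides never seen get no row) and a
    run report with read totals and assignment / coupling / edit fractions.
    Raises ``ValueError`` if the two files hold different numbers of reads.
    """
    by_id = {rec.guide_id: rec for rec in library}
    counts = SampleCounts(sample_id=sample_id, timepoint_days=timepoint_days)
    aligner = _make_aligner(params)
    n_pairs = n_assigned = n_coupled = n_uncoupled = n_edited = n_qfail = 0

    with _open_text(fastq_r1) as h1, _open_text(fastq_r2) as h2:
        for rec1, rec2 in zip_longest(_iter_fastq(h1), _iter_fastq(h2)):
            if rec1 is None or rec2 is None:
                raise ValueError(
                    f"mate-count mismatch between {fastq_r1} and {fastq_r2}"
                )
            n_pairs += 1
            _, seq1, qual1 = rec1
            _, seq2, qual2 = rec2
            if params.min_mean_q is not None and (
                _mean_quality(qual1) < params.min_mean_q
                or _mean_quality(qual2) < params.min_mean_q
            ):
                n_qfail += 1
                continue
            gid = assign_guide(
                seq2, library, params.max_mismatch, params.anchor, params.anchor_mm
            )
            if gid is None:
                continue
            n_assigned += 1
            rc = classify_reporter(seq1, by_id[gid], library, params, _aligner=aligner)
            counts.add(gid, rc.coupling, rc.edit)
            if rc.coupling == COUPLED:
                n_coupled += 1
                if rc.edit == EDITED:
                    n_edited += 1
            elif rc.coupling == UNCOUPLED:
                n_uncoupled += 1

    counts.validate()
    resolved = n_coupled + n_uncoupled
    report = {
        "sample_id": sample_id,
        "n_pairs": n_pairs,
        "n_quality_failed": n_qfail,
        "n_assigned": n_assigned,
        "n_unassigned": n_pairs - n_qfail - n_assigned,
        "n_coupled": n_coupled,
        "n_uncoupled": n_uncoupled,
        "n_edited": n_edited,
        "frac_assigned": n_assigned / n_pairs if n_pairs else 0.0,
        "coupling_rate": n_coupled / resolved if resolved else 0.0,
        "edit_rate": n_edited / n_coupled if n_coupled else 0.0,
    }
    return counts, report


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2) + "\n")
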