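"""Guide-reporter library definitions and I/O.

A self-reporting CRISPR library couples every sgRNA expression cassette
with a "reporter" copy of its own target site on the same lentiviral
construct.  Each library member is therefore described by its spacer
(the 20-nt protospacer the guide programs Cas9 with) and by the reporter
amplicon that embeds that protospacer, plus a PAM, inside fixed flanking
sequence.  Because the reporter is cut by the same guide, the indel rate
at the reporter cut site proxies editing of the endogenous target.

Coordinates are 0-based and half-open throughout.  ``cut_offset`` is the
index in ``reporter_seq`` of the first base 3' of the expected blunt cut
(between protospacer positions 17 and 18 for SpCas9).
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

REQUIRED_COLUMNS = ("guide_id", "gene", "spacer", "reporter_seq", "cut_offset", "role")
OPTIONAL_COLUMNS = ("coding_pos_pct", "offtarget_rank_pct")

ROLE_TARGETING = "targeting"
ROLE_NEGATIVE_CONTROL = "negative_control"
VALID_ROLES = frozenset({ROLE_TARGETING, ROLE_NEGATIVE_CONTROL})


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved per base)."""
    return seq.translate(_COMPLEMENT)[::-1]


class LibraryError(ValueError):
    """Raised when a guide library violates its invariants."""


@dataclass(frozen=True)
class GuideRecord:
    """One member of a guide-reporter library.

    Parameters
    ----------
    guide_id:
        Unique identifier within the library.
    gene:
        Target gene symbol (negative controls carry a placeholder symbol).
    spacer:
        Protospacer sequence, typically 20 nt, as programmed into the guide.
    reporter_seq:
        Reporter amplicon containing the protospacer (on either strand)
        embedded in fixed flanks.
    cut_offset:
        0-based index in ``reporter_seq`` of the first base 3' of the
        expected blunt cut.
    role:
        ``"targeting"`` or ``"negative_control"``.
    coding_pos_pct, offtarget_rank_pct:
        Optional per-guide covariates (percent position of the cut within
        the CDS; off-target rank percentile); carried through unchanged.
    """

    guide_id: str
    gene: str
    spacer: str
    reporter_seq: str
    cut_offset: int
    role: str
    coding_pos_pct: Optional[float] = None
    offtarget_rank_pct: Optional[float] = None

    def __post_init__(self) -> None:
        if self.role not in VALID_ROLES:
            raise LibraryError(
                f"guide {self.guide_id!r}: role {self.role!r} not in {sorted(VALID_ROLES)}"
            )
        if not (0 <= self.cut_offset < len(self.reporter_seq)):
            raise LibraryError(
                f"guide {self.guide_id!r}: cut_offset {self.cut_offset} outside "
                f"reporter of length {len(self.reporter_seq)}"
            )
        # enforced eagerly so every constructed record is locatable
        locate_protospacer(self)


@dataclass(frozen=True)
class GeneReference:
    """Reference essential / non-essential gene sets for benchmarking."""

    essential: frozenset[str]
    nonessential: frozenset[str]

    def __post_init__(self) -> None:
        overlap = self.essential & self.nonessential
        if overlap:
            raise LibraryError(
                f"essential and nonessential sets overlap: {sorted(overlap)[:5]}"
            )

    def label(self, gene: str) -> str:
        if gene in self.essential:
            return "essential"
        if gene in self.nonessential:
            return "nonessential"
        return "other"


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, start = [], 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return hits
        hits.append(i)
        start = i + 1


def locate_protospacer(record: GuideRecord) -> tuple[int, int, bool]:
    """Locate the protospacer within the reporter amplicon.

    Returns ``(start, end, is_reverse)`` with 0-based half-open
    coordinates such that ``reporter_seq[start:end]`` equals the spacer
    (``is_reverse=False``) or its reverse complement (``is_reverse=True``).

    Raises :class:`LibraryError` if the spacer occurs zero times or more
    than once across both strands, or if ``cut_offset`` falls outside
    ``[start - 10, end + 10]``.
    """
    rep = record.reporter_seq.upper()
    fwd = _find_all(rep, record.spacer.upper())
    rev = _find_all(rep, reverse_complement(record.spacer.upper()))
    # a palindromic spacer hits both strands at one position; count it once
    hits = [(i, False) for i in fwd] + [(i, True) for i in rev if i not in fwd]
    if len(hits) != 1:
        raise LibraryError(
            f"guide {record.guide_id!r}: spacer found {len(hits)} times in reporter "
            "(expected exactly once on either strand)"
        )
    start, is_reverse = hits[0]
    end = start + len(record.spacer)
    if not (start - 10 <= record.cut_offset <= end + 10):
        raise LibraryError(
            f"guide {record.guide_id!r}: cut_offset {record.cut_offset} not within "
            f"10 nt of protospacer interval ({start}, {end})"
        )
    return start, end, is_reverse


def read_library(path: str | Path) -> list[GuideRecord]:
    """Read a guide-reporter library from a TSV/CSV file.

    The file must have a header with at least the columns
    ``guide_id, gene, spacer, reporter_seq, cut_offset, role``; the
    optional covariate columns ``coding_pos_pct`` and
    ``offtarget_rank_pct`` are read when present.  Delimiter is inferred
    from the extension (``.csv`` -> comma, otherwise tab).
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype={"guide_id": str, "gene": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise LibraryError(f"{path}: missing required columns {missing}")

    dup = df["guide_id"][df["guide_id"].duplicated()]
    if not dup.empty:
        raise LibraryError(f"{path}: duplicate guide_id(s): {sorted(set(dup))[:5]}")

    records = []
    for row in df.itertuples(index=False):
        kwargs = {}
        for col in OPTIONAL_COLUMNS:
            if col in df.columns:
                val = getattr(row, col)
                kwargs[col] = None if pd.isna(val) else float(val)
        records.append(
            GuideRecord(
                guide_id=str(row.guide_id),
                gene=str(row.gene),
                spacer=str(row.spacer).upper(),
                reporter_seq=str(row.reporter_seq).upper(),
                cut_offset=int(row.cut_offset),
                role=str(row.role),
                **kwargs,
            )
        )
    return records


def write_library(records: Sequence[GuideRecord], path: str | Path) -> None:
    """Write a library to TSV (CSV if the path ends in .csv); round-trips
    with :func:`read_library`."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    rows = [dataclasses.asdict(r) for r in records]
    df = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS))
    drop = [c for c in OPTIONAL_COLUMNS if df[c].isna().all()]
    df = df.drop(columns=drop)
    df.to_csv(path, sep=sep, index=False)


def read_gene_list(path: str | Path) -> frozenset[str]:
    """Read a plain-text gene list, one symbol per line; '#' comments and
    blank lines are ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        sym = line.split("#", 1)[0].strip()
        if sym:
            out.add(sym)
    return frozenset(out)


def read_gene_reference(essential_path: str | Path, nonessential_path: str | Path) -> GeneReference:
    """Build a :class:`GeneReference` from two plain-text gene lists."""
    return GeneReference(
        essential=read_gene_list(essential_path),
        nonessential=read_gene_list(nonessential_path),
    )


def load_builtin_reference() -> GeneReference:
    """Curated reduced sets of constitutive-essential and non-expressed
    genes, shipped for tests and examples.

    These are small subsets of the commonly used core-essential /
    non-essential benchmarking lists, not the full published sets;
    real analyses should pass their own lists.
    """
    pkg = importlib.resources.files("repscreen.data")

    def parse(name: str) -> frozenset[str]:
        out = set()
        for line in (pkg / name).read_text().splitlines():
            sym = line.split("#", 1)[0].strip()
            if sym:
                out.add(sym)
        return frozenset(out)

    return GeneReference(
        essential=parse("essential_core_subset.txt"),
        nonessential=parse("nonessential_subset.txt"),
    )
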