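"""Synthetic reporter-coupled dropout screens with known ground truth.

The generative model mirrors the coupled-editing scenario the analysis
assumes.  Each guide g has a true edited-cell fraction ``X_true`` (its
cutting activity) and its gene a true relative viability ``v_true`` of
edited cells.  Cutting itself carries a mild fitness cost (DNA-damage
response), modelled as a multiplier ``1 + s`` on edited cells — for
negative controls this is the *only* fitness effect.  With
``v_eff = v_true * (1 + s)`` the terminal expectations are

    fc_expected        = (1 - X) + X * v_eff
    indel_obs_expected = X * v_eff / fc_expected      (among coupled reads)

Reporters are coupled to their cassette with fidelity ``kappa``; a
decoupled read carries another guide's protospacer (detectable, hence
excluded from indel statistics) and an edit state drawn from the
population average, independent of its own cell.

Read sampling is multinomial over guides at a fixed depth, with binomial
thinning into coupled and edited subsets; ``emit_fastq`` additionally
renders each pair as sequences (spacer cassette on read 2, reporter on
read 1, short deletion at the cut for edited reads, swapped protospacer
for decoupled reads, iid substitution errors) alongside a per-read truth
table.  All randomness flows from the config seed; identical seeds give
bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .library_io import GuideRecord, ROLE_NEGATIVE_CONTROL, ROLE_TARGETING
from .read_classify import GuideCounts, SampleCounts
from .screen_quant import GuideQuant

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# fixed cassette architecture shared by every simulated library member
REPORTER_FLANK5 = "GCTTACCGTAACTTGAAAGTATTTC"  # 25 nt
REPORTER_FLANK3 = "GTCCTAGGTACCGAATTCGAGCTCG"  # 25 nt
READ2_PREFIX = "TTGTGGAAAGGACGAAACACCG"  # U6 3' end incl. the CACCG anchor site
SCAFFOLD = "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCGTTATCAACTTGAAAAAGTG"
VECTOR_TAIL = "GTCGACCTCGAGACAAATGGCAGTATTCATCCACAATTTTAAAAGAAAAGGGGGGATTGG"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of a simulated screen.

    Defaults emulate a moderately sized custom library: essential genes
    deplete to 10-30% viability, neutral genes are fully viable, guide
    activity is broadly heterogeneous (X ~ U(0.05, 0.95)), 94% of
    reporters are correctly coupled, and cutting costs 10% fitness
    (``ddr_slope = -0.1``).  ``seed`` is mandatory: every random draw
    derives from it.
    """

    seed: int
    n_genes: int = 500
    n_essential: int = 100
    guides_per_gene: int = 3
    n_controls: int = 100
    v_essential: tuple[float, float] = (0.1, 0.3)
    v_neutral: float = 1.0
    x_range: tuple[float, float] = (0.05, 0.95)
    coupling_fidelity: float = 0.94
    ddr_slope: float = -0.1
    abundance_sigma: float = 0.5
    read_depth: int = 2_000_000
    seq_error_rate: float = 0.0
    spacer_len: int = 20
    read_len: int = 90
    insertion_fraction: float = 0.0  # fraction of edits rendered as insertions

    def __post_init__(self) -> None:
        if not (0.0 <= self.coupling_fidelity <= 1.0):
            raise ValueError("coupling_fidelity must be in [0, 1]")
        if self.read_depth < 0:
            raise ValueError("read_depth must be >= 0")
        if self.n_essential > self.n_genes:
            raise ValueError("n_essential cannot exceed n_genes")
        if not (0.0 <= self.seq_error_rate < 1.0):
            raise ValueError("seq_error_rate must be in [0, 1)")
        lo, hi = self.x_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("x_range must be within [0, 1]")


@dataclass(frozen=True)
class GuideTruth:
    guide_id: str
    gene: str
    role: str
    x_true: float
    v_true: float  # viability of target disruption (1.0 for controls)
    v_eff: float
    fc_expected: float
    indel_obs_expected: float
    abundance0: float


@dataclass
class SimTruth:
    """Ground truth of one simulated screen."""

    config: SimConfig
    gene_v: dict[str, float]
    guides: list[GuideTruth]

    def by_id(self) -> dict[str, GuideTruth]:
        return {g.guide_id: g for g in self.guides}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(g) for g in self.guides])


def _coupled_expectations(x: float, v_eff: float) -> tuple[float, float]:
    fc = (1.0 - x) + x * v_eff
    indel = x * v_eff / fc if fc > 0 else (1.0 if x > 0 else 0.0)
    return fc, indel


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return bytes(rng.choice(BASES, size=length)).decode()


def simulate_truth(config: SimConfig) -> SimTruth:
    """Draw per-gene viabilities, per-guide activities and abundances.

    Deterministic given ``config.seed``; the expected fold change and
    coupled-read indel frequency of every guide are populated in closed
    form.  Gene ids ``G0001..`` (the first ``n_essential`` essential),
    guide ids ``<gene>_g<i>`` and ``CTRL_c<i>`` for negative controls.
    """
    rng = np.random.default_rng([0, config.seed])
    s = config.ddr_slope
    gene_v: dict[str, float] = {}
    guides: list[GuideTruth] = []

    for i in range(config.n_genes):
        gene = f"G{i + 1:04d}"
        if i < config.n_essential:
            v = float(rng.uniform(*config.v_essential))
        else:
            v = config.v_neutral
        gene_v[gene] = v
        for j in range(config.guides_per_gene):
            x = float(rng.uniform(*config.x_range))
            v_eff = v * (1.0 + s)
            fc, indel = _coupled_expectations(x, v_eff)
            guides.append(
                GuideTruth(
                    guide_id=f"{gene}_g{j + 1}", gene=gene, role=ROLE_TARGETING,
                    x_true=x, v_true=v, v_eff=v_eff,
                    fc_expected=fc, indel_obs_expected=indel, abundance0=0.0,
                )
            )
    for i in range(config.n_controls):
        x = float(rng.uniform(*config.x_range))
        v_eff = 1.0 + s
        fc, indel = _coupled_expectations(x, v_eff)
        guides.append(
            GuideTruth(
                guide_id=f"CTRL_c{i + 1:03d}", gene="CTRL", role=ROLE_NEGATIVE_CONTROL,
                x_true=x, v_true=1.0, v_eff=v_eff,
                fc_expected=fc, indel_obs_expected=indel, abundance0=0.0,
            )
        )

    ab = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=len(guides))
    ab /= ab.sum()
    guides = [dataclasses.replace(g, abundance0=float(a)) for g, a in zip(guides, ab)]
    return SimTruth(config=config, gene_v=gene_v, guides=guides)


def interpolate_truth(truth: SimTruth, fraction: float) -> SimTruth:
    """Truth at an intermediate timepoint, with editing scaled to
    ``fraction`` of its terminal extent (linear stand-in for the gradual
    accumulation of indels over a screen)."""
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must be in [0, 1]")
    guides = []
    for g in truth.guides:
        x = g.x_true * fraction
        fc, indel = _coupled_expectations(x, g.v_eff)
        guides.append(
            dataclasses.replace(g, x_true=x, fc_expected=fc, indel_obs_expected=indel)
        )
    return SimTruth(config=truth.config, gene_v=dict(truth.gene_v), guides=guides)


def expected_quants(truth: SimTruth) -> list[GuideQuant]:
    """Noiseless quantification: what infinite sequencing depth would give.

    Final frequencies are renormalised by the mean population fitness, as
    in a real screen; the control-based FC0 normalisation downstream
    absorbs exactly this factor.
    """
    w = sum(g.abundance0 * g.fc_expected for g in truth.guides)
    out = []
    for g in truth.guides:
        freq_final = g.abundance0 * g.fc_expected / w
        out.append(
            GuideQuant(
                guide_id=g.guide_id,
                freq_ref=g.abundance0,
                freq_final=freq_final,
                rpt_ref=1000.0 * g.abundance0,
                fc_raw=freq_final / g.abundance0,
                indel_obs=g.indel_obs_expected,
                qc_pass=True,
            )
        )
    return out


def sample_counts(
    truth: SimTruth, config: Optional[SimConfig] = None
) -> tuple[SampleCounts, SampleCounts]:
    """Sample reference and final read counts at the configured depth.

    Both samples draw guide totals from a multinomial over relative
    abundances (initial, and initial times expected fold change).
    Coupled reads are a binomial thinning at the coupling fidelity —
    emulating a classifier that recognises and excludes swapped
    reporters — and edited reads a binomial draw among coupled reads at
    the guide's expected indel frequency (zero in the reference sample,
    which precedes editing).
    """
    config = config or truth.config
    rng = np.random.default_rng([1, config.seed])
    ab0 = np.array([g.abundance0 for g in truth.guides])
    fc = np.array([g.fc_expected for g in truth.guides])
    indel = np.array([g.indel_obs_expected for g in truth.guides])
    kappa = config.coupling_fidelity

    n_ref = rng.multinomial(config.read_depth, ab0)
    p_fin = ab0 * fc
    p_fin = p_fin / p_fin.sum()
    n_fin = rng.multinomial(config.read_depth, p_fin)
    c_ref = rng.binomial(n_ref, kappa)
    c_fin = rng.binomial(n_fin, kappa)
    e_fin = rng.binomial(c_fin, indel)

    ref = SampleCounts(sample_id="reference", timepoint_days=0.0)
    fin = SampleCounts(sample_id="final", timepoint_days=21.0)
    for i, g in enumerate(truth.guides):
        ref.counts[g.guide_id] = GuideCounts(int(n_ref[i]), int(c_ref[i]), 0)
        fin.counts[g.guide_id] = GuideCounts(int(n_fin[i]), int(c_fin[i]), int(e_fin[i]))
    ref.validate()
    fin.validate()
    return ref, fin


def make_library(config: SimConfig) -> list[GuideRecord]:
    """Random guide-reporter library matching the simulated truth layout.

    Spacers are iid random 20-mers (random 20-mers are mutually far apart
    in Hamming distance, so single-mismatch assignment is unambiguous;
    exact duplicates are re-drawn); each reporter embeds its protospacer
    and an NGG PAM between the fixed flanks, cut site between protospacer
    positions 17 and 18.
    """
    rng = np.random.default_rng([3, config.seed])
    truth = simulate_truth(config)  # same id universe as the truth table

    seen: set[str] = set()
    records = []
    for g in truth.guides:
        sp = _random_seq(rng, config.spacer_len)
        while sp in seen:
            sp = _random_seq(rng, config.spacer_len)
        seen.add(sp)
        pam = _random_seq(rng, 1) + "GG"
        reporter = REPORTER_FLANK5 + sp + pam + REPORTER_FLANK3
        records.append(
            GuideRecord(
                guide_id=g.guide_id,
                gene=g.gene,
                spacer=sp,
                reporter_seq=reporter,
                cut_offset=len(REPORTER_FLANK5) + 17,
                role=g.role,
            )
        )
    return records


# ---------------------------------------------------------------------------
# FASTQ rendering
# ---------------------------------------------------------------------------

def _pad_to(seq: str, length: int, filler: str) -> str:
    while len(seq) < length:
        seq += filler
    return seq[:length]


def _apply_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = BASES[BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return bytes(arr).decode()


def emit_fastq(
    truth: SimTruth,
    counts: SampleCounts,
    library: Sequence[GuideRecord],
    out_r1: str | Path,
    out_r2: str | Path,
    config: Optional[SimConfig] = None,
    max_pairs: Optional[int] = None,
) -> pd.DataFrame:
    """Render a sample's counts as a paired FASTQ with per-read truth.

    For each guide, ``n_coupled`` reads carry its own reporter
    (``n_edited`` of them with a short deletion — or insertion, per the
    config fraction — at the cut site) and ``n_total - n_coupled`` reads
    carry a randomly swapped protospacer whose edit state is drawn from
    the population-average edit rate.  Substitution errors are applied
    iid at the configured rate.  Files ending in ``.gz`` are gzipped.
    Returns the truth table (read_id, guide_id, coupling, edit).
    Raises ``ValueError`` if a read template exceeds ``read_len``.
    """
    config = config or truth.config
    rng = np.random.default_rng([2, config.seed])
    by_id = {r.guide_id: r for r in library}
    tbl = truth.by_id()

    # population-average edit rate among survivors, for decoupled reporters
    tot = sum(g.abundance0 * g.fc_expected for g in truth.guides)
    avg_edit = sum(
        g.abundance0 * g.fc_expected * g.indel_obs_expected for g in truth.guides
    ) / tot if tot > 0 else 0.0

    flank5, flank3 = len(REPORTER_FLANK5), len(REPORTER_FLANK3)
    rows = []
    read_id = 0

    def reporter_read(rec: GuideRecord, edited: bool) -> str:
        rep = rec.reporter_seq
        if edited:
            size = int(rng.integers(1, 4))
            cut = rec.cut_offset
            if config.insertion_fraction > 0 and rng.random() < config.insertion_fraction:
                rep = rep[:cut] + _random_seq(rng, size) + rep[cut:]
            else:
                start = max(0, cut - (size + 1) // 2)
                rep = rep[:start] + rep[start + size:]
        if len(rep) > config.read_len:
            raise ValueError(
                f"read_len {config.read_len} shorter than reporter template ({len(rep)})"
            )
        return _pad_to(rep, config.read_len, VECTOR_TAIL)

    def spacer_read(rec: GuideRecord) -> str:
        template = READ2_PREFIX + rec.spacer + SCAFFOLD
        if len(READ2_PREFIX) + len(rec.spacer) > config.read_len:
            raise ValueError(
                f"read_len {config.read_len} shorter than cassette template"
            )
        return _pad_to(template, config.read_len, VECTOR_TAIL)

    def opener(path: str | Path):
        path = Path(path)
        return gzip.open(path, "wt") if path.suffix == ".gz" else open(path, "wt")

    others = [r for r in library]
    qual = "I" * config.read_len
    n_emitted = 0
    with opener(out_r1) as h1, opener(out_r2) as h2:
        for gid in sorted(counts.counts):
            gc = counts.counts[gid]
            rec = by_id[gid]
            n_unc = gc.n_total - gc.n_coupled
            # per-read plan: edited-coupled, unedited-coupled, uncoupled
            plan = (
                [("coupled", True)] * gc.n_edited
                + [("coupled", False)] * (gc.n_coupled - gc.n_edited)
                + [("uncoupled", None)] * n_unc
            )
            for coupling, edited in plan:
                if max_pairs is not None and n_emitted >= max_pairs:
                    break
                read_id += 1
                rid = f"sim_{read_id:08d}"
                if coupling == "uncoupled":
                    swap = others[int(rng.integers(len(others)))]
                    while swap.guide_id == gid and len(others) > 1:
                        swap = others[int(rng.integers(len(others)))]
                    edited = bool(rng.random() < avg_edit)
                    # the read belongs to rec's cassette but carries swap's
                    # reporter segment spliced into the shared flanks
                    r1 = (
                        rec.reporter_seq[:flank5]
                        + swap.reporter_seq[flank5: len(swap.reporter_seq) - flank3]
                        + rec.reporter_seq[len(rec.reporter_seq) - flank3:]
                    )
                    if edited:
                        size = int(rng.integers(1, 4))
                        cut = swap.cut_offset
                        start = max(0, cut - (size + 1) // 2)
                        r1 = r1[:start] + r1[start + size:]
                    r1 = _pad_to(r1, config.read_len, VECTOR_TAIL)
                    truth_edit = "unclassified"
                else:
                    r1 = reporter_read(rec, bool(edited))
                    truth_edit = "edited" if edited else "unedited"
                r2 = spacer_read(rec)
                r1 = _apply_errors(r1, rng, config.seq_error_rate)
                r2 = _apply_errors(r2, rng, config.seq_error_rate)
                h1.write(f"@{rid}/1\n{r1}\n+\n{qual}\n")
                h2.write(f"@{rid}/2\n{r2}\n+\n{qual}\n")
                rows.append((rid, gid, coupling, truth_edit))
                n_emitted += 1
            if max_pairs is not None and n_emitted >= max_pairs:
                break
    return pd.DataFrame(rows, columns=["read_id", "guide_id", "coupling", "edit"])
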