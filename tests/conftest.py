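import numpy as np
import pytest

from repscreen import GuideRecord, SimConfig, make_library, simulate_truth
from repscreen.library_io import ROLE_NEGATIVE_CONTROL, ROLE_TARGETING

FLANK5 = "GCTTACCGTAACTTGAAAGTATTTC"
FLANK3 = "GTCCTAGGTACCGAATTCGAGCTCG"


def make_record(
    guide_id: str,
    spacer: str,
    gene: str = "GENE1",
    role: str = ROLE_TARGETING,
    pam: str = "TGG",
) -> GuideRecord:
    """Hand-built guide-reporter record with the standard cassette layout."""
    return GuideRecord(
        guide_id=guide_id,
        gene=gene,
        spacer=spacer,
        reporter_seq=FLANK5 + spacer + pam + FLANK3,
        cut_offset=len(FLANK5) + 17,
        role=role,
    )


@pytest.fixture
def toy_library() -> list[GuideRecord]:
    """Four hand-picked guides (mutually distant spacers) plus a control."""
    return [
        make_record("g1", "ACGTACGTACGTACGTACGT"),
        make_record("g2", "TTTTCCCCGGGGAAAATTTT", gene="GENE2"),
        make_record("g3", "GATCGATCGATCGATCGATC", gene="GENE2"),
        make_record("g4", "CCAATTGGCCAATTGGCCAA", gene="GENE3"),
        make_record("c1", "AAGGTTCCAAGGTTCCAAGG", gene="CTRL", role=ROLE_NEGATIVE_CONTROL),
    ]


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated screen shared by read-level tests."""
    cfg = SimConfig(
        seed=11, n_genes=10, n_essential=3, guides_per_gene=2,
        n_controls=10, read_depth=5000, coupling_fidelity=0.9,
    )
    truth = simulate_truth(cfg)
    library = make_library(cfg)
    return cfg, truth, library


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)
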