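import pytest

from ltrlayers.defrag import Candidate
from ltrlayers.formats import Fragment, LibraryEntry


def make_fragment(
    gs,
    ge,
    family="Osr1",
    part="IN",
    cs=1,
    ce=None,
    strand="+",
    contig="chr1",
    score=1000.0,
    divergence=0.0,
):
    if ce is None:
        ce = cs + (ge - gs)
    return Fragment(
        contig_id=contig,
        g_start=gs,
        g_end=ge,
        strand=strand,
        family_id=family,
        part=part,
        c_start=cs,
        c_end=ce,
        divergence=divergence,
        score=score,
    )


def make_candidate(
    gs,
    ge,
    family="Osr1",
    part="IN",
    cs=1,
    ce=None,
    strand="+",
    contig="chr1",
    score=1000.0,
    consensus_length=None,
):
    if ce is None:
        ce = cs + (ge - gs)
    return Candidate(
        contig_id=contig,
        g_start=gs,
        g_end=ge,
        strand=strand,
        family_id=family,
        part=part,
        covered=[(cs, ce)],
        members=[],
        score=score,
        consensus_length=consensus_length,
    )


@pytest.fixture
def worked_library():
    """Consensus lengths for the worked three-fragment example."""
    return {
        ("Osr1", "IN"): 1000,
        ("Osr1", "LTR"): 400,
        ("Osr2", "IN"): 800,
        ("Osr2", "LTR"): 300,
    }


@pytest.fixture
def worked_candidates():
    """Fragments a, b, c of the worked IN-IN example (genome 1001-1500 /
    1501-1800 / 1801-2300)."""
    a = make_candidate(1001, 1500, "Osr1", "IN", 1, 500)
    b = make_candidate(1501, 1800, "Osr2", "LTR", 1, 300)
    c = make_candidate(1801, 2300, "Osr1", "IN", 501, 1000)
    return a, b, c
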