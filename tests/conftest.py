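import pytest

from debubble.dbg import build_dbg, count_kmers
from debubble.graph import WeightedDigraph

# the two-transcript worked example: an exon-skipping-like pair whose DBG
# (k=3) contains exactly one bubble, from CTG to GCG
SEQ_PAIR = ["ACTGGAGCG", "ACTGCG"]
K = 3


@pytest.fixture
def toy_dbg():
    """DBG (k=3, min_count=1) of the two toy transcripts, 8 vertices/8 arcs."""
    return build_dbg(count_kmers(SEQ_PAIR, K, 1))


@pytest.fixture
def toy_ids(toy_dbg):
    """k-mer label -> vertex id for the toy DBG."""
    return {lab: i for i, lab in enumerate(toy_dbg.labels)}


@pytest.fixture
def diamond():
    """s=0 -> {a=1, b=2} -> t=3, unit weights."""
    return WeightedDigraph(4, [(0, 1, 1), (0, 2, 1), (1, 3, 1), (2, 3, 1)])


@pytest.fixture
def corridors():
    """Three parallel length-2 corridors from s=0 to t=4."""
    return WeightedDigraph(5, [(0, 1, 1), (0, 2, 1), (0, 3, 1),
                               (1, 4, 1), (2, 4, 1), (3, 4, 1)])
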