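import random

import networkx as nx
import pytest

from debubble.bubbles import EnumLimits, enumerate_all_sources
from debubble.dbg import (bcc_decompose, build_dbg, compress_linear_paths,
                          count_kmers)
from debubble.graph import WeightedDigraph

SEQ_PAIR = ["ACTGGAGCG", "ACTGCG"]


def random_dna(rng, length):
    return "".join(rng.choice("ACGT") for _ in range(length))


# -- k-mer counting ---------------------------------------------------------

def test_count_kmers_toy_pair():
    table = count_kmers(SEQ_PAIR, 3, 1)
    assert set(table.counts) == {"ACT", "CTG", "TGG", "GGA", "GAG", "AGC", "GCG", "TGC"}
    table2 = count_kmers(SEQ_PAIR, 3, 2)
    assert set(table2.counts) == {"ACT", "CTG", "GCG"}


def test_count_kmers_k_longer_than_sequences():
    assert len(count_kmers(["ACGT"], 10, 1)) == 0


def test_count_kmers_skips_n_windows_and_rejects_junk():
    table = count_kmers(["ACNGT"], 2, 1)
    assert set(table.counts) == {"AC", "GT"}
    with pytest.raises(ValueError, match="invalid characters"):
        count_kmers(["ACXGT"], 2, 1)
    with pytest.raises(ValueError):
        count_kmers([], 1, 1)


# -- DBG construction -------------------------------------------------------

def test_build_dbg_toy_pair_exact_arcs(toy_dbg):
    assert (toy_dbg.n, toy_dbg.m) == (8, 8)
    arcs = {(toy_dbg.labels[u], toy_dbg.labels[v]) for u, v, w in toy_dbg.arcs()}
    assert arcs == {("ACT", "CTG"), ("CTG", "TGG"), ("CTG", "TGC"),
                    ("TGG", "GGA"), ("GGA", "GAG"), ("GAG", "AGC"),
                    ("AGC", "GCG"), ("TGC", "GCG")}
    assert all(w == 1 for _, _, w in toy_dbg.arcs())


def test_build_dbg_single_kmer_and_self_loop():
    g = build_dbg(count_kmers(["ACGT"], 4, 1))
    assert (g.n, g.m) == (1, 0)
    g = build_dbg(count_kmers(["AAAA"], 3, 1))  # AAA overlaps itself
    assert (g.n, g.m) == (1, 0)


def test_arc_rule_totality_on_random_tables():
    """build_dbg realises an arc iff the (k-1)-overlap holds, for every
    ordered k-mer pair -- exhaustively verified."""
    rng = random.Random(11)
    for k in (3, 4, 5):
        seqs = [random_dna(rng, rng.randint(k, 40)) for _ in range(6)]
        table = count_kmers(seqs, k, 1)
        assert len(table) <= 200
        g = build_dbg(table)
        kmers = table.kmers()
        arcs = {(g.labels[u], g.labels[v]) for u, v, _ in g.arcs()}
        for a in kmers:
            for b in kmers:
                expected = a[1:] == b[:-1] and a != b
                assert ((a, b) in arcs) == expected


# -- linear-path compression ------------------------------------------------

def test_compress_toy_pair(toy_dbg):
    cd = compress_linear_paths(toy_dbg, 3)
    g = cd.graph
    assert sorted(g.labels) == ["ACTG", "GCG", "TGC", "TGGAGC"]
    arcs = {(g.labels[u], g.labels[v]): w for u, v, w in g.arcs()}
    assert arcs == {("ACTG", "TGGAGC"): 4, ("ACTG", "TGC"): 1,
                    ("TGGAGC", "GCG"): 1, ("TGC", "GCG"): 1}
    # the two compressed source->sink paths have lengths 5 and 2
    ids = {lab: i for i, lab in enumerate(g.labels)}
    assert arcs[("ACTG", "TGGAGC")] + arcs[("TGGAGC", "GCG")] == 5
    assert arcs[("ACTG", "TGC")] + arcs[("TGC", "GCG")] == 2


def test_compress_simple_path_collapses():
    # 7 k-mers forming a pure chain (no accidental extra overlaps)
    g = build_dbg(count_kmers(["AACCGGTTA"], 3, 1))
    cd = compress_linear_paths(g, 3)
    assert (cd.graph.n, cd.graph.m) == (1, 0)
    assert cd.graph.labels == ["AACCGGTTA"]


def test_compress_preserves_branch_vertices(diamond):
    g = WeightedDigraph(4, [(0, 1, 1), (0, 2, 1), (1, 3, 1), (2, 3, 1)],
                        labels=["AAC", "ACG", "ACT", "CTT"])
    # a perfect diamond has no in1/out1 chain of length > 1 to merge
    cd = compress_linear_paths(g, 3)
    assert cd.graph.n == 4 and cd.graph.m == 4


def test_compression_preserves_path_lengths():
    """For random sequence sets, the compressed distance between unit-end
    vertices equals the uncompressed arc count of the same path."""
    from debubble.sssp import dijkstra_truncated
    rng = random.Random(5)
    checked = 0
    for trial in range(100):
        k = rng.choice((3, 4))
        seqs = [random_dna(rng, rng.randint(k + 2, 30)) for _ in range(3)]
        g = build_dbg(count_kmers(seqs, k, 1))
        cd = compress_linear_paths(g, k)
        ends = {cd.unit_end(u): u for u in cd.graph.vertices()}
        for orig_end, unit in ends.items():
            full = dijkstra_truncated(g, orig_end, None).dist
            comp = dijkstra_truncated(cd.graph, unit, None).dist
            for other_unit, d in comp.items():
                orig_other = cd.unit_end(other_unit)
                assert full[orig_other] == d
                checked += 1
    assert checked > 100


def test_compression_is_maximal():
    """No mergeable arc survives compression: every remaining arc leaves a
    branching tail or enters a branching head, except arcs of isolated
    directed cycles (left uncompressed by design)."""
    rng = random.Random(9)
    for trial in range(30):
        seqs = [random_dna(rng, rng.randint(6, 25)) for _ in range(4)]
        g = build_dbg(count_kmers(seqs, 3, 1))
        cd = compress_linear_paths(g, 3)
        cg = cd.graph
        for u, v, _ in cg.arcs():
            if cg.out_degree(u) == 1 and cg.in_degree(v) == 1:
                # must lie on a cycle: follow successors back to u
                cur, hops = v, 0
                while cur != u and hops <= cg.n:
                    assert cg.out_degree(cur) == 1
                    (cur, _, _), = cg.out_arcs(cur)
                    hops += 1
                assert cur == u


# -- biconnected components -------------------------------------------------

def test_bcc_diamond(diamond):
    comps = bcc_decompose(diamond, 4)
    assert len(comps) == 1 and comps[0].vertices == [0, 1, 2, 3]


def test_bcc_directed_path_all_discarded():
    g = WeightedDigraph(6, [(i, i + 1, 1) for i in range(5)])
    assert bcc_decompose(g, 4) == []
    comps = bcc_decompose(g, 1)
    assert sorted(sorted(c.vertices) for c in comps) == [[0, 1], [1, 2], [2, 3], [3, 4], [4, 5]]


def test_bcc_toy_dbg(toy_dbg, toy_ids):
    comps = bcc_decompose(toy_dbg, 1)
    sets = sorted(sorted(toy_dbg.labels[v] for v in c.vertices) for c in comps)
    assert sets == [["ACT", "CTG"],
                    ["AGC", "CTG", "GAG", "GCG", "GGA", "TGC", "TGG"]]
    assert len(bcc_decompose(toy_dbg, 4)) == 1  # the 2-vertex BCC is dropped


def test_bcc_matches_networkx():
    rng = random.Random(17)
    for trial in range(40):
        n = rng.randint(3, 12)
        arcs = [(u, v, 1) for u in range(n) for v in range(n)
                if u != v and rng.random() < 0.25]
        arcs = [a for a in arcs if (a[1], a[0], 1) not in arcs or a[0] < a[1]]
        g = WeightedDigraph(n, arcs)
        und = nx.Graph()
        und.add_nodes_from(range(n))
        und.add_edges_from((u, v) for u, v, _ in arcs)
        expected = sorted(sorted(c) for c in nx.biconnected_components(und)
                          if len(c) >= 2)
        got = sorted(c.vertices for c in bcc_decompose(g, 1))
        assert got == expected


def test_bcc_partition_preserves_bubbles():
    rng = random.Random(23)
    for trial in range(25):
        n = rng.randint(4, 9)
        arcs = [(u, v, 1) for u in range(n) for v in range(n)
                if u != v and rng.random() < 0.3]
        g = WeightedDigraph(n, arcs)
        whole = {b.key() for b in enumerate_all_sources(g, n, n)}
        comps = bcc_decompose(g, 1)
        per_bcc = {b.key()
                   for b in enumerate_all_sources(g, n, n, bccs=comps)}
        assert whole == per_bcc
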