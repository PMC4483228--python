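import random

import pytest

from debubble.graph import GraphDelta, WeightedDigraph


def test_constructor_rejects_malformed_arcs():
    with pytest.raises(ValueError, match="self-loop"):
        WeightedDigraph(2, [(0, 0, 1)])
    with pytest.raises(ValueError, match="duplicate"):
        WeightedDigraph(2, [(0, 1, 1), (0, 1, 2)])
    with pytest.raises(ValueError, match="negative"):
        WeightedDigraph(2, [(0, 1, -1)])
    with pytest.raises(TypeError):
        WeightedDigraph(2, [(0, 1, 0.5)])  # binary floats are banned


def test_remove_vertex_counts(diamond):
    delta = GraphDelta(diamond)
    delta.checkpoint()
    diamond.remove_vertex(1, delta)
    assert (diamond.n, diamond.m) == (3, 2)
    delta.restore()
    assert (diamond.n, diamond.m) == (4, 4)


def test_remove_then_restore_is_identity(diamond):
    before = diamond.arc_set()
    snap = diamond.snapshot()
    delta = GraphDelta(diamond)
    delta.checkpoint()
    diamond.remove_vertex(2, delta)
    delta.restore()
    assert diamond.arc_set() == before
    assert diamond.snapshot() == snap


def test_remove_vertex_toy_dbg(toy_dbg, toy_ids):
    delta = GraphDelta(toy_dbg)
    delta.checkpoint()
    toy_dbg.remove_vertex(toy_ids["CTG"], delta)
    assert toy_dbg.m == 5
    alive = {(toy_dbg.labels[u], toy_dbg.labels[v]) for u, v, _ in toy_dbg.arcs()}
    assert ("ACT", "CTG") not in alive
    assert ("CTG", "TGG") not in alive and ("CTG", "TGC") not in alive


def test_remove_vertex_requires_alive(diamond):
    delta = GraphDelta(diamond)
    delta.checkpoint()
    diamond.remove_vertex(1, delta)
    with pytest.raises(ValueError):
        diamond.remove_vertex(1, delta)
    with pytest.raises(ValueError):
        diamond.remove_vertex(99, delta)


def test_remove_out_arcs(toy_dbg, toy_ids):
    delta = GraphDelta(toy_dbg)
    delta.checkpoint()
    toy_dbg.remove_out_arcs(toy_ids["CTG"], delta)
    alive = {(toy_dbg.labels[u], toy_dbg.labels[v]) for u, v, _ in toy_dbg.arcs()}
    assert ("CTG", "TGG") not in alive and ("CTG", "TGC") not in alive
    assert ("ACT", "CTG") in alive  # in-arcs and the vertex survive
    assert toy_dbg.is_vertex_alive(toy_ids["CTG"])
    # second application is a no-op
    size = len(delta)
    toy_dbg.remove_out_arcs(toy_ids["CTG"], delta)
    assert len(delta) == size


def test_remove_out_arcs_sink_is_noop(diamond):
    delta = GraphDelta(diamond)
    delta.checkpoint()
    diamond.remove_out_arcs(3, delta)
    assert diamond.m == 4 and len(delta) == 0


def test_restore_without_checkpoint_errors(diamond):
    with pytest.raises(ValueError):
        GraphDelta(diamond).restore()


def test_nested_checkpoints_restore_lifo():
    rng = random.Random(7)
    for _ in range(25):
        n = rng.randint(3, 9)
        arcs = [(u, v, rng.randint(1, 5)) for u in range(n) for v in range(n)
                if u != v and rng.random() < 0.4]
        g = WeightedDigraph(n, arcs)
        pristine = g.arc_set()
        delta = GraphDelta(g)
        snapshots = []
        for _ in range(rng.randint(1, 6)):
            delta.checkpoint()
            snapshots.append(g.snapshot())
            alive = list(g.vertices())
            v = rng.choice(alive)
            if rng.random() < 0.5 and g.n > 1:
                g.remove_vertex(v, delta)
            else:
                g.remove_out_arcs(v, delta)
        while snapshots:
            snap = snapshots.pop()
            delta.restore()
            assert g.snapshot() == snap
        assert g.arc_set() == pristine


def test_log_size_bounded_by_graph_size():
    rng = random.Random(3)
    n = 10
    arcs = [(u, v, 1) for u in range(n) for v in range(n)
            if u != v and rng.random() < 0.5]
    g = WeightedDigraph(n, arcs)
    delta = GraphDelta(g)
    delta.checkpoint()
    for v in range(n):
        if g.is_vertex_alive(v):
            g.remove_vertex(v, delta)
    # along one root-to-leaf removal sequence each arc/vertex is logged once
    assert len(delta) <= len(arcs) + n


def test_reverse_view(toy_dbg, toy_ids):
    rev = toy_dbg.reverse()
    assert rev.reverse() is toy_dbg
    assert {(v, u, w) for u, v, w in toy_dbg.arcs()} == set(rev.arcs())
    # GCG has in-degree 2 in the DBG, hence out-degree 2 in the reverse view
    assert sum(1 for _ in rev.out_arcs(toy_ids["GCG"])) == 2
    # liveness is shared with the underlying graph
    delta = GraphDelta(toy_dbg)
    delta.checkpoint()
    toy_dbg.remove_vertex(toy_ids["GCG"], delta)
    assert sum(1 for _ in rev.out_arcs(toy_ids["GCG"])) == 0
    delta.restore()


def test_reverse_of_empty_graph():
    g = WeightedDigraph(0)
    assert list(g.reverse().arcs()) == []
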