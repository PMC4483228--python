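"""Polynomial-delay enumeration of (s,t,alpha1,alpha2)-bubbles.

A bubble from a fixed source ``s`` is a pair of internally vertex-disjoint
directed paths ``p1, p2`` from ``s`` to a common target ``t != s`` with
``|p1| <= alpha1`` and ``|p2| <= alpha2`` (lengths are sums of arc weights;
nucleotides in the de Bruijn graph use case).  In transcriptomics such
bubbles are the signature of variants -- SNPs, indels and alternative
splicing events -- in the de Bruijn graph of an RNA-seq read set.

The enumerator follows the binary partition method.  Its state is a pair
of partial paths ending at ``e1`` and ``e2`` with remaining length budgets
``r1, r2``; the interiors of both prefixes are removed from the working
graph.  The solution space -- all pairs of compatible completion paths,
i.e. paths ``e1 ~> t`` and ``e2 ~> t`` to a common ``t`` that share no
vertex except ``t`` and fit the budgets -- is split on the out-arcs of one
endpoint: one branch per out-arc ``(u, v)`` (the completions whose
``u``-side path starts with that arc, explored in the graph minus ``u``),
plus one branch for the completions that use none of them (explored in the
graph minus those arcs, which forces ``u`` to be the target).  A branch is
entered only after a shortest-path certificate shows it is non-empty, so
every recursion leaf corresponds to exactly one compatible pair and the
number of recursion nodes between consecutive leaves is bounded by 4n.

The feasibility certificates are pure shortest-path computations:

* a pair of compatible paths for ``e1 != e2`` exists iff some ``t`` has
  ``d(e1, t) <= r1`` and ``d(e2, t) <= r2`` (cut the two witness paths at
  their first common vertex);
* all out-arc branches of ``u`` are certified together by one truncated
  Dijkstra from the other endpoint in ``G - u`` followed by one reverse
  multi-source Dijkstra from the reached set -- a constant-time lookup
  then answers each out-neighbour.

The lower bound ``beta`` (both path lengths >= beta) and the canonical
orientation rule that collapses the two role assignments of a bubble are
applied as stateless output filters: pushing either into the branch
certificates would add a lower-bound constraint, and deciding bubble
existence under a lower bound is NP-hard.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Iterator

from .graph import GraphDelta, Weight, WeightedDigraph
from .sssp import DEFAULT_HEAP, dijkstra_truncated, reverse_dist_to_sink

__all__ = ["Bubble", "EnumLimits", "EnumStats", "exists_compatible_pair",
           "exists_bubble_from", "extension_feasibility",
           "enumerate_bubbles", "enumerate_all_sources"]


@dataclass(frozen=True)
class Bubble:
    """Two internally vertex-disjoint (s,t)-paths with their lengths.

    ``path1``/``path2`` are vertex sequences starting at ``s`` and ending
    at ``t``; ``len1``/``len2`` are their arc-weight sums.
    """

    s: int
    t: int
    path1: tuple[int, ...]
    path2: tuple[int, ...]
    len1: Weight
    len2: Weight

    def key(self) -> tuple:
        """Canonical identity: the unordered pair of paths."""
        a, b = sorted((self.path1, self.path2))
        return (self.s, self.t, a, b)

    def check(self, g: WeightedDigraph | None = None) -> None:
        """Validate the bubble invariants; raises AssertionError on failure."""
        p1, p2 = self.path1, self.path2
        assert p1[0] == p2[0] == self.s and p1[-1] == p2[-1] == self.t
        assert self.s != self.t
        assert len(p1) >= 2 and len(p2) >= 2 and p1 != p2
        assert len(set(p1)) == len(p1) and len(set(p2)) == len(p2)
        assert set(p1) & set(p2) == {self.s, self.t}
        if g is not None:
            for path, plen in ((p1, self.len1), (p2, self.len2)):
                total = 0
                for u, v in zip(path, path[1:]):
                    arcs = {h: w for h, w, _ in g.out_arcs(u)}
                    assert v in arcs, f"missing arc ({u},{v})"
                    total += arcs[v]
                assert total == plen


@dataclass
class EnumLimits:
    """Stop conditions mirroring the practical enumeration setup: stop after
    ``max_bubbles`` reported bubbles (complex components with more are
    dominated by false positives) or after ``timeout`` seconds on a
    monotonic clock; ``beta`` is the lower bound imposed on both path
    lengths for specificity."""

    max_bubbles: int = 10_000
    timeout: float = 900.0
    beta: Weight = 0

    def __post_init__(self) -> None:
        if self.max_bubbles < 1:
            raise ValueError("max_bubbles must be >= 1")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")


@dataclass
class EnumStats:
    """Instrumentation of one enumeration run.

    ``leaves`` counts recursion leaves (= ordered compatible-path pairs
    found, before the beta / orientation output filters); ``emitted``
    counts bubbles actually yielded.  ``max_gap`` is the largest number of
    recursion-node visits between consecutive leaves, the quantity bounded
    by 4n in the delay analysis.  ``stopped`` records which stop condition
    fired (``"max_bubbles"``, ``"timeout"`` or None).
    """

    nodes: int = 0
    leaves: int = 0
    emitted: int = 0
    filtered_beta: int = 0
    filtered_orientation: int = 0
    max_gap: int = 0
    stopped: str | None = None
    _gap: int = field(default=0, repr=False)

    def _visit_node(self) -> None:
        self.nodes += 1
        self._gap += 1
        if self._gap > self.max_gap:
            self.max_gap = self._gap

    def _visit_leaf(self) -> None:
        self.leaves += 1
        self._gap = 0


class _StopEnumeration(Exception):
    pass


def exists_compatible_pair(g, s1: int, s2: int, alpha1: Weight, alpha2: Weight,
                           heap: str = DEFAULT_HEAP) -> bool:
    """True iff a pair of compatible paths for ``s1 != s2`` exists.

    Certificate: some ``t`` with ``d(s1,t) <= alpha1`` and
    ``d(s2,t) <= alpha2``; the two witness shortest paths, cut at their
    first common vertex, form an internally disjoint pair.  Implemented as
    two truncated Dijkstras and a reached-set intersection test.
    """
    if s1 == s2:
        raise ValueError("exists_compatible_pair requires s1 != s2 "
                         "(the bubble root case is handled separately)")
    if alpha1 < 0 or alpha2 < 0:
        return False
    d1 = dijkstra_truncated(g, s1, alpha1, heap).dist
    d2 = dijkstra_truncated(g, s2, alpha2, heap).dist
    if len(d2) < len(d1):
        d1, d2 = d2, d1
    return any(v in d2 for v in d1)


def exists_bubble_from(g: WeightedDigraph, s: int, alpha1: Weight, alpha2: Weight,
                       heap: str = DEFAULT_HEAP) -> bool:
    """True iff some (s,t,alpha1,alpha2)-bubble exists for the given source.

    For each out-arc ``(s, v)`` we test for a compatible pair for ``s`` and
    ``v`` with budgets ``(alpha1, alpha2 - w(s,v))``.  Two degenerate
    witnesses must be excluded for the test to be exact: paths cycling back
    into ``s`` (which would put the common vertex at ``s``) and a p1-side
    witness equal to the arc ``(s, v)`` itself (which would duplicate p2's
    first arc).  Both are ruled out by removing the in-arcs of ``s`` and
    the tested arc before the shortest-path certificate -- no bubble path
    uses either, so no solution is lost.
    """
    if not g.is_vertex_alive(s):
        raise ValueError(f"source {s} is not an alive vertex")
    delta = GraphDelta(g)
    out = list(g.out_arcs(s))
    try:
        for v, w, aid in out:
            if w > alpha2:
                continue
            delta.checkpoint()
            for _, _, in_aid in list(g.in_arcs(s)):
                g.remove_arc(in_aid, delta)
            g.remove_arc(aid, delta)
            found = exists_compatible_pair(g, s, v, alpha1, alpha2 - w, heap)
            delta.restore()
            if found:
                return True
        return False
    finally:
        while delta.depth:
            delta.restore()


def extension_feasibility(g: WeightedDigraph, u: int, other: int,
                          rem_u: Weight, rem_other: Weight,
                          heap: str = DEFAULT_HEAP) -> dict[int, bool]:
    """For each out-neighbour ``v`` of ``u``: can the pair (other, v) be
    completed in ``G - u`` within budgets ``(rem_other, rem_u - w(u,v))``?

    One truncated Dijkstra from ``other`` in ``G - u`` yields the reached
    set within ``rem_other``; one reverse multi-source Dijkstra from that
    set yields, for every vertex, the distance to the nearest reached
    vertex.  Each out-neighbour is then answered in O(1), so certifying all
    include-arc branches of a recursion node costs two Dijkstra runs total.
    """
    if u == other:
        raise ValueError("extension_feasibility requires u != other")
    if not g.is_vertex_alive(u):
        raise ValueError(f"vertex {u} is not alive")
    out = list(g.out_arcs(u))
    if not out:
        return {}
    delta = GraphDelta(g)
    delta.checkpoint()
    g.remove_vertex(u, delta)
    try:
        reached = dijkstra_truncated(g, other, rem_other, heap).dist
        if reached:
            to_sink = reverse_dist_to_sink(g, reached, bound=rem_u, heap=heap)
        else:
            to_sink = {}
    finally:
        delta.restore()
    result: dict[int, bool] = {}
    for v, w, _ in out:
        budget = rem_u - w
        result[v] = budget >= 0 and v in to_sink and to_sink[v] <= budget
    return result


def _choose_side(g, e1, e2):
    """Extend the p2-side endpoint while it still has out-arcs, else p1."""
    for _ in g.out_arcs(e2):
        return 2
    return 1


def _recurse(g: WeightedDigraph, delta: GraphDelta, stats: EnumStats,
             prefix1: list[int], prefix2: list[int],
             e1: int, e2: int, r1: Weight, r2: Weight,
             len1: Weight, len2: Weight, emit, heap: str,
             deadline: float | None, limits: EnumLimits) -> Iterator[Bubble]:
    stats._visit_node()
    if deadline is not None and time.monotonic() > deadline:
        stats.stopped = "timeout"
        raise _StopEnumeration
    side = _choose_side(g, e1, e2)
    if side == 2:
        u, other, rem_u, rem_other = e2, e1, r2, r1
    else:
        u, other, rem_u, rem_other = e1, e2, r1, r2

    out = list(g.out_arcs(u))
    feas = extension_feasibility(g, u, other, rem_u, rem_other, heap) if out else {}
    for v, w, _ in out:
        if w > rem_u:
            continue
        if v == other:
            # the two paths meet: a recursion leaf holding exactly one pair
            stats._visit_leaf()
            if side == 2:
                p1 = tuple(prefix1)
                p2 = tuple(prefix2) + (v,)
                l1, l2 = len1, len2 + w
            else:
                p1 = tuple(prefix1) + (v,)
                p2 = tuple(prefix2)
                l1, l2 = len1 + w, len2
            yield from emit(Bubble(s=p1[0], t=v, path1=p1, path2=p2,
                                   len1=l1, len2=l2))
        elif feas.get(v, False):
            delta.checkpoint()
            g.remove_vertex(u, delta)
            if side == 2:
                prefix2.append(v)
                yield from _recurse(g, delta, stats, prefix1, prefix2,
                                    e1, v, r1, rem_u - w, len1, len2 + w,
                                    emit, heap, deadline, limits)
                prefix2.pop()
            else:
                prefix1.append(v)
                yield from _recurse(g, delta, stats, prefix1, prefix2,
                                    v, e2, rem_u - w, r2, len1 + w, len2,
                                    emit, heap, deadline, limits)
                prefix1.pop()
            delta.restore()

    # exclude branch: none of u's current out-arcs is used, forcing u = t
    if out:
        delta.checkpoint()
        g.remove_out_arcs(u, delta)
        if exists_compatible_pair(g, e1, e2, r1, r2, heap):
            yield from _recurse(g, delta, stats, prefix1, prefix2,
                                e1, e2, r1, r2, len1, len2,
                                emit, heap, deadline, limits)
        delta.restore()


def enumerate_bubbles(g: WeightedDigraph, s: int, alpha1: Weight, alpha2: Weight,
                      limits: EnumLimits | None = None,
                      stats: EnumStats | None = None,
                      heap: str = DEFAULT_HEAP) -> Iterator[Bubble]:
    """Enumerate every (s,t,alpha1,alpha2)-bubble with both path lengths
    >= ``limits.beta``, each exactly once, as a stream.

    A bubble whose two paths fit the bounds under both role assignments
    would be discovered at two leaves; only the orientation in which
    ``path1``'s first-arc head has the smaller vertex id is reported.  The
    working graph is restored to its input state when the generator is
    exhausted or closed; stop-condition hits are recorded on ``stats``
    (``stats.stopped``), not raised.
    """
    if limits is None:
        limits = EnumLimits()
    if stats is None:
        stats = EnumStats()
    if alpha1 < 0 or alpha2 < 0:
        raise ValueError("alpha bounds must be non-negative")
    if not g.is_vertex_alive(s):
        raise ValueError(f"source {s} is not an alive vertex")

    def emit(b: Bubble) -> Iterator[Bubble]:
        if b.len1 < limits.beta or b.len2 < limits.beta:
            stats.filtered_beta += 1
            return
        # duplicate-orientation canonicalization (stateless)
        if b.len2 <= alpha1 and b.len1 <= alpha2 and b.path2[1] < b.path1[1]:
            stats.filtered_orientation += 1
            return
        stats.emitted += 1
        yield b
        if stats.emitted >= limits.max_bubbles:
            stats.stopped = "max_bubbles"
            raise _StopEnumeration

    deadline = time.monotonic() + limits.timeout if limits.timeout else None
    delta = GraphDelta(g)
    first_arcs = list(g.out_arcs(s))
    try:
        stats._visit_node()  # root
        for v1, w1, _ in first_arcs:          # p1's first arc
            if w1 > alpha1:
                continue
            for v2, w2, _ in first_arcs:      # p2's first arc
                if v2 == v1 or w2 > alpha2:
                    continue
                delta.checkpoint()
                g.remove_vertex(s, delta)
                if exists_compatible_pair(g, v1, v2, alpha1 - w1, alpha2 - w2, heap):
                    yield from _recurse(g, delta, stats, [s, v1], [s, v2],
                                        v1, v2, alpha1 - w1, alpha2 - w2,
                                        w1, w2, emit, heap, deadline, limits)
                delta.restore()
    except _StopEnumeration:
        pass
    finally:
        while delta.depth:
            delta.restore()


def enumerate_all_sources(g: WeightedDigraph, alpha1: Weight, alpha2: Weight,
                          limits: EnumLimits | None = None,
                          bccs=None, heap: str = DEFAULT_HEAP,
                          stats: EnumStats | None = None) -> Iterator[Bubble]:
    """Union of ``enumerate_bubbles`` over all alive sources, deduplicated.

    When ``bccs`` (a sequence of biconnected components as produced by
    :func:`debubble.dbg.bcc_decompose`) is supplied, each component's
    induced subgraph is enumerated independently -- every bubble lies
    entirely within exactly one component -- and bubbles are mapped back to
    original vertex ids.
    """
    if limits is None:
        limits = EnumLimits()
    if stats is None:
        stats = EnumStats()
    seen: set[tuple] = set()
    budget = limits.max_bubbles
    deadline = time.monotonic() + limits.timeout if limits.timeout else None

    def run(graph: WeightedDigraph, id_map=None) -> Iterator[Bubble]:
        nonlocal budget
        for s in list(graph.vertices()):
            if budget < 1:
                stats.stopped = stats.stopped or "max_bubbles"
                return
            timeout = limits.timeout
            if deadline is not None:
                timeout = deadline - time.monotonic()
                if timeout <= 0:
                    stats.stopped = "timeout"
                    return
            st = EnumStats()
            sub_limits = EnumLimits(max_bubbles=budget, timeout=timeout,
                                    beta=limits.beta)
            for b in enumerate_bubbles(graph, s, alpha1, alpha2,
                                       limits=sub_limits, stats=st, heap=heap):
                if id_map is not None:
                    b = Bubble(s=id_map[b.s], t=id_map[b.t],
                               path1=tuple(id_map[v] for v in b.path1),
                               path2=tuple(id_map[v] for v in b.path2),
                               len1=b.len1, len2=b.len2)
                k = b.key()
                if k in seen:
                    continue
                seen.add(k)
                budget -= 1
                yield b
            stats.nodes += st.nodes
            stats.leaves += st.leaves
            stats.emitted += st.emitted
            stats.filtered_beta += st.filtered_beta
            stats.filtered_orientation += st.filtered_orientation
            stats.max_gap = max(stats.max_gap, st.max_gap)
            if st.stopped == "timeout":
                stats.stopped = "timeout"
                return

    if bccs is None:
        yield from run(g)
    else:
        for comp in bccs:
            yield from run(comp.subgraph, id_map=comp.vertices)
    if budget < 1 and stats.stopped is None:
        stats.stopped = "max_bubbles"
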