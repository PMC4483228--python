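"""Truncated single-source shortest paths with pluggable priority queues.

The enumeration machinery never needs full shortest-path trees: every query
is of the form "which vertices lie within distance alpha of the root?".
Dijkstra expansion is therefore truncated at the bound -- a vertex whose
tentative distance exceeds alpha is never pushed -- which on de Bruijn
graphs (after pruning arcs heavier than alpha_1) keeps all keys below
alpha_1 and makes a radix heap applicable.

Three queue variants are provided and must agree exactly:

``bin``
    classic binary heap with decrease-key (indexed heap);
``bin-no-dec``
    binary heap with lazy deletion instead of decrease-key -- the default,
    the variant that wins in practice on sparse compressed DBGs;
``radix``
    one-level radix heap, valid only for non-negative integer weights.

Ties (equal distances) are broken by ascending vertex id so that parent
trees, not only distances, are deterministic across runs.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .graph import GraphDelta, Weight, WeightedDigraph

HEAP_VARIANTS = ("bin", "bin-no-dec", "radix")
DEFAULT_HEAP = "bin-no-dec"

__all__ = ["ShortestPathTree", "dijkstra_truncated", "prune_heavy_arcs",
           "reverse_dist_to_sink", "HEAP_VARIANTS", "DEFAULT_HEAP"]


@dataclass
class ShortestPathTree:
    """Result of a truncated Dijkstra run.

    ``dist`` maps every vertex settled within the bound to its exact
    distance from ``root``; vertices farther than ``alpha`` (or unreachable)
    are absent -- no sentinel infinities.  ``parent`` maps each non-root
    reached vertex to the arc id used to settle it.
    """

    root: int
    alpha: Weight | None
    dist: dict[int, Weight] = field(default_factory=dict)
    parent: dict[int, int] = field(default_factory=dict)

    @property
    def reached(self) -> set[int]:
        """V_alpha: the set of vertices within distance alpha of the root."""
        return set(self.dist)


class _IndexedBinaryHeap:
    """Binary min-heap over (key, vertex) with decrease-key support."""

    def __init__(self) -> None:
        self._heap: list[tuple[Weight, int]] = []
        self._pos: dict[int, int] = {}

    def __len__(self) -> int:
        return len(self._heap)

    def _sift_up(self, i: int) -> None:
        heap, pos = self._heap, self._pos
        item = heap[i]
        while i > 0:
            parent = (i - 1) >> 1
            if heap[parent] <= item:
                break
            heap[i] = heap[parent]
            pos[heap[i][1]] = i
            i = parent
        heap[i] = item
        pos[item[1]] = i

    def _sift_down(self, i: int) -> None:
        heap, pos = self._heap, self._pos
        n = len(heap)
        item = heap[i]
        while True:
            child = 2 * i + 1
            if child >= n:
                break
            if child + 1 < n and heap[child + 1] < heap[child]:
                child += 1
            if item <= heap[child]:
                break
            heap[i] = heap[child]
            pos[heap[i][1]] = i
            i = child
        heap[i] = item
        pos[item[1]] = i

    def push_or_decrease(self, key: Weight, v: int) -> None:
        pos = self._pos.get(v)
        if pos is None:
            self._heap.append((key, v))
            self._sift_up(len(self._heap) - 1)
        elif key < self._heap[pos][0]:
            self._heap[pos] = (key, v)
            self._sift_up(pos)

    def pop(self) -> tuple[Weight, int]:
        heap, pos = self._heap, self._pos
        top = heap[0]
        del pos[top[1]]
        last = heap.pop()
        if heap:
            heap[0] = last
            pos[last[1]] = 0
            self._sift_down(0)
        return top


class _RadixHeap:
    """One-level radix heap for monotone non-negative integer keys.

    Buckets group keys by the position of the highest bit in which they
    differ from the last extracted minimum; extracting from a non-trivial
    bucket advances the minimum and redistributes the bucket.  Stale
    entries are handled by the caller (lazy deletion), so only ``push`` and
    ``pop`` are needed.
    """

    _BUCKETS = 66  # enough for keys up to 2**64

    def __init__(self) -> None:
        self._buckets: list[list[tuple[int, int]]] = [[] for _ in range(self._BUCKETS)]
        self._last = 0
        self._size = 0

    def __len__(self) -> int:
        return self._size

    def _bucket_index(self, key: int) -> int:
        return (key ^ self._last).bit_length()

    def push(self, key: int, v: int) -> None:
        if key < self._last:  # monotonicity violated -> caller bug
            raise AssertionError("radix heap keys must be non-decreasing")
        self._buckets[self._bucket_index(key)].append((key, v))
        self._size += 1

    def pop(self) -> tuple[int, int]:
        buckets = self._buckets
        i = 0
        while not buckets[i]:
            i += 1
        if i > 0:
            # advance the floor to the bucket minimum and redistribute
            bucket = buckets[i]
            buckets[i] = []
            self._last = min(k for k, _ in bucket)
            for item in bucket:
                buckets[self._bucket_index(item[0])].append(item)
        bucket0 = buckets[0]
        # all keys in bucket 0 equal the floor; break ties by vertex id
        j = min(range(len(bucket0)), key=lambda idx: bucket0[idx][1])
        item = bucket0.pop(j)
        self._size -= 1
        return item


def _dijkstra(graph, sources: Iterable[tuple[int, Weight]],
              alpha: Weight | None, heap: str) -> tuple[dict, dict]:
    """Multi-source truncated Dijkstra on any graph-like object.

    ``graph`` needs ``out_arcs(v) -> (head, weight, arc_id)`` and
    ``is_vertex_alive``.  Returns ``(dist, parent)``.
    """
    if heap not in HEAP_VARIANTS:
        raise ValueError(f"unknown heap variant {heap!r}; choose from {HEAP_VARIANTS}")
    dist: dict[int, Weight] = {}
    parent: dict[int, int] = {}
    tentative: dict[int, Weight] = {}
    tentative_arc: dict[int, int | None] = {}

    init = sorted(sources, key=lambda sv: (sv[1], sv[0]))
    for v, d0 in init:
        if alpha is not None and d0 > alpha:
            continue
        if v not in tentative or d0 < tentative[v]:
            tentative[v] = d0
            tentative_arc[v] = None

    if heap == "bin":
        q = _IndexedBinaryHeap()
        for v, d0 in tentative.items():
            q.push_or_decrease(d0, v)
        while len(q):
            d, u = q.pop()
            dist[u] = d
            if tentative_arc[u] is not None:
                parent[u] = tentative_arc[u]
            for v, w, aid in graph.out_arcs(u):
                if v in dist:
                    continue
                nd = d + w
                if alpha is not None and nd > alpha:
                    continue
                if v not in tentative or nd < tentative[v]:
                    tentative[v] = nd
                    tentative_arc[v] = aid
                    q.push_or_decrease(nd, v)
        return dist, parent

    if heap == "radix":
        rq = _RadixHeap()
        for v, d0 in tentative.items():
            if not isinstance(d0, int):
                raise ValueError("radix heap requires integer distances")
            rq.push(d0, v)
        while len(rq):
            d, u = rq.pop()
            if u in dist:
                continue  # stale entry
            dist[u] = d
            if tentative_arc[u] is not None:
                parent[u] = tentative_arc[u]
            for v, w, aid in graph.out_arcs(u):
                if not isinstance(w, int):
                    raise ValueError("radix heap requires non-negative integer weights")
                if v in dist:
                    continue
                nd = d + w
                if alpha is not None and nd > alpha:
                    continue
                if v not in tentative or nd < tentative[v]:
                    tentative[v] = nd
                    tentative_arc[v] = aid
                    rq.push(nd, v)
        return dist, parent

    # bin-no-dec: heapq with lazy deletion; (dist, id) tuples give the
    # ascending-id tie-break for free.
    pq: list[tuple[Weight, int]] = [(d0, v) for v, d0 in tentative.items()]
    heapq.heapify(pq)
    while pq:
        d, u = heapq.heappop(pq)
        if u in dist:
            continue
        dist[u] = d
        if tentative_arc[u] is not None:
            parent[u] = tentative_arc[u]
        for v, w, aid in graph.out_arcs(u):
            if v in dist:
                continue
            nd = d + w
            if alpha is not None and nd > alpha:
                continue
            if v not in tentative or nd < tentative[v]:
                tentative[v] = nd
                tentative_arc[v] = aid
                heapq.heappush(pq, (nd, v))
    return dist, parent


def dijkstra_truncated(g, s: int, alpha: Weight | None,
                       heap: str = DEFAULT_HEAP) -> ShortestPathTree:
    """Shortest-path tree rooted at ``s`` truncated at distance ``alpha``.

    ``alpha=None`` disables truncation.  Works on a :class:`WeightedDigraph`
    or a reverse view.
    """
    if not g.is_vertex_alive(s):
        raise ValueError(f"source {s} is not an alive vertex")
    dist, parent = _dijkstra(g, [(s, 0)], alpha, heap)
    return ShortestPathTree(root=s, alpha=alpha, dist=dist, parent=parent)


def prune_heavy_arcs(g: WeightedDigraph, alpha1: Weight, delta: GraphDelta) -> int:
    """Remove every arc heavier than ``alpha1``; returns the count removed.

    No path of a bubble whose lengths are bounded by ``alpha1 >= alpha2``
    can traverse such an arc, so the bubble set is unchanged.
    """
    heavy = [aid for u in g.vertices() for _, w, aid in g.out_arcs(u) if w > alpha1]
    for aid in heavy:
        g.remove_arc(aid, delta)
    return len(heavy)


def reverse_dist_to_sink(g, sources_at_zero: Iterable[int],
                         bound: Weight | None = None,
                         heap: str = DEFAULT_HEAP) -> dict[int, Weight]:
    """Distances d(v, r) to a virtual sink r reachable at cost 0 from every
    vertex in ``sources_at_zero``.

    Equivalent to ``min_y d(v, y)`` over the source set; computed with one
    multi-source Dijkstra on the reverse view, without materialising r.
    Vertices that cannot reach any source are absent from the mapping.
    """
    sources = [(v, 0) for v in sources_at_zero]
    if not sources:
        raise ValueError("sources_at_zero must be non-empty")
    dist, _ = _dijkstra(g.reverse(), sources, bound, heap)
    return dist
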