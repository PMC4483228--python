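"""Mutable weighted digraph with O(diff) reversible deletions.

The bubble enumerator explores a recursion tree in which every call removes
either a vertex (with its incident arcs) or the out-neighbourhood of a
vertex, and must undo those removals when the call returns.  Copying the
graph per call would break the linear-space bound of the enumeration, so a
single graph instance is mutated in place and every removal is logged in a
:class:`GraphDelta`; popping a checkpoint restores the graph bit-for-bit.

Weights are exact (``int`` or :class:`fractions.Fraction`), never binary
floats, so comparisons against length bounds are exact.  The graph is
simple: parallel arcs and self-loops are rejected at construction (loaders
prune self-loops with a warning before constructing).
"""

from __future__ import annotations

import logging
from fractions import Fraction
from typing import Iterable, Iterator, Sequence

log = logging.getLogger(__name__)

Weight = int | Fraction

__all__ = ["WeightedDigraph", "GraphDelta", "ReverseView", "Weight"]


def _check_weight(w: Weight) -> Weight:
    if isinstance(w, bool) or not isinstance(w, (int, Fraction)):
        raise TypeError(f"arc weight must be int or Fraction, got {type(w).__name__}")
    if w < 0:
        raise ValueError(f"negative arc weight {w}")
    return w


class WeightedDigraph:
    """Simple digraph on dense vertex ids ``0..n_total-1`` with non-negative
    exact arc weights and alive/dead flags supporting reversible deletion.

    Parameters
    ----------
    n_vertices:
        Size of the id space.  All ids in ``arcs`` must be below it.
    arcs:
        Iterable of ``(u, v, w)`` triples.  Self-loops and duplicate
        ``(u, v)`` pairs raise ``ValueError``.
    labels:
        Optional per-vertex string labels (e.g. k-mers); kept for output
        only, never consulted by algorithms.
    """

    __slots__ = ("_tail", "_head", "_weight", "_out", "_in",
                 "_v_alive", "_a_alive", "_n", "_m", "labels")

    def __init__(self, n_vertices: int,
                 arcs: Iterable[tuple[int, int, Weight]] = (),
                 labels: Sequence[str] | None = None):
        if n_vertices < 0:
            raise ValueError("n_vertices must be >= 0")
        self._tail: list[int] = []
        self._head: list[int] = []
        self._weight: list[Weight] = []
        self._out: list[list[int]] = [[] for _ in range(n_vertices)]
        self._in: list[list[int]] = [[] for _ in range(n_vertices)]
        seen: set[tuple[int, int]] = set()
        for u, v, w in arcs:
            if not (0 <= u < n_vertices and 0 <= v < n_vertices):
                raise ValueError(f"arc ({u},{v}) outside vertex range 0..{n_vertices - 1}")
            if u == v:
                raise ValueError(f"self-loop at vertex {u}")
            if (u, v) in seen:
                raise ValueError(f"duplicate arc ({u},{v})")
            seen.add((u, v))
            aid = len(self._tail)
            self._tail.append(u)
            self._head.append(v)
            self._weight.append(_check_weight(w))
            self._out[u].append(aid)
            self._in[v].append(aid)
        # deterministic iteration: neighbours in ascending vertex-id order
        for u in range(n_vertices):
            self._out[u].sort(key=self._head.__getitem__)
            self._in[u].sort(key=self._tail.__getitem__)
        self._v_alive = bytearray(b"\x01" * n_vertices)
        self._a_alive = bytearray(b"\x01" * len(self._tail))
        self._n = n_vertices
        self._m = len(self._tail)
        if labels is not None and len(labels) != n_vertices:
            raise ValueError("labels length must equal n_vertices")
        self.labels = list(labels) if labels is not None else None

    # -- observers ---------------------------------------------------------

    @property
    def n(self) -> int:
        """Number of alive vertices."""
        return self._n

    @property
    def m(self) -> int:
        """Number of alive arcs."""
        return self._m

    @property
    def n_total(self) -> int:
        """Size of the vertex id space (alive or dead)."""
        return len(self._out)

    def is_vertex_alive(self, v: int) -> bool:
        return bool(self._v_alive[v])

    def vertices(self) -> Iterator[int]:
        """Alive vertices in ascending id order."""
        alive = self._v_alive
        return (v for v in range(len(alive)) if alive[v])

    def out_arcs(self, u: int) -> Iterator[tuple[int, Weight, int]]:
        """Alive out-arcs of ``u`` as ``(head, weight, arc_id)``, ascending head."""
        alive = self._a_alive
        for aid in self._out[u]:
            if alive[aid]:
                yield self._head[aid], self._weight[aid], aid

    def in_arcs(self, v: int) -> Iterator[tuple[int, Weight, int]]:
        """Alive in-arcs of ``v`` as ``(tail, weight, arc_id)``, ascending tail."""
        alive = self._a_alive
        for aid in self._in[v]:
            if alive[aid]:
                yield self._tail[aid], self._weight[aid], aid

    def out_degree(self, u: int) -> int:
        return sum(1 for _ in self.out_arcs(u))

    def in_degree(self, v: int) -> int:
        return sum(1 for _ in self.in_arcs(v))

    def arcs(self) -> Iterator[tuple[int, int, Weight]]:
        """All alive arcs ``(u, v, w)`` in arc-id order."""
        alive = self._a_alive
        for aid in range(len(alive)):
            if alive[aid]:
                yield self._tail[aid], self._head[aid], self._weight[aid]

    def arc_set(self) -> set[tuple[int, int, Weight]]:
        return set(self.arcs())

    def weight(self, aid: int) -> Weight:
        return self._weight[aid]

    def arc_ends(self, aid: int) -> tuple[int, int]:
        return self._tail[aid], self._head[aid]

    def snapshot(self) -> tuple:
        """Hashable full-state fingerprint (used by state-hygiene tests)."""
        return (bytes(self._v_alive), bytes(self._a_alive))

    def label_of(self, v: int) -> str:
        return self.labels[v] if self.labels is not None else str(v)

    # -- reversible mutation ----------------------------------------------

    def _kill_arc(self, aid: int, delta: "GraphDelta") -> None:
        self._a_alive[aid] = 0
        self._m -= 1
        delta._log.append(~aid)  # negative tag marks an arc record

    def remove_vertex(self, v: int, delta: "GraphDelta") -> None:
        """Remove ``v`` and every incident alive arc, logging into ``delta``."""
        if not (0 <= v < len(self._out)) or not self._v_alive[v]:
            raise ValueError(f"vertex {v} is unknown or already removed")
        alive = self._a_alive
        for aid in self._out[v]:
            if alive[aid]:
                self._kill_arc(aid, delta)
        for aid in self._in[v]:
            if alive[aid]:
                self._kill_arc(aid, delta)
        self._v_alive[v] = 0
        self._n -= 1
        delta._log.append(v)

    def remove_out_arcs(self, v: int, delta: "GraphDelta") -> None:
        """Remove exactly the alive out-arcs of ``v`` (a no-op if none)."""
        if not (0 <= v < len(self._out)) or not self._v_alive[v]:
            raise ValueError(f"vertex {v} is unknown or already removed")
        alive = self._a_alive
        for aid in self._out[v]:
            if alive[aid]:
                self._kill_arc(aid, delta)

    def remove_arc(self, aid: int, delta: "GraphDelta") -> None:
        if not self._a_alive[aid]:
            raise ValueError(f"arc {aid} already removed")
        self._kill_arc(aid, delta)

    def reverse(self) -> "ReverseView":
        """O(1) view presenting every arc ``(u,v,w)`` as ``(v,u,w)``.

        The view shares liveness with this graph: removals performed on the
        underlying graph are immediately visible through the view.
        """
        return ReverseView(self)


class ReverseView:
    """Read-only reversed presentation of a :class:`WeightedDigraph`."""

    __slots__ = ("_g",)

    def __init__(self, g: WeightedDigraph):
        self._g = g

    @property
    def n(self) -> int:
        return self._g.n

    @property
    def m(self) -> int:
        return self._g.m

    @property
    def n_total(self) -> int:
        return self._g.n_total

    def is_vertex_alive(self, v: int) -> bool:
        return self._g.is_vertex_alive(v)

    def vertices(self) -> Iterator[int]:
        return self._g.vertices()

    def out_arcs(self, u: int) -> Iterator[tuple[int, Weight, int]]:
        return self._g.in_arcs(u)

    def in_arcs(self, v: int) -> Iterator[tuple[int, Weight, int]]:
        return self._g.out_arcs(v)

    def arcs(self) -> Iterator[tuple[int, int, Weight]]:
        return ((v, u, w) for u, v, w in self._g.arcs())

    def reverse(self) -> WeightedDigraph:
        """Reversing a reversed view yields the original graph."""
        return self._g


class GraphDelta:
    """Checkpointed removal log for one :class:`WeightedDigraph`.

    Records are LIFO: :meth:`restore` pops everything down to the most
    recent :meth:`checkpoint`, reviving vertices and arcs in reverse order
    of removal, which restores the graph to a bit-identical state.  Along
    any root-to-leaf removal sequence each arc and vertex is logged at most
    once, so the log never exceeds ``m + n`` records.
    """

    __slots__ = ("g", "_log", "_marks")

    def __init__(self, g: WeightedDigraph):
        self.g = g
        self._log: list[int] = []   # v >= 0: vertex record; ~aid < 0: arc record
        self._marks: list[int] = []

    def checkpoint(self) -> None:
        self._marks.append(len(self._log))

    @property
    def depth(self) -> int:
        return len(self._marks)

    def __len__(self) -> int:
        return len(self._log)

    def restore(self) -> None:
        """Undo every removal since the last checkpoint and pop it."""
        if not self._marks:
            raise ValueError("restore() without a matching checkpoint")
        mark = self._marks.pop()
        g = self.g
        logrec = self._log
        while len(logrec) > mark:
            rec = logrec.pop()
            if rec >= 0:
                g._v_alive[rec] = 1
                g._n += 1
            else:
                g._a_alive[~rec] = 1
                g._m += 1
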