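"""De Bruijn graph construction and the standard preprocessing pipeline.

Sequences are decomposed into k-mers (single-stranded, no
reverse-complement canonicalisation); k-mers below an abundance threshold
are discarded as likely sequencing errors; the k-mer graph links u -> v
whenever the (k-1)-suffix of u equals the (k-1)-prefix of v -- all such
overlaps, not only those observed consecutively in a read.  Maximal
non-branching linear paths are then compressed into single labelled
vertices, and the underlying undirected graph is decomposed into
biconnected components; both steps are lossless for bubbles.

Length convention: in the uncompressed graph every arc has weight 1, so a
path length counts its arcs.  In the compressed graph the arc (u, v)
carries weight ``len(label(v)) - (k - 1)``, i.e. the number of k-mers
merged into v, so that the length of a compressed path from unit U to unit
W equals the number of uncompressed arcs from the last k-mer of U to the
last k-mer of W.  Sums stay exact integers, and length bounds on bubbles
mean the same thing before and after compression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .graph import GraphDelta, WeightedDigraph

log = logging.getLogger(__name__)

ALPHABET = "ACGT"
DEFAULT_MIN_COUNT = 3  # abundance filter: drop k-mers seen fewer times

__all__ = ["KmerTable", "count_kmers", "build_dbg", "CompressedDBG",
           "compress_linear_paths", "BCC", "bcc_decompose",
           "ALPHABET", "DEFAULT_MIN_COUNT"]


@dataclass
class KmerTable:
    """Multiplicities of the k-mers retained from a sequence set."""

    k: int
    counts: dict[str, int]

    def __len__(self) -> int:
        return len(self.counts)

    def kmers(self) -> list[str]:
        return sorted(self.counts)


def count_kmers(sequences: Iterable[str], k: int,
                min_count: int = DEFAULT_MIN_COUNT) -> KmerTable:
    """Sliding-window k-mer counting with an abundance filter.

    Windows containing ``N`` are skipped; any character outside ``ACGTN``
    raises ``ValueError``.  Sequences shorter than ``k`` contribute
    nothing.  Each sequence is counted independently (every occurrence,
    including repeats within one sequence).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    valid = set(ALPHABET) | {"N"}
    counts: dict[str, int] = {}
    for seq in sequences:
        seq = seq.upper()
        bad = set(seq) - valid
        if bad:
            raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
        for i in range(len(seq) - k + 1):
            kmer = seq[i:i + k]
            if "N" in kmer:
                continue
            counts[kmer] = counts.get(kmer, 0) + 1
    if min_count > 1:
        counts = {kmer: c for kmer, c in counts.items() if c >= min_count}
    return KmerTable(k=k, counts=counts)


def build_dbg(table: KmerTable) -> WeightedDigraph:
    """De Bruijn graph of the retained k-mers, unit arc weights.

    One vertex per k-mer (labels kept on the graph, ids assigned in sorted
    k-mer order); an arc for every ordered pair whose (k-1)-suffix/prefix
    match.  Self-overlapping k-mers (e.g. AAA) would yield self-loops,
    which cannot lie on any simple bubble path and are dropped with a
    warning.
    """
    if not table.counts:
        raise ValueError("cannot build a de Bruijn graph from an empty k-mer table")
    kmers = table.kmers()
    idx = {kmer: i for i, kmer in enumerate(kmers)}
    by_prefix: dict[str, list[str]] = {}
    for kmer in kmers:
        by_prefix.setdefault(kmer[:-1], []).append(kmer)
    arcs = []
    dropped_loops = 0
    for kmer in kmers:
        for succ in by_prefix.get(kmer[1:], ()):
            if succ == kmer:
                dropped_loops += 1
                continue
            arcs.append((idx[kmer], idx[succ], 1))
    if dropped_loops:
        log.warning("dropped %d self-loop(s) on self-overlapping k-mers", dropped_loops)
    return WeightedDigraph(len(kmers), arcs, labels=kmers)


@dataclass
class CompressedDBG:
    """Compressed de Bruijn graph: ``graph.labels[v]`` is the merged DNA
    label of unit ``v`` (length >= k) and arcs denote (k-1)-overlaps with
    weight ``len(label(head)) - (k - 1)``."""

    graph: WeightedDigraph
    k: int
    units: list[list[int]]  # original k-mer vertex ids merged into each unit

    def unit_end(self, v: int) -> int:
        """Original-graph id of the last k-mer in unit ``v`` (the vertex at
        which compressed path lengths are anchored)."""
        return self.units[v][-1]


def compress_linear_paths(g: WeightedDigraph, k: int | None = None) -> CompressedDBG:
    """Merge maximal non-branching linear paths into single vertices.

    An arc (u, v) is merged when u has out-degree 1 and v in-degree 1.
    Labels are concatenated minus the (k-1)-overlaps.  Isolated directed
    cycles in which every arc is mergeable have no canonical start and
    cannot contain bubbles; their vertices are left as singleton units.
    Compressed self-loops (a unit whose tail links back to its own head)
    likewise cannot lie on a simple bubble path and are pruned with a
    warning.
    """
    if g.labels is None:
        raise ValueError("compress_linear_paths needs vertex labels")
    if k is None:
        k = len(g.labels[0])
    verts = list(g.vertices())
    outd = {v: g.out_degree(v) for v in verts}
    ind = {v: g.in_degree(v) for v in verts}

    def mergeable(u: int, v: int) -> bool:
        return outd[u] == 1 and ind[v] == 1

    # unit starts: vertices not absorbed through a mergeable unique in-arc
    starts = []
    for v in verts:
        if ind[v] != 1:
            starts.append(v)
        else:
            (u, _, _), = g.in_arcs(v)  # unique in-arc
            if not mergeable(u, v):
                starts.append(v)

    units: list[list[int]] = []
    merged_arcs: set[int] = set()
    in_unit: dict[int, int] = {}
    for start in starts:
        chain = [start]
        cur = start
        while outd[cur] == 1:
            (nxt, _, aid), = g.out_arcs(cur)
            if ind[nxt] != 1 or nxt in in_unit or nxt == start:
                break
            chain.append(nxt)
            merged_arcs.add(aid)
            cur = nxt
        uid = len(units)
        units.append(chain)
        for v in chain:
            in_unit[v] = uid
    # vertices on pure cycles (never reached from a start) stay singleton
    for v in verts:
        if v not in in_unit:
            uid = len(units)
            units.append([v])
            in_unit[v] = uid

    labels = []
    for chain in units:
        label = g.labels[chain[0]]
        for v in chain[1:]:
            label += g.labels[v][k - 1:]
        labels.append(label)

    arcs = []
    dropped_loops = 0
    for u in verts:
        for v, _, aid in g.out_arcs(u):
            if aid in merged_arcs:
                continue
            cu, cv = in_unit[u], in_unit[v]
            if cu == cv:
                dropped_loops += 1
                continue
            arcs.append((cu, cv, len(labels[cv]) - (k - 1)))
    if dropped_loops:
        log.warning("dropped %d compressed self-loop(s)", dropped_loops)
    graph = WeightedDigraph(len(units), arcs, labels=labels)
    return CompressedDBG(graph=graph, k=k, units=units)


@dataclass
class BCC:
    """One biconnected component of the underlying undirected graph:
    original vertex ids (sorted) plus the induced directed subgraph on
    local ids ``0..len(vertices)-1`` (``vertices[i]`` is local id ``i``)."""

    vertices: list[int]
    subgraph: WeightedDigraph


def bcc_decompose(g: WeightedDigraph, min_vertices: int = 4) -> list[BCC]:
    """Biconnected components of the underlying undirected graph.

    Articulation vertices appear in every component they join.  Components
    with fewer than ``min_vertices`` vertices are discarded -- a bubble
    needs at least four vertices, and every bubble lies entirely within
    exactly one component, so the default filter is lossless for bubbles.
    Components are returned sorted by their smallest original vertex id.
    """
    # undirected adjacency over alive vertices
    und: dict[int, set[int]] = {v: set() for v in g.vertices()}
    for u, v, _ in g.arcs():
        und[u].add(v)
        und[v].add(u)

    # iterative Hopcroft-Tarjan DFS; a component is the slice of the edge
    # stack above the tree edge into a subtree with no back edge past its root
    comps: list[set[int]] = []
    visited: set[int] = set()
    disc: dict[int, int] = {}
    low: dict[int, int] = {}
    counter = 0
    for root in und:
        if root in visited:
            continue
        visited.add(root)
        disc[root] = low[root] = counter
        counter += 1
        edge_stack: list[tuple[int, int]] = []
        # frame: (v, parent, neighbour iterator, edge-stack mark at entry)
        frames: list[tuple[int, int | None, object, int]] = [
            (root, None, iter(sorted(und[root])), 0)]
        while frames:
            v, parent, it, mark = frames[-1]
            descended = False
            for w in it:
                if w == parent:
                    continue  # the single tree edge back (graph is simple)
                if w not in visited:
                    visited.add(w)
                    disc[w] = low[w] = counter
                    counter += 1
                    new_mark = len(edge_stack)
                    edge_stack.append((v, w))
                    frames.append((w, v, iter(sorted(und[w])), new_mark))
                    descended = True
                    break
                if disc[w] < disc[v]:  # back edge, recorded once (upwards)
                    edge_stack.append((v, w))
                    if disc[w] < low[v]:
                        low[v] = disc[w]
            if descended:
                continue
            frames.pop()
            if parent is not None:
                if low[v] < low[parent]:
                    low[parent] = low[v]
                if low[v] >= disc[parent]:
                    # parent is an articulation point (or the root) for this
                    # subtree: the edges pushed since entering v form one BCC
                    comp = set()
                    for a, b in edge_stack[mark:]:
                        comp.add(a)
                        comp.add(b)
                    del edge_stack[mark:]
                    comps.append(comp)

    result = []
    for comp in comps:
        if len(comp) < min_vertices:
            continue
        vertices = sorted(comp)
        local = {v: i for i, v in enumerate(vertices)}
        arcs = [(local[u], local[v], w) for u, v, w in g.arcs()
                if u in local and v in local]
        labels = None
        if g.labels is not None:
            labels = [g.labels[v] for v in vertices]
        result.append(BCC(vertices=vertices,
                          subgraph=WeightedDigraph(len(vertices), arcs, labels=labels)))
    result.sort(key=lambda c: c.vertices[0])
    return result
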