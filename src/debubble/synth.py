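"""Seeded synthetic inputs and exhaustive brute-force oracles.

The oracles are written straight from the definitions -- exhaustive simple
path enumeration and pairwise disjointness checks -- and share no code with
the fast enumeration machinery, so agreement between the two is a
meaningful correctness check on small instances.

The sequence generator plants an alternative-splicing-like event: two
transcripts ``a w b`` and ``a w' b`` sharing flanks a and b (each at least
k long) around variable parts w and w' that share no k-mer.  Such a pair
creates a bubble in the de Bruijn graph between the last k-mer of the
common prefix and the first k-mer of the common suffix; when w' is empty
(exon skipping, intron retention, most indels) the junction-side path has
at most k-1 internal vertices.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .bubbles import Bubble
from .graph import WeightedDigraph

__all__ = ["SynthConfig", "random_digraph", "plant_as_event", "PlantedEvent",
           "hamiltonian_reduction_instance", "brute_force_bubbles",
           "brute_force_disjoint_paths", "brute_force_d_bubbles"]

ALPHABET = "ACGT"


@dataclass
class SynthConfig:
    """Parameters of the synthetic generators; the seed fixes everything.

    Graph side: ``n`` vertices, each ordered pair carries an arc with
    probability ``arc_probability``, integer weights uniform in
    ``weight_range`` (inclusive).  Sequence side: word length ``k``, flank
    lengths ``len_a``/``len_b`` (must be >= k) and variable-part lengths
    ``len_w``/``len_w_prime``.
    """

    n: int = 8
    arc_probability: float = 0.3
    weight_range: tuple[int, int] = (1, 3)
    seed: int = 0
    k: int = 8
    len_a: int = 10
    len_b: int = 10
    len_w: int = 12
    len_w_prime: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (0.0 <= self.arc_probability <= 1.0):
            raise ValueError("arc_probability must be in [0, 1]")
        if self.len_a < self.k or self.len_b < self.k:
            raise ValueError("flank lengths must be >= k")
        if min(self.len_w, self.len_w_prime) < 0:
            raise ValueError("variable-part lengths must be >= 0")


def random_digraph(cfg: SynthConfig) -> WeightedDigraph:
    """G(n, p) digraph with integer weights; pure function of the config."""
    rng = random.Random(cfg.seed)
    lo, hi = cfg.weight_range
    arcs = []
    for u in range(cfg.n):
        for v in range(cfg.n):
            if u != v and rng.random() < cfg.arc_probability:
                arcs.append((u, v, rng.randint(lo, hi)))
    return WeightedDigraph(cfg.n, arcs)


@dataclass
class PlantedEvent:
    """An awb / aw'b transcript pair with its predicted bubble endpoints."""

    seq1: str               # a + w + b
    seq2: str               # a + w' + b
    a: str
    b: str
    w: str
    w_prime: str
    source_kmer: str        # last k-mer of the common prefix
    target_kmer: str        # first k-mer of the common suffix
    path1_kmers: list[str] = field(repr=False, default_factory=list)
    path2_kmers: list[str] = field(repr=False, default_factory=list)


def _kmers(seq: str, k: int) -> list[str]:
    return [seq[i:i + k] for i in range(len(seq) - k + 1)]


def _common_prefix_len(x: str, y: str) -> int:
    n = min(len(x), len(y))
    i = 0
    while i < n and x[i] == y[i]:
        i += 1
    return i


def plant_as_event(cfg: SynthConfig, max_tries: int = 1000) -> PlantedEvent:
    """Rejection-sample a clean planted event.

    Acceptance requires the defining constraint (w and w' share no k-mer)
    plus genericity of the random flanks: the two k-mer walks between the
    predicted endpoints must be simple, internally disjoint and avoid the
    endpoints internally -- i.e. no accidental k-mer repeat blurs the
    planted bubble.  Pathological configurations (tiny alphabet, huge k)
    exhaust the retry budget and raise.
    """
    rng = random.Random(cfg.seed)
    k = cfg.k
    for _ in range(max_tries):
        a = "".join(rng.choice(ALPHABET) for _ in range(cfg.len_a))
        b = "".join(rng.choice(ALPHABET) for _ in range(cfg.len_b))
        w = "".join(rng.choice(ALPHABET) for _ in range(cfg.len_w))
        wp = "".join(rng.choice(ALPHABET) for _ in range(cfg.len_w_prime))
        if set(_kmers(w, k)) & set(_kmers(wp, k)):
            continue
        seq1, seq2 = a + w + b, a + wp + b
        if seq1 == seq2:
            continue
        c = _common_prefix_len(seq1, seq2)
        e = _common_prefix_len(seq1[::-1], seq2[::-1])
        # branch point and rejoin point must leave both walks >= 1 arc
        if c - k < 0 or c >= min(len(seq1), len(seq2)) - e + k - 1:
            continue
        source = seq1[c - k:c]
        target = seq1[len(seq1) - e:len(seq1) - e + k]
        walk1 = [seq1[i:i + k] for i in range(c - k, len(seq1) - e + 1)]
        walk2 = [seq2[i:i + k] for i in range(c - k, len(seq2) - e + 1)]
        if walk1[-1] != target or walk2[-1] != target or source == target:
            continue
        ok = True
        for walk in (walk1, walk2):
            if len(set(walk)) != len(walk):
                ok = False
        inner1, inner2 = set(walk1[1:-1]), set(walk2[1:-1])
        if inner1 & inner2 or {source, target} & (inner1 | inner2):
            ok = False
        # the planted walks must not re-enter the flank k-mers elsewhere
        flank = (set(_kmers(seq1, k)) | set(_kmers(seq2, k))) - set(walk1) - set(walk2)
        if (inner1 | inner2) & flank:
            ok = False
        if not ok:
            continue
        return PlantedEvent(seq1=seq1, seq2=seq2, a=a, b=b, w=w, w_prime=wp,
                            source_kmer=source, target_kmer=target,
                            path1_kmers=walk1, path2_kmers=walk2)
    raise RuntimeError(f"plant_as_event: rejection budget exhausted for {cfg}")


def hamiltonian_reduction_instance(g: WeightedDigraph, s: int, t: int
                                   ) -> tuple[WeightedDigraph, int]:
    """Hardness-style stress instance for the lower-bound filter.

    Adds s' and t', the arcs (s', s) and (t, t'), and a fresh corridor of
    exactly |V| vertices from s' to t', all with unit weights.  The result
    contains a bubble whose two path lengths both equal |V| + 1 (i.e. both
    paths have |V| + 2 vertices) iff ``g`` has a Hamiltonian s -> t path:
    one side is the corridor, the other must thread through every original
    vertex.  Returns ``(G', bound)`` with ``bound = |V| + 1``, the value to
    use for alpha1, alpha2 and beta in length units.
    """
    if s == t:
        raise ValueError("s and t must differ")
    nv = g.n
    base = g.n_total
    s_prime, t_prime = base, base + 1
    corridor = list(range(base + 2, base + 2 + nv))
    arcs = list(g.arcs())
    arcs.append((s_prime, s, 1))
    arcs.append((t, t_prime, 1))
    chain = [s_prime] + corridor + [t_prime]
    for u, v in zip(chain, chain[1:]):
        arcs.append((u, v, 1))
    return WeightedDigraph(base + 2 + nv, arcs), nv + 1


def _simple_paths_from(g: WeightedDigraph, s: int, max_len) -> list[tuple[tuple[int, ...], int]]:
    """All simple directed paths (>= 1 arc) from s with length <= max_len."""
    out: list[tuple[tuple[int, ...], int]] = []

    def dfs(path: list[int], length, on_path: set[int]) -> None:
        for v, w, _ in g.out_arcs(path[-1]):
            if v in on_path:
                continue
            nl = length + w
            if max_len is not None and nl > max_len:
                continue
            path.append(v)
            on_path.add(v)
            out.append((tuple(path), nl))
            dfs(path, nl, on_path)
            on_path.remove(v)
            path.pop()

    dfs([s], 0, {s})
    return out


def brute_force_bubbles(g: WeightedDigraph, s: int, alpha1, alpha2,
                        beta=0, max_n: int = 12) -> set[Bubble]:
    """Definition-level bubble oracle: enumerate all simple paths from s,
    test every pair for a shared endpoint, exact {s,t} intersection and the
    length bounds, then canonicalize orientation exactly like the fast
    enumerator (path1 is the orientation-valid path whose first-arc head is
    smaller when both role assignments fit the bounds)."""
    if g.n > max_n:
        raise ValueError(f"brute-force oracle limited to n <= {max_n}")
    paths = _simple_paths_from(g, s, max(alpha1, alpha2))
    found: set[Bubble] = set()
    for i, (p, lp) in enumerate(paths):
        for q, lq in paths[i + 1:]:
            if p[-1] != q[-1]:
                continue
            if set(p) & set(q) != {s, p[-1]}:
                continue
            fwd = lp <= alpha1 and lq <= alpha2
            rev = lq <= alpha1 and lp <= alpha2
            if fwd and rev:
                first = (p, lp, q, lq) if p[1] < q[1] else (q, lq, p, lp)
            elif fwd:
                first = (p, lp, q, lq)
            elif rev:
                first = (q, lq, p, lp)
            else:
                continue
            p1, l1, p2, l2 = first
            if l1 < beta or l2 < beta:
                continue
            found.add(Bubble(s=s, t=p[-1], path1=p1, path2=p2, len1=l1, len2=l2))
    return found


def brute_force_ordered_pairs(g: WeightedDigraph, s: int, alpha1, alpha2,
                              max_n: int = 12) -> int:
    """Number of ordered compatible-path pairs (the pre-filter leaf count of
    the enumerator): orientations counted separately when both fit."""
    if g.n > max_n:
        raise ValueError(f"brute-force oracle limited to n <= {max_n}")
    paths = _simple_paths_from(g, s, max(alpha1, alpha2))
    count = 0
    for i, (p, lp) in enumerate(paths):
        for q, lq in paths[i + 1:]:
            if p[-1] != q[-1] or set(p) & set(q) != {s, p[-1]}:
                continue
            count += (lp <= alpha1 and lq <= alpha2)
            count += (lq <= alpha1 and lp <= alpha2)
    return count


def _all_simple_paths(g: WeightedDigraph, s: int, t: int) -> list[tuple[int, ...]]:
    return [p for p, _ in _simple_paths_from(g, s, None) if p[-1] == t]


def brute_force_disjoint_paths(g: WeightedDigraph, s: int, t: int,
                               max_n: int = 8) -> tuple[int, list[tuple[tuple[int, ...], ...]]]:
    """Maximum number of pairwise internally vertex-disjoint s->t paths and
    one maximum witness family per maximal size, by exhaustive search."""
    best, families = 0, []
    for d, fams in enumerate(brute_force_d_bubbles_by_size(g, s, t, max_n)):
        if fams:
            best = d + 1
            families = fams
    return best, families


def brute_force_d_bubbles_by_size(g: WeightedDigraph, s: int, t: int,
                                  max_n: int = 8) -> list[list[tuple[tuple[int, ...], ...]]]:
    """families[d-1] = all unordered families of d pairwise internally
    disjoint simple s->t paths (exhaustive; intended for n <= max_n)."""
    if g.n > max_n:
        raise ValueError(f"brute-force oracle limited to n <= {max_n}")
    if s == t:
        raise ValueError("s and t must differ")
    paths = _all_simple_paths(g, s, t)
    interiors = [frozenset(p[1:-1]) for p in paths]
    results: list[list[tuple[tuple[int, ...], ...]]] = []

    def extend(start: int, chosen: list[int], used: frozenset) -> None:
        d = len(chosen)
        if d > 0:
            while len(results) < d:
                results.append([])
            results[d - 1].append(tuple(sorted(paths[i] for i in chosen)))
        for j in range(start, len(paths)):
            if interiors[j] & used:
                continue
            extend(j + 1, chosen + [j], used | interiors[j])

    extend(0, [], frozenset())
    return results


def brute_force_d_bubbles(g: WeightedDigraph, s: int, t: int, d: int,
                          max_n: int = 8) -> set[tuple]:
    """All (s,t)-d-bubbles as canonical keys, by exhaustive family search."""
    by_size = brute_force_d_bubbles_by_size(g, s, t, max_n)
    if len(by_size) < d:
        return set()
    return {(s, t, fam) for fam in by_size[d - 1]}
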