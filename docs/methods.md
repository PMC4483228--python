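# Methods

## Model

All computation happens on a simple directed graph with non-negative exact
arc weights (integers or `fractions.Fraction`; binary floats are rejected
so that comparisons against the length bounds α₁, α₂, β are exact). A
path's length is the sum of its arc weights. An (s,t,α₁,α₂)-bubble is a
pair of internally vertex-disjoint (s,t)-paths p₁, p₂ with |p₁| ≤ α₁ and
|p₂| ≤ α₂; both paths must have at least one arc and s ≠ t.

In the de Bruijn graph use case the weights are nucleotide counts: the
uncompressed k-mer graph has unit weights, and after linear-path
compression the arc (u, v) carries `len(label(v)) − (k−1)`, the number of
k-mers merged into v. With this convention the length of a compressed
path from unit U to unit W equals the number of uncompressed arcs from the
last k-mer of U to the last k-mer of W, so length bounds keep their
meaning across compression (verified mechanically by comparing all
compressed shortest-path distances between unit-end vertices with the
uncompressed ones).

## The enumerator

The recursion state is a pair of partial paths with endpoints (e₁, e₂)
and remaining budgets (r₁, r₂); prefix interiors are removed from the
working graph, so any completion is automatically disjoint from them. The
solution space — pairs of completion paths to a common target, within
budgets, sharing no vertex but that target — is partitioned on the
out-arcs of one endpoint u: one branch per arc (u, v) (solutions whose
u-side continues with that arc, explored in G − u with the budget reduced
by w(u,v)) and one branch with all of δ⁺(u) deleted (solutions in which u
itself is the target). When an extension arc reaches the *other*
endpoint, the two partial paths have met: that recursion leaf holds
exactly one solution, which is emitted.

Branch certificates keep every entered subtree non-empty:

* **Pairwise test.** A pair of compatible paths for e₁ ≠ e₂ exists iff
  some t satisfies d(e₁,t) ≤ r₁ and d(e₂,t) ≤ r₂; cutting the two witness
  shortest paths at their first common vertex yields a disjoint pair (the
  cut can land on e₁ or e₂ itself, which corresponds to one completion
  being empty — a valid continuation mid-recursion since the prefixes
  already carry arcs). Implemented as two truncated Dijkstras plus a
  reached-set intersection.
* **Batched arc test.** All out-arc branches of u are certified together:
  one truncated Dijkstra from the other endpoint in G − u gives the set
  V_r of vertices within its budget; one multi-source Dijkstra on the
  reverse graph, seeded at V_r with distance 0 (the "virtual sink"
  construction), gives for every v the distance to the nearest member of
  V_r; each out-neighbour is then answered in O(1). Two Dijkstra runs per
  recursion node instead of one per out-arc is what brings the delay to
  O(n(m + n log n)).

**Root case.** The generic step cannot start from e₁ = e₂ = s (removing s
would destroy both paths), so the root branches over ordered pairs of
distinct first arcs out of s, removes s, and enters the generic recursion
with both prefixes seeded. Each ordered pair is gated by the pairwise
test in G − s; because s is gone, no degenerate witness can cycle back
into the source.

**Source-existence test.** The standalone `exists_bubble_from` tests, for
each arc (s, v), a compatible pair for (s, v) with budgets
(α₁, α₂ − w(s,v)). Two degenerate witnesses must be excluded: a path
cycling back into s (the cut lands on s, giving a closed walk rather than
a bubble) and a p₁-witness equal to the arc (s, v) itself (the two paths
would coincide). Both are removed structurally — the in-arcs of s and the
tested arc are deleted before the test — which loses no genuine bubble
since bubble paths never re-enter s and p₁ never uses p₂'s first arc.

**Duplicate orientation.** A bubble whose two paths fit the bounds under
both role assignments is discovered at two leaves (the role assignment is
part of the search space). The two discoveries are collapsed by a
stateless filter: emit only the orientation whose p₁ first-arc head has
the smaller vertex id when both orientations are valid. The filter is
deliberately *not* pushed into the branch certificates: excluding the
duplicate orientation inside the recursion would impose a lower-bound
constraint on path lengths, and bubble existence under a lower bound is
NP-hard (see the stress construction below). The same reasoning applies
to β, which is likewise an output filter. Consequently the delay
guarantee — at most 4n recursion nodes between consecutive leaves, each
leaf carrying one ordered solution — is stated and instrumented on the
leaf stream; the `EnumStats` object exposes the leaf count, the emitted
count, and the maximal node gap, and the test suite checks the leaf count
against an independent ordered-pair oracle.

**Reversible deletions.** The recursion mutates one shared graph through
alive flags with a checkpointed log (`GraphDelta`); restoring a
checkpoint revives records in LIFO order, and along any root-to-leaf
branch each arc and vertex is logged at most once, giving the O(m+n)
space bound. The enumerator restores the graph in a `finally` block, so
abandoning the generator mid-stream also leaves the graph bit-identical.

**Determinism.** Out-neighbours are iterated in ascending head id,
equal-distance heap entries pop in ascending vertex id, and all output
writers sort canonically, so identical inputs give byte-identical
outputs across runs.

## Shortest-path machinery

Truncated Dijkstra never pushes a tentative distance above the bound α,
so unreached vertices are simply absent (no sentinel infinities). Three
queues are provided: an indexed binary heap with decrease-key (`bin`), a
lazy-deletion binary heap (`bin-no-dec`, the default — the variant that
wins in practice on sparse bounded-degree compressed DBGs), and a
one-level radix heap (`radix`) valid for integer weights, whose key range
is bounded once arcs heavier than α₁ are pruned (`prune_heavy_arcs`; such
arcs can sit on no bubble path, verified by a before/after bubble-set
comparison). All variants must produce identical distance maps; the suite
checks them against each other and against Bellman–Ford. A Fibonacci
heap variant is not provided: its asymptotics are better on paper but it
is dominated in practice on these sparse graphs.

## d-bubbles

For path sets without length constraints, vertex splitting (v → v_in →
v_out, all capacities 1, arcs (u,v) → (u_out, v_in)) turns internal
vertex disjointness into arc disjointness; flow is routed from s_out to
t_in, so the endpoints' internal arcs never constrain it and d paths may
start and end there. `max_disjoint_paths` runs at most d BFS augmenting
iterations (O(md)) and decomposes the resulting flow into explicit paths
by walking saturated arcs — unit internal capacities make every walk
simple and the extracted family pairwise internally disjoint.

Enumeration cannot be reduced to flow enumeration (adding a circulation
changes the flow but not the path set, so exponentially many flows can
encode one d-bubble). Instead the binary partition generalizes: the state
is the multiset S of current path endpoints, the smallest endpoint ≠ t is
expanded, and each branch is gated by a flow test on a super-source
network (one arc per distinct source, capacity = its multiplicity in S).
Internal capacities stay 1, so a repeated non-target endpoint is
correctly infeasible — two partial paths meeting anywhere but t can never
complete disjointly. The root multiset {s × d} is handled by branching
over unordered d-subsets of distinct first arcs, which also makes each
unordered d-bubble appear exactly once. The choice of which endpoint to
expand is validated by oracle equivalence against exhaustive family
enumeration.

Length-constrained d-bubbles are refused at the API level
(`length_constrained_d_bubbles` raises): for d ≥ 2 with both endpoints
fixed the decision problem contains min-max two-disjoint-paths, which is
NP-complete, and for free target it is NP-hard from d ≥ 3.

## Synthetic data and oracles

The oracles (`brute_force_bubbles`, `brute_force_disjoint_paths`,
`brute_force_d_bubbles`) are written directly from the definitions —
exhaustive DFS over simple paths, pairwise disjointness tests, the same
canonical orientation rule — and share no code with the fast paths. They
guard themselves against large inputs (n ≤ 12 / n ≤ 8).

`random_digraph` draws each ordered pair independently (G(n,p) style)
with integer weights; every generator is a pure function of its
`SynthConfig`, whose seed fixes all randomness. The suite's standard
conditions are n in 4..10, arc probability 0.3, weights 1..3, with bound
settings (6,6), (6,4) and (5,5) plus β ∈ {0, 2} — small enough for
exhaustive oracles, dense enough that bubbles are common.

`plant_as_event` emulates the sequence-level origin of a bubble: flanks a
and b (each ≥ k, defaults 10 with k = 8) around variable parts w and w′
(defaults: |w| = 12, w′ empty — the exon-skipping shape; tests also use
|w′| = 5). Acceptance requires the defining constraint (w and w′ share no
k-mer) plus genericity of the random draw: the two predicted k-mer walks
between the branch point (last k-mer of the common sequence prefix) and
the rejoin point (first k-mer of the common suffix) must be simple,
internally disjoint, avoid the endpoints internally and not recur in the
flanks. These conditions are exactly what makes the textbook
sequence-to-bubble correspondence hold; rejected draws are resampled (the
rejection rate is a few percent at the defaults). What the generator does
*not* emulate: sequencing errors, coverage fluctuation, reverse-strand
reads and genuine repeat structure — so passing tests show the graph
machinery is correct, not that the abundance filter or the β/α defaults
are well-tuned for any particular library.

The Hamiltonian stress instance wires a fresh corridor of |V| vertices
between two new terminals s′ → s and t → t′. Both bubble paths then have
exactly |V| + 1 arcs (|V| + 2 vertices), and a bubble surviving the
filter α₁ = α₂ = β = |V| + 1 exists iff the base graph has a Hamiltonian
s→t path. The bounds are returned by the constructor in arc-length units;
note the construction's natural bookkeeping is in vertex counts
(|V| + 2), which differ by one from lengths on unit-weight graphs.

## Preprocessing

k-mer counting is single-stranded (no reverse-complement
canonicalization; the worked examples and the planted-event
correspondence are single-stranded — a `--canonical` mode would be a
strict extension). Windows containing N are skipped; the abundance
filter defaults to `min_count = 3`, the usual error-removal threshold,
but every entry point exposes it. The DBG links *all* (k−1)-overlaps
among retained k-mers, not only read-adjacent ones. Self-loops
(self-overlapping k-mers such as AAA, or a compressed unit looping onto
itself) are pruned with a warning — no simple bubble path can use them.

Linear-path compression merges the arc (u, v) when u has out-degree 1 and
v in-degree 1; isolated directed cycles, where every arc is mergeable,
have no canonical start and cannot contain bubbles, so their vertices
stay singleton units. Biconnected components of the underlying undirected
graph are computed with an iterative Hopcroft–Tarjan DFS (cross-checked
against networkx in the tests); components below `min_vertices = 4` are
discarded since a bubble needs four vertices, and every bubble lies
entirely within one component (checked by comparing whole-graph
enumeration with per-component enumeration at `min_vertices = 1`).

One further preprocessing step used by downstream AS-event pipelines —
merging "non-branching bubbles with equal path lengths" — is defined in
the surrounding tool ecosystem rather than by this package's model and is
intentionally not implemented.

## Limits, sizes, degenerate inputs

* `EnumLimits` defaults: 10,000 bubbles (components beyond that are
  dominated by artifact bubbles) and a 900 s monotonic-clock timeout,
  checked at recursion-node entry; hits set `stats.stopped`, they do not
  raise.
* `enumerate_all_sources` deduplicates via a seen-set (memory bounded by
  output size; the O(m+n) space claim applies to the fixed-source
  enumerator) and can iterate per biconnected component.
* Empty graphs, sources with out-degree < 2, α = 0 and β larger than any
  path all yield empty streams, not errors; misuse (dead vertices,
  restore without checkpoint, s = t) raises `ValueError`.
* Test-suite problem sizes — 500 oracle graphs at n ≤ 10, 200 heap /
  Menger graphs, 100 planted events — complete in well under a minute in
  total; the oracle sizes are dictated by the exhaustive searches, which
  grow factorially beyond n ≈ 12.
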