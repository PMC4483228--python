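"""Preprocessing: linear-path compression and biconnected components.

Compression merges non-branching chains into single labelled vertices while
preserving every path length (arc weights record the merged k-mer counts);
the biconnected-component decomposition then isolates the regions that can
contain bubbles.
"""

from debubble import bcc_decompose, build_dbg, compress_linear_paths, count_kmers

graph = build_dbg(count_kmers(["ACTGGAGCG", "ACTGCG"], k=3, min_count=1))
cdbg = compress_linear_paths(graph, k=3)

print(f"uncompressed: {graph.n} vertices / {graph.m} arcs")
print(f"compressed:   {cdbg.graph.n} vertices / {cdbg.graph.m} arcs")
for u, v, w in sorted(cdbg.graph.arcs()):
    print(f"  {cdbg.graph.labels[u]:>7} -> {cdbg.graph.labels[v]:<7} weight {w}")
# weight(u, v) = len(label(v)) - (k-1): compressed path lengths equal
# uncompressed arc counts, so bubble length bounds mean the same thing.

for comp in bcc_decompose(graph, min_vertices=4):
    names = [graph.labels[v] for v in comp.vertices]
    print(f"retained biconnected component ({len(names)} vertices): {names}")
# The ACT-CTG bridge is a 2-vertex component: discarded, it cannot hold a bubble.
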