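"""Two transcripts differing by a skipped segment -> one bubble.

Builds the de Bruijn graph (k=3) of ACTGGAGCG and ACTGCG, enumerates
length-bounded bubbles from the branch k-mer CTG and prints the two paths.
"""

from debubble import build_dbg, count_kmers, enumerate_bubbles

sequences = ["ACTGGAGCG", "ACTGCG"]  # a-w-b and a-b: an exon-skipping-like pair
table = count_kmers(sequences, k=3, min_count=1)
graph = build_dbg(table)
print(f"de Bruijn graph: {graph.n} k-mers, {graph.m} overlap arcs")

source = graph.labels.index("CTG")
for bubble in enumerate_bubbles(graph, source, alpha1=5, alpha2=2):
    p1 = "->".join(graph.labels[v] for v in bubble.path1)
    p2 = "->".join(graph.labels[v] for v in bubble.path2)
    print(f"bubble from {graph.labels[bubble.s]} to {graph.labels[bubble.t]}:")
    print(f"  inclusion path ({bubble.len1} nt of arcs): {p1}")
    print(f"  junction path  ({bubble.len2} nt of arcs): {p2}")
    print(f"  internal vertices on the junction path: {len(bubble.path2) - 2}")

# The junction path has k-1-1 = 1 internal vertex: the skipped segment GGA
# shares its first letter G with the downstream flank GCG.
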