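"""Plant an alternative-splicing-like event and recover it.

The generator draws transcripts a+w+b and a+w'+b whose variable parts share
no k-mer, predicts the bubble endpoints (branch and rejoin k-mers), and the
enumerator finds a bubble between exactly those endpoints.
"""

from debubble import SynthConfig, build_dbg, count_kmers, enumerate_bubbles, plant_as_event

cfg = SynthConfig(seed=11, k=8, len_a=10, len_b=10, len_w=12, len_w_prime=0)
event = plant_as_event(cfg)
print(f"transcript 1 (a+w+b): {event.seq1}")
print(f"transcript 2 (a+b):   {event.seq2}")
print(f"predicted endpoints: {event.source_kmer} .. {event.target_kmer}")

graph = build_dbg(count_kmers([event.seq1, event.seq2], cfg.k, min_count=1))
ids = {lab: i for i, lab in enumerate(graph.labels)}
alpha = len(event.seq1)
hits = [b for b in enumerate_bubbles(graph, ids[event.source_kmer], alpha, alpha)
        if b.t == ids[event.target_kmer]]
print(f"bubbles recovered between the predicted endpoints: {len(hits)}")
b = hits[0]
shorter = min((b.path1, b.path2), key=len)
print(f"junction-side internal vertices: {len(shorter) - 2} (bound: k-1 = {cfg.k - 1})")
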