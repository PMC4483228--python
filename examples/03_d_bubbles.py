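"""d-bubbles: d pairwise internally vertex-disjoint (s,t)-paths.

Three parallel corridors admit three disjoint paths; unit-capacity max flow
on the split network counts them, and the binary-partition enumerator lists
every unordered family of a requested size exactly once.
"""

from debubble import WeightedDigraph, enumerate_d_bubbles, max_disjoint_paths

# s=0 -> {1,2,3} -> t=4
corridors = WeightedDigraph(5, [(0, 1, 1), (0, 2, 1), (0, 3, 1),
                                (1, 4, 1), (2, 4, 1), (3, 4, 1)])

flow, witness = max_disjoint_paths(corridors, 0, 4, d_cap=3)
print(f"max internally disjoint 0->4 paths (Menger number): {flow}")
for p in witness:
    print(f"  witness path: {'->'.join(map(str, p))}")

for d in (2, 3):
    families = list(enumerate_d_bubbles(corridors, 0, 4, d))
    print(f"d={d}: {len(families)} d-bubble(s)")  # choose(3,2)=3 and choose(3,3)=1
    for db in families:
        print("   ", " | ".join("->".join(map(str, p)) for p in db.paths))
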