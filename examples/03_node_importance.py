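"""Score node importance on a small directed graph with simplified PageRank
and compare with classical topological measures on an undirected network.

The five-node graph is built so that node A's in-neighbors B, C, E each have
two outgoing links: the fixed point then satisfies
s_A = s_B/2 + s_C/2 + s_E/2 exactly.
"""

import numpy as np

from unibrainnet import BinaryGraph, make_toy_graph, node_scores, pagerank

edges = [
    (0, 1), (0, 2), (0, 4),  # A -> B, C, E
    (1, 0), (1, 3),          # B -> A, D
    (2, 0), (2, 3),          # C -> A, D
    (3, 1),                  # D -> B
    (4, 0), (4, 3),          # E -> A, D
]
graph = BinaryGraph.from_matrix(make_toy_graph(5, edges))
scores = pagerank(graph)
names = "ABCDE"
print("simplified PageRank:",
      ", ".join(f"{n}={s:.4f}" for n, s in zip(names, scores.s)))
lhs = scores.s[0]
rhs = scores.s[1] / 2 + scores.s[2] / 2 + scores.s[4] / 2
print(f"fixed-point check: s_A={lhs:.6f} vs s_B/2+s_C/2+s_E/2={rhs:.6f}")

# comparators on an undirected ring with one chord
ring = [(i, (i + 1) % 6) for i in range(6)] + [(0, 3)]
ring += [(v, u) for u, v in ring]
b = BinaryGraph.from_matrix(make_toy_graph(6, ring))
for method in ("avgdeg", "clustering", "closeness", "radiality"):
    s = node_scores(b, method).s
    print(f"{method:10s}: {np.round(s, 3)}")
# Node 0 and 3 carry the chord, so degree/closeness single them out.
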