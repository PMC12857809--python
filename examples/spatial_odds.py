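"""Quantify epithelial-immune mingling with the geometric odds ratio OR*.

Simulates three ROIs at increasing mixing levels, builds each ROI's 50-um
Delaunay proximity graph, and prints OR* with a permutation-null p-value.
OR* near 0 means the two cell types are spatially segregated; OR* near 1
means their contacts look like random labeling; larger values would mean
preferential cross-type contact.
"""

import numpy as np

from epimm import (
    SpatialSimConfig,
    build_proximity_graph,
    classify_edges,
    compute_interaction_odds,
    permutation_null,
    simulate_spatial_roi,
)

print(f"{'mixing':>7} {'eAB':>5} {'OR*':>8} {'corrected':>9} {'perm p':>8}")
for lam in (0.0, 0.5, 1.0):
    cfg = SpatialSimConfig(n_epi=100, n_imm=100, mixing=lam, seed=7,
                           roi_id=f"roi_lambda_{lam}")
    cells = simulate_spatial_roi(cfg)
    graph = build_proximity_graph(cells, max_edge_len=50)
    counts = classify_edges(graph, "EPI", "IMM")
    result = compute_interaction_odds(counts)
    null = permutation_null(graph, "EPI", "IMM", n_perm=500, seed=7)
    print(f"{lam:>7.2f} {counts.eAB:>5d} {result.OR_star:>8.4f} "
          f"{str(result.corrected):>9} {null.empirical_p:>8.3f}")

print("\nSegregated tissue (mixing 0) gives OR* near 0 with p near 1 under the")
print("one-sided 'greater mixing than random' test; fully mixed tissue gives")
print("OR* near 1 and an unexceptional p.")
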