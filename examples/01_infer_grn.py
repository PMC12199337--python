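"""Infer a gene-regulatory network from synthetic single-cell counts.

Builds a small dataset in which two TFs each drive eight target genes,
runs the triplet information decomposition, and shows that the true edges
receive the highest weights.
"""

import numpy as np

from tfactnet import generate_truth, infer_grn, simulate_counts
from tfactnet.preprocess import filter_genes

truth = generate_truth(n_tfs=2, targets_per_tf=8, cells_per_type=80,
                       seed=0, n_background=20)
expr = filter_genes(simulate_counts(truth, seed=1), min_cells=5)
print(f"data: {expr.n_genes} genes x {expr.n_cells} cells "
      f"({len(truth.true_edges)} true edges)")

grn = infer_grn(expr, regulators=truth.tf_ids)

true_pairs = {(r, t) for r, t, _ in truth.true_edges.edges}
ranked = sorted(grn.edges, key=lambda e: -e[2])
print("\ntop 10 inferred edges (weight in (0, 1]; * marks a true edge):")
for r, t, w in ranked[:10]:
    mark = "*" if (r, t) in true_pairs else " "
    print(f"  {mark} {r} -> {t}   W = {w:.3f}")

top_n = len(true_pairs)
hits = sum((r, t) in true_pairs for r, t, _ in ranked[:top_n])
print(f"\n{hits}/{top_n} true edges among the top-{top_n} weights; a high "
      "fraction means expression alone already ranks the regulator's "
      "targets above unrelated gene pairs.")
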