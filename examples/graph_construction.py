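"""Build one graph sample from an EEG window and inspect its pieces.

The adjacency blends the Pearson correlation R of the channel signals
with a block-constant brain-region similarity H:  A = R + lambda * H
(lambda = 0.5).  Self-loops are added and the matrix is symmetrically
degree-normalized into the propagation operator A_hat used by the graph
convolution layers.
"""

import numpy as np

from gfacnn import (
    GraphConfig, build_adjacency, build_graph_sample, normalize_adjacency,
    pearson_matrix, region_similarity, simulate_segment,
)
from gfacnn.montage import DEFAULT_REGION_MAP

seg = simulate_segment("resistant", seed=5)

R = pearson_matrix(seg)
H = region_similarity(seg, DEFAULT_REGION_MAP)
comp = build_adjacency(R, H, lam=0.5)
norm = normalize_adjacency(comp, negative_policy="abs")

names = seg.channel_names
print("window:", seg.samples.shape, "at", seg.fs, "Hz")
print(f"R range  [{R.min():+.3f}, {R.max():+.3f}]   "
      f"(Pearson correlation of channel signals)")
print(f"H range  [{H.min():+.3f}, {H.max():+.3f}]   "
      f"(region similarity, block-constant)")
print(f"A = R + 0.5 H   range [{comp.A.min():+.3f}, {comp.A.max():+.3f}]")
print(f"A_hat: symmetric={np.allclose(norm.A_hat, norm.A_hat.T)}, "
      f"eigenvalues in [{np.linalg.eigvalsh(norm.A_hat).min():+.3f}, "
      f"{np.linalg.eigvalsh(norm.A_hat).max():+.3f}]")

i, j = names.index("F3"), names.index("F4")
k = names.index("O1")
print()
print(f"example entries:  A[F3,F4] = {comp.A[i, j]:+.3f} (same region), "
      f"A[F3,O1] = {comp.A[i, k]:+.3f} (frontal vs occipital)")

sample = build_graph_sample(seg, GraphConfig())
print(f"graph sample: X {sample.X.shape} (band powers per channel), "
      f"attention weights in [{sample.attention.values.min():.2f}, "
      f"{sample.attention.values.max():.2f}]")
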