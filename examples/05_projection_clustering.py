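"""Uncentered PCA of median profiles with average-linkage clustering.

The protein x condition matrix of background-referenced medians is decomposed
by plain SVD (no centering, no scaling — all columns share provenance), and
proteins are clustered by average-linkage agglomeration, sweeping partitions
from 3 to 12 groups on one dendrogram.
"""

import apmsdiff as a

sim = a.SimConfig(n_conditions=4, n_replicates=3, n_background_binders=300,
                  n_specific_per_condition=30, n_shared_specific=15,
                  enrichment_log2=8.0, seed=13)
cfg = a.RunConfig(b_perm=50, seed=13, make_plots=False, cluster_k=8)
res = a.run_pipeline(cfg, sim_config=sim)

proj = res.projection
ev = proj.explained_fraction
print("explained fraction per component:",
      ", ".join(f"{v * 100:.1f}%" for v in ev[:4]))
print("(uncentered: fractions refer to total sum of squares, and the shared")
print(" background-binder offset concentrates in the first component)")

print("\ncondition loadings (the 'arrows'):")
print(proj.loadings.iloc[:, :3].round(3).to_string())

sizes = {k: int(labels.value_counts().max()) for k, labels in res.partitions.items()}
print("\nlargest cluster size per partition k=3..12:", sizes)
print(f"chosen k={proj.k}: cluster sizes",
      proj.cluster_labels.value_counts().sort_index().tolist())
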