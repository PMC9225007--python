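"""Cluster community metabolite trajectories with divisive minimum-spanning-
tree cutting and distill each cluster into a species presence/absence rule.

Prints the cluster sizes, the elbow diagnostic and the decision-tree rules.
"""

import numpy as np

import micos
from micos.glv import metabolites_from_abundances

pool_size = 8
pool = micos.DEFAULT_POOL[:pool_size]
params = micos.generate_ground_truth(
    pool_size, "mild", seed=5, a_offdiag_mean=-0.15, a_offdiag_sd=0.25,
    a_diag_range=(-2.0, -1.0))
rng = np.random.default_rng(1)
# metabolite production dominated by two keystone species, so communities
# fall into presence/absence-determined trajectory classes
W = np.abs(rng.normal(0.3, 0.2, (4, pool_size)))
W[0, 4] = 6.0   # EL-like keystone for metabolite 1
W[1, 6] = 6.0   # second keystone for metabolite 2

designs = micos.design_test_communities(pool_size, n=60, min_richness=3, seed=3)
tables = [metabolites_from_abundances(
    micos.simulate_glv(params, d, times=np.arange(0, 49, 16.0),
                       sample_id=f"c{i}"), W, mode="cumulative")
    for i, d in enumerate(designs)]

vectors = np.stack([tb.C.ravel() for tb in tables])  # 4 metabolites x 4 times
curve = micos.elbow_curve(vectors, range(1, 8), [5])
k = micos.pick_elbow(curve, 5)
print(f"elbow diagnostic suggests {k} clusters (max curvature of the mean "
      "intracluster distance)")

res = micos.mst_cluster(vectors, n_clusters=k, min_cluster_size=5)
print(f"cluster sizes: {res.sizes}; "
      f"{len(res.skipped_edges)} edge removals skipped by the min-size rule")

presence = np.stack([tb.design.mask().astype(int) for tb in tables])
rules = micos.decision_tree_rules(res.labels, presence, pool)
print("presence/absence design rules per cluster:")
for c, rule in sorted(rules.items()):
    print(f"  cluster {c} (n={res.sizes[c]}): {rule} "
          f"[coverage {rule.coverage:.0%}]")
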