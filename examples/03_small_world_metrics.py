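"""Small-world battery of one synthetic control connectome.

Computes Lp, Eg, Eloc, Cp, nodal betweenness, and the normalized ratios
gamma / lambda / sigma against 100 degree-preserving rewired networks.
sigma > 1 is the small-world signature.
"""

import numpy as np

from strucnet import (
    CohortSpec,
    betweenness_centrality,
    generate_cohort,
    small_world,
)

subjects, _ = generate_cohort(CohortSpec(n_per_group={"NC": 2}, seed=42))
subject = subjects[0]
adjacency = (subject.counts > 3).astype(np.int8)

gm = small_world(adjacency, n_null=100, rng=np.random.default_rng(0))
print(f"subject {subject.subject_id}: connected={gm.connected}")
print(f"  Lp    = {gm.lp:.3f}   (characteristic path length, hops)")
print(f"  Eg    = {gm.eg:.3f}   (global efficiency)")
print(f"  Eloc  = {gm.eloc:.3f}   (local efficiency)")
print(f"  Cp    = {gm.cp:.3f}   (clustering coefficient)")
print(f"  gamma = {gm.gamma:.3f}, lambda = {gm.lam:.3f}, sigma = {gm.sigma:.3f}")

bc = betweenness_centrality(adjacency)
top = np.argsort(bc)[::-1][:5]
print("top-5 hub nodes by betweenness:",
      ", ".join(f"{i} ({bc[i]:.0f})" for i in top))
# sigma well above 1: the modular template is more clustered than its
# degree-matched random counterparts at a comparable path length.
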