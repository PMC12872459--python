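"""Group inference on topographic scores: t / d_z / Holm, TFCE, coverage.

Twenty simulated participants carry a contiguous blob of true effect
(d_z = 1) in a sea of null vertices; the suite should flag the blob and
nothing else.
"""

import numpy as np

import cortexcf as c
from cortexcf.mesh import geodesic_matrix

mesh = c.flat_patch_mesh(16.0, 16.0, 1.0)
gd = geodesic_matrix(mesh)
blob = gd[mesh.n_vertices // 2] < 4.0

rng = np.random.default_rng(7)
scores = rng.standard_normal((20, mesh.n_vertices)) + blob * 1.0

res = c.group_topography_test(scores)
print(f"critical d_z at n=20: {c.critical_effect_size(20):.3f}")
print(f"blob mean d_z = {res.d_z[blob].mean():.2f}, "
      f"background mean d_z = {res.d_z[~blob].mean():.2f}")
print(f"Holm-significant vertices: {(res.p <= 0.05).sum()} "
      f"(of {blob.sum()} true-effect vertices)")

tfce = c.tfce_correct(scores, mesh, n_perm=500, alpha=0.01, seed=8)
print(f"TFCE-significant: {tfce.significant[blob].mean():.0%} of blob, "
      f"{tfce.significant[~blob].mean():.1%} of background")

cov = c.bootstrap_coverage(scores, np.where(blob, "blob", "rest"),
                           n_boot=500, seed=9)
for roi, (mean, lo, hi) in cov.coverage.items():
    print(f"coverage {roi:>4s}: {mean:5.1f}%  [{lo:.1f}, {hi:.1f}]")
print("-> TFCE keeps family-wise error controlled while the contiguous")
print("   effect survives; bootstrap CIs quantify per-ROI coverage.")
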