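"""Spatial-autocorrelation-preserving surrogates and the permutation tests.

Sign-flipping a map's per-eigenfunction coefficients preserves its amplitude
spectrum (hence its smoothness) while randomizing structure.  Against such
surrogates we test (a) split-half map agreement and (b) local searchlight
alignment between two maps.
"""

import numpy as np

import cortexcf as c

mesh = c.flat_patch_mesh(16.0, 16.0, 1.0)
basis = c.compute_basis(mesh, 40, drop_constant=False)
rng = np.random.default_rng(4)

# two "split-half" maps sharing structure plus independent noise
shared = rng.standard_normal(basis.k)
coef_a = shared + 0.4 * rng.standard_normal(basis.k)
coef_b = shared + 0.4 * rng.standard_normal(basis.k)
map_a = coef_a @ basis.eigenfunctions.T
map_b = coef_b @ basis.eigenfunctions.T

ens_a = c.make_surrogates(coef_a, basis, n=500, seed=5)
ens_b = c.make_surrogates(coef_b, basis, n=500, seed=6)
surr_a = np.stack([ens_a.surrogate_fields(i)[0] for i in range(500)])
surr_b = np.stack([ens_b.surrogate_fields(i)[0] for i in range(500)])

res = c.splithalf_permutation(map_a, map_b, surr_a, surr_b)
print(f"split-half agreement r = {res.r:.2f} (Fisher z = {res.fisher_z:.2f})")
print(f"summed permutation p = {res.p_sum:.4f} "
      f"(protected: {res.p_sum_protected:.4f})")
print("-> a summed p near 0 says the agreement beats chance even after")
print("   accounting for spatial autocorrelation; ~1 would mean chance level.")

sl = c.searchlight_alignment(map_a, map_b, mesh, surr_a, radius_mm=5.0)
sig = (sl.chunk_p <= 0.05).mean()
print(f"\nsearchlight: {len(sl.chunk_r)} chunks of radius 5 mm, "
      f"median |r| = {np.median(np.abs(sl.chunk_r)):.2f}, "
      f"{sig:.0%} of chunks at p <= 0.05")
print("-> per-vertex minimum p maps localize where the two maps align.")
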