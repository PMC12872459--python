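"""Simulate a session with known Gaussian connective fields and recover them.

Builds a 40 x 20 mm source patch carrying an edge-geodesic somatotopy-style
coordinate, simulates 30 targets whose time courses are Gaussian-weighted
sums of the source activity (sigma = 6 mm, SNR 1), fits the spectral
connective-field model, and compares recovered preferred coordinates with
the generating truth.
"""

import numpy as np

import cortexcf as c
from cortexcf.preprocess import RunSeries, split_train_test

space = c.make_source_space(c.SourceSpec(
    name="somato", width_mm=40.0, height_mm=20.0, spacing_mm=1.25,
    gradient="edge_geodesic", n_modes=40))

rng = np.random.default_rng(0)
truths = [c.GroundTruthCF(int(v), sigma_mm=6.0, band_gains={"somato": 1.0})
          for v in rng.integers(0, space.mesh.n_vertices, 30)]
sim = c.simulate_session(
    c.SimulationConfig(runs=4, samples_per_run=250, snr=1.0, seed=1),
    {"somato": space}, truths)

sp = split_train_test([RunSeries(r) for r in sim.source_runs["somato"]], 50)
yp = split_train_test([RunSeries(r) for r in sim.target_runs], 50)
design = c.assemble_design(
    {"somato": c.model_timecourses(sp.train, space.basis)},
    {"somato": c.model_timecourses(sp.test, space.basis)},
    run_lengths=sp.train_run_lengths)
mu = yp.train.T.mean(axis=0)
fit = c.fit_banded_ridge(design, yp.train.T - mu,
                         lambda_grid=np.logspace(-2, 6, 10))

est = []
for j in range(len(truths)):
    cf = c.reconstruct_cf(fit, space.basis, "somato", target=j)
    est.append(c.project_to_map(cf, space.coordinates).preferred_coordinate)
est = np.asarray(est)
true = sim.true_coordinates["somato"]

r = np.corrcoef(est, true)[0, 1]
mae = np.abs(est - true).mean()
print(f"recovered vs true preferred coordinate: r = {r:.3f}, "
      f"mean abs error = {mae:.2f} mm")
print("-> r near 1 and an error well below sigma mean the model localizes")
print("   each target's connective field on the source map correctly.")
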