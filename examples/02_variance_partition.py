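"""Two-source banded ridge: variance partitioning and topographic scores.

Targets are driven only by the somatosensory source; the visual source is
pure distractor.  The product measure splits each target's out-of-set R^2
into per-source shares that sum exactly to the total, and the topographic
connectivity score corrects each share by a non-spatial (source-mean) null
model.
"""

import numpy as np

import cortexcf as c
from cortexcf.preprocess import RunSeries, split_train_test

somato = c.make_source_space(c.SourceSpec(
    name="somato", width_mm=40.0, height_mm=20.0, spacing_mm=1.25, n_modes=40))
visual = c.make_source_space(c.SourceSpec(
    name="visual", width_mm=30.0, height_mm=20.0, spacing_mm=1.25, n_modes=40))
spaces = {"somato": somato, "visual": visual}

rng = np.random.default_rng(2)
truths = [c.GroundTruthCF(int(v), 4.0, {"somato": 1.0, "visual": 0.0})
          for v in rng.integers(0, somato.mesh.n_vertices, 40)]
sim = c.simulate_session(
    c.SimulationConfig(runs=4, samples_per_run=250, snr=1.0, seed=3),
    spaces, truths)

splits = {b: split_train_test([RunSeries(r) for r in sim.source_runs[b]], 50)
          for b in spaces}
yp = split_train_test([RunSeries(r) for r in sim.target_runs], 50)
design = c.assemble_design(
    {b: c.model_timecourses(splits[b].train, spaces[b].basis) for b in spaces},
    {b: c.model_timecourses(splits[b].test, spaces[b].basis) for b in spaces},
    run_lengths=splits["somato"].train_run_lengths)
mu = yp.train.T.mean(axis=0)
mean_series = {b: (splits[b].train.mean(axis=0) - splits[b].train.mean(),
                   splits[b].test.mean(axis=0) - splits[b].train.mean())
               for b in spaces}
scores, fit, _ = c.topographic_connectivity_scores(
    design, yp.train.T - mu, yp.test.T - mu, mean_series,
    lambda_grid=np.logspace(-2, 6, 8))
part = c.product_measure(fit, design, yp.test.T - mu)

print(f"test R^2 (total):            {part.r2_total.mean():.3f}")
print(f"  somatosensory share R~^2:  {part.r2_band['somato'].mean():.3f}")
print(f"  visual share R~^2:         {part.r2_band['visual'].mean():.4f}")
print(f"additivity error:            {part.additivity_error():.1e}")
print(f"topographic score > 0:       {(scores['somato'] > 0).mean():.0%} "
      "of targets (somatosensory band)")
print("-> the driving band takes essentially all explained variance; the")
print("   distractor's share sits at zero (implicit feature-space selection),")
print("   and positive null-corrected scores mark genuinely spatial coupling.")
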