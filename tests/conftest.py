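"""Shared fixtures: all inputs are generated programmatically at test time.

The heavyweight simulated sessions are session-scoped so recovery-style
checks across modules reuse one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

import cortexcf as c
from cortexcf.preprocess import RunSeries, split_train_test


@pytest.fixture(scope="session")
def small_patch():
    """10 x 10 mm unit-spacing flat patch (121 vertices)."""
    return c.flat_patch_mesh(10.0, 10.0, 1.0)


@pytest.fixture(scope="session")
def dense_patch():
    """30 x 30 mm patch at 0.75 mm spacing for geodesic-metric checks."""
    return c.flat_patch_mesh(30.0, 30.0, 0.75)


@pytest.fixture(scope="session")
def dense_patch_gdist(dense_patch):
    return c.geodesic_matrix(dense_patch)


@pytest.fixture(scope="session")
def somato_space():
    """40 x 20 mm source patch with an edge-geodesic coordinate, 40 modes."""
    return c.make_source_space(c.SourceSpec(
        name="somato", kind="patch", width_mm=40.0, height_mm=20.0,
        spacing_mm=1.25, gradient="edge_geodesic", n_modes=40))


@pytest.fixture(scope="session")
def visual_space():
    return c.make_source_space(c.SourceSpec(
        name="visual", kind="patch", width_mm=30.0, height_mm=20.0,
        spacing_mm=1.25, gradient="edge_geodesic", n_modes=40))


def _fit_session(sim, spaces, tail_s=50.0, lambda_points=8):
    """Split, assemble and fit one simulated session; return the pieces."""
    splits = {b: split_train_test([RunSeries(r) for r in sim.source_runs[b]],
                                  tail_s) for b in spaces}
    ysplit = split_train_test([RunSeries(r) for r in sim.target_runs], tail_s)
    train_b = {b: c.model_timecourses(splits[b].train, spaces[b].basis)
               for b in spaces}
    test_b = {b: c.model_timecourses(splits[b].test, spaces[b].basis)
              for b in spaces}
    first = next(iter(spaces))
    design = c.assemble_design(train_b, test_b,
                               run_lengths=splits[first].train_run_lengths)
    mu = ysplit.train.T.mean(axis=0)
    y_train = ysplit.train.T - mu
    y_test = ysplit.test.T - mu
    grid = np.logspace(-2, 6, lambda_points)
    fit = c.fit_banded_ridge(design, y_train, lambda_grid=grid)
    mean_series = {
        b: (splits[b].train.mean(axis=0) - splits[b].train.mean(),
            splits[b].test.mean(axis=0) - splits[b].train.mean())
        for b in spaces}
    return dict(design=design, fit=fit, y_train=y_train, y_test=y_test,
                splits=splits, mean_series=mean_series, grid=grid)


@pytest.fixture(scope="session")
def recovery_session(somato_space):
    """50 targets from sigma = 6 mm ground-truth CFs at SNR 1, 4 x 250 samples."""
    rng = np.random.default_rng(101)
    centers = rng.integers(0, somato_space.mesh.n_vertices, 50)
    truths = [c.GroundTruthCF(int(v), 6.0, {"somato": 1.0}) for v in centers]
    sim = c.simulate_session(
        c.SimulationConfig(runs=4, samples_per_run=250, snr=1.0, seed=202),
        {"somato": somato_space}, truths)
    out = _fit_session(sim, {"somato": somato_space})
    out["sim"] = sim
    out["space"] = somato_space
    return out


@pytest.fixture(scope="session")
def two_band_session(somato_space, visual_space):
    """100 targets driven only by the somatosensory band (sigma = 4 mm, SNR 1)."""
    rng = np.random.default_rng(303)
    centers = rng.integers(0, somato_space.mesh.n_vertices, 100)
    truths = [c.GroundTruthCF(int(v), 4.0, {"somato": 1.0, "visual": 0.0})
              for v in centers]
    spaces = {"somato": somato_space, "visual": visual_space}
    sim = c.simulate_session(
        c.SimulationConfig(runs=4, samples_per_run=250, snr=1.0, seed=404),
        spaces, truths)
    out = _fit_session(sim, spaces)
    out["sim"] = sim
    out["spaces"] = spaces
    return out
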