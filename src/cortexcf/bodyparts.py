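"""Keypoint-based forward model of visual body-part selectivity.

Natural images annotated with pose keypoints (17 per human entity: nose,
eyes, ears, shoulders, elbows, wrists, hips, knees, ankles, left/right)
are converted into per-part selectivity regressors

    X_part = presence_part * (number of the other 16 parts absent)

so an image showing an ankle and nothing else scores the ankle regressor at
its maximum (16), while an image with every part visible scores 0 for all.
Voxel responses are fit to this design by ridge regression with run-wise
cross-validation; the preferred body position of a voxel is the
beta-weighted position of the parts on the ordinal toe-to-tongue
(ankle-to-nose) axis of the somatosensory homunculus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import linalg as sla

__all__ = [
    "KEYPOINT_NAMES",
    "DEFAULT_ORDINAL_RANKS",
    "KeypointTable",
    "BodypartFit",
    "keypoint_presence",
    "selectivity_design",
    "fit_bodypart_model",
    "preferred_body_position",
]

KEYPOINT_NAMES: Tuple[str, ...] = (
    "nose",
    "left_eye", "right_eye",
    "left_ear", "right_ear",
    "left_shoulder", "right_shoulder",
    "left_elbow", "right_elbow",
    "left_wrist", "right_wrist",
    "left_hip", "right_hip",
    "left_knee", "right_knee",
    "left_ankle", "right_ankle",
)

# Ankle(1) -> nose(9) along the homunculus; left/right share a rank.
_BASE_RANK = {"ankle": 1.0, "knee": 2.0, "hip": 3.0, "wrist": 4.0,
              "elbow": 5.0, "shoulder": 6.0, "ear": 7.0, "eye": 8.0,
              "nose": 9.0}
DEFAULT_ORDINAL_RANKS: Dict[str, float] = {
    name: _BASE_RANK[name.split("_")[-1]] for name in KEYPOINT_NAMES
}


@dataclass
class KeypointTable:
    """Per-image keypoint presence frequencies (mean over entities)."""

    frequencies: pd.DataFrame      # images x 17, values in [0, 1]
    entity_counts: np.ndarray
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if list(self.frequencies.columns) != list(KEYPOINT_NAMES):
            raise ValueError("frequency columns must be the 17 keypoints")
        vals = self.frequencies.to_numpy()
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError("frequencies must lie in [0, 1]")


def _inside(xy: Sequence[float], box: Sequence[float]) -> bool:
    x0, y0, x1, y1 = box
    return x0 <= xy[0] <= x1 and y0 <= xy[1] <= y1


def keypoint_presence(images: Sequence[Mapping]) -> KeypointTable:
    """Tabulate per-part presence frequencies from entity keypoint records.

    Each image record is a mapping with keys ``entities`` (a sequence of
    per-entity mappings part name -> (x, y, present_flag)) and ``crop_box``
    ((x0, y0, x1, y1) in keypoint coordinates).  A keypoint counts as
    present only when flagged present AND inside the crop box — keypoints
    cropped out of the analysed image are recoded absent.  Images with no
    entities get all-zero frequencies.  Malformed entity records are skipped
    and counted.
    """
    rows, counts, skipped = [], [], 0
    for rec in images:
        box = rec.get("crop_box")
        freq = np.zeros(len(KEYPOINT_NAMES))
        n_ent = 0
        for ent in rec.get("entities", []):
            try:
                present = np.zeros(len(KEYPOINT_NAMES))
                for k, name in enumerate(KEYPOINT_NAMES):
                    val = ent.get(name)
                    if val is None:
                        continue
                    x, y, flag = val
                    if flag and (box is None or _inside((x, y), box)):
                        present[k] = 1.0
            except (TypeError, ValueError):
                skipped += 1
                continue
            freq += present
            n_ent += 1
        rows.append(freq / n_ent if n_ent else freq)
        counts.append(n_ent)
    if skipped:
        warnings.warn(f"skipped {skipped} malformed entity records",
                      stacklevel=2)
    df = pd.DataFrame(rows, columns=list(KEYPOINT_NAMES))
    return KeypointTable(frequencies=df, entity_counts=np.asarray(counts),
                         n_skipped=skipped)


def selectivity_design(table: KeypointTable) -> pd.DataFrame:
    """Selectivity regressors: presence times the count of absent other parts.

    ``X_part = freq_part * #{other 16 parts with freq == 0}``; a regressor
    is zero wherever its part is absent, maximal (16) for an image showing
    exactly that part, and zero everywhere when all parts are present.
    """
    f = table.frequencies.to_numpy()
    absent = (f == 0)
    n_other_absent = absent.sum(axis=1, keepdims=True) - absent
    x = f * n_other_absent
    return pd.DataFrame(x, columns=list(KEYPOINT_NAMES),
                        index=table.frequencies.index)


@dataclass
class BodypartFit:
    """Ridge fit of the selectivity model with run-wise CV."""

    beta: np.ndarray          # (17, n_voxels)
    test_r2: np.ndarray       # (n_voxels,)
    lambda_: np.ndarray       # (n_voxels,)
    cv_scores: np.ndarray     # (n_lambda, n_voxels)
    lambda_grid: np.ndarray
    train_runs: List
    test_runs: List


def fit_bodypart_model(design: pd.DataFrame, responses: np.ndarray,
                       run_of_trial: Sequence, test_runs: Sequence,
                       lambda_grid: Optional[Sequence[float]] = None) -> BodypartFit:
    """Ridge regression of voxel responses on the selectivity design.

    Trials are grouped by run; ``test_runs`` are held out entirely, the rest
    are used for k-fold (leave-one-run-out) selection of the ridge penalty.
    Design and responses are centred by training means; the per-voxel
    penalty maximizes mean held-out R^2, coefficients are refit on all
    training runs, and test R^2 is reported on the held-out runs.
    """
    x = design.to_numpy(dtype=float)
    y = np.asarray(responses, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    runs = np.asarray(run_of_trial)
    if len(runs) != len(x) or len(x) != len(y):
        raise ValueError("design, responses and run labels must align trial-wise")
    test_runs = list(test_runs)
    is_test = np.isin(runs, test_runs)
    if not is_test.any() or is_test.all():
        raise ValueError("test_runs must hold out a proper, non-empty subset")
    train_runs = [r for r in pd.unique(runs) if r not in test_runs]
    if len(train_runs) < 2:
        raise ValueError("need >= 2 training runs for cross-validation")

    if lambda_grid is None:
        lambda_grid = np.logspace(-2, 5, 15)
    lambda_grid = np.asarray(lambda_grid, dtype=float)

    xtr, ytr = x[~is_test], y[~is_test]
    runs_tr = runs[~is_test]
    x_mean, y_mean = xtr.mean(axis=0), ytr.mean(axis=0)
    xtr_c, ytr_c = xtr - x_mean, ytr - y_mean
    xte_c, yte_c = x[is_test] - x_mean, y[is_test] - y_mean

    folds = [(runs_tr != r, runs_tr == r) for r in train_runs]
    n_vox = y.shape[1]
    scores = np.zeros((lambda_grid.size, n_vox))
    # grid is evaluated descending so ties in argmax prefer larger penalties
    grid_desc = lambda_grid[np.argsort(-lambda_grid)]
    for li, lam in enumerate(grid_desc):
        fold_r2 = np.zeros((len(folds), n_vox))
        for fi, (tr, ho) in enumerate(folds):
            g = xtr_c[tr].T @ xtr_c[tr]
            g[np.diag_indices_from(g)] += lam
            b = sla.solve(g, xtr_c[tr].T @ ytr_c[tr], assume_a="pos")
            resid = ytr_c[ho] - xtr_c[ho] @ b
            ss = (ytr_c[ho] ** 2).sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                fold_r2[fi] = 1.0 - (resid ** 2).sum(axis=0) / ss
        scores[li] = fold_r2.mean(axis=0)
    best = scores.argmax(axis=0)

    beta = np.empty((x.shape[1], n_vox))
    for li in np.unique(best):
        sel = best == li
        g = xtr_c.T @ xtr_c
        g[np.diag_indices_from(g)] += grid_desc[li]
        beta[:, sel] = sla.solve(g, xtr_c.T @ ytr_c[:, sel], assume_a="pos")

    resid = yte_c - xte_c @ beta
    ss = (yte_c ** 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        test_r2 = 1.0 - (resid ** 2).sum(axis=0) / ss
    return BodypartFit(beta=beta, test_r2=test_r2,
                       lambda_=grid_desc[best], cv_scores=scores,
                       lambda_grid=grid_desc, train_runs=train_runs,
                       test_runs=test_runs)


def preferred_body_position(fit: BodypartFit,
                            ranks: Optional[Mapping[str, float]] = None,
                            mode: str = "rectified") -> np.ndarray:
    """Per-voxel preferred position on the ordinal ankle-to-nose axis.

    ``mode='rectified'`` (default): ``sum(beta+ * rank) / sum(beta+)`` with
    negative betas clipped — a weighted mean bounded by the axis range;
    voxels with no positive beta are NaN.  ``mode='dot'``: the plain dot
    product of betas and ranks (unbounded; conflates amplitude with
    position but matches the simplest readout).
    """
    if ranks is None:
        ranks = DEFAULT_ORDINAL_RANKS
    r = np.array([ranks[name] for name in KEYPOINT_NAMES])
    if mode == "dot":
        return r @ fit.beta
    if mode != "rectified":
        raise ValueError("mode must be 'rectified' or 'dot'")
    bpos = np.clip(fit.beta, 0.0, None)
    mass = bpos.sum(axis=0)
    flagged = mass <= 0
    if flagged.any():
        warnings.warn(f"{int(flagged.sum())} voxels with no positive beta",
                      stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        pos = (r @ bpos) / mass
    pos[flagged] = np.nan
    return pos
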