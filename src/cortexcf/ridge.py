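"""Banded ridge regression with per-band regularization and the product measure.

The model solves, per target time course ``y``,

    b* = argmin_b || sum_i X_i b_i - y ||^2 + sum_i lambda_i || b_i ||^2

where ``X_i`` are the design's bands (one per source region / modality) and
each band carries its own penalty ``lambda_i``, selected by leave-one-run-out
cross-validation on a per-band grid.  Separate penalties let the model learn
to ignore an uninformative band by driving its lambda large — implicit
feature-space selection.

Out-of-set performance is decomposed with the product measure

    R~^2_i = sum_t yhat_i (2 y - yhat) / sum_t y y

whose band shares sum exactly (algebraically) to the total R^2.  The
topographic connectivity score corrects each band's R~^2 by the test R^2 of
a non-topographic null model whose only regressor is that source's spatial
mean time course.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import linalg as sla

from .design import BandedDesign, assemble_design

__all__ = [
    "BandedRidgeFit",
    "VariancePartition",
    "default_lambda_grid",
    "fit_banded_ridge",
    "product_measure",
    "topographic_connectivity_scores",
]


def default_lambda_grid(n_points: int = 20) -> np.ndarray:
    """Log-spaced penalty candidates, 1e-2 ... 1e6."""
    return np.logspace(-2, 6, n_points)


@dataclass
class BandedRidgeFit:
    """Per-target coefficients, selected per-band penalties, CV record."""

    coefficients: np.ndarray          # (P, n_targets)
    lambdas: Dict[str, np.ndarray]    # band -> (n_targets,)
    band_slices: Dict[str, slice]
    cv_lambda_combos: np.ndarray      # (n_combo, n_bands)
    cv_scores: np.ndarray             # (n_combo, n_targets) mean held-out R^2
    cv_best_score: np.ndarray         # (n_targets,)
    degenerate: np.ndarray            # (n_targets,) bool: no combo beat -inf
    target_ids: Optional[Sequence] = None

    @property
    def bands(self) -> List[str]:
        return list(self.band_slices)

    def predict(self, x: np.ndarray, band: Optional[str] = None) -> np.ndarray:
        """Predictions (T, n_targets); a single band's sub-prediction if named."""
        if band is None:
            return x @ self.coefficients
        sl = self.band_slices[band]
        return x[:, sl] @ self.coefficients[sl]


@dataclass
class VariancePartition:
    """Product-measure decomposition of R^2 into per-band shares."""

    r2_band: Dict[str, np.ndarray]  # band -> (n_targets,)
    r2_total: np.ndarray            # (n_targets,)
    dataset_tag: str = "test"
    undefined: Optional[np.ndarray] = None  # targets with sum(y*y) == 0

    def additivity_error(self) -> float:
        s = np.sum(list(self.r2_band.values()), axis=0)
        return float(np.nanmax(np.abs(s - self.r2_total)))


def _column_lambdas(design: BandedDesign, combo: Mapping[str, float]) -> np.ndarray:
    lam = np.empty(design.n_columns)
    for band, sl in design.band_slices.items():
        lam[sl] = combo[band]
    return lam


def _solve(gram: np.ndarray, xty: np.ndarray, col_lam: np.ndarray) -> np.ndarray:
    a = gram.copy()
    a[np.diag_indices_from(a)] += col_lam
    return sla.solve(a, xty, assume_a="pos")


def fit_banded_ridge(design: BandedDesign,
                     y: np.ndarray,
                     lambda_grid: Union[None, Sequence[float],
                                        Mapping[str, Sequence[float]]] = None,
                     target_ids: Optional[Sequence] = None) -> BandedRidgeFit:
    """Fit the banded ridge model with leave-one-run-out penalty selection.

    Parameters
    ----------
    design : BandedDesign
        Must carry >= 2 training runs.
    y : (T,) or (T, n_targets)
        Target series on the training samples; should be mean-removed
        consistently with the design's standardization.
    lambda_grid : per-band candidate penalties
        A mapping band -> sequence, a flat sequence shared by all bands, or
        None for the default 20-point log grid.  The search is the Cartesian
        product across bands; candidates must be positive.

    Selection maximizes the mean held-out-run R^2 per target; ties prefer the
    more regularized combination.  Final coefficients are refit on all
    training runs at the selected penalties.  Targets for which every
    candidate produces a non-finite CV score are flagged ``degenerate`` (fit
    at the most regularized combo).
    """
    y = np.asarray(y, dtype=float)
    squeeze = y.ndim == 1
    if squeeze:
        y = y[:, None]
    if y.shape[0] != design.train.shape[0]:
        raise ValueError("y length must match the design's training samples")
    if len(design.run_lengths) < 2:
        raise ValueError("leave-one-run-out CV needs >= 2 training runs")

    bands = design.bands
    if lambda_grid is None:
        lambda_grid = {b: default_lambda_grid() for b in bands}
    elif not isinstance(lambda_grid, Mapping):
        g = np.asarray(list(lambda_grid), dtype=float)
        lambda_grid = {b: g for b in bands}
    for b in bands:
        g = np.asarray(list(lambda_grid[b]), dtype=float)
        if g.size == 0:
            raise ValueError(f"empty lambda grid for band {b!r}")
        if (g <= 0).any():
            raise ValueError("lambda candidates must be positive")
        lambda_grid[b] = g

    combos = np.array(list(itertools.product(*(lambda_grid[b] for b in bands))))
    # Descending total penalty so that argmax (first max) breaks ties toward
    # the more regularized combination.
    order = np.argsort(-np.log(combos).sum(axis=1), kind="stable")
    combos = combos[order]

    x = design.train
    folds = design.run_folds()
    grams, xtys, youts, xouts = [], [], [], []
    for tr, out in folds:
        xt = x[tr]
        grams.append(xt.T @ xt)
        xtys.append(xt.T @ y[tr])
        xouts.append(x[out])
        youts.append(y[out])

    n_t = y.shape[1]
    scores = np.zeros((len(combos), n_t))
    for ci, combo in enumerate(combos):
        col_lam = _column_lambdas(design, dict(zip(bands, combo)))
        fold_r2 = np.zeros((len(folds), n_t))
        for fi in range(len(folds)):
            b = _solve(grams[fi], xtys[fi], col_lam)
            resid = youts[fi] - xouts[fi] @ b
            ss_y = (youts[fi] ** 2).sum(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                fold_r2[fi] = 1.0 - (resid ** 2).sum(axis=0) / ss_y
        scores[ci] = fold_r2.mean(axis=0)

    finite = np.isfinite(scores)
    masked = np.where(finite, scores, -np.inf)
    best = masked.argmax(axis=0)
    degenerate = ~finite.any(axis=0)
    best[degenerate] = 0  # most regularized combo

    gram_full = x.T @ x
    xty_full = x.T @ y
    coef = np.empty((design.n_columns, n_t))
    for ci in np.unique(best):
        sel = best == ci
        col_lam = _column_lambdas(design, dict(zip(bands, combos[ci])))
        coef[:, sel] = _solve(gram_full, xty_full[:, sel], col_lam)

    lambdas = {b: combos[best, bi] for bi, b in enumerate(bands)}
    return BandedRidgeFit(
        coefficients=coef,
        lambdas=lambdas,
        band_slices=dict(design.band_slices),
        cv_lambda_combos=combos,
        cv_scores=scores,
        cv_best_score=masked.max(axis=0),
        degenerate=degenerate,
        target_ids=target_ids,
    )


def product_measure(fit: BandedRidgeFit, design: BandedDesign, y: np.ndarray,
                    dataset: str = "test") -> VariancePartition:
    """Per-band R~^2 shares and the total R^2 on train or test data.

    ``R~^2_i = sum_t yhat_i (2y - yhat) / sum_t y y`` with ``yhat_i`` the
    band-i sub-prediction under the joint fit.  The shares sum exactly to
    ``1 - sum (y - yhat)^2 / sum y^2``; shares can be negative (a band whose
    sub-prediction opposes the data).  Evaluation data must be standardized
    with training statistics.
    """
    x = design.test if dataset == "test" else design.train
    if x is None:
        raise ValueError(f"design has no {dataset!r} matrix")
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    yhat = fit.predict(x)
    ss_y = (y ** 2).sum(axis=0)
    undefined = ss_y == 0
    ss_safe = np.where(undefined, 1.0, ss_y)
    r2_band = {}
    for band in fit.bands:
        yh_i = fit.predict(x, band=band)
        r2_band[band] = (yh_i * (2 * y - yhat)).sum(axis=0) / ss_safe
        r2_band[band][undefined] = np.nan
    r2_total = 1.0 - ((y - yhat) ** 2).sum(axis=0) / ss_safe
    r2_total[undefined] = np.nan
    return VariancePartition(r2_band=r2_band, r2_total=r2_total,
                             dataset_tag=dataset, undefined=undefined)


def topographic_connectivity_scores(
        design: BandedDesign,
        y_train: np.ndarray,
        y_test: np.ndarray,
        source_mean_series: Mapping[str, Tuple[np.ndarray, np.ndarray]],
        lambda_grid=None,
        null_lambda_grid=None,
        fit: Optional[BandedRidgeFit] = None,
):
    """Null-corrected per-band generalization scores.

    For each band ``i``: ``score_i = R~^2_i(test, full model) - R^2(test,
    null model i)`` where null model ``i`` has a single regressor — the
    source's spatial mean time course (train/test pair in
    ``source_mean_series``) — fit with the same leave-one-run-out protocol.
    A negative score marks non-topographic connectivity: the spatial model
    generalizes no better than the source's mean signal.

    Returns ``(scores, fit, null_fits)`` with ``scores[band]`` of shape
    (n_targets,).
    """
    missing = [b for b in design.bands if b not in source_mean_series]
    if missing:
        raise ValueError(f"missing null mean series for bands {missing}")
    if fit is None:
        fit = fit_banded_ridge(design, y_train, lambda_grid=lambda_grid)
    part = product_measure(fit, design, y_test, dataset="test")

    scores: Dict[str, np.ndarray] = {}
    null_fits: Dict[str, BandedRidgeFit] = {}
    for band in design.bands:
        mean_tr, mean_te = source_mean_series[band]
        null_design = assemble_design(
            {band: np.asarray(mean_tr, dtype=float).reshape(-1, 1)},
            {band: np.asarray(mean_te, dtype=float).reshape(-1, 1)},
            run_lengths=design.run_lengths,
        )
        nfit = fit_banded_ridge(null_design, y_train,
                                lambda_grid=null_lambda_grid)
        npart = product_measure(nfit, null_design, y_test, dataset="test")
        scores[band] = part.r2_band[band] - npart.r2_total
        null_fits[band] = nfit
    return scores, fit, null_fits
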