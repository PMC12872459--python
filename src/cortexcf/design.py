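"""Banded design matrices of spectral model time courses.

Each source region contributes one regularization band.  A band's columns
are model time courses: the source time series weighted by each
Laplace-Beltrami eigenfunction and summed over vertices.  Columns are
z-scored over the concatenated training runs; test columns are standardized
with the training statistics (never their own), so generalization scores are
honest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .basis import LaplaceBasis

__all__ = ["BandedDesign", "model_timecourses", "assemble_design"]

BandBlocks = Union[np.ndarray, Sequence[np.ndarray]]


def model_timecourses(source_series: np.ndarray, basis: LaplaceBasis) -> np.ndarray:
    """Eigenfunction-weighted sums of the source series, (time, K).

    Column k is ``sum_v phi_k(v) * s_v(t)``: the source activity pattern at
    each time point projected onto one spatial profile.
    """
    s = np.asarray(source_series, dtype=float)
    if s.shape[0] != basis.n_vertices:
        raise ValueError(
            f"series has {s.shape[0]} vertices, basis has {basis.n_vertices}")
    return s.T @ basis.eigenfunctions


@dataclass
class BandedDesign:
    """Stacked, z-scored model time courses with band bookkeeping.

    Attributes
    ----------
    train, test : (T, P) arrays
        Standardized with training statistics; ``test`` may be None.
    band_slices : band label -> slice into the columns (bands contiguous).
    column_band, column_block, column_mode : per-column provenance
        (band label, block index within band, eigenfunction index).
    run_lengths : training-run lengths for leave-one-run-out CV.
    """

    train: np.ndarray
    test: Optional[np.ndarray]
    band_slices: Dict[str, slice]
    column_band: np.ndarray
    column_block: np.ndarray
    column_mode: np.ndarray
    run_lengths: List[int]
    col_mean: np.ndarray
    col_std: np.ndarray
    dropped: List[Tuple[str, int, int]] = field(default_factory=list)

    @property
    def n_columns(self) -> int:
        return self.train.shape[1]

    @property
    def bands(self) -> List[str]:
        return list(self.band_slices)

    def run_folds(self):
        """(train_idx, heldout_idx) pairs, one per left-out training run."""
        bounds = np.cumsum([0] + list(self.run_lengths))
        t = np.arange(self.train.shape[0])
        folds = []
        for r in range(len(self.run_lengths)):
            out = (t >= bounds[r]) & (t < bounds[r + 1])
            folds.append((t[~out], t[out]))
        return folds

    def band_columns(self, band: str) -> np.ndarray:
        return np.arange(self.n_columns)[self.band_slices[band]]


def assemble_design(train_bands: Mapping[str, BandBlocks],
                    test_bands: Optional[Mapping[str, BandBlocks]] = None,
                    run_lengths: Optional[Sequence[int]] = None,
                    std_floor: float = 1e-12) -> BandedDesign:
    """Stack per-band model time courses into one standardized design.

    Parameters
    ----------
    train_bands : band label -> (T, K) matrix or sequence of block matrices
        Blocks (e.g. the two hemispheres of one modality) are concatenated
        inside their band and share its regularization.
    test_bands : same keys/shapes on the test samples, optional.
    run_lengths : training-run lengths (sum must equal T); required for CV.

    Zero-variance columns are dropped (with a warning) and recorded on the
    result.
    """
    if test_bands is not None and set(test_bands) != set(train_bands):
        raise ValueError("test bands must match train bands")

    cols_tr, cols_te = [], []
    band_names, block_idx, mode_idx = [], [], []
    t_train = None
    for band, blocks in train_bands.items():
        blocks = [blocks] if isinstance(blocks, np.ndarray) else list(blocks)
        te_blocks = None
        if test_bands is not None:
            tb = test_bands[band]
            te_blocks = [tb] if isinstance(tb, np.ndarray) else list(tb)
            if len(te_blocks) != len(blocks):
                raise ValueError(f"band {band!r}: block count mismatch")
        for bi, blk in enumerate(blocks):
            blk = np.asarray(blk, dtype=float)
            if blk.ndim != 2:
                raise ValueError("each block must be (time, K)")
            if t_train is None:
                t_train = blk.shape[0]
            elif blk.shape[0] != t_train:
                raise ValueError("bands must share the time dimension")
            cols_tr.append(blk)
            if te_blocks is not None:
                cols_te.append(np.asarray(te_blocks[bi], dtype=float))
            band_names += [band] * blk.shape[1]
            block_idx += [bi] * blk.shape[1]
            mode_idx += list(range(blk.shape[1]))

    x_tr = np.concatenate(cols_tr, axis=1)
    x_te = np.concatenate(cols_te, axis=1) if cols_te else None
    band_names = np.asarray(band_names)
    block_idx = np.asarray(block_idx)
    mode_idx = np.asarray(mode_idx)

    mean = x_tr.mean(axis=0)
    std = x_tr.std(axis=0)
    keep = std > std_floor
    dropped = [(band_names[i], int(block_idx[i]), int(mode_idx[i]))
               for i in np.flatnonzero(~keep)]
    if dropped:
        warnings.warn(f"dropped {len(dropped)} zero-variance design columns",
                      stacklevel=2)
    x_tr = (x_tr[:, keep] - mean[keep]) / std[keep]
    if x_te is not None:
        x_te = (x_te[:, keep] - mean[keep]) / std[keep]
    band_names, block_idx, mode_idx = (band_names[keep], block_idx[keep],
                                       mode_idx[keep])

    band_slices: Dict[str, slice] = {}
    start = 0
    for band in train_bands:
        n = int((band_names == band).sum())
        band_slices[band] = slice(start, start + n)
        start += n

    if run_lengths is None:
        run_lengths = [t_train]
    if sum(run_lengths) != t_train:
        raise ValueError("run_lengths must sum to the training length")

    return BandedDesign(
        train=x_tr, test=x_te, band_slices=band_slices,
        column_band=band_names, column_block=block_idx, column_mode=mode_idx,
        run_lengths=list(run_lengths),
        col_mean=mean[keep], col_std=std[keep], dropped=dropped,
    )
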