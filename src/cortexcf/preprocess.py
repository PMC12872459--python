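"""Temporal preprocessing and train/test partitioning of run-wise BOLD series.

All operations are strictly per run: filtering never crosses run boundaries,
so no temporal leakage between runs can occur.  The protocol is
high-pass filtering (the residual of a third-order, 210 s Savitzky-Golay
smooth), conversion to percent signal change, then splitting each run's final
``tail_s`` seconds into a concatenated test set (e.g. four runs with 103 s
tails give a 412 s test set).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np
from scipy.signal import savgol_filter

__all__ = ["RunSeries", "TrainTestSplit", "savgol_highpass",
           "percent_signal_change", "split_train_test"]


@dataclass
class RunSeries:
    """One run of vertex-wise time series, sampled at ``1/dt`` Hz."""

    data: np.ndarray  # (vertices, time)
    dt: float = 1.0   # sampling interval, s
    run_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("run data must be (vertices, time)")
        if not np.isfinite(self.data).all():
            raise ValueError(f"non-finite samples in run {self.run_id!r}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class TrainTestSplit:
    """Concatenated train heads and test tails, with run bookkeeping for CV."""

    train: np.ndarray
    test: np.ndarray
    train_run_lengths: List[int]
    test_run_lengths: List[int]
    run_ids: List[str] = field(default_factory=list)

    @property
    def train_boundaries(self) -> np.ndarray:
        return np.cumsum([0] + self.train_run_lengths)


def savgol_highpass(run: RunSeries, order: int = 3,
                    window_s: float = 210.0) -> RunSeries:
    """High-pass: data minus its Savitzky-Golay low-pass fit, per vertex.

    The window is ``window_s`` seconds rounded to the nearest odd sample
    count (210 s at 1 Hz -> 211 samples).  Edges use a polynomial fit on the
    truncated terminal window (``mode='interp'``).  A constant or purely
    polynomial drift of degree <= ``order`` is removed exactly.
    """
    window = int(round(window_s / run.dt))
    if window % 2 == 0:
        window += 1
    if window >= run.n_samples:
        raise ValueError(
            f"window of {window} samples >= run length {run.n_samples} "
            f"(run {run.run_id!r})")
    if window <= order:
        raise ValueError("window must exceed the polynomial order")
    smooth = savgol_filter(run.data, window_length=window, polyorder=order,
                           axis=1, mode="interp")
    return RunSeries(run.data - smooth, dt=run.dt, run_id=run.run_id)


def percent_signal_change(run: RunSeries, mean_floor: float = 1e-8) -> RunSeries:
    """100 * (x - mean) / mean per vertex; zero-mean vertices flagged to 0."""
    mean = run.data.mean(axis=1, keepdims=True)
    bad = np.abs(mean[:, 0]) < mean_floor
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} vertices with near-zero temporal mean set to 0 "
            f"in run {run.run_id!r}", stacklevel=2)
    safe = np.where(np.abs(mean) < mean_floor, 1.0, mean)
    out = 100.0 * (run.data - mean) / safe
    out[bad] = 0.0
    return RunSeries(out, dt=run.dt, run_id=run.run_id)


def split_train_test(runs: Sequence[RunSeries],
                     tail_s: float = 103.0) -> TrainTestSplit:
    """Split each run's final ``tail_s`` seconds into the test set.

    Train = concatenated run heads, test = concatenated run tails, run order
    preserved, boundaries recorded for leave-one-run-out CV.
    """
    if not runs:
        raise ValueError("no runs supplied")
    nv = runs[0].data.shape[0]
    trains, tests, tr_len, te_len, ids = [], [], [], [], []
    for run in runs:
        if run.data.shape[0] != nv:
            raise ValueError(f"run {run.run_id!r} has mismatched vertex count")
        tail = int(round(tail_s / run.dt))
        if tail >= run.n_samples:
            raise ValueError(
                f"run {run.run_id!r} shorter than tail of {tail} samples")
        head = run.n_samples - tail
        trains.append(run.data[:, :head])
        tests.append(run.data[:, head:])
        tr_len.append(head)
        te_len.append(tail)
        ids.append(run.run_id)
    test = (np.concatenate(tests, axis=1) if sum(te_len)
            else np.empty((nv, 0)))
    return TrainTestSplit(
        train=np.concatenate(trains, axis=1),
        test=test,
        train_run_lengths=tr_len,
        test_run_lengths=te_len,
        run_ids=ids,
    )
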