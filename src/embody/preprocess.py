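"""Analysis-side signal conditioning and label alignment.

Only the minimal native-space steps live here: per-block linear detrending,
confound (e.g., head-motion) regression, and the hemodynamic label shift.
Slice-timing and motion *correction* are upstream responsibilities for real
scanner data; synthetic data does not need them.
"""
from __future__ import annotations

import warnings

import numpy as np
from scipy.signal import detrend as _scipy_detrend

from .containers import UNLABELED, LabelSeries, VoxelTimeSeries


def _block_slices(block_id: np.ndarray):
    """Contiguous segments of constant block id, in order."""
    boundaries = np.flatnonzero(np.diff(block_id)) + 1
    edges = np.concatenate([[0], boundaries, [block_id.shape[0]]])
    return [slice(a, b) for a, b in zip(edges[:-1], edges[1:])]


def detrend_linear(ts: VoxelTimeSeries) -> VoxelTimeSeries:
    """Remove each voxel's best-fit line, independently within each block.

    Blocks are separate scanner runs, so scanner drift is fit and removed
    per block; the residual has zero mean per voxel per block.
    """
    if ts.n_volumes < 3:
        raise ValueError("detrending requires at least 3 volumes")
    out = np.empty_like(ts.data)
    for seg in _block_slices(ts.block_id):
        chunk = ts.data[:, seg]
        if chunk.shape[1] < 2:
            out[:, seg] = chunk - chunk.mean(axis=1, keepdims=True)
        else:
            out[:, seg] = _scipy_detrend(chunk, axis=1, type="linear")
    return VoxelTimeSeries(out, ts.tr_seconds, ts.block_id.copy(),
                           None if ts.decodable is None else ts.decodable.copy())


def regress_confounds(ts: VoxelTimeSeries, confounds: np.ndarray) -> VoxelTimeSeries:
    """Residualize each voxel on the confound columns (plus an intercept).

    ``confounds`` is a volumes x k matrix (e.g., motion parameters). A
    rank-deficient design triggers a warning and a pseudo-inverse fit.
    """
    confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
    if confounds.shape[0] != ts.n_volumes:
        if confounds.shape[1] == ts.n_volumes:
            confounds = confounds.T
        else:
            raise ValueError("confound rows must match the volume count")
    if confounds.shape[1] < 1:
        raise ValueError("need at least one confound column")
    X = np.column_stack([np.ones(ts.n_volumes), confounds])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("confound matrix is rank deficient; using pseudo-inverse")
    beta = np.linalg.pinv(X) @ ts.data.T
    resid = ts.data - (X @ beta).T
    return VoxelTimeSeries(resid, ts.tr_seconds, ts.block_id.copy(),
                           None if ts.decodable is None else ts.decodable.copy())


def shift_labels(labels: LabelSeries, lag_seconds: float = 6.0,
                 tr_seconds: float = 1.0) -> LabelSeries:
    """Shift condition labels later in time to account for hemodynamic lag.

    The label originally at time ``t`` applies to the volume at
    ``t + lag_seconds``. Shifts are applied within each block independently;
    volumes before the first shifted label become unlabeled and labels
    pushed past the block end are dropped. A lag that is not a multiple of
    the sampling interval is rounded to the nearest volume with a warning.
    """
    if lag_seconds < 0:
        raise ValueError("lag_seconds must be nonnegative")
    shift_f = lag_seconds / tr_seconds
    shift = int(round(shift_f))
    if abs(shift_f - shift) > 1e-9:
        warnings.warn(
            f"lag {lag_seconds} s is not a multiple of TR {tr_seconds} s; "
            f"rounding to {shift} volumes"
        )
    new = np.full(labels.n_volumes, UNLABELED, dtype=object)
    for seg in _block_slices(labels.block_id):
        src = labels.labels[seg]
        if shift < src.shape[0]:
            new[seg.start + shift: seg.stop] = src[: src.shape[0] - shift]
    return LabelSeries(new, labels.block_id.copy(),
                       lag_seconds=labels.lag_seconds + lag_seconds)
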