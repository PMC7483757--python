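"""Core in-memory containers shared across the pipeline."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Sentinel condition label for volumes that carry no task condition
#: (baseline, auditory instructions, volumes vacated by the hemodynamic
#: label shift). Unlabeled volumes are excluded from classifier training
#: and from accuracy denominators.
UNLABELED = "unlabeled"


@dataclass
class VoxelTimeSeries:
    """One scanner run: a voxels x volumes signal matrix.

    ``data`` is indexed ``[voxel, volume]``; ``tr_seconds`` is the sampling
    interval, so volume index times ``tr_seconds`` is acquisition time within
    the run. ``block_id`` marks the task block each volume belongs to (blocks
    are separate scanner runs and are detrended independently).
    ``decodable``, when present, masks volumes that carry task content —
    instruction periods at the start of meditation blocks are ``False`` and
    are never decoded.
    """

    data: np.ndarray
    tr_seconds: float = 1.0
    block_id: np.ndarray | None = None
    decodable: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D voxels x volumes matrix")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("voxel time series must contain only finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.block_id is None:
            self.block_id = np.zeros(self.data.shape[1], dtype=int)
        self.block_id = np.asarray(self.block_id, dtype=int)
        if self.block_id.shape != (self.data.shape[1],):
            raise ValueError("block_id must have one entry per volume")
        if self.decodable is not None:
            self.decodable = np.asarray(self.decodable, dtype=bool)
            if self.decodable.shape != (self.data.shape[1],):
                raise ValueError("decodable mask must have one entry per volume")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]


@dataclass
class LabelSeries:
    """Per-volume condition labels aligned with a :class:`VoxelTimeSeries`.

    ``labels`` holds one condition identifier (or :data:`UNLABELED`) per
    volume. ``lag_seconds`` records the total hemodynamic shift that has been
    applied to the series (0 for freshly generated designs).
    """

    labels: np.ndarray
    block_id: np.ndarray | None = None
    lag_seconds: float = 0.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.ndim != 1:
            raise ValueError("labels must be one-dimensional")
        if self.lag_seconds < 0:
            raise ValueError("lag_seconds must be nonnegative")
        if self.block_id is None:
            self.block_id = np.zeros(self.labels.shape[0], dtype=int)
        self.block_id = np.asarray(self.block_id, dtype=int)
        if self.block_id.shape != self.labels.shape:
            raise ValueError("block_id must have one entry per volume")

    @property
    def n_volumes(self) -> int:
        return self.labels.shape[0]

    @property
    def labeled_mask(self) -> np.ndarray:
        """Boolean mask of volumes that carry a task condition."""
        return self.labels != UNLABELED


def concat_runs(
    runs: list[VoxelTimeSeries], labels: list[LabelSeries]
) -> tuple[VoxelTimeSeries, LabelSeries]:
    """Concatenate per-block runs into one series, preserving block identity."""
    if len(runs) != len(labels) or not runs:
        raise ValueError("need matching, non-empty run and label lists")
    for r, l in zip(runs, labels):
        if r.n_volumes != l.n_volumes:
            raise ValueError("run and label series lengths differ")
    data = np.concatenate([r.data for r in runs], axis=1)
    block = np.concatenate([np.full(r.n_volumes, i) for i, r in enumerate(runs)])
    lab = np.concatenate([l.labels for l in labels])
    ts = VoxelTimeSeries(data, tr_seconds=runs[0].tr_seconds, block_id=block)
    ls = LabelSeries(lab, block_id=block, lag_seconds=labels[0].lag_seconds)
    return ts, ls
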