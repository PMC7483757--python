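"""Classifier importance maps: which voxels drive each condition's decoding.

A voxel's importance for a condition is the product of its classifier weight
for that condition and its z-scored average activation during the condition's
volumes. Voxels where both factors are positive carry *positive importance*;
voxels where both are negative carry *negative importance*; mixed-sign voxels
belong to neither class and are never retained. Maps are thresholded at
+/- 2 SD (z-scored across voxels) to isolate the most important voxels, and
can be aggregated into per-voxel subject-frequency maps or intersected with
binary anatomical masks.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .classifier import ClassifierModel
from .containers import LabelSeries, VoxelTimeSeries

POSITIVE = "positive"
NEGATIVE = "negative"
NONE = "none"


@dataclass
class ImportanceMap:
    """Per-voxel importance values and sign classes for one condition.

    ``retained`` is filled by :func:`threshold_map`; it is ``None`` for an
    unthresholded map.
    """

    values: np.ndarray
    sign_class: np.ndarray
    condition: str
    subject: str | None = None
    retained: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sign_class = np.asarray(self.sign_class, dtype=object)
        if self.values.shape != self.sign_class.shape:
            raise ValueError("values and sign_class must share one voxel grid")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]


def compute_importance(
    model: ClassifierModel,
    ts: VoxelTimeSeries,
    labels: LabelSeries,
    condition: str,
    *,
    zscore_axis: str = "time",
) -> ImportanceMap:
    """Weight x z-scored mean activation importance for one condition.

    With the default ``zscore_axis="time"``, each voxel's series is z-scored
    across all volumes and then averaged over the condition's labeled
    volumes, giving the z-scored average activation; ``"voxels"`` instead
    z-scores the raw condition means across voxels. Both give a signed
    activation term whose sign is compared with the weight's.
    """
    if condition not in model.condition_order:
        raise ValueError(f"condition {condition!r} not in model")
    if zscore_axis not in ("time", "voxels"):
        raise ValueError("zscore_axis must be 'time' or 'voxels'")
    mask = labels.labels == condition
    if not mask.any():
        from .classifier import MissingClassError

        raise MissingClassError(f"no labeled volumes for condition {condition!r}")
    if zscore_axis == "time":
        mu = ts.data.mean(axis=1, keepdims=True)
        sd = ts.data.std(axis=1, keepdims=True)
        z = np.divide(ts.data - mu, sd, out=np.zeros_like(ts.data), where=sd > 0)
        activation = z[:, mask].mean(axis=1)
    else:
        means = ts.data[:, mask].mean(axis=1)
        sd = means.std()
        activation = (means - means.mean()) / sd if sd > 0 else np.zeros_like(means)
    w = model.weights[model.condition_order.index(condition)]
    values = w * activation
    sign_class = np.full(values.shape, NONE, dtype=object)
    sign_class[(w > 0) & (activation > 0)] = POSITIVE
    sign_class[(w < 0) & (activation < 0)] = NEGATIVE
    return ImportanceMap(values, sign_class, condition)


def threshold_map(imp: ImportanceMap, sd_threshold: float = 2.0) -> ImportanceMap:
    """Retain voxels whose importance is at least ``sd_threshold`` SDs extreme.

    Importances are z-scored across voxels; voxels with ``|z| >= threshold``
    *and* a concordant sign class are retained. A map with zero variance
    across voxels retains nothing (with a warning).
    """
    if imp.n_voxels < 2:
        raise ValueError("thresholding requires at least 2 voxels")
    sd = imp.values.std()
    if sd == 0.0:
        warnings.warn("importance values have zero variance; nothing retained")
        retained = np.zeros(imp.n_voxels, dtype=bool)
    else:
        z = (imp.values - imp.values.mean()) / sd
        retained = (np.abs(z) >= sd_threshold) & (imp.sign_class != NONE)
    return ImportanceMap(
        imp.values.copy(), imp.sign_class.copy(), imp.condition, imp.subject, retained
    )


def frequency_map(maps: list[ImportanceMap], sign: str = "both") -> np.ndarray:
    """Per-voxel count of subjects retaining the voxel (thresholded maps).

    ``sign`` selects which importance classes count: ``"both"`` (default),
    ``"positive"`` or ``"negative"``. Counts never exceed the number of maps.
    """
    if sign not in ("both", POSITIVE, NEGATIVE):
        raise ValueError("sign must be 'both', 'positive', or 'negative'")
    if not maps:
        return np.zeros(0, dtype=int)
    n_voxels = maps[0].n_voxels
    counts = np.zeros(n_voxels, dtype=int)
    for m in maps:
        if m.n_voxels != n_voxels:
            raise ValueError("all maps must share one voxel grid")
        if m.retained is None:
            raise ValueError("frequency maps require thresholded inputs")
        keep = m.retained
        if sign != "both":
            keep = keep & (m.sign_class == sign)
        counts += keep.astype(int)
    return counts


def mask_fraction(imp: ImportanceMap, mask: np.ndarray) -> float:
    """Percentage of retained voxels that fall inside a binary mask.

    Returns NaN (with a warning) when the retained set is empty.
    """
    if imp.retained is None:
        raise ValueError("mask_fraction requires a thresholded map")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != imp.values.shape:
        raise ValueError("mask must share the map's voxel grid")
    n_ret = int(imp.retained.sum())
    if n_ret == 0:
        warnings.warn("retained set is empty; mask fraction undefined")
        return float("nan")
    return 100.0 * int((imp.retained & mask).sum()) / n_ret
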