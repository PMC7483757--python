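"""Reading and writing the pipeline's on-disk formats.

Voxel data travel either as plain voxels x time TSV (with a JSON sidecar
holding the sampling interval, block ids, and decodable mask) or as 4-D
NIfTI; trial schedules and mental events as BIDS-style ``events.tsv``
(columns: onset, duration, trial_type, rating, block); classifier models,
ground truth, and reports as JSON.
"""
from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .classifier import ClassifierModel
from .containers import UNLABELED, LabelSeries, VoxelTimeSeries
from .design import Block, TaskDesign, Trial
from .simulate import GroundTruth


# ---------------------------------------------------------------- voxel data

def save_voxels_tsv(ts: VoxelTimeSeries, path: str | Path) -> None:
    """Write a run as voxels x time TSV plus a ``.json`` sidecar."""
    path = Path(path)
    pd.DataFrame(ts.data).to_csv(path, sep="\t", header=False, index=False)
    sidecar = {
        "tr_seconds": ts.tr_seconds,
        "block_id": ts.block_id.tolist(),
        "decodable": None if ts.decodable is None else ts.decodable.astype(int).tolist(),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_voxels_tsv(path: str | Path) -> VoxelTimeSeries:
    path = Path(path)
    data = pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float)
    sidecar_path = path.with_suffix(".json")
    tr, block_id, decodable = 1.0, None, None
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        tr = sidecar.get("tr_seconds", 1.0)
        block_id = sidecar.get("block_id")
        if sidecar.get("decodable") is not None:
            decodable = np.asarray(sidecar["decodable"], dtype=bool)
    return VoxelTimeSeries(data, tr, block_id, decodable)


def save_nifti(ts: VoxelTimeSeries, path: str | Path) -> None:
    """Write a run as 4-D NIfTI (voxels laid out along the first axis)."""
    img = nib.Nifti1Image(
        ts.data.reshape(ts.n_voxels, 1, 1, ts.n_volumes).astype(np.float32),
        affine=np.eye(4),
    )
    img.header.set_zooms((1.0, 1.0, 1.0, ts.tr_seconds))
    nib.save(img, str(path))


def load_nifti(path: str | Path) -> VoxelTimeSeries:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 1.0
    return VoxelTimeSeries(data.reshape(-1, data.shape[-1]), tr or 1.0)


# -------------------------------------------------------------------- events

def design_to_events(design: TaskDesign) -> pd.DataFrame:
    """BIDS-style events table; onsets are block-relative (blocks = runs)."""
    rows = []
    for b, _, trial in design.trials():
        rows.append(
            {
                "onset": trial.onset_seconds,
                "duration": trial.duration_seconds,
                "trial_type": trial.condition,
                "rating": trial.rating if trial.rating is not None else "n/a",
                "block": b,
            }
        )
    return pd.DataFrame(rows)


def save_events_tsv(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, sep="\t", index=False)


def load_events_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["n/a"])


def design_from_events(events: pd.DataFrame, tr_seconds: float = 1.0) -> TaskDesign:
    """Rebuild a :class:`TaskDesign` from an events table."""
    blocks = []
    for b in sorted(events["block"].unique()):
        sub = events[events["block"] == b].sort_values("onset")
        trials = []
        for _, row in sub.iterrows():
            rating = row.get("rating")
            has_rating = rating is not None and np.isfinite(float(rating)) if not isinstance(rating, str) else False
            trials.append(
                Trial(
                    condition=str(row["trial_type"]),
                    onset_seconds=float(row["onset"]),
                    duration_seconds=float(row["duration"]),
                    rating=int(rating) if has_rating else None,
                    rating_eligible=has_rating,
                )
            )
        blocks.append(Block(tuple(trials)))
    return TaskDesign(tuple(blocks), tr_seconds=tr_seconds)


def labels_from_events(
    events: pd.DataFrame, n_volumes: int, block: int, tr_seconds: float = 1.0
) -> LabelSeries:
    """Per-volume labels for one block of an events table (unshifted)."""
    labels = np.full(n_volumes, UNLABELED, dtype=object)
    for _, row in events[events["block"] == block].iterrows():
        start = int(round(float(row["onset"]) / tr_seconds))
        stop = start + int(round(float(row["duration"]) / tr_seconds))
        labels[start:stop] = str(row["trial_type"])
    return LabelSeries(labels, block_id=np.full(n_volumes, block))


def events_from_decoded(events) -> pd.DataFrame:
    """Mental events as a BIDS-style table (trial_type = state)."""
    return pd.DataFrame(
        [
            {
                "onset": e.onset_seconds,
                "duration": e.duration_seconds,
                "trial_type": e.state,
                "n_volumes": e.n_volumes,
            }
            for e in events
        ]
    )


# --------------------------------------------------------------- model, JSON

def save_model(model: ClassifierModel, path: str | Path) -> None:
    payload = {
        "condition_order": list(model.condition_order),
        "penalty": model.penalty,
        "training_volume_count": model.training_volume_count,
        "intercepts": model.intercepts.tolist(),
        "weights": model.weights.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> ClassifierModel:
    payload = json.loads(Path(path).read_text())
    return ClassifierModel(
        weights=np.asarray(payload["weights"]),
        intercepts=np.asarray(payload["intercepts"]),
        penalty=payload["penalty"],
        condition_order=tuple(payload["condition_order"]),
        training_volume_count=payload["training_volume_count"],
    )


def save_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "snr": truth.snr,
        "noise_sd": truth.noise_sd,
        "occupancy": truth.occupancy,
        "active_voxels": truth.active_voxels.astype(int).tolist(),
        "condition_patterns": {k: v.tolist() for k, v in truth.condition_patterns.items()},
        "trial_fidelity": [f.tolist() for f in truth.trial_fidelity],
        "meditation_states": (
            None if truth.meditation_states is None else truth.meditation_states.tolist()
        ),
    }
    Path(path).write_text(json.dumps(payload))


def save_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=float))
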