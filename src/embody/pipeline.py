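"""End-to-end convenience pipelines: simulate -> preprocess -> decode -> score.

These glue functions are what the command-line interface, the test suite,
and typical interactive use call; each stage remains available individually
through its own module.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classifier import (
    AccuracyReport,
    ClassifierModel,
    CrossValResult,
    cross_validate,
    evaluate,
    train,
)
from .containers import LabelSeries, VoxelTimeSeries, concat_runs
from .decoder import DecodedRun, decode_run
from .design import TaskDesign, make_task_design
from .metrics import AttentionMetrics, compute_metrics
from .preprocess import detrend_linear, shift_labels
from .simulate import GroundTruth, simulate_meditation, simulate_subject

HEMODYNAMIC_LAG_SECONDS = 6.0


def prepare_blocks(
    runs: list[VoxelTimeSeries],
    labels: list[LabelSeries],
    lag_seconds: float = HEMODYNAMIC_LAG_SECONDS,
) -> list[tuple[VoxelTimeSeries, LabelSeries]]:
    """Detrend each block and shift its labels by the hemodynamic lag."""
    return [
        (detrend_linear(ts), shift_labels(lab, lag_seconds, ts.tr_seconds))
        for ts, lab in zip(runs, labels)
    ]


@dataclass
class SubjectResult:
    design: TaskDesign
    truth: GroundTruth
    cv: CrossValResult
    report: AccuracyReport


def crossval_pipeline(
    seed: int,
    n_voxels: int = 100,
    snr: float = 1.0,
    penalty: float = 0.01,
    design: TaskDesign | None = None,
    lag_seconds: float = HEMODYNAMIC_LAG_SECONDS,
    **sim_kwargs,
) -> SubjectResult:
    """Simulate one subject and run the full Step-1 cross-validation."""
    design = design if design is not None else make_task_design(seed)
    runs, labels, truth = simulate_subject(design, n_voxels, snr, seed, **sim_kwargs)
    blocks = prepare_blocks(runs, labels, lag_seconds)
    cv = cross_validate(blocks, penalty, design.conditions)
    report = evaluate(cv.decisions, cv.true_labels, design.conditions)
    return SubjectResult(design, truth, cv, report)


def mean_accuracy(
    seeds, n_voxels: int = 500, snr: float = 0.0, penalty: float = 0.01, **sim_kwargs
) -> float:
    """Mean cross-validated accuracy (%) over conditions and seeds."""
    accs = [
        crossval_pipeline(s, n_voxels, snr, penalty, **sim_kwargs).report.mean_accuracy
        for s in seeds
    ]
    return float(np.mean(accs))


def train_full_model(
    seed: int,
    n_voxels: int = 200,
    snr: float = 2.0,
    penalty: float = 0.01,
    design: TaskDesign | None = None,
    lag_seconds: float = HEMODYNAMIC_LAG_SECONDS,
    **sim_kwargs,
) -> tuple[ClassifierModel, GroundTruth, TaskDesign]:
    """Train on all blocks (the Step-2 model uses every labeled volume)."""
    design = design if design is not None else make_task_design(seed)
    runs, labels, truth = simulate_subject(design, n_voxels, snr, seed, **sim_kwargs)
    blocks = prepare_blocks(runs, labels, lag_seconds)
    ts, lab = concat_runs([b[0] for b in blocks], [b[1] for b in blocks])
    model = train(ts, lab, penalty, design.conditions)
    return model, truth, design


@dataclass
class MeditationResult:
    model: ClassifierModel
    truth: GroundTruth
    decoded: DecodedRun
    metrics: AttentionMetrics
    true_states: np.ndarray


def meditation_pipeline(
    seed: int,
    n_voxels: int = 200,
    snr: float = 2.0,
    penalty: float = 0.01,
    n_volumes: int = 600,
    min_dwell: int = 3,
    occupancy: dict[str, float] | None = None,
    **sim_kwargs,
) -> MeditationResult:
    """Simulate, train on the IA task, decode meditation, compute metrics."""
    if occupancy is not None:
        sim_kwargs["occupancy"] = occupancy
    model, truth, _ = train_full_model(seed, n_voxels, snr, penalty, **sim_kwargs)
    run, states = simulate_meditation(truth, n_volumes, min_dwell, seed)
    decoded = decode_run(model, detrend_linear(run))
    metrics = compute_metrics(decoded, subject=str(seed))
    return MeditationResult(model, truth, decoded, metrics, states)


def decoded_occupancy(result: MeditationResult) -> dict[str, float]:
    """Fraction of decodable volumes whose smoothed decision is each state."""
    dec = result.decoded.smoothed_decisions
    return {s: float((dec == s).mean()) for s in result.decoded.states}


def true_occupancy(result: MeditationResult) -> dict[str, float]:
    return {
        s: float((result.true_states == s).mean()) for s in result.decoded.states
    }
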