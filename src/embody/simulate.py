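"""Synthetic multivoxel fMRI data with known ground truth.

Every downstream stage of the pipeline is testable without any scanner data:
this module emits labeled IA-task runs, an unlabeled meditation run with a
known hidden state sequence, and subjective attention ratings coupled to the
fidelity of the emitted patterns.

Signal model
------------
Each condition has a fixed multivoxel activation pattern. During a trial the
pattern is added to the signal, delayed by the hemodynamic lag (a pure 6-s
onset delay, mirroring the analysis-side label shift), and scaled by a
per-trial attention *fidelity* drawn from a configurable range — attention
waxes and wanes, and ratings and decodability both track it. On top of the
pattern sit a per-voxel linear drift and AR(1) Gaussian noise, the minimal
realistic fMRI noise structure with a tunable signal-to-noise knob:
``snr`` is the per-voxel pattern amplitude divided by the noise SD, so
``snr=0`` removes all condition-dependent signal.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .containers import UNLABELED, LabelSeries, VoxelTimeSeries
from .design import (
    MEDITATION_STATES,
    TaskDesign,
    label_series,
    with_ratings,
)

#: Default hidden-state occupancy for the meditation run: mostly on the
#: breath, with equal shares of mind wandering and self-referential thought.
DEFAULT_OCCUPANCY = {"Breath": 0.5, "MW": 0.25, "Self": 0.25}

#: Meditation block structure: a 4-min and a 6-min block. Each block is
#: preceded by 6 s of instructions plus a 2-s reminder, modeled as
#: non-decodable volumes prepended to the block so that exactly
#: ``n_volumes`` decodable volumes remain.
MEDITATION_BLOCK_FRACTIONS = (0.4, 0.6)
MEDITATION_INSTRUCTION_SECONDS = 8.0


@dataclass
class GroundTruth:
    """What the generator actually planted, for validating recovery.

    ``condition_patterns`` maps each condition to its mean voxel pattern
    (amplitude ``snr * noise_sd`` on the active voxels). ``trial_fidelity``
    records the attention fidelity applied to every trial, indexed
    ``[block][trial]``. ``meditation_states`` is filled in by
    :func:`simulate_meditation`.
    """

    condition_patterns: dict[str, np.ndarray]
    snr: float
    noise_sd: float
    occupancy: dict[str, float]
    trial_fidelity: list[np.ndarray]
    active_voxels: np.ndarray
    meditation_states: np.ndarray | None = None

    def __post_init__(self) -> None:
        dims = {p.shape for p in self.condition_patterns.values()}
        if len(dims) != 1:
            raise ValueError("condition patterns must share one voxel grid")
        total = sum(self.occupancy.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError("occupancy fractions must sum to 1")


def _ar1_noise(rng, n_voxels: int, n_volumes: int, sd: float, phi: float) -> np.ndarray:
    """AR(1) noise with marginal SD ``sd`` (innovations scaled by sqrt(1-phi^2))."""
    white = rng.normal(0.0, sd * math.sqrt(max(1.0 - phi**2, 1e-12)), (n_voxels, n_volumes))
    return lfilter([1.0], [1.0, -phi], white, axis=1)


def simulate_subject(
    design: TaskDesign,
    n_voxels: int,
    snr: float,
    seed: int,
    *,
    noise_sd: float = 1.0,
    ar_phi: float = 0.3,
    drift_scale: float = 1.0,
    hemo_lag_seconds: float = 6.0,
    active_fraction: float = 1.0,
    fidelity_range: tuple[float, float] = (0.7, 1.0),
    occupancy: dict[str, float] | None = None,
) -> tuple[list[VoxelTimeSeries], list[LabelSeries], GroundTruth]:
    """Simulate one subject's labeled IA-task runs.

    Returns one :class:`VoxelTimeSeries` and one :class:`LabelSeries` per
    block (labels unshifted; the analysis side applies the hemodynamic
    shift), plus the :class:`GroundTruth`. Identical seeds give bit-identical
    output.

    ``active_fraction`` restricts the condition patterns to a random voxel
    subset (1.0 = dense patterns); the subset is recorded in the ground truth
    so importance-map recovery can be validated. ``drift_scale`` is the
    maximum linear drift excursion over a block, in noise-SD units.
    """
    if n_voxels < 2:
        raise ValueError("n_voxels must be at least 2")
    if snr < 0:
        raise ValueError("snr must be nonnegative")
    if not 0.0 < active_fraction <= 1.0:
        raise ValueError("active_fraction must be in (0, 1]")
    lo, hi = fidelity_range
    if not 0.0 <= lo <= hi:
        raise ValueError("fidelity_range must satisfy 0 <= low <= high")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    n_active = max(1, int(round(active_fraction * n_voxels)))
    active = np.zeros(n_voxels, dtype=bool)
    active[rng.permutation(n_voxels)[:n_active]] = True

    patterns = {}
    for cond in design.conditions:
        p = np.zeros(n_voxels)
        p[active] = rng.normal(0.0, 1.0, n_active) * snr * noise_sd
        patterns[cond] = p

    lag_vols = int(round(hemo_lag_seconds / design.tr_seconds))
    runs: list[VoxelTimeSeries] = []
    labels = label_series(design)
    fidelity: list[np.ndarray] = []
    for b, block in enumerate(design.blocks):
        n = design.n_volumes(b)
        signal = np.zeros((n_voxels, n))
        fids = np.empty(len(block.trials))
        for t, trial in enumerate(block.trials):
            f = rng.uniform(lo, hi)
            fids[t] = f
            start = int(round(trial.onset_seconds / design.tr_seconds)) + lag_vols
            stop = min(n, start + int(round(trial.duration_seconds / design.tr_seconds)))
            signal[:, start:stop] += f * patterns[trial.condition][:, None]
        slope = rng.uniform(-1.0, 1.0, n_voxels) * drift_scale * noise_sd
        ramp = np.linspace(-0.5, 0.5, n)
        data = signal + slope[:, None] * ramp + _ar1_noise(rng, n_voxels, n, noise_sd, ar_phi)
        runs.append(
            VoxelTimeSeries(data, tr_seconds=design.tr_seconds, block_id=np.full(n, b))
        )
        fidelity.append(fids)

    truth = GroundTruth(
        condition_patterns=patterns,
        snr=float(snr),
        noise_sd=float(noise_sd),
        occupancy=dict(occupancy or DEFAULT_OCCUPANCY),
        trial_fidelity=fidelity,
        active_voxels=active,
    )
    return runs, labels, truth


def _dwell_chain(rng, states, occupancy, n_volumes, min_dwell, mean_dwell):
    """Semi-Markov hidden-state sequence with dwell times >= ``min_dwell``.

    Mean dwell per state is proportional to its target occupancy; successors
    are drawn uniformly among the other states, so visit frequencies are
    uniform and long-run occupancy matches the target.
    """
    k = len(states)
    if k == 1:
        return np.array([states[0]] * n_volumes, dtype=object)
    occ = np.array([occupancy[s] for s in states])
    mean_by_state = np.maximum(k * occ * mean_dwell, float(min_dwell))
    seq: list[str] = []
    current = rng.choice(len(states), p=occ / occ.sum())
    while len(seq) < n_volumes:
        mean_extra = mean_by_state[current] - min_dwell
        if mean_extra <= 0:
            dwell = min_dwell
        else:
            dwell = min_dwell + rng.geometric(1.0 / (1.0 + mean_extra)) - 1
        seq.extend([states[current]] * int(dwell))
        others = [i for i in range(k) if i != current]
        current = others[rng.integers(len(others))]
    seq = seq[:n_volumes]
    # Truncation can leave a trailing run shorter than min_dwell; absorb it
    # into the previous run so every run respects the dwell floor.
    tail = 1
    while tail < len(seq) and seq[-tail - 1] == seq[-1]:
        tail += 1
    if tail < min_dwell and len(seq) > tail:
        seq[-tail:] = [seq[-tail - 1]] * tail
    return np.array(seq, dtype=object)


def simulate_meditation(
    truth: GroundTruth,
    n_volumes: int = 600,
    min_dwell: int = 3,
    seed: int = 0,
    *,
    mean_dwell_seconds: float = 10.0,
    tr_seconds: float = 1.0,
    ar_phi: float = 0.3,
    drift_scale: float = 1.0,
    block_lengths: tuple[int, ...] | None = None,
) -> tuple[VoxelTimeSeries, np.ndarray]:
    """Simulate a meditation run with a known hidden state sequence.

    The hidden sequence alternates among the meditation-relevant states in
    ``truth.occupancy`` with dwell times of at least ``min_dwell`` volumes.
    Data are emitted from the same condition patterns as the subject's IA
    runs. The run is split into two blocks (4- and 6-min proportions by
    default); each block is prefixed with 8 s of instruction volumes that are
    flagged non-decodable, so exactly ``n_volumes`` decodable volumes remain.
    """
    if min_dwell < 1:
        raise ValueError("min_dwell must be at least 1")
    if n_volumes < min_dwell:
        raise ValueError("n_volumes must be at least min_dwell")
    states = tuple(truth.occupancy)
    for s in states:
        if s not in MEDITATION_STATES:
            raise ValueError(f"unknown meditation state in occupancy: {s!r}")
        if s not in truth.condition_patterns:
            raise ValueError(f"occupancy state {s!r} has no condition pattern")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 13]))
    hidden = _dwell_chain(
        rng, states, truth.occupancy, n_volumes, min_dwell,
        mean_dwell_seconds / tr_seconds,
    )

    if block_lengths is None:
        first = int(round(MEDITATION_BLOCK_FRACTIONS[0] * n_volumes))
        block_lengths = (first, n_volumes - first)
    if sum(block_lengths) != n_volumes:
        raise ValueError("block_lengths must sum to n_volumes")

    n_voxels = truth.active_voxels.shape[0]
    n_instr = int(round(MEDITATION_INSTRUCTION_SECONDS / tr_seconds))
    data_parts, block_ids, decodable = [], [], []
    pos = 0
    for b, length in enumerate(block_lengths):
        total = n_instr + length
        signal = np.zeros((n_voxels, total))
        for i, s in enumerate(hidden[pos:pos + length]):
            signal[:, n_instr + i] = truth.condition_patterns[s]
        slope = rng.uniform(-1.0, 1.0, n_voxels) * drift_scale * truth.noise_sd
        ramp = np.linspace(-0.5, 0.5, total)
        data = signal + slope[:, None] * ramp + _ar1_noise(
            rng, n_voxels, total, truth.noise_sd, ar_phi
        )
        data_parts.append(data)
        block_ids.append(np.full(total, b))
        mask = np.ones(total, dtype=bool)
        mask[:n_instr] = False
        decodable.append(mask)
        pos += length

    run = VoxelTimeSeries(
        np.concatenate(data_parts, axis=1),
        tr_seconds=tr_seconds,
        block_id=np.concatenate(block_ids),
        decodable=np.concatenate(decodable),
    )
    truth.meditation_states = hidden
    return run, hidden


def simulate_ratings(
    design: TaskDesign,
    truth: GroundTruth,
    coupling: float = 1.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> TaskDesign:
    """Attach 1-4 subjective attention ratings to the eligible trials.

    Ratings are a monotone (rank-quartile) discretization of
    ``coupling * fidelity + noise`` per trial, so ``coupling=0`` makes them
    independent of pattern fidelity while still spanning the full 1-4 range.
    MW trials and trials in the first half of the experiment are never rated.
    """
    eligible = [(b, t) for b, t, trial in design.trials() if trial.rating_eligible]
    if not eligible:
        raise ValueError("design has no rating-eligible trials")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 17]))
    scores = np.array(
        [coupling * truth.trial_fidelity[b][t] for b, t in eligible]
    ) + rng.normal(0.0, noise_sd, len(eligible))
    order = np.argsort(scores, kind="stable")
    ranks = np.empty(len(eligible), dtype=int)
    ranks[order] = np.arange(len(eligible))
    ratings = 1 + np.minimum(3, (4 * ranks) // len(eligible))
    return with_ratings(design, {key: int(r) for key, r in zip(eligible, ratings)})
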