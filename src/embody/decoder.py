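"""Decoding the meditation run into Breath / MW / Self mental events.

The classifier trained on all five IA conditions is applied to each
decodable meditation volume, restricted to the three meditation-relevant
states. Because the five binary models are independent, restriction is
simply an argmax over the three corresponding evidences (no renormalization).

Raw decisions are then cleaned of spurious single-volume flips: a lone
discordant decision sandwiched between two runs of one same state (each run
at least ``min_flank`` volumes long) is relabeled to the flanking state in a
single left-to-right pass. Mental events are maximal same-state runs of at
least ``min_event_length`` consecutive decisions; shorter runs are excluded
from event-based metrics. Events never span the boundary between the two
meditation blocks, since a state cannot be observed across a scan gap.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classifier import ClassifierModel, decide
from .containers import VoxelTimeSeries
from .design import MEDITATION_STATES


@dataclass(frozen=True)
class MentalEvent:
    """A maximal run of >= ``min_event_length`` identical state decisions."""

    state: str
    onset_seconds: float
    duration_seconds: float
    n_volumes: int


@dataclass
class DecodedRun:
    """Full decoding output for one meditation run.

    Arrays cover the decodable volumes only, in acquisition order;
    ``volume_index`` maps each entry back to its volume in the raw run.
    """

    evidence: np.ndarray
    raw_decisions: np.ndarray
    smoothed_decisions: np.ndarray
    events: list[MentalEvent]
    pct_smoothed: float
    pct_excluded: float
    states: tuple[str, ...]
    tr_seconds: float
    block_id: np.ndarray
    volume_index: np.ndarray

    @property
    def n_volumes(self) -> int:
        return self.raw_decisions.shape[0]


def _runs(seq: np.ndarray) -> list[tuple[int, int, object]]:
    """Run-length encode: (start, length, value) per maximal run."""
    out = []
    start = 0
    for i in range(1, len(seq) + 1):
        if i == len(seq) or seq[i] != seq[start]:
            out.append((start, i - start, seq[start]))
            start = i
    return out


def decode(
    model: ClassifierModel,
    run: VoxelTimeSeries,
    allowed: tuple[str, ...] = MEDITATION_STATES,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Evidence and raw argmax decisions for the decodable volumes.

    Returns ``(evidence, decisions, volume_index)`` where ``evidence`` is
    decodable-volumes x len(allowed) (columns in ``allowed`` order as they
    appear in the model) and ``volume_index`` gives each decision's volume
    in the raw run. Conditions outside ``allowed`` are never emitted.
    """
    ev_all = model.evidence(run)  # raises on voxel-grid mismatch
    mask = (
        np.ones(run.n_volumes, dtype=bool) if run.decodable is None else run.decodable
    )
    cols = [model.condition_order.index(c) for c in allowed]
    cols.sort()
    names = tuple(model.condition_order[c] for c in cols)
    ev = ev_all[mask][:, cols]
    decisions = decide(ev_all[mask], names, model.condition_order)
    return ev, decisions, np.flatnonzero(mask)


def smooth_decisions(
    decisions: np.ndarray,
    min_flank: int = 2,
    block_id: np.ndarray | None = None,
    iterative: bool = False,
) -> tuple[np.ndarray, float]:
    """Relabel singleton decisions sandwiched between same-state runs.

    A run of length 1 whose two neighboring runs share one state and each
    have length >= ``min_flank`` takes that state, so the merged run is long
    enough to count as an event. One left-to-right pass over the original
    run structure by default; ``iterative=True`` repeats until no singleton
    qualifies. Smoothing never crosses a block boundary. Returns the
    smoothed decisions and the percentage of volumes relabeled.
    """
    decisions = np.asarray(decisions, dtype=object)
    if decisions.size == 0:
        raise ValueError("decisions must be non-empty")
    if block_id is None:
        block_id = np.zeros(decisions.shape[0], dtype=int)
    out = decisions.copy()
    total_changed = 0
    for b in np.unique(block_id):
        seg_idx = np.flatnonzero(block_id == b)
        seg = out[seg_idx]
        while True:
            runs = _runs(seg)
            changed = 0
            for i in range(1, len(runs) - 1):
                start, length, value = runs[i]
                ps, pl, pv = runs[i - 1]
                ns, nl, nv = runs[i + 1]
                if length == 1 and pv == nv and pv != value and pl >= min_flank and nl >= min_flank:
                    seg[start] = pv
                    changed += 1
            total_changed += changed
            if not iterative or changed == 0:
                break
        out[seg_idx] = seg
    return out, 100.0 * total_changed / decisions.shape[0]


def extract_events(
    decisions: np.ndarray,
    min_event_length: int = 3,
    tr_seconds: float = 1.0,
    block_id: np.ndarray | None = None,
    volume_index: np.ndarray | None = None,
) -> tuple[list[MentalEvent], float]:
    """Segment decisions into mental events, excluding sub-threshold runs.

    Maximal same-state runs of at least ``min_event_length`` decisions become
    events; the rest are excluded and counted in ``pct_excluded``. Runs are
    broken at block boundaries. ``volume_index``, when given, anchors event
    onsets to raw-run volume indices (times in seconds from run start).
    """
    decisions = np.asarray(decisions, dtype=object)
    if decisions.size == 0:
        raise ValueError("decisions must be non-empty")
    if block_id is None:
        block_id = np.zeros(decisions.shape[0], dtype=int)
    if volume_index is None:
        volume_index = np.arange(decisions.shape[0])
    events: list[MentalEvent] = []
    excluded = 0
    for b in np.unique(block_id):
        seg_idx = np.flatnonzero(block_id == b)
        for start, length, value in _runs(decisions[seg_idx]):
            if length >= min_event_length:
                onset = float(volume_index[seg_idx[start]]) * tr_seconds
                events.append(
                    MentalEvent(str(value), onset, length * tr_seconds, length)
                )
            else:
                excluded += length
    events.sort(key=lambda e: e.onset_seconds)
    return events, 100.0 * excluded / decisions.shape[0]


def decode_run(
    model: ClassifierModel,
    run: VoxelTimeSeries,
    allowed: tuple[str, ...] = MEDITATION_STATES,
    *,
    min_flank: int = 2,
    min_event_length: int = 3,
    smoothing: bool = True,
    iterative_smoothing: bool = False,
) -> DecodedRun:
    """Full Step-2 decoding: evidence, decisions, smoothing, events."""
    ev, raw, vol_idx = decode(model, run, allowed)
    block = run.block_id[vol_idx]
    if smoothing:
        smoothed, pct_smoothed = smooth_decisions(
            raw, min_flank, block, iterative=iterative_smoothing
        )
    else:
        smoothed, pct_smoothed = raw.copy(), 0.0
    events, pct_excluded = extract_events(
        smoothed, min_event_length, run.tr_seconds, block, vol_idx
    )
    return DecodedRun(
        evidence=ev,
        raw_decisions=raw,
        smoothed_decisions=smoothed,
        events=events,
        pct_smoothed=pct_smoothed,
        pct_excluded=pct_excluded,
        states=tuple(allowed),
        tr_seconds=run.tr_seconds,
        block_id=block,
        volume_index=vol_idx,
    )
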