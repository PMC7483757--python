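"""Internal-attention (IA) task designs.

The IA task directs a subject's attention, via short auditory instructions,
to one of five internal states: breath sensations (Breath), foot sensations
(Feet), mind wandering (MW), self-referential processing (Self), and ambient
scanner sounds (Sounds). Six task blocks are acquired, each a balanced 13-trial
schedule delivering exactly 72 s of every condition per block, flanked by 20-s
baseline periods. Short conditions (Breath/Feet/Sounds) run three trials per
block with even durations between 16 and 32 s, arranged so that across the
experiment every even duration in that range is used exactly twice per
condition. MW and Self run two longer trials per block (even durations,
22-50 s) that pair up to 72 s.

This schedule yields 432 labeled volumes per condition and 2,160 in total at
a 1-s sampling interval, which is the training corpus for the per-subject
classifiers.
"""
from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, replace

import numpy as np

from .containers import UNLABELED, LabelSeries

#: Fixed condition declaration order; argmax ties are broken by this order.
CONDITIONS = ("Breath", "Feet", "MW", "Self", "Sounds")
#: The three states decoded during meditation.
MEDITATION_STATES = ("Breath", "MW", "Self")
#: Conditions with three short trials per block.
SHORT_TRIAL_CONDITIONS = ("Breath", "Feet", "Sounds")
#: Conditions with two long trials per block.
LONG_TRIAL_CONDITIONS = ("MW", "Self")

INSTRUCTION_SECONDS = 2.0
BASELINE_SECONDS = 20.0
SECONDS_PER_CONDITION_PER_BLOCK = 72.0

_SHORT_DURATIONS = tuple(range(16, 33, 2))  # even 16..32 s
_LONG_DURATIONS = tuple(range(22, 51, 2))  # even 22..50 s


class InfeasibleDesignError(ValueError):
    """Raised when the requested block count cannot satisfy design balance."""


@dataclass(frozen=True)
class Trial:
    """One attention trial inside a block.

    ``onset_seconds`` is the offset of the trial's first labeled second from
    the start of its block (each block is a separate scanner run). The 2-s
    auditory instruction immediately precedes the onset and is unlabeled.
    ``rating_eligible`` marks trials that receive a 1-4 subjective attention
    rating (trials in the last half of the experiment, never MW trials, since
    subjects are told to stop attending during MW).
    """

    condition: str
    onset_seconds: float
    duration_seconds: float
    rating: int | None = None
    rating_eligible: bool = False


@dataclass(frozen=True)
class Block:
    trials: tuple[Trial, ...]
    baseline_pre_seconds: float = BASELINE_SECONDS
    baseline_post_seconds: float = BASELINE_SECONDS

    @property
    def duration_seconds(self) -> float:
        labeled = sum(t.duration_seconds for t in self.trials)
        instructions = INSTRUCTION_SECONDS * len(self.trials)
        return self.baseline_pre_seconds + instructions + labeled + self.baseline_post_seconds


@dataclass(frozen=True)
class TaskDesign:
    blocks: tuple[Block, ...]
    conditions: tuple[str, ...] = CONDITIONS
    tr_seconds: float = 1.0

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def n_volumes(self, block: int) -> int:
        return int(round(self.blocks[block].duration_seconds / self.tr_seconds))

    def trials(self):
        """Iterate (block_index, trial_index, trial) over the whole design."""
        for b, block in enumerate(self.blocks):
            for t, trial in enumerate(block.trials):
                yield b, t, trial


def _partition_triples(pool: list[int], n_groups: int, target: int, rng) -> list[list[int]]:
    """Partition a duration multiset into triples with a fixed sum.

    Backtracking over the value with the largest remaining count first keeps
    the search shallow; candidate completions are shuffled so different seeds
    yield different (valid) block assignments.
    """
    counts = Counter(pool)
    values = sorted(counts)

    def helper(counts: Counter, n_left: int):
        if n_left == 0:
            return []
        vmax = max(v for v in values if counts[v] > 0)
        c2 = counts.copy()
        c2[vmax] -= 1
        rest = target - vmax
        avail = [v for v in values if c2[v] > 0]
        cands = []
        for combo in itertools.combinations_with_replacement(avail, 2):
            if sum(combo) != rest:
                continue
            cc = Counter(combo)
            if all(c2[v] >= k for v, k in cc.items()):
                cands.append(combo)
        rng.shuffle(cands)
        for combo in cands:
            c3 = c2.copy()
            for v in combo:
                c3[v] -= 1
            sub = helper(c3, n_left - 1)
            if sub is not None:
                return [[vmax, *combo]] + sub
        return None

    groups = helper(counts, n_groups)
    if groups is None:  # pragma: no cover - pool construction guarantees feasibility
        raise InfeasibleDesignError("could not balance trial durations across blocks")
    rng.shuffle(groups)
    for g in groups:
        rng.shuffle(g)
    return groups


def make_task_design(seed: int, n_blocks: int = 6, order_set: int = 1,
                     tr_seconds: float = 1.0) -> TaskDesign:
    """Generate a balanced IA task design.

    Parameters
    ----------
    seed
        Seeds every randomized choice (trial order, duration assignment).
        Identical seeds reproduce identical designs.
    n_blocks
        Number of task blocks. Duration balance (each short duration used the
        same number of times per condition) requires a multiple of 3; other
        values raise :class:`InfeasibleDesignError`.
    order_set
        Selects one of four condition-order permutation sets derived from the
        seed, mirroring a randomized stimulus-order protocol.
    """
    if not isinstance(n_blocks, (int, np.integer)) or n_blocks < 1:
        raise ValueError("n_blocks must be a positive integer")
    if order_set not in (1, 2, 3, 4):
        raise ValueError("order_set must be 1, 2, 3, or 4")
    if n_blocks % 3 != 0:
        raise InfeasibleDesignError(
            f"n_blocks={n_blocks}: duration balance requires a multiple of 3 blocks"
        )

    # Four cached condition-order permutation sets per seed; order_set picks one.
    order_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7919]))
    slot_template = (
        list(SHORT_TRIAL_CONDITIONS) * 3 + list(LONG_TRIAL_CONDITIONS) * 2
    )
    order_sets = []
    for _ in range(4):
        per_block = []
        for _ in range(n_blocks):
            seq = list(slot_template)
            order_rng.shuffle(seq)
            per_block.append(seq)
        order_sets.append(per_block)
    block_orders = order_sets[order_set - 1]

    dur_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 104729, order_set]))

    # Short conditions: each even duration 16..32 appears n_blocks/3 times per
    # condition; partition each condition's pool into per-block triples of 72 s.
    copies = n_blocks // 3
    short_pools: dict[str, list[list[int]]] = {}
    for cond in SHORT_TRIAL_CONDITIONS:
        pool = [d for d in _SHORT_DURATIONS for _ in range(copies)]
        short_pools[cond] = _partition_triples(
            pool, n_blocks, int(SECONDS_PER_CONDITION_PER_BLOCK), dur_rng
        )

    # Long conditions: one (d, 72-d) pair per block, d spread over 22..50 s.
    long_pools: dict[str, list[list[int]]] = {}
    for cond in LONG_TRIAL_CONDITIONS:
        choices = list(_LONG_DURATIONS)
        dur_rng.shuffle(choices)
        pairs = []
        for b in range(n_blocks):
            d = int(choices[b % len(choices)])
            pair = [d, int(SECONDS_PER_CONDITION_PER_BLOCK) - d]
            dur_rng.shuffle(pair)
            pairs.append(pair)
        long_pools[cond] = pairs

    rating_start_block = n_blocks - n_blocks // 2  # last half of the experiment
    blocks = []
    for b in range(n_blocks):
        queues = {c: list(short_pools[c][b]) for c in SHORT_TRIAL_CONDITIONS}
        queues.update({c: list(long_pools[c][b]) for c in LONG_TRIAL_CONDITIONS})
        t = BASELINE_SECONDS
        trials = []
        for cond in block_orders[b]:
            dur = queues[cond].pop()
            onset = t + INSTRUCTION_SECONDS
            eligible = b >= rating_start_block and cond != "MW"
            trials.append(
                Trial(cond, float(onset), float(dur), rating_eligible=eligible)
            )
            t = onset + dur
        blocks.append(Block(tuple(trials)))
    return TaskDesign(tuple(blocks), tr_seconds=tr_seconds)


def label_series(design: TaskDesign) -> list[LabelSeries]:
    """Per-block, per-volume condition labels (unshifted, lag 0).

    Baseline and instruction volumes are :data:`~embody.containers.UNLABELED`.
    """
    out = []
    for b, block in enumerate(design.blocks):
        n = design.n_volumes(b)
        labels = np.full(n, UNLABELED, dtype=object)
        for trial in block.trials:
            start = int(round(trial.onset_seconds / design.tr_seconds))
            stop = start + int(round(trial.duration_seconds / design.tr_seconds))
            labels[start:stop] = trial.condition
        out.append(LabelSeries(labels, block_id=np.full(n, b), lag_seconds=0.0))
    return out


def with_ratings(design: TaskDesign, ratings: dict[tuple[int, int], int]) -> TaskDesign:
    """Return a copy of the design with ratings attached.

    ``ratings`` maps ``(block_index, trial_index)`` to an integer 1-4; only
    rating-eligible trials may appear.
    """
    new_blocks = []
    for b, block in enumerate(design.blocks):
        new_trials = []
        for t, trial in enumerate(block.trials):
            if (b, t) in ratings:
                if not trial.rating_eligible:
                    raise ValueError(f"trial ({b}, {t}) is not rating-eligible")
                value = int(ratings[(b, t)])
                if value not in (1, 2, 3, 4):
                    raise ValueError("ratings must be integers 1-4")
                new_trials.append(replace(trial, rating=value))
            else:
                new_trials.append(trial)
        new_blocks.append(replace(block, trials=tuple(new_trials)))
    return replace(design, blocks=tuple(new_blocks))
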