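"""Meditation decoding, singleton smoothing, and event segmentation."""
import numpy as np
import pytest

from embody import (
    decode_run,
    extract_events,
    meditation_pipeline,
    smooth_decisions,
)


def _seq(s):
    return np.array(list(s), dtype=object)


# ------------------------------------------------------- independent oracles

def _naive_smooth(seq, min_flank=2):
    """Pointwise singleton check on the original sequence."""
    seq = list(seq)
    out = list(seq)
    n = len(seq)
    for i in range(n):
        if i - min_flank < 0 or i + min_flank >= n:
            continue
        left = seq[i - min_flank: i]
        right = seq[i + 1: i + 1 + min_flank]
        if (
            len(set(left)) == 1
            and set(left) == set(right)
            and left[0] != seq[i]
        ):
            # left run must not extend into i (it cannot: left[-1] != seq[i])
            # but the run of left[0] must be at least min_flank long ending at
            # i-1 and starting no later than i-min_flank, which the window
            # equality already guarantees.
            out[i] = left[0]
    return np.array(out, dtype=object)


def _naive_events(seq, min_len=3):
    """Explicit scan for maximal same-state runs."""
    events = []
    excluded = 0
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len:
            events.append((i, j - i, seq[i]))
        else:
            excluded += j - i
        i = j
    return events, 100.0 * excluded / n


class TestSmoothing:
    def test_worked_example(self):
        out, pct = smooth_decisions(_seq("MMMSMMM"))
        assert "".join(out) == "MMMMMMM"
        assert pct == pytest.approx(100.0 / 7.0)

    def test_no_singletons_unchanged(self):
        out, pct = smooth_decisions(_seq("BBBMMMSSS"))
        assert "".join(out) == "BBBMMMSSS"
        assert pct == 0.0

    def test_all_singletons_unchanged_with_default_flank(self):
        out, pct = smooth_decisions(_seq("BSB"))
        assert "".join(out) == "BSB"
        assert pct == 0.0

    def test_flank_length_requirement(self):
        # left flank has length 1: not an event-worthy neighbor
        out, _ = smooth_decisions(_seq("SBSBB"))
        assert "".join(out) == "SBSBB"
        out, _ = smooth_decisions(_seq("BBSBB"))
        assert "".join(out) == "BBBBB"

    def test_looser_flank_reading(self):
        out, _ = smooth_decisions(_seq("BSB"), min_flank=1)
        assert "".join(out) == "BBB"

    def test_single_pass_evaluates_original_runs(self):
        # the second singleton's right flank has length 1 on the original
        # sequence, so it is left alone even though the first was relabeled
        out, _ = smooth_decisions(_seq("BBSBBSB"))
        assert "".join(out) == "BBBBBSB"

    def test_iterative_mode_rescans_merged_runs(self):
        seq = _seq("BBSBSBB")
        out_once, _ = smooth_decisions(seq, min_flank=1)
        assert "".join(out_once) == "BBBSBBB"
        out_iter, _ = smooth_decisions(seq, min_flank=1, iterative=True)
        assert "".join(out_iter) == "BBBBBBB"

    def test_blocks_not_crossed(self):
        seq = _seq("BBSBB")
        block = np.array([0, 0, 0, 1, 1])
        out, pct = smooth_decisions(seq, block_id=block)
        assert "".join(out) == "BBSBB"
        assert pct == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            smooth_decisions(np.array([], dtype=object))


class TestEvents:
    def test_worked_example(self):
        events, pct = extract_events(_seq("SSSSBBMMM"))
        assert [(e.state, e.n_volumes, e.onset_seconds) for e in events] == [
            ("S", 4, 0.0),
            ("M", 3, 6.0),
        ]
        assert pct == pytest.approx(2 / 9 * 100)

    def test_single_long_event(self):
        events, pct = extract_events(np.array(["B"] * 600, dtype=object))
        assert len(events) == 1
        assert events[0].duration_seconds == 600.0
        assert pct == 0.0

    def test_alternating_gives_no_events(self):
        events, pct = extract_events(_seq("BSBSBSBS"))
        assert events == []
        assert pct == 100.0

    def test_block_boundary_truncates_runs(self):
        seq = np.array(["B"] * 6, dtype=object)
        block = np.array([0, 0, 0, 0, 1, 1])
        events, pct = extract_events(seq, block_id=block)
        assert [(e.state, e.n_volumes) for e in events] == [("B", 4)]
        assert pct == pytest.approx(2 / 6 * 100)

    def test_conservation(self):
        rng = np.random.default_rng(0)
        seq = rng.choice(np.array(list("BMS"), dtype=object), size=200)
        events, pct = extract_events(seq)
        event_vols = sum(e.n_volumes for e in events)
        assert event_vols + round(pct / 100 * 200) == 200


@pytest.mark.parametrize("n_sequences", [2000])
def test_smoothing_and_events_match_bruteforce(n_sequences):
    """Run-length implementation agrees with naive references on random data."""
    rng = np.random.default_rng(42)
    states = np.array(list("BMS"), dtype=object)
    for _ in range(n_sequences):
        seq = rng.choice(states, size=int(rng.integers(1, 51)))
        sm, pct = smooth_decisions(seq)
        ref = _naive_smooth(seq)
        np.testing.assert_array_equal(sm, ref)
        assert pct == pytest.approx(100.0 * (sm != seq).sum() / len(seq))
        events, pct_ex = extract_events(sm)
        ref_events, ref_pct = _naive_events(list(sm))
        assert [(e.onset_seconds, e.n_volumes, e.state) for e in events] == [
            (float(i), l, s) for i, l, s in ref_events
        ]
        assert pct_ex == pytest.approx(ref_pct)


class TestDecodeRun:
    def test_restriction_and_count(self):
        res = meditation_pipeline(5, n_voxels=60, snr=1.5)
        d = res.decoded
        assert d.n_volumes == 600
        assert set(d.raw_decisions.tolist()) <= {"Breath", "MW", "Self"}
        assert set(d.smoothed_decisions.tolist()) <= {"Breath", "MW", "Self"}
        assert d.evidence.shape == (600, 3)
        assert 0.0 <= d.pct_smoothed <= 100.0
        assert 0.0 <= d.pct_excluded <= 100.0

    def test_event_volume_conservation(self):
        res = meditation_pipeline(6, n_voxels=60, snr=1.0)
        d = res.decoded
        event_vols = sum(e.n_volumes for e in d.events)
        assert event_vols + round(d.pct_excluded / 100 * d.n_volumes) == d.n_volumes
        # every event volume carries the event's state in the smoothed series
        pos = {int(v): i for i, v in enumerate(d.volume_index)}
        for e in d.events:
            start = pos[int(e.onset_seconds)]
            assert all(
                d.smoothed_decisions[start + k] == e.state for k in range(e.n_volumes)
            )

    def test_pure_breath_run_decodes_as_breath(self):
        # decode the raw emission directly: demeaning a run that never leaves
        # one state would remove its pattern (see the methods note), so the
        # pure-pattern contract is a property of decode() on the raw signal
        from embody.decoder import decode
        from embody.pipeline import train_full_model
        from embody.simulate import simulate_meditation

        for seed in (1, 2, 3):
            model, truth, _ = train_full_model(seed, n_voxels=60, snr=2.0,
                                               occupancy={"Breath": 1.0})
            run, _ = simulate_meditation(truth, seed=seed)
            _, decisions, _ = decode(model, run)
            assert float((decisions == "Breath").mean()) >= 0.95

    def test_voxel_mismatch(self):
        from embody.containers import VoxelTimeSeries
        from embody.decoder import decode
        from embody.pipeline import train_full_model

        model, _, _ = train_full_model(1, n_voxels=20, snr=1.0)
        run = VoxelTimeSeries(np.zeros((10, 30)))
        with pytest.raises(ValueError, match="voxels"):
            decode(model, run)
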