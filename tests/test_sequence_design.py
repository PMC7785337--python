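"""Design invariants of the six stimulus paradigms."""

import numpy as np
import pytest

from oddball_mismatch.sequence_design import (
    Direction,
    Paradigm,
    Role,
    StimulusEvent,
    StimulusSequence,
    events_to_frame,
    make_cascade,
    make_dev_alone,
    make_many_standards,
    make_oddball,
    make_tone_set,
    validate_sequence,
)


class TestToneSet:
    def test_half_octave_steps_span_4_5_octaves(self):
        ts = make_tone_set(1000.0, 0.5, 10, 60.0)
        assert ts.frequencies_hz[9] == pytest.approx(1000 * 2**4.5)
        assert np.log2(ts.frequencies_hz[9] / ts.frequencies_hz[0]) == pytest.approx(4.5)
        # consistent with tone sets spanning roughly 0.6-42.5 kHz
        lo = make_tone_set(600.0, 0.5, 10)
        assert lo.frequencies_hz[9] == pytest.approx(600 * 2**4.5)
        assert 13000 < lo.frequencies_hz[9] < 42500

    def test_one_octave_step_doubles(self):
        ts = make_tone_set(1000.0, 1.0, 2)
        assert list(ts.frequencies_hz) == [1000.0, 2000.0]

    def test_log_spacing_matches_octave_step(self):
        ts = make_tone_set(1234.5, 0.5, 10)
        steps = np.diff(np.log2(ts.frequencies_hz))
        assert np.allclose(steps, 0.5, atol=1e-9)

    @pytest.mark.parametrize("base,n", [(-1.0, 10), (0.0, 10), (1000.0, 1)])
    def test_invalid_arguments_rejected(self, base, n):
        with pytest.raises(ValueError):
            make_tone_set(base, 0.5, n)


class TestOddball:
    def test_default_counts_40_dev_360_std(self, tones):
        seq = make_oddball(tones, 5, seed=1)
        assert seq.role_positions(Role.DEV).size == 40
        assert seq.role_positions(Role.STD).size == 360

    def test_zero_dev_prob_gives_all_std(self, tones):
        seq = make_oddball(tones, 5, dev_prob=0.0, seed=3)
        assert seq.role_positions(Role.DEV).size == 0
        assert seq.role_positions(Role.STD).size == 400

    def test_small_sequences_all_valid_and_gap_rule_holds(self, tones):
        """Brute-force scan: 100 seeds of a 40-event oddball."""
        for seed in range(100):
            seq = make_oddball(tones, 5, n_events=40, dev_prob=0.10, seed=seed)
            rep = validate_sequence(seq)
            assert rep.ok, rep.offenders
            dev = seq.role_positions(Role.DEV)
            roles = [e.role for e in seq.events]
            for p in dev:
                assert p >= 10
                assert all(r is Role.STD for r in roles[p - 3 : p])

    def test_direction_sets_dev_frequency_side(self, tones):
        up = make_oddball(tones, 5, Direction.ASCENDING, seed=0)
        down = make_oddball(tones, 5, Direction.DESCENDING, seed=0)
        for seq, cmp in ((up, np.greater), (down, np.less)):
            dev = seq.role_positions(Role.DEV)
            std = seq.role_positions(Role.STD)
            f_dev = tones.frequencies_hz[seq.tone_indices()[dev[0]]]
            f_std = tones.frequencies_hz[seq.tone_indices()[std[0]]]
            assert cmp(f_dev, f_std)

    def test_seeded_reproducibility_and_seed_sensitivity(self, tones):
        a = make_oddball(tones, 5, seed=42)
        b = make_oddball(tones, 5, seed=42)
        assert a.events == b.events
        collisions = 0
        for s in range(0, 200, 2):
            x = make_oddball(tones, 5, seed=s)
            y = make_oddball(tones, 5, seed=s + 1)
            if np.array_equal(x.role_positions(Role.DEV), y.role_positions(Role.DEV)):
                collisions += 1
        assert collisions == 0

    def test_infeasible_design_raises(self, tones):
        with pytest.raises(ValueError):
            make_oddball(tones, 5, n_events=100, dev_prob=0.5, seed=0)

    def test_presentation_rate_is_soa_inverse(self, tones):
        seq = make_oddball(tones, 5, seed=0)
        assert np.allclose(np.diff(seq.onsets()), seq.soa_s)
        assert seq.n_events / seq.duration_s == pytest.approx(1 / seq.soa_s)


class TestCascade:
    def test_ascending_ramp_pattern(self, tones):
        seq = make_cascade(tones, Direction.ASCENDING, 400)
        assert np.array_equal(seq.tone_indices(), np.tile(np.arange(10), 40))
        counts = np.bincount(seq.tone_indices(), minlength=10)
        assert np.all(counts == 40)  # per-tone probability 0.10

    def test_reversed_ascending_equals_descending(self, tones):
        up = make_cascade(tones, Direction.ASCENDING, 400)
        down = make_cascade(tones, Direction.DESCENDING, 400)
        assert np.array_equal(up.tone_indices()[::-1], down.tone_indices())

    def test_predecessor_matches_oddball(self, tones):
        """The tone before the tone of interest is the same in the
        ascending cascade and the ascending oddball."""
        k = 5
        cas = make_cascade(tones, Direction.ASCENDING, 400)
        idx = cas.tone_indices()
        occ = np.nonzero(idx == k)[0]
        occ = occ[occ > 0]
        assert np.all(idx[occ - 1] == k - 1)
        odd = make_oddball(tones, k, Direction.ASCENDING, seed=9)
        oidx = odd.tone_indices()
        dev = odd.role_positions(Role.DEV)
        assert np.all(oidx[dev - 1] == k - 1)

    def test_indivisible_event_count_rejected(self, tones):
        with pytest.raises(ValueError):
            make_cascade(tones, Direction.ASCENDING, 401)


class TestManyStandards:
    def test_equal_histogram_and_determinism(self, tones):
        a = make_many_standards(tones, 400, seed=7)
        b = make_many_standards(tones, 400, seed=7)
        assert a.events == b.events
        assert np.all(np.bincount(a.tone_indices(), minlength=10) == 40)

    def test_no_adjacent_repeats_over_many_seeds(self, tones):
        """Brute-force scan across seeds: no tone ever repeats back-to-back."""
        for seed in range(300):
            seq = make_many_standards(tones, 400, seed=seed)
            assert np.all(np.diff(seq.tone_indices()) != 0)


class TestDevAlone:
    def test_min_silent_gap_is_1925_ms(self, tones):
        odd = make_oddball(tones, 5, seed=1)
        da = make_dev_alone(odd)
        audible = da.onsets(Role.DEV_ALONE)
        min_gap = np.diff(audible).min() - da.events[0].duration_s
        assert min_gap == pytest.approx(4 * odd.soa_s - 0.075)
        assert min_gap == pytest.approx(1.925)

    def test_muting_preserves_dev_events(self, tones):
        odd = make_oddball(tones, 5, seed=2)
        da = make_dev_alone(odd)
        dev_onsets = odd.onsets(Role.DEV)
        assert np.array_equal(da.onsets(Role.DEV_ALONE), dev_onsets)
        assert da.role_positions(Role.DEV_ALONE).size == 40
        muted = [da.events[i] for i in da.role_positions(Role.MUTED)]
        assert all(e.tone_index is None for e in muted)

    def test_non_oddball_input_rejected(self, tones):
        with pytest.raises(ValueError):
            make_dev_alone(make_cascade(tones, Direction.ASCENDING, 400))


class TestValidateSequence:
    def test_valid_sequences_pass(self, tones):
        for seq in (
            make_oddball(tones, 5, seed=0),
            make_cascade(tones, Direction.DESCENDING, 400),
            make_many_standards(tones, 400, seed=0),
            make_dev_alone(make_oddball(tones, 5, seed=0)),
        ):
            assert validate_sequence(seq).ok

    def test_injected_short_gap_detected(self, tones):
        odd = make_oddball(tones, 5, seed=0)
        events = list(odd.events)
        dev = odd.role_positions(Role.DEV)
        bad = int(dev[0]) + 2  # two STDs after a DEV -> 2-STD gap
        events[bad] = StimulusEvent(
            onset_s=events[bad].onset_s, role=Role.DEV, tone_index=5
        )
        broken = StimulusSequence(
            paradigm=odd.paradigm, events=tuple(events), tones=odd.tones,
            soa_s=odd.soa_s, target_tone=odd.target_tone, direction=odd.direction,
        )
        rep = validate_sequence(broken)
        assert not rep.checks["min_std_gap_before_dev"]
        assert bad in rep.offenders["min_std_gap_before_dev"]

    def test_swapped_cascade_pair_detected(self, tones):
        cas = make_cascade(tones, Direction.ASCENDING, 400)
        events = list(cas.events)
        events[3], events[4] = (
            StimulusEvent(events[3].onset_s, Role.CASCADE, events[4].tone_index),
            StimulusEvent(events[4].onset_s, Role.CASCADE, events[3].tone_index),
        )
        broken = StimulusSequence(
            paradigm=cas.paradigm, events=tuple(events), tones=cas.tones,
            soa_s=cas.soa_s,
        )
        rep = validate_sequence(broken)
        assert not rep.checks["cyclic_ramp"]


def test_events_frame_schema(tones):
    seq = make_oddball(tones, 5, seed=0)
    df = events_to_frame(seq, "s1")
    assert len(df) == 400
    assert set(df.columns) >= {
        "sequence_id", "paradigm", "event_index", "onset_s", "tone_index",
        "frequency_hz", "role", "target_flag",
    }
    assert df["target_flag"].sum() == 40
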