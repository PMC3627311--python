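"""Block-design schedule generation: token arithmetic and invariants."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import nirschange as nc
from nirschange.schedule import (
    ADULT_CONDITIONS,
    BASELINE_WORD,
    CONDITION_WORDS,
    PHONEME_DURATIONS_MS,
    Block,
    ScheduleConfig,
)


class TestWordDurations:
    @pytest.mark.parametrize(
        "word, expected_ms",
        [("abna", 458.6), ("abuna", 584.1), ("abuuna", 822.5)],
    )
    def test_word_duration_is_phoneme_sum(self, word, expected_ms):
        assert nc.word_duration_ms(word) == pytest.approx(expected_ms, abs=1e-9)
        assert nc.word_duration_ms(word) == pytest.approx(
            sum(PHONEME_DURATIONS_MS[word]), abs=1e-12
        )

    def test_unknown_word_raises(self):
        with pytest.raises(KeyError):
            nc.word_duration_ms("banana")

    def test_every_word_fits_in_one_soa_slot(self):
        soa_ms = ScheduleConfig().soa_s * 1000
        for word in PHONEME_DURATIONS_MS:
            assert nc.word_duration_ms(word) < soa_ms


class TestTokenCounts:
    def test_nine_second_target_block_holds_six_tokens(self, rng):
        block = Block("target", "cluster", 0.0, 9.0)
        tokens = nc.token_sequence(block, ScheduleConfig(), rng)
        assert len(tokens) == 6

    def test_eighteen_second_baseline_block_holds_twelve_tokens(self, rng):
        block = Block("baseline", None, 0.0, 18.0)
        tokens = nc.token_sequence(block, ScheduleConfig(), rng)
        assert len(tokens) == 12
        assert all(t.word == BASELINE_WORD for t in tokens)

    def test_target_block_mixes_only_the_two_expected_words(self, rng):
        block = Block("target", "cluster", 0.0, 9.0)
        words = {t.word for t in nc.token_sequence(block, ScheduleConfig(), rng)}
        assert words <= {BASELINE_WORD, CONDITION_WORDS["cluster"]}
        assert CONDITION_WORDS["cluster"] in words

    def test_no_word_run_longer_than_two(self, rng):
        block = Block("target", "duration", 0.0, 18.0)
        cfg = ScheduleConfig(target_duration_s=18.0, baseline_jitter_s=(18.0, 18.0))
        for _ in range(20):
            words = [t.word for t in nc.token_sequence(block, cfg, rng)]
            for i in range(len(words) - 2):
                assert not (words[i] == words[i + 1] == words[i + 2])

    def test_multi_mode_never_repeats_a_token_immediately(self, rng):
        block = Block("baseline", None, 0.0, 18.0)
        tokens = nc.token_sequence(block, ScheduleConfig(), rng)
        for a, b in zip(tokens, tokens[1:]):
            assert (a.word, a.token_index) != (b.word, b.token_index)

    def test_single_mode_uses_token_one_only(self, rng):
        cfg = ScheduleConfig(token_mode="single")
        block = Block("target", "cluster", 0.0, 9.0)
        assert {t.token_index for t in nc.token_sequence(block, cfg, rng)} == {1}


class TestInfantSchedule:
    @given(seed=st.integers(0, 10_000))
    def test_structure_invariants(self, seed):
        sched = nc.generate_infant_schedule(seed=seed)
        kinds = [b.kind for b in sched.blocks]
        # strict alternation, baseline first and last
        assert kinds[0] == kinds[-1] == "baseline"
        assert all(a != b for a, b in zip(kinds, kinds[1:]))
        # balanced conditions
        conds = [b.condition for b in sched.blocks if b.kind == "target"]
        assert conds.count("cluster") == conds.count("duration")
        # blocks contiguous; baselines inside the jitter interval on SOA grid
        t = 0.0
        for b in sched.blocks:
            assert b.onset_s == pytest.approx(t)
            t = b.end_s
            if b.kind == "baseline":
                assert 9.0 <= b.duration_s <= 18.0
                assert (b.duration_s / 1.5) == pytest.approx(round(b.duration_s / 1.5))

    @given(seed=st.integers(0, 10_000))
    def test_every_token_fits_inside_its_block(self, seed):
        sched = nc.generate_infant_schedule(seed=seed)
        for block in sched.blocks:
            inside = [
                t for t in sched.tokens
                if block.onset_s - 1e-9 <= t.onset_s < block.end_s
            ]
            n = round(block.duration_s / sched.config.soa_s)
            assert len(inside) == n
            for tok in inside:
                assert tok.onset_s + nc.word_duration_ms(tok.word) / 1000 < block.end_s

    def test_same_seed_reproduces_schedule(self):
        a = nc.generate_infant_schedule(seed=5)
        b = nc.generate_infant_schedule(seed=5)
        assert a == b

    def test_jitter_without_soa_multiple_raises(self):
        with pytest.raises(ValueError, match="SOA multiple"):
            ScheduleConfig(baseline_jitter_s=(9.1, 9.4))

    def test_infant_jitter_must_cover_target_duration(self):
        cfg = ScheduleConfig(baseline_jitter_s=(6.0, 18.0), target_duration_s=9.0)
        with pytest.raises(ValueError, match="lower bound"):
            nc.generate_infant_schedule(cfg)


class TestSessionDuration:
    def test_analytic_expectation_for_maximal_design(self):
        cfg = ScheduleConfig(n_target_blocks=30)
        # 30 x 9 s targets + 31 baselines averaging 13.5 s
        assert nc.expected_session_duration_s(cfg) == pytest.approx(688.5)
        assert nc.expected_session_duration_s(cfg) / 60 == pytest.approx(11.475)

    def test_empirical_mean_matches_expectation_within_one_percent(self):
        cfg = ScheduleConfig(n_target_blocks=30)
        expected = nc.expected_session_duration_s(cfg)
        durations = [
            nc.generate_infant_schedule(cfg, seed=s, populate_tokens=False).duration_s
            for s in range(1000)
        ]
        assert abs(np.mean(durations) - expected) / expected < 0.01

    def test_minimal_design_is_about_six_and_a_half_minutes(self):
        cfg = ScheduleConfig(n_target_blocks=16)
        assert nc.expected_session_duration_s(cfg) / 60 == pytest.approx(6.4, abs=0.3)


class TestAdultSchedule:
    @pytest.mark.parametrize("name", list(ADULT_CONDITIONS))
    def test_block_lengths_and_jitter_per_condition(self, name):
        sched = nc.generate_adult_schedule(name, seed=3)
        target_s = 15.0 if name.startswith("long") else 9.0
        lo, hi = (15.0, 22.0) if name.startswith("long") else (9.0, 18.0)
        for b in sched.blocks:
            if b.kind == "target":
                assert b.duration_s == target_s
            else:
                assert lo <= b.duration_s <= hi

    @pytest.mark.parametrize("name", list(ADULT_CONDITIONS))
    def test_expected_session_is_four_to_five_minutes(self, name):
        minutes = nc.expected_session_duration_s(ADULT_CONDITIONS[name]) / 60
        assert 3.8 <= minutes <= 5.1

    def test_single_mode_uses_one_distinct_token_per_word(self):
        sched = nc.generate_adult_schedule("long-single", seed=2)
        for word in {t.word for t in sched.tokens}:
            indices = {t.token_index for t in sched.tokens if t.word == word}
            assert indices == {1}

    def test_unknown_condition_raises(self):
        with pytest.raises(KeyError):
            nc.generate_adult_schedule("medium-double")
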