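"""Copy-spelling protocol: targets, categories, stop rules, dwell simulator."""

import numpy as np
import pytest

from shufflespeller import (
    EngineConfig,
    SessionConfig,
    SessionLog,
    WORD_POOL,
    WordList,
    categorize_selection,
    intended_target,
    replay_categories,
    run_copy_session,
    sample_word_lists,
)
from shufflespeller.dwell import DwellGazeModel, DwellSpellerState, simulate_dwell_speller
from shufflespeller.engine import Partition, QueryEvidence
from shufflespeller.session import WORD_COMPLETE, apply_selection
from shufflespeller.users import OracleUserModel, UnrecognizedUserModel


def symmetric_channel(k: int, accuracy: float) -> np.ndarray:
    off = (1.0 - accuracy) / (k - 1)
    return np.full((k, k), off) + np.eye(k) * (accuracy - off)


class WrongBoxUserModel:
    """Always produces confident evidence for a wrong box."""

    def __init__(self, trial_duration_s=2.0):
        self.trial_duration_s = trial_duration_s

    def respond(self, partition, intended):
        true_box = partition.box_of_character(intended)
        lk = np.full(partition.n_boxes, 0.05)
        lk[(true_box + 1) % partition.n_boxes] = 0.85
        from shufflespeller.engine import evidence_from_likelihoods

        return evidence_from_likelihoods(lk, self.trial_duration_s)


class TestIntendedTarget:
    @pytest.mark.parametrize(
        "typed,word,expected",
        [
            ("", "HOUSE", "H"),
            ("HO", "HOUSE", "U"),
            ("HOX", "HOUSE", "<"),
            ("HOXX", "HOUSE", "<"),
            ("HOUSE", "HOUSE", WORD_COMPLETE),
        ],
    )
    def test_next_selection(self, typed, word, expected):
        assert intended_target(typed, word) == expected

    @pytest.mark.parametrize(
        "selected,typed,word,expected",
        [
            ("H", "", "HOUSE", "correct_letter"),
            ("<", "HOX", "HOUSE", "correct_backspace"),
            ("Q", "", "HOUSE", "incorrect"),
            ("<", "", "HOUSE", "incorrect"),  # nothing to delete
            ("H", "HOX", "HOUSE", "incorrect"),  # should have backspaced
        ],
    )
    def test_categorize(self, selected, typed, word, expected):
        assert categorize_selection(selected, typed, word) == expected

    def test_apply_selection_backspace_deletes(self):
        assert apply_selection("HOX", "<") == "HO"
        assert apply_selection("HO", "U") == "HOU"
        assert apply_selection("", "<") == ""


class TestWordLists:
    def test_pool_is_65_unique_five_letter_words(self):
        assert len(WORD_POOL) == 65
        assert len(set(WORD_POOL)) == 65
        assert all(len(w) == 5 and w.isalpha() and w.isupper()
                   for w in WORD_POOL)

    def test_26_sampled_lists_are_distinct(self):
        lists = sample_word_lists(26, seed=1)
        assert len(lists) == 26
        keys = {tuple(sorted(wl.words)) for wl in lists}
        assert len(keys) == 26
        for wl in lists:
            assert len(set(wl.words)) == 5

    def test_invalid_words_rejected(self):
        with pytest.raises(ValueError):
            WordList(words=("HOUSE", "HOUSE", "WATER", "LIGHT", "PLANT"))
        with pytest.raises(ValueError):
            WordList(words=("HOUSE", "CAT", "WATER", "LIGHT", "PLANT"))


@pytest.fixture
def word_list():
    return WordList(words=("HOUSE", "WATER", "LIGHT", "PLANT", "MUSIC"))


class TestRunCopySession:
    def test_perfect_user_types_all_words(self, word_list):
        w = symmetric_channel(4, 0.95)
        user = OracleUserModel(correct=0.95, incorrect=0.05)
        cfg = SessionConfig(condition="SSBCI", seed=1)
        log = run_copy_session(cfg, user, word_list, w)
        cats = [e.category for e in log.selections]
        assert cats == ["correct_letter"] * 25
        advances = [e for e in log.events if e.kind == "word_advance"]
        assert len(advances) == 5
        assert all(a.reason == "word-complete" for a in advances)

    def test_four_consecutive_errors_advance_word(self, word_list):
        w = symmetric_channel(4, 0.95)
        cfg = SessionConfig(condition="SSBCI", seed=1,
                            session_cap_s=10_000, early_stop_s=10_000)
        log = run_copy_session(cfg, WrongBoxUserModel(), word_list, w)
        advances = [e for e in log.events if e.kind == "word_advance"]
        assert advances and all(a.reason == "consecutive-errors"
                                for a in advances)
        # Exactly 4 incorrect selections precede each advance.
        cats = [e.category for e in log.selections]
        assert all(c == "incorrect" for c in cats)
        assert len(cats) == 4 * len(advances)

    def test_early_stop_without_correct_selections(self, word_list):
        # Slow, always-wrong user: the 5-min early stop fires before any
        # word advances complete the list.
        w = symmetric_channel(4, 0.95)
        user = WrongBoxUserModel(trial_duration_s=100.0)
        cfg = SessionConfig(condition="SSBCI", seed=1)
        log = run_copy_session(cfg, user, word_list, w)
        stops = [e for e in log.events if e.kind == "stop"]
        assert stops[-1].reason == "early-stop"
        assert stops[-1].timestamp_s >= 300.0
        assert all(e.category != "correct_letter" for e in log.selections)

    def test_session_cap_fires_for_slow_correct_user(self, word_list):
        w = symmetric_channel(4, 0.95)
        user = OracleUserModel(correct=0.95, incorrect=0.05,
                               trial_duration_s=100.0)
        cfg = SessionConfig(condition="SSBCI", seed=1)
        log = run_copy_session(cfg, user, word_list, w)
        stops = [e for e in log.events if e.kind == "stop"]
        assert stops[-1].reason == "session-cap"
        assert stops[-1].timestamp_s >= 1200.0

    def test_unrecognized_runs_advance_words(self, word_list):
        w = symmetric_channel(4, 0.9)
        cfg = SessionConfig(condition="SSBCI", seed=1)
        log = run_copy_session(cfg, UnrecognizedUserModel(), word_list, w)
        advances = [e for e in log.events if e.kind == "word_advance"]
        assert len(advances) == 5
        assert all(a.reason == "unrecognized-input" for a in advances)
        assert log.selections == []

    def test_replay_reproduces_categories(self, word_list):
        rng = np.random.default_rng(3)
        w = symmetric_channel(4, 0.7)
        user = OracleUserModel(confusion=w, rng=rng)
        cfg = SessionConfig(condition="SSET", seed=3)
        log = run_copy_session(cfg, user, word_list, w)
        assert log.selections  # noisy session still makes selections
        assert replay_categories(log) == [e.category for e in log.selections]

    def test_active_time_excludes_between_word_breaks(self, word_list):
        w = symmetric_channel(4, 0.95)
        user = OracleUserModel(correct=0.95, incorrect=0.05)
        cfg = SessionConfig(condition="SSBCI", seed=1,
                            between_word_break_s=30.0)
        log = run_copy_session(cfg, user, word_list, w)
        durations = sum(e.duration_s for e in log.selections)
        assert log.active_typing_time_s == pytest.approx(durations)
        assert log.active_typing_time_s < log.wall_time_s

    def test_invalid_condition_rejected(self, word_list):
        with pytest.raises(ValueError):
            SessionConfig(condition="BOGUS", seed=1)
        cfg = SessionConfig(condition="C1.2", seed=1)
        with pytest.raises(ValueError):
            run_copy_session(cfg, OracleUserModel(), word_list,
                             symmetric_channel(4, 0.9))

    def test_jsonl_round_trip(self, tmp_path, word_list):
        w = symmetric_channel(4, 0.8)
        user = OracleUserModel(confusion=w, rng=np.random.default_rng(5))
        cfg = SessionConfig(condition="SSBCI", seed=5)
        log = run_copy_session(cfg, user, word_list, w)
        log.to_jsonl(tmp_path / "s.jsonl")
        back = SessionLog.from_jsonl(tmp_path / "s.jsonl")
        assert back.condition == log.condition
        assert back.active_typing_time_s == log.active_typing_time_s
        assert [e.category for e in back.selections] == [
            e.category for e in log.selections
        ]


class TestDwellSimulator:
    def test_fixed_gaze_selects_box_at_exact_dwell_time(self, word_list):
        # With zero scatter the first *character* lands after exactly three
        # box dwells of ceil(dwell x rate)/rate seconds each.
        cfg = SessionConfig(condition="C1.2", seed=1)
        log = simulate_dwell_speller(cfg, DwellGazeModel.create(0.0, 1),
                                     word_list)
        first = log.selections[0]
        assert first.timestamp_s == pytest.approx(3 * 1.2, abs=1e-9)
        assert first.character == "H"

    def test_alternating_gaze_never_selects(self, word_list):
        class AlternatingGaze:
            def __init__(self):
                self.i = 0
                from shufflespeller import ScreenLayout

                self.centers = [ScreenLayout().boxes[0].center,
                                ScreenLayout().boxes[1].center]

            def sample(self, center):
                # Switch boxes every 0.5 s (30 samples at 60 Hz).
                self.i += 1
                return np.asarray(self.centers[(self.i // 30) % 2])

        cfg = SessionConfig(condition="C1.2", seed=1, early_stop_s=60.0)
        log = simulate_dwell_speller(cfg, AlternatingGaze(), word_list)
        assert log.selections == []
        assert [e.reason for e in log.events if e.kind == "stop"] == ["early-stop"]

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_infinite_scatter_reproduces_zero_accuracy_baseline(self, seed,
                                                                word_list):
        cfg = SessionConfig(condition="C2.5", seed=seed)
        log = simulate_dwell_speller(cfg, DwellGazeModel.create(1e9, seed),
                                     word_list)
        assert sum(e.category != "incorrect" for e in log.selections) == 0
        assert [e.reason for e in log.events if e.kind == "stop"] == ["early-stop"]

    def test_noiseless_dwell_session_is_perfect(self, word_list):
        cfg = SessionConfig(condition="C2.5", seed=1)
        log = simulate_dwell_speller(cfg, DwellGazeModel.create(0.0, 1),
                                     word_list)
        cats = [e.category for e in log.selections]
        assert cats == ["correct_letter"] * 25
        assert replay_categories(log) == cats

    def test_three_step_hierarchy_reaches_every_character(self):
        from shufflespeller.engine import ALPHABET

        state = DwellSpellerState()
        for ch in ALPHABET:
            state.reset()
            # Level 1: pick the box whose group holds ch.
            for level in range(3):
                screen = state.current_screen()
                box = screen.box_leading_to(ch)
                assert box is not None, f"{ch} unreachable at level {level + 1}"
                typed = state.advance(box)
            assert typed == ch

    def test_go_back_recovers_from_wrong_group(self):
        state = DwellSpellerState()
        state.advance(0)  # wrong group for "Z"
        assert state.current_screen().box_leading_to("Z") is None
        state.go_back()
        assert state.level == 1
        assert state.current_screen().box_leading_to("Z") is not None
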