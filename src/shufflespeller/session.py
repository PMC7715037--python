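"""Copy-spelling protocol: targets, selection categories, stop rules, logs.

A session presents five 5-letter target words.  The user types the next
letter of the current word; after an erroneous selection the intended
response becomes backspace until the typed string is again a prefix of the
target.  Sessions are capped at 20 minutes, terminate early if no correct
selection occurs in the first 5 minutes, and advance to the next word after
four consecutive incorrect selections or a run of unrecognized inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import BACKSPACE, EngineConfig, QueryUserModel, run_selection
from .likelihood import ConfusionMatrix

WORD_COMPLETE = ""

#: 65 common five-letter English words (public-domain list assembled for this
#: package; word identity does not affect any computation).
WORD_POOL: tuple[str, ...] = (
    "ABOUT", "ABOVE", "AFTER", "AGAIN", "ALONE", "ALONG", "BEACH", "BEGAN",
    "BEGIN", "BELOW", "BIRDS", "BLACK", "BREAD", "BRING", "BROWN", "BUILD",
    "CARRY", "CHAIR", "CLEAN", "CLEAR", "CLOCK", "CLOSE", "CLOUD", "DANCE",
    "DREAM", "DRINK", "EARLY", "EARTH", "FIELD", "FIRST", "FLOOR", "FOUND",
    "FRESH", "FRONT", "FRUIT", "GLASS", "GREEN", "HAPPY", "HEART", "HORSE",
    "HOUSE", "LARGE", "LAUGH", "LEARN", "LIGHT", "MONEY", "MUSIC", "NIGHT",
    "OCEAN", "PAPER", "PARTY", "PLACE", "PLANT", "QUIET", "RIVER", "ROUND",
    "SLEEP", "SMALL", "SMILE", "SOUND", "STONE", "TABLE", "VOICE", "WATER",
    "WORLD",
)

CONDITIONS = ("C1.2", "C2.5", "SSET", "SSBCI")


@dataclass(frozen=True)
class WordList:
    """Five unique 5-letter uppercase words for one session."""

    words: tuple[str, ...]

    def __post_init__(self) -> None:
        words = tuple(w.upper() for w in self.words)
        object.__setattr__(self, "words", words)
        if len(set(words)) != len(words):
            raise ValueError("words within a list must be unique")
        for w in words:
            if len(w) != 5 or not w.isalpha():
                raise ValueError(f"word {w!r} is not a 5-letter alphabetic word")


def sample_word_lists(
    n_lists: int = 26,
    words_per_list: int = 5,
    seed: int | np.random.Generator = 0,
    pool: tuple[str, ...] = WORD_POOL,
) -> list[WordList]:
    """Draw distinct word lists (unique words within each list) from the pool."""
    rng = np.random.default_rng(seed)
    lists: list[WordList] = []
    seen: set[tuple[str, ...]] = set()
    while len(lists) < n_lists:
        words = tuple(sorted(rng.choice(pool, size=words_per_list, replace=False)))
        if words not in seen:
            seen.add(words)
            lists.append(WordList(words=words))
    return lists


@dataclass(frozen=True)
class SessionConfig:
    """Protocol parameters for one copy-spelling session."""

    condition: str
    seed: int = 0
    session_cap_s: float = 1200.0
    early_stop_s: float = 300.0
    consecutive_error_limit: int = 4
    dwell_s: float | None = None  # required for C1.2 / C2.5
    between_word_break_s: float = 0.0
    engine: EngineConfig = field(default_factory=EngineConfig)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if self.session_cap_s <= 0 or self.early_stop_s <= 0:
            raise ValueError("session caps must be positive")
        if self.condition in ("C1.2", "C2.5") and self.dwell_s is None:
            object.__setattr__(
                self, "dwell_s", 1.2 if self.condition == "C1.2" else 2.5
            )


@dataclass
class SessionEvent:
    """One timestamped protocol event."""

    timestamp_s: float
    kind: str  # query | selection | word_advance | stop
    character: str | None = None
    category: str | None = None  # correct_letter | correct_backspace | incorrect
    n_queries: int | None = None
    reason: str | None = None
    target_word: str | None = None
    duration_s: float | None = None


@dataclass
class SessionLog:
    """Ordered event record of one session plus its active typing time."""

    condition: str
    word_list: tuple[str, ...]
    events: list[SessionEvent] = field(default_factory=list)
    active_typing_time_s: float = 0.0
    seed: int | None = None

    def append(self, event: SessionEvent) -> None:
        if self.events and event.timestamp_s < self.events[-1].timestamp_s - 1e-9:
            raise ValueError("event timestamps must be nondecreasing")
        self.events.append(event)

    @property
    def selections(self) -> list[SessionEvent]:
        return [e for e in self.events if e.kind == "selection"]

    @property
    def wall_time_s(self) -> float:
        return self.events[-1].timestamp_s if self.events else 0.0

    def to_jsonl(self, path: str | Path) -> None:
        path = Path(path)
        header = {
            "kind": "session_header",
            "condition": self.condition,
            "word_list": list(self.word_list),
            "active_typing_time_s": self.active_typing_time_s,
            "seed": self.seed,
        }
        with path.open("w") as fh:
            fh.write(json.dumps(header) + "\n")
            for e in self.events:
                fh.write(json.dumps(asdict(e)) + "\n")

    @classmethod
    def from_jsonl(cls, path: str | Path) -> "SessionLog":
        lines = Path(path).read_text().splitlines()
        header = json.loads(lines[0])
        log = cls(
            condition=header["condition"],
            word_list=tuple(header["word_list"]),
            active_typing_time_s=header["active_typing_time_s"],
            seed=header.get("seed"),
        )
        for line in lines[1:]:
            rec = json.loads(line)
            rec.pop("kind_header", None)
            log.events.append(SessionEvent(**rec))
        return log

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame([asdict(e) for e in self.events]).to_csv(path, index=False)


def intended_target(typed_string: str, target_word: str) -> str:
    """The correct next selection: next letter, backspace, or word-complete.

    If the typed string is not a prefix of the target the user must erase
    (backspace) until it is; an exact match returns the word-complete
    sentinel (empty string).
    """
    if not target_word.startswith(typed_string):
        return BACKSPACE
    if typed_string == target_word:
        return WORD_COMPLETE
    return target_word[len(typed_string)]


def categorize_selection(
    selected: str, typed_string_before: str, target_word: str
) -> str:
    """Classify a selection as correct_letter / correct_backspace / incorrect.

    An appropriate backspace (deleting an erroneous character) counts as
    correct; backspace with nothing to delete is incorrect.
    """
    intended = intended_target(typed_string_before, target_word)
    if selected == intended and intended == BACKSPACE:
        return "correct_backspace"
    if selected == intended and intended != WORD_COMPLETE:
        return "correct_letter"
    return "incorrect"


def apply_selection(typed_string: str, selected: str) -> str:
    """Typed-string transition: backspace deletes the last character."""
    if selected == BACKSPACE:
        return typed_string[:-1]
    return typed_string + selected


def replay_categories(log: SessionLog) -> list[str]:
    """Recompute every selection's category from the event stream alone."""
    categories = []
    typed = ""
    for e in log.events:
        if e.kind == "selection":
            categories.append(categorize_selection(e.character, typed, e.target_word))
            typed = apply_selection(typed, e.character)
        elif e.kind == "word_advance":
            typed = ""
    return categories


def run_copy_session(
    config: SessionConfig,
    user_model: QueryUserModel,
    word_list: WordList,
    confusion: ConfusionMatrix | np.ndarray,
) -> SessionLog:
    """Run one Shuffle-condition (SSET/SSBCI) copy-spelling session.

    Stop rules, in precedence order: the 20-min session cap; the 5-min early
    stop with zero correct selections; word advancement after the consecutive
    -error limit or an unrecognized-input run.  All rule firings are logged.
    """
    if config.condition not in ("SSET", "SSBCI"):
        raise ValueError(
            f"run_copy_session handles SSET/SSBCI; got {config.condition!r}"
        )
    log = SessionLog(condition=config.condition, word_list=word_list.words,
                     seed=config.seed)
    clock = 0.0
    n_correct = 0
    stopped = False

    for word in word_list.words:
        typed = ""
        consecutive_incorrect = 0
        while True:
            intended = intended_target(typed, word)
            if intended == WORD_COMPLETE:
                log.append(SessionEvent(clock, "word_advance", reason="word-complete",
                                        target_word=word))
                break
            outcome = run_selection(confusion, user_model, intended,
                                    config=config.engine)
            clock += outcome.elapsed_s
            log.active_typing_time_s += outcome.elapsed_s
            log.append(SessionEvent(clock, "query", n_queries=outcome.n_queries,
                                    duration_s=outcome.elapsed_s))
            if outcome.character is not None:
                category = categorize_selection(outcome.character, typed, word)
                log.append(SessionEvent(clock, "selection",
                                        character=outcome.character,
                                        category=category,
                                        n_queries=outcome.n_queries,
                                        target_word=word,
                                        duration_s=outcome.elapsed_s))
                typed = apply_selection(typed, outcome.character)
                if category == "incorrect":
                    consecutive_incorrect += 1
                else:
                    consecutive_incorrect = 0
                    n_correct += 1
            # Stop rules in precedence order.
            if clock >= config.session_cap_s:
                log.append(SessionEvent(clock, "stop", reason="session-cap"))
                stopped = True
                break
            if clock >= config.early_stop_s and n_correct == 0:
                log.append(SessionEvent(clock, "stop", reason="early-stop"))
                stopped = True
                break
            if outcome.abort_reason is not None:
                log.append(SessionEvent(clock, "word_advance",
                                        reason=outcome.abort_reason,
                                        target_word=word))
                break
            if consecutive_incorrect >= config.consecutive_error_limit:
                log.append(SessionEvent(clock, "word_advance",
                                        reason="consecutive-errors",
                                        target_word=word))
                break
        if stopped:
            break
        clock += config.between_word_break_s
    if not stopped:
        log.append(SessionEvent(clock, "stop", reason="word-list-complete"))
    return log
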