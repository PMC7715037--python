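"""Dwell-based three-step speller simulator (baseline eye-tracking conditions).

The baseline interface arranges the 28 characters in fixed alphabetical
groups: each character selection requires three successive box selections —
a large group (up to 7 characters), a small group within it (up to 2), and
the individual character.  A box is selected when cumulative *continuous*
gaze inside it reaches the dwell time (1.2 s or 2.5 s); the accumulator
resets whenever gaze leaves the box.  A "go back" target (modeled as a small
fifth box at screen center) lets the user recover from selecting a wrong
group.

The simulated user fixates the box that leads toward the intended character
(or the go-back target after a wrong turn), with isotropic Gaussian gaze
scatter; selection errors arise when scattered gaze dwells in a neighboring
box.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import ALPHABET, BACKSPACE
from .session import (
    SessionConfig,
    SessionEvent,
    SessionLog,
    WORD_COMPLETE,
    WordList,
    apply_selection,
    categorize_selection,
    intended_target,
)
from .stimulus import Box, ScreenLayout

GO_BACK = ">back"

#: Fixed first-level grouping: alphabetical blocks of 7 assigned to the
#: top, right, bottom and left boxes.
FIRST_LEVEL_GROUPS: tuple[tuple[str, ...], ...] = (
    tuple("ABCDEFG"),
    tuple("HIJKLMN"),
    tuple("OPQRSTU"),
    ("V", "W", "X", "Y", "Z", "_", "<"),
)
#: Box order for first-level groups: top, right, bottom, left.
FIRST_LEVEL_BOXES = (0, 3, 1, 2)


def _chunk(seq: tuple[str, ...], size: int) -> list[tuple[str, ...]]:
    return [tuple(seq[i : i + size]) for i in range(0, len(seq), size)]


@dataclass(frozen=True)
class DwellScreen:
    """One screen of the three-step hierarchy: items shown per box."""

    items: dict[int, tuple[str, ...]]  # box index -> characters offered
    level: int  # 1, 2 or 3

    def box_leading_to(self, character: str) -> int | None:
        for box, chars in self.items.items():
            if character in chars:
                return box
        return None


@dataclass
class DwellSpellerState:
    """Navigation state of the three-step interface."""

    level: int = 1
    group: tuple[str, ...] | None = None
    subgroup: tuple[str, ...] | None = None

    def current_screen(self) -> DwellScreen:
        if self.level == 1:
            items = {
                box: group
                for group, box in zip(FIRST_LEVEL_GROUPS, FIRST_LEVEL_BOXES)
            }
            return DwellScreen(items=items, level=1)
        if self.level == 2:
            chunks = _chunk(self.group, 2)
            items = {FIRST_LEVEL_BOXES[i]: c for i, c in enumerate(chunks)}
            return DwellScreen(items=items, level=2)
        items = {
            FIRST_LEVEL_BOXES[i]: (c,) for i, c in enumerate(self.subgroup)
        }
        return DwellScreen(items=items, level=3)

    def advance(self, box: int) -> str | None:
        """Apply a box selection; returns a typed character at level 3."""
        screen = self.current_screen()
        chars = screen.items.get(box)
        if chars is None:
            return None  # empty box: selection has no effect
        if self.level == 1:
            self.group = chars
            self.level = 2
            return None
        if self.level == 2:
            self.subgroup = chars
            self.level = 3
            return None
        typed = chars[0]
        self.reset()
        return typed

    def go_back(self) -> None:
        if self.level == 3:
            self.level = 2
            self.subgroup = None
        elif self.level == 2:
            self.level = 1
            self.group = None

    def reset(self) -> None:
        self.level = 1
        self.group = None
        self.subgroup = None


@dataclass
class DwellGazeModel:
    """Seeded gaze-point stream: fixates a desired target with smooth scatter.

    Gaze error follows a stationary AR(1) process with per-sample correlation
    ``rho`` (time constant ~0.3 s at 60 Hz for the default 0.95), so the
    marginal scatter is N(0, scatter^2 I) while excursions persist over
    hundreds of milliseconds the way fixational error does — a prerequisite
    for continuous-dwell selection, and the mechanism by which large scatter
    produces wrong or absent selections.
    """

    scatter_deg: float
    rng: np.random.Generator
    rho: float = 0.95
    _error: np.ndarray | None = None

    @classmethod
    def create(cls, scatter_deg: float, seed: int, rho: float = 0.95) -> "DwellGazeModel":
        return cls(scatter_deg=scatter_deg, rng=np.random.default_rng(seed), rho=rho)

    def sample(self, center: tuple[float, float]) -> np.ndarray:
        if self._error is None:
            self._error = self.scatter_deg * self.rng.standard_normal(2)
        else:
            self._error = (
                self.rho * self._error
                + np.sqrt(1 - self.rho**2) * self.scatter_deg
                * self.rng.standard_normal(2)
            )
        return np.asarray(center) + self._error


def _go_back_box() -> Box:
    return Box(center=(0.0, 0.0), size=(3.0, 3.0))


def simulate_dwell_speller(
    config: SessionConfig,
    gaze_model: DwellGazeModel,
    word_list: WordList,
    layout: ScreenLayout | None = None,
    gaze_rate_hz: float = 60.0,
) -> SessionLog:
    """Simulate one C1.2/C2.5 copy-spelling session sample by sample.

    Emits the same SessionLog schema as the Shuffle conditions; the session
    cap and early-stop rules are checked continuously on the simulated
    clock, word advancement after consecutive errors as in the main
    protocol.
    """
    if config.condition not in ("C1.2", "C2.5"):
        raise ValueError("simulate_dwell_speller handles C1.2/C2.5 conditions")
    dwell_s = float(config.dwell_s)
    layout = layout or ScreenLayout()
    back_box = _go_back_box()
    dt = 1.0 / gaze_rate_hz

    log = SessionLog(condition=config.condition, word_list=word_list.words,
                     seed=config.seed)
    clock = 0.0
    n_correct = 0
    state = DwellSpellerState()
    accumulators = np.zeros(len(layout.boxes) + 1)  # + go-back target
    selection_start = 0.0
    stopped = False

    word_idx = 0
    typed = ""
    consecutive_incorrect = 0
    while word_idx < len(word_list.words):
        word = word_list.words[word_idx]
        intended = intended_target(typed, word)
        if intended == WORD_COMPLETE:
            log.append(SessionEvent(clock, "word_advance", reason="word-complete",
                                    target_word=word))
            word_idx += 1
            typed = ""
            consecutive_incorrect = 0
            state.reset()
            accumulators[:] = 0.0
            clock += config.between_word_break_s
            selection_start = clock
            continue

        # Desired target for this sample: the box leading toward the intended
        # character, or the go-back target after a wrong group selection.
        screen = state.current_screen()
        lead = screen.box_leading_to(intended)
        if lead is not None:
            desired_center = layout.boxes[lead].center
        else:
            desired_center = back_box.center

        point = gaze_model.sample(desired_center)
        clock += dt
        log.active_typing_time_s += dt

        # Continuous-dwell accumulation: any box not under gaze resets.
        inside = [bool(b.contains(point[None, :])[0]) for b in layout.boxes]
        inside.append(bool(back_box.contains(point[None, :])[0]))
        for i, flag in enumerate(inside):
            accumulators[i] = accumulators[i] + dt if flag else 0.0

        hit = int(np.argmax(accumulators)) if accumulators.max() >= dwell_s - 1e-9 else None
        if hit is not None:
            accumulators[:] = 0.0
            if hit == len(layout.boxes):  # go-back target
                state.go_back()
            else:
                typed_char = state.advance(hit)
                if typed_char is not None:
                    category = categorize_selection(typed_char, typed, word)
                    log.append(SessionEvent(
                        clock, "selection", character=typed_char,
                        category=category, n_queries=1, target_word=word,
                        duration_s=clock - selection_start,
                    ))
                    typed = apply_selection(typed, typed_char)
                    selection_start = clock
                    if category == "incorrect":
                        consecutive_incorrect += 1
                    else:
                        consecutive_incorrect = 0
                        n_correct += 1
                    if consecutive_incorrect >= config.consecutive_error_limit:
                        log.append(SessionEvent(clock, "word_advance",
                                                reason="consecutive-errors",
                                                target_word=word))
                        word_idx += 1
                        typed = ""
                        consecutive_incorrect = 0
                        state.reset()
                        clock += config.between_word_break_s
                        selection_start = clock

        # Stop rules on the continuous clock, in precedence order.
        if clock >= config.session_cap_s:
            log.append(SessionEvent(clock, "stop", reason="session-cap"))
            stopped = True
            break
        if clock >= config.early_stop_s and n_correct == 0:
            log.append(SessionEvent(clock, "stop", reason="early-stop"))
            stopped = True
            break

    if not stopped:
        log.append(SessionEvent(clock, "stop", reason="word-list-complete"))
    return log
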