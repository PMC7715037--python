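"""Stimulus and screen-geometry definitions for the four-box speller.

The speller presents four boxes centered at the top, bottom, left and right
edges of the screen.  In the BCI condition each box has a neighboring LED
patch flickering at a distinct frequency, so that attending a box elicits a
steady-state visual evoked potential (SSVEP) at that frequency and its
harmonics.  All coordinates are degrees of visual angle, origin at screen
center, x to the right, y up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default LED flicker frequencies (Hz), one per box: top, bottom, left, right.
DEFAULT_FREQUENCIES_HZ = (8.0, 9.7, 11.3, 13.0)

#: Box centers in degrees of visual angle (top, bottom, left, right edges).
DEFAULT_TARGET_POSITIONS = ((0.0, 11.0), (0.0, -11.0), (-16.0, 0.0), (16.0, 0.0))

TARGET_NAMES = ("top", "bottom", "left", "right")


@dataclass(frozen=True)
class StimulusSet:
    """The four flicker stimuli and where their targets sit on screen.

    Parameters
    ----------
    frequencies_hz
        Stimulation frequency per target box.  Must be positive and pairwise
        distinct.
    n_harmonics
        Number of harmonics (including the fundamental) present in the evoked
        response and used by the reference bank.
    target_positions
        Screen-edge centers of the four targets, degrees of visual angle.
    """

    frequencies_hz: tuple[float, ...] = DEFAULT_FREQUENCIES_HZ
    n_harmonics: int = 2
    target_positions: tuple[tuple[float, float], ...] = DEFAULT_TARGET_POSITIONS

    def __post_init__(self) -> None:
        freqs = tuple(float(f) for f in self.frequencies_hz)
        object.__setattr__(self, "frequencies_hz", freqs)
        if any(f <= 0 for f in freqs):
            raise ValueError("stimulation frequencies must be strictly positive")
        if len(set(freqs)) != len(freqs):
            raise ValueError("stimulation frequencies must be pairwise distinct")
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")
        if len(self.target_positions) != 4:
            raise ValueError("exactly 4 target positions are required")

    @property
    def n_targets(self) -> int:
        return len(self.frequencies_hz)

    @property
    def max_harmonic_hz(self) -> float:
        return max(self.frequencies_hz) * self.n_harmonics


@dataclass(frozen=True)
class Box:
    """Axis-aligned box: center and (width, height) in degrees of visual angle."""

    center: tuple[float, float]
    size: tuple[float, float]

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Vectorized membership test for an (n, 2) array of gaze points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        dx = np.abs(pts[:, 0] - self.center[0])
        dy = np.abs(pts[:, 1] - self.center[1])
        return (dx <= self.size[0] / 2) & (dy <= self.size[1] / 2)

    def overlaps(self, other: "Box") -> bool:
        return (
            abs(self.center[0] - other.center[0]) < (self.size[0] + other.size[0]) / 2
            and abs(self.center[1] - other.center[1]) < (self.size[1] + other.size[1]) / 2
        )


def _default_boxes() -> tuple[Box, ...]:
    # Top/bottom boxes are wide and short (15 deg x 7 deg); left/right are
    # narrow and tall (6 deg x 18 deg), matching the study layout.
    return (
        Box(DEFAULT_TARGET_POSITIONS[0], (15.0, 7.0)),
        Box(DEFAULT_TARGET_POSITIONS[1], (15.0, 7.0)),
        Box(DEFAULT_TARGET_POSITIONS[2], (6.0, 18.0)),
        Box(DEFAULT_TARGET_POSITIONS[3], (6.0, 18.0)),
    )


def _default_leds() -> tuple[Box, ...]:
    # Each LED patch (1.6 deg x 2.4 deg) sits just outside its box, toward the
    # screen edge.
    offsets = ((0.0, 5.0), (0.0, -5.0), (-5.0, 0.0), (5.0, 0.0))
    return tuple(
        Box((b.center[0] + dx, b.center[1] + dy), (1.6, 2.4))
        for b, (dx, dy) in zip(_default_boxes(), offsets)
    )


@dataclass(frozen=True)
class ScreenLayout:
    """Geometry of the four selection boxes and their LED patches.

    Invariants: boxes do not overlap, and each box is adjacent to exactly one
    LED patch (the nearest patch is its own).
    """

    boxes: tuple[Box, ...] = field(default_factory=_default_boxes)
    led_patches: tuple[Box, ...] = field(default_factory=_default_leds)
    calibration_target_size: tuple[float, float] = (0.8, 0.8)

    def __post_init__(self) -> None:
        if len(self.boxes) != 4 or len(self.led_patches) != 4:
            raise ValueError("layout requires 4 boxes and 4 LED patches")
        for i, a in enumerate(self.boxes):
            for b in self.boxes[i + 1 :]:
                if a.overlaps(b):
                    raise ValueError("boxes must not overlap")
        for i, box in enumerate(self.boxes):
            dists = [
                np.hypot(box.center[0] - led.center[0], box.center[1] - led.center[1])
                for led in self.led_patches
            ]
            if int(np.argmin(dists)) != i:
                raise ValueError(f"box {i} is not adjacent to its own LED patch")

    def box_containing(self, point: tuple[float, float]) -> int | None:
        """Index of the box containing ``point``, or None if outside all boxes."""
        for i, box in enumerate(self.boxes):
            if bool(box.contains(np.array([point]))[0]):
                return i
        return None
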