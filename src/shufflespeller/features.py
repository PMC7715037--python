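"""Canonical-correlation SSVEP features.

For each stimulation frequency a reference bank holds sin/cos pairs at the
fundamental and its harmonics.  The feature for a trial is, per frequency,
the first (largest) canonical correlation between the multichannel EEG
segment and that frequency's reference bank — a scalar in [0, 1] that is
large when the attended stimulus drives the EEG.

The canonical correlation is computed by the classical generalized-eigenvalue
route on the covariance blocks, with mean-centered channels and a small ridge
(1e-12 x trace) on each auto-covariance block for numerical stability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .stimulus import StimulusSet
from .synth import EEGSegment

RIDGE_FRACTION = 1e-12


@dataclass(frozen=True)
class ReferenceBank:
    """Per-frequency harmonic reference matrices.

    ``references[k]`` is a (2 * n_harmonics, n_samples) array with rows
    sin(2*pi*h*f_k*t), cos(2*pi*h*f_k*t) for h = 1..n_harmonics.
    """

    frequencies_hz: tuple[float, ...]
    references: tuple[np.ndarray, ...]
    rate_hz: float

    @property
    def n_samples(self) -> int:
        return self.references[0].shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz


@dataclass(frozen=True)
class CCAScores:
    """First canonical correlation per stimulation frequency, each in [0, 1]."""

    scores: np.ndarray
    segment_duration_s: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=float))

    def __len__(self) -> int:
        return len(self.scores)


def build_reference_bank(
    stimulus_set: StimulusSet,
    duration_s: float,
    rate_hz: float,
) -> ReferenceBank:
    """Construct sin/cos harmonic references for every stimulation frequency."""
    n = int(round(duration_s * rate_hz))
    n_rows = 2 * stimulus_set.n_harmonics
    if n < 2 * n_rows:
        raise ValueError(
            f"segment of {n} samples too short for {stimulus_set.n_harmonics} harmonics"
        )
    t = np.arange(n) / rate_hz
    refs = []
    for f in stimulus_set.frequencies_hz:
        rows = []
        for h in range(1, stimulus_set.n_harmonics + 1):
            rows.append(np.sin(2 * np.pi * h * f * t))
            rows.append(np.cos(2 * np.pi * h * f * t))
        refs.append(np.vstack(rows))
    return ReferenceBank(
        frequencies_hz=stimulus_set.frequencies_hz,
        references=tuple(refs),
        rate_hz=rate_hz,
    )


def _first_canonical_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Largest canonical correlation between row-variable matrices x and y.

    Solves the generalized eigenproblem  Cxy Cyy^-1 Cyx w = rho^2 Cxx w  via
    ``scipy.linalg.eigh`` after ridging the auto-covariance blocks.
    """
    x = x - x.mean(axis=1, keepdims=True)
    y = y - y.mean(axis=1, keepdims=True)
    n = x.shape[1]
    cxx = x @ x.T / n
    cyy = y @ y.T / n
    cxy = x @ y.T / n
    cxx = cxx + RIDGE_FRACTION * np.trace(cxx) * np.eye(cxx.shape[0])
    cyy = cyy + RIDGE_FRACTION * np.trace(cyy) * np.eye(cyy.shape[0])
    m = cxy @ scipy.linalg.solve(cyy, cxy.T, assume_a="pos")
    eigvals = scipy.linalg.eigh(m, cxx, eigvals_only=True)
    rho_sq = float(eigvals[-1])
    return float(np.sqrt(np.clip(rho_sq, 0.0, 1.0)))


def cca_scores(segment: EEGSegment, bank: ReferenceBank) -> CCAScores:
    """First canonical correlation between the EEG channels and each bank.

    Invariant to channel order and per-channel affine rescaling.  A constant
    (rank-deficient) segment yields all-zero scores with ``degenerate=True``
    and a warning.
    """
    if segment.n_samples != bank.n_samples:
        raise ValueError(
            f"segment has {segment.n_samples} samples but bank expects {bank.n_samples}"
        )
    if segment.n_channels < 1:
        raise ValueError("segment must have at least one channel")

    x = segment.samples
    if np.allclose(x.std(axis=1), 0.0):
        warnings.warn("degenerate (constant) EEG segment; CCA scores set to 0",
                      RuntimeWarning, stacklevel=2)
        return CCAScores(
            scores=np.zeros(len(bank.frequencies_hz)),
            segment_duration_s=segment.duration_s,
            degenerate=True,
        )
    scores = np.array(
        [_first_canonical_correlation(x, ref) for ref in bank.references]
    )
    return CCAScores(scores=scores, segment_duration_s=segment.duration_s)
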