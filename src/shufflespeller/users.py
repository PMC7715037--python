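"""Simulated users: seeded response models for closed-loop simulation.

Each user model answers one query by "attending" the box that contains the
intended character, producing a synthetic trial through the same generator
used for calibration, and converting it to a per-box likelihood vector via
the fitted likelihood model — exactly the evidence path a live session
would follow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import (
    Partition,
    QueryEvidence,
    RECOGNITION_MIN_MAX,
    RECOGNITION_MIN_RATIO,
    evidence_from_likelihoods,
)
from .features import ReferenceBank, build_reference_bank, cca_scores
from .likelihood import (
    GazeLikelihoodModel,
    KDELikelihoodModel,
    class_likelihoods,
    gaze_trial_feature,
)
from .stimulus import ScreenLayout, StimulusSet
from .synth import generate_gaze_trial, generate_ssvep_trial


@dataclass
class SSVEPUserModel:
    """Simulated BCI user: attends the LED of the intended character's box."""

    model: KDELikelihoodModel
    stimulus_set: StimulusSet
    trial_duration_s: float
    snr: float
    rng: np.random.Generator
    recognition_min_max: float = RECOGNITION_MIN_MAX
    recognition_min_ratio: float = RECOGNITION_MIN_RATIO
    _bank: ReferenceBank | None = field(default=None, repr=False)

    @classmethod
    def create(cls, model, stimulus_set, trial_duration_s, snr, seed) -> "SSVEPUserModel":
        return cls(model=model, stimulus_set=stimulus_set,
                   trial_duration_s=trial_duration_s, snr=snr,
                   rng=np.random.default_rng(seed))

    def respond(self, partition: Partition, intended: str) -> QueryEvidence:
        box = partition.box_of_character(intended)
        seg = generate_ssvep_trial(
            intended_target=box,
            duration_s=self.trial_duration_s,
            snr=self.snr,
            stimulus_set=self.stimulus_set,
            seed=self.rng,
        )
        if self._bank is None or self._bank.n_samples != seg.n_samples:
            self._bank = build_reference_bank(
                self.stimulus_set, seg.duration_s, seg.rate_hz
            )
        scores = cca_scores(seg, self._bank)
        lk = class_likelihoods(self.model, scores)
        return evidence_from_likelihoods(
            lk, self.trial_duration_s,
            min_max=self.recognition_min_max,
            min_ratio=self.recognition_min_ratio,
        )


@dataclass
class GazeUserModel:
    """Simulated eye-tracking user: fixates the intended character's box."""

    model: GazeLikelihoodModel
    layout: ScreenLayout
    trial_duration_s: float
    scatter_deg: float
    dropout_rate: float
    rng: np.random.Generator
    recognition_min_max: float = RECOGNITION_MIN_MAX
    recognition_min_ratio: float = RECOGNITION_MIN_RATIO

    @classmethod
    def create(cls, model, layout, trial_duration_s, scatter_deg,
               dropout_rate, seed) -> "GazeUserModel":
        return cls(model=model, layout=layout,
                   trial_duration_s=trial_duration_s, scatter_deg=scatter_deg,
                   dropout_rate=dropout_rate, rng=np.random.default_rng(seed))

    def respond(self, partition: Partition, intended: str) -> QueryEvidence:
        box = partition.box_of_character(intended)
        trail = generate_gaze_trial(
            intended_target=box,
            duration_s=self.trial_duration_s,
            scatter_deg=self.scatter_deg,
            dropout_rate=self.dropout_rate,
            layout=self.layout,
            seed=self.rng,
        )
        feature = gaze_trial_feature(trail)
        if feature is None:
            k = self.model.n_targets
            return QueryEvidence(likelihoods=np.zeros(k), recognized=False,
                                 trial_duration_s=self.trial_duration_s)
        lk = class_likelihoods(self.model, feature)
        return evidence_from_likelihoods(
            lk, self.trial_duration_s,
            min_max=self.recognition_min_max,
            min_ratio=self.recognition_min_ratio,
        )


@dataclass
class OracleUserModel:
    """Idealized user for closed-form checks and protocol tests.

    Without ``confusion``: emits likelihood ``correct`` on the intended
    character's box and ``incorrect`` on the others every query (e.g. 19:1
    for a near-noiseless user).  With ``confusion``: samples the decoded box
    from the intended box's confusion row and emits the decoded box's
    likelihood column P(decoded | intended = b) — the calibrated generative
    evidence for that channel.
    """

    correct: float = 0.85
    incorrect: float = 0.05
    trial_duration_s: float = 2.0
    confusion: np.ndarray | None = None
    rng: np.random.Generator | None = None

    def respond(self, partition: Partition, intended: str) -> QueryEvidence:
        n = partition.n_boxes
        true_box = partition.box_of_character(intended)
        if self.confusion is None:
            lk = np.full(n, self.incorrect)
            lk[true_box] = self.correct
        else:
            if self.rng is None:
                raise ValueError("confusion sampling requires an rng")
            decoded = int(self.rng.choice(n, p=self.confusion[true_box]))
            lk = self.confusion[:, decoded].copy()
        return evidence_from_likelihoods(lk, self.trial_duration_s)


@dataclass
class UnrecognizedUserModel:
    """User whose input is never recognized (e.g. total tracker dropout)."""

    trial_duration_s: float = 2.0
    n_boxes: int = 4

    def respond(self, partition: Partition, intended: str) -> QueryEvidence:
        return QueryEvidence(likelihoods=np.zeros(self.n_boxes),
                             recognized=False,
                             trial_duration_s=self.trial_duration_s)
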