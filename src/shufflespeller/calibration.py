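"""Calibration as a fitted model: trials in, decoder + diagnostics out.

``SpellerCalibration`` is the modelling entry point: build it from raw
calibration trials (or an existing CCA-score table) and call ``fit()``.
The returned ``CalibrationResult`` carries the fitted KDE likelihood model,
the leave-one-out confusion matrix, its Nykopp channel capacity with the
optimal input distribution, and (when trials are available) the adaptive
trial-length plan, with a ``summary()`` table in the usual fitted-model
style.

Example
-------
>>> trials = simulate_calibration_trials(snr=1.0, seed=0)
>>> result = SpellerCalibration.from_trials(trials).fit()
>>> print(result.summary())          # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .itr import (
    CapacityResult,
    DEFAULT_CANDIDATE_LENGTHS_S,
    DEFAULT_OVERHEAD_S,
    TrialLengthPlan,
    nykopp_capacity,
    scores_table,
    select_trial_length,
)
from .likelihood import (
    ConfusionMatrix,
    KDELikelihoodModel,
    estimate_confusion,
    fit_kde_model,
)
from .stimulus import StimulusSet
from .synth import EEGSegment, generate_ssvep_trial

DEFAULT_TRIALS_PER_TARGET = 20
DEFAULT_CALIBRATION_TRIAL_S = 6.0


def simulate_calibration_trials(
    snr: float,
    seed: int,
    stimulus_set: StimulusSet | None = None,
    trials_per_target: int = DEFAULT_TRIALS_PER_TARGET,
    duration_s: float = DEFAULT_CALIBRATION_TRIAL_S,
) -> list[tuple[int, EEGSegment]]:
    """Generate a full calibration block: 20 trials x 4 targets by default."""
    stimulus_set = stimulus_set or StimulusSet()
    rng = np.random.default_rng(seed)
    trials = []
    for target in range(stimulus_set.n_targets):
        for _ in range(trials_per_target):
            trials.append(
                (target, generate_ssvep_trial(target, duration_s, snr,
                                              stimulus_set, seed=rng))
            )
    return trials


class SpellerCalibration:
    """Model object: a calibration block awaiting fitting.

    Parameters
    ----------
    scores
        CCA-score table (one row per trial: ``intended_target``,
        ``score_f1..score_fK``).
    trials
        Raw (intended_target, EEGSegment) pairs; kept for trial-length
        selection by truncation.  Optional when only scores are available.
    stimulus_set
        The stimulation frequencies the scores refer to.
    """

    def __init__(
        self,
        scores: pd.DataFrame,
        trials: list[tuple[int, EEGSegment]] | None = None,
        stimulus_set: StimulusSet | None = None,
    ) -> None:
        self.scores = scores
        self.trials = trials
        self.stimulus_set = stimulus_set or StimulusSet()

    @classmethod
    def from_trials(
        cls,
        trials: list[tuple[int, EEGSegment]],
        stimulus_set: StimulusSet | None = None,
    ) -> "SpellerCalibration":
        stimulus_set = stimulus_set or StimulusSet()
        return cls(scores=scores_table(trials, stimulus_set), trials=trials,
                   stimulus_set=stimulus_set)

    @classmethod
    def from_csv(cls, path: str | Path,
                 stimulus_set: StimulusSet | None = None) -> "SpellerCalibration":
        return cls(scores=pd.read_csv(path), stimulus_set=stimulus_set)

    def fit(
        self,
        smoothing: float = 0.5,
        select_length: bool = False,
        candidate_lengths_s: tuple[float, ...] = DEFAULT_CANDIDATE_LENGTHS_S,
        overhead_s: float = DEFAULT_OVERHEAD_S,
    ) -> "CalibrationResult":
        """Fit densities, estimate the confusion channel, compute capacity.

        ``select_length=True`` additionally runs trial-length selection by
        truncating the raw trials (requires ``trials``).
        """
        model = fit_kde_model(self.scores)
        confusion = estimate_confusion(self.scores, smoothing=smoothing)
        capacity = nykopp_capacity(confusion)
        plan = None
        if select_length:
            if self.trials is None:
                raise ValueError("trial-length selection requires raw trials")
            plan = select_trial_length(
                self.trials, self.stimulus_set,
                candidate_lengths_s=candidate_lengths_s,
                overhead_s=overhead_s, smoothing=smoothing,
            )
        return CalibrationResult(model=self, likelihood_model=model,
                                 confusion=confusion, capacity=capacity,
                                 trial_length_plan=plan)


@dataclass
class CalibrationResult:
    """Fitted calibration: decoder components plus channel diagnostics."""

    model: SpellerCalibration
    likelihood_model: KDELikelihoodModel
    confusion: ConfusionMatrix
    capacity: CapacityResult
    trial_length_plan: TrialLengthPlan | None = None

    def refit_at_length(self, length_s: float, smoothing: float = 0.5) -> "CalibrationResult":
        """Refit the decoder on calibration trials truncated to ``length_s``.

        Online queries run at the chosen trial length, so the likelihood
        model and confusion matrix must be fitted on scores computed at that
        same length — score distributions shift with duration.  Requires the
        raw trials.
        """
        if self.model.trials is None:
            raise ValueError("refit at a new length requires raw trials")
        table = scores_table(self.model.trials, self.model.stimulus_set,
                             duration_s=length_s)
        truncated = SpellerCalibration(scores=table, trials=self.model.trials,
                                       stimulus_set=self.model.stimulus_set)
        fitted = truncated.fit(smoothing=smoothing)
        return CalibrationResult(model=truncated,
                                 likelihood_model=fitted.likelihood_model,
                                 confusion=fitted.confusion,
                                 capacity=fitted.capacity,
                                 trial_length_plan=self.trial_length_plan)

    @property
    def loo_accuracy(self) -> float:
        """Leave-one-out decoding accuracy implied by the raw confusion counts."""
        m = self.confusion
        # Undo Laplace smoothing to recover the LOO counts on the diagonal.
        counts = m.matrix * (m.n_trials + m.k * m.smoothing)[:, None] - m.smoothing
        counts = np.clip(np.round(counts), 0, None)
        return float(np.trace(counts) / counts.sum())

    def summary(self) -> str:
        lines = []
        k = self.confusion.k
        freqs = self.model.stimulus_set.frequencies_hz
        lines.append("SSVEP Speller Calibration Results")
        lines.append("=" * 46)
        lines.append(f"{'Targets':<32}{k}")
        lines.append(f"{'Trials per target':<32}"
                     f"{', '.join(str(n) for n in self.confusion.n_trials)}")
        lines.append(f"{'LOO decoding accuracy':<32}{self.loo_accuracy:.3f}")
        lines.append(f"{'Nykopp capacity (bits/query)':<32}"
                     f"{self.capacity.capacity_bits:.4f}")
        lines.append(f"{'Capacity upper bound log2(K)':<32}{np.log2(k):.4f}")
        lines.append(f"{'BA iterations (converged)':<32}"
                     f"{self.capacity.iterations} ({self.capacity.converged})")
        lines.append("-" * 46)
        lines.append("Confusion matrix (rows: intended target)")
        for i, row in enumerate(self.confusion.matrix):
            label = f"{freqs[i]:.1f} Hz" if i < len(freqs) else f"t{i}"
            lines.append(f"  {label:<10}" + "  ".join(f"{v:.3f}" for v in row))
        lines.append("-" * 46)
        lines.append("Optimal input distribution: "
                     + ", ".join(f"{p:.3f}"
                                 for p in self.capacity.optimal_input_distribution))
        if self.trial_length_plan is not None:
            p = self.trial_length_plan
            lines.append("-" * 46)
            lines.append(f"{'Chosen trial length (s)':<32}{p.chosen_length_s:.2f}")
            lines.append(f"{'Best rate (bits/s)':<32}{p.rate_per_length.max():.4f}")
            if p.degenerate:
                lines.append("WARNING: degenerate plan (max rate < "
                             "0.05 bits/s); calibration uninformative")
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> None:
        """Write scores CSV, model JSON, confusion CSV (and plan JSON)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.model.scores.to_csv(outdir / "calibration_scores.csv", index=False)
        self.likelihood_model.to_json(outdir / "likelihood_model.json")
        self.confusion.to_csv(outdir / "confusion_matrix.csv")
        if self.trial_length_plan is not None:
            self.trial_length_plan.to_json(outdir / "trial_length_plan.json")
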