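"""Class-conditional likelihood models fitted on calibration trials.

BCI channel: for each (intended target t, stimulation frequency k) pair a
one-dimensional Gaussian kernel density estimate is fitted over the CCA
score at frequency k observed while the user attends target t — 16 densities
for 4 targets.  The joint likelihood of a score vector treats frequencies as
independent: L_t(s) = prod_k f_{t,k}(s_k).

Eye-tracking channel: per intended target a bivariate Gaussian KDE over the
trial's robust (20%-trimmed) mean gaze position of valid samples; trials with
fewer than 25% valid samples are classed "unrecognized" rather than forced
to a target.

The intended-vs-decoded confusion matrix is estimated by leave-one-out
classification over the calibration set with Laplace smoothing, and is the
channel model used for capacity and alphabet partitioning downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .features import CCAScores

DENSITY_FLOOR = 1e-12
MIN_TRIALS_PER_TARGET = 5
BANDWIDTH_FLOOR = 1e-3
MIN_VALID_FRACTION = 0.25
TRIM_FRACTION = 0.2


class InsufficientCalibrationError(ValueError):
    """Raised when a target has too few calibration trials to fit a density."""


def silverman_bandwidth(samples: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth, floored for degenerate samples.

    h = 0.9 * min(std, IQR/1.34) * n^(-1/5); the floor keeps repeated-datum
    calibration sets (zero spread) usable as narrow peaks.
    """
    samples = np.asarray(samples, dtype=float)
    n = len(samples)
    std = samples.std(ddof=1) if n > 1 else 0.0
    iqr = np.subtract(*np.percentile(samples, [75, 25]))
    spread_candidates = [s for s in (std, iqr / 1.34) if s > 0]
    spread = min(spread_candidates) if spread_candidates else 0.0
    return max(0.9 * spread * n ** (-0.2), BANDWIDTH_FLOOR)


@dataclass(frozen=True)
class GaussianKDE1D:
    """One-dimensional Gaussian-kernel density with fixed bandwidth."""

    samples: np.ndarray
    bandwidth: float

    @classmethod
    def fit(cls, samples: np.ndarray) -> "GaussianKDE1D":
        samples = np.asarray(samples, dtype=float)
        return cls(samples=samples, bandwidth=silverman_bandwidth(samples))

    def pdf(self, x: np.ndarray | float) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        z = (x[:, None] - self.samples[None, :]) / self.bandwidth
        dens = stats.norm.pdf(z).mean(axis=1) / self.bandwidth
        return dens

    def logpdf(self, x: np.ndarray | float) -> np.ndarray:
        return np.log(np.maximum(self.pdf(x), DENSITY_FLOOR))


@dataclass(frozen=True)
class GaussianKDE2D:
    """Isotropic bivariate Gaussian-kernel density with fixed bandwidth."""

    samples: np.ndarray  # (n, 2)
    bandwidth: float

    @classmethod
    def fit(cls, samples: np.ndarray) -> "GaussianKDE2D":
        samples = np.asarray(samples, dtype=float)
        per_dim = [silverman_bandwidth(samples[:, j]) for j in range(2)]
        return cls(samples=samples, bandwidth=max(float(np.mean(per_dim)),
                                                  BANDWIDTH_FLOOR))

    def pdf(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        d = xy[:, None, :] - self.samples[None, :, :]
        sq = (d**2).sum(axis=2) / self.bandwidth**2
        dens = np.exp(-sq / 2).mean(axis=1) / (2 * np.pi * self.bandwidth**2)
        return dens


@dataclass
class KDELikelihoodModel:
    """Per (intended target, frequency) KDE densities over CCA scores."""

    densities: list[list[GaussianKDE1D]]  # [target][frequency]
    n_fit_samples: list[int]

    @property
    def n_targets(self) -> int:
        return len(self.densities)

    @property
    def n_frequencies(self) -> int:
        return len(self.densities[0])

    def log_likelihoods(self, scores: np.ndarray) -> np.ndarray:
        scores = np.asarray(scores, dtype=float)
        if scores.shape != (self.n_frequencies,):
            raise ValueError(
                f"expected {self.n_frequencies} scores, got shape {scores.shape}"
            )
        out = np.empty(self.n_targets)
        for t in range(self.n_targets):
            out[t] = sum(
                float(self.densities[t][k].logpdf(scores[k])[0])
                for k in range(self.n_frequencies)
            )
        return out

    def to_json(self, path: str | Path, grid: np.ndarray | None = None) -> None:
        """Serialize fitted densities (sample points + bandwidths) to JSON."""
        doc = {
            "model": "kde_ssvep",
            "n_targets": self.n_targets,
            "n_frequencies": self.n_frequencies,
            "n_fit_samples": self.n_fit_samples,
            "densities": [
                [
                    {"samples": d.samples.tolist(), "bandwidth": d.bandwidth}
                    for d in row
                ]
                for row in self.densities
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "KDELikelihoodModel":
        doc = json.loads(Path(path).read_text())
        densities = [
            [
                GaussianKDE1D(samples=np.asarray(d["samples"]),
                              bandwidth=float(d["bandwidth"]))
                for d in row
            ]
            for row in doc["densities"]
        ]
        return cls(densities=densities, n_fit_samples=list(doc["n_fit_samples"]))


@dataclass
class GazeLikelihoodModel:
    """Per-target bivariate KDE over robust mean gaze positions."""

    densities: list[GaussianKDE2D]
    min_valid_fraction: float = MIN_VALID_FRACTION

    @property
    def n_targets(self) -> int:
        return len(self.densities)

    def log_likelihoods(self, position: np.ndarray) -> np.ndarray:
        position = np.asarray(position, dtype=float)
        if position.shape != (2,):
            raise ValueError("gaze feature must be a 2-vector")
        return np.array(
            [np.log(max(float(d.pdf(position[None, :])[0]), DENSITY_FLOOR))
             for d in self.densities]
        )


@dataclass(frozen=True)
class ConfusionMatrix:
    """Row-stochastic intended-vs-decoded matrix P(decoded j | intended i)."""

    matrix: np.ndarray
    n_trials: np.ndarray
    smoothing: float

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(m < 0):
            raise ValueError("confusion matrix entries must be nonnegative")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("confusion matrix rows must sum to 1")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "n_trials", np.asarray(self.n_trials, dtype=int))

    @property
    def k(self) -> int:
        return self.matrix.shape[0]

    def to_csv(self, path: str | Path) -> None:
        k = self.k
        df = pd.DataFrame(
            self.matrix,
            index=[f"intended_{i}" for i in range(k)],
            columns=[f"decoded_{j}" for j in range(k)],
        )
        df["n_trials"] = self.n_trials
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, smoothing: float = float("nan")) -> "ConfusionMatrix":
        df = pd.read_csv(path, index_col=0)
        n_trials = df.pop("n_trials").to_numpy()
        return cls(matrix=df.to_numpy(), n_trials=n_trials, smoothing=smoothing)


def _group_scores(
    calibration_scores: pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray]:
    """Split a calibration table into (labels, score matrix)."""
    score_cols = [c for c in calibration_scores.columns if c.startswith("score_")]
    labels = calibration_scores["intended_target"].to_numpy(dtype=int)
    scores = calibration_scores[score_cols].to_numpy(dtype=float)
    return labels, scores


def fit_kde_model(
    calibration_scores: pd.DataFrame,
    min_trials: int = MIN_TRIALS_PER_TARGET,
) -> KDELikelihoodModel:
    """Fit the 4x4 grid of per-(target, frequency) score densities.

    ``calibration_scores`` has one row per trial with columns
    ``intended_target`` and ``score_f1 .. score_fK``.
    """
    labels, scores = _group_scores(calibration_scores)
    n_targets = int(labels.max()) + 1 if len(labels) else 0
    n_freqs = scores.shape[1]
    densities: list[list[GaussianKDE1D]] = []
    n_fit = []
    for t in range(n_targets):
        rows = scores[labels == t]
        if len(rows) < min_trials:
            raise InsufficientCalibrationError(
                f"target {t} has {len(rows)} calibration trials; need >= {min_trials}"
            )
        densities.append([GaussianKDE1D.fit(rows[:, k]) for k in range(n_freqs)])
        n_fit.append(len(rows))
    return KDELikelihoodModel(densities=densities, n_fit_samples=n_fit)


def gaze_trial_feature(trail) -> np.ndarray | None:
    """Robust per-trial gaze feature: 20%-trimmed mean of valid samples.

    Returns None ("unrecognized") when fewer than 25% of samples are valid.
    """
    valid = trail.points[trail.validity]
    if len(valid) < MIN_VALID_FRACTION * trail.n_samples or len(valid) == 0:
        return None
    return np.array(
        [stats.trim_mean(valid[:, 0], TRIM_FRACTION),
         stats.trim_mean(valid[:, 1], TRIM_FRACTION)]
    )


def fit_gaze_model(
    trials: list[tuple[int, object]],
    min_trials: int = MIN_TRIALS_PER_TARGET,
) -> GazeLikelihoodModel:
    """Fit per-target bivariate densities from (intended_target, GazeTrail) pairs."""
    n_targets = max(t for t, _ in trials) + 1
    feats: list[list[np.ndarray]] = [[] for _ in range(n_targets)]
    for t, trail in trials:
        f = gaze_trial_feature(trail)
        if f is not None:
            feats[t].append(f)
    densities = []
    for t in range(n_targets):
        if len(feats[t]) < min_trials:
            raise InsufficientCalibrationError(
                f"target {t} has {len(feats[t])} usable gaze trials; need >= {min_trials}"
            )
        densities.append(GaussianKDE2D.fit(np.vstack(feats[t])))
    return GazeLikelihoodModel(densities=densities)


def class_likelihoods(
    model: KDELikelihoodModel | GazeLikelihoodModel,
    observed: CCAScores | np.ndarray,
) -> np.ndarray:
    """Unnormalized, strictly positive likelihood per intended target.

    Densities are floored at 1e-12 so no class is ever assigned exactly zero
    mass; downstream Bayes updates normalize, making the overall scale
    irrelevant.
    """
    if isinstance(observed, CCAScores):
        observed = observed.scores
    logs = model.log_likelihoods(np.asarray(observed, dtype=float))
    # Rescale before exponentiating; likelihoods are only defined up to a
    # constant and the shift avoids underflow for many frequencies.
    return np.exp(logs - logs.max())


def estimate_confusion(
    calibration_scores: pd.DataFrame,
    smoothing: float = 0.5,
    min_trials: int = MIN_TRIALS_PER_TARGET,
) -> ConfusionMatrix:
    """Leave-one-out confusion matrix of the KDE classifier.

    Each trial is decoded by the argmax class likelihood of a model fitted
    without that trial; counts are Laplace-smoothed by ``smoothing`` and rows
    normalized.
    """
    labels, scores = _group_scores(calibration_scores)
    n_targets = int(labels.max()) + 1
    n_freqs = scores.shape[1]
    for t in range(n_targets):
        if int((labels == t).sum()) < min_trials:
            raise InsufficientCalibrationError(
                f"target {t} has {(labels == t).sum()} calibration trials; "
                f"need >= {min_trials}"
            )

    counts = np.zeros((n_targets, n_targets))
    for i in range(len(labels)):
        mask = np.ones(len(labels), dtype=bool)
        mask[i] = False
        loo_labels, loo_scores = labels[mask], scores[mask]
        densities = [
            [GaussianKDE1D.fit(loo_scores[loo_labels == t][:, k])
             for k in range(n_freqs)]
            for t in range(n_targets)
        ]
        loo_model = KDELikelihoodModel(
            densities=densities,
            n_fit_samples=[int((loo_labels == t).sum()) for t in range(n_targets)],
        )
        decoded = int(np.argmax(loo_model.log_likelihoods(scores[i])))
        counts[labels[i], decoded] += 1

    n_trials = counts.sum(axis=1).astype(int)
    smoothed = counts + smoothing
    matrix = smoothed / smoothed.sum(axis=1, keepdims=True)
    return ConfusionMatrix(matrix=matrix, n_trials=n_trials, smoothing=smoothing)


def estimate_gaze_confusion(
    trials: list[tuple[int, object]],
    smoothing: float = 0.5,
    min_trials: int = MIN_TRIALS_PER_TARGET,
) -> ConfusionMatrix:
    """Leave-one-out confusion for the gaze model (unrecognized trials dropped)."""
    n_targets = max(t for t, _ in trials) + 1
    feats = []
    for t, trail in trials:
        f = gaze_trial_feature(trail)
        if f is not None:
            feats.append((t, f))
    labels = np.array([t for t, _ in feats])
    positions = np.vstack([f for _, f in feats])
    counts = np.zeros((n_targets, n_targets))
    for i in range(len(labels)):
        mask = np.ones(len(labels), dtype=bool)
        mask[i] = False
        densities = []
        for t in range(n_targets):
            rows = positions[mask][labels[mask] == t]
            if len(rows) < min_trials:
                raise InsufficientCalibrationError(
                    f"target {t} has {len(rows)} usable gaze trials; "
                    f"need >= {min_trials}"
                )
            densities.append(GaussianKDE2D.fit(rows))
        model = GazeLikelihoodModel(densities=densities)
        decoded = int(np.argmax(model.log_likelihoods(positions[i])))
        counts[labels[i], decoded] += 1
    n_trials = counts.sum(axis=1).astype(int)
    smoothed = counts + smoothing
    matrix = smoothed / smoothed.sum(axis=1, keepdims=True)
    return ConfusionMatrix(matrix=matrix, n_trials=n_trials, smoothing=smoothing)
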