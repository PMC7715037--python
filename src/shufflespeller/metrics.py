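"""Dependent variables computed from session logs.

Two accuracy definitions (with and without counting appropriate backspaces
as correct) and three characters-per-minute measures over active typing
time (which excludes between-word breaks):

* total CPM — all selections / minutes,
* correct CPM (letters + backspace) — correct selections / minutes,
* correct CPM (letters only) — correct letter selections / minutes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .session import SessionLog


class EmptySessionError(ValueError):
    """Log contains no selections."""


class InvalidLogError(ValueError):
    """Log has non-positive active typing time."""


@dataclass(frozen=True)
class SessionMetrics:
    """Per-session dependent variables (accuracies in percent, CPM per minute)."""

    n_correct_letters: int
    n_correct_backspaces: int
    n_incorrect: int
    accuracy_incl_backspace: float
    accuracy_letters_only: float
    cpm_total: float
    ccpm_letters_and_backspace: float
    ccpm_letters_only: float
    active_typing_minutes: float

    @property
    def n_selections(self) -> int:
        return self.n_correct_letters + self.n_correct_backspaces + self.n_incorrect

    def as_row(self) -> dict:
        return asdict(self)


def compute_metrics(log: SessionLog) -> SessionMetrics:
    """Accuracies and the three CPM measures for one session log."""
    selections = log.selections
    if not selections:
        raise EmptySessionError("session log contains no selections")
    if log.active_typing_time_s <= 0:
        raise InvalidLogError("active typing time must be positive")
    n_letters = sum(1 for e in selections if e.category == "correct_letter")
    n_back = sum(1 for e in selections if e.category == "correct_backspace")
    n_incorrect = sum(1 for e in selections if e.category == "incorrect")
    total = len(selections)
    minutes = log.active_typing_time_s / 60.0
    return SessionMetrics(
        n_correct_letters=n_letters,
        n_correct_backspaces=n_back,
        n_incorrect=n_incorrect,
        accuracy_incl_backspace=100.0 * (n_letters + n_back) / total,
        accuracy_letters_only=100.0 * n_letters / total,
        cpm_total=total / minutes,
        ccpm_letters_and_backspace=(n_letters + n_back) / minutes,
        ccpm_letters_only=n_letters / minutes,
        active_typing_minutes=minutes,
    )


METRIC_FIELDS = (
    "accuracy_incl_backspace",
    "accuracy_letters_only",
    "cpm_total",
    "ccpm_letters_and_backspace",
    "ccpm_letters_only",
)


@dataclass(frozen=True)
class ConditionSummary:
    """Mean / min / max of each metric over one condition's sessions."""

    condition: str
    n_sessions: int
    mean: dict
    min: dict
    max: dict


def summarize_conditions(
    logs_by_condition: dict[str, list[SessionLog]],
) -> dict[str, ConditionSummary]:
    """Per-condition central tendency and range of every session metric.

    Empty groups are skipped with a warning.  Also see ``condition_plot_data``
    for the alternating-treatments series (session index vs accuracy).
    """
    import warnings

    out: dict[str, ConditionSummary] = {}
    for condition, logs in logs_by_condition.items():
        if not logs:
            warnings.warn(f"condition {condition!r} has no sessions; skipped",
                          stacklevel=2)
            continue
        rows = [compute_metrics(log) for log in logs]
        values = {f: np.array([getattr(r, f) for r in rows]) for f in METRIC_FIELDS}
        out[condition] = ConditionSummary(
            condition=condition,
            n_sessions=len(rows),
            mean={f: float(v.mean()) for f, v in values.items()},
            min={f: float(v.min()) for f, v in values.items()},
            max={f: float(v.max()) for f, v in values.items()},
        )
    return out


def condition_plot_data(
    logs_in_order: list[SessionLog],
    metric: str = "accuracy_incl_backspace",
) -> pd.DataFrame:
    """Alternating-treatments series: session index, condition, metric value."""
    rows = []
    for i, log in enumerate(logs_in_order, start=1):
        m = compute_metrics(log)
        rows.append({"session": i, "condition": log.condition,
                     metric: getattr(m, metric)})
    return pd.DataFrame(rows)


def metrics_table(logs: list[SessionLog]) -> pd.DataFrame:
    """One row per session; accuracies rounded to one decimal in the export."""
    rows = []
    for i, log in enumerate(logs, start=1):
        row = {"session": i, "condition": log.condition}
        row.update(compute_metrics(log).as_row())
        rows.append(row)
    df = pd.DataFrame(rows)
    for col in ("accuracy_incl_backspace", "accuracy_letters_only"):
        df[col] = df[col].round(1)
    return df


def summaries_to_json(summaries: dict[str, ConditionSummary], path: str | Path) -> None:
    doc = {c: asdict(s) for c, s in summaries.items()}
    Path(path).write_text(json.dumps(doc, indent=2))


def plot_accuracy_by_session(
    logs_in_order: list[SessionLog],
    path: str | Path,
    metric: str = "accuracy_incl_backspace",
    baseline_sessions: int = 0,
) -> None:
    """Session-by-session accuracy plot, condition-coded, phases separated
    by a dashed line after the baseline sessions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = condition_plot_data(logs_in_order, metric=metric)
    fig, ax = plt.subplots(figsize=(7, 4))
    for condition, grp in df.groupby("condition"):
        ax.plot(grp["session"], grp[metric], marker="o", label=condition)
    if baseline_sessions:
        ax.axvline(baseline_sessions + 0.5, linestyle="--", color="gray")
    ax.set_xlabel("Session")
    ax.set_ylabel(metric.replace("_", " "))
    ax.set_ylim(-5, 105)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
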