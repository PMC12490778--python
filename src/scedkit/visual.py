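"""Quantified visual analysis of phase designs.

Structured visual analysis of single-case data examines six features:
level change between phases, variability within phases, trend,
immediacy of effect at the phase boundary, overlap of data points
between phases (POD), and consistency across participants.  This module
quantifies the first five per outcome; consistency across participants
is supported by tabulating participants side by side, the judgment
itself stays with the analyst.

POD here counts later-phase points *not improved beyond the most
favorable value of the previous phase*: for an outcome where improvement
is a decrease, a later point overlaps when it lies strictly above the
previous phase's minimum (points tied with the extreme count as
non-overlapping by default; a ``ties="overlap"`` switch counts them as
overlapping).  POD of 0% between A and B indicates a perfect effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .daily import DailySeries
from .design import PhaseDesign

__all__ = [
    "PhaseSummary",
    "OverlapResult",
    "ParticipantReport",
    "summarize_phase",
    "level_change",
    "pod",
    "immediacy",
    "analyze_participant",
    "table2",
    "plot_participant",
]

OUTCOMES = ("anxiety", "impact", "value_action")


@dataclass(frozen=True)
class PhaseSummary:
    """Descriptives of one outcome in one phase (observed values only).

    When the phase holds no observed value the numeric fields are NaN —
    an explicit "insufficient data" result so that reports still render.
    Trend fields are NaN when fewer than 2 points are observed.
    """

    phase: str
    n_observed: int
    mean: float
    minimum: float
    maximum: float
    trend_slope: float
    trend_intercept: float
    trend_method: str = "ols"

    @property
    def range(self) -> float:
        return self.maximum - self.minimum


@dataclass(frozen=True)
class OverlapResult:
    from_phase: str
    to_phase: str
    n_later_observed: int
    n_overlapping: int
    direction: str
    ties: str = "no_overlap"

    @property
    def pod_percent(self) -> float:
        if self.n_later_observed < 1:
            return math.nan
        return 100.0 * self.n_overlapping / self.n_later_observed


def _phase_points(series: DailySeries, phase: str) -> tuple[np.ndarray, np.ndarray]:
    """(day indices, values) of observed points in a phase."""
    days = series.design.phase_days(phase)
    idx = np.arange(days.start, days.stop)
    vals = series.values[days.start - 1 : days.stop - 1]
    keep = ~np.isnan(vals)
    return idx[keep], vals[keep]


def _split_middle_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Split-middle trend: medians of the two halves define the line.

    The traditional hand-drawn trend method of single-case visual
    analysis: split the points into first and second halves (middle point
    dropped when n is odd) and pass a line through the two
    (median day, median value) points.
    """
    n = len(x)
    h = n // 2
    x1, y1 = np.median(x[:h]), np.median(y[:h])
    x2, y2 = np.median(x[n - h:]), np.median(y[n - h:])
    if x2 == x1:
        return math.nan, math.nan
    slope = (y2 - y1) / (x2 - x1)
    return slope, y1 - slope * x1


def summarize_phase(
    series: DailySeries, phase: str, trend_method: str = "ols"
) -> PhaseSummary:
    """Level, variability and trend of one phase.

    Trend is a least-squares line of value on (absolute) day index by
    default, or the split-middle median line.
    """
    if trend_method not in ("ols", "split_middle"):
        raise ValueError(f"unknown trend method {trend_method!r}")
    x, y = _phase_points(series, phase)
    n = len(y)
    if n == 0:
        nan = math.nan
        return PhaseSummary(phase, 0, nan, nan, nan, nan, nan, trend_method)
    slope = intercept = math.nan
    if n >= 2:
        if trend_method == "ols":
            slope, intercept = np.polyfit(x, y, 1)
        else:
            slope, intercept = _split_middle_slope(x, y)
    return PhaseSummary(
        phase=phase,
        n_observed=n,
        mean=float(np.mean(y)),
        minimum=float(np.min(y)),
        maximum=float(np.max(y)),
        trend_slope=float(slope),
        trend_intercept=float(intercept),
        trend_method=trend_method,
    )


def level_change(series: DailySeries, from_phase: str, to_phase: str) -> float:
    """Signed difference of phase means, later minus earlier.

    Negative means the outcome decreased from the earlier to the later
    phase — improvement for anxiety and impact.  NaN when either phase
    has no observed value.
    """
    _, y_from = _phase_points(series, from_phase)
    _, y_to = _phase_points(series, to_phase)
    if len(y_from) == 0 or len(y_to) == 0:
        return math.nan
    return float(np.mean(y_to) - np.mean(y_from))


def pod(
    series: DailySeries,
    from_phase: str,
    to_phase: str,
    direction: str | None = None,
    ties: str = "no_overlap",
) -> OverlapResult:
    """Percent of overlapping data between two phases.

    A later-phase point overlaps when it has not improved beyond the
    previous phase's most favorable value: strictly above the previous
    minimum when improvement is a decrease, strictly below the previous
    maximum when improvement is an increase.  ``ties="overlap"`` counts
    points equal to the extreme as overlapping instead.
    """
    direction = direction or series.direction
    if direction not in ("decrease", "increase"):
        raise ValueError(f"direction must be 'decrease' or 'increase', got {direction!r}")
    if ties not in ("no_overlap", "overlap"):
        raise ValueError(f"ties must be 'no_overlap' or 'overlap', got {ties!r}")
    _, y_from = _phase_points(series, from_phase)
    _, y_to = _phase_points(series, to_phase)
    if len(y_from) == 0 or len(y_to) == 0:
        return OverlapResult(from_phase, to_phase, len(y_to), 0, direction, ties)
    if direction == "decrease":
        extreme = np.min(y_from)
        n_overlap = int(np.sum(y_to > extreme) if ties == "no_overlap"
                        else np.sum(y_to >= extreme))
    else:
        extreme = np.max(y_from)
        n_overlap = int(np.sum(y_to < extreme) if ties == "no_overlap"
                        else np.sum(y_to <= extreme))
    return OverlapResult(from_phase, to_phase, len(y_to), n_overlap, direction, ties)


def immediacy(series: DailySeries, window_k: int = 3) -> float:
    """Level change right at treatment entry.

    Mean of the first ``window_k`` observed treatment-phase values minus
    the mean of the last ``window_k`` observed baseline values; same sign
    convention as :func:`level_change`.  NaN when either side has fewer
    than ``window_k`` observed values.  A delayed effect shows a small
    immediacy despite a large full-phase level change.
    """
    if window_k < 1:
        raise ValueError("window_k must be >= 1")
    _, y_a = _phase_points(series, "A")
    _, y_b = _phase_points(series, "B")
    if len(y_a) < window_k or len(y_b) < window_k:
        return math.nan
    return float(np.mean(y_b[:window_k]) - np.mean(y_a[-window_k:]))


@dataclass(frozen=True)
class ParticipantReport:
    """All quantified visual-analysis features for one participant."""

    participant_id: str
    design: PhaseDesign
    summaries: dict[str, dict[str, PhaseSummary]]     # outcome -> phase -> summary
    level_changes: dict[str, dict[str, float]]        # outcome -> "A_to_B"/"B_to_C"
    overlaps: dict[str, dict[str, OverlapResult]]     # outcome -> "A_to_B"/"B_to_C"
    immediacies: dict[str, float]                     # outcome -> value
    ties: str
    trend_method: str


def analyze_participant(
    series_by_outcome: dict[str, DailySeries],
    design: PhaseDesign,
    trend_method: str = "ols",
    ties: str = "no_overlap",
    immediacy_window: int = 3,
) -> ParticipantReport:
    """Quantify level, variability, trend, immediacy and overlap per outcome."""
    pid = next(iter(series_by_outcome.values())).participant_id
    summaries: dict[str, dict[str, PhaseSummary]] = {}
    changes: dict[str, dict[str, float]] = {}
    overlaps: dict[str, dict[str, OverlapResult]] = {}
    immediacies: dict[str, float] = {}
    for outcome, series in series_by_outcome.items():
        summaries[outcome] = {
            ph: summarize_phase(series, ph, trend_method) for ph in ("A", "B", "C")
        }
        changes[outcome] = {
            "A_to_B": level_change(series, "A", "B"),
            "B_to_C": level_change(series, "B", "C"),
        }
        overlaps[outcome] = {
            "A_to_B": pod(series, "A", "B", ties=ties),
            "B_to_C": pod(series, "B", "C", ties=ties),
        }
        immediacies[outcome] = immediacy(series, immediacy_window)
    return ParticipantReport(
        pid, design, summaries, changes, overlaps, immediacies, ties, trend_method
    )


def table2(reports: list[ParticipantReport], outcome: str = "anxiety") -> pd.DataFrame:
    """Mean level change and POD per participant, display-rounded.

    Mean changes to one decimal, POD to whole percent; one row per
    participant with A-to-B and B-to-C columns.
    """
    rows = []
    for r in reports:
        rows.append(
            {
                "participant_id": r.participant_id,
                "mean_change_A_to_B": round(r.level_changes[outcome]["A_to_B"], 1),
                "mean_change_B_to_C": round(r.level_changes[outcome]["B_to_C"], 1),
                "pod_A_to_B_percent": _round_pct(r.overlaps[outcome]["A_to_B"].pod_percent),
                "pod_B_to_C_percent": _round_pct(r.overlaps[outcome]["B_to_C"].pod_percent),
            }
        )
    return pd.DataFrame(rows)


def _round_pct(x: float) -> float:
    return x if math.isnan(x) else round(x)


def plot_participant(
    series_by_outcome: dict[str, DailySeries],
    design: PhaseDesign,
    path: str,
    trend_method: str = "ols",
) -> None:
    """Phase plot per outcome: points, phase mean lines, trend lines, separators."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outcomes = [o for o in OUTCOMES if o in series_by_outcome]
    fig, axes = plt.subplots(len(outcomes), 1, figsize=(9, 2.6 * len(outcomes)),
                             sharex=True, squeeze=False)
    for ax, outcome in zip(axes[:, 0], outcomes):
        series = series_by_outcome[outcome]
        days = np.arange(1, design.total_days + 1)
        ax.plot(days, series.values, "o-", ms=3, lw=0.8, color="0.4")
        for ph in ("A", "B", "C"):
            s = summarize_phase(series, ph, trend_method)
            pd_range = design.phase_days(ph)
            x = np.array([pd_range.start, pd_range.stop - 1])
            if s.n_observed:
                ax.hlines(s.mean, x[0], x[1], color="red", lw=1.5)
            if not math.isnan(s.trend_slope):
                ax.plot(x, s.trend_intercept + s.trend_slope * x, color="black", lw=1.2)
        for boundary in (design.baseline_days + 0.5,
                         design.baseline_days + design.treatment_days + 0.5):
            ax.axvline(boundary, ls=":", color="black")
        ax.set_ylabel(outcome)
    axes[-1, 0].set_xlabel("day")
    fig.suptitle(series_by_outcome[outcomes[0]].participant_id)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
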