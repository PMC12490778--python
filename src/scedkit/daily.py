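"""Daily text-message outcome items: validation, recoding, scoring, CSV I/O.

Each day a participant answers five items on a raw 1–10 scale, recoded to
0–9 for analysis.  Items 1–3 are anxiety items and are summed to a daily
anxiety score (0–27); item 4 measures the impact of anxiety (0–9); item 5
measures value-based action (0–9) and is oriented so that *higher* is
better — the analytic modules carry that orientation rather than
arithmetically flipping the score (an optional ``reverse_item5`` switch
performs ``9 - x`` for users who want the flipped scale).

Only responses answered on the same day they were prompted are valid;
a response with ``same_day=False`` scores as wholly missing.  There is no
imputation anywhere: missing stays missing and every downstream statistic
is computed over observed values only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .design import PhaseDesign, phase_of

__all__ = [
    "ValidationError",
    "DailyResponse",
    "ScoredDay",
    "DailySeries",
    "OUTCOME_BOUNDS",
    "recode_item",
    "score_day",
    "score_dataset",
    "missingness_report",
    "series_from_scored",
    "read_daily_csv",
    "write_daily_csv",
    "write_scored_csv",
    "read_scored_csv",
]

log = logging.getLogger(__name__)

#: Inclusive (low, high) bounds of each scored daily outcome.
OUTCOME_BOUNDS: dict[str, tuple[int, int]] = {
    "anxiety": (0, 27),
    "impact": (0, 9),
    "value_action": (0, 9),
}

#: Improvement direction per outcome: anxiety and its impact should fall,
#: value-based action should rise.
OUTCOME_DIRECTION: dict[str, str] = {
    "anxiety": "decrease",
    "impact": "decrease",
    "value_action": "increase",
}

RAW_MIN, RAW_MAX = 1, 10


class ValidationError(ValueError):
    """Input data violates the daily-measure data model."""


@dataclass(frozen=True)
class DailyResponse:
    """One day's raw item responses (1–10 scale; ``None`` = unanswered)."""

    participant_id: str
    day_index: int
    items: tuple[int | None, int | None, int | None, int | None, int | None]
    same_day: bool = True

    def __post_init__(self) -> None:
        if len(self.items) != 5:
            raise ValidationError(
                f"participant {self.participant_id} day {self.day_index}: "
                f"expected 5 items, got {len(self.items)}"
            )
        if self.day_index < 1:
            raise ValidationError(
                f"participant {self.participant_id}: day_index must be >= 1, "
                f"got {self.day_index}"
            )
        for i, v in enumerate(self.items, start=1):
            if v is not None and not (RAW_MIN <= v <= RAW_MAX):
                raise ValidationError(
                    f"participant {self.participant_id} day {self.day_index} "
                    f"item {i}: raw value {v} outside [{RAW_MIN}, {RAW_MAX}]"
                )


@dataclass(frozen=True)
class ScoredDay:
    """Scored daily outcomes; ``None`` marks a missing score."""

    participant_id: str
    day_index: int
    anxiety_sum: int | None
    impact: int | None
    value_action: int | None

    def value(self, outcome: str) -> int | None:
        if outcome == "anxiety":
            return self.anxiety_sum
        if outcome in ("impact", "value_action"):
            return getattr(self, outcome)
        raise ValueError(f"unknown outcome {outcome!r}")

    @property
    def all_missing(self) -> bool:
        return self.anxiety_sum is None and self.impact is None and self.value_action is None


@dataclass(frozen=True)
class DailySeries:
    """One outcome over a participant's full measurement course.

    ``values`` is a float array of length ``design.total_days`` indexed by
    day (position 0 = day 1); missing days are NaN.
    """

    participant_id: str
    design: PhaseDesign
    outcome_name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if len(vals) != self.design.total_days:
            raise ValidationError(
                f"participant {self.participant_id}: series length {len(vals)} "
                f"!= design total_days {self.design.total_days}"
            )
        lo, hi = OUTCOME_BOUNDS[self.outcome_name]
        obs = vals[~np.isnan(vals)]
        if obs.size and (obs.min() < lo or obs.max() > hi):
            raise ValidationError(
                f"participant {self.participant_id} outcome {self.outcome_name}: "
                f"values outside [{lo}, {hi}]"
            )

    def phase_values(self, phase: str) -> np.ndarray:
        """Observed (non-missing) values within one phase, in day order."""
        days = self.design.phase_days(phase)
        sub = self.values[days.start - 1 : days.stop - 1]
        return sub[~np.isnan(sub)]

    @property
    def direction(self) -> str:
        """Improvement direction of this outcome."""
        return OUTCOME_DIRECTION[self.outcome_name]


def recode_item(raw: int) -> int:
    """Recode a raw 1–10 item response to the analysis 0–9 scale."""
    if not (RAW_MIN <= raw <= RAW_MAX):
        raise ValidationError(f"raw item value {raw} outside [{RAW_MIN}, {RAW_MAX}]")
    return raw - 1


def score_day(r: DailyResponse, reverse_item5: bool = False) -> ScoredDay:
    """Score one day's response.

    The anxiety sum requires all of items 1–3; impact and value-based
    action are scored independently from their own item.  A response not
    answered on the day it was sent is invalid and scores as missing.
    """
    if not r.same_day:
        return ScoredDay(r.participant_id, r.day_index, None, None, None)
    coded = [None if v is None else recode_item(v) for v in r.items]
    anxiety = None
    if all(c is not None for c in coded[:3]):
        anxiety = coded[0] + coded[1] + coded[2]
    impact = coded[3]
    value_action = coded[4]
    if reverse_item5 and value_action is not None:
        value_action = 9 - value_action
    return ScoredDay(r.participant_id, r.day_index, anxiety, impact, value_action)


def score_dataset(
    responses: list[DailyResponse], reverse_item5: bool = False
) -> list[ScoredDay]:
    """Score a dataset, enforcing (participant, day) uniqueness."""
    seen: set[tuple[str, int]] = set()
    out = []
    for r in responses:
        key = (r.participant_id, r.day_index)
        if key in seen:
            raise ValidationError(
                f"duplicate response for participant {r.participant_id} "
                f"day {r.day_index}"
            )
        seen.add(key)
        out.append(score_day(r, reverse_item5=reverse_item5))
    return out


def missingness_report(
    scored: list[ScoredDay], designs: dict[str, PhaseDesign]
) -> pd.DataFrame:
    """Per-participant and overall missing-day bookkeeping.

    A day counts as missing when it has no valid score on any outcome —
    either no response was recorded or the response was invalid
    (answered late).  Percentages are reported to one decimal.
    """
    present: dict[str, set[int]] = {pid: set() for pid in designs}
    for s in scored:
        if s.participant_id not in designs:
            raise ValidationError(
                f"participant {s.participant_id} has no phase design"
            )
        if not s.all_missing:
            present[s.participant_id].add(s.day_index)
    rows = []
    for pid, design in designs.items():
        n_expected = design.total_days
        n_missing = n_expected - len(present[pid])
        rows.append(
            {
                "participant_id": pid,
                "n_expected": n_expected,
                "n_missing": n_missing,
                "percent_missing": round(100.0 * n_missing / n_expected, 1),
            }
        )
    total_expected = sum(r["n_expected"] for r in rows)
    total_missing = sum(r["n_missing"] for r in rows)
    rows.append(
        {
            "participant_id": "overall",
            "n_expected": total_expected,
            "n_missing": total_missing,
            "percent_missing": round(100.0 * total_missing / total_expected, 1),
        }
    )
    return pd.DataFrame(rows)


def series_from_scored(
    scored: list[ScoredDay],
    participant_id: str,
    design: PhaseDesign,
    outcome: str,
) -> DailySeries:
    """Assemble one participant's day-indexed series for one outcome."""
    values = np.full(design.total_days, np.nan)
    for s in scored:
        if s.participant_id != participant_id:
            continue
        if not (1 <= s.day_index <= design.total_days):
            raise ValidationError(
                f"participant {participant_id} day {s.day_index} outside "
                f"1..{design.total_days}"
            )
        v = s.value(outcome)
        if v is not None:
            values[s.day_index - 1] = v
    return DailySeries(participant_id, design, outcome, values)


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------

DAILY_COLUMNS = ["participant_id", "day_index", "item1", "item2", "item3",
                 "item4", "item5", "same_day"]
SCORED_COLUMNS = ["participant_id", "day_index", "phase", "anxiety_sum",
                  "impact", "value_action"]


def _cell_to_item(cell, row_no: int) -> int | None:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)) or cell == "":
        return None
    try:
        f = float(cell)
    except (TypeError, ValueError):
        raise ValidationError(f"row {row_no}: non-numeric item value {cell!r}")
    if not f.is_integer():
        raise ValidationError(f"row {row_no}: non-integer item value {cell!r}")
    return int(f)


def read_daily_csv(path: str | Path) -> list[DailyResponse]:
    """Read the long-format daily-response CSV.

    Required columns: participant_id, day_index, item1..item5 and either a
    boolean ``same_day`` column or an ``answered_date``/``sent_date`` pair
    from which same-day validity is derived.  Malformed rows raise
    :class:`ValidationError` naming the offending row.
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    base_required = DAILY_COLUMNS[:-1]
    missing_cols = [c for c in base_required if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"{path}: missing required columns {missing_cols}")
    if "same_day" in df.columns:
        same_day = df["same_day"]
        known = set(DAILY_COLUMNS)
    elif {"answered_date", "sent_date"} <= set(df.columns):
        same_day = df["answered_date"] == df["sent_date"]
        known = set(base_required) | {"answered_date", "sent_date"}
    else:
        raise ValidationError(
            f"{path}: need a same_day column or answered_date/sent_date pair"
        )
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        log.warning("%s: ignoring unknown columns %s", path, unknown)

    responses = []
    for pos, (_, row) in enumerate(df.iterrows()):
        row_no = pos + 2  # header is line 1
        try:
            day = int(row["day_index"])
        except (TypeError, ValueError):
            raise ValidationError(
                f"row {row_no}: day_index {row['day_index']!r} is not an integer"
            )
        items = tuple(_cell_to_item(row[f"item{i}"], row_no) for i in range(1, 6))
        sd = same_day.iloc[pos]
        if isinstance(sd, str):
            sd = sd.strip().lower() in ("true", "1", "yes")
        responses.append(
            DailyResponse(str(row["participant_id"]), day, items, bool(sd))
        )
    # uniqueness check with row context
    seen: dict[tuple[str, int], int] = {}
    for pos, r in enumerate(responses):
        key = (r.participant_id, r.day_index)
        if key in seen:
            raise ValidationError(
                f"row {pos + 2}: duplicate (participant {r.participant_id}, "
                f"day {r.day_index}); first seen at row {seen[key] + 2}"
            )
        seen[key] = pos
    return responses


def write_daily_csv(responses: list[DailyResponse], path: str | Path) -> None:
    """Write raw responses in the long-format daily CSV dialect."""
    rows = []
    for r in responses:
        row: dict = {"participant_id": r.participant_id, "day_index": r.day_index}
        for i, v in enumerate(r.items, start=1):
            row[f"item{i}"] = "" if v is None else v
        row["same_day"] = r.same_day
        rows.append(row)
    pd.DataFrame(rows, columns=DAILY_COLUMNS).to_csv(path, index=False)


def write_scored_csv(
    scored: list[ScoredDay],
    designs: dict[str, PhaseDesign],
    path: str | Path,
) -> None:
    """Write scored days with their phase label."""
    rows = []
    for s in scored:
        if s.participant_id not in designs:
            raise ValidationError(f"participant {s.participant_id} has no phase design")
        rows.append(
            {
                "participant_id": s.participant_id,
                "day_index": s.day_index,
                "phase": phase_of(s.day_index, designs[s.participant_id]),
                "anxiety_sum": "" if s.anxiety_sum is None else s.anxiety_sum,
                "impact": "" if s.impact is None else s.impact,
                "value_action": "" if s.value_action is None else s.value_action,
            }
        )
    pd.DataFrame(rows, columns=SCORED_COLUMNS).to_csv(path, index=False)


def read_scored_csv(path: str | Path) -> list[ScoredDay]:
    """Read a scored CSV back into :class:`ScoredDay` records."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing_cols = [c for c in SCORED_COLUMNS if c not in df.columns and c != "phase"]
    if missing_cols:
        raise ValidationError(f"{path}: missing required columns {missing_cols}")
    out = []
    for pos, (_, row) in enumerate(df.iterrows()):
        row_no = pos + 2
        out.append(
            ScoredDay(
                str(row["participant_id"]),
                int(row["day_index"]),
                _cell_to_item(row["anxiety_sum"], row_no),
                _cell_to_item(row["impact"], row_no),
                _cell_to_item(row["value_action"], row_no),
            )
        )
    return out
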