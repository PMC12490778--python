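"""Secondary-outcome questionnaire scoring at the four assessment points.

Questionnaires are answered at baseline, treatment start, end of
treatment and follow-up.  Scoring specs (item count, item range, sum vs
mean aggregation) are data, loaded from a bundled YAML file; the module
computes total scores only.  Missing items are an error — these
instruments are scored only when complete.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .daily import ValidationError

__all__ = [
    "QuestionnaireSpec",
    "AssessmentRecord",
    "TIME_POINTS",
    "load_specs",
    "score",
    "change_table",
    "read_questionnaire_csv",
]

TIME_POINTS = ("baseline", "start", "end_of_treatment", "follow_up")


@dataclass(frozen=True)
class QuestionnaireSpec:
    name: str
    n_items: int
    item_min: int
    item_max: int
    aggregation: str  # "sum" | "mean"

    def __post_init__(self) -> None:
        if self.aggregation not in ("sum", "mean"):
            raise ValidationError(
                f"{self.name}: aggregation must be 'sum' or 'mean', "
                f"got {self.aggregation!r}"
            )

    @property
    def score_min(self) -> float:
        return self.n_items * self.item_min if self.aggregation == "sum" else float(self.item_min)

    @property
    def score_max(self) -> float:
        return self.n_items * self.item_max if self.aggregation == "sum" else float(self.item_max)


@dataclass(frozen=True)
class AssessmentRecord:
    participant_id: str
    time_point: str
    questionnaire: str
    responses: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.time_point not in TIME_POINTS:
            raise ValidationError(
                f"participant {self.participant_id}: unknown time point "
                f"{self.time_point!r}; expected one of {TIME_POINTS}"
            )


def load_specs(path: str | Path | None = None) -> dict[str, QuestionnaireSpec]:
    """Load questionnaire specs from YAML (bundled specs by default)."""
    if path is None:
        text = (resources.files("scedkit") / "data" / "questionnaire_specs.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return {name: QuestionnaireSpec(name=name, **cfg) for name, cfg in raw.items()}


def score(record: AssessmentRecord, spec: QuestionnaireSpec) -> float:
    """Total (sum or mean) score of one completed assessment."""
    if len(record.responses) != spec.n_items:
        raise ValidationError(
            f"participant {record.participant_id} {spec.name} at "
            f"{record.time_point}: expected {spec.n_items} items, "
            f"got {len(record.responses)} (missing items are not scored)"
        )
    for i, v in enumerate(record.responses, start=1):
        if not (spec.item_min <= v <= spec.item_max):
            raise ValidationError(
                f"participant {record.participant_id} {spec.name} at "
                f"{record.time_point} item {i}: value {v} outside "
                f"[{spec.item_min}, {spec.item_max}]"
            )
    total = float(sum(record.responses))
    return total if spec.aggregation == "sum" else total / spec.n_items


def change_table(
    records: list[AssessmentRecord], spec: QuestionnaireSpec
) -> pd.DataFrame:
    """Participants x time-points score table with baseline-to-follow-up change.

    Mean subscale scores are rendered at full precision; use one decimal
    for display to match conventional reporting.
    """
    cells: dict[tuple[str, str], float] = {}
    for r in records:
        if r.questionnaire != spec.name:
            continue
        key = (r.participant_id, r.time_point)
        if key in cells:
            raise ValidationError(
                f"duplicate {spec.name} record for participant "
                f"{r.participant_id} at {r.time_point}"
            )
        cells[key] = score(r, spec)
    participants = sorted({pid for pid, _ in cells})
    rows = []
    for pid in participants:
        row: dict = {"participant_id": pid}
        for tp in TIME_POINTS:
            row[tp] = cells.get((pid, tp))
        if row["baseline"] is not None and row["follow_up"] is not None:
            row["change_baseline_to_follow_up"] = row["follow_up"] - row["baseline"]
        else:
            row["change_baseline_to_follow_up"] = None
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["participant_id", *TIME_POINTS, "change_baseline_to_follow_up"],
    )


def read_questionnaire_csv(
    path: str | Path, specs: dict[str, QuestionnaireSpec]
) -> list[AssessmentRecord]:
    """Read assessment records: participant_id, time_point, questionnaire, item_1..item_k."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    for col in ("participant_id", "time_point", "questionnaire"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col}")
    records = []
    for pos, (_, row) in enumerate(df.iterrows()):
        qname = str(row["questionnaire"])
        if qname not in specs:
            raise ValidationError(
                f"row {pos + 2}: unknown questionnaire {qname!r}"
            )
        spec = specs[qname]
        responses = []
        for i in range(1, spec.n_items + 1):
            col = f"item_{i}"
            if col not in df.columns or pd.isna(row[col]):
                raise ValidationError(
                    f"row {pos + 2}: participant {row['participant_id']} "
                    f"{qname}: missing item_{i}"
                )
            responses.append(int(row[col]))
        records.append(
            AssessmentRecord(
                str(row["participant_id"]),
                str(row["time_point"]),
                qname,
                tuple(responses),
            )
        )
    return records
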