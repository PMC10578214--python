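"""Data model and I/O for longitudinal item-level assessments.

The visits file is long ("tidy") CSV with one recorded score per row::

    participant_id,scheduled_month,actual_month,item_code,state,value

``state`` is ``OFF``/``ON`` for motor-exam items scored per medication state
and ``NA`` otherwise.  Missing scores are simply absent rows — never zero.
The covariate file is wide CSV, one row per participant, using the column
names in :data:`pdmilestones.items.COVARIATE_COLUMNS`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .items import (
    COGNITIVE_TESTS,
    COVARIATE_COLUMNS,
    ITEM_TABLE,
    POSITIVE_COVARIATES,
    SCHEDULE_MONTHS,
    STATES,
    VISIT_GRID,
)


class ParseError(ValueError):
    """Malformed row in an input file."""


class IntegrityError(ValueError):
    """Duplicate (participant, month, item, state) record."""


class RangeValidationError(ValueError):
    """Score outside the instrument's documented range."""


_FLAG_NAMES = {
    "FLAG_PDD": "pdd_diagnosis",
    "FLAG_COG_FUNC_IMPAIR": "functional_impairment_cognitive",
}
_FLAG_CODES = {v: k for k, v in _FLAG_NAMES.items()}


@dataclass
class VisitAssessment:
    """One participant-visit's item-level scores.

    Missing is representable and distinct from zero throughout: an item
    absent from ``items`` (or a ``None`` state score / flag) is missing.
    """

    participant_id: str
    scheduled_month: int
    actual_month: Optional[float] = None
    items: dict = field(default_factory=dict)  # code -> value
    motor_state_items: dict = field(default_factory=dict)  # code -> {state: value}
    bp: dict = field(default_factory=dict)  # (measure, position) -> value
    cognitive_scores: dict = field(default_factory=dict)  # test code -> z
    investigator_flags: dict = field(default_factory=dict)  # name -> bool

    def __post_init__(self):
        if self.scheduled_month not in VISIT_GRID:
            raise ParseError(
                f"scheduled_month {self.scheduled_month} not on per-protocol grid"
            )
        if self.actual_month is None:
            self.actual_month = float(self.scheduled_month)
        if self.actual_month < 0:
            raise ParseError("actual_month must be nonnegative")

    # -- accessors used by the milestone engine ---------------------------
    def get_item(self, code: str) -> Optional[float]:
        return self.items.get(code)

    def get_motor(self, code: str) -> dict:
        return self.motor_state_items.get(code, {})

    def get_bp(self, measure: str, position: str) -> Optional[float]:
        return self.bp.get((measure, position))

    def get_flag(self, name: str) -> Optional[bool]:
        return self.investigator_flags.get(name)

    @property
    def cognitive_domain_scores(self) -> dict:
        """Map cognitive-domain name -> list of z-scores recorded this visit."""
        out: dict[str, list] = {}
        for code, z in self.cognitive_scores.items():
            out.setdefault(COGNITIVE_TESTS[code], []).append(z)
        return out

    @property
    def n_recorded(self) -> int:
        n = len(self.items) + len(self.bp) + len(self.cognitive_scores)
        n += sum(v is not None for v in self.investigator_flags.values())
        n += sum(
            v is not None for d in self.motor_state_items.values() for v in d.values()
        )
        return n

    def iter_records(self):
        """Yield (item_code, state, value) rows for serialization."""
        for code, v in sorted(self.items.items()):
            yield code, "NA", v
        for code, states in sorted(self.motor_state_items.items()):
            for state, v in sorted(states.items()):
                if v is not None:
                    yield code, state, v
        for (meas, pos), v in sorted(self.bp.items()):
            yield f"BP_{meas}_{pos}", "NA", v
        for code, v in sorted(self.cognitive_scores.items()):
            yield code, "NA", v
        for name, v in sorted(self.investigator_flags.items()):
            if v is not None:
                yield _FLAG_CODES[name], "NA", float(v)


@dataclass
class ValidationReport:
    """Informational findings from parsing / schedule validation."""

    unknown_codes: list = field(default_factory=list)
    missing_visits: dict = field(default_factory=dict)  # pid -> [months]
    out_of_grid: list = field(default_factory=list)
    off_schedule_items: list = field(default_factory=list)  # (pid, month, code)
    notes: list = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not (
            self.unknown_codes
            or self.missing_visits
            or self.out_of_grid
            or self.off_schedule_items
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "unknown_codes": sorted(set(self.unknown_codes)),
                "missing_visits": self.missing_visits,
                "out_of_grid": self.out_of_grid,
                "off_schedule_items": self.off_schedule_items,
                "notes": self.notes,
            },
            indent=2,
        )


class CovariateTable:
    """Wide baseline covariate table, one row per participant."""

    def __init__(self, frame: pd.DataFrame):
        if "participant_id" not in frame.columns:
            raise ParseError("covariates file lacks participant_id column")
        frame = frame.copy()
        frame["participant_id"] = frame["participant_id"].astype(str)
        if frame["participant_id"].duplicated().any():
            dups = frame.loc[
                frame["participant_id"].duplicated(), "participant_id"
            ].tolist()
            raise IntegrityError(f"duplicate covariate rows for {dups}")
        for col in POSITIVE_COVARIATES:
            if col in frame.columns:
                bad = frame[col].dropna() <= 0
                if bad.any():
                    raise RangeValidationError(
                        f"covariate {col} must be positive; offending participants: "
                        f"{frame.loc[bad[bad].index, 'participant_id'].tolist()}"
                    )
        if "med_initiation_month" in frame.columns:
            bad = frame["med_initiation_month"].dropna() < 0
            if bad.any():
                raise RangeValidationError("med_initiation_month must be >= 0")
        self.frame = frame.set_index("participant_id", drop=False)

    @property
    def participants(self) -> list:
        return list(self.frame.index)

    def med_initiation(self, pid: str) -> Optional[float]:
        if "med_initiation_month" not in self.frame.columns:
            return None
        v = self.frame.loc[pid, "med_initiation_month"]
        return None if pd.isna(v) else float(v)

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class StudyDataset:
    """Validated visits + covariates for one cohort."""

    visits: dict  # (participant_id, scheduled_month) -> VisitAssessment
    covariates: CovariateTable
    report: ValidationReport = field(default_factory=ValidationReport)

    def __post_init__(self):
        cov_ids = set(self.covariates.participants)
        visit_ids = {pid for pid, _ in self.visits}
        missing = visit_ids - cov_ids
        if missing:
            raise IntegrityError(
                f"participants in visits but not covariates: {sorted(missing)}"
            )

    @property
    def participants(self) -> list:
        return self.covariates.participants

    def visit(self, pid: str, month: int) -> Optional[VisitAssessment]:
        return self.visits.get((pid, month))

    def participant_months(self, pid: str) -> list:
        return sorted(m for p, m in self.visits if p == pid)

    @property
    def n_enrolled(self) -> int:
        return len(self.covariates)


def _build_visit(pid, month, actual, rows, report, allow_out_of_range):
    visit = VisitAssessment(str(pid), int(month), actual)
    bad_cells = []
    for code, state, value, line in rows:
        spec = ITEM_TABLE.get(code)
        if spec is None:
            report.unknown_codes.append(code)
            visit.items[code] = value
            continue
        if not spec.in_range(value) and not allow_out_of_range:
            bad_cells.append((pid, month, code, state, value, line))
            continue
        if spec.kind == "motor":
            if state not in ("OFF", "ON"):
                raise ParseError(
                    f"line {line}: motor item {code} requires state OFF or ON"
                )
            visit.motor_state_items.setdefault(code, {})[state] = value
        elif spec.kind == "bp":
            _, meas, pos = code.split("_")
            visit.bp[(meas, pos)] = value
        elif spec.kind == "cognitive":
            visit.cognitive_scores[code] = value
        elif spec.kind == "flag":
            visit.investigator_flags[_FLAG_NAMES[code]] = bool(value)
        else:
            visit.items[code] = value
    if bad_cells:
        raise RangeValidationError(
            "scores outside instrument range: "
            + "; ".join(
                f"line {ln}: {p}/{m}/{c} state={s} value={v}"
                for p, m, c, s, v, ln in bad_cells
            )
        )
    return visit


def dataset_from_frames(
    visits_df: pd.DataFrame,
    covariates_df: pd.DataFrame,
    allow_out_of_range: bool = False,
) -> StudyDataset:
    """Build a StudyDataset from in-memory long-format frames."""
    report = ValidationReport()
    required = {"participant_id", "scheduled_month", "item_code", "state", "value"}
    missing_cols = required - set(visits_df.columns)
    if missing_cols:
        raise ParseError(f"visits table lacks columns: {sorted(missing_cols)}")

    df = visits_df.copy()
    df["_line"] = np.arange(2, len(df) + 2)  # header is line 1
    bad_state = ~df["state"].isin(STATES)
    if bad_state.any():
        ln = int(df.loc[bad_state, "_line"].iloc[0])
        raise ParseError(f"line {ln}: state must be one of {STATES}")
    vals = pd.to_numeric(df["value"], errors="coerce")
    if vals.isna().any():
        ln = int(df.loc[vals.isna(), "_line"].iloc[0])
        raise ParseError(f"line {ln}: non-numeric value")
    df["value"] = vals
    months = pd.to_numeric(df["scheduled_month"], errors="coerce")
    if months.isna().any():
        ln = int(df.loc[months.isna(), "_line"].iloc[0])
        raise ParseError(f"line {ln}: non-numeric scheduled_month")
    df["scheduled_month"] = months.astype(int)

    dup = df.duplicated(
        subset=["participant_id", "scheduled_month", "item_code", "state"], keep=False
    )
    if dup.any():
        first = df.loc[dup].iloc[0]
        raise IntegrityError(
            f"duplicate record for participant {first['participant_id']} month "
            f"{first['scheduled_month']} item {first['item_code']} "
            f"state {first['state']}"
        )

    has_actual = "actual_month" in df.columns
    df = df.sort_values(["participant_id", "scheduled_month"], kind="stable")
    pids = df["participant_id"].astype(str).tolist()
    months = df["scheduled_month"].tolist()
    actuals = (
        pd.to_numeric(df["actual_month"], errors="coerce").tolist()
        if has_actual
        else None
    )
    codes = df["item_code"].tolist()
    row_states = df["state"].tolist()
    values = df["value"].tolist()
    lines = df["_line"].tolist()

    visits: dict = {}
    i, n_rows = 0, len(df)
    while i < n_rows:
        pid, month = pids[i], months[i]
        j = i
        while j < n_rows and pids[j] == pid and months[j] == month:
            j += 1
        actual = None
        if actuals is not None:
            for k in range(i, j):
                a = actuals[k]
                if a == a:  # not NaN
                    actual = float(a)
                    break
        rows = list(zip(codes[i:j], row_states[i:j], values[i:j], lines[i:j]))
        visits[(pid, int(month))] = _build_visit(
            pid, month, actual, rows, report, allow_out_of_range
        )
        i = j

    covariates = CovariateTable(covariates_df)
    return StudyDataset(visits=visits, covariates=covariates, report=report)


def read_study_tables(
    visits_path, covariates_path, allow_out_of_range: bool = False
) -> StudyDataset:
    """Read and validate the long-format visits CSV and wide covariates CSV."""
    try:
        # keep_default_na so the literal state "NA" survives parsing
        visits_df = pd.read_csv(
            visits_path, dtype={"participant_id": str},
            keep_default_na=False, na_values=[""],
            float_precision="round_trip",
        )
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas message varies
        raise ParseError(f"malformed visits file: {exc}") from exc
    covariates_df = pd.read_csv(covariates_path, dtype={"participant_id": str})
    return dataset_from_frames(visits_df, covariates_df, allow_out_of_range)


def write_study_tables(ds: StudyDataset, visits_path, covariates_path) -> None:
    """Write a dataset back to the two-CSV external format (round-trip safe)."""
    rows = []
    for (pid, month) in sorted(ds.visits):
        v = ds.visits[(pid, month)]
        for code, state, value in v.iter_records():
            rows.append((pid, month, v.actual_month, code, state, value))
    pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "scheduled_month",
            "actual_month",
            "item_code",
            "state",
            "value",
        ],
    ).to_csv(visits_path, index=False)
    cov = ds.covariates.frame.reset_index(drop=True)
    cov.to_csv(covariates_path, index=False)


def actual_month_from_days(days: float) -> float:
    """Convert days from enrollment to months (mean-month convention)."""
    return days / 30.4375


def validate_schedule(ds: StudyDataset) -> ValidationReport:
    """Report missing scheduled visits and off-schedule item recordings.

    Informational only: a participant seen at {0, 12, 24} has the interim
    visits in between listed as missing; an annual-only measure recorded at
    an interim visit is flagged.  Nothing here is fatal.
    """
    report = ValidationReport()
    for pid in ds.participants:
        months = ds.participant_months(pid)
        if not months:
            continue
        last = months[-1]
        expected = [m for m in VISIT_GRID if m <= last]
        missed = sorted(set(expected) - set(months))
        if missed:
            report.missing_visits[pid] = missed
        for m in months:
            visit = ds.visits[(pid, m)]
            codes = set(visit.items)
            codes |= set(visit.motor_state_items)
            codes |= {f"BP_{a}_{b}" for a, b in visit.bp}
            codes |= set(visit.cognitive_scores)
            codes |= {_FLAG_CODES[k] for k, v in visit.investigator_flags.items()
                      if v is not None}
            for code in sorted(codes):
                spec = ITEM_TABLE.get(code)
                if spec is None:
                    continue
                if m not in SCHEDULE_MONTHS[spec.schedule]:
                    report.off_schedule_items.append([pid, m, code])
    return report
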