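"""Composite time-to-first-event endpoint derivation and tabulation.

Two data-source modes are supported: ``annual`` scans only the annual
follow-up visits (12, 24, 36, 48, 60 months); ``all`` additionally scans the
interim visits (3, 6, 9, 18, 30, 42, 54 months) with milestone evaluation
restricted to each milestone's collection schedule.  In both modes
participants who never reach a milestone are censored at their last
completed annual visit.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .items import ANNUAL_MONTHS, INTERIM_MONTHS
from .milestone_engine import MilestoneRegistry, evaluate_visit
from .study_data import StudyDataset

SOURCE_MODES = ("annual", "all")

EXCLUSION_NONE = "none"
EXCLUSION_BASELINE = "baseline_milestone"
EXCLUSION_NO_FOLLOWUP = "no_followup"
EXCLUSION_NO_BASELINE = "no_baseline"


@dataclass
class EndpointRecord:
    """Per-participant composite-endpoint outcome."""

    participant_id: str
    included: bool
    exclusion_reason: str = EXCLUSION_NONE
    event: Optional[int] = None
    time_months: Optional[float] = None
    first_event_milestones: set = field(default_factory=set)
    first_event_domains: set = field(default_factory=set)
    source_mode: str = "annual"
    # censoring fell back to an interim visit because no annual visit exists
    censor_deviation: bool = False

    def __post_init__(self):
        if self.event == 1 and not self.first_event_milestones:
            raise ValueError("event=1 requires a nonempty first-event milestone set")


def _scanned_months(source_mode: str) -> list:
    if source_mode == "annual":
        return sorted(ANNUAL_MONTHS)
    if source_mode == "all":
        return sorted(ANNUAL_MONTHS + INTERIM_MONTHS)
    raise ValueError(f"source_mode must be one of {SOURCE_MODES}")


def _completed(ds: StudyDataset, pid: str, month: int) -> bool:
    v = ds.visit(pid, month)
    return v is not None and v.n_recorded >= 1


def derive_endpoint(
    ds: StudyDataset,
    registry: MilestoneRegistry,
    source_mode: str = "annual",
    missing_baseline: str = "exclude",
) -> list:
    """Derive one :class:`EndpointRecord` per enrolled participant.

    Baseline is evaluated with every milestone (schedule-unrestricted) for
    the exclusion rule.  Event time is the ``actual_month`` of the first
    scanned visit with at least one hit; censoring time is the last
    completed annual visit (falling back to the last interim visit, with a
    deviation flag, when no annual visit was completed).
    """
    if missing_baseline not in ("exclude", "error"):
        raise ValueError("missing_baseline must be 'exclude' or 'error'")
    months = _scanned_months(source_mode)
    records = []
    for pid in ds.participants:
        baseline = ds.visit(pid, 0)
        if baseline is None:
            if missing_baseline == "error":
                raise ValueError(f"participant {pid} has no baseline visit")
            records.append(
                EndpointRecord(pid, False, EXCLUSION_NO_BASELINE, source_mode=source_mode)
            )
            continue
        if evaluate_visit(registry, baseline, restrict_to_schedule=False).hits:
            records.append(
                EndpointRecord(pid, False, EXCLUSION_BASELINE, source_mode=source_mode)
            )
            continue

        scanned = [m for m in months if _completed(ds, pid, m)]
        if not scanned:
            records.append(
                EndpointRecord(
                    pid, False, EXCLUSION_NO_FOLLOWUP, source_mode=source_mode
                )
            )
            continue

        event_visit = None
        hitset = None
        for m in scanned:
            hs = evaluate_visit(registry, ds.visit(pid, m), restrict_to_schedule=True)
            if hs.hits:
                event_visit, hitset = m, hs
                break

        if event_visit is not None:
            records.append(
                EndpointRecord(
                    pid,
                    True,
                    EXCLUSION_NONE,
                    event=1,
                    time_months=float(ds.visit(pid, event_visit).actual_month),
                    first_event_milestones=set(hitset.hits),
                    first_event_domains=set(hitset.domains_hit),
                    source_mode=source_mode,
                )
            )
            continue

        annual_completed = [m for m in ANNUAL_MONTHS if _completed(ds, pid, m)]
        if annual_completed:
            censor_month, deviation = annual_completed[-1], False
        else:
            censor_month, deviation = scanned[-1], True
        records.append(
            EndpointRecord(
                pid,
                True,
                EXCLUSION_NONE,
                event=0,
                time_months=float(ds.visit(pid, censor_month).actual_month),
                source_mode=source_mode,
                censor_deviation=deviation,
            )
        )
    return records


@dataclass
class FirstEventTable:
    """Counts of participants whose first event included each milestone/domain."""

    n_included: int
    n_events: int
    milestone_counts: Counter
    domain_counts: Counter
    multi_domain: Counter  # number of domains spanned -> participant count
    source_mode: str

    def milestone_percent(self, milestone_id: str) -> float:
        return 100.0 * self.milestone_counts.get(milestone_id, 0) / self.n_included

    def domain_percent(self, domain: str) -> float:
        return 100.0 * self.domain_counts.get(domain, 0) / self.n_included

    def to_frame(self, registry: MilestoneRegistry) -> pd.DataFrame:
        rows = [
            {
                "level": "overall",
                "name": "any_milestone",
                "count": self.n_events,
                "percent": 100.0 * self.n_events / self.n_included
                if self.n_included
                else 0.0,
            }
        ]
        for domain in sorted({d.domain for d in registry}):
            rows.append(
                {
                    "level": "domain",
                    "name": domain,
                    "count": self.domain_counts.get(domain, 0),
                    "percent": self.domain_percent(domain) if self.n_included else 0.0,
                }
            )
        for m in registry.milestone_ids:
            rows.append(
                {
                    "level": "milestone",
                    "name": m,
                    "count": self.milestone_counts.get(m, 0),
                    "percent": self.milestone_percent(m) if self.n_included else 0.0,
                }
            )
        return pd.DataFrame(rows)


def tabulate_first_events(
    records: Iterable[EndpointRecord], registry: MilestoneRegistry
) -> FirstEventTable:
    """Tabulate first-event milestone/domain contributions (participants, not
    milestone instances) plus the multi-domain breakdown."""
    records = list(records)
    modes = {r.source_mode for r in records}
    if len(modes) > 1:
        raise ValueError(f"records mix source modes: {sorted(modes)}")
    included = [r for r in records if r.included]
    events = [r for r in included if r.event == 1]
    milestone_counts: Counter = Counter()
    domain_counts: Counter = Counter()
    multi: Counter = Counter()
    for r in events:
        for m in r.first_event_milestones:
            milestone_counts[m] += 1
        for d in r.first_event_domains:
            domain_counts[d] += 1
        multi[len(r.first_event_domains)] += 1
    return FirstEventTable(
        n_included=len(included),
        n_events=len(events),
        milestone_counts=milestone_counts,
        domain_counts=domain_counts,
        multi_domain=multi,
        source_mode=modes.pop() if modes else "annual",
    )


def tabulate_ever_reached(
    ds: StudyDataset, registry: MilestoneRegistry, source_mode: str = "annual"
) -> dict:
    """Count included participants who ever hit each milestone/domain at any
    scanned visit, regardless of event order."""
    records = derive_endpoint(ds, registry, source_mode)
    included = {r.participant_id for r in records if r.included}
    months = _scanned_months(source_mode)
    milestone_counts: Counter = Counter()
    domain_counts: Counter = Counter()
    for pid in included:
        ever_m: set = set()
        for m in months:
            if not _completed(ds, pid, m):
                continue
            ever_m |= evaluate_visit(
                registry, ds.visit(pid, m), restrict_to_schedule=True
            ).hits
        for mi in ever_m:
            milestone_counts[mi] += 1
        for d in registry.domains_of(ever_m):
            domain_counts[d] += 1
    return {
        "n_included": len(included),
        "milestone_counts": milestone_counts,
        "domain_counts": domain_counts,
        "source_mode": source_mode,
    }


def records_to_frame(records: Iterable[EndpointRecord]) -> pd.DataFrame:
    """Endpoint records as the external CSV layout."""
    rows = []
    for r in records:
        rows.append(
            {
                "participant_id": r.participant_id,
                "included": int(r.included),
                "exclusion_reason": r.exclusion_reason,
                "event": r.event if r.event is not None else "",
                "time_months": r.time_months if r.time_months is not None else "",
                "first_event_milestones": ";".join(sorted(r.first_event_milestones)),
                "first_event_domains": ";".join(sorted(r.first_event_domains)),
                "source_mode": r.source_mode,
                "censor_deviation": int(r.censor_deviation),
            }
        )
    return pd.DataFrame(rows)


def records_from_frame(df: pd.DataFrame) -> list:
    """Inverse of :func:`records_to_frame`."""
    out = []
    for row in df.itertuples(index=False):
        included = bool(int(row.included))
        event = None
        time_months = None
        if included:
            event = int(row.event)
            time_months = float(row.time_months)
        out.append(
            EndpointRecord(
                participant_id=str(row.participant_id),
                included=included,
                exclusion_reason=row.exclusion_reason,
                event=event,
                time_months=time_months,
                first_event_milestones=set(
                    str(row.first_event_milestones).split(";")
                )
                if isinstance(row.first_event_milestones, str)
                and row.first_event_milestones
                else set(),
                first_event_domains=set(str(row.first_event_domains).split(";"))
                if isinstance(row.first_event_domains, str)
                and row.first_event_domains
                else set(),
                source_mode=row.source_mode,
                censor_deviation=bool(int(row.censor_deviation)),
            )
        )
    return out
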