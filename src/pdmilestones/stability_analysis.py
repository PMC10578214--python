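"""Milestone stability: persistent vs. temporary vs. permanent reverters.

Event participants are scanned for any-milestone status at each subsequent
annual visit.  A participant who still meets any milestone at the next
annual visit is *persistent*; one who misses at the next visit but meets
again later is a *temporary reverter*; one who never meets again is a
*permanent reverter*.  Participants without a subsequent annual visit are
set aside.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd
from scipy import stats

from .items import ANNUAL_MONTHS
from .milestone_engine import MilestoneRegistry, evaluate_visit
from .study_data import StudyDataset

PERSISTENT = "persistent"
TEMPORARY = "temporary_reverter"
PERMANENT = "permanent_reverter"
NO_FOLLOWUP = "no_subsequent_annual_visit"


@dataclass
class ReverterRecord:
    participant_id: str
    category: str
    reversion_gap_years: Optional[float] = None  # temporary reverters only
    n_subsequent_annual_visits: int = 0
    le2_additional_followups: bool = False


def _event_month(record) -> int:
    # events occur at grid visits; actual_month defaults to scheduled_month
    return int(round(record.time_months))


def classify_reverters(
    ds: StudyDataset,
    registry: MilestoneRegistry,
    records: Iterable,
    restrict_to_schedule: bool = True,
) -> list:
    """Classify each (annual-mode) event participant by any-milestone status
    at subsequent completed annual visits."""
    out = []
    for r in records:
        if not r.included or r.event != 1:
            continue
        if r.source_mode != "annual":
            raise ValueError("reverter classification expects annual-mode records")
        pid = r.participant_id
        event_month = _event_month(r)
        later = [
            m
            for m in ANNUAL_MONTHS
            if m > event_month
            and ds.visit(pid, m) is not None
            and ds.visit(pid, m).n_recorded >= 1
        ]
        if not later:
            out.append(ReverterRecord(pid, NO_FOLLOWUP))
            continue
        status = [
            bool(
                evaluate_visit(
                    registry, ds.visit(pid, m), restrict_to_schedule
                ).hits
            )
            for m in later
        ]
        n_later = len(later)
        if status[0]:
            category, gap = PERSISTENT, None
        elif any(status):
            first_recur = later[status.index(True)]
            category, gap = TEMPORARY, (first_recur - event_month) / 12.0
        else:
            category, gap = PERMANENT, None
        out.append(
            ReverterRecord(
                pid,
                category,
                reversion_gap_years=gap,
                n_subsequent_annual_visits=n_later,
                le2_additional_followups=n_later <= 2,
            )
        )
    return out


def reverter_summary(reverters: Iterable[ReverterRecord]) -> dict:
    """Counts per category plus the reversion-gap distribution (years)."""
    reverters = list(reverters)
    counts = Counter(r.category for r in reverters)
    gaps = Counter(
        r.reversion_gap_years for r in reverters if r.category == TEMPORARY
    )
    with_followup = [r for r in reverters if r.category != NO_FOLLOWUP]
    n_active = len(with_followup)
    ever_again = counts[PERSISTENT] + counts[TEMPORARY]
    return {
        "counts": dict(counts),
        "n_with_followup": n_active,
        "prop_ever_again": ever_again / n_active if n_active else float("nan"),
        "reversion_gaps": dict(gaps),
    }


def domain_persistence(
    ds: StudyDataset,
    registry: MilestoneRegistry,
    records: Iterable,
    restrict_to_schedule: bool = True,
) -> pd.DataFrame:
    """Per first-event domain: proportion meeting criteria within the same
    domain at the next annual visit, within any domain at the next visit,
    and within any domain at any subsequent annual visit."""
    agg: dict = {}
    for r in records:
        if not r.included or r.event != 1:
            continue
        pid = r.participant_id
        event_month = _event_month(r)
        later = [
            m
            for m in ANNUAL_MONTHS
            if m > event_month
            and ds.visit(pid, m) is not None
            and ds.visit(pid, m).n_recorded >= 1
        ]
        if not later:
            continue
        hitsets = [
            evaluate_visit(registry, ds.visit(pid, m), restrict_to_schedule)
            for m in later
        ]
        next_domains = hitsets[0].domains_hit
        any_next = bool(hitsets[0].hits)
        any_ever = any(bool(h.hits) for h in hitsets)
        for domain in r.first_event_domains:
            d = agg.setdefault(
                domain, {"n": 0, "same_next": 0, "any_next": 0, "any_ever": 0}
            )
            d["n"] += 1
            d["same_next"] += int(domain in next_domains)
            d["any_next"] += int(any_next)
            d["any_ever"] += int(any_ever)
    rows = []
    for domain, d in sorted(agg.items()):
        rows.append(
            {
                "domain": domain,
                "n": d["n"],
                "same_domain_next": d["same_next"] / d["n"],
                "any_domain_next": d["any_next"] / d["n"],
                "any_domain_any_subsequent": d["any_ever"] / d["n"],
                "permanent_reversion": 1.0 - d["any_ever"] / d["n"],
            }
        )
    return pd.DataFrame(rows)


@dataclass
class Association2x2Result:
    counts: list
    chi2: float
    dof: int
    p_value: float
    correction: bool


def pearson_chi2_2x2(counts, correction: bool = False) -> Association2x2Result:
    """Pearson chi-square for a 2x2 table, df=1; continuity correction off by
    default."""
    import numpy as np

    table = np.asarray(counts)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        table = table.astype(float)
        if np.any(table < 0) or np.any(table != np.round(table)):
            raise ValueError("counts must be nonnegative integers")
        table = table.astype(int)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("every margin must be positive")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=correction)
    return Association2x2Result(
        counts=table.tolist(), chi2=float(chi2), dof=int(dof), p_value=float(p),
        correction=correction,
    )


def compare_reverter_followups(reverters: Iterable[ReverterRecord]) -> Association2x2Result:
    """Permanent vs temporary reverters, split by completing <=2 additional
    annual follow-ups."""
    perm = [r for r in reverters if r.category == PERMANENT]
    temp = [r for r in reverters if r.category == TEMPORARY]
    table = [
        [sum(r.le2_additional_followups for r in perm),
         sum(not r.le2_additional_followups for r in perm)],
        [sum(r.le2_additional_followups for r in temp),
         sum(not r.le2_additional_followups for r in temp)],
    ]
    return pearson_chi2_2x2(table, correction=False)
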