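"""Declarative registry of the 25 progression milestones and their evaluation.

Each milestone is a boolean criterion tree over atomic threshold tests on
item-level scores.  Evaluation is conservative under missing data: any
required score that is absent makes its atom false, so removing information
can never create a milestone hit.  Motor-exam atoms marked "ON or OFF" are
true if either state's score satisfies the threshold — a single available
state suffices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .items import (
    ITEM_TABLE,
    SCHEDULE_ANNUAL_ONLY,
    SCHEDULE_MONTHS,
    SCHEDULE_SIX_MONTH_THEN_ANNUAL,
    SCHEDULE_STANDARD,
)
from .study_data import VisitAssessment

DOMAINS = (
    "walking_balance",
    "motor_complications",
    "cognition",
    "autonomic",
    "functional_dependence",
    "adl",
)

#: Default z-score cutoff defining impairment on a single cognitive test.
DEFAULT_COGNITIVE_CUTOFF = -1.5


class ConfigurationError(ValueError):
    """Criterion references an unknown item code."""


_CMP = {
    ">=": lambda v, t: v >= t,
    "=": lambda v, t: v == t,
    "<": lambda v, t: v < t,
}


@dataclass(frozen=True)
class ItemAtom:
    """Threshold test on a single item; ``on_or_off`` atoms accept either
    medication state."""

    item_code: str
    comparator: str  # >= | = | <
    threshold: float
    on_or_off: bool = False

    def __post_init__(self):
        spec = ITEM_TABLE.get(self.item_code)
        if spec is None:
            raise ConfigurationError(f"unknown item code {self.item_code}")
        if not (spec.lo <= self.threshold <= spec.hi):
            raise ConfigurationError(
                f"threshold {self.threshold} outside range of {self.item_code}"
            )
        if self.on_or_off and spec.kind != "motor":
            raise ConfigurationError(f"{self.item_code} is not a per-state item")
        if self.comparator not in _CMP:
            raise ConfigurationError(f"unknown comparator {self.comparator}")

    def evaluate(self, visit: VisitAssessment) -> bool:
        cmp = _CMP[self.comparator]
        if self.on_or_off:
            states = visit.get_motor(self.item_code)
            return any(
                v is not None and cmp(v, self.threshold) for v in states.values()
            )
        v = visit.get_item(self.item_code)
        return v is not None and cmp(v, self.threshold)

    def to_dict(self) -> dict:
        return {
            "atom": "item",
            "item": self.item_code,
            "comparator": self.comparator,
            "threshold": self.threshold,
            "on_or_off": self.on_or_off,
        }


@dataclass(frozen=True)
class BPDropAtom:
    """Positional blood-pressure drop of at least ``min_drop`` mm Hg."""

    measure: str  # SYS | DIA
    from_position: str
    to_position: str
    min_drop: float

    def evaluate(self, visit: VisitAssessment) -> bool:
        a = visit.get_bp(self.measure, self.from_position)
        b = visit.get_bp(self.measure, self.to_position)
        if a is None or b is None:
            return False
        return (a - b) >= self.min_drop

    def to_dict(self) -> dict:
        return {
            "atom": "bp_drop",
            "measure": self.measure,
            "from": self.from_position,
            "to": self.to_position,
            "min_drop": self.min_drop,
        }


@dataclass(frozen=True)
class CognitiveImpairmentAtom:
    """Impairment (>=1 test z-score at or below the cutoff) on at least
    ``min_domains`` of the four cognitive-battery domains."""

    min_domains: int = 2
    cutoff: float = DEFAULT_COGNITIVE_CUTOFF

    def evaluate(self, visit: VisitAssessment) -> bool:
        impaired = sum(
            any(z <= self.cutoff for z in scores)
            for scores in visit.cognitive_domain_scores.values()
        )
        return impaired >= self.min_domains

    def to_dict(self) -> dict:
        return {
            "atom": "cognitive_impairment",
            "min_domains": self.min_domains,
            "cutoff": self.cutoff,
        }


@dataclass(frozen=True)
class FlagAtom:
    """Investigator yes/no determination; missing counts as no."""

    flag: str  # pdd_diagnosis | functional_impairment_cognitive

    def evaluate(self, visit: VisitAssessment) -> bool:
        return visit.get_flag(self.flag) is True

    def to_dict(self) -> dict:
        return {"atom": "flag", "flag": self.flag}


@dataclass(frozen=True)
class All:
    children: tuple

    def evaluate(self, visit: VisitAssessment) -> bool:
        return all(c.evaluate(visit) for c in self.children)

    def to_dict(self) -> dict:
        return {"all": [c.to_dict() for c in self.children]}


@dataclass(frozen=True)
class Any_:
    children: tuple

    def evaluate(self, visit: VisitAssessment) -> bool:
        return any(c.evaluate(visit) for c in self.children)

    def to_dict(self) -> dict:
        return {"any": [c.to_dict() for c in self.children]}


@dataclass(frozen=True)
class MilestoneDefinition:
    milestone_id: str
    domain: str
    criterion: object
    schedule_class: str = SCHEDULE_STANDARD

    def assessable_at(self, month: int) -> bool:
        return month in SCHEDULE_MONTHS[self.schedule_class]

    def evaluate(self, visit: VisitAssessment) -> bool:
        return self.criterion.evaluate(visit)

    def to_dict(self) -> dict:
        return {
            "milestone_id": self.milestone_id,
            "domain": self.domain,
            "schedule_class": self.schedule_class,
            "criterion": self.criterion.to_dict(),
        }


class MilestoneRegistry:
    """Immutable mapping of milestone_id -> MilestoneDefinition."""

    def __init__(self, definitions):
        self._defs = {d.milestone_id: d for d in definitions}

    def __len__(self):
        return len(self._defs)

    def __iter__(self):
        return iter(self._defs.values())

    def __getitem__(self, milestone_id: str) -> MilestoneDefinition:
        return self._defs[milestone_id]

    def __contains__(self, milestone_id: str) -> bool:
        return milestone_id in self._defs

    @property
    def milestone_ids(self) -> list:
        return list(self._defs)

    @property
    def domains(self) -> set:
        return {d.domain for d in self}

    def domain_of(self, milestone_id: str) -> str:
        return self._defs[milestone_id].domain

    def domains_of(self, milestone_ids) -> set:
        return {self._defs[m].domain for m in milestone_ids}

    def assessable_at(self, month: int) -> list:
        return [d.milestone_id for d in self if d.assessable_at(month)]

    # -- serialization ----------------------------------------------------
    def to_yaml(self) -> str:
        return yaml.safe_dump(
            [d.to_dict() for d in self], sort_keys=False, allow_unicode=True
        )

    @classmethod
    def from_yaml(cls, text: str) -> "MilestoneRegistry":
        defs = [
            MilestoneDefinition(
                milestone_id=d["milestone_id"],
                domain=d["domain"],
                schedule_class=d["schedule_class"],
                criterion=_criterion_from_dict(d["criterion"]),
            )
            for d in yaml.safe_load(text)
        ]
        return cls(defs)


def _criterion_from_dict(d: dict):
    if "all" in d:
        return All(tuple(_criterion_from_dict(c) for c in d["all"]))
    if "any" in d:
        return Any_(tuple(_criterion_from_dict(c) for c in d["any"]))
    kind = d["atom"]
    if kind == "item":
        return ItemAtom(d["item"], d["comparator"], d["threshold"], d["on_or_off"])
    if kind == "bp_drop":
        return BPDropAtom(d["measure"], d["from"], d["to"], d["min_drop"])
    if kind == "cognitive_impairment":
        return CognitiveImpairmentAtom(d["min_domains"], d["cutoff"])
    if kind == "flag":
        return FlagAtom(d["flag"])
    raise ConfigurationError(f"unknown atom kind {kind}")


def build_registry(
    cognitive_cutoff: float = DEFAULT_COGNITIVE_CUTOFF,
) -> MilestoneRegistry:
    """Construct the 25-milestone registry.

    ``cognitive_cutoff`` sets the z-score at or below which a single
    cognitive test counts as impaired for the composite dementia criterion.
    """

    def ge(code, t=3, on_or_off=False):
        return ItemAtom(code, ">=", t, on_or_off)

    defs = [
        # -- Domain 1: walking and balance --------------------------------
        MilestoneDefinition("walking_balance", "walking_balance", ge("UPDRS_2_12")),
        MilestoneDefinition("freezing", "walking_balance", ge("UPDRS_2_13")),
        MilestoneDefinition(
            "gait", "walking_balance", ge("UPDRS_3_10", on_or_off=True)
        ),
        MilestoneDefinition(
            "freezing_of_gait",
            "walking_balance",
            ItemAtom("UPDRS_3_11", "=", 4, on_or_off=True),
        ),
        MilestoneDefinition(
            "postural_instability",
            "walking_balance",
            ge("UPDRS_3_12", on_or_off=True),
        ),
        MilestoneDefinition(
            "hoehn_yahr", "walking_balance", ge("HY", 4, on_or_off=True)
        ),
        # -- Domain 2: motor complications ---------------------------------
        MilestoneDefinition(
            "dyskinesias",
            "motor_complications",
            All((ge("UPDRS_4_1"), ge("UPDRS_4_2"))),
        ),
        MilestoneDefinition(
            "fluctuations_functional", "motor_complications", ge("UPDRS_4_4")
        ),
        MilestoneDefinition(
            "fluctuations_complexity", "motor_complications", ge("UPDRS_4_5")
        ),
        # -- Domain 3: cognition -------------------------------------------
        MilestoneDefinition(
            "cognitive_impairment_moca",
            "cognition",
            ItemAtom("MOCA_TOTAL", "<", 21),
            schedule_class=SCHEDULE_ANNUAL_ONLY,
        ),
        MilestoneDefinition("cognitive_impairment_updrs", "cognition", ge("UPDRS_1_1")),
        MilestoneDefinition("hallucinations", "cognition", ge("UPDRS_1_2")),
        MilestoneDefinition("apathy", "cognition", ge("UPDRS_1_5")),
        MilestoneDefinition(
            "dementia_clinical",
            "cognition",
            FlagAtom("pdd_diagnosis"),
            schedule_class=SCHEDULE_ANNUAL_ONLY,
        ),
        MilestoneDefinition(
            "dementia_composite",
            "cognition",
            All(
                (
                    CognitiveImpairmentAtom(min_domains=2, cutoff=cognitive_cutoff),
                    FlagAtom("functional_impairment_cognitive"),
                )
            ),
            schedule_class=SCHEDULE_ANNUAL_ONLY,
        ),
        # -- Domain 4: autonomic dysfunction -------------------------------
        MilestoneDefinition(
            "urinary_incontinence",
            "autonomic",
            All(
                (
                    ge("UPDRS_1_10"),
                    Any_((ge("SCOPA_8", 2), ge("SCOPA_9", 2))),
                )
            ),
            schedule_class=SCHEDULE_SIX_MONTH_THEN_ANNUAL,
        ),
        MilestoneDefinition(
            "orthostatic_hypotension",
            "autonomic",
            All(
                (
                    ge("SCOPA_15", 2),
                    BPDropAtom("SYS", "SITTING", "STANDING", 20),
                    BPDropAtom("DIA", "SITTING", "STANDING", 10),
                )
            ),
            schedule_class=SCHEDULE_SIX_MONTH_THEN_ANNUAL,
        ),
        MilestoneDefinition(
            "syncope_updrs", "autonomic", ItemAtom("UPDRS_1_12", "=", 4)
        ),
        MilestoneDefinition(
            "syncope_scopa",
            "autonomic",
            ge("SCOPA_16", 1),
            schedule_class=SCHEDULE_SIX_MONTH_THEN_ANNUAL,
        ),
        # -- Domain 5: functional dependence -------------------------------
        MilestoneDefinition(
            "schwab_england", "functional_dependence", ItemAtom("SE_ADL", "<", 80)
        ),
        # -- Domain 6: activities of daily living --------------------------
        MilestoneDefinition("choking", "adl", ge("UPDRS_2_3")),
        MilestoneDefinition("eating", "adl", ge("UPDRS_2_4")),
        MilestoneDefinition("dressing", "adl", ge("UPDRS_2_5")),
        MilestoneDefinition("hygiene", "adl", ge("UPDRS_2_6")),
        MilestoneDefinition("speech", "adl", ge("UPDRS_3_1", on_or_off=True)),
    ]
    return MilestoneRegistry(defs)


@dataclass
class MilestoneHitSet:
    """Milestones met at one visit, with derived domain set."""

    participant_id: str
    scheduled_month: int
    hits: set = field(default_factory=set)
    domains_hit: set = field(default_factory=set)

    def __bool__(self) -> bool:
        return bool(self.hits)


def evaluate_visit(
    registry: MilestoneRegistry,
    visit: VisitAssessment,
    restrict_to_schedule: bool = True,
) -> MilestoneHitSet:
    """Evaluate every milestone assessable at this visit.

    With ``restrict_to_schedule`` false, all 25 milestones are evaluated
    regardless of the visit month (used for baseline exclusion).
    """
    hits = set()
    for definition in registry:
        if restrict_to_schedule and not definition.assessable_at(
            visit.scheduled_month
        ):
            continue
        if definition.evaluate(visit):
            hits.add(definition.milestone_id)
    return MilestoneHitSet(
        participant_id=visit.participant_id,
        scheduled_month=visit.scheduled_month,
        hits=hits,
        domains_hit=registry.domains_of(hits),
    )
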