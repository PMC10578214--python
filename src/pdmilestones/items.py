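"""Published item-code table: instrument codes, score ranges, and visit schedules.

Every score that enters milestone classification is addressed by a namespaced
string code (``UPDRS_2_12``, ``SCOPA_8``, ``MOCA_TOTAL``, ...).  The table
records, for each code, the documented instrument range, whether the item is
scored separately in the medication OFF and ON states, and the visit-schedule
class on which it is collected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

#: Per-protocol visit grid, months from enrollment.
VISIT_GRID: tuple[int, ...] = (0, 3, 6, 9, 12, 18, 24, 30, 36, 42, 48, 54, 60)

#: Annual follow-up visits (the "annual visits" data source).
ANNUAL_MONTHS: tuple[int, ...] = (12, 24, 36, 48, 60)

#: Interim visits added by the "all visits" data source.
INTERIM_MONTHS: tuple[int, ...] = (3, 6, 9, 18, 30, 42, 54)

# Schedule classes.  "standard" measures are collected quarterly in year one
# and semiannually thereafter; "six_month_then_annual" at month 6 and then
# annually; "annual_only" at annual visits only.  Baseline is included in all
# three (baseline collection exists for every instrument).
SCHEDULE_STANDARD = "standard"
SCHEDULE_SIX_MONTH_THEN_ANNUAL = "six_month_then_annual"
SCHEDULE_ANNUAL_ONLY = "annual_only"

SCHEDULE_MONTHS: dict[str, frozenset[int]] = {
    SCHEDULE_STANDARD: frozenset(VISIT_GRID),
    SCHEDULE_SIX_MONTH_THEN_ANNUAL: frozenset((0, 6) + ANNUAL_MONTHS),
    SCHEDULE_ANNUAL_ONLY: frozenset((0,) + ANNUAL_MONTHS),
}

#: Valid motor-exam states in the visits file.
STATES = ("OFF", "ON", "NA")

#: Blood-pressure positions and measures.
BP_POSITIONS = ("SUPINE", "SITTING", "STANDING")
BP_MEASURES = ("SYS", "DIA")


@dataclass(frozen=True)
class ItemSpec:
    """Range and collection metadata for one item code."""

    code: str
    lo: float
    hi: float
    kind: str  # item | motor | bp | cognitive | flag
    schedule: str = SCHEDULE_STANDARD
    step: Optional[float] = None  # granularity, e.g. 5 for Schwab & England

    def in_range(self, value: float) -> bool:
        if not (self.lo <= value <= self.hi):
            return False
        if self.step is not None and (value / self.step) % 1 != 0:
            return False
        return True


def _updrs(code: str) -> ItemSpec:
    return ItemSpec(code, 0, 4, "item")


def _updrs_motor(code: str) -> ItemSpec:
    return ItemSpec(code, 0, 4, "motor")


#: Cognitive battery tests and the domain each belongs to.  Scores are
#: standardized z-scores per published norms, so no hard range applies.
COGNITIVE_TESTS: dict[str, str] = {
    "COG_HVLT_RECALL": "memory",
    "COG_HVLT_RECOG": "memory",
    "COG_JOLO": "visuospatial",
    "COG_SDMT": "processing_speed",
    "COG_LNS": "executive",
    "COG_FLUENCY": "executive",
}

COGNITIVE_DOMAINS: tuple[str, ...] = (
    "memory",
    "visuospatial",
    "processing_speed",
    "executive",
)

_SPECS: list[ItemSpec] = [
    # MDS-UPDRS Part I (non-motor experiences of daily living)
    _updrs("UPDRS_1_1"),
    _updrs("UPDRS_1_2"),
    _updrs("UPDRS_1_5"),
    _updrs("UPDRS_1_10"),
    _updrs("UPDRS_1_12"),
    # Part II (motor experiences of daily living)
    _updrs("UPDRS_2_3"),
    _updrs("UPDRS_2_4"),
    _updrs("UPDRS_2_5"),
    _updrs("UPDRS_2_6"),
    _updrs("UPDRS_2_12"),
    _updrs("UPDRS_2_13"),
    # Part III (motor examination; scored per medication state)
    _updrs_motor("UPDRS_3_1"),
    _updrs_motor("UPDRS_3_10"),
    _updrs_motor("UPDRS_3_11"),
    _updrs_motor("UPDRS_3_12"),
    # Part IV (motor complications)
    _updrs("UPDRS_4_1"),
    _updrs("UPDRS_4_2"),
    _updrs("UPDRS_4_4"),
    _updrs("UPDRS_4_5"),
    # Stage / global scales
    ItemSpec("HY", 0, 5, "motor"),
    ItemSpec("SE_ADL", 0, 100, "item", step=5),
    ItemSpec("MOCA_TOTAL", 0, 30, "item", schedule=SCHEDULE_ANNUAL_ONLY),
    # SCOPA-AUT autonomic items
    ItemSpec("SCOPA_8", 0, 3, "item", schedule=SCHEDULE_SIX_MONTH_THEN_ANNUAL),
    ItemSpec("SCOPA_9", 0, 3, "item", schedule=SCHEDULE_SIX_MONTH_THEN_ANNUAL),
    ItemSpec("SCOPA_15", 0, 3, "item", schedule=SCHEDULE_SIX_MONTH_THEN_ANNUAL),
    ItemSpec("SCOPA_16", 0, 3, "item", schedule=SCHEDULE_SIX_MONTH_THEN_ANNUAL),
    # Investigator cognitive-categorization flags (yes=1 / no=0)
    ItemSpec("FLAG_PDD", 0, 1, "flag", schedule=SCHEDULE_ANNUAL_ONLY, step=1),
    ItemSpec(
        "FLAG_COG_FUNC_IMPAIR", 0, 1, "flag", schedule=SCHEDULE_ANNUAL_ONLY, step=1
    ),
]

# Blood pressure readings, by measure and position.
for _pos in BP_POSITIONS:
    for _meas in BP_MEASURES:
        _SPECS.append(
            ItemSpec(
                f"BP_{_meas}_{_pos}",
                0,
                350,
                "bp",
                schedule=SCHEDULE_SIX_MONTH_THEN_ANNUAL,
            )
        )

# Cognitive battery z-scores (annual only).
for _code in COGNITIVE_TESTS:
    _SPECS.append(ItemSpec(_code, -10, 10, "cognitive", schedule=SCHEDULE_ANNUAL_ONLY))

ITEM_TABLE: dict[str, ItemSpec] = {s.code: s for s in _SPECS}

#: Columns of the wide baseline-covariate CSV.
COVARIATE_COLUMNS: tuple[str, ...] = (
    "participant_id",
    "age",
    "sex",  # 1 = male, 0 = female
    "site_nonus",  # 1 = non-US site
    "bmi",
    "orthostatic_sys_bp_change",  # supine -> standing, mm Hg
    "disease_duration",  # months from diagnosis
    "updrs_total",
    "hy_stage",
    "pigd_score",
    "tremor_score",
    "se_adl",
    "moca",
    "scopa_aut_total",
    "upsit_raw",
    "anosmia",
    "ess",
    "rbdsq",
    "gds15",
    "stai_total",
    "sbr_striatum",
    "sbr_putamen",
    "urate",
    "csf_asyn",
    "csf_hb",
    "csf_abeta",
    "csf_ttau",
    "csf_ptau",
    "csf_ttau_abeta_ratio",
    "ttau_abeta_gt_0222",
    "med_initiation_month",
)

#: Covariates that must be strictly positive when present.
POSITIVE_COVARIATES: tuple[str, ...] = (
    "bmi",
    "sbr_striatum",
    "sbr_putamen",
    "urate",
    "csf_asyn",
    "csf_hb",
    "csf_abeta",
    "csf_ttau",
    "csf_ptau",
    "csf_ttau_abeta_ratio",
)


def bp_code(measure: str, position: str) -> str:
    """Item code for a blood-pressure reading."""
    if measure not in BP_MEASURES or position not in BP_POSITIONS:
        raise KeyError(f"unknown BP reading {measure}/{position}")
    return f"BP_{measure}_{position}"
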