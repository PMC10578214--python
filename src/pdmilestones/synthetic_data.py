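"""Cohort simulator with exact milestone ground truth.

The generator is truth-first: it draws baseline covariates, a latent
progression time from a proportional-hazards model on the same reporting
scales the fitting workflow uses, assigns first-event milestones from a
mixture, snaps event times to the next scheduled visit of the milestone's
collection schedule, and only then back-fills item-level scores so that the
milestone engine reproduces the intended states exactly.  Medication
initiation, dropout, and item-level missingness are layered on top without
ever touching a score that certifies an active milestone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .endpoint_pipeline import EndpointRecord
from .items import (
    COVARIATE_COLUMNS,
    ITEM_TABLE,
    SCHEDULE_MONTHS,
    VISIT_GRID,
)
from .milestone_engine import (
    DEFAULT_COGNITIVE_CUTOFF,
    MilestoneRegistry,
    build_registry,
    evaluate_visit,
)
from .study_data import StudyDataset, dataset_from_frames
from .survival_models import default_covariate_specs, transform_covariates


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def default_milestone_weights() -> dict:
    """First-event milestone mixture (normalized); mass roughly follows the
    relative first-event frequencies the framework is designed around."""
    raw = {
        "cognitive_impairment_moca": 25,
        "dementia_composite": 13,
        "apathy": 11,
        "cognitive_impairment_updrs": 10,
        "dementia_clinical": 3,
        "hallucinations": 1,
        "schwab_england": 45,
        "urinary_incontinence": 20,
        "syncope_scopa": 20,
        "syncope_updrs": 2,
        "orthostatic_hypotension": 1,
        "postural_instability": 13,
        "walking_balance": 8,
        "gait": 7,
        "hoehn_yahr": 3,
        "freezing": 2,
        "freezing_of_gait": 1,
        "fluctuations_complexity": 10,
        "fluctuations_functional": 11,
        "dyskinesias": 0,
        "choking": 11,
        "speech": 5,
        "dressing": 1,
        "eating": 1,
        "hygiene": 0,
    }
    total = sum(raw.values())
    return {k: v / total for k, v in raw.items()}


def default_log_hazard_ratios() -> dict:
    """True effects on the reporting scales of the fitting workflow."""
    return {
        "age": math.log(1.25),  # per 5-year increase
        "updrs_total": math.log(1.18),  # per 5-unit increase
        "gds15": math.log(1.07),  # per point
        "sbr_striatum": math.log(1.07),  # per 0.1-unit decrease
        "csf_asyn": math.log(1.09),  # per decile decrease
    }


@dataclass
class SimulationConfig:
    n: int = 400
    seed: int = 0
    #: true log hazard ratios keyed by covariate name (reporting scales)
    log_hazard_ratios: dict = field(default_factory=default_log_hazard_ratios)
    #: constant per-month baseline hazard, or per-interval hazards on the
    #: visit grid (len(VISIT_GRID) - 1 values; last extends beyond 60)
    baseline_monthly_hazard: object = 0.0089
    milestone_weights: dict = field(default_factory=default_milestone_weights)
    #: probability the first event adds a second, concurrently-met milestone
    concurrent_milestone_prob: float = 0.15
    #: probability an active milestone is still met at each later visit of
    #: its collection schedule
    persistence_prob: float = 0.8
    baseline_milestone_frac: float = 0.05
    med_monthly_hazard: float = 0.03
    annual_dropout_prob: float = 0.04  # ~18% cumulative by year 5
    item_missing_prob: float = 0.02
    baseline_flag_missing_prob: float = 0.749
    cognitive_cutoff: float = DEFAULT_COGNITIVE_CUTOFF
    # baseline covariate distribution knobs
    age_mean: float = 61.5
    age_sd: float = 9.0
    male_prob: float = 0.65
    updrs_mean: float = 32.0
    updrs_sd: float = 12.0
    sbr_mean: float = 1.4
    sbr_sd: float = 0.4
    csf_asyn_log_mean: float = 7.2
    csf_asyn_log_sd: float = 0.35
    hb_contamination_frac: float = 0.05

    def __post_init__(self):
        if self.n < 1:
            raise ConfigError("n must be >= 1")
        total = sum(self.milestone_weights.values())
        if any(w < 0 for w in self.milestone_weights.values()):
            raise ConfigError("milestone weights must be nonnegative")
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-6):
            raise ConfigError(f"milestone weights must sum to 1 (got {total})")
        for p in (
            self.concurrent_milestone_prob,
            self.persistence_prob,
            self.baseline_milestone_frac,
            self.annual_dropout_prob,
            self.item_missing_prob,
            self.baseline_flag_missing_prob,
        ):
            if not 0 <= p <= 1:
                raise ConfigError(f"probability {p} outside [0, 1]")


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside a simulated dataset."""

    #: (participant_id, month) -> frozenset of active milestone ids, for
    #: every emitted visit
    states: dict
    #: participant_id -> snapped first-event month (None if never, or beyond
    #: follow-up horizon); baseline meeters have month 0
    first_event_month: dict
    #: participant_id -> milestone set at the first event
    first_event_milestones: dict
    #: true log hazard ratios used
    log_hazard_ratios: dict
    #: participant_id -> last scheduled month with an emitted visit
    last_visit_month: dict


# ---------------------------------------------------------------------------
# Covariates and latent survival
# ---------------------------------------------------------------------------


def _truncated_normal(rng, mean, sd, size, lo=-np.inf, hi=np.inf):
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out < lo) | (out > hi)
    return out


def draw_covariates(rng: np.random.Generator, config: SimulationConfig) -> pd.DataFrame:
    n = config.n
    age = _truncated_normal(rng, config.age_mean, config.age_sd, n, lo=30)
    sex = (rng.uniform(size=n) < config.male_prob).astype(int)
    updrs = _truncated_normal(rng, config.updrs_mean, config.updrs_sd, n, lo=5)
    sbr_striatum = _truncated_normal(rng, config.sbr_mean, config.sbr_sd, n, lo=0.3)
    sbr_putamen = np.maximum(
        0.1, 0.7 * sbr_striatum + rng.normal(0, 0.08, n)
    )
    csf_asyn = rng.lognormal(config.csf_asyn_log_mean, config.csf_asyn_log_sd, n)
    csf_hb = rng.lognormal(3.4, 1.0, n)
    contaminated = rng.uniform(size=n) < config.hb_contamination_frac
    csf_hb[contaminated] = 200.0 + rng.exponential(400.0, contaminated.sum())
    csf_abeta = rng.lognormal(6.7, 0.30, n)
    csf_ttau = rng.lognormal(5.2, 0.35, n)
    csf_ptau = rng.lognormal(2.8, 0.35, n)
    upsit = np.clip(np.round(rng.normal(22, 8, n)), 0, 40)
    frame = pd.DataFrame(
        {
            "participant_id": [f"P{i:05d}" for i in range(n)],
            "age": np.round(age, 1),
            "sex": sex,
            "site_nonus": (rng.uniform(size=n) < 0.35).astype(int),
            "bmi": np.round(_truncated_normal(rng, 27, 4.5, n, lo=15), 1),
            "orthostatic_sys_bp_change": np.round(rng.normal(2, 8, n), 1),
            "disease_duration": np.round(
                _truncated_normal(rng, 6.6, 6.0, n, lo=0.5), 1
            ),
            "updrs_total": np.round(updrs),
            "hy_stage": 1 + (rng.uniform(size=n) < 0.55).astype(int),
            "pigd_score": np.round(_truncated_normal(rng, 0.23, 0.2, n, lo=0), 2),
            "tremor_score": np.round(_truncated_normal(rng, 0.45, 0.3, n, lo=0), 2),
            "se_adl": np.clip(5 * np.round(rng.normal(92, 6, n) / 5), 80, 100),
            "moca": np.clip(np.round(rng.normal(27, 2.3, n)), 21, 30),
            "scopa_aut_total": np.round(_truncated_normal(rng, 9, 6, n, lo=0)),
            "upsit_raw": upsit,
            "anosmia": (upsit <= 18).astype(int),
            "ess": np.clip(np.round(rng.normal(5.8, 3.5, n)), 0, 24),
            "rbdsq": np.clip(np.round(rng.normal(4.1, 2.7, n)), 0, 13),
            "gds15": rng.negative_binomial(2, 2.0 / (2.0 + 2.3), n),
            "stai_total": np.clip(np.round(rng.normal(65, 18, n)), 40, 160),
            "sbr_striatum": np.round(sbr_striatum, 3),
            "sbr_putamen": np.round(sbr_putamen, 3),
            "urate": np.round(_truncated_normal(rng, 5.3, 1.3, n, lo=1), 2),
            "csf_asyn": np.round(csf_asyn, 1),
            "csf_hb": np.round(csf_hb, 1),
            "csf_abeta": np.round(csf_abeta, 1),
            "csf_ttau": np.round(csf_ttau, 1),
            "csf_ptau": np.round(csf_ptau, 2),
        }
    )
    frame["csf_ttau_abeta_ratio"] = np.round(
        frame["csf_ttau"] / frame["csf_abeta"], 4
    )
    frame["ttau_abeta_gt_0222"] = (frame["csf_ttau_abeta_ratio"] > 0.222).astype(int)
    frame["med_initiation_month"] = np.nan  # filled by the caller
    return frame[list(COVARIATE_COLUMNS)]


def linear_predictor(
    covariates: pd.DataFrame, log_hazard_ratios: dict
) -> np.ndarray:
    """Centered linear predictor on the fitting workflow's reporting scales."""
    specs = [s for s in default_covariate_specs() if s.name in log_hazard_ratios]
    missing = set(log_hazard_ratios) - {s.name for s in specs}
    if missing:
        raise ConfigError(f"no covariate spec for effect(s): {sorted(missing)}")
    X = transform_covariates(covariates, specs)
    lp = np.zeros(len(covariates))
    for name, beta in log_hazard_ratios.items():
        col = X[name].to_numpy(dtype=float)
        lp += beta * (col - np.nanmean(col))
    return lp


def _hazard_edges(config: SimulationConfig):
    h = config.baseline_monthly_hazard
    if np.isscalar(h):
        edges = np.array([0.0, 1e6])
        hazards = np.array([float(h)])
    else:
        hazards = np.asarray(h, dtype=float)
        if len(hazards) != len(VISIT_GRID) - 1:
            raise ConfigError(
                "piecewise baseline hazard needs one value per grid interval"
            )
        edges = np.concatenate([np.asarray(VISIT_GRID, dtype=float), [1e6]])
        hazards = np.concatenate([hazards, [hazards[-1]]])
    if np.any(hazards < 0):
        raise ConfigError("hazards must be nonnegative")
    return edges, hazards


def draw_latent_times(
    rng: np.random.Generator, lp: np.ndarray, config: SimulationConfig
) -> np.ndarray:
    """Latent progression times under the piecewise-constant baseline hazard
    and proportional hazards exp(lp)."""
    edges, hazards = _hazard_edges(config)
    cumhaz = np.concatenate([[0.0], np.cumsum(hazards * np.diff(edges))])
    target = rng.exponential(size=len(lp)) / np.exp(lp)
    return np.interp(target, cumhaz, edges)


# ---------------------------------------------------------------------------
# Item back-filling
# ---------------------------------------------------------------------------

_BENIGN_BP = {
    ("SYS", "SUPINE"): (125.0, 10.0),
    ("SYS", "SITTING"): (128.0, 10.0),
    ("DIA", "SUPINE"): (78.0, 8.0),
    ("DIA", "SITTING"): (80.0, 8.0),
}


def _benign_value(code: str, rng: np.random.Generator, size: int) -> np.ndarray:
    """Scores strictly below every milestone threshold."""
    spec = ITEM_TABLE[code]
    if code == "MOCA_TOTAL":
        return rng.integers(25, 31, size).astype(float)
    if code == "SE_ADL":
        return 5.0 * rng.integers(16, 21, size)  # 80..100
    if code == "SCOPA_16":
        return np.zeros(size)
    if code.startswith("SCOPA"):
        return rng.integers(0, 2, size).astype(float)
    if spec.kind == "cognitive":
        return np.maximum(rng.normal(0.0, 0.8, size), -1.4)
    if spec.kind == "flag":
        return np.zeros(size)
    if code == "HY":
        return rng.integers(0, 3, size).astype(float)
    # MDS-UPDRS items: thresholds are >=3 (or =4), so 0-2 is always benign
    return rng.integers(0, 3, size).astype(float)


def _satisfy_rows(milestone_id: str, rng: np.random.Generator, cutoff: float):
    """(code, state, value) rows certifying one milestone."""

    def hi(code, lo=3, hi_=5):
        return float(rng.integers(lo, hi_))

    rows = {
        "walking_balance": lambda: [("UPDRS_2_12", "NA", hi("UPDRS_2_12"))],
        "freezing": lambda: [("UPDRS_2_13", "NA", hi("UPDRS_2_13"))],
        "gait": lambda: [("UPDRS_3_10", "OFF", hi("UPDRS_3_10"))],
        "freezing_of_gait": lambda: [("UPDRS_3_11", "OFF", 4.0)],
        "postural_instability": lambda: [("UPDRS_3_12", "OFF", hi("UPDRS_3_12"))],
        "hoehn_yahr": lambda: [("HY", "OFF", float(rng.integers(4, 6)))],
        "dyskinesias": lambda: [
            ("UPDRS_4_1", "NA", hi("UPDRS_4_1")),
            ("UPDRS_4_2", "NA", hi("UPDRS_4_2")),
        ],
        "fluctuations_functional": lambda: [("UPDRS_4_4", "NA", hi("UPDRS_4_4"))],
        "fluctuations_complexity": lambda: [("UPDRS_4_5", "NA", hi("UPDRS_4_5"))],
        "cognitive_impairment_moca": lambda: [
            ("MOCA_TOTAL", "NA", float(rng.integers(0, 21)))
        ],
        "cognitive_impairment_updrs": lambda: [("UPDRS_1_1", "NA", hi("UPDRS_1_1"))],
        "hallucinations": lambda: [("UPDRS_1_2", "NA", hi("UPDRS_1_2"))],
        "apathy": lambda: [("UPDRS_1_5", "NA", hi("UPDRS_1_5"))],
        "dementia_clinical": lambda: [("FLAG_PDD", "NA", 1.0)],
        "dementia_composite": lambda: [
            ("COG_HVLT_RECALL", "NA", cutoff - float(rng.uniform(0.2, 1.5))),
            ("COG_SDMT", "NA", cutoff - float(rng.uniform(0.2, 1.5))),
            ("FLAG_COG_FUNC_IMPAIR", "NA", 1.0),
        ],
        "urinary_incontinence": lambda: [
            ("UPDRS_1_10", "NA", hi("UPDRS_1_10")),
            ("SCOPA_8", "NA", float(rng.integers(2, 4))),
        ],
        "orthostatic_hypotension": lambda: [
            ("SCOPA_15", "NA", float(rng.integers(2, 4))),
            ("BP_SYS_SITTING", "NA", round(float(rng.normal(140, 8)), 1)),
            ("BP_SYS_STANDING", "NA", None),  # filled below from the drop
            ("BP_DIA_SITTING", "NA", round(float(rng.normal(85, 6)), 1)),
            ("BP_DIA_STANDING", "NA", None),
        ],
        "syncope_updrs": lambda: [("UPDRS_1_12", "NA", 4.0)],
        "syncope_scopa": lambda: [("SCOPA_16", "NA", float(rng.integers(1, 4)))],
        "schwab_england": lambda: [("SE_ADL", "NA", 5.0 * float(rng.integers(0, 16)))],
        "choking": lambda: [("UPDRS_2_3", "NA", hi("UPDRS_2_3"))],
        "eating": lambda: [("UPDRS_2_4", "NA", hi("UPDRS_2_4"))],
        "dressing": lambda: [("UPDRS_2_5", "NA", hi("UPDRS_2_5"))],
        "hygiene": lambda: [("UPDRS_2_6", "NA", hi("UPDRS_2_6"))],
        "speech": lambda: [("UPDRS_3_1", "OFF", hi("UPDRS_3_1"))],
    }[milestone_id]()
    if milestone_id == "orthostatic_hypotension":
        out = []
        sys_sit = dia_sit = None
        for code, state, value in rows:
            if code == "BP_SYS_SITTING":
                sys_sit = value
            if code == "BP_DIA_SITTING":
                dia_sit = value
            if code == "BP_SYS_STANDING":
                value = round(sys_sit - float(rng.uniform(20, 45)), 1)
            if code == "BP_DIA_STANDING":
                value = round(dia_sit - float(rng.uniform(10, 25)), 1)
            out.append((code, state, value))
        return out
    return rows


# ---------------------------------------------------------------------------
# Main generator
# ---------------------------------------------------------------------------


def _snap_to_schedule(t: float, schedule_class: str) -> Optional[int]:
    """Next scheduled visit (month > 0) of the class at or after time t."""
    for m in sorted(SCHEDULE_MONTHS[schedule_class]):
        if m > 0 and m >= t:
            return m
    return None


def simulate_cohort(config: SimulationConfig):
    """Generate a PPMI-like dataset with exact ground truth.

    Returns ``(StudyDataset, SimulationTruth)``.  Re-evaluating the emitted
    item scores through the milestone engine recovers the truth states
    exactly (missingness never deletes a score certifying an active
    milestone).
    """
    rng = np.random.default_rng(config.seed)
    registry = build_registry(config.cognitive_cutoff)
    n = config.n
    covariates = draw_covariates(rng, config)
    pids = covariates["participant_id"].tolist()
    lp = linear_predictor(covariates, config.log_hazard_ratios)

    latent_t = draw_latent_times(rng, lp, config)
    milestone_ids = list(config.milestone_weights)
    weights = np.array([config.milestone_weights[m] for m in milestone_ids])
    chosen = rng.choice(len(milestone_ids), size=n, p=weights)
    baseline_meeter = rng.uniform(size=n) < config.baseline_milestone_frac

    dropout_rate = -math.log(1.0 - config.annual_dropout_prob) / 12.0
    if dropout_rate > 0:
        dropout_t = rng.exponential(1.0 / dropout_rate, n)
    else:
        dropout_t = np.full(n, np.inf)
    med_t = rng.exponential(1.0 / config.med_monthly_hazard, n)
    med_col = np.where(med_t <= 60.0, np.round(med_t, 1), np.nan)
    covariates = covariates.copy()
    covariates["med_initiation_month"] = med_col

    states: dict = {}
    first_event_month: dict = {}
    first_event_milestones: dict = {}
    last_visit_month: dict = {}

    grid = list(VISIT_GRID)
    for i, pid in enumerate(pids):
        horizon = min(dropout_t[i], 60.0)
        attended = [m for m in grid if m <= horizon]
        if not attended:
            attended = [0]
        last_visit_month[pid] = attended[-1]
        active: dict[int, set] = {m: set() for m in attended}

        primary = milestone_ids[chosen[i]]
        sched = registry[primary].schedule_class
        if baseline_meeter[i]:
            event_month: Optional[int] = 0
        else:
            event_month = _snap_to_schedule(latent_t[i], sched)
        ms_set = {primary}
        if event_month is not None and rng.uniform() < config.concurrent_milestone_prob:
            compatible = [
                m
                for m in milestone_ids
                if m != primary
                and config.milestone_weights[m] > 0
                and (
                    event_month == 0
                    or event_month in SCHEDULE_MONTHS[registry[m].schedule_class]
                )
            ]
            if compatible:
                w2 = np.array([config.milestone_weights[m] for m in compatible])
                ms_set.add(compatible[rng.choice(len(compatible), p=w2 / w2.sum())])

        first_event_month[pid] = event_month
        first_event_milestones[pid] = ms_set if event_month is not None else set()
        if event_month is not None and event_month in active:
            active[event_month] |= ms_set
            later = [
                m
                for m in attended
                if m > event_month and m in SCHEDULE_MONTHS[sched]
            ]
            for m in later:
                if rng.uniform() < config.persistence_prob:
                    active[m].add(primary)
        states.update({(pid, m): frozenset(s) for m, s in active.items()})

    visits_df = _emit_visits(rng, config, registry, states, last_visit_month)
    ds = dataset_from_frames(visits_df, covariates)
    truth = SimulationTruth(
        states=states,
        first_event_month=first_event_month,
        first_event_milestones=first_event_milestones,
        log_hazard_ratios=dict(config.log_hazard_ratios),
        last_visit_month=last_visit_month,
    )
    return ds, truth


def _emit_visits(rng, config, registry, states, last_visit_month) -> pd.DataFrame:
    """Vectorized benign emission plus targeted overrides for active
    milestones; item-level missingness only ever deletes benign rows."""
    # benign block, month by month
    by_month: dict[int, list] = {}
    for pid, last in last_visit_month.items():
        for m in VISIT_GRID:
            if m <= last:
                by_month.setdefault(m, []).append(pid)
    cols = {k: [] for k in
            ("participant_id", "scheduled_month", "item_code", "state", "value")}

    def block(month, month_pids, code, state, values):
        cols["participant_id"].append(np.asarray(month_pids, dtype=object))
        cols["scheduled_month"].append(np.full(len(month_pids), month))
        cols["item_code"].append(np.full(len(month_pids), code, dtype=object))
        cols["state"].append(np.full(len(month_pids), state, dtype=object))
        cols["value"].append(np.asarray(values, dtype=float))

    for month, month_pids in sorted(by_month.items()):
        k = len(month_pids)
        sitting = {}
        for code, spec in ITEM_TABLE.items():
            if month not in SCHEDULE_MONTHS[spec.schedule]:
                continue
            if spec.kind == "motor":
                for state in ("OFF", "ON"):
                    block(month, month_pids, code, state,
                          _benign_value(code, rng, k))
            elif spec.kind == "bp":
                _, meas, pos = code.split("_")
                if pos == "STANDING":
                    continue  # tied to sitting, emitted below
                values = np.round(rng.normal(*_BENIGN_BP[(meas, pos)], size=k), 1)
                if pos == "SITTING":
                    sitting[meas] = values
                block(month, month_pids, code, "NA", values)
            else:
                block(month, month_pids, code, "NA",
                      _benign_value(code, rng, k))
        if sitting:
            # standing BP tied to sitting with a strictly sub-threshold drop
            for meas, drop_hi in (("SYS", 18.0), ("DIA", 8.0)):
                drop = rng.uniform(-5.0, drop_hi, k)
                block(month, month_pids, f"BP_{meas}_STANDING", "NA",
                      np.round(sitting[meas] - drop, 1))
    benign = pd.DataFrame({k: np.concatenate(v) for k, v in cols.items()})
    benign["scheduled_month"] = benign["scheduled_month"].astype(int)

    # targeted overrides for active milestones
    override_rows = []
    for (pid, month), milestones in states.items():
        for ms in milestones:
            for code, state, value in _satisfy_rows(
                ms, rng, config.cognitive_cutoff
            ):
                override_rows.append((pid, month, code, state, value))
    if override_rows:
        override = pd.DataFrame(
            override_rows,
            columns=[
                "participant_id",
                "scheduled_month",
                "item_code",
                "state",
                "value",
            ],
        )
        # a participant may hit two milestones sharing an item; keep one row
        override = override.drop_duplicates(
            subset=["participant_id", "scheduled_month", "item_code", "state"]
        )
    else:
        override = pd.DataFrame(columns=benign.columns)

    key_cols = ["participant_id", "scheduled_month", "item_code", "state"]
    # missingness: benign rows only
    keep = rng.uniform(size=len(benign)) >= config.item_missing_prob
    # baseline investigator flags are missing far more often
    flag_mask = (
        benign["item_code"].isin(["FLAG_PDD", "FLAG_COG_FUNC_IMPAIR"])
        & (benign["scheduled_month"] == 0)
    ).to_numpy()
    keep[flag_mask] = (
        rng.uniform(size=int(flag_mask.sum())) >= config.baseline_flag_missing_prob
    )
    benign = benign.loc[keep]

    if len(override):
        merged = benign.merge(override[key_cols], on=key_cols, how="left", indicator=True)
        benign = benign.loc[(merged["_merge"] == "left_only").to_numpy()]
        combined = pd.concat([benign, override], ignore_index=True)
    else:
        combined = benign
    combined = combined.sort_values(key_cols, kind="stable").reset_index(drop=True)
    combined["actual_month"] = combined["scheduled_month"].astype(float)
    return combined[
        [
            "participant_id",
            "scheduled_month",
            "actual_month",
            "item_code",
            "state",
            "value",
        ]
    ]


def engine_roundtrip_check(
    ds: StudyDataset, truth: SimulationTruth, registry: MilestoneRegistry
) -> dict:
    """Verify the engine recovers the truth states on every emitted visit."""
    mismatches = []
    for (pid, month), visit in ds.visits.items():
        hits = evaluate_visit(registry, visit, restrict_to_schedule=True).hits
        expected = set(truth.states.get((pid, month), frozenset()))
        if hits != expected:
            mismatches.append(
                {"participant_id": pid, "month": month,
                 "expected": sorted(expected), "observed": sorted(hits)}
            )
    return {"passed": not mismatches, "n_visits": len(ds.visits),
            "mismatches": mismatches}


# ---------------------------------------------------------------------------
# Fast survival-only path (no item emission)
# ---------------------------------------------------------------------------


def simulate_survival_records(config: SimulationConfig):
    """Latent survival component only: endpoint records on the annual grid
    plus the covariate table, sharing the cohort model of
    :func:`simulate_cohort`.  Used for large replicate studies where item
    back-filling would only reproduce the same event times."""
    rng = np.random.default_rng(config.seed)
    covariates = draw_covariates(rng, config)
    lp = linear_predictor(covariates, config.log_hazard_ratios)
    latent_t = draw_latent_times(rng, lp, config)
    n = config.n
    event_month = np.ceil(latent_t / 12.0) * 12.0  # next annual visit
    dropout_rate = -math.log(1.0 - config.annual_dropout_prob) / 12.0
    dropout_t = (
        rng.exponential(1.0 / dropout_rate, n)
        if dropout_rate > 0
        else np.full(n, np.inf)
    )
    last_annual = np.clip(np.floor(np.minimum(dropout_t, 60.0) / 12.0) * 12.0, 0, 60)
    med_t = rng.exponential(1.0 / config.med_monthly_hazard, n)
    covariates = covariates.copy()
    covariates["med_initiation_month"] = np.where(
        med_t <= 60.0, np.round(med_t, 1), np.nan
    )
    records = []
    for i, pid in enumerate(covariates["participant_id"]):
        if last_annual[i] < 12.0:
            records.append(
                EndpointRecord(pid, False, "no_followup", source_mode="annual")
            )
            continue
        if event_month[i] <= last_annual[i]:
            records.append(
                EndpointRecord(
                    pid,
                    True,
                    event=1,
                    time_months=float(event_month[i]),
                    first_event_milestones={"schwab_england"},
                    first_event_domains={"functional_dependence"},
                    source_mode="annual",
                )
            )
        else:
            records.append(
                EndpointRecord(
                    pid,
                    True,
                    event=0,
                    time_months=float(last_annual[i]),
                    source_mode="annual",
                )
            )
    return records, covariates
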