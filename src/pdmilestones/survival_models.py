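"""Kaplan-Meier estimation and the Cox predictor-selection workflow.

The Cox workflow mirrors the study's analysis plan: univariable screening at
the 0.10 level with 90% CIs, multicollinearity priority rules, then backward
elimination to 0.05 with sex and the time-dependent symptomatic-medication
indicator forced into every model.  Ties are handled with Efron's
approximation (the lifelines default for both fitters used here).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from lifelines import CoxTimeVaryingFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

from .endpoint_pipeline import EndpointRecord

MEDICATION = "medication"  # reserved name for the time-dependent covariate


class CoxFitError(RuntimeError):
    """Model failed to converge; message carries the lifelines diagnostics."""


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


@dataclass
class SurvivalCurve:
    """Product-limit estimate on a time grid (months)."""

    times: np.ndarray  # includes 0
    survival: np.ndarray  # S(times), S(0) = 1
    at_risk: np.ndarray
    events: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if self.times[0] != 0 or self.survival[0] != 1:
            raise ValueError("curve must start at S(0)=1")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be nonincreasing")

    def at(self, t: float) -> float:
        """Step-function lookup: S at the largest grid time <= t."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(idx, 0)])


def round_to_grid(t, step: float = 3.0):
    """Round times to the nearest multiple of ``step`` (half rounds up)."""
    return np.floor(np.asarray(t, dtype=float) / step + 0.5) * step


def km_curve(
    records: Iterable[EndpointRecord], round_to_3_months: bool = True
) -> SurvivalCurve:
    """Kaplan-Meier estimate from included endpoint records.

    Deaths precede censorings at tied times (the standard product-limit
    convention).  With rounding enabled, analysis time is per-protocol time:
    each time mapped to the nearest multiple of 3 months before estimation.
    """
    included = [r for r in records if r.included]
    if not included:
        raise ValueError("no included records")
    t = np.array([r.time_months for r in included], dtype=float)
    e = np.array([r.event for r in included], dtype=int)
    if round_to_3_months:
        t = round_to_grid(t)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    times = [0.0]
    surv = [1.0]
    at_risk = [len(t)]
    events = [0]
    s = 1.0
    for ti in np.unique(t):
        mask = t == ti
        d = int(e[mask].sum())
        n_at_risk = int((t >= ti).sum())
        s *= 1.0 - d / n_at_risk
        times.append(float(ti))
        surv.append(s)
        at_risk.append(n_at_risk)
        events.append(d)
    return SurvivalCurve(
        np.array(times), np.array(surv), np.array(at_risk), np.array(events)
    )


# ---------------------------------------------------------------------------
# Covariate specification and transforms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CovariateSpec:
    """How one baseline covariate enters the Cox models."""

    name: str
    transform: str = "identity"  # identity | per_k | decile_rank | binary
    k: float = 1.0
    direction: str = "increase"  # decrease => negated so HR>1 means worse
    role: str = "candidate"  # forced | candidate
    binary_threshold: Optional[float] = None
    superseded_by: Optional[str] = None  # multicollinearity priority rule
    source_column: Optional[str] = None  # defaults to name
    hb_filtered: bool = False  # drop values with CSF hemoglobin > 200 ng/mL

    @property
    def column(self) -> str:
        return self.source_column or self.name


def default_covariate_specs() -> list:
    """The pre-specified candidate-predictor set with reporting scales."""
    dec = "decrease"
    return [
        CovariateSpec("age", "per_k", k=5),
        CovariateSpec("sex", "binary", role="forced", binary_threshold=0.5),
        CovariateSpec("site_nonus", "binary", binary_threshold=0.5),
        CovariateSpec("bmi"),
        CovariateSpec("orthostatic_sys_bp_change"),
        CovariateSpec("disease_duration"),
        CovariateSpec("updrs_total", "per_k", k=5),
        CovariateSpec(
            "hy_stage", "binary", binary_threshold=1.5, superseded_by="updrs_total"
        ),
        CovariateSpec(
            "pigd_score", "per_k", k=0.1, direction=dec, superseded_by="updrs_total"
        ),
        CovariateSpec("tremor_score"),
        CovariateSpec("se_adl", "per_k", k=10, direction=dec),
        CovariateSpec("moca", "per_k", k=1, direction=dec),
        CovariateSpec("scopa_aut_total"),
        CovariateSpec("anosmia", "binary", binary_threshold=0.5),
        CovariateSpec("upsit_raw", "per_k", k=1, direction=dec),
        CovariateSpec("ess"),
        CovariateSpec("rbdsq"),
        CovariateSpec("gds15"),
        CovariateSpec("stai_total"),
        CovariateSpec("sbr_striatum", "per_k", k=0.1, direction=dec),
        CovariateSpec(
            "sbr_putamen", "per_k", k=0.1, direction=dec, superseded_by="sbr_striatum"
        ),
        CovariateSpec(
            "csf_abeta",
            "decile_rank",
            direction=dec,
            superseded_by="csf_ttau_abeta_ratio",
        ),
        CovariateSpec("csf_ttau", "decile_rank"),
        CovariateSpec("csf_ptau", "decile_rank"),
        CovariateSpec("csf_ttau_abeta_ratio", "decile_rank"),
        CovariateSpec("ttau_abeta_gt_0222", "binary", binary_threshold=0.5),
        CovariateSpec("csf_asyn", "decile_rank", direction=dec),
        CovariateSpec("urate"),
    ]


def decile_of_rank(values: pd.Series) -> pd.Series:
    """Map values to decile scores 1-10 via mid-ranks (ties share ranks)."""
    notna = values.dropna()
    ranks = notna.rank(method="average")
    deciles = np.ceil(ranks * 10.0 / len(notna)).clip(1, 10)
    out = pd.Series(np.nan, index=values.index, dtype=float)
    out.loc[notna.index] = deciles
    return out


def transform_covariates(
    covariates: pd.DataFrame,
    specs: Iterable[CovariateSpec],
    hb_filter: bool = False,
    hb_column: str = "csf_hb",
    hb_limit: float = 200.0,
) -> pd.DataFrame:
    """Build the model matrix on each covariate's reporting scale.

    ``decrease``-direction covariates are negated so a reported HR above 1
    means faster progression with lower values.  With ``hb_filter`` on,
    hemoglobin-contaminated CSF α-synuclein values are set missing.
    """
    frame = covariates
    if "participant_id" in frame.columns:
        frame = frame.set_index(frame["participant_id"].astype(str))
    out = {}
    for spec in specs:
        if spec.column not in frame.columns:
            warnings.warn(f"covariate {spec.column} absent; dropped")
            continue
        col = pd.to_numeric(frame[spec.column], errors="coerce").astype(float)
        if hb_filter and (spec.hb_filtered or spec.name == "csf_asyn"):
            if hb_column in frame.columns:
                hb = pd.to_numeric(frame[hb_column], errors="coerce")
                col = col.where(~(hb > hb_limit))
        if col.notna().sum() == 0:
            warnings.warn(f"covariate {spec.name} all-missing; dropped")
            continue
        if spec.transform == "identity":
            x = col
        elif spec.transform == "per_k":
            x = col / spec.k
        elif spec.transform == "decile_rank":
            x = decile_of_rank(col)
        elif spec.transform == "binary":
            x = (col > spec.binary_threshold).astype(float).where(col.notna())
        else:
            raise ValueError(f"unknown transform {spec.transform}")
        if spec.direction == "decrease":
            x = -x
        out[spec.name] = x
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Cox models with the time-dependent medication covariate
# ---------------------------------------------------------------------------


@dataclass
class CoxModelResult:
    """Fitted-model summary plus the selection trace."""

    table: pd.DataFrame  # index covariate; coef, se, hr, ci_lower, ci_upper, p
    ci_level: float
    ties: str = "efron"
    selection_trace: list = field(default_factory=list)  # (name, p_at_removal)
    n: int = 0
    n_events: int = 0

    @property
    def covariates(self) -> list:
        return list(self.table.index)


def build_episodes(
    records: Iterable[EndpointRecord],
    model_matrix: pd.DataFrame,
    med_initiation: Optional[Mapping] = None,
) -> pd.DataFrame:
    """Counting-process (start, stop] rows with the medication indicator
    switching from 0 to 1 at initiation.  Complete cases only."""
    rows = []
    cols = list(model_matrix.columns)
    for r in records:
        if not r.included:
            continue
        pid = r.participant_id
        if pid not in model_matrix.index:
            continue
        x = model_matrix.loc[pid]
        if x.isna().any():
            continue
        t = float(r.time_months)
        if t <= 0:
            continue
        m = None if med_initiation is None else med_initiation.get(pid)
        base = dict(zip(cols, x.to_numpy(dtype=float)))
        if m is not None and 0 < m < t:
            rows.append({"id": pid, "start": 0.0, "stop": float(m),
                         "event": 0, MEDICATION: 0.0, **base})
            rows.append({"id": pid, "start": float(m), "stop": t,
                         "event": int(r.event), MEDICATION: 1.0, **base})
        else:
            med0 = 1.0 if (m is not None and m <= 0) else 0.0
            rows.append({"id": pid, "start": 0.0, "stop": t,
                         "event": int(r.event), MEDICATION: med0, **base})
    return pd.DataFrame(rows)


def _summary_to_result(summary, ci_level, n, n_events) -> CoxModelResult:
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    coef = summary["coef"]
    se = summary["se(coef)"]
    table = pd.DataFrame(
        {
            "coef": coef,
            "se": se,
            "hr": np.exp(coef),
            "ci_lower": np.exp(coef - z * se),
            "ci_upper": np.exp(coef + z * se),
            "p": summary["p"],
        }
    )
    return CoxModelResult(table=table, ci_level=ci_level, n=n, n_events=n_events)


def fit_cox_td(
    records: Iterable[EndpointRecord],
    model_matrix: pd.DataFrame,
    med_initiation: Optional[Mapping] = None,
    include_medication: bool = True,
    ci_level: float = 0.95,
) -> CoxModelResult:
    """Cox partial likelihood (Efron ties) with an episode-split
    time-dependent medication indicator."""
    records = [r for r in records if r.included]
    if sum(r.event for r in records) < 1:
        raise ValueError("at least one event is required")
    df = build_episodes(records, model_matrix, med_initiation)
    if df.empty:
        raise ValueError("no complete-case rows to fit")
    covs = list(model_matrix.columns) + ([MEDICATION] if include_medication else [])
    if not include_medication:
        df = df.drop(columns=[MEDICATION])
        # collapse split episodes back to single rows per participant
        df = (
            df.groupby("id")
            .agg(
                start=("start", "min"),
                stop=("stop", "max"),
                event=("event", "max"),
                **{c: (c, "first") for c in model_matrix.columns},
            )
            .reset_index()
        )
    # a medication indicator that never switches carries no information;
    # the model degenerates to the fit without it
    if include_medication and df[MEDICATION].nunique() <= 1:
        covs = [c for c in covs if c != MEDICATION]
    constant = [c for c in covs if df[c].nunique() <= 1]
    if constant:
        raise ValueError(f"constant covariates cannot be fit: {constant}")
    if not covs:
        raise ValueError("no covariates left to fit")
    n = df["id"].nunique()
    n_events = int(df["event"].sum())
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ctv = CoxTimeVaryingFitter()
            ctv.fit(
                df[["id", "start", "stop", "event"] + covs],
                id_col="id",
                event_col="event",
                start_col="start",
                stop_col="stop",
                show_progress=False,
            )
    except ConvergenceError as exc:
        raise CoxFitError(f"Cox model failed to converge: {exc}") from exc
    result = _summary_to_result(ctv.summary, ci_level, n, n_events)
    return result


@dataclass
class ScreeningResult:
    """Univariable screening table and the resulting full-model covariates."""

    table: pd.DataFrame  # hr, ci, p, passed, excluded_by_priority
    selected: list  # candidate names entering the full model (non-forced)
    forced: list
    alpha: float


def screen_predictors(
    records: Iterable[EndpointRecord],
    covariates: pd.DataFrame,
    specs: Optional[Iterable[CovariateSpec]] = None,
    med_initiation: Optional[Mapping] = None,
    alpha: float = 0.10,
    hb_filter: bool = False,
) -> ScreeningResult:
    """One univariable Cox fit per candidate (90% CIs by default); the
    medication indicator is screened as its own time-dependent model.
    Priority rules then mark superseded covariates before the full model."""
    specs = list(default_covariate_specs() if specs is None else specs)
    records = [r for r in records if r.included]
    X = transform_covariates(covariates, specs, hb_filter=hb_filter)
    ci_level = 1.0 - 2 * alpha  # 90% CI for alpha = 0.10
    rows = []
    fitted_p = {}
    for spec in specs:
        if spec.name not in X.columns:
            continue
        xcol = X[[spec.name]].dropna()
        if xcol[spec.name].nunique() <= 1:
            warnings.warn(f"candidate {spec.name} is constant; dropped")
            continue
        try:
            res = fit_cox_td(
                records, xcol, med_initiation=None, include_medication=False,
                ci_level=ci_level,
            )
        except (CoxFitError, ValueError) as exc:
            warnings.warn(f"screening fit failed for {spec.name}: {exc}")
            continue
        row = res.table.loc[spec.name]
        fitted_p[spec.name] = row["p"]
        rows.append({"name": spec.name, "role": spec.role, **row.to_dict()})
    # medication: own time-dependent model with no other covariates
    if med_initiation is not None:
        empty = pd.DataFrame(index=[r.participant_id for r in records])
        try:
            res = fit_cox_td(
                records, empty, med_initiation=med_initiation,
                include_medication=True, ci_level=ci_level,
            )
            row = res.table.loc[MEDICATION]
            fitted_p[MEDICATION] = row["p"]
            rows.append({"name": MEDICATION, "role": "forced", **row.to_dict()})
        except (CoxFitError, ValueError) as exc:
            warnings.warn(f"medication screening fit failed: {exc}")
    table = pd.DataFrame(rows).set_index("name")
    table["passed"] = table["p"] <= alpha
    # priority rules: a covariate is dropped when its prioritized alternative
    # passed screening
    by_name = {s.name: s for s in specs}
    excluded = []
    for name in table.index:
        spec = by_name.get(name)
        if spec is None or spec.superseded_by is None:
            continue
        sup = spec.superseded_by
        if fitted_p.get(sup, 1.0) <= alpha:
            excluded.append(name)
    table["excluded_by_priority"] = [n in excluded for n in table.index]
    forced = [s.name for s in specs if s.role == "forced" and s.name in table.index]
    if med_initiation is not None:
        forced.append(MEDICATION)
    selected = [
        n
        for n in table.index
        if table.loc[n, "passed"]
        and not table.loc[n, "excluded_by_priority"]
        and n not in forced
    ]
    return ScreeningResult(table=table, selected=selected, forced=forced, alpha=alpha)


def backward_select(
    records: Iterable[EndpointRecord],
    model_matrix: pd.DataFrame,
    med_initiation: Optional[Mapping] = None,
    forced: Iterable[str] = ("sex", MEDICATION),
    retain_alpha: float = 0.05,
    ci_level: float = 0.95,
) -> CoxModelResult:
    """Backward elimination: repeatedly drop the non-forced covariate with
    the largest p > ``retain_alpha`` (ties broken by smaller \\|coef\\|),
    refitting after each removal.  Forced covariates are never removed."""
    forced = set(forced)
    include_med = MEDICATION in forced and med_initiation is not None
    current = list(model_matrix.columns)
    trace = []
    while True:
        res = fit_cox_td(
            records,
            model_matrix[current],
            med_initiation=med_initiation if include_med else None,
            include_medication=include_med,
            ci_level=ci_level,
        )
        removable = res.table.loc[[c for c in res.table.index if c not in forced]]
        if removable.empty:
            break
        worst_p = removable["p"].max()
        if worst_p <= retain_alpha:
            break
        ties_mask = removable["p"] == worst_p
        worst = removable.loc[ties_mask, "coef"].abs().idxmin()
        trace.append((worst, float(worst_p)))
        current = [c for c in current if c != worst]
    res.selection_trace = trace
    return res


def fit_workflow(
    records: Iterable[EndpointRecord],
    covariates: pd.DataFrame,
    specs: Optional[Iterable[CovariateSpec]] = None,
    med_initiation: Optional[Mapping] = None,
    screen_alpha: float = 0.10,
    retain_alpha: float = 0.05,
    hb_filter: bool = False,
):
    """Full screening -> priority rules -> backward-selection workflow."""
    specs = list(default_covariate_specs() if specs is None else specs)
    screening = screen_predictors(
        records, covariates, specs, med_initiation, alpha=screen_alpha,
        hb_filter=hb_filter,
    )
    X = transform_covariates(covariates, specs, hb_filter=hb_filter)
    full_cols = [
        n for n in screening.forced if n != MEDICATION and n in X.columns
    ] + screening.selected
    final = backward_select(
        records,
        X[full_cols],
        med_initiation=med_initiation,
        forced=set(screening.forced),
        retain_alpha=retain_alpha,
    )
    return screening, final
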