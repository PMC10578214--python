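"""Independent brute-force oracles, kept deliberately separate from the
package's implementation paths.

``oracle_hits`` is a literal, flat transcription of the published milestone
criteria table: no registry, no atom classes, no shared helpers.  Missing
scores never satisfy a criterion.
"""

import numpy as np

from pdmilestones.items import VISIT_GRID


def _motor_any(visit, code, pred):
    return any(
        v is not None and pred(v)
        for v in visit.motor_state_items.get(code, {}).values()
    )


def _item(visit, code):
    return visit.items.get(code)


def _ge(visit, code, t):
    v = _item(visit, code)
    return v is not None and v >= t


def oracle_hits(visit, cutoff=-1.5):
    """Literal re-read of the criteria table; returns the set of milestone
    ids met at this visit (schedule-unrestricted)."""
    hits = set()

    # Domain 1: walking and balance
    if _ge(visit, "UPDRS_2_12", 3):
        hits.add("walking_balance")
    if _ge(visit, "UPDRS_2_13", 3):
        hits.add("freezing")
    if _motor_any(visit, "UPDRS_3_10", lambda v: v >= 3):
        hits.add("gait")
    if _motor_any(visit, "UPDRS_3_11", lambda v: v == 4):
        hits.add("freezing_of_gait")
    if _motor_any(visit, "UPDRS_3_12", lambda v: v >= 3):
        hits.add("postural_instability")
    if _motor_any(visit, "HY", lambda v: v >= 4):
        hits.add("hoehn_yahr")

    # Domain 2: motor complications
    if _ge(visit, "UPDRS_4_1", 3) and _ge(visit, "UPDRS_4_2", 3):
        hits.add("dyskinesias")
    if _ge(visit, "UPDRS_4_4", 3):
        hits.add("fluctuations_functional")
    if _ge(visit, "UPDRS_4_5", 3):
        hits.add("fluctuations_complexity")

    # Domain 3: cognition
    moca = _item(visit, "MOCA_TOTAL")
    if moca is not None and moca < 21:
        hits.add("cognitive_impairment_moca")
    if _ge(visit, "UPDRS_1_1", 3):
        hits.add("cognitive_impairment_updrs")
    if _ge(visit, "UPDRS_1_2", 3):
        hits.add("hallucinations")
    if _ge(visit, "UPDRS_1_5", 3):
        hits.add("apathy")
    if visit.investigator_flags.get("pdd_diagnosis") is True:
        hits.add("dementia_clinical")
    n_impaired = sum(
        any(z <= cutoff for z in scores)
        for scores in visit.cognitive_domain_scores.values()
    )
    if n_impaired >= 2 and (
        visit.investigator_flags.get("functional_impairment_cognitive") is True
    ):
        hits.add("dementia_composite")

    # Domain 4: autonomic dysfunction
    s8 = _item(visit, "SCOPA_8")
    s9 = _item(visit, "SCOPA_9")
    if _ge(visit, "UPDRS_1_10", 3) and (
        (s8 is not None and s8 >= 2) or (s9 is not None and s9 >= 2)
    ):
        hits.add("urinary_incontinence")
    sys_sit = visit.bp.get(("SYS", "SITTING"))
    sys_std = visit.bp.get(("SYS", "STANDING"))
    dia_sit = visit.bp.get(("DIA", "SITTING"))
    dia_std = visit.bp.get(("DIA", "STANDING"))
    s15 = _item(visit, "SCOPA_15")
    if (
        s15 is not None
        and s15 >= 2
        and sys_sit is not None
        and sys_std is not None
        and (sys_sit - sys_std) >= 20
        and dia_sit is not None
        and dia_std is not None
        and (dia_sit - dia_std) >= 10
    ):
        hits.add("orthostatic_hypotension")
    v112 = _item(visit, "UPDRS_1_12")
    if v112 is not None and v112 == 4:
        hits.add("syncope_updrs")
    if _ge(visit, "SCOPA_16", 1):
        hits.add("syncope_scopa")

    # Domain 5: functional dependence
    se = _item(visit, "SE_ADL")
    if se is not None and se < 80:
        hits.add("schwab_england")

    # Domain 6: activities of daily living
    for code, name in [
        ("UPDRS_2_3", "choking"),
        ("UPDRS_2_4", "eating"),
        ("UPDRS_2_5", "dressing"),
        ("UPDRS_2_6", "hygiene"),
    ]:
        if _ge(visit, code, 3):
            hits.add(name)
    if _motor_any(visit, "UPDRS_3_1", lambda v: v >= 3):
        hits.add("speech")

    return hits


def random_visit(rng, make_visit, pid="R", month=None):
    """Random visit with item values spanning each instrument's full range
    and plenty of missingness, so thresholds are crossed often."""
    if month is None:
        month = int(rng.choice(VISIT_GRID))
    items = {}
    for code in [
        "UPDRS_1_1", "UPDRS_1_2", "UPDRS_1_5", "UPDRS_1_10", "UPDRS_1_12",
        "UPDRS_2_3", "UPDRS_2_4", "UPDRS_2_5", "UPDRS_2_6", "UPDRS_2_12",
        "UPDRS_2_13", "UPDRS_4_1", "UPDRS_4_2", "UPDRS_4_4", "UPDRS_4_5",
    ]:
        if rng.uniform() < 0.8:
            items[code] = int(rng.integers(0, 5))
    if rng.uniform() < 0.8:
        items["MOCA_TOTAL"] = int(rng.integers(0, 31))
    if rng.uniform() < 0.8:
        items["SE_ADL"] = int(rng.integers(0, 21)) * 5
    for code in ["SCOPA_8", "SCOPA_9", "SCOPA_15", "SCOPA_16"]:
        if rng.uniform() < 0.8:
            items[code] = int(rng.integers(0, 4))
    motor = {}
    for code in ["UPDRS_3_1", "UPDRS_3_10", "UPDRS_3_11", "UPDRS_3_12"]:
        states = {}
        for state in ("OFF", "ON"):
            if rng.uniform() < 0.6:
                states[state] = int(rng.integers(0, 5))
        if states:
            motor[code] = states
    hy = {}
    for state in ("OFF", "ON"):
        if rng.uniform() < 0.6:
            hy[state] = int(rng.integers(0, 6))
    if hy:
        motor["HY"] = hy
    bp = {}
    for meas, base in (("SYS", 130), ("DIA", 80)):
        for pos in ("SUPINE", "SITTING", "STANDING"):
            if rng.uniform() < 0.7:
                bp[(meas, pos)] = float(np.round(rng.normal(base, 20), 1))
    cog = {}
    for code in [
        "COG_HVLT_RECALL", "COG_HVLT_RECOG", "COG_JOLO", "COG_SDMT",
        "COG_LNS", "COG_FLUENCY",
    ]:
        if rng.uniform() < 0.6:
            cog[code] = float(np.round(rng.normal(-0.8, 1.2), 2))
    flags = {}
    for name in ("pdd_diagnosis", "functional_impairment_cognitive"):
        if rng.uniform() < 0.6:
            flags[name] = bool(rng.uniform() < 0.3)
    return make_visit(
        pid=pid, month=month, items=items, motor=motor, bp=bp, cog=cog,
        flags=flags,
    )


def km_by_hand(times, events):
    """Plain product-limit computation (deaths before censorings at ties)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    s = 1.0
    out = {}
    for t in np.unique(times):
        d = int(events[times == t].sum())
        n = int((times >= t).sum())
        s *= 1 - d / n
        out[float(t)] = s
    return out


def chi2_closed_form(table):
    """n (ad - bc)^2 / (r1 r2 c1 c2) for a 2x2 table."""
    (a, b), (c, d) = table
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
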