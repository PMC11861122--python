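"""Synthetic claims generator with known ground truth.

Emulates the structure of an administrative claims database: enrollment
spans, ICD-coded diagnoses (ITP plus comorbidities), dated drug
prescriptions with dose and days supplied, splenectomy procedures, and
adverse-outcome processes with a known multiplicative corticosteroid
effect, so that the downstream pipeline can be tested for parameter
recovery.

The outcome model is a discrete-time (daily) logistic hazard: on each
at-risk day ``t`` after cohort entry the outcome occurs with probability
``expit(logit(h0) + log(true_or) * exposed(t))`` where ``exposed(t)`` is
1 once the patient has received any CS prescription before day ``t``
("ever" definition, the default) or while covered ("current").  Under
this model the incidence-density-sampled conditional-logistic odds ratio
has ``true_or`` as its exact estimand, which makes recovery testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import skewnorm

from itpclaims.io import (ClaimsTables, DIAGNOSIS_COLUMNS,
                          PATIENT_COLUMNS, PRESCRIPTION_COLUMNS,
                          PROCEDURE_COLUMNS)


class ParamError(ValueError):
    """Raised for infeasible simulation parameters."""


@dataclass
class SimulationParams:
    """Knobs of the synthetic claims generator."""

    n_patients: int = 1000
    span_start: str = "2014-04"
    span_end: str = "2022-08"
    p_female: float = 0.51
    # age at entry: truncated skew-normal targeting median ~78, IQR 68-84
    age_loc: float = 86.0
    age_scale: float = 14.0
    age_skew: float = -4.0
    age_range: tuple[int, int] = (20, 101)
    p_itp: float = 0.9
    p_suspected_only: float = 0.02
    p_short_lookback: float = 0.05
    p_inpatient_entry: float = 0.24
    p_treated_given_itp: float = 0.5
    # (daily PSL-eq mg, probability) of the initial CS dose
    initial_cs_dose_distribution: tuple[tuple[float, float], ...] = (
        (5.0, 0.10), (15.0, 0.20), (30.0, 0.42), (50.0, 0.18), (70.0, 0.10))
    # (week index, fraction of initial dose); fraction 0 ends treatment
    taper_schedule: tuple[tuple[int, float], ...] = (
        (0, 1.0), (2, 0.5), (4, 0.25), (8, 0.125), (12, 0.0))
    cs_start_delay_max_days: int = 60
    mean_assessment_months: float = 18.0
    switch_hazards: dict[str, float] = field(default_factory=lambda: {
        "first_line_epag": 0.15, "cs_add_epag": 0.20,
        "epag_readminister_cs": 0.30, "to_romi": 0.03, "to_rtx": 0.03})
    era_multipliers: dict[int, float] = field(default_factory=dict)
    comorbidity_prevalence: dict[str, float] = field(default_factory=lambda: {
        "hypertension": 0.58, "dyslipidemia": 0.43, "diabetes": 0.36,
        "pulmonary_disease": 0.27, "liver_disease": 0.22,
        "malignancy": 0.23, "osteoporosis": 0.23, "infection": 0.22,
        "cataract": 0.21, "glaucoma": 0.13})
    # outcome name -> per-day baseline hazard probability
    outcome_h0: dict[str, float] = field(default_factory=lambda: {
        "infection": 5e-4})
    # outcome name -> multiplicative odds effect of CS exposure
    true_or: dict[str, float] = field(default_factory=lambda: {
        "infection": 2.0})
    exposure_definition: str = "ever"   # or "current"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("p_female", "p_itp", "p_suspected_only",
                     "p_short_lookback", "p_inpatient_entry",
                     "p_treated_given_itp"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParamError(f"{name} must be in [0, 1], got {v}")
        fracs = [f for _, f in sorted(self.taper_schedule)]
        if any(f2 > f1 for f1, f2 in zip(fracs, fracs[1:])):
            raise ParamError("taper fractions must be non-increasing")
        for name, r in self.true_or.items():
            if r <= 0:
                raise ParamError(f"true_or[{name!r}] must be > 0")
        for name, h in self.outcome_h0.items():
            if not 0.0 < h < 1.0:
                raise ParamError(f"outcome_h0[{name!r}] must be in (0, 1)")
        if self.exposure_definition not in ("ever", "current"):
            raise ParamError("exposure_definition must be 'ever' or "
                             "'current'")
        if self.n_patients < 0:
            raise ParamError("n_patients must be >= 0")
        total = sum(p for _, p in self.initial_cs_dose_distribution)
        if abs(total - 1.0) > 1e-9:
            raise ParamError("initial_cs_dose_distribution probabilities "
                             f"must sum to 1, got {total}")


@dataclass
class GroundTruth:
    """What the generator knows that the analysis must recover."""

    patients: pd.DataFrame       # per-patient truth (entry, cs start, events)
    true_or: dict[str, float]
    exposure_definition: str


def _empty_tables() -> ClaimsTables:
    return ClaimsTables(
        patients=pd.DataFrame(columns=PATIENT_COLUMNS),
        diagnoses=pd.DataFrame(columns=DIAGNOSIS_COLUMNS),
        prescriptions=pd.DataFrame(columns=PRESCRIPTION_COLUMNS),
        procedures=pd.DataFrame(columns=PROCEDURE_COLUMNS),
    )


_UNIX_ORDINAL = 719163  # proleptic ordinal of 1970-01-01


def _ordinal_to_datetime(ordinals: np.ndarray) -> pd.DatetimeIndex:
    return pd.to_datetime(np.asarray(ordinals) - _UNIX_ORDINAL, unit="D")


def _taper_fraction_by_week(schedule) -> np.ndarray:
    """Expand (week, fraction) breakpoints into a per-week step function."""
    pts = sorted(schedule)
    last_week = pts[-1][0]
    frac = np.zeros(last_week + 1)
    for (w0, f0), (w1, _) in zip(pts, pts[1:] + [(last_week + 1, 0.0)]):
        frac[w0:w1] = f0
    return frac


def _draw_event_days(rng: np.random.Generator, h0: float, or_: float,
                     switch_day: np.ndarray, followup: np.ndarray,
                     exposure_end: np.ndarray | None = None) -> np.ndarray:
    """Exact draw from the phase-wise daily Bernoulli process.

    Days 1..switch_day are at baseline hazard, days switch_day+1..
    exposure_end at the odds-multiplied hazard, and later days (for the
    "current" definition, where exposure_end is finite) at baseline
    again.  switch_day = inf encodes never exposed.  Returns the event
    day since entry, or 0 where no event occurs within follow-up.
    """
    n = len(switch_day)
    p0 = h0
    p1 = float(expit(logit(h0) + np.log(or_)))
    t1 = rng.geometric(p0, size=n).astype(float)
    t2 = rng.geometric(p1, size=n).astype(float)
    t3 = rng.geometric(p0, size=n).astype(float)
    if exposure_end is None:
        exposure_end = np.full(n, np.inf)
    event = np.where(
        t1 <= switch_day, t1,
        np.where(switch_day + t2 <= exposure_end, switch_day + t2,
                 exposure_end + t3))
    event = np.where(event <= followup, event, 0.0)
    return event.astype(int)


def simulate_claims(params: SimulationParams
                    ) -> tuple[ClaimsTables, GroundTruth]:
    """Generate the four claims tables plus ground truth, reproducibly."""
    params.validate()
    rng = np.random.default_rng(params.rng_seed)
    n = params.n_patients
    if n == 0:
        truth = GroundTruth(pd.DataFrame(columns=["patient_id"]),
                            dict(params.true_or),
                            params.exposure_definition)
        return _empty_tables(), truth

    span_start = pd.Period(params.span_start, freq="M")
    span_end = pd.Period(params.span_end, freq="M")
    n_months = (span_end - span_start).n + 1

    ids = np.array([f"P{i:06d}" for i in range(1, n + 1)])
    female = rng.random(n) < params.p_female
    gender = np.where(female, "female", "male")

    lo, hi = params.age_range
    age = skewnorm.rvs(params.age_skew, loc=params.age_loc,
                       scale=params.age_scale, size=n, random_state=rng)
    age = np.clip(np.round(age), lo, hi).astype(int)

    # enrollment: start month somewhere in the span, end month at or after
    # start + 9 months (so look-back + some follow-up is usually feasible)
    start_off = rng.integers(0, max(1, n_months - 12), size=n)
    end_off = np.minimum(
        n_months - 1,
        start_off + 9 + rng.integers(0, n_months, size=n))
    obs_start = pd.PeriodIndex(span_start + start_off)
    obs_end = pd.PeriodIndex(span_start + end_off)
    months = pd.period_range(span_start, span_end, freq="M")
    month_start_ord = np.array(
        [p.to_timestamp(how="start").toordinal() for p in months])
    month_end_ord = np.array(
        [p.to_timestamp(how="end").toordinal() for p in months])
    obs_start_day = month_start_ord[start_off]
    obs_end_day = month_end_ord[end_off]

    has_itp = rng.random(n) < params.p_itp
    suspected_only = has_itp & (rng.random(n) < params.p_suspected_only)
    short_lookback = has_itp & (rng.random(n) < params.p_short_lookback)

    lookback_days = 190  # > 6 calendar months, so look-back always fits

    # entry day: uniform inside the feasible window (after look-back,
    # leaving >= 1 month of follow-up); short-lookback patients enter early
    feas_lo = obs_start_day + lookback_days
    feas_hi = obs_end_day - 30
    u = rng.random(n)
    entry_day = (feas_lo + u * np.maximum(0, feas_hi - feas_lo)).astype(int)
    early = obs_start_day + (u * 120).astype(int)
    entry_day = np.where(short_lookback, early, entry_day)
    infeasible = feas_hi < feas_lo
    entry_day = np.where(infeasible & ~short_lookback,
                         np.minimum(early, obs_end_day), entry_day)
    entry_day = np.minimum(entry_day, obs_end_day)

    # assessment length in months (monthly ITP codes from entry onward)
    assess_months = 1 + rng.geometric(
        1.0 / max(1.0, params.mean_assessment_months), size=n)
    entry_midx = np.searchsorted(month_start_ord, entry_day,
                                 side="right") - 1
    months_left = np.maximum(1, end_off - entry_midx + 1)
    assess_months = np.minimum(assess_months, months_left)

    treated = has_itp & ~suspected_only & \
        (rng.random(n) < params.p_treated_given_itp)
    epag_first = treated & (rng.random(n) <
                            params.switch_hazards.get("first_line_epag", 0.0))
    cs_first = treated & ~epag_first

    doses = np.array([d for d, _ in params.initial_cs_dose_distribution])
    probs = np.array([p for _, p in params.initial_cs_dose_distribution])
    init_dose = rng.choice(doses, size=n, p=probs)

    assess_end_day = np.minimum(
        month_end_ord[np.minimum(entry_midx + assess_months - 1,
                                 len(months) - 1)],
        obs_end_day)

    delay = rng.integers(0, params.cs_start_delay_max_days + 1, size=n)
    cs_start_day = entry_day + np.minimum(
        delay, np.maximum(0, assess_end_day - entry_day))
    cs_start_day = np.where(cs_first, cs_start_day, -1)

    # ---- diagnoses: monthly ITP codes over the assessment period --------
    # chunks of (pid, day, code, suspected, inpatient) arrays
    chunks: list[tuple[np.ndarray, np.ndarray, np.ndarray,
                       np.ndarray, np.ndarray]] = []
    itp_idx = np.flatnonzero(has_itp)
    rep = assess_months[itp_idx]
    rpid = np.repeat(itp_idx, rep)
    k = np.arange(rep.sum()) - np.repeat(np.cumsum(rep) - rep, rep)
    day = np.minimum(month_start_ord[entry_midx[rpid] + k] + 14,
                     obs_end_day[rpid])
    day = np.where(k == 0, entry_day[rpid], day)
    inpt_draw = rng.random(n) < params.p_inpatient_entry
    chunks.append((rpid, day, np.full(len(rpid), "D693"),
                   suspected_only[rpid],
                   (k == 0) & inpt_draw[rpid]))

    # baseline comorbidity codes inside the look-back window
    for concept, prev in params.comorbidity_prevalence.items():
        hit = np.flatnonzero(rng.random(n) < prev)
        offs = rng.integers(10, 170, size=len(hit))
        cday = np.maximum(obs_start_day[hit], entry_day[hit] - offs)
        code = _CONCEPT_CODE.get(concept, "R69")
        chunks.append((hit, cday, np.full(len(hit), code),
                       np.zeros(len(hit), dtype=bool),
                       np.zeros(len(hit), dtype=bool)))

    # ---- CS prescriptions: weekly scripts following the taper -----------
    frac = _taper_fraction_by_week(params.taper_schedule)
    frac_pos = frac[frac > 0]
    cs_idx = np.flatnonzero(cs_first)
    wgrid = np.arange(len(frac_pos))
    cs_day = cs_start_day[cs_idx, None] + 7 * wgrid[None, :]
    keep = cs_day <= assess_end_day[cs_idx, None]
    cs_rows = np.repeat(cs_idx, keep.sum(axis=1))
    cs_days_flat = cs_day[keep]
    cs_dose_flat = (init_dose[cs_idx, None] * frac_pos[None, :]
                    )[keep]

    rx_pid, rx_day, rx_cls, rx_name, rx_route, rx_dose, rx_days = \
        (list(ids[cs_rows]), list(cs_days_flat),
         ["CS"] * len(cs_rows), ["prednisolone"] * len(cs_rows),
         ["oral"] * len(cs_rows), list(cs_dose_flat.astype(float)),
         [7] * len(cs_rows))

    # EPAG: first line or added on after the CS taper ends
    add_epag = cs_first & (rng.random(n) <
                           params.switch_hazards.get("cs_add_epag", 0.0))
    epag_users = np.flatnonzero(epag_first | add_epag)
    taper_len_days = 7 * int(np.sum(frac > 0))
    for i in epag_users:
        start = int(entry_day[i]) if epag_first[i] else \
            int(cs_start_day[i]) + taper_len_days
        months = 1 + int(rng.geometric(0.2))
        for k in range(months):
            day = start + 30 * k
            if day > assess_end_day[i]:
                break
            rx_pid.append(ids[i]); rx_day.append(day)
            rx_cls.append("EPAG"); rx_name.append("eltrombopag")
            rx_route.append("oral")
            rx_dose.append(25.0); rx_days.append(30)

    # occasional ROMI / RTX third-line use
    for cls, name, route, dose, nd, gap in (
            ("ROMI", "romiplostim", "injection", 0.25, 1, 7),
            ("RTX", "rituximab", "injection", 375.0, 1, 7)):
        p = params.switch_hazards.get(
            "to_romi" if cls == "ROMI" else "to_rtx", 0.0)
        for i in np.flatnonzero(treated & (rng.random(n) < p)):
            start = int(entry_day[i]) + 30
            for k in range(4):
                day = start + gap * k
                if day > assess_end_day[i]:
                    break
                rx_pid.append(ids[i]); rx_day.append(day)
                rx_cls.append(cls); rx_name.append(name)
                rx_route.append(route)
                rx_dose.append(dose); rx_days.append(nd)

    # ---- adverse outcomes: two-phase daily logistic hazard --------------
    followup = np.maximum(0, obs_end_day - entry_day)
    switch = np.where(cs_start_day >= 0,
                      (cs_start_day - entry_day).astype(float), np.inf)
    if params.exposure_definition == "current":
        # exposed only while the taper covers the day; exposure ends at
        # the end of continuous CS coverage
        taper_days = 7 * int(np.sum(_taper_fraction_by_week(
            params.taper_schedule) > 0))
        exposure_end = switch + taper_days
    else:
        exposure_end = np.full(n, np.inf)
    outcome_days: dict[str, np.ndarray] = {}
    for name, h0 in params.outcome_h0.items():
        or_ = params.true_or.get(name, 1.0)
        ev = _draw_event_days(rng, h0, or_, switch, followup,
                              exposure_end=exposure_end)
        ev = np.where(has_itp & ~suspected_only, ev, 0)
        outcome_days[name] = ev
        code = _CONCEPT_CODE.get(name, "R69")
        hit = np.flatnonzero(ev > 0)
        chunks.append((hit, entry_day[hit] + ev[hit],
                       np.full(len(hit), code),
                       np.zeros(len(hit), dtype=bool),
                       np.zeros(len(hit), dtype=bool)))

    # ---- assemble tables -------------------------------------------------
    patients = pd.DataFrame({
        "patient_id": ids,
        "gender": gender,
        "birth_year": (pd.PeriodIndex(obs_start).year - age).astype(int),
        "observation_start": pd.PeriodIndex(obs_start),
        "observation_end": pd.PeriodIndex(obs_end),
    })
    d_idx = np.concatenate([c[0] for c in chunks]).astype(int)
    diagnoses = pd.DataFrame({
        "patient_id": ids[d_idx],
        "date": _ordinal_to_datetime(
            np.concatenate([c[1] for c in chunks]).astype(int)),
        "code": np.concatenate([c[2] for c in chunks]),
        "suspected": np.concatenate([c[3] for c in chunks]),
        "inpatient": np.concatenate([c[4] for c in chunks]),
    }).sort_values(["patient_id", "date", "code"],
                   kind="stable").reset_index(drop=True)
    prescriptions = pd.DataFrame({
        "patient_id": rx_pid,
        "date": _ordinal_to_datetime(np.asarray(rx_day, dtype=int)),
        "drug_class": rx_cls,
        "drug_name": rx_name,
        "route": rx_route,
        "daily_dose_mg": rx_dose,
        "days_supplied": rx_days,
    }).sort_values(["patient_id", "date", "drug_class"],
                   kind="stable").reset_index(drop=True)
    procedures = pd.DataFrame(columns=PROCEDURE_COLUMNS)

    truth_df = pd.DataFrame({
        "patient_id": ids,
        "has_itp": has_itp & ~suspected_only,
        "treated_cs": cs_first,
        "entry_date": _ordinal_to_datetime(entry_day),
        "cs_start_offset_days": np.where(
            cs_start_day >= 0, cs_start_day - entry_day, -1),
        "followup_days": followup,
    })
    for name, ev in outcome_days.items():
        truth_df[f"outcome_{name}_day"] = ev  # 0 = no event
    truth = GroundTruth(truth_df, dict(params.true_or),
                        params.exposure_definition)
    return ClaimsTables(patients, diagnoses, prescriptions,
                        procedures), truth


_CONCEPT_CODE = {
    "itp": "D693", "pregnancy_itp": "O993", "diabetes": "E11",
    "malignancy": "C80", "pulmonary_disease": "J44", "liver_disease": "K76",
    "osteoporosis": "M80", "dyslipidemia": "E78", "hypertension": "I10",
    "cataract": "H25", "glaucoma": "H40", "infection": "A49",
    "peptic_ulcer": "K25", "thromboembolism": "I26", "psychosis": "F09",
    "depression": "F32", "insomnia": "G47",
}


def simulate_withdrawal_claims(median_days_by_era: Mapping[str, float],
                               n_per_era: int, seed: int,
                               era_start_year: Mapping[str, int] | None = None,
                               ) -> ClaimsTables:
    """Cohort with exponentially distributed CS coverage lengths per era.

    Each patient starts CS at entry and is covered continuously for
    ``D ~ Exponential(median / ln 2)`` days (rounded, >= 1), after which
    no CS is prescribed again, so the time to withdrawal equals the
    coverage length exactly.  Used to check Kaplan-Meier recovery of
    known medians.
    """
    if era_start_year is None:
        era_start_year = {"2015-2019": 2017, "2020-2021": 2020}
    rng = np.random.default_rng(seed)
    rows_p, rows_d, rows_rx = [], [], []
    pid = 0
    for era, median in median_days_by_era.items():
        year = era_start_year[era]
        scale = median / np.log(2.0)
        dur = np.maximum(1, np.round(rng.exponential(scale, n_per_era))
                         ).astype(int)
        for d in dur:
            pid += 1
            patient = f"W{pid:05d}"
            entry = pd.Timestamp(year=year, month=3, day=1) + \
                pd.Timedelta(days=int(rng.integers(0, 90)))
            rows_p.append({
                "patient_id": patient, "gender": "female",
                "birth_year": entry.year - 70,
                "observation_start": pd.Period(entry, "M") - 7,
                "observation_end": pd.Period(entry, "M") + 18,
            })
            # monthly ITP codes through entry month + 12 (assessment end
            # far beyond coverage end + 60 days)
            for k in range(13):
                per = pd.Period(entry, "M") + k
                day = entry if k == 0 else \
                    per.to_timestamp(how="start") + pd.Timedelta(days=14)
                rows_d.append({"patient_id": patient, "date": day,
                               "code": "D693", "suspected": False,
                               "inpatient": False})
            # CS scripts of up to 14 days, last one truncated to length D
            left = int(d)
            day = entry
            while left > 0:
                supply = min(14, left)
                rows_rx.append({
                    "patient_id": patient, "date": day, "drug_class": "CS",
                    "drug_name": "prednisolone", "route": "oral",
                    "daily_dose_mg": 20.0, "days_supplied": supply})
                day = day + pd.Timedelta(days=supply)
                left -= supply
    return ClaimsTables(
        patients=pd.DataFrame(rows_p, columns=PATIENT_COLUMNS),
        diagnoses=pd.DataFrame(rows_d, columns=DIAGNOSIS_COLUMNS),
        prescriptions=pd.DataFrame(rows_rx, columns=PRESCRIPTION_COLUMNS),
        procedures=pd.DataFrame(columns=PROCEDURE_COLUMNS),
    )
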