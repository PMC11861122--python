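"""CS exposure quantification.

Builds merged treatment episodes per drug class, converts corticosteroid
doses to prednisolone (PSL) equivalents, flags pulse/high-dose therapy,
and computes daily dose series, durations, the weekly dose grid,
cumulative dose, and time to withdrawal.

Date conventions
----------------
A prescription dated ``d`` with ``days_supplied = k`` covers days
``d .. d+k-1``; its exclusive end date is ``d + k``.  Two consecutive
prescriptions of one class merge into one episode when
``next.date - previous_end_exclusive <= gap_days`` (for injectables the
interval is between consecutive prescription *dates*).  Withdrawal
occurs at a coverage end date followed by >= 60 CS-free days (to the
next prescription, or to the assessment end).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from itpclaims.config import AnalysisConfig, ConfigError


# ---------------------------------------------------------------------------
# dose conversion
# ---------------------------------------------------------------------------

def to_psl_equivalent(drug_name: str, daily_dose_mg: float,
                      config: AnalysisConfig) -> float:
    """Convert a native daily dose to mg/day prednisolone equivalent."""
    try:
        factor = config.psl_equivalence[drug_name]
    except KeyError:
        raise ConfigError(
            f"no PSL-equivalence factor configured for CS drug "
            f"{drug_name!r}") from None
    return daily_dose_mg * factor


def psl_dose_series(prescriptions: pd.DataFrame,
                    config: AnalysisConfig) -> pd.Series:
    """Vectorised PSL-equivalent dose for CS prescription rows."""
    cs = prescriptions["drug_class"] == "CS"
    unmapped = sorted(set(prescriptions.loc[cs, "drug_name"]) -
                      set(config.psl_equivalence))
    if unmapped:
        raise ConfigError("no PSL-equivalence factor configured for CS "
                          f"drug(s) {unmapped}")
    factors = prescriptions["drug_name"].map(config.psl_equivalence)
    out = prescriptions["daily_dose_mg"] * factors.where(cs, 0.0)
    return out.fillna(0.0)


# ---------------------------------------------------------------------------
# pulse / high-dose therapy flags
# ---------------------------------------------------------------------------

def flag_pulse_and_hdd(prescriptions: pd.DataFrame,
                       config: AnalysisConfig) -> pd.Series:
    """Boolean mask over prescription rows belonging to a pulse or
    high-dose-dexamethasone run.

    Pulse: methylprednisolone 500-1000 mg/day as injection covering
    exactly 3 consecutive days.  High-dose dexamethasone: 20-40 mg/day
    (oral or injection) covering exactly 4 consecutive days.  Flagged
    days are excluded from dose quantification but still count as CS
    exposure presence.
    """
    flagged = pd.Series(False, index=prescriptions.index)
    plo, phi = config.pulse_dose_range_mg
    dlo, dhi = config.hdd_dose_range_mg
    specs = [
        (prescriptions["drug_name"].eq("methylprednisolone") &
         prescriptions["route"].eq("injection") &
         prescriptions["daily_dose_mg"].between(plo, phi),
         config.pulse_run_days),
        (prescriptions["drug_name"].eq("dexamethasone") &
         prescriptions["daily_dose_mg"].between(dlo, dhi),
         config.hdd_run_days),
    ]
    for candidate, run_days in specs:
        cand = prescriptions[candidate & prescriptions["drug_class"].eq("CS")]
        for _, group in cand.groupby("patient_id"):
            days = _day_numbers(group["date"])
            ends = days + group["days_supplied"].to_numpy()
            # maximal consecutive-coverage runs among candidate scripts
            order = np.argsort(days, kind="stable")
            runs: list[list[int]] = []
            cur: list[int] = []
            cur_end = None
            for k in order:
                if cur and days[k] > cur_end:
                    runs.append(cur)
                    cur, cur_end = [], None
                cur.append(k)
                cur_end = ends[k] if cur_end is None else max(cur_end,
                                                              ends[k])
            if cur:
                runs.append(cur)
            for run in runs:
                start = min(days[k] for k in run)
                end = max(ends[k] for k in run)
                if end - start == run_days:
                    flagged.loc[group.index[run]] = True
    return flagged


def _day_numbers(dates: pd.Series) -> np.ndarray:
    return dates.map(pd.Timestamp.toordinal).to_numpy()


# ---------------------------------------------------------------------------
# episodes
# ---------------------------------------------------------------------------

def build_episodes(prescriptions: pd.DataFrame,
                   config: AnalysisConfig) -> pd.DataFrame:
    """Merge prescriptions into continuous treatment episodes.

    One row per (patient, drug class) episode with inclusive ``start``
    and ``end`` dates and the exclusive coverage end ``end_exclusive``.
    """
    rows = []
    for (pid, cls), group in prescriptions.groupby(
            ["patient_id", "drug_class"], sort=True):
        gap = config.gap_days_by_class.get(cls, 30)
        group = group.sort_values("date", kind="stable")
        days = _day_numbers(group["date"])
        ends = days + group["days_supplied"].to_numpy()
        inject = group["route"].eq("injection").to_numpy()
        start = days[0]
        run_end = ends[0]
        last_date = days[0]
        n_rx = 1
        for i in range(1, len(group)):
            interval = (days[i] - last_date) if inject[i] \
                else (days[i] - run_end)
            if interval <= gap:
                run_end = max(run_end, ends[i])
                last_date = days[i]
                n_rx += 1
            else:
                rows.append((pid, cls, start, run_end, n_rx))
                start, run_end, last_date, n_rx = (days[i], ends[i],
                                                   days[i], 1)
        rows.append((pid, cls, start, run_end, n_rx))
    out = pd.DataFrame(rows, columns=["patient_id", "drug_class",
                                      "start_day", "end_exclusive_day",
                                      "n_prescriptions"])
    out["start"] = out["start_day"].map(pd.Timestamp.fromordinal)
    out["end"] = (out["end_exclusive_day"] - 1).map(
        pd.Timestamp.fromordinal)
    out["end_exclusive"] = out["end_exclusive_day"].map(
        pd.Timestamp.fromordinal)
    return out[["patient_id", "drug_class", "start", "end",
                "end_exclusive", "n_prescriptions"]]


# ---------------------------------------------------------------------------
# daily dose series
# ---------------------------------------------------------------------------

@dataclass
class DailySeries:
    """Per-day CS state over the assessment period of one patient.

    Offsets are days since entry; ``dose`` is PSL-eq mg/day with
    pulse/HDD doses removed, ``covered`` marks prescribed days (pulse
    days included), ``allowed`` marks days outside excluded months.
    """

    entry_day: int
    dose: np.ndarray
    covered: np.ndarray
    allowed: np.ndarray

    @property
    def n_days(self) -> int:
        return len(self.dose)


def daily_series(cs_rx: pd.DataFrame, entry: pd.Timestamp,
                 assessment_end: pd.Timestamp, excluded_months: set[str],
                 config: AnalysisConfig,
                 flagged: pd.Series | None = None) -> DailySeries:
    """Build the day-level dose/coverage arrays for one patient."""
    e0 = entry.toordinal()
    n = assessment_end.toordinal() - e0 + 1
    dose = np.zeros(n)
    covered = np.zeros(n, dtype=bool)
    if len(cs_rx):
        psl = psl_dose_series(cs_rx, config)
        days = _day_numbers(cs_rx["date"])
        ends = days + cs_rx["days_supplied"].to_numpy()
        flags = flagged.reindex(cs_rx.index).fillna(False).to_numpy() \
            if flagged is not None else np.zeros(len(cs_rx), dtype=bool)
        for d, e, v, fl in zip(days, ends, psl.to_numpy(), flags):
            lo, hi = max(d - e0, 0), min(e - e0, n)
            if lo >= hi:
                continue
            covered[lo:hi] = True
            if not fl:
                dose[lo:hi] += v
    allowed = np.ones(n, dtype=bool)
    for month in excluded_months:
        per = pd.Period(month, freq="M")
        lo = max(per.to_timestamp(how="start").toordinal() - e0, 0)
        hi = min(per.to_timestamp(how="end").toordinal() - e0 + 1, n)
        if lo < hi:
            allowed[lo:hi] = False
    dose[~allowed] = 0.0
    return DailySeries(e0, dose, covered, allowed)


def cs_duration(series: DailySeries, up_to: int | None = None) -> int:
    """Covered CS days inside the assessment period (excluded months
    skipped), optionally restricted to offsets strictly before ``up_to``."""
    mask = series.covered & series.allowed
    if up_to is not None:
        mask = mask[:max(0, min(up_to, len(mask)))]
    return int(mask.sum())


def cumulative_dose(series: DailySeries, up_to: int | None = None) -> float:
    """Total PSL-eq mg over covered days (pulse/HDD dose excluded),
    optionally restricted to offsets strictly before ``up_to``."""
    dose = series.dose
    if up_to is not None:
        dose = dose[:max(0, min(up_to, len(dose)))]
    return float(dose.sum())


# ---------------------------------------------------------------------------
# bin labels
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return f"{x:g}"


def band_labels(cuts: list[float], zero_label: str = "0") -> list[str]:
    """Labels ``[zero, >0-<c1, >=c1-<c2, ..., >=cK]`` for given cuts."""
    labels = [zero_label, f">0-<{_fmt(cuts[0])}"]
    for lo, hi in zip(cuts, cuts[1:]):
        labels.append(f">={_fmt(lo)}-<{_fmt(hi)}")
    labels.append(f">={_fmt(cuts[-1])}")
    return labels


def band_bin(value: float, cuts: list[float],
             zero_label: str = "0") -> str:
    """Assign ``value`` to its band (0 | >0-<c1 | >=c1-<c2 | ... | >=cK)."""
    labels = band_labels(cuts, zero_label)
    if value == 0:
        return labels[0]
    for i, cut in enumerate(cuts):
        if value < cut:
            return labels[i + 1]
    return labels[-1]


def duration_bin(days: float, config: AnalysisConfig) -> str:
    return band_bin(days, config.duration_bins_days, "untreated")


def dose_bin(mg_per_day: float, config: AnalysisConfig) -> str:
    return band_bin(mg_per_day, config.dose_bins_mg_per_day, "0")


def ncc_duration_bin(days: float, config: AnalysisConfig) -> str:
    return band_bin(days, config.ncc_duration_bins_days, "untreated")


def ncc_cumdose_bin(mg: float, config: AnalysisConfig) -> str:
    return band_bin(mg, config.ncc_cumdose_bins_mg, "untreated")


# ---------------------------------------------------------------------------
# per-cohort computations
# ---------------------------------------------------------------------------

def _excluded_set(value) -> set[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return set()
    return set(filter(None, str(value).split(";")))


def patient_series_map(cohort: pd.DataFrame, prescriptions: pd.DataFrame,
                       config: AnalysisConfig) -> dict[str, DailySeries]:
    """DailySeries for every cohort patient (empty series if untreated)."""
    cs = prescriptions[prescriptions["drug_class"] == "CS"]
    flagged = flag_pulse_and_hdd(cs, config)
    groups = dict(tuple(cs.groupby("patient_id")))
    out = {}
    for row in cohort.itertuples(index=False):
        rx = groups.get(row.patient_id,
                        cs.iloc[0:0])
        out[row.patient_id] = daily_series(
            rx, row.entry_date, row.assessment_end,
            _excluded_set(row.excluded_months), config, flagged)
    return out


def duration_table(cohort: pd.DataFrame, prescriptions: pd.DataFrame,
                   config: AnalysisConfig,
                   series_map: dict[str, DailySeries] | None = None
                   ) -> tuple[pd.DataFrame, pd.Series]:
    """Per-patient CS duration plus the binned summary table."""
    if series_map is None:
        series_map = patient_series_map(cohort, prescriptions, config)
    durations = pd.Series({pid: cs_duration(s)
                           for pid, s in series_map.items()},
                          name="cs_duration_days")
    labels = band_labels(config.duration_bins_days, "untreated")
    binned = durations.map(lambda d: duration_bin(d, config))
    counts = binned.value_counts().reindex(labels, fill_value=0)
    n = len(durations)
    table = pd.DataFrame({
        "bin": labels,
        "n": counts.to_numpy(),
        "percent": np.round(100.0 * counts.to_numpy() / n, 2)
        if n else 0.0})
    return table, durations


def weekly_dose_grid(cohort: pd.DataFrame, prescriptions: pd.DataFrame,
                     config: AnalysisConfig,
                     series_map: dict[str, DailySeries] | None = None
                     ) -> pd.DataFrame:
    """Dose-bin counts at each grid week after CS initiation.

    Week ``w`` uses the 7-day window starting at day ``7 w`` after the
    first CS prescription (week 0 = the initial week).  A patient enters
    the week-``w`` denominator while the assessment period covers day
    ``7 w``; a window mean of 0 mg/day means no CS prescribed that week.
    """
    if series_map is None:
        series_map = patient_series_map(cohort, prescriptions, config)
    cs = prescriptions[prescriptions["drug_class"] == "CS"]
    first_cs = cs.groupby("patient_id")["date"].min()
    labels = band_labels(config.dose_bins_mg_per_day, "0")
    records = []
    for week in config.week_grid:
        counts = dict.fromkeys(labels, 0)
        denom = 0
        for pid, series in series_map.items():
            if pid not in first_cs.index:
                continue
            init = first_cs[pid].toordinal() - series.entry_day
            if init < 0 or init >= series.n_days:
                continue
            w0 = init + 7 * week
            if w0 >= series.n_days:
                continue
            window = slice(w0, min(w0 + 7, series.n_days))
            ok = series.allowed[window]
            if not ok.any():
                continue
            mean_dose = float(series.dose[window][ok].mean())
            denom += 1
            counts[dose_bin(mean_dose, config)] += 1
        for label in labels:
            records.append({
                "week": week, "bin": label, "n": counts[label],
                "denominator": denom,
                "percent": round(100.0 * counts[label] / denom, 2)
                if denom else np.nan})
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# withdrawal
# ---------------------------------------------------------------------------

def withdrawal_time(cs_rx: pd.DataFrame, assessment_end: pd.Timestamp,
                    config: AnalysisConfig) -> tuple[int, bool]:
    """(time in days since CS start, event flag) for one patient.

    Withdrawal happens at a coverage end followed by a CS-free interval
    of at least ``withdrawal_gap_days`` (to the next prescription date,
    or to the assessment end).  Time is censored at
    ``followup_cap_withdrawal_days`` and at the assessment end.
    """
    rx = cs_rx.sort_values("date", kind="stable")
    days = _day_numbers(rx["date"])
    ends = days + rx["days_supplied"].to_numpy()
    start = days[0]
    gap = config.withdrawal_gap_days
    cap = min(config.followup_cap_withdrawal_days,
              assessment_end.toordinal() - start)
    event_time = None
    run_end = ends[0]
    for i in range(1, len(rx)):
        if days[i] - run_end >= gap:
            event_time = run_end - start
            break
        run_end = max(run_end, ends[i])
    if event_time is None and \
            assessment_end.toordinal() - run_end >= gap:
        event_time = run_end - start
    if event_time is not None and event_time <= cap:
        return event_time, True
    return cap, False


def _era_of(year: int, config: AnalysisConfig) -> str | None:
    for era, (lo, hi) in config.era_years.items():
        if lo <= year <= hi:
            return era
    return None


def withdrawal_table(cohort: pd.DataFrame, prescriptions: pd.DataFrame,
                     config: AnalysisConfig) -> pd.DataFrame:
    """Per-patient withdrawal outcomes for all CS-treated patients."""
    cs = prescriptions[prescriptions["drug_class"] == "CS"]
    groups = dict(tuple(cs.groupby("patient_id")))
    rows = []
    for row in cohort.itertuples(index=False):
        rx = groups.get(row.patient_id)
        if rx is None:
            continue
        rx = rx[(rx["date"] >= row.entry_date) &
                (rx["date"] <= row.assessment_end)]
        if rx.empty:
            continue
        cs_start = rx["date"].min()
        t, event = withdrawal_time(rx, row.assessment_end, config)
        rows.append({
            "patient_id": row.patient_id,
            "cs_start": cs_start,
            "time_days": t,
            "event": event,
            "era": _era_of(cs_start.year, config)})
    return pd.DataFrame(rows, columns=["patient_id", "cs_start",
                                       "time_days", "event", "era"])
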