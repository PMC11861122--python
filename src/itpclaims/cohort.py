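"""New-user cohort selection, assessment periods, and baseline covariates.

Selection flow (each criterion is applied in order; a patient is tallied
under the first criterion it fails, so selected + tallied partitions the
input):

1. at least one non-suspected ITP diagnosis (its first date = entry date)
2. age >= 20 years at entry
3. enrollment covers the full look-back window (6 calendar months
   before the entry date)
4. no CS prescription inside the look-back window (new users only)
5. none of the configured exclusion concepts coded in the look-back

The assessment period runs from the entry date to the last day of the
last month carrying a (non-suspected) ITP code; months carrying the
pregnancy-with-ITP code are excluded from all downstream person-time.
"""

from __future__ import annotations

import pandas as pd

from itpclaims.config import AnalysisConfig, BASELINE_COMORBIDITIES
from itpclaims.io import ClaimsTables


def match_concept(codes: pd.Series, config: AnalysisConfig,
                  concept: str) -> pd.Series:
    """Boolean mask: code starts with one of the concept's prefixes."""
    prefixes = tuple(config.code_prefixes(concept))
    return codes.str.startswith(prefixes)


def _lookback_start(entry: pd.Series, months: int) -> pd.Series:
    return entry - pd.DateOffset(months=months)


def select_cohort(tables: ClaimsTables, config: AnalysisConfig
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the selection flow.

    Returns ``(cohort, exclusion_flow)`` where ``cohort`` has one row per
    selected patient (entry date, assessment period, excluded months,
    baseline covariates) and ``exclusion_flow`` tallies every input
    patient once.
    """
    patients = tables.patients
    dx = tables.diagnoses
    rx = tables.prescriptions

    n_input = len(patients)
    flow: list[tuple[str, int]] = [("patients_in_database", n_input)]

    itp_dx = dx[match_concept(dx["code"], config, "itp") & ~dx["suspected"]]
    entry = itp_dx.groupby("patient_id")["date"].min()

    df = patients.set_index("patient_id").copy()
    df["entry_date"] = entry
    has_itp = df["entry_date"].notna()
    flow.append(("no_itp_diagnosis", int((~has_itp).sum())))
    df = df[has_itp].copy()

    df["age_at_entry"] = df["entry_date"].dt.year - df["birth_year"]
    adult = df["age_at_entry"] >= config.min_age
    flow.append(("age_below_minimum", int((~adult).sum())))
    df = df[adult].copy()

    lb_start = _lookback_start(df["entry_date"], config.lookback_months)
    covered = df["observation_start"].dt.to_timestamp() <= \
        lb_start.dt.to_period("M").dt.to_timestamp()
    flow.append(("insufficient_lookback", int((~covered).sum())))
    df = df[covered].copy()
    df["lookback_start"] = _lookback_start(df["entry_date"],
                                           config.lookback_months)

    cs = rx[rx["drug_class"] == "CS"]
    cs_entry = cs["patient_id"].map(df["entry_date"])
    cs_lb = cs["patient_id"].map(df["lookback_start"])
    prevalent = cs.loc[(cs["date"] >= cs_lb) & (cs["date"] < cs_entry),
                       "patient_id"].unique()
    flow.append(("prevalent_cs_user", len(prevalent)))
    df = df.drop(index=prevalent)

    for concept in config.cohort_exclusion_concepts:
        hits = dx[match_concept(dx["code"], config, concept) &
                  ~dx["suspected"]]
        d_entry = hits["patient_id"].map(df["entry_date"])
        d_lb = hits["patient_id"].map(df["lookback_start"])
        bad = hits.loc[(hits["date"] >= d_lb) & (hits["date"] <= d_entry),
                       "patient_id"].unique()
        flow.append((f"exclusion_code_{concept}", len(bad)))
        df = df.drop(index=bad)

    flow.append(("selected", len(df)))

    # -- assessment period -------------------------------------------------
    kept_itp = itp_dx[itp_dx["patient_id"].isin(df.index)]
    last_month = kept_itp.groupby("patient_id")["date"].max().dt.to_period(
        "M")
    df["assessment_end"] = last_month.dt.to_timestamp(how="end").dt.normalize()

    preg = dx[match_concept(dx["code"], config, "pregnancy_itp") &
              dx["patient_id"].isin(df.index)]
    excl = preg.assign(month=preg["date"].dt.to_period("M").astype(str)) \
        .groupby("patient_id")["month"] \
        .apply(lambda m: ";".join(sorted(set(m))))
    df["excluded_months"] = excl.reindex(df.index).fillna("")

    # -- baseline covariates ----------------------------------------------
    entry_dx = dx.merge(df["entry_date"], left_on="patient_id",
                        right_index=True)
    at_entry = entry_dx[(entry_dx["date"] == entry_dx["entry_date"]) &
                        match_concept(entry_dx["code"], config, "itp")]
    inpatient = at_entry.groupby("patient_id")["inpatient"].any()
    df["inpatient_at_entry"] = inpatient.reindex(df.index,
                                                 fill_value=False)

    win = dx.merge(df[["entry_date", "lookback_start"]],
                   left_on="patient_id", right_index=True)
    win = win[~win["suspected"] & (win["date"] >= win["lookback_start"]) &
              (win["date"] <= win["entry_date"])]
    for concept in BASELINE_COMORBIDITIES:
        if concept not in config.code_lists:
            continue
        flag = win.loc[match_concept(win["code"], config, concept),
                       "patient_id"].unique()
        df[f"comorbid_{concept}"] = df.index.isin(flag)

    cohort = df.reset_index()[
        ["patient_id", "gender", "birth_year", "entry_date",
         "age_at_entry", "lookback_start", "assessment_end",
         "excluded_months", "inpatient_at_entry"] +
        [c for c in df.columns if c.startswith("comorbid_")] +
        ["observation_start", "observation_end"]]
    exclusion_flow = pd.DataFrame(flow, columns=["criterion", "n"])
    return cohort, exclusion_flow


def assessment_period(cohort_row: pd.Series
                      ) -> tuple[pd.Timestamp, pd.Timestamp, set[str]]:
    """(entry_date, assessment_end, excluded YYYY-MM months) of a patient."""
    months = set(filter(None, str(cohort_row["excluded_months"] or
                                  "").split(";")))
    return cohort_row["entry_date"], cohort_row["assessment_end"], months


def baseline_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Long-format baseline summary (counts, percentages, age statistics)."""
    if cohort.empty:
        raise ValueError("baseline_table requires a non-empty cohort")
    n = len(cohort)
    rows: list[dict] = [{"section": "all", "item": "patients",
                         "n": n, "percent": 100.0}]
    for level in ("female", "male"):
        k = int((cohort["gender"] == level).sum())
        rows.append({"section": "gender", "item": level, "n": k,
                     "percent": round(100.0 * k / n, 2)})
    age = cohort["age_at_entry"]
    for stat, value in [("mean", age.mean()), ("sd", age.std(ddof=1)),
                        ("median", age.median()),
                        ("q1", age.quantile(0.25)),
                        ("q3", age.quantile(0.75)),
                        ("min", age.min()), ("max", age.max())]:
        rows.append({"section": "age", "item": stat, "n": None,
                     "percent": None, "value": float(value)})
    for level, mask in [("inpatient", cohort["inpatient_at_entry"]),
                        ("outpatient", ~cohort["inpatient_at_entry"])]:
        k = int(mask.sum())
        rows.append({"section": "inpatient_status", "item": level, "n": k,
                     "percent": round(100.0 * k / n, 2)})
    for col in sorted(c for c in cohort.columns
                      if c.startswith("comorbid_")):
        k = int(cohort[col].sum())
        rows.append({"section": "comorbidity",
                     "item": col.removeprefix("comorbid_"), "n": k,
                     "percent": round(100.0 * k / n, 2)})
    return pd.DataFrame(rows)
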