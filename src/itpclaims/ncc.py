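"""Nested case-control analysis by risk-set sampling.

For each adverse outcome: ascertain the first post-entry event, wash out
patients with the outcome coded in the look-back window, sample up to
``matching_ratio`` controls per case from the risk set at the case's
event time (time since cohort entry; future cases may serve as controls
and controls may be reused across sets), code CS exposure up to the
event time, and estimate odds ratios by matched-set (conditional)
logistic regression maximised with Newton iterations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from itpclaims.config import AnalysisConfig, ConfigError
from itpclaims.cohort import match_concept
from itpclaims.exposure import (DailySeries, cs_duration, cumulative_dose,
                                band_labels, ncc_cumdose_bin,
                                ncc_duration_bin, patient_series_map)

log = logging.getLogger(__name__)


class SeparationError(RuntimeError):
    """The conditional likelihood is monotone in some coefficient."""


class ConvergenceError(RuntimeError):
    """Newton iterations failed to converge."""


class NoInformationError(RuntimeError):
    """A covariate has no within-set variation in any matched set."""


# ---------------------------------------------------------------------------
# outcome ascertainment
# ---------------------------------------------------------------------------

def ascertain_outcome(cohort: pd.DataFrame, diagnoses: pd.DataFrame,
                      config: AnalysisConfig, outcome: str) -> pd.DataFrame:
    """First post-entry event time per patient, with look-back washout.

    Returns one row per cohort patient: ``event_day`` (days since entry,
    NaN when event-free), ``at_risk`` (False when the washout concept is
    coded in the look-back window), and ``followup_days`` (entry to end
    of observation).
    """
    event_concept, washout_concept = config.outcomes[outcome]
    dx = diagnoses[~diagnoses["suspected"]]
    hits = dx[match_concept(dx["code"], config, event_concept)]
    merged = hits.merge(
        cohort[["patient_id", "entry_date", "lookback_start"]],
        on="patient_id")
    events = merged[merged["date"] > merged["entry_date"]]
    first = events.groupby("patient_id").agg(
        first_date=("date", "min"), entry=("entry_date", "first"))
    event_day = (first["first_date"] - first["entry"]).dt.days

    wash_hits = dx[match_concept(dx["code"], config, washout_concept)]
    wash = wash_hits.merge(
        cohort[["patient_id", "entry_date", "lookback_start"]],
        on="patient_id")
    washed = wash.loc[(wash["date"] >= wash["lookback_start"]) &
                      (wash["date"] <= wash["entry_date"]),
                      "patient_id"].unique()

    out = cohort[["patient_id", "entry_date"]].copy()
    obs_end = cohort["observation_end"].dt.to_timestamp(how="end") \
        .dt.normalize()
    out["followup_days"] = (obs_end.to_numpy() -
                            cohort["entry_date"].to_numpy()
                            ).astype("timedelta64[D]").astype(int)
    out["event_day"] = out["patient_id"].map(event_day)
    out["at_risk"] = ~out["patient_id"].isin(washed)
    return out


# ---------------------------------------------------------------------------
# risk-set sampling
# ---------------------------------------------------------------------------

def sample_risk_sets(ascertained: pd.DataFrame, ratio: int,
                     seed: int) -> pd.DataFrame:
    """Incidence-density sample up to ``ratio`` controls per case.

    Controls are drawn, without replacement within a set, from patients
    still at risk at the case's event time on the time-since-entry
    clock; a control may be reused across sets and a future case may
    serve as a control.  Cases with no eligible control are dropped.
    Sampling is reproducible under a fixed seed and independent of the
    input row order.
    """
    if ratio < 1:
        raise ConfigError("matching_ratio must be >= 1")
    pool = ascertained[ascertained["at_risk"]] \
        .sort_values("patient_id", kind="stable").reset_index(drop=True)
    pids = pool["patient_id"].to_numpy()
    event = pool["event_day"].to_numpy(dtype=float)
    event_or_inf = np.where(np.isnan(event), np.inf, event)
    followup = pool["followup_days"].to_numpy(dtype=float)

    cases = pool[pool["event_day"].notna()].sort_values(
        ["event_day", "patient_id"], kind="stable")
    rng = np.random.default_rng(seed)
    rows = []
    set_id = 0
    n_dropped = 0
    for case_pos, case_pid, t in zip(cases.index, cases["patient_id"],
                                     cases["event_day"]):
        eligible = (followup >= t) & (event_or_inf > t)
        eligible[case_pos] = False
        idx = np.flatnonzero(eligible)
        if len(idx) == 0:
            n_dropped += 1
            continue
        take = min(ratio, len(idx))
        chosen = idx if len(idx) <= ratio else \
            rng.choice(idx, size=take, replace=False)
        set_id += 1
        rows.append((set_id, case_pid, True, float(t)))
        for j in sorted(chosen):
            rows.append((set_id, pids[j], False, float(t)))
    if n_dropped:
        log.info("risk-set sampling: %d case(s) dropped with no eligible "
                 "control", n_dropped)
    return pd.DataFrame(rows, columns=["set_id", "patient_id", "is_case",
                                       "event_time"])


# ---------------------------------------------------------------------------
# exposure coding
# ---------------------------------------------------------------------------

def code_exposure(sets: pd.DataFrame, series_map: dict[str, DailySeries],
                  config: AnalysisConfig) -> pd.DataFrame:
    """Attach presence/duration/cumulative-dose exposure categories,
    truncated at each member's matched event time."""
    out = sets.copy()
    presence, duration_cat, cumdose_cat = [], [], []
    for pid, t in zip(out["patient_id"], out["event_time"]):
        series = series_map[pid]
        days = cs_duration(series, up_to=int(t))
        mg = cumulative_dose(series, up_to=int(t))
        presence.append(days > 0)
        duration_cat.append(ncc_duration_bin(days, config))
        cumdose_cat.append(ncc_cumdose_bin(mg, config))
    out["cs_presence"] = presence
    out["cs_duration_cat"] = duration_cat
    out["cs_cumdose_cat"] = cumdose_cat
    return out


def code_presence_fast(sets: pd.DataFrame, cohort: pd.DataFrame,
                       prescriptions: pd.DataFrame) -> pd.DataFrame:
    """Presence-only exposure coding without day-level series.

    Presence at matched time t = any CS prescription dated on or after
    entry and strictly before entry + t days.
    """
    cs = prescriptions[prescriptions["drug_class"] == "CS"]
    first_cs = cs.groupby("patient_id")["date"].min()
    entry = cohort.set_index("patient_id")["entry_date"]
    offset = (first_cs - entry.reindex(first_cs.index)).dt.days
    out = sets.copy()
    member_offset = out["patient_id"].map(offset)
    out["cs_presence"] = member_offset.notna() & \
        (member_offset < out["event_time"])
    return out


def attach_covariates(sets: pd.DataFrame,
                      cohort: pd.DataFrame) -> pd.DataFrame:
    """Merge the adjustment covariates onto matched-set members."""
    cov = pd.DataFrame({
        "patient_id": cohort["patient_id"],
        "male": (cohort["gender"] == "male").astype(float),
        "age": cohort["age_at_entry"].astype(float),
        "malignancy": cohort.get(
            "comorbid_malignancy",
            pd.Series(False, index=cohort.index)).astype(float),
        "pulmonary_disease": cohort.get(
            "comorbid_pulmonary_disease",
            pd.Series(False, index=cohort.index)).astype(float),
        "liver_disease": cohort.get(
            "comorbid_liver_disease",
            pd.Series(False, index=cohort.index)).astype(float),
    })
    return sets.merge(cov, on="patient_id", how="left")


# ---------------------------------------------------------------------------
# conditional logistic regression
# ---------------------------------------------------------------------------

@dataclass
class ClogitFit:
    """Matched-set conditional logistic fit (one case per set)."""

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    n_sets: int
    n_iter: int

    @property
    def odds_ratio(self) -> np.ndarray:
        return np.exp(self.beta)

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        z = stats.norm.ppf(0.5 + level / 2)
        return np.exp(np.c_[self.beta - z * self.se,
                            self.beta + z * self.se])

    @property
    def p_values(self) -> np.ndarray:
        z = self.beta / self.se
        return 2 * stats.norm.sf(np.abs(z))

    def summary(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame({
            "term": self.names, "coef": self.beta,
            "odds_ratio": self.odds_ratio,
            "ci_low": ci[:, 0], "ci_high": ci[:, 1],
            "p": self.p_values, "se": self.se})


def conditional_logistic(X: pd.DataFrame, is_case, set_ids,
                         max_iter: int = 60,
                         tol: float = 1e-10) -> ClogitFit:
    """Maximise the matched-set conditional likelihood by Newton steps.

    ``X`` holds one row per set member; ``is_case`` marks exactly one
    case per set.  Raises :class:`NoInformationError` when a column has
    no within-set variation, :class:`SeparationError` on monotone
    likelihood, and :class:`ConvergenceError` when Newton fails.
    """
    names = list(X.columns)
    order = np.argsort(np.asarray(set_ids), kind="stable")
    Xs = np.asarray(X, dtype=float)[order]
    ys = np.asarray(is_case, dtype=bool)[order]
    sids = np.asarray(set_ids)[order]
    starts = np.flatnonzero(np.r_[True, sids[1:] != sids[:-1]])
    counts = np.diff(np.r_[starts, len(sids)])
    set_pos = np.repeat(np.arange(len(starts)), counts)
    if not np.all(np.add.reduceat(ys.astype(int), starts) == 1):
        raise ValueError("each matched set must contain exactly one case")

    # within-set centring to detect uninformative columns
    set_means = np.add.reduceat(Xs, starts, axis=0) / counts[:, None]
    centred = Xs - set_means[set_pos]
    dead = np.abs(centred).max(axis=0) < 1e-12
    if dead.any():
        raise NoInformationError(
            "no within-set variation for "
            f"{[n for n, d in zip(names, dead) if d]}; the conditional "
            "likelihood carries no information on these terms")

    k = Xs.shape[1]
    beta = np.zeros(k)
    ll_old = -np.inf
    for it in range(1, max_iter + 1):
        eta = Xs @ beta
        mx = np.maximum.reduceat(eta, starts)
        w = np.exp(eta - mx[set_pos])
        denom = np.add.reduceat(w, starts)
        p = w / denom[set_pos]
        ll = float(eta[ys].sum() - (np.log(denom) + mx).sum())
        grad = Xs[ys].sum(axis=0) - (p[:, None] * Xs).sum(axis=0)
        S1 = np.add.reduceat(p[:, None] * Xs, starts, axis=0)
        info = (Xs * p[:, None]).T @ Xs - S1.T @ S1   # observed information
        if np.abs(grad).max() < tol and ll - ll_old < 1e-12:
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            raise SeparationError(
                "singular information matrix; likely complete separation "
                f"in one of {names}") from None
        # step-halving safeguard
        factor = 1.0
        while factor > 1e-4:
            cand = beta + factor * step
            eta_c = Xs @ cand
            mx_c = np.maximum.reduceat(eta_c, starts)
            w_c = np.exp(eta_c - mx_c[set_pos])
            ll_c = float(eta_c[ys].sum() -
                         (np.log(np.add.reduceat(w_c, starts)) + mx_c).sum())
            if ll_c >= ll - 1e-12:
                break
            factor /= 2
        beta = beta + factor * step
        ll_old = ll
        if np.abs(beta).max() > 15:
            worst = names[int(np.abs(beta).argmax())]
            raise SeparationError(
                f"coefficient for {worst!r} diverging "
                f"(|beta| > 15): complete separation")
    else:
        raise ConvergenceError(
            f"Newton did not converge in {max_iter} iterations "
            f"(gradient norm {np.abs(grad).max():.3e})")

    eta = Xs @ beta
    mx = np.maximum.reduceat(eta, starts)
    w = np.exp(eta - mx[set_pos])
    denom = np.add.reduceat(w, starts)
    p = w / denom[set_pos]
    ll = float(eta[ys].sum() - (np.log(denom) + mx).sum())
    S1 = np.add.reduceat(p[:, None] * Xs, starts, axis=0)
    info = (Xs * p[:, None]).T @ Xs - S1.T @ S1
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    return ClogitFit(names=names, beta=beta, se=se, loglik=ll,
                     n_sets=len(starts), n_iter=it)


def crude_or(a: float, b: float, c: float, d: float,
             continuity: bool = False) -> tuple[float, tuple[float, float]]:
    """Cross-product odds ratio ``(a d)/(b c)`` with Woolf 95% CI.

    a = exposed cases, b = exposed controls, c = unexposed cases,
    d = unexposed controls.  A zero margin requires ``continuity`` (adds
    0.5 to every cell).
    """
    cells = np.array([a, b, c, d], dtype=float)
    if (cells < 0).any():
        raise ValueError("counts must be non-negative")
    if (cells == 0).any():
        if not continuity:
            raise ValueError("zero cell; enable the continuity correction")
        cells = cells + 0.5
    a, b, c, d = cells
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.975)
    lo, hi = np.exp(np.log(or_) - z * se), np.exp(np.log(or_) + z * se)
    return float(or_), (float(lo), float(hi))


# ---------------------------------------------------------------------------
# full per-outcome pipeline
# ---------------------------------------------------------------------------

_CODING_COLUMNS = {"presence": "cs_presence",
                   "duration": "cs_duration_cat",
                   "cumdose": "cs_cumdose_cat"}


def _exposure_design(members: pd.DataFrame, coding: str,
                     config: AnalysisConfig) -> pd.DataFrame:
    if coding == "presence":
        return pd.DataFrame({"cs_yes":
                             members["cs_presence"].astype(float)})
    cuts = config.ncc_duration_bins_days if coding == "duration" \
        else config.ncc_cumdose_bins_mg
    levels = band_labels(cuts, "untreated")[1:]
    col = _CODING_COLUMNS[coding]
    return pd.DataFrame({f"{coding}[{lev}]":
                         (members[col] == lev).astype(float)
                         for lev in levels})


def run_all_outcomes(cohort: pd.DataFrame, diagnoses: pd.DataFrame,
                     prescriptions: pd.DataFrame, config: AnalysisConfig,
                     seed: int | None = None,
                     codings: tuple[str, ...] = ("presence", "duration",
                                                 "cumdose"),
                     models: tuple[str, ...] = ("univariate",
                                                "multivariate"),
                     ) -> dict[str, pd.DataFrame]:
    """NCC estimation for every configured outcome.

    Returns ``incidence``, ``matched_sets`` and ``results`` tables.
    Outcomes with fewer matched cases than ``config.min_cases`` are
    skipped with a logged reason.
    """
    seed = config.rng_seed if seed is None else seed
    need_series = any(c in codings for c in ("duration", "cumdose"))
    series_map = patient_series_map(cohort, prescriptions, config) \
        if need_series else None
    incidence_rows, set_frames, result_rows = [], [], []
    for outcome in config.outcomes:
        asc = ascertain_outcome(cohort, diagnoses, config, outcome)
        sets = sample_risk_sets(asc, config.matching_ratio, seed)
        n_at_risk = int(asc["at_risk"].sum())
        n_cases = int(sets["is_case"].sum())
        incidence_rows.append({
            "outcome": outcome, "n_at_risk": n_at_risk,
            "n_cases": n_cases,
            "incidence_percent": round(100.0 * n_cases / n_at_risk, 2)
            if n_at_risk else np.nan})
        if n_cases < config.min_cases:
            log.info("outcome %s skipped: insufficient cases "
                     "(%d < %d)", outcome, n_cases, config.min_cases)
            continue
        if need_series:
            members = code_exposure(sets, series_map, config)
        else:
            members = code_presence_fast(sets, cohort, prescriptions)
        members = attach_covariates(members, cohort)
        members.insert(0, "outcome", outcome)
        set_frames.append(members)
        for coding in codings:
            X_exp = _exposure_design(members, coding, config)
            for model in models:
                X = X_exp.copy()
                if model == "multivariate":
                    for cov in ("male", "age", "malignancy",
                                "pulmonary_disease", "liver_disease"):
                        X[cov] = members[cov].to_numpy()
                try:
                    fit = conditional_logistic(
                        X, members["is_case"], members["set_id"])
                except (SeparationError, NoInformationError,
                        ConvergenceError) as exc:
                    log.warning("outcome %s, %s %s: %s", outcome, coding,
                                model, exc)
                    continue
                summary = fit.summary()
                for _, r in summary.iterrows():
                    if model == "multivariate" and \
                            r["term"] in ("male", "age", "malignancy",
                                          "pulmonary_disease",
                                          "liver_disease"):
                        continue
                    result_rows.append({
                        "outcome": outcome, "coding": coding,
                        "model": model, "term": r["term"],
                        "n_cases": n_cases,
                        "n_controls": int((~members["is_case"]).sum()),
                        "odds_ratio": r["odds_ratio"],
                        "ci_low": r["ci_low"], "ci_high": r["ci_high"],
                        "p": r["p"]})
    return {
        "incidence": pd.DataFrame(incidence_rows),
        "matched_sets": pd.concat(set_frames, ignore_index=True)
        if set_frames else pd.DataFrame(),
        "results": pd.DataFrame(result_rows),
    }
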