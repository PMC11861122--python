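import numpy as np
import pandas as pd
import pytest

from itpclaims import ncc as N
from itpclaims.config import AnalysisConfig, ConfigError
from itpclaims.exposure import patient_series_map


# ---------------------------------------------------------------------------
# ascertainment
# ---------------------------------------------------------------------------

def test_ascertain_fixture_infection(cohort, tables, config):
    asc = N.ascertain_outcome(cohort, tables.diagnoses, config,
                              "infection")
    idx = asc.set_index("patient_id")
    # P16: infection coded 2019-09-01, entry 2019-05-01 -> day 123
    assert idx.loc["P16", "event_day"] == 123
    assert idx.loc["P16", "at_risk"]
    # P17 has the code in the look-back: washed out
    assert not idx.loc["P17", "at_risk"]
    # untreated patients without the code are at risk, event-free
    assert idx.loc["P02", "at_risk"]
    assert np.isnan(idx.loc["P02", "event_day"])


def test_washout_removes_lookback_diabetes(cohort, tables, config):
    asc = N.ascertain_outcome(cohort, tables.diagnoses, config,
                              "diabetes")
    idx = asc.set_index("patient_id")
    assert not idx.loc["P20", "at_risk"]    # E11 coded 2018-05-01


# ---------------------------------------------------------------------------
# risk-set sampling
# ---------------------------------------------------------------------------

def make_ascertained(n=30, event=(), followup=2000):
    rows = []
    for i in range(n):
        pid = f"S{i:02d}"
        rows.append({"patient_id": pid,
                     "entry_date": pd.Timestamp("2018-01-01"),
                     "followup_days": followup,
                     "event_day": dict(event).get(pid, np.nan),
                     "at_risk": True})
    return pd.DataFrame(rows)


def test_sampling_ratio_capped_and_reproducible():
    asc = make_ascertained(event=[("S00", 100.0)])
    a = N.sample_risk_sets(asc, 5, seed=9)
    b = N.sample_risk_sets(asc, 5, seed=9)
    assert len(a[~a["is_case"]]) == 5
    pd.testing.assert_frame_equal(a, b)
    c = N.sample_risk_sets(asc, 5, seed=10)
    assert not a.equals(c)


def test_sampling_order_independent():
    asc = make_ascertained(event=[("S00", 100.0), ("S07", 60.0)])
    a = N.sample_risk_sets(asc, 3, seed=4)
    b = N.sample_risk_sets(asc.sample(frac=1, random_state=1), 3, seed=4)
    pd.testing.assert_frame_equal(a.reset_index(drop=True),
                                  b.reset_index(drop=True))


def test_future_case_can_be_control():
    # two cases; S01's event (day 500) is after S00's (day 100)
    asc = make_ascertained(n=2, event=[("S00", 100.0), ("S01", 500.0)])
    sets = N.sample_risk_sets(asc, 5, seed=0)
    s0 = sets[sets["event_time"] == 100.0]
    assert "S01" in set(s0.loc[~s0["is_case"], "patient_id"])


def test_case_with_no_eligible_control_dropped():
    asc = make_ascertained(n=2, event=[("S00", 100.0)], followup=50)
    asc.loc[asc["patient_id"] == "S00", "followup_days"] = 2000
    sets = N.sample_risk_sets(asc, 5, seed=0)
    assert sets.empty


def test_controls_at_risk_at_event_time(cohort, tables, config):
    asc = N.ascertain_outcome(cohort, tables.diagnoses, config,
                              "infection")
    sets = N.sample_risk_sets(asc, config.matching_ratio, seed=1)
    idx = asc.set_index("patient_id")
    for _, row in sets[~sets["is_case"]].iterrows():
        member = idx.loc[row["patient_id"]]
        assert member["followup_days"] >= row["event_time"]
        assert np.isnan(member["event_day"]) or \
            member["event_day"] > row["event_time"]
        assert member["at_risk"]


def test_invalid_ratio_rejected():
    with pytest.raises(ConfigError):
        N.sample_risk_sets(make_ascertained(), 0, seed=0)


# ---------------------------------------------------------------------------
# exposure coding
# ---------------------------------------------------------------------------

def test_code_exposure_fixture(cohort, tables, config):
    asc = N.ascertain_outcome(cohort, tables.diagnoses, config,
                              "infection")
    sets = N.sample_risk_sets(asc, 5, seed=1)
    series_map = patient_series_map(cohort, tables.prescriptions, config)
    coded = N.code_exposure(sets, series_map, config)
    case = coded[coded["is_case"]].iloc[0]
    # P16: 30 covered days before day 123, 900 mg cumulative
    assert case["patient_id"] == "P16"
    assert case["cs_presence"]
    assert case["cs_duration_cat"] == ">=15-<60"
    assert case["cs_cumdose_cat"] == ">=500-<1500"
    untreated = coded[coded["patient_id"] == "P02"]
    if len(untreated):
        assert (untreated["cs_duration_cat"] == "untreated").all()


def test_presence_fast_agrees_with_series(cohort, tables, config):
    asc = N.ascertain_outcome(cohort, tables.diagnoses, config,
                              "infection")
    sets = N.sample_risk_sets(asc, 5, seed=1)
    series_map = patient_series_map(cohort, tables.prescriptions, config)
    slow = N.code_exposure(sets, series_map, config)
    fast = N.code_presence_fast(sets, cohort, tables.prescriptions)
    assert (slow["cs_presence"].to_numpy() ==
            fast["cs_presence"].to_numpy()).all()


# ---------------------------------------------------------------------------
# conditional logistic
# ---------------------------------------------------------------------------

def pair_sets(n10, n01, n11=0, n00=0):
    """1:1 matched pairs with given discordance counts."""
    rows = []
    sid = 0
    for (case_x, ctrl_x), count in [((1, 0), n10), ((0, 1), n01),
                                    ((1, 1), n11), ((0, 0), n00)]:
        for _ in range(count):
            sid += 1
            rows.append((sid, True, case_x))
            rows.append((sid, False, ctrl_x))
    df = pd.DataFrame(rows, columns=["set_id", "is_case", "x"])
    return df


def test_mcnemar_closed_form():
    df = pair_sets(n10=12, n01=6)
    fit = N.conditional_logistic(df[["x"]], df["is_case"], df["set_id"])
    assert fit.odds_ratio[0] == pytest.approx(2.0, abs=1e-8)


def test_mcnemar_with_concordant_pairs_unchanged():
    df = pair_sets(n10=12, n01=6, n11=5, n00=7)
    fit = N.conditional_logistic(df[["x"]], df["is_case"], df["set_id"])
    assert fit.odds_ratio[0] == pytest.approx(2.0, abs=1e-8)


def test_no_within_set_variation_flagged():
    df = pair_sets(n10=0, n01=0, n11=10, n00=10)
    with pytest.raises(N.NoInformationError, match="x"):
        N.conditional_logistic(df[["x"]], df["is_case"], df["set_id"])


def test_complete_separation_detected():
    df = pair_sets(n10=20, n01=0)
    with pytest.raises(N.SeparationError):
        N.conditional_logistic(df[["x"]], df["is_case"], df["set_id"])


def test_multiple_cases_per_set_rejected():
    df = pair_sets(n10=3, n01=2)
    df.loc[1, "is_case"] = True
    with pytest.raises(ValueError, match="exactly one case"):
        N.conditional_logistic(df[["x"]], df["is_case"], df["set_id"])


def test_clogit_matches_statsmodels():
    # independent route: statsmodels ConditionalLogit on 1:3 sets
    import statsmodels.api as sm
    rng = np.random.default_rng(21)
    rows = []
    for sid in range(80):
        xs = rng.random(4) < 0.4
        case = int(rng.integers(0, 4))
        for j, x in enumerate(xs):
            rows.append((sid, j == case, float(x), rng.random()))
    df = pd.DataFrame(rows, columns=["set_id", "is_case", "x", "z"])
    fit = N.conditional_logistic(df[["x", "z"]], df["is_case"],
                                 df["set_id"])
    ref = sm.ConditionalLogit(
        df["is_case"].astype(int), df[["x", "z"]],
        groups=df["set_id"]).fit(disp=0, method="newton", tol=1e-12)
    assert fit.beta == pytest.approx(ref.params.to_numpy(), abs=1e-6)
    assert fit.se == pytest.approx(ref.bse.to_numpy(), abs=1e-6)


def test_clogit_order_invariant():
    df = pair_sets(n10=12, n01=6, n11=3)
    perm = df.sample(frac=1, random_state=2)
    a = N.conditional_logistic(df[["x"]], df["is_case"], df["set_id"])
    b = N.conditional_logistic(perm[["x"]], perm["is_case"],
                               perm["set_id"])
    assert a.beta == pytest.approx(b.beta, abs=1e-10)


# ---------------------------------------------------------------------------
# crude OR
# ---------------------------------------------------------------------------

def test_crude_or_published_counts_infection():
    or_, _ = N.crude_or(290, 735, 290, 2165)
    assert or_ == pytest.approx(2.946, abs=1e-3)


def test_crude_or_published_counts_diabetes():
    or_, _ = N.crude_or(91, 192, 21, 368)
    assert or_ == pytest.approx(8.306, abs=1e-3)


def test_crude_or_symmetry():
    or_, (lo, hi) = N.crude_or(7, 7, 7, 7)
    assert or_ == 1.0
    assert lo < 1.0 < hi


def test_crude_or_zero_margin():
    with pytest.raises(ValueError, match="continuity"):
        N.crude_or(0, 5, 5, 5)
    or_, _ = N.crude_or(0, 5, 5, 5, continuity=True)
    assert or_ > 0


# ---------------------------------------------------------------------------
# full outcome pipeline
# ---------------------------------------------------------------------------

def test_run_all_outcomes_min_cases_skip(cohort, tables, config, caplog):
    with caplog.at_level("INFO", logger="itpclaims.ncc"):
        res = N.run_all_outcomes(cohort, tables.diagnoses,
                                 tables.prescriptions, config, seed=1)
    assert "insufficient cases" in caplog.text
    assert res["results"].empty
    inc = res["incidence"].set_index("outcome")
    assert inc.loc["infection", "n_cases"] == 1
    assert inc.loc["infection", "n_at_risk"] == 14   # P17 washed out


def test_run_all_outcomes_small_min_cases(cohort, tables, config):
    cfg = AnalysisConfig(min_cases=1)
    res = N.run_all_outcomes(cohort, tables.diagnoses,
                             tables.prescriptions, cfg, seed=1)
    sets = res["matched_sets"]
    inf = sets[sets["outcome"] == "infection"]
    assert inf.loc[inf["is_case"], "patient_id"].iloc[0] == "P16"
    assert "P17" not in set(inf["patient_id"])
    assert len(inf[~inf["is_case"]]) == 5
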