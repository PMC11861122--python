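"""Treatment patterns: yearly modality counts, states, switches, lines.

States are derived by sweeping episode boundaries: every maximal
interval with a constant set of active treatments is one state
(splenectomy enters the active set for a configured window after the
procedure).  Switch sequences collapse consecutive duplicate state
labels; rare full patterns are pooled into ``Others2``.  Treatment lines
use a start-window rule: all classes starting within the combo window of
a line's first start form one regimen, and a class outside the current
regimen starting later opens the next line.
"""

from __future__ import annotations

import json
from collections import Counter

import pandas as pd

from itpclaims.config import AnalysisConfig

#: canonical ordering of state/regimen members
CLASS_ORDER = ["CS", "EPAG", "ROMI", "RTX", "Splenectomy", "Others1"]

_CLASS_LABEL = {"CS": "CS", "EPAG": "EPAG", "ROMI": "ROMI", "RTX": "RTX",
                "OTHER_IS": "Others1"}


def _label(active: frozenset[str]) -> str:
    return "|".join(c for c in CLASS_ORDER if c in active)


def _treatment_intervals(episodes: pd.DataFrame, procedures: pd.DataFrame,
                         config: AnalysisConfig) -> pd.DataFrame:
    """Episodes plus splenectomy pseudo-episodes as (label, day) intervals."""
    iv = pd.DataFrame({
        "patient_id": episodes["patient_id"],
        "label": episodes["drug_class"].map(_CLASS_LABEL),
        "start_day": episodes["start"].map(pd.Timestamp.toordinal),
        "end_exclusive_day": episodes["end_exclusive"].map(
            pd.Timestamp.toordinal),
    })
    spl = procedures[procedures["procedure"] == "splenectomy"]
    if len(spl):
        days = spl["date"].map(pd.Timestamp.toordinal)
        iv = pd.concat([iv, pd.DataFrame({
            "patient_id": spl["patient_id"],
            "label": "Splenectomy",
            "start_day": days,
            "end_exclusive_day": days + config.splenectomy_state_days,
        })], ignore_index=True)
    return iv


def yearly_modality_counts(prescriptions: pd.DataFrame,
                           procedures: pd.DataFrame,
                           config: AnalysisConfig) -> pd.DataFrame:
    """Distinct treated patients per modality per calendar year.

    Repeat prescriptions within a year count once; the percentage
    denominator is the number of patients with any ITP treatment that
    year.
    """
    y0, y1 = config.pattern_years
    rx = prescriptions.assign(
        year=prescriptions["date"].dt.year,
        modality=prescriptions["drug_class"].map(_CLASS_LABEL))
    spl = procedures[procedures["procedure"] == "splenectomy"]
    frames = [rx[["patient_id", "year", "modality"]]]
    if len(spl):
        spl = spl.assign(year=spl["date"].dt.year, modality="Splenectomy")
        frames.append(spl[["patient_id", "year", "modality"]])
    ev = pd.concat(frames, ignore_index=True)
    ev = ev[(ev["year"] >= y0) & (ev["year"] <= y1)]
    tpo = ev[ev["modality"].isin(["EPAG", "ROMI"])].assign(modality="TPO-RA")
    ev = pd.concat([ev, tpo], ignore_index=True)
    rows = []
    for year, group in ev.groupby("year"):
        denom = group.loc[group["modality"] != "TPO-RA",
                          "patient_id"].nunique()
        for modality, sub in group.groupby("modality"):
            n = sub["patient_id"].nunique()
            rows.append({"year": int(year), "modality": modality, "n": n,
                         "denominator": denom,
                         "percent": round(100.0 * n / denom, 2)})
    return pd.DataFrame(rows)


def derive_states(episodes: pd.DataFrame, procedures: pd.DataFrame,
                  config: AnalysisConfig) -> pd.DataFrame:
    """Maximal constant-active-set intervals per patient."""
    iv = _treatment_intervals(episodes, procedures, config)
    rows = []
    for pid, group in iv.groupby("patient_id", sort=True):
        bounds = sorted(set(group["start_day"]) |
                        set(group["end_exclusive_day"]))
        pending: tuple[frozenset, int, int] | None = None
        for lo, hi in zip(bounds, bounds[1:]):
            active = frozenset(
                group.loc[(group["start_day"] <= lo) &
                          (group["end_exclusive_day"] > lo), "label"])
            if not active:
                if pending:
                    rows.append((pid, *pending[1:], _label(pending[0])))
                    pending = None
                continue
            if pending and pending[0] == active and pending[2] == lo:
                pending = (active, pending[1], hi)
            else:
                if pending:
                    rows.append((pid, *pending[1:], _label(pending[0])))
                pending = (active, lo, hi)
        if pending:
            rows.append((pid, *pending[1:], _label(pending[0])))
    out = pd.DataFrame(rows, columns=["patient_id", "start_day",
                                      "end_exclusive_day", "label"])
    out["start"] = out["start_day"].map(pd.Timestamp.fromordinal)
    out["end"] = (out["end_exclusive_day"] - 1).map(pd.Timestamp.fromordinal)
    return out[["patient_id", "start", "end", "label", "start_day",
                "end_exclusive_day"]]


def switch_sequence(states: pd.DataFrame, config: AnalysisConfig
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-patient ordered state labels and the population flow table.

    Consecutive duplicate labels collapse; sequences are truncated after
    ``max_switches`` switches; full patterns occurring fewer than
    ``min_pattern_n`` times are relabelled ``Others2`` at every position.
    """
    seqs: dict[str, list[str]] = {}
    for pid, group in states.sort_values(
            ["patient_id", "start_day"]).groupby("patient_id", sort=True):
        labels = []
        for lab in group["label"]:
            if not labels or labels[-1] != lab:
                labels.append(lab)
        seqs[pid] = labels[:config.max_switches + 1]
    pattern_counts = Counter(tuple(s) for s in seqs.values())
    rows = []
    for pid, seq in seqs.items():
        rare = pattern_counts[tuple(seq)] < config.min_pattern_n
        shown = ["Others2"] * len(seq) if rare else seq
        rows.append({"patient_id": pid,
                     "sequence": ">".join(seq),
                     "shown_sequence": ">".join(shown),
                     "n_switches": len(seq) - 1,
                     "pooled": rare})
    seq_df = pd.DataFrame(rows)
    flow_counts: Counter = Counter()
    for row in rows:
        shown = row["shown_sequence"].split(">")
        for i in range(len(shown) - 1):
            flow_counts[(i, shown[i], shown[i + 1])] += 1
    flows = pd.DataFrame(
        [{"switch_index": i, "source": a, "target": b, "n": n}
         for (i, a, b), n in sorted(flow_counts.items())],
        columns=["switch_index", "source", "target", "n"])
    return seq_df, flows


def sankey_export(flows: pd.DataFrame) -> dict:
    """Nodes/links JSON for any Sankey renderer.

    Nodes are keyed by (switch index, label); link values are patient
    counts.
    """
    node_keys: list[tuple[int, str]] = []
    for _, row in flows.iterrows():
        for key in [(int(row["switch_index"]), row["source"]),
                    (int(row["switch_index"]) + 1, row["target"])]:
            if key not in node_keys:
                node_keys.append(key)
    node_keys.sort()
    index = {key: i for i, key in enumerate(node_keys)}
    nodes = [{"id": i, "switch_index": k, "label": lab}
             for (k, lab), i in index.items()]
    links = [{"source": index[(int(r["switch_index"]), r["source"])],
              "target": index[(int(r["switch_index"]) + 1, r["target"])],
              "value": int(r["n"])}
             for _, r in flows.iterrows()]
    return {"nodes": nodes, "links": links}


def write_sankey(flows: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        json.dump(sankey_export(flows), fh, indent=2, sort_keys=True)


def derive_lines(episodes: pd.DataFrame, procedures: pd.DataFrame,
                 config: AnalysisConfig
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Treatment lines per patient plus the line x regimen table."""
    iv = _treatment_intervals(episodes, procedures, config)
    window = config.combo_window_days
    line_rows = []
    for pid, group in iv.groupby("patient_id", sort=True):
        starts = group.sort_values(["start_day", "label"])[
            ["start_day", "label"]].to_numpy()
        line_index = 0
        current: set[str] = set()
        line_start = None
        for day, label in starts:
            if line_index and label in current:
                continue
            if line_index == 0 or day > line_start + window:
                line_index += 1
                line_start = day
                current = {lab for d, lab in starts
                           if line_start <= d <= line_start + window}
                line_rows.append({
                    "patient_id": pid, "line_index": line_index,
                    "regimen": _label(frozenset(current)),
                    "start": pd.Timestamp.fromordinal(int(line_start))})
            else:
                # starts within the window of the current line joined it
                continue
    lines = pd.DataFrame(line_rows, columns=["patient_id", "line_index",
                                             "regimen", "start"])
    rows = []
    for li, group in lines.groupby("line_index"):
        total = len(group)
        for regimen, sub in group.groupby("regimen"):
            rows.append({"line_index": int(li), "regimen": regimen,
                         "n": len(sub), "total": total,
                         "percent": round(100.0 * len(sub) / total, 2)})
    table = pd.DataFrame(rows, columns=["line_index", "regimen", "n",
                                        "total", "percent"])
    return lines, table
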