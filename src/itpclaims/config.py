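"""Analysis configuration.

Every tunable of the analysis lives here: ICD-like code lists, per-class
gap periods, prednisolone-equivalence factors, dose/duration bins, the
weekly dose grid, matching ratio and thresholds.  All values can be
overridden from a YAML file; the defaults document the analysis choices.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

DRUG_CLASSES = ("CS", "EPAG", "ROMI", "RTX", "OTHER_IS")

#: standard glucocorticoid equivalence: PSL 5 mg == mPSL 4 mg
#: == dexamethasone/betamethasone 0.75 mg == hydrocortisone 20 mg
DEFAULT_PSL_EQUIVALENCE = {
    "prednisolone": 1.0,
    "prednisone": 1.0,
    "methylprednisolone": 1.25,
    "dexamethasone": 20.0 / 3.0,
    "betamethasone": 20.0 / 3.0,
    "hydrocortisone": 0.25,
}

DEFAULT_GAP_DAYS = {
    "CS": 30,
    "EPAG": 30,
    "ROMI": 28,   # weekly injection
    "RTX": 90,    # course-based (e.g. 4 weekly infusions)
    "OTHER_IS": 30,
}

#: concept -> set of code prefixes (a diagnosis code matches a concept when
#: it starts with one of the prefixes).  Real dictionaries are proprietary;
#: these defaults define the synthetic dialect and are fully overridable.
DEFAULT_CODE_LISTS = {
    "itp": ["D693"],
    "pregnancy_itp": ["O993"],
    "diabetes": ["E11"],
    "malignancy": ["C80"],
    "pulmonary_disease": ["J44"],
    "liver_disease": ["K76"],
    "osteoporosis": ["M80"],
    "dyslipidemia": ["E78"],
    "hypertension": ["I10"],
    "cataract": ["H25"],
    "glaucoma": ["H40"],
    "infection": ["A49"],
    "peptic_ulcer": ["K25"],
    "thromboembolism": ["I26", "I21", "I63"],
    "psychosis": ["F09"],
    "depression": ["F32"],
    "insomnia": ["G47"],
}

#: adverse-outcome name -> (event concept, look-back washout concept)
DEFAULT_OUTCOMES = {
    "infection": ("infection", "infection"),
    "diabetes": ("diabetes", "diabetes"),
    "osteoporosis": ("osteoporosis", "osteoporosis"),
    "dyslipidemia": ("dyslipidemia", "dyslipidemia"),
    "hypertension": ("hypertension", "hypertension"),
    "peptic_ulcer": ("peptic_ulcer", "peptic_ulcer"),
    "psychosis": ("psychosis", "psychosis"),
    "cataract": ("cataract", "cataract"),
    "glaucoma": ("glaucoma", "glaucoma"),
    "thromboembolism": ("thromboembolism", "thromboembolism"),
}

BASELINE_COMORBIDITIES = (
    "diabetes", "malignancy", "pulmonary_disease", "liver_disease",
    "osteoporosis", "dyslipidemia", "hypertension", "cataract", "glaucoma",
    "infection", "thromboembolism", "peptic_ulcer", "depression", "insomnia",
)

ADJUSTMENT_COVARIATES = ("gender", "age", "malignancy", "pulmonary_disease",
                         "liver_disease")


class ConfigError(ValueError):
    """Raised for invalid or incomplete configuration."""


@dataclass
class AnalysisConfig:
    """All tunables of the pipeline, with documented defaults."""

    lookback_months: int = 6
    min_age: int = 20
    gap_days_by_class: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GAP_DAYS))
    withdrawal_gap_days: int = 60
    followup_cap_withdrawal_days: int = 183
    psl_equivalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PSL_EQUIVALENCE))
    # dose bins (mg/day PSL-eq): 0 | >0-<2.5 | >=2.5-<5 | ... | >=60
    dose_bins_mg_per_day: list[float] = field(
        default_factory=lambda: [2.5, 5.0, 7.5, 10.0, 20.0, 40.0, 60.0])
    # descriptive duration bins (days): untreated | >0-<60 | >=60-<90 | ...
    duration_bins_days: list[float] = field(
        default_factory=lambda: [60.0, 90.0, 180.0])
    ncc_duration_bins_days: list[float] = field(
        default_factory=lambda: [15.0, 60.0])
    ncc_cumdose_bins_mg: list[float] = field(
        default_factory=lambda: [500.0, 1500.0])
    # dose grid weeks after CS initiation (0 = initial prescription)
    week_grid: list[int] = field(default_factory=lambda: [
        0, 2, 4, 6, 8, 10, 12, 14, 16, 18, 20, 24, 28, 52, 104, 156])
    matching_ratio: int = 5
    min_cases: int = 10
    # pulse therapy: methylprednisolone injection 500-1000 mg/day x 3 days
    pulse_dose_range_mg: tuple[float, float] = (500.0, 1000.0)
    pulse_run_days: int = 3
    # high-dose dexamethasone: 20-40 mg/day x 4 days, oral or injection
    hdd_dose_range_mg: tuple[float, float] = (20.0, 40.0)
    hdd_run_days: int = 4
    # treatment patterns
    combo_window_days: int = 14
    splenectomy_state_days: int = 90
    min_pattern_n: int = 5
    max_switches: int = 5
    pattern_years: tuple[int, int] = (2015, 2021)
    era_years: dict[str, tuple[int, int]] = field(default_factory=lambda: {
        "2015-2019": (2015, 2019), "2020-2021": (2020, 2021)})
    code_lists: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in
                                 DEFAULT_CODE_LISTS.items()})
    outcomes: dict[str, tuple[str, str]] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOMES))
    cohort_exclusion_concepts: list[str] = field(default_factory=list)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if self.matching_ratio < 1:
            raise ConfigError("matching_ratio must be >= 1")
        if self.lookback_months < 0:
            raise ConfigError("lookback_months must be >= 0")
        for name, cuts in [("dose_bins_mg_per_day", self.dose_bins_mg_per_day),
                           ("duration_bins_days", self.duration_bins_days),
                           ("ncc_duration_bins_days",
                            self.ncc_duration_bins_days),
                           ("ncc_cumdose_bins_mg", self.ncc_cumdose_bins_mg)]:
            if any(nxt <= prev for prev, nxt in zip(cuts, cuts[1:])):
                raise ConfigError(f"{name} cut points must be "
                                  "strictly increasing")
        if sorted(self.week_grid) != list(self.week_grid):
            raise ConfigError("week_grid must be ordered")
        for drug, factor in self.psl_equivalence.items():
            if factor <= 0:
                raise ConfigError(
                    f"psl_equivalence factor for {drug!r} must be positive")

    # -- code-list helpers ------------------------------------------------
    def code_prefixes(self, concept: str) -> list[str]:
        try:
            prefixes = self.code_lists[concept]
        except KeyError:
            raise ConfigError(f"no code list configured for "
                              f"concept {concept!r}") from None
        if not prefixes:
            raise ConfigError(f"code list for concept {concept!r} is empty")
        return list(prefixes)

    # -- (de)serialisation ------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["pulse_dose_range_mg"] = list(self.pulse_dose_range_mg)
        d["hdd_dose_range_mg"] = list(self.hdd_dose_range_mg)
        d["pattern_years"] = list(self.pattern_years)
        d["era_years"] = {k: list(v) for k, v in self.era_years.items()}
        d["outcomes"] = {k: list(v) for k, v in self.outcomes.items()}
        return d

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        for key in ("pulse_dose_range_mg", "hdd_dose_range_mg",
                    "pattern_years"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        if "era_years" in kwargs:
            kwargs["era_years"] = {k: tuple(v) for k, v in
                                   kwargs["era_years"].items()}
        if "outcomes" in kwargs:
            kwargs["outcomes"] = {k: tuple(v) for k, v in
                                  kwargs["outcomes"].items()}
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
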