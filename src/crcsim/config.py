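"""Configuration objects for the screening microsimulation.

Every tunable quantity of the model lives here: synthetic demography, adenoma
natural history, FIT operating characteristics, follow-up strategy rules,
colonoscopy complication rates, and unit costs (2021 CAD). Defaults encode the
base-case study conditions; named presets cover the alternative scenarios
(100 ng/mL threshold, all-annual / all-biennial screening, cost and
complication sensitivity analyses).

Configs are plain frozen-by-convention dataclasses with eager validation, and
round-trip to YAML/JSON through :func:`load_scenario` / :func:`save_scenario`.
"""

from __future__ import annotations

import copy
import dataclasses
import json
import math
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "ConfigurationError",
    "LogicError",
    "SizeClass",
    "LesionClass",
    "DemographyConfig",
    "NaturalHistoryConfig",
    "FITConfig",
    "StrategyConfig",
    "ComplicationConfig",
    "ColonoscopyConfig",
    "CostConfig",
    "ProgramConfig",
    "Scenario",
    "gompertz_life_table",
    "load_scenario",
    "save_scenario",
]


class ConfigurationError(ValueError):
    """Raised when a configuration violates a model invariant."""


class LogicError(RuntimeError):
    """Raised when the simulation is driven into an impossible state."""


class SizeClass(IntEnum):
    """Adenoma size class: 0-5 mm, 6-9 mm, >=10 mm."""

    SMALL = 0  # 0-5 mm
    MEDIUM = 1  # 6-9 mm
    LARGE = 2  # >= 10 mm


class LesionClass(IntEnum):
    """Ordered hierarchy of a person's most advanced lesion.

    FIT positivity is keyed to this hierarchy: none < adenoma 0-5 mm <
    adenoma 6-9 mm < adenoma >=10 mm < preclinical CRC.
    """

    NONE = 0
    ADENOMA_SMALL = 1
    ADENOMA_MEDIUM = 2
    ADENOMA_LARGE = 3
    PRECLINICAL_CRC = 4


MIN_ELIGIBLE_AGE = 50
MAX_ELIGIBLE_AGE = 74
MAX_AGE = 110

#: Number of single-year ages in the screening-eligible window (50..74).
N_ELIGIBLE_AGES = MAX_ELIGIBLE_AGE - MIN_ELIGIBLE_AGE + 1


def gompertz_life_table(a: float = 0.004, b: float = 0.085) -> tuple[float, ...]:
    """Synthetic Gompertz-shaped life table for ages 50..110.

    Annual non-CRC death probability ``q(age) = min(1, a * exp(b*(age-50)))``.
    Defaults give q(50) ~ 0.004, q(74) ~ 0.031, q(90) ~ 0.12 — a plausible
    all-cause mortality shape for a mixed-sex adult population. The table is
    config-replaceable; it is a stand-in, not an official life table.
    """
    return tuple(
        min(1.0, a * math.exp(b * (age - MIN_ELIGIBLE_AGE)))
        for age in range(MIN_ELIGIBLE_AGE, MAX_AGE + 1)
    )


def _uniform_age_weights() -> tuple[float, ...]:
    return tuple(1.0 / N_ELIGIBLE_AGES for _ in range(N_ELIGIBLE_AGES))


@dataclass
class DemographyConfig:
    """Synthetic screening-eligible population (ages 50-74).

    ``total_eligible_population`` is the full-scale head count (1,190,189 for
    Alberta in 2023); ``scale_factor`` shrinks it for desk-scale runs.
    ``entry_rate`` is the annual inflow of new 50-year-olds as a fraction of
    the scaled starting population, chosen to keep the eligible pool roughly
    stationary. ``mortality_table`` holds per-age annual non-CRC death
    probabilities for ages 50..110.
    """

    total_eligible_population: int = 1_190_189
    scale_factor: float = 1.0
    age_distribution: tuple[float, ...] = field(default_factory=_uniform_age_weights)
    entry_rate: float = 0.04
    mortality_table: tuple[float, ...] = field(default_factory=gompertz_life_table)

    def __post_init__(self) -> None:
        self.age_distribution = tuple(self.age_distribution)
        self.mortality_table = tuple(self.mortality_table)
        self.validate()

    def validate(self) -> None:
        if not (0.0 < self.scale_factor <= 1.0):
            raise ConfigurationError(
                f"scale_factor must be in (0, 1], got {self.scale_factor}"
            )
        if self.scaled_population <= 0:
            raise ConfigurationError("scaled population size must be positive")
        if len(self.age_distribution) != N_ELIGIBLE_AGES:
            raise ConfigurationError(
                f"age_distribution needs {N_ELIGIBLE_AGES} weights (ages 50-74)"
            )
        if any(w < 0 for w in self.age_distribution):
            raise ConfigurationError("age_distribution weights must be non-negative")
        if abs(sum(self.age_distribution) - 1.0) > 1e-9:
            raise ConfigurationError("age_distribution weights must sum to 1")
        if len(self.mortality_table) != MAX_AGE - MIN_ELIGIBLE_AGE + 1:
            raise ConfigurationError("mortality_table must cover ages 50-110")
        if any(not (0.0 <= q <= 1.0) for q in self.mortality_table):
            raise ConfigurationError("mortality probabilities must lie in [0, 1]")

    @property
    def scaled_population(self) -> int:
        return round(self.total_eligible_population * self.scale_factor)

    def mortality_at(self, age: int) -> float:
        """Annual non-CRC death probability; ages past the table die surely."""
        idx = age - MIN_ELIGIBLE_AGE
        if idx < 0:
            return 0.0
        if idx >= len(self.mortality_table):
            return 1.0
        return self.mortality_table[idx]


@dataclass
class NaturalHistoryConfig:
    """Adenoma-carcinoma natural history rates (all annual probabilities).

    Adenomas arise on normal mucosa, and each year independently grow one
    size class, revert to normal mucosa, progress to preclinical cancer, or
    stay. Progression risk rises with size but is strictly positive in every
    class — small adenomas also carry elevated risk relative to normal
    mucosa. Preclinical cancer surfaces clinically after a geometric sojourn;
    clinical cancer carries an annual death hazard.

    The default rate set is synthetic: it is tuned (see the methods note)
    only so that low-risk-adenoma yield among FIT-positive colonoscopies sits
    near 26 per 100 and full-scale annual incidence is of a realistic order.
    """

    onset_base: float = 0.012
    onset_slope: float = 0.0008  # added per year of age above 50
    grow_prob: tuple[float, float, float] = (0.05, 0.05, 0.0)
    revert_prob: tuple[float, float, float] = (0.10, 0.05, 0.02)
    progress_prob: tuple[float, float, float] = (0.0004, 0.004, 0.04)
    villous_fraction: float = 0.05
    dysplasia_fraction: float = 0.05
    sojourn_mean_years: float = 4.0
    crc_annual_death_prob: float = 0.12
    max_new_adenomas_per_year: int = 1

    def __post_init__(self) -> None:
        self.grow_prob = tuple(self.grow_prob)
        self.revert_prob = tuple(self.revert_prob)
        self.progress_prob = tuple(self.progress_prob)
        self.validate()

    def validate(self) -> None:
        for name in ("grow_prob", "revert_prob", "progress_prob"):
            probs = getattr(self, name)
            if len(probs) != 3:
                raise ConfigurationError(f"{name} needs one value per size class")
            if any(not (0.0 <= p <= 1.0) for p in probs):
                raise ConfigurationError(f"{name} values must lie in [0, 1]")
        for sc in SizeClass:
            total = (
                self.grow_prob[sc] + self.revert_prob[sc] + self.progress_prob[sc]
            )
            if total > 1.0 + 1e-12:
                raise ConfigurationError(
                    f"transition probabilities for size class {sc.name} exceed 1"
                )
        if self.grow_prob[SizeClass.LARGE] != 0.0:
            raise ConfigurationError(">=10 mm adenomas cannot grow further")
        # The shipped default satisfies the strict chain large > medium >=
        # small > 0 (every adenoma class carries elevated risk); degenerate
        # zero-progress configs are admitted for controlled experiments.
        p0, p1, p2 = self.progress_prob
        if not (p2 >= p1 >= p0 >= 0.0):
            raise ConfigurationError(
                "progression must be non-decreasing in size class"
            )
        for name in (
            "villous_fraction",
            "dysplasia_fraction",
            "crc_annual_death_prob",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.sojourn_mean_years < 1.0:
            raise ConfigurationError("mean sojourn time must be >= 1 year")

    def onset_rate(self, age: int) -> float:
        """Annual probability that a new 0-5 mm adenoma arises, by age."""
        return min(1.0, max(0.0, self.onset_base + self.onset_slope * (age - 50)))


@dataclass
class FITConfig:
    """FIT operating characteristics at one positivity threshold.

    Positivity is governed by the person's most advanced lesion at the time
    of the test. Sensitivities for >=10 mm adenomas and CRC follow published
    magnitudes; sub-10 mm sensitivities and the false-positive rate are
    synthetic values calibrated so that low-risk-adenoma yield among
    FIT-positive colonoscopies is near 26/100 under the default natural
    history (they are stand-ins, freely overridable).
    """

    threshold_label: str = "75 ng/mL"
    # indexed by LesionClass - 1: (0-5 mm, 6-9 mm, >=10 mm, preclinical CRC)
    sensitivity: tuple[float, float, float, float] = (0.09, 0.19, 0.45, 0.80)
    false_positive_rate: float = 0.026
    participation_rate: float = 0.42

    def __post_init__(self) -> None:
        self.sensitivity = tuple(self.sensitivity)
        self.validate()

    def validate(self) -> None:
        if len(self.sensitivity) != 4:
            raise ConfigurationError("sensitivity needs 4 values (lesion hierarchy)")
        if any(not (0.0 <= s <= 1.0) for s in self.sensitivity):
            raise ConfigurationError("sensitivities must lie in [0, 1]")
        if list(self.sensitivity) != sorted(self.sensitivity):
            raise ConfigurationError(
                "sensitivity must be non-decreasing along the lesion hierarchy"
            )
        for name in ("false_positive_rate", "participation_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1]")

    def positivity(self, lesion: LesionClass) -> float:
        if lesion is LesionClass.NONE:
            return self.false_positive_rate
        return self.sensitivity[lesion - 1]

    @classmethod
    def fit75(cls) -> "FITConfig":
        """Base-case 75 ng/mL threshold (current Alberta practice)."""
        return cls()

    @classmethod
    def fit100(cls) -> "FITConfig":
        """100 ng/mL threshold: relative sensitivity reductions applied to
        the sub-10 mm classes of the 75 ng/mL preset; lower false-positive
        rate at the higher threshold."""
        return cls(
            threshold_label="100 ng/mL",
            sensitivity=(0.07, 0.15, 0.42, 0.78),
            false_positive_rate=0.020,
        )


LRA_FOLLOWUP_COLONOSCOPY = "colonoscopy_5y"
LRA_FOLLOWUP_FIT = "fit_5y"


@dataclass
class StrategyConfig:
    """Post-polypectomy follow-up rules.

    The two strategies differ only in ``lra_followup`` — what happens five
    years after a colonoscopy that found 1-2 low-risk adenomas: another
    colonoscopy (status quo) or resumption of routine FIT screening (new
    strategy). The new rule is policy-gated: it applies only to index
    colonoscopies performed in ``policy_start_year`` or later.
    """

    name: str = "status_quo"
    lra_followup: str = LRA_FOLLOWUP_COLONOSCOPY
    policy_start_year: int = 2023
    normal_return_years: int = 10
    high_risk_first_years: int = 3
    high_risk_second_years: int = 5
    lra_years: int = 5

    def __post_init__(self) -> None:
        if self.lra_followup not in (LRA_FOLLOWUP_COLONOSCOPY, LRA_FOLLOWUP_FIT):
            raise ConfigurationError(f"unknown lra_followup {self.lra_followup!r}")
        for name in (
            "normal_return_years",
            "high_risk_first_years",
            "high_risk_second_years",
            "lra_years",
        ):
            v = getattr(self, name)
            if not (isinstance(v, int) and v > 0):
                raise ConfigurationError(f"{name} must be a positive integer")

    @classmethod
    def status_quo(cls) -> "StrategyConfig":
        return cls(name="status_quo", lra_followup=LRA_FOLLOWUP_COLONOSCOPY)

    @classmethod
    def return_to_fit(cls) -> "StrategyConfig":
        return cls(name="return_to_fit", lra_followup=LRA_FOLLOWUP_FIT)


@dataclass
class ComplicationConfig:
    """Per-procedure colonoscopy complication rates, per 1000 colonoscopies."""

    major_bleed_per_1000: float = 0.3
    perforation_per_1000: float = 1.7
    mortality_per_1000: float = 0.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ConfigurationError(f"{f.name} must be >= 0")


@dataclass
class ColonoscopyConfig:
    """Colonoscopy detection operating characteristics.

    Detection is perfect for >=10 mm adenomas and cancer, slightly below 1
    for smaller adenomas.
    """

    detection_sensitivity: tuple[float, float, float] = (0.85, 0.95, 1.0)
    cancer_detection: float = 1.0

    def __post_init__(self) -> None:
        self.detection_sensitivity = tuple(self.detection_sensitivity)
        if len(self.detection_sensitivity) != 3:
            raise ConfigurationError("detection_sensitivity needs 3 values")
        probs = (*self.detection_sensitivity, self.cancer_detection)
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ConfigurationError("detection probabilities must lie in [0, 1]")


@dataclass
class CostConfig:
    """Unit costs in undiscounted 2021 CAD.

    ``cancer_mgmt_annual`` is a synthetic per-person-year cancer-management
    stand-in so the three-group cost report has the right structure; its
    absolute level is not reproducible from published unit costs.
    """

    fit_kit: float = 26.13
    fit_extra_visit: float = 38.03
    positive_consult: float = 146.03
    diagnostic_colonoscopy: float = 866.43
    operative_colonoscopy: float = 1036.43
    bleed_cost: float = 3864.74
    perforation_cost: float = 37779.83
    recruitment_cost: float = 0.0
    cancer_mgmt_annual: float = 12000.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ConfigurationError(f"{f.name} must be >= 0")


@dataclass
class ProgramConfig:
    """Organized-screening program structure.

    ``frequency_mix`` splits FIT participants between annual and biennial
    cadence. ``colonoscopy_primary_fraction`` is the share of the eligible
    population screened primarily by colonoscopy (significant family
    history) rather than FIT; they contribute the "screening colonoscopies
    without FIT" volume and are outside the FIT program, so the low-risk
    adenoma strategy change never applies to them.
    """

    frequency_mix: dict = field(
        default_factory=lambda: {"annual": 0.5, "biennial": 0.5}
    )
    colonoscopy_primary_fraction: float = 0.12
    colonoscopy_primary_interval_years: int = 10
    cancer_surveillance_years: int = 5
    program_start_year: int = 2008

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        mix = self.frequency_mix
        if set(mix) != {"annual", "biennial"}:
            raise ConfigurationError("frequency_mix needs 'annual' and 'biennial'")
        if any(v < 0 for v in mix.values()):
            raise ConfigurationError("frequency_mix fractions must be >= 0")
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ConfigurationError("frequency_mix fractions must sum to 1")
        if not (0.0 <= self.colonoscopy_primary_fraction < 1.0):
            raise ConfigurationError("colonoscopy_primary_fraction must be in [0, 1)")
        if self.colonoscopy_primary_interval_years < 1:
            raise ConfigurationError("colonoscopy_primary_interval_years must be >= 1")
        if self.cancer_surveillance_years < 0:
            raise ConfigurationError("cancer_surveillance_years must be >= 0")


@dataclass
class Scenario:
    """Full configuration bundle for one simulation scenario.

    The simulation runs from ``program.program_start_year`` (burn-in: the
    organized FIT program is assumed in place since 2008) and outcomes are
    reported for the ``report_start``..``report_end`` window (2023-2042).
    """

    demography: DemographyConfig = field(default_factory=DemographyConfig)
    natural_history: NaturalHistoryConfig = field(
        default_factory=NaturalHistoryConfig
    )
    fit: FITConfig = field(default_factory=FITConfig.fit75)
    program: ProgramConfig = field(default_factory=ProgramConfig)
    colonoscopy: ColonoscopyConfig = field(default_factory=ColonoscopyConfig)
    complications: ComplicationConfig = field(default_factory=ComplicationConfig)
    costs: CostConfig = field(default_factory=CostConfig)
    report_start: int = 2023
    report_end: int = 2042

    def __post_init__(self) -> None:
        if self.report_end < self.report_start:
            raise ConfigurationError("report_end must be >= report_start")
        if self.program.program_start_year > self.report_start:
            raise ConfigurationError("burn-in must start at or before report_start")

    def scaled(self, n_persons: int) -> "Scenario":
        """Copy of this scenario scaled so the starting cohort has
        ``n_persons`` people."""
        sc = copy.deepcopy(self)
        sc.demography.scale_factor = (
            n_persons / sc.demography.total_eligible_population
        )
        sc.demography.validate()
        return sc

    # -- named presets (alternative scenarios & sensitivity analyses) -------

    @classmethod
    def preset(cls, name: str = "base") -> "Scenario":
        sc = cls()
        if name == "base":
            return sc
        if name == "fit100":
            sc.fit = FITConfig.fit100()
            return sc
        if name == "all_annual":
            sc.program.frequency_mix = {"annual": 1.0, "biennial": 0.0}
            return sc
        if name == "all_biennial":
            sc.program.frequency_mix = {"annual": 0.0, "biennial": 1.0}
            return sc
        if name == "low_colonoscopy_cost":
            # user-editable placeholders for the unpublished low estimates
            sc.costs.diagnostic_colonoscopy = 650.00
            sc.costs.operative_colonoscopy = 780.00
            return sc
        if name == "high_colonoscopy_cost":
            sc.costs.diagnostic_colonoscopy = 1300.00
            sc.costs.operative_colonoscopy = 1560.00
            return sc
        if name == "alt_complications":
            sc.complications = ComplicationConfig(
                major_bleed_per_1000=0.4,
                perforation_per_1000=0.8,
            )
            return sc
        raise ConfigurationError(f"unknown scenario preset {name!r}")

    @classmethod
    def preset_names(cls) -> tuple[str, ...]:
        return (
            "base",
            "fit100",
            "all_annual",
            "all_biennial",
            "low_colonoscopy_cost",
            "high_colonoscopy_cost",
            "alt_complications",
        )


# ---------------------------------------------------------------------------
# serialisation


_SECTION_TYPES = {
    "demography": DemographyConfig,
    "natural_history": NaturalHistoryConfig,
    "fit": FITConfig,
    "program": ProgramConfig,
    "colonoscopy": ColonoscopyConfig,
    "complications": ComplicationConfig,
    "costs": CostConfig,
}


def scenario_to_dict(scenario: Scenario) -> dict:
    out: dict = {}
    for name, cfg_type in _SECTION_TYPES.items():
        section = dataclasses.asdict(getattr(scenario, name))
        for k, v in section.items():
            if isinstance(v, tuple):
                section[k] = list(v)
        out[name] = section
    out["report_start"] = scenario.report_start
    out["report_end"] = scenario.report_end
    return out


def scenario_from_dict(data: Mapping) -> Scenario:
    """Build a Scenario from a (possibly partial) nested mapping.

    Unspecified sections and fields keep their defaults, so config files
    only need to state deviations from the base case.
    """
    kwargs: dict = {}
    for name, cfg_type in _SECTION_TYPES.items():
        section = data.get(name)
        if section is None:
            continue
        valid = {f.name for f in dataclasses.fields(cfg_type)}
        unknown = set(section) - valid
        if unknown:
            raise ConfigurationError(
                f"unknown keys in section {name!r}: {sorted(unknown)}"
            )
        defaults = dataclasses.asdict(cfg_type()) if name != "fit" else dataclasses.asdict(FITConfig.fit75())
        defaults.update(section)
        kwargs[name] = cfg_type(**defaults)
    for key in ("report_start", "report_end"):
        if key in data:
            kwargs[key] = int(data[key])
    return Scenario(**kwargs)


def load_scenario(path: str | Path) -> Scenario:
    """Load a scenario from a YAML or JSON file (partial overrides allowed)."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, Mapping):
        raise ConfigurationError(f"{path} does not contain a mapping")
    return scenario_from_dict(data)


def save_scenario(scenario: Scenario, path: str | Path) -> None:
    path = Path(path)
    data = scenario_to_dict(scenario)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
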