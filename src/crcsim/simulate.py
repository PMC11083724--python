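"""Single-strategy simulation driver.

Runs one strategy over one synthetic population from the program burn-in
year (2008 by default — the organized FIT program is assumed in place well
before the 2023 policy change) through the end of the reporting horizon.

Event order within a simulated year is fixed:

1. natural-history update (adenoma onset/fates, cancer phase, CRC death);
2. symptomatic presentation → diagnostic colonoscopy in the same year;
3. scheduled follow-up event (surveillance colonoscopy, or return to
   routine FIT, which re-enables routine screening from this year);
4. routine screening (FIT with same-year colonoscopy on a positive result,
   or a primary screening colonoscopy for the family-history pathway);
5. non-CRC mortality and aging.

Every person draws from a private random stream seeded from (run seed,
person id), so paired strategy runs on the same seed share randomness
person-by-person: their histories are bitwise identical until the first
follow-up decision that actually differs (common random numbers).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import pandas as pd

from .colonoscopy import (
    CATEGORIES,
    ColonoscopyRecord,
    FindingsClass,
    ScheduledFollowUp,
    perform_colonoscopy,
    schedule_followup,
)
from .config import (
    MIN_ELIGIBLE_AGE,
    MAX_ELIGIBLE_AGE,
    Scenario,
    StrategyConfig,
)
from .costing import CostAccumulator, CostLedger
from .natural_history import initialize_lesions, step_natural_history
from .population import Person, advance_year, build_cohort
from .screening import assign_profile, assign_screening_profiles, perform_fit

__all__ = ["AnnualOutcomes", "SimulationResult", "run_strategy", "derive_seed"]


def derive_seed(seed: int, stream: int) -> int:
    """Deterministic 31-bit child seed for a named stream."""
    return (seed * 2_654_435_761 + stream) % (2**31)


def _person_seed(run_seed: int, pid: int) -> int:
    return ((run_seed + 1) * 1_000_003 + 7_919 * pid) % (2**63)


@dataclass
class AnnualOutcomes:
    """Counts and costs for one simulated calendar year."""

    year: int
    crc_cases: int = 0
    crc_deaths: int = 0
    deaths: int = 0
    fit_screens: int = 0
    colonoscopies: dict = field(
        default_factory=lambda: {c: 0 for c in CATEGORIES}
    )
    major_bleeds: int = 0
    perforations: int = 0
    costs: CostLedger | None = None

    @property
    def total_colonoscopies(self) -> int:
        return sum(self.colonoscopies.values())

    def as_dict(self) -> dict:
        costs = self.costs if self.costs is not None else CostLedger(self.year)
        out = {
            "year": self.year,
            "crc_cases": self.crc_cases,
            "crc_deaths": self.crc_deaths,
            "deaths": self.deaths,
            "fit_screens": self.fit_screens,
            "major_bleeds": self.major_bleeds,
            "perforations": self.perforations,
            "total_colonoscopies": self.total_colonoscopies,
            "cost_screening": costs.screening,
            "cost_clinical_diagnosis": costs.clinical_diagnosis,
            "cost_cancer_management": costs.cancer_management,
            "cost_screening_diagnostics": (
                costs.screening_cents + costs.clinical_cents
            )
            / 100.0,
            "cost_total": costs.total,
        }
        for cat in CATEGORIES:
            out[f"colo_{cat}"] = self.colonoscopies[cat]
        return out


@dataclass
class SimulationResult:
    """All annual outcomes of one strategy run, plus bookkeeping totals."""

    strategy: str
    outcomes: list[AnnualOutcomes]
    n_created: int
    n_deaths: int
    findings_tally: dict = field(default_factory=dict)
    persons: list = field(default_factory=list, repr=False)

    @property
    def final_alive(self) -> int:
        return sum(1 for p in self.persons if p.alive)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([o.as_dict() for o in self.outcomes]).set_index(
            "year"
        )

    def window(self, start: int, end: int) -> pd.DataFrame:
        return self.frame().loc[start:end]

    def lra_yield_per_100(self, category: str = "after_positive_fit") -> float:
        """Low-risk-adenoma findings per 100 colonoscopies of a category."""
        total = sum(
            n for (cat, _), n in self.findings_tally.items() if cat == category
        )
        if total == 0:
            return float("nan")
        lra = self.findings_tally.get((category, "lra_1_2"), 0)
        return 100.0 * lra / total


class _Runner:
    """Internal per-run state; one instance per strategy run."""

    def __init__(self, scenario: Scenario, strategy: StrategyConfig, seed: int):
        self.scenario = scenario
        self.strategy = strategy
        self.seed = seed
        self.acc = CostAccumulator(scenario.costs)
        self.out: AnnualOutcomes | None = None
        # (category, findings) -> count over the whole run; feeds the
        # low-risk-adenoma yield diagnostics
        self.findings_tally: dict[tuple[str, str], int] = {}

    # -- colonoscopy plumbing ------------------------------------------------

    def _colonoscopy(
        self, person: Person, year: int, category: str, rng
    ) -> ColonoscopyRecord:
        sc = self.scenario
        rec = perform_colonoscopy(
            person, year, category, sc.colonoscopy, sc.complications, rng
        )
        out = self.out
        out.colonoscopies[category] += 1
        for compl in rec.complications:
            if compl == "major_bleed":
                out.major_bleeds += 1
            else:
                out.perforations += 1
        if rec.newly_diagnosed:
            out.crc_cases += 1
        key = (category, rec.findings.value)
        self.findings_tally[key] = self.findings_tally.get(key, 0) + 1
        self.acc.add_colonoscopy(rec)
        return rec

    def _handle_findings(
        self,
        person: Person,
        rec: ColonoscopyRecord,
        year: int,
        prior_phase: str | None,
    ) -> None:
        """Schedule what follows a non-cancer-surveillance colonoscopy."""
        if not person.alive:
            return
        prof = person.profile
        if rec.newly_diagnosed:
            # enter annual surveillance-after-cancer; cancer patients do not
            # return to routine screening
            prof.in_surveillance = True
            person.next_event = ScheduledFollowUp(
                "colonoscopy", year + 1, FindingsClass.CANCER
            )
            return
        if rec.findings is FindingsClass.CANCER:
            # already-diagnosed clinical cancer seen again; schedule unchanged
            return
        fu = schedule_followup(
            rec.findings,
            year,
            self.strategy,
            prior_phase=prior_phase,
            in_fit_program=prof.participant,
        )
        if fu.modality == "fit":
            if prof.colonoscopy_primary:
                # family-history pathway: released people resume primary
                # screening colonoscopies at the release year, not FIT
                prof.next_primary_colo_year = fu.due_year
                prof.in_surveillance = False
                person.next_event = None
            else:
                prof.in_surveillance = True
                person.next_event = fu
        else:
            prof.in_surveillance = True
            person.next_event = fu

    # -- one person-year -----------------------------------------------------

    def person_year(self, person: Person, year: int) -> None:
        sc = self.scenario
        rng = person.rng
        out = self.out

        step_natural_history(person, year, sc.natural_history, rng)

        # symptomatic presentation: sojourn elapsed without detection
        if person.alive:
            cancer = person.cancer
            if (
                cancer is not None
                and cancer.phase == "preclinical"
                and year >= cancer.clinical_due
            ):
                rec = self._colonoscopy(
                    person, year, "symptomatic_diagnostic", rng
                )
                self._handle_findings(person, rec, year, None)

        # scheduled follow-up (surveillance colonoscopy or return to FIT)
        if person.alive:
            ev = person.next_event
            if ev is not None and ev.due_year <= year:
                person.next_event = None
                prof = person.profile
                if ev.modality == "fit":
                    # release back to routine screening from this year on
                    prof.in_surveillance = False
                    prof.next_routine_fit_year = year
                elif ev.reason is FindingsClass.CANCER:
                    self._colonoscopy(
                        person, year, "surveillance_after_cancer", rng
                    )
                    cancer = person.cancer
                    if (
                        person.alive
                        and cancer is not None
                        and cancer.diagnosis_year is not None
                        and year + 1
                        <= cancer.diagnosis_year
                        + sc.program.cancer_surveillance_years
                    ):
                        person.next_event = ScheduledFollowUp(
                            "colonoscopy", year + 1, FindingsClass.CANCER
                        )
                else:
                    rec = self._colonoscopy(
                        person, year, "surveillance_after_adenoma", rng
                    )
                    self._handle_findings(person, rec, year, ev.phase)

        # routine screening
        if person.alive:
            prof = person.profile
            if (
                not prof.in_surveillance
                and MIN_ELIGIBLE_AGE <= person.age <= MAX_ELIGIBLE_AGE
            ):
                if (
                    prof.participant
                    and year >= prof.next_routine_fit_year
                ):
                    positive = perform_fit(person, year, sc.fit, rng)
                    out.fit_screens += 1
                    self.acc.add_fit(year)
                    if positive:
                        rec = self._colonoscopy(
                            person, year, "after_positive_fit", rng
                        )
                        self._handle_findings(person, rec, year, None)
                elif (
                    prof.colonoscopy_primary
                    and year >= prof.next_primary_colo_year
                ):
                    rec = self._colonoscopy(
                        person, year, "screening_no_fit", rng
                    )
                    self._handle_findings(person, rec, year, None)

        # cancer management accrues per clinical person-year
        if (
            person.alive
            and person.cancer is not None
            and person.cancer.phase == "clinical"
        ):
            self.acc.add_cancer_year(year)

        # aging and non-CRC mortality close the year
        if person.alive:
            advance_year(person, year, sc.demography, rng)

        if not person.alive and person.death_year == year:
            out.deaths += 1
            if person.death_cause == "crc":
                out.crc_deaths += 1


def run_strategy(
    scenario: Scenario, strategy: StrategyConfig, seed: int
) -> SimulationResult:
    """Run one strategy on one freshly built population.

    Deterministic for a fixed (scenario, strategy, seed); paired strategy
    runs on the same seed share per-person random streams (common random
    numbers).
    """
    demo = scenario.demography
    program = scenario.program
    start = program.program_start_year
    end = scenario.report_end

    persons = build_cohort(demo, start, derive_seed(seed, 1))
    assign_screening_profiles(
        persons, scenario.fit, None, derive_seed(seed, 2), program, start
    )
    for p in persons:
        p.rng = random.Random(_person_seed(seed, p.id))
        initialize_lesions(p, start, scenario.natural_history, p.rng)

    entry_rng = random.Random(derive_seed(seed, 3))
    n_entry = round(demo.entry_rate * demo.scaled_population)
    next_id = len(persons)

    runner = _Runner(scenario, strategy, seed)
    outcomes: list[AnnualOutcomes] = []
    n_deaths = 0

    for year in range(start, end + 1):
        out = AnnualOutcomes(year)
        runner.out = out
        if year > start:
            for _ in range(n_entry):
                p = Person(next_id, year - MIN_ELIGIBLE_AGE, MIN_ELIGIBLE_AGE)
                assign_profile(p, scenario.fit, program, year, entry_rng)
                p.rng = random.Random(_person_seed(seed, next_id))
                initialize_lesions(p, year, scenario.natural_history, p.rng)
                persons.append(p)
                next_id += 1
        for person in persons:
            if person.alive:
                runner.person_year(person, year)
        n_deaths += out.deaths
        outcomes.append(out)

    ledgers = runner.acc.ledgers()
    for out in outcomes:
        out.costs = ledgers.get(out.year, CostLedger(out.year))

    return SimulationResult(
        strategy=strategy.name,
        outcomes=outcomes,
        n_created=next_id,
        n_deaths=n_deaths,
        findings_tally=runner.findings_tally,
        persons=persons,
    )
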