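"""Routine FIT screening: participation, cadence, and threshold positivity.

Participation is a lifetime trait (42% of the eligible population in the
base case); participants split between annual and biennial cadence per the
configured mix, with biennial phases staggered uniformly at random. FIT
positivity is governed by the person's most advanced lesion at test time.
Routine FIT runs only at ages 50-74 and is suspended while a person is in a
surveillance pathway.
"""

from __future__ import annotations

import random

from .config import (
    MIN_ELIGIBLE_AGE,
    MAX_ELIGIBLE_AGE,
    ConfigurationError,
    FITConfig,
    LogicError,
    ProgramConfig,
)
from .natural_history import most_advanced_lesion
from .population import Person

__all__ = ["ScreeningProfile", "assign_screening_profiles", "perform_fit"]


class ScreeningProfile:
    """Lifetime screening pathway assignment for one person."""

    __slots__ = (
        "participant",
        "frequency",
        "colonoscopy_primary",
        "last_fit_year",
        "next_routine_fit_year",
        "in_surveillance",
        "next_primary_colo_year",
    )

    def __init__(self):
        self.participant = False
        self.frequency = None
        self.colonoscopy_primary = False
        self.last_fit_year = None
        self.next_routine_fit_year = None
        self.in_surveillance = False
        self.next_primary_colo_year = None


def assign_profile(
    person: Person,
    fit_config: FITConfig,
    program: ProgramConfig,
    year: int,
    rng: random.Random,
) -> None:
    """Assign one person's lifetime screening profile.

    Participant with probability ``participation_rate``; participants are
    annual vs biennial per the frequency mix, with biennial start years
    staggered. Non-participants may instead be colonoscopy-primary
    screeners (family-history pathway), with start years staggered over the
    primary interval.
    """
    prof = ScreeningProfile()
    p_part = fit_config.participation_rate
    if rng.random() < p_part:
        prof.participant = True
        if rng.random() < program.frequency_mix["annual"]:
            prof.frequency = "annual"
            prof.next_routine_fit_year = year
        else:
            prof.frequency = "biennial"
            prof.next_routine_fit_year = year + rng.randrange(2)
    else:
        frac = program.colonoscopy_primary_fraction
        if frac > 0.0:
            if p_part >= 1.0 or frac / (1.0 - p_part) > 1.0:
                raise ConfigurationError(
                    "colonoscopy_primary_fraction incompatible with "
                    "participation_rate"
                )
            if rng.random() < frac / (1.0 - p_part):
                prof.colonoscopy_primary = True
                prof.next_primary_colo_year = year + rng.randrange(
                    program.colonoscopy_primary_interval_years
                )
    person.profile = prof


def assign_screening_profiles(
    cohort: list[Person],
    fit_config: FITConfig,
    frequency_mix: dict | None,
    seed: int,
    program: ProgramConfig | None = None,
    start_year: int | None = None,
) -> list[Person]:
    """Assign screening profiles across a cohort, deterministically per seed.

    ``frequency_mix`` overrides the program's mix when given (fractions must
    sum to 1). Returns the cohort for chaining.
    """
    program = program or ProgramConfig()
    if frequency_mix is not None:
        program = ProgramConfig(
            frequency_mix=dict(frequency_mix),
            colonoscopy_primary_fraction=program.colonoscopy_primary_fraction,
            colonoscopy_primary_interval_years=(
                program.colonoscopy_primary_interval_years
            ),
            cancer_surveillance_years=program.cancer_surveillance_years,
            program_start_year=program.program_start_year,
        )
    year = start_year if start_year is not None else program.program_start_year
    rng = random.Random(seed)
    for person in cohort:
        assign_profile(person, fit_config, program, year, rng)
    return cohort


def perform_fit(
    person: Person,
    year: int,
    fit_config: FITConfig,
    rng,
    scheduled: bool = False,
) -> bool:
    """Administer one FIT; returns True when positive.

    Positivity probability is the configured sensitivity of the most
    advanced lesion, or the false-positive rate when lesion-free. Updates
    the routine cadence bookkeeping. The caller performs the follow-up
    colonoscopy on a positive result in the same year (100% compliance).
    """
    prof = person.profile
    if prof is None or (not prof.participant and not scheduled):
        raise LogicError(
            f"FIT on non-participant person {person.id} outside a scheduled "
            "surveillance FIT"
        )
    if not (MIN_ELIGIBLE_AGE <= person.age <= MAX_ELIGIBLE_AGE):
        raise LogicError(f"FIT at ineligible age {person.age}")
    lesion = most_advanced_lesion(person)
    positive = rng.random() < fit_config.positivity(lesion)
    prof.last_fit_year = year
    interval = 1 if prof.frequency == "annual" else 2
    prof.next_routine_fit_year = year + interval
    person.record(year, "fit", "positive" if positive else "negative")
    return positive
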