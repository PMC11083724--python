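"""Synthetic screening-eligible population: cohort construction and demography.

One :class:`Person` at a time carries the full simulated history — adenomas,
cancer state, screening profile, scheduled follow-up, and a dated event log.
Cohorts are built at the burn-in start year with ages drawn from the
configured age distribution; each subsequent year a configurable inflow of
new 50-year-olds keeps the eligible pool roughly stationary, and everyone is
exposed to per-age non-CRC mortality. People who age out of FIT eligibility
at 75 remain simulated until death.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import (
    MIN_ELIGIBLE_AGE,
    MAX_ELIGIBLE_AGE,
    ConfigurationError,
    DemographyConfig,
)

__all__ = [
    "Person",
    "build_cohort",
    "advance_year",
    "cohort_to_dataframe",
    "histories_to_dataframe",
]

logger = logging.getLogger(__name__)


class Person:
    """One simulated individual.

    Attributes mirror the simulation state machine: ``adenomas`` is the
    current lesion set, ``cancer`` the optional cancer state, ``profile``
    the screening profile, ``next_event`` an optional scheduled follow-up,
    and ``history`` an ordered list of dated ``(year, kind, detail)`` events.
    A dead person accrues no further events or costs.
    """

    __slots__ = (
        "id",
        "birth_year",
        "age",
        "alive",
        "death_year",
        "death_cause",
        "adenomas",
        "cancer",
        "profile",
        "next_event",
        "history",
        "rng",
    )

    def __init__(self, pid: int, birth_year: int, age: int):
        self.id = pid
        self.birth_year = birth_year
        self.age = age
        self.alive = True
        self.death_year = None
        self.death_cause = None
        self.adenomas = []
        self.cancer = None
        self.profile = None
        self.next_event = None
        self.history = []
        self.rng = None

    def record(self, year: int, kind: str, detail=None) -> None:
        self.history.append((year, kind, detail))

    def die(self, year: int, cause: str) -> None:
        self.alive = False
        self.death_year = year
        self.death_cause = cause
        self.record(year, "death", cause)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        status = "alive" if self.alive else f"dead({self.death_cause})"
        return (
            f"Person(id={self.id}, age={self.age}, {status}, "
            f"adenomas={len(self.adenomas)}, cancer={self.cancer is not None})"
        )


def build_cohort(
    config: DemographyConfig, start_year: int, seed: int
) -> list[Person]:
    """Create the scaled starting cohort with ages 50-74.

    Ages are sampled from ``config.age_distribution`` with a dedicated
    numpy generator, so the cohort is bitwise reproducible for a fixed seed.
    """
    config.validate()
    if start_year < 2008:
        raise ConfigurationError(
            "start_year must be >= 2008 (organized FIT program start)"
        )
    n = config.scaled_population
    if n <= 0:
        raise ConfigurationError("cohort size must be positive")
    rng = np.random.default_rng(seed)
    ages = rng.choice(
        np.arange(MIN_ELIGIBLE_AGE, MAX_ELIGIBLE_AGE + 1),
        size=n,
        p=np.asarray(config.age_distribution),
    )
    return [
        Person(pid, start_year - int(age), int(age))
        for pid, age in enumerate(ages)
    ]


def advance_year(
    person: Person, year: int, config: DemographyConfig, rng
) -> Person:
    """Age the person by one year and apply non-CRC mortality.

    Ages beyond the mortality table are treated as probability 1 (forced
    death) and logged. Returns the same person for chaining.
    """
    person.age += 1
    q = config.mortality_at(person.age)
    if q >= 1.0 and person.age > MIN_ELIGIBLE_AGE + len(config.mortality_table) - 1:
        logger.debug("age %d beyond mortality table; forcing death", person.age)
    if rng.random() < q:
        person.die(year, "other")
    return person


def cohort_to_dataframe(cohort: list[Person]) -> pd.DataFrame:
    """Snapshot a cohort as a DataFrame (id, age, alive, lesions, cancer)."""
    rows = []
    for p in cohort:
        if p.cancer is None:
            cancer_status = "none"
        else:
            cancer_status = p.cancer.phase
        rows.append((p.id, p.age, p.alive, len(p.adenomas), cancer_status))
    return pd.DataFrame(
        rows, columns=["id", "age", "alive", "n_adenomas", "cancer_status"]
    )


def histories_to_dataframe(cohort: list[Person]) -> pd.DataFrame:
    """Debug trace: every person's dated event log as one long table."""
    rows = [
        (p.id, year, kind, "" if detail is None else str(detail))
        for p in cohort
        for (year, kind, detail) in p.history
    ]
    return pd.DataFrame(rows, columns=["id", "year", "event", "detail"])
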