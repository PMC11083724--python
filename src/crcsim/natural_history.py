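"""Adenoma-carcinoma natural history.

Each simulated year an alive person may develop a new 0-5 mm adenoma, and
every existing adenoma independently progresses to preclinical cancer, grows
one size class, reverts to normal mucosa, or stays put (in that tie-break
order on a single uniform draw, so that raising the progression probability
can only move draws *into* the progression region — a monotonicity the
property tests rely on). Preclinical cancer surfaces clinically after a
geometric sojourn; clinical cancer carries an annual death hazard.
"""

from __future__ import annotations

import math

from .config import LesionClass, NaturalHistoryConfig, SizeClass
from .population import Person

__all__ = [
    "Adenoma",
    "CancerState",
    "is_low_risk",
    "step_natural_history",
    "initialize_lesions",
    "most_advanced_lesion",
    "sample_sojourn",
]


class Adenoma:
    """A single adenomatous polyp.

    ``size_class`` moves only between adjacent classes in one annual step;
    ``villous`` and ``dysplasia`` are histology flags fixed at onset that
    drive risk classification at colonoscopy.
    """

    __slots__ = ("size_class", "villous", "dysplasia", "onset_year")

    def __init__(
        self,
        size_class: SizeClass,
        villous: bool = False,
        dysplasia: bool = False,
        onset_year: int = 0,
    ):
        self.size_class = size_class
        self.villous = villous
        self.dysplasia = dysplasia
        self.onset_year = onset_year

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        flags = ("villous" if self.villous else "tubular") + (
            "+dysplasia" if self.dysplasia else ""
        )
        return f"Adenoma({SizeClass(self.size_class).name}, {flags})"


class CancerState:
    """Colorectal cancer, preclinical (screen-detectable) or clinical.

    ``clinical_due`` is the year the sampled sojourn elapses and the cancer
    presents symptomatically if still undetected. ``detected_by`` records the
    detection route once diagnosed.
    """

    __slots__ = ("phase", "diagnosis_year", "detected_by", "clinical_due", "onset_year")

    def __init__(self, onset_year: int, clinical_due: int):
        self.phase = "preclinical"
        self.diagnosis_year = None
        self.detected_by = None
        self.clinical_due = clinical_due
        self.onset_year = onset_year

    def diagnose(self, year: int, detected_by: str) -> None:
        self.phase = "clinical"
        self.diagnosis_year = year
        self.detected_by = detected_by


def is_low_risk(adenoma: Adenoma) -> bool:
    """Low-risk adenoma: tubular (not villous), < 10 mm, no dysplasia."""
    return (
        not adenoma.villous
        and adenoma.size_class < SizeClass.LARGE
        and not adenoma.dysplasia
    )


def sample_sojourn(config: NaturalHistoryConfig, rng) -> int:
    """Geometric preclinical sojourn (support 1, 2, ...) with the configured
    mean."""
    p = 1.0 / config.sojourn_mean_years
    if p >= 1.0:
        return 1
    u = rng.random()
    # inverse-CDF of the geometric distribution on {1, 2, ...}
    return 1 + int(math.log(1.0 - u) / math.log(1.0 - p))


def step_natural_history(
    person: Person, year: int, config: NaturalHistoryConfig, rng
) -> Person:
    """Advance one person's lesions and cancer state by one year.

    Order within the step: existing adenomas transition first, then at most
    ``max_new_adenomas_per_year`` new adenomas arise (a new adenoma first
    transitions the following year), then the cancer state updates
    (symptomatic presentation is handled by the caller when
    ``clinical_due`` has elapsed; clinical cancer applies the annual death
    hazard).
    """
    adenomas = person.adenomas
    if adenomas:
        grow = config.grow_prob
        revert = config.revert_prob
        progress = config.progress_prob
        kept = []
        n_progressed = 0
        for ad in adenomas:
            sc = ad.size_class
            u = rng.random()
            pp = progress[sc]
            if u < pp:
                n_progressed += 1
                continue
            gp = pp + grow[sc]
            if u < gp:
                ad.size_class = SizeClass(sc + 1)
                kept.append(ad)
                continue
            if u < gp + revert[sc]:
                continue  # reverted to normal mucosa
            kept.append(ad)
        person.adenomas = kept
        if n_progressed:
            for _ in range(n_progressed):
                due = year + sample_sojourn(config, rng)
                if person.cancer is None:
                    person.cancer = CancerState(year, due)
                elif person.cancer.phase == "preclinical":
                    # an additional progressing adenoma can only shorten the
                    # sojourn of the single active cancer state
                    person.cancer.clinical_due = min(
                        person.cancer.clinical_due, due
                    )

    for _ in range(config.max_new_adenomas_per_year):
        if rng.random() < config.onset_rate(person.age):
            villous = rng.random() < config.villous_fraction
            dysplasia = rng.random() < config.dysplasia_fraction
            person.adenomas.append(
                Adenoma(SizeClass.SMALL, villous, dysplasia, year)
            )

    cancer = person.cancer
    if cancer is not None and cancer.phase == "clinical":
        if rng.random() < config.crc_annual_death_prob:
            person.die(year, "crc")
    return person


#: Age at which adenoma dynamics start when pre-filling a cohort's lesions.
LESION_BURNIN_START_AGE = 20


def initialize_lesions(
    person: Person, start_year: int, config: NaturalHistoryConfig, rng
) -> Person:
    """Pre-fill a person's lesions at cohort entry.

    Runs the adenoma dynamics (onset, growth, reversion, progression) from
    age 20 up to the person's entry age, so the starting cohort carries a
    near-stationary adenoma prevalence instead of entering lesion-free. A
    progression whose sampled sojourn would have ended before ``start_year``
    corresponds to a cancer diagnosed (and resolved) before baseline; such
    cancers are dropped — baseline clinical-cancer survivors are outside the
    model. Progressions still preclinical at baseline are kept, giving the
    small undiagnosed preclinical pool a screening program would find.
    """
    onset = config.onset_rate
    grow = config.grow_prob
    revert = config.revert_prob
    progress = config.progress_prob
    for age in range(LESION_BURNIN_START_AGE, person.age):
        year = start_year - (person.age - age)
        adenomas = person.adenomas
        if adenomas:
            kept = []
            for ad in adenomas:
                sc = ad.size_class
                u = rng.random()
                pp = progress[sc]
                if u < pp:
                    due = year + sample_sojourn(config, rng)
                    if due >= start_year:
                        if person.cancer is None:
                            person.cancer = CancerState(year, due)
                        else:
                            person.cancer.clinical_due = min(
                                person.cancer.clinical_due, due
                            )
                    continue
                gp = pp + grow[sc]
                if u < gp:
                    ad.size_class = SizeClass(sc + 1)
                    kept.append(ad)
                    continue
                if u < gp + revert[sc]:
                    continue
                kept.append(ad)
            person.adenomas = kept
        for _ in range(config.max_new_adenomas_per_year):
            if rng.random() < onset(age):
                villous = rng.random() < config.villous_fraction
                dysplasia = rng.random() < config.dysplasia_fraction
                person.adenomas.append(
                    Adenoma(SizeClass.SMALL, villous, dysplasia, year)
                )
    return person


def most_advanced_lesion(person: Person) -> LesionClass:
    """The highest-ranked lesion the person carries.

    Hierarchy: none < adenoma 0-5 mm < adenoma 6-9 mm < adenoma >=10 mm <
    preclinical CRC. Any cancer state ranks at the top.
    """
    if person.cancer is not None:
        return LesionClass.PRECLINICAL_CRC
    best = LesionClass.NONE
    for ad in person.adenomas:
        lesion = LesionClass(ad.size_class + 1)
        if lesion > best:
            best = lesion
    return best
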