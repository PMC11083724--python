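"""Colonoscopy execution, findings classification, and follow-up scheduling.

This is the core of the strategy comparison. A colonoscopy detects and
removes adenomas (per-size-class sensitivity), detects preclinical cancer,
and samples complications. Findings are classified into one of four classes:

* ``normal`` — nothing removed, no cancer;
* ``lra_1_2`` — 1-2 low-risk adenomas (tubular, < 10 mm, no dysplasia);
* ``high_risk`` — any villous adenoma, any adenoma >= 10 mm, any dysplasia,
  or more than 2 low-risk adenomas;
* ``cancer`` — overrides everything else.

Follow-up after polypectomy is where the two strategies diverge: 1-2
low-risk adenomas lead either to a surveillance colonoscopy in 5 years
(status quo) or a return to routine FIT screening in 5 years (new strategy,
policy-gated to index colonoscopies in 2023 or later and to people screened
within the FIT program).
"""

from __future__ import annotations

from enum import Enum

from .config import (
    ColonoscopyConfig,
    ComplicationConfig,
    LogicError,
    LRA_FOLLOWUP_FIT,
    StrategyConfig,
)
from .natural_history import Adenoma, is_low_risk
from .population import Person

__all__ = [
    "FindingsClass",
    "ColonoscopyRecord",
    "ScheduledFollowUp",
    "CATEGORIES",
    "perform_colonoscopy",
    "classify_findings",
    "schedule_followup",
]


class FindingsClass(Enum):
    NORMAL = "normal"
    LRA_1_2 = "lra_1_2"
    HIGH_RISK = "high_risk"
    CANCER = "cancer"


#: The five mutually exclusive colonoscopy reporting categories.
CATEGORIES = (
    "screening_no_fit",
    "after_positive_fit",
    "symptomatic_diagnostic",
    "surveillance_after_adenoma",
    "surveillance_after_cancer",
)

#: Detection route recorded on a cancer diagnosis, by category.
_DETECTED_BY = {
    "screening_no_fit": "screen",
    "after_positive_fit": "screen",
    "symptomatic_diagnostic": "symptoms",
    "surveillance_after_adenoma": "surveillance",
    "surveillance_after_cancer": "surveillance",
}

PHASE_FIRST_3Y = "first_3y"
PHASE_SECOND_5Y = "second_5y"


class ColonoscopyRecord:
    """One performed colonoscopy with its reporting category and findings."""

    __slots__ = (
        "year",
        "category",
        "findings",
        "n_adenomas_removed",
        "operative",
        "complications",
        "fatal",
        "newly_diagnosed",
    )

    def __init__(
        self,
        year: int,
        category: str,
        findings: FindingsClass,
        n_adenomas_removed: int,
        complications: tuple[str, ...],
        fatal: bool = False,
        newly_diagnosed: bool = False,
    ):
        self.year = year
        self.category = category
        self.findings = findings
        self.n_adenomas_removed = n_adenomas_removed
        self.operative = n_adenomas_removed > 0
        self.complications = complications
        self.fatal = fatal
        self.newly_diagnosed = newly_diagnosed

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"ColonoscopyRecord({self.year}, {self.category}, "
            f"{self.findings.value}, removed={self.n_adenomas_removed})"
        )


class ScheduledFollowUp:
    """A scheduled follow-up event: surveillance colonoscopy or return to FIT."""

    __slots__ = ("modality", "due_year", "reason", "phase")

    def __init__(
        self,
        modality: str,
        due_year: int,
        reason: FindingsClass,
        phase: str | None = None,
    ):
        if modality not in ("colonoscopy", "fit"):
            raise LogicError(f"unknown follow-up modality {modality!r}")
        self.modality = modality
        self.due_year = due_year
        self.reason = reason
        self.phase = phase


def classify_findings(
    removed_adenomas: list[Adenoma], cancer_found: bool
) -> FindingsClass:
    """Deterministic findings classification.

    Cancer overrides all other classes. With adenomas only: 1-2 low-risk
    adenomas and nothing else is ``lra_1_2``; any non-low-risk adenoma
    (villous, >= 10 mm, or dysplastic) or more than 2 low-risk adenomas is
    ``high_risk``.
    """
    if cancer_found:
        return FindingsClass.CANCER
    if not removed_adenomas:
        return FindingsClass.NORMAL
    if all(is_low_risk(ad) for ad in removed_adenomas):
        if len(removed_adenomas) <= 2:
            return FindingsClass.LRA_1_2
        return FindingsClass.HIGH_RISK
    return FindingsClass.HIGH_RISK


def perform_colonoscopy(
    person: Person,
    year: int,
    category: str,
    colo_config: ColonoscopyConfig,
    compl_config: ComplicationConfig,
    rng,
) -> ColonoscopyRecord:
    """Perform one colonoscopy on an alive person.

    Each adenoma is independently detected (and removed) with its
    size-class sensitivity. A preclinical cancer, when detected, becomes
    clinical with the detection route implied by the category; the record's
    ``newly_diagnosed`` flag marks that transition. Complications are
    sampled independently at the configured per-procedure rates; a sampled
    mortality event (default rate 0) is fatal.
    """
    if category not in CATEGORIES:
        raise LogicError(f"unknown colonoscopy category {category!r}")
    if not person.alive:
        raise LogicError("colonoscopy on a dead person")

    sens = colo_config.detection_sensitivity
    removed: list[Adenoma] = []
    kept: list[Adenoma] = []
    for ad in person.adenomas:
        if rng.random() < sens[ad.size_class]:
            removed.append(ad)
        else:
            kept.append(ad)
    person.adenomas = kept

    cancer_found = False
    newly_diagnosed = False
    cancer = person.cancer
    if cancer is not None:
        if cancer.phase == "clinical":
            cancer_found = True
        elif rng.random() < colo_config.cancer_detection:
            cancer_found = True
            newly_diagnosed = True
            cancer.diagnose(year, _DETECTED_BY[category])

    complications = []
    if rng.random() < compl_config.major_bleed_per_1000 / 1000.0:
        complications.append("major_bleed")
    if rng.random() < compl_config.perforation_per_1000 / 1000.0:
        complications.append("perforation")
    fatal = (
        compl_config.mortality_per_1000 > 0.0
        and rng.random() < compl_config.mortality_per_1000 / 1000.0
    )

    record = ColonoscopyRecord(
        year,
        category,
        classify_findings(removed, cancer_found),
        len(removed),
        tuple(complications),
        fatal=fatal,
        newly_diagnosed=newly_diagnosed,
    )
    person.record(year, "colonoscopy", (category, record.findings.value))
    if newly_diagnosed:
        person.record(year, "diagnosis", _DETECTED_BY[category])
    if fatal:
        person.die(year, "colonoscopy")
    return record


def schedule_followup(
    findings: FindingsClass,
    year: int,
    strategy: StrategyConfig,
    prior_phase: str | None = None,
    in_fit_program: bool = True,
) -> ScheduledFollowUp:
    """Determine the follow-up after a completed colonoscopy.

    * normal → return to routine FIT in ``normal_return_years`` (10 y) —
      except a normal result at the 3-year high-risk check, which still gets
      the second surveillance colonoscopy 5 years after;
    * 1-2 low-risk adenomas → per strategy: surveillance colonoscopy in 5 y
      (status quo) or routine FIT resuming in 5 y (new strategy). The new
      rule applies only when the index colonoscopy year is at or past the
      policy start (2023) *and* the person is screened within the FIT
      program; otherwise status-quo behaviour;
    * high-risk findings → colonoscopy in 3 y (repeated high-risk findings
      restart the 3-year clock);
    * cancer → annual surveillance-after-cancer colonoscopy starting next
      year (the simulation loop continues the configured schedule).

    Findings at a surveillance colonoscopy are themselves re-classified
    under the active strategy, so the returned follow-up can recurse.
    """
    if findings is FindingsClass.NORMAL:
        if prior_phase == PHASE_FIRST_3Y:
            return ScheduledFollowUp(
                "colonoscopy",
                year + strategy.high_risk_second_years,
                FindingsClass.HIGH_RISK,
                phase=PHASE_SECOND_5Y,
            )
        return ScheduledFollowUp(
            "fit", year + strategy.normal_return_years, FindingsClass.NORMAL
        )
    if findings is FindingsClass.LRA_1_2:
        use_new_rule = (
            strategy.lra_followup == LRA_FOLLOWUP_FIT
            and year >= strategy.policy_start_year
            and in_fit_program
        )
        if use_new_rule:
            return ScheduledFollowUp(
                "fit", year + strategy.lra_years, FindingsClass.LRA_1_2
            )
        return ScheduledFollowUp(
            "colonoscopy", year + strategy.lra_years, FindingsClass.LRA_1_2
        )
    if findings is FindingsClass.HIGH_RISK:
        return ScheduledFollowUp(
            "colonoscopy",
            year + strategy.high_risk_first_years,
            FindingsClass.HIGH_RISK,
            phase=PHASE_FIRST_3Y,
        )
    if findings is FindingsClass.CANCER:
        return ScheduledFollowUp("colonoscopy", year + 1, FindingsClass.CANCER)
    raise LogicError(f"unknown findings class {findings!r}")
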