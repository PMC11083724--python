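"""Undiscounted cost accounting in 2021 CAD.

Costs accrue per event and are aggregated into the three reporting groups:

* **screening** — FIT kits and result-discussion visits, the positive-test
  consultation, screening colonoscopies without FIT, and colonoscopies
  after a positive FIT;
* **clinical diagnosis** — diagnostic colonoscopies for symptomatic
  patients and surveillance colonoscopies after adenoma detection;
* **cancer management** — surveillance colonoscopies after cancer
  detection plus an annual per-person cancer-management stand-in cost.

Complication costs attach to the colonoscopy that caused them (hence to its
group). Arithmetic is exact: all amounts are held as integer cents, so
ledger totals are bit-stable and additive.
"""

from __future__ import annotations

from .config import CostConfig, LogicError
from .colonoscopy import ColonoscopyRecord

__all__ = [
    "FITEvent",
    "CancerCareYear",
    "CostLedger",
    "CostAccumulator",
    "GROUP_OF_CATEGORY",
    "cost_of_fit",
    "cost_of_colonoscopy",
    "aggregate_annual_costs",
]

#: Cost-group assignment for the five colonoscopy categories.
GROUP_OF_CATEGORY = {
    "screening_no_fit": "screening",
    "after_positive_fit": "screening",
    "symptomatic_diagnostic": "clinical_diagnosis",
    "surveillance_after_adenoma": "clinical_diagnosis",
    "surveillance_after_cancer": "cancer_management",
}


class FITEvent:
    """One administered FIT (kit plus result-discussion visit)."""

    __slots__ = ("year",)

    def __init__(self, year: int):
        self.year = year


class CancerCareYear:
    """One person-year of clinical cancer management."""

    __slots__ = ("year",)

    def __init__(self, year: int):
        self.year = year


def _cents(amount: float) -> int:
    return round(amount * 100)


class CostLedger:
    """Costs for one calendar year, split into the three reporting groups.

    Internally integer cents; the ``screening`` / ``clinical_diagnosis`` /
    ``cancer_management`` / ``total`` properties are dollars.
    """

    __slots__ = ("year", "screening_cents", "clinical_cents", "cancer_cents")

    def __init__(
        self,
        year: int,
        screening_cents: int = 0,
        clinical_cents: int = 0,
        cancer_cents: int = 0,
    ):
        self.year = year
        self.screening_cents = screening_cents
        self.clinical_cents = clinical_cents
        self.cancer_cents = cancer_cents

    @property
    def screening(self) -> float:
        return self.screening_cents / 100.0

    @property
    def clinical_diagnosis(self) -> float:
        return self.clinical_cents / 100.0

    @property
    def cancer_management(self) -> float:
        return self.cancer_cents / 100.0

    @property
    def total_cents(self) -> int:
        return self.screening_cents + self.clinical_cents + self.cancer_cents

    @property
    def total(self) -> float:
        return self.total_cents / 100.0

    def add(self, group: str, cents: int) -> None:
        if group == "screening":
            self.screening_cents += cents
        elif group == "clinical_diagnosis":
            self.clinical_cents += cents
        elif group == "cancer_management":
            self.cancer_cents += cents
        else:
            raise LogicError(f"unknown cost group {group!r}")

    def __add__(self, other: "CostLedger") -> "CostLedger":
        return CostLedger(
            self.year,
            self.screening_cents + other.screening_cents,
            self.clinical_cents + other.clinical_cents,
            self.cancer_cents + other.cancer_cents,
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CostLedger)
            and self.year == other.year
            and self.screening_cents == other.screening_cents
            and self.clinical_cents == other.clinical_cents
            and self.cancer_cents == other.cancer_cents
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"CostLedger({self.year}, screening={self.screening:.2f}, "
            f"clinical={self.clinical_diagnosis:.2f}, "
            f"cancer={self.cancer_management:.2f})"
        )


def cost_of_fit(config: CostConfig) -> float:
    """Cost of one FIT screen: kit plus the result-discussion visit."""
    return (_cents(config.fit_kit) + _cents(config.fit_extra_visit)) / 100.0


def _colonoscopy_cents(record: ColonoscopyRecord, config: CostConfig) -> int:
    cents = _cents(
        config.operative_colonoscopy
        if record.operative
        else config.diagnostic_colonoscopy
    )
    for compl in record.complications:
        if compl == "major_bleed":
            cents += _cents(config.bleed_cost)
        elif compl == "perforation":
            cents += _cents(config.perforation_cost)
        else:
            raise LogicError(f"unknown complication {compl!r}")
    if record.category == "after_positive_fit":
        cents += _cents(config.positive_consult)
    return cents


def cost_of_colonoscopy(record: ColonoscopyRecord, config: CostConfig) -> float:
    """Cost of one colonoscopy: base fee (operative when any polypectomy was
    performed), complication costs, and — for colonoscopies after a positive
    FIT — the positive-test consultation fee."""
    return _colonoscopy_cents(record, config) / 100.0


class CostAccumulator:
    """Streaming per-year cost aggregation used by the simulation loop."""

    def __init__(self, config: CostConfig):
        self.config = config
        self._fit_cents = _cents(config.fit_kit) + _cents(config.fit_extra_visit)
        self._cancer_cents = _cents(config.cancer_mgmt_annual)
        self._ledgers: dict[int, CostLedger] = {}

    def _ledger(self, year: int) -> CostLedger:
        ledger = self._ledgers.get(year)
        if ledger is None:
            ledger = CostLedger(year)
            self._ledgers[year] = ledger
        return ledger

    def add_fit(self, year: int) -> None:
        self._ledger(year).add("screening", self._fit_cents)

    def add_colonoscopy(self, record: ColonoscopyRecord) -> None:
        group = GROUP_OF_CATEGORY.get(record.category)
        if group is None:
            raise LogicError(f"unknown colonoscopy category {record.category!r}")
        self._ledger(record.year).add(
            group, _colonoscopy_cents(record, self.config)
        )

    def add_cancer_year(self, year: int) -> None:
        self._ledger(year).add("cancer_management", self._cancer_cents)

    def ledgers(self) -> dict[int, CostLedger]:
        return dict(self._ledgers)


def aggregate_annual_costs(events, config: CostConfig) -> dict[int, CostLedger]:
    """Aggregate an event stream into per-year three-group ledgers.

    Events may be :class:`FITEvent`, :class:`ColonoscopyRecord`, or
    :class:`CancerCareYear`; anything else is a logic error. The result
    satisfies total = screening + clinical_diagnosis + cancer_management
    exactly, and is additive across disjoint event sets.
    """
    acc = CostAccumulator(config)
    for event in events:
        if isinstance(event, FITEvent):
            acc.add_fit(event.year)
        elif isinstance(event, ColonoscopyRecord):
            acc.add_colonoscopy(event)
        elif isinstance(event, CancerCareYear):
            acc.add_cancer_year(event.year)
        else:
            raise LogicError(f"unknown cost event {event!r}")
    return acc.ledgers()
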