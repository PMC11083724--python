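"""Cost accounting: worked examples, additivity, and monotonicity."""

import dataclasses

import pytest
from hypothesis import given, settings, strategies as st

from crcsim import (
    CostConfig,
    FindingsClass,
    aggregate_annual_costs,
    cost_of_colonoscopy,
    cost_of_fit,
)
from crcsim.colonoscopy import CATEGORIES, ColonoscopyRecord
from crcsim.costing import CancerCareYear, FITEvent


def _record(
    year=2024,
    category="surveillance_after_adenoma",
    n_removed=0,
    complications=(),
):
    return ColonoscopyRecord(
        year,
        category,
        FindingsClass.NORMAL if n_removed == 0 else FindingsClass.LRA_1_2,
        n_removed,
        tuple(complications),
    )


ZERO = CostConfig(
    fit_kit=0, fit_extra_visit=0, positive_consult=0,
    diagnostic_colonoscopy=0, operative_colonoscopy=0,
    bleed_cost=0, perforation_cost=0, recruitment_cost=0,
    cancer_mgmt_annual=0,
)


class TestUnitCosts:
    def test_fit_cost_is_kit_plus_extra_visit(self):
        assert cost_of_fit(CostConfig()) == 64.16

    def test_fit_cost_without_extra_visit(self):
        assert cost_of_fit(CostConfig(fit_extra_visit=0.0)) == 26.13

    def test_fit_cost_all_zero(self):
        assert cost_of_fit(ZERO) == 0.0

    def test_non_operative_surveillance_colonoscopy(self):
        rec = _record(category="surveillance_after_adenoma")
        assert cost_of_colonoscopy(rec, CostConfig()) == 866.43

    def test_operative_with_perforation(self):
        rec = _record(n_removed=1, complications=("perforation",))
        assert cost_of_colonoscopy(rec, CostConfig()) == 38816.26

    def test_positive_fit_consult_attaches_to_screening_colonoscopy(self):
        rec = _record(category="after_positive_fit")
        assert cost_of_colonoscopy(rec, CostConfig()) == 1012.46

    def test_zeroed_config_costs_nothing(self):
        rec = _record(n_removed=2, complications=("major_bleed", "perforation"))
        assert cost_of_colonoscopy(rec, ZERO) == 0.0


class TestAggregation:
    def test_empty_stream_empty_ledger(self):
        assert aggregate_annual_costs([], CostConfig()) == {}

    def test_worked_screening_group_example(self):
        """One FIT plus one non-operative colonoscopy after a positive FIT:
        screening group = 64.16 + 146.03 + 866.43 = 1076.62."""
        events = [FITEvent(2024), _record(category="after_positive_fit")]
        ledgers = aggregate_annual_costs(events, CostConfig())
        ledger = ledgers[2024]
        assert ledger.screening == 1076.62
        assert ledger.clinical_diagnosis == 0.0
        assert ledger.cancer_management == 0.0
        assert ledger.total == 1076.62

    def test_group_assignment_of_categories(self):
        events = [_record(category=c) for c in CATEGORIES]
        ledger = aggregate_annual_costs(events, CostConfig())[2024]
        assert ledger.screening == 1878.89
        assert ledger.clinical_diagnosis == 1732.86
        assert ledger.cancer_management == 866.43

    def test_unknown_event_is_logic_error(self):
        with pytest.raises(Exception):
            aggregate_annual_costs([object()], CostConfig())


# hypothesis event-stream generator: dated FITs, colonoscopies with optional
# polypectomy/complications, and cancer-care years
_events = st.lists(
    st.one_of(
        st.integers(2023, 2027).map(FITEvent),
        st.integers(2023, 2027).map(CancerCareYear),
        st.builds(
            _record,
            year=st.integers(2023, 2027),
            category=st.sampled_from(CATEGORIES),
            n_removed=st.integers(0, 4),
            complications=st.sets(
                st.sampled_from(["major_bleed", "perforation"])
            ).map(tuple),
        ),
    ),
    max_size=40,
)


class TestLedgerProperties:
    @given(events=_events)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_total_equals_brute_force_per_event_sum(self, events):
        """Ledger totals equal an independent per-event cost summation."""
        cfg = CostConfig()
        ledgers = aggregate_annual_costs(events, cfg)
        expected_cents = 0
        for e in events:
            if isinstance(e, FITEvent):
                expected_cents += round(cost_of_fit(cfg) * 100)
            elif isinstance(e, CancerCareYear):
                expected_cents += round(cfg.cancer_mgmt_annual * 100)
            else:
                expected_cents += round(cost_of_colonoscopy(e, cfg) * 100)
        assert sum(l.total_cents for l in ledgers.values()) == expected_cents
        # and the three groups partition the total exactly
        for ledger in ledgers.values():
            assert (
                ledger.screening_cents
                + ledger.clinical_cents
                + ledger.cancer_cents
                == ledger.total_cents
            )

    @given(events=_events, split=st.integers(0, 40))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_additivity_over_disjoint_event_sets(self, events, split):
        cfg = CostConfig()
        a, b = events[:split], events[split:]
        combined = aggregate_annual_costs(events, cfg)
        la = aggregate_annual_costs(a, cfg)
        lb = aggregate_annual_costs(b, cfg)
        years = set(la) | set(lb)
        assert set(combined) == {
            y for y in years
        }
        for y in years:
            total = la[y].total_cents if y in la else 0
            total += lb[y].total_cents if y in lb else 0
            assert combined[y].total_cents == total

    def test_zero_cost_config_zero_ledger(self):
        events = [FITEvent(2024), _record(n_removed=3), CancerCareYear(2025)]
        ledgers = aggregate_annual_costs(events, ZERO)
        assert all(l.total_cents == 0 for l in ledgers.values())

    def test_raising_any_unit_cost_never_decreases_groups(self):
        events = [
            FITEvent(2024),
            _record(category="after_positive_fit", n_removed=1),
            _record(category="surveillance_after_adenoma",
                    complications=("major_bleed",)),
            _record(category="surveillance_after_cancer"),
            CancerCareYear(2024),
        ]
        base = aggregate_annual_costs(events, CostConfig())[2024]
        for fld in dataclasses.fields(CostConfig):
            cfg = CostConfig(**{fld.name: getattr(CostConfig(), fld.name) + 100.0})
            bumped = aggregate_annual_costs(events, cfg)[2024]
            assert bumped.screening_cents >= base.screening_cents
            assert bumped.clinical_cents >= base.clinical_cents
            assert bumped.cancer_cents >= base.cancer_cents
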