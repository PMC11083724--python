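"""Colonoscopy execution, findings classification, and follow-up scheduling."""

import random

import pytest
from scipy import stats

from crcsim import (
    ColonoscopyConfig,
    ComplicationConfig,
    FindingsClass,
    SizeClass,
    StrategyConfig,
    classify_findings,
    perform_colonoscopy,
    schedule_followup,
)
from crcsim.colonoscopy import PHASE_FIRST_3Y, PHASE_SECOND_5Y
from crcsim.natural_history import Adenoma, CancerState
from crcsim.population import Person


def _tubular(size, dysplasia=False):
    return Adenoma(size, villous=False, dysplasia=dysplasia)


def _person(adenomas=(), cancer=None):
    p = Person(0, 1960, 63)
    p.adenomas = list(adenomas)
    p.cancer = cancer
    return p


class TestClassifyFindings:
    @pytest.mark.parametrize(
        "removed, cancer, expected",
        [
            ([], False, FindingsClass.NORMAL),
            ([_tubular(SizeClass.SMALL)], False, FindingsClass.LRA_1_2),
            (
                [_tubular(SizeClass.SMALL), _tubular(SizeClass.MEDIUM)],
                False,
                FindingsClass.LRA_1_2,
            ),
            # >2 low-risk adenomas are a high-risk finding
            ([_tubular(SizeClass.SMALL)] * 3, False, FindingsClass.HIGH_RISK),
            # any villous adenoma
            (
                [Adenoma(SizeClass.SMALL, villous=True)],
                False,
                FindingsClass.HIGH_RISK,
            ),
            # any >=10 mm adenoma
            ([_tubular(SizeClass.LARGE)], False, FindingsClass.HIGH_RISK),
            # dysplasia disqualifies an otherwise low-risk adenoma
            (
                [_tubular(SizeClass.SMALL, dysplasia=True)],
                False,
                FindingsClass.HIGH_RISK,
            ),
            # cancer overrides everything
            ([_tubular(SizeClass.SMALL)], True, FindingsClass.CANCER),
            ([], True, FindingsClass.CANCER),
        ],
    )
    def test_classification(self, removed, cancer, expected):
        assert classify_findings(removed, cancer) == expected


class TestPerformColonoscopy:
    def test_lesion_free_person_normal_non_operative(self, rng):
        rec = perform_colonoscopy(
            _person(),
            2024,
            "after_positive_fit",
            ColonoscopyConfig(),
            ComplicationConfig(0.0, 0.0, 0.0),
            rng,
        )
        assert rec.findings is FindingsClass.NORMAL
        assert rec.n_adenomas_removed == 0 and not rec.operative

    def test_two_medium_tubular_adenomas_are_lra_finding(self, rng):
        p = _person([_tubular(SizeClass.MEDIUM), _tubular(SizeClass.MEDIUM)])
        rec = perform_colonoscopy(
            p,
            2024,
            "after_positive_fit",
            ColonoscopyConfig(detection_sensitivity=(1.0, 1.0, 1.0)),
            ComplicationConfig(0.0, 0.0, 0.0),
            rng,
        )
        assert rec.findings is FindingsClass.LRA_1_2
        assert rec.n_adenomas_removed == 2 and rec.operative
        assert p.adenomas == []  # removed from the person's set

    def test_missed_adenomas_stay_with_the_person(self, rng):
        p = _person([_tubular(SizeClass.SMALL)])
        rec = perform_colonoscopy(
            p,
            2024,
            "after_positive_fit",
            ColonoscopyConfig(detection_sensitivity=(0.0, 0.0, 0.0)),
            ComplicationConfig(0.0, 0.0, 0.0),
            rng,
        )
        assert rec.findings is FindingsClass.NORMAL
        assert len(p.adenomas) == 1

    def test_preclinical_cancer_detection_diagnoses(self, rng):
        p = _person(cancer=CancerState(2020, 2028))
        rec = perform_colonoscopy(
            p,
            2024,
            "after_positive_fit",
            ColonoscopyConfig(),
            ComplicationConfig(0.0, 0.0, 0.0),
            rng,
        )
        assert rec.findings is FindingsClass.CANCER and rec.newly_diagnosed
        assert p.cancer.phase == "clinical"
        assert p.cancer.detected_by == "screen"
        assert p.cancer.diagnosis_year == 2024

    def test_perforation_rate_recovered_at_10k(self):
        """Quick per-procedure complication check (the full 100k-procedure
        rate-recovery run lives in the acceptance suite)."""
        rng = random.Random(8)
        n = 10_000
        perfs = sum(
            "perforation"
            in perform_colonoscopy(
                _person(), 2024, "screening_no_fit",
                ColonoscopyConfig(), ComplicationConfig(), rng
            ).complications
            for _ in range(n)
        )
        lo = stats.binom.ppf(0.005, n, 1.7 / 1000)
        hi = stats.binom.ppf(0.995, n, 1.7 / 1000)
        assert lo <= perfs <= hi

    def test_invalid_category_rejected(self, rng):
        with pytest.raises(Exception):
            perform_colonoscopy(
                _person(), 2024, "not_a_category",
                ColonoscopyConfig(), ComplicationConfig(), rng
            )


class TestScheduleFollowup:
    def test_lra_under_new_strategy_returns_to_fit_in_5y(self):
        fu = schedule_followup(
            FindingsClass.LRA_1_2, 2024, StrategyConfig.return_to_fit()
        )
        assert fu.modality == "fit" and fu.due_year == 2029

    def test_policy_gate_pre_2023_index_behaves_status_quo(self):
        fu = schedule_followup(
            FindingsClass.LRA_1_2, 2022, StrategyConfig.return_to_fit()
        )
        assert fu.modality == "colonoscopy" and fu.due_year == 2027

    def test_lra_outside_fit_program_behaves_status_quo(self):
        fu = schedule_followup(
            FindingsClass.LRA_1_2,
            2024,
            StrategyConfig.return_to_fit(),
            in_fit_program=False,
        )
        assert fu.modality == "colonoscopy" and fu.due_year == 2029

    def test_lra_under_status_quo_surveillance_colonoscopy_in_5y(self):
        fu = schedule_followup(
            FindingsClass.LRA_1_2, 2024, StrategyConfig.status_quo()
        )
        assert fu.modality == "colonoscopy" and fu.due_year == 2029

    def test_normal_returns_to_fit_in_10y(self):
        fu = schedule_followup(FindingsClass.NORMAL, 2025, StrategyConfig.status_quo())
        assert fu.modality == "fit" and fu.due_year == 2035

    def test_high_risk_sequence_3y_then_5y(self):
        first = schedule_followup(
            FindingsClass.HIGH_RISK, 2024, StrategyConfig.status_quo()
        )
        assert first.modality == "colonoscopy"
        assert first.due_year == 2027 and first.phase == PHASE_FIRST_3Y
        # a normal result at the 3-year check still gets the 5-year follow-up
        second = schedule_followup(
            FindingsClass.NORMAL,
            2027,
            StrategyConfig.status_quo(),
            prior_phase=PHASE_FIRST_3Y,
        )
        assert second.modality == "colonoscopy"
        assert second.due_year == 2032 and second.phase == PHASE_SECOND_5Y
        # repeated high-risk findings restart the 3-year clock
        again = schedule_followup(
            FindingsClass.HIGH_RISK,
            2027,
            StrategyConfig.status_quo(),
            prior_phase=PHASE_FIRST_3Y,
        )
        assert again.due_year == 2030 and again.phase == PHASE_FIRST_3Y

    def test_cancer_schedules_next_year_surveillance(self):
        fu = schedule_followup(FindingsClass.CANCER, 2024, StrategyConfig.status_quo())
        assert fu.modality == "colonoscopy" and fu.due_year == 2025
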