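"""Adenoma-carcinoma natural-history dynamics."""

import random

import pytest
from scipy import stats

from crcsim import (
    Adenoma,
    LesionClass,
    NaturalHistoryConfig,
    Scenario,
    SizeClass,
    StrategyConfig,
    most_advanced_lesion,
    run_strategy,
    step_natural_history,
)
from crcsim.natural_history import CancerState, sample_sojourn
from crcsim.population import Person


def _person(age=60, adenomas=(), cancer=None):
    p = Person(0, 2008 - age, age)
    p.adenomas = list(adenomas)
    p.cancer = cancer
    return p


def _quiet_config(**overrides):
    """No onset, no transitions unless overridden."""
    base = dict(
        onset_base=0.0,
        onset_slope=0.0,
        grow_prob=(0.0, 0.0, 0.0),
        revert_prob=(0.0, 0.0, 0.0),
        progress_prob=(0.0, 0.0, 0.0),
    )
    base.update(overrides)
    return NaturalHistoryConfig(**base)


class TestStepNaturalHistory:
    def test_absorbing_no_event_case(self, rng):
        """All transition probabilities 0, onset 0: state unchanged."""
        cfg = _quiet_config()
        ad = Adenoma(SizeClass.MEDIUM)
        p = _person(adenomas=[ad])
        step_natural_history(p, 2010, cfg, rng)
        assert p.adenomas == [ad]
        assert ad.size_class == SizeClass.MEDIUM
        assert p.cancer is None and p.alive

    def test_forced_progression_of_large_adenoma(self, rng):
        cfg = _quiet_config(progress_prob=(0.0, 0.0, 1.0))
        p = _person(adenomas=[Adenoma(SizeClass.LARGE)])
        step_natural_history(p, 2010, cfg, rng)
        assert p.adenomas == []
        assert p.cancer is not None and p.cancer.phase == "preclinical"

    def test_growth_moves_one_adjacent_class(self, rng):
        cfg = _quiet_config(grow_prob=(1.0, 1.0, 0.0))
        p = _person(adenomas=[Adenoma(SizeClass.SMALL)])
        step_natural_history(p, 2010, cfg, rng)
        assert p.adenomas[0].size_class == SizeClass.MEDIUM
        step_natural_history(p, 2011, cfg, rng)
        assert p.adenomas[0].size_class == SizeClass.LARGE

    def test_fate_fractions_match_multinomial_oracle(self):
        """One size class with (grow, revert, progress) = (0.2, 0.1, 0.05):
        100,000 adenoma-steps match the exact multinomial within 99% bounds."""
        cfg = _quiet_config(
            grow_prob=(0.0, 0.2, 0.0),
            revert_prob=(0.0, 0.1, 0.0),
            progress_prob=(0.0, 0.05, 0.05),
        )
        n = 100_000
        rng = random.Random(99)
        counts = {"grow": 0, "revert": 0, "progress": 0, "stay": 0}
        for _ in range(n):
            p = _person(adenomas=[Adenoma(SizeClass.MEDIUM)])
            step_natural_history(p, 2010, cfg, rng)
            if p.cancer is not None:
                counts["progress"] += 1
            elif not p.adenomas:
                counts["revert"] += 1
            elif p.adenomas[0].size_class == SizeClass.LARGE:
                counts["grow"] += 1
            else:
                counts["stay"] += 1
        expected = {"grow": 0.2, "revert": 0.1, "progress": 0.05, "stay": 0.65}
        for fate, prob in expected.items():
            lo = stats.binom.ppf(0.005, n, prob)
            hi = stats.binom.ppf(0.995, n, prob)
            assert lo <= counts[fate] <= hi, fate

    def test_onset_adds_small_adenoma(self, rng):
        cfg = _quiet_config(onset_base=1.0)
        p = _person()
        step_natural_history(p, 2010, cfg, rng)
        assert len(p.adenomas) == 1
        assert p.adenomas[0].size_class == SizeClass.SMALL

    def test_clinical_cancer_death_hazard(self):
        cfg = _quiet_config(crc_annual_death_prob=1.0)
        cancer = CancerState(2005, 2006)
        cancer.diagnose(2008, "symptoms")
        p = _person(cancer=cancer)
        step_natural_history(p, 2010, cfg, random.Random(1))
        assert not p.alive and p.death_cause == "crc"

    def test_probabilities_outside_unit_interval_rejected(self):
        with pytest.raises(Exception):
            NaturalHistoryConfig(grow_prob=(1.2, 0.0, 0.0))


class TestMostAdvancedLesion:
    @pytest.mark.parametrize(
        "adenomas, cancer, expected",
        [
            ((), None, LesionClass.NONE),
            (
                (Adenoma(SizeClass.SMALL), Adenoma(SizeClass.MEDIUM)),
                None,
                LesionClass.ADENOMA_MEDIUM,
            ),
            ((Adenoma(SizeClass.LARGE),), None, LesionClass.ADENOMA_LARGE),
            (
                (Adenoma(SizeClass.LARGE),),
                CancerState(2005, 2012),
                LesionClass.PRECLINICAL_CRC,
            ),
        ],
    )
    def test_hierarchy_maximum(self, adenomas, cancer, expected):
        assert most_advanced_lesion(_person(adenomas=adenomas, cancer=cancer)) == expected


class TestPopulationLevelProperties:
    def test_zero_onset_zero_incidence(self):
        """No onset and empty initial adenoma sets: CRC incidence exactly 0."""
        scenario = Scenario().scaled(1000)
        scenario.natural_history = _quiet_config(
            grow_prob=(0.05, 0.05, 0.0),
            revert_prob=(0.1, 0.05, 0.02),
            progress_prob=(0.01, 0.02, 0.04),
        )
        res = run_strategy(scenario, StrategyConfig.status_quo(), seed=11)
        frame = res.frame()
        assert int(frame["crc_cases"].sum()) == 0
        assert int(frame["crc_deaths"].sum()) == 0

    def test_raising_progression_never_lowers_incidence(self):
        """Monotone hazard at two config points with common random numbers."""

        def cancer_ever(progress_large):
            cfg = NaturalHistoryConfig(
                progress_prob=(0.0004, 0.004, progress_large)
            )
            count = 0
            for pid in range(4000):
                rng = random.Random(1_000_003 + pid)  # shared across configs
                p = _person(age=60, adenomas=[Adenoma(SizeClass.MEDIUM)])
                for year in range(2010, 2030):
                    step_natural_history(p, year, cfg, rng)
                    if not p.alive:
                        break
                count += p.cancer is not None or p.death_cause == "crc"
            return count

        assert cancer_ever(0.08) >= cancer_ever(0.02)

    def test_default_progression_strictly_increasing(self):
        """The shipped default encodes elevated risk in every size class."""
        p0, p1, p2 = NaturalHistoryConfig().progress_prob
        assert p2 > p1 >= p0 > 0.0


def test_sojourn_sample_mean_matches_config():
    cfg = NaturalHistoryConfig(sojourn_mean_years=4.0)
    rng = random.Random(5)
    n = 20_000
    mean = sum(sample_sojourn(cfg, rng) for _ in range(n)) / n
    assert abs(mean - 4.0) < 0.1
    assert all(sample_sojourn(cfg, rng) >= 1 for _ in range(100))
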