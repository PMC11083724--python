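"""Paired strategy experiments, replicate statistics, and report tables.

The comparison runs both follow-up strategies on the same sequence of
replicate populations (common random numbers by default), averages each
outcome over the 20 reporting years within each run, and summarises the
per-replicate differences (new strategy minus status quo) with a two-sided
95% t-interval. Incremental complication counts are derived by multiplying
the incremental number of colonoscopies by the per-procedure incidence
rates, mirroring how screening programs report them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .colonoscopy import CATEGORIES
from .config import (
    ComplicationConfig,
    ConfigurationError,
    Scenario,
    StrategyConfig,
)
from .simulate import SimulationResult, derive_seed, run_strategy

__all__ = [
    "ReplicatePair",
    "IncrementalReport",
    "run_replicates",
    "incremental_ci",
    "complication_increment",
    "build_incremental_report",
    "write_reports",
    "round_half_away",
]

#: Outcome columns summarised in the incremental report.
OUTCOME_COLUMNS = (
    "crc_cases",
    "crc_deaths",
    "fit_screens",
    "colo_screening_no_fit",
    "colo_after_positive_fit",
    "colo_symptomatic_diagnostic",
    "colo_surveillance_after_adenoma",
    "colo_surveillance_after_cancer",
    "total_colonoscopies",
    "major_bleeds",
    "perforations",
    "cost_screening",
    "cost_clinical_diagnosis",
    "cost_cancer_management",
    "cost_screening_diagnostics",
    "cost_total",
)


def round_half_away(x: float) -> int:
    """Round to nearest integer with halves away from zero (display rule)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class ReplicatePair:
    """One replicate: both strategy runs plus the seeds that produced them."""

    replicate: int
    seed_status_quo: int
    seed_new: int
    status_quo: pd.DataFrame  # per-year outcomes, reporting window
    new: pd.DataFrame


def run_replicates(
    scenario: Scenario,
    strategies: tuple[StrategyConfig, StrategyConfig] | None = None,
    n_replicates: int = 12,
    seed: int = 1,
    common_random_numbers: bool = True,
) -> list[ReplicatePair]:
    """Run paired strategy simulations.

    Each replicate builds a fresh population and runs both strategies on
    it. With ``common_random_numbers`` (default) the two arms share every
    random stream, so differences reflect the strategy alone; otherwise the
    arms use independent streams.
    """
    if n_replicates < 2:
        raise ConfigurationError(
            "n_replicates must be >= 2 (confidence interval impossible)"
        )
    if strategies is None:
        strategies = (StrategyConfig.status_quo(), StrategyConfig.return_to_fit())
    sq_strategy, new_strategy = strategies
    start, end = scenario.report_start, scenario.report_end

    pairs: list[ReplicatePair] = []
    for rep in range(n_replicates):
        seed_sq = derive_seed(seed, 1_000 + rep)
        seed_new = (
            seed_sq if common_random_numbers else derive_seed(seed, 2_000 + rep)
        )
        res_sq = run_strategy(scenario, sq_strategy, seed_sq)
        res_new = run_strategy(scenario, new_strategy, seed_new)
        pairs.append(
            ReplicatePair(
                replicate=rep,
                seed_status_quo=seed_sq,
                seed_new=seed_new,
                status_quo=res_sq.window(start, end),
                new=res_new.window(start, end),
            )
        )
    return pairs


def incremental_ci(differences) -> tuple[float, float, float]:
    """Mean and two-sided 95% t-interval of per-replicate differences.

    Returns ``(mean, ci_low, ci_high)``; zero variance degenerates to
    ``(mean, mean, mean)``.
    """
    diffs = np.asarray(list(differences), dtype=float)
    n = diffs.size
    if n < 2:
        raise ConfigurationError("need at least 2 replicates for a t-interval")
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    if sd == 0.0:
        return mean, mean, mean
    half = float(stats.t.ppf(0.975, n - 1)) * sd / math.sqrt(n)
    return mean, mean - half, mean + half


def complication_increment(
    colonoscopy_diff: float, rates: ComplicationConfig
) -> dict:
    """Incremental complications implied by an incremental colonoscopy count.

    Multiplies the incremental number of colonoscopies by the per-1000
    incidence rates; returns raw products and display-rounded integers.
    """
    bleed = colonoscopy_diff * rates.major_bleed_per_1000 / 1000.0
    perf = colonoscopy_diff * rates.perforation_per_1000 / 1000.0
    return {
        "major_bleed_diff": bleed,
        "major_bleed_diff_rounded": round_half_away(bleed),
        "perforation_diff": perf,
        "perforation_diff_rounded": round_half_away(perf),
    }


@dataclass
class IncrementalReport:
    """Average-annual incremental outcomes with replicate t-intervals.

    ``table`` has one row per outcome: status-quo and new-strategy means,
    mean difference, the 95% t-interval, and percent change versus the
    status quo. ``complication_increments`` holds the multiplication-derived
    bleed/perforation differences; ``timeseries`` the per-year mean
    incremental series behind the "savings begin 5 years after switching"
    check.
    """

    table: pd.DataFrame
    complication_increments: dict
    timeseries: pd.DataFrame
    n_replicates: int


def _average_annual(frame: pd.DataFrame) -> pd.Series:
    return frame[list(OUTCOME_COLUMNS)].mean(axis=0)


def build_incremental_report(
    pairs: list[ReplicatePair],
    complications: ComplicationConfig | None = None,
) -> IncrementalReport:
    """Summarise replicate pairs into the incremental report."""
    complications = complications or ComplicationConfig()
    sq = pd.DataFrame([_average_annual(p.status_quo) for p in pairs])
    new = pd.DataFrame([_average_annual(p.new) for p in pairs])
    diffs = new - sq

    rows = []
    for col in OUTCOME_COLUMNS:
        mean, lo, hi = incremental_ci(diffs[col])
        sq_mean = float(sq[col].mean())
        pct = (mean / sq_mean * 100.0) if sq_mean != 0.0 else float("nan")
        rows.append(
            {
                "outcome": col,
                "status_quo": sq_mean,
                "new_strategy": float(new[col].mean()),
                "diff": mean,
                "ci_low": lo,
                "ci_high": hi,
                "pct_change": pct,
            }
        )
    table = pd.DataFrame(rows).set_index("outcome")

    incs = complication_increment(
        float(table.loc["total_colonoscopies", "diff"]), complications
    )

    # per-year mean incremental series across replicates
    yearly_diff = sum(
        p.new[list(OUTCOME_COLUMNS)] - p.status_quo[list(OUTCOME_COLUMNS)]
        for p in pairs
    ) / len(pairs)
    timeseries = yearly_diff[
        ["fit_screens", "total_colonoscopies",
         "colo_surveillance_after_adenoma", "cost_total"]
    ].rename(columns=lambda c: f"incremental_{c}")

    return IncrementalReport(
        table=table,
        complication_increments=incs,
        timeseries=timeseries,
        n_replicates=len(pairs),
    )


# ---------------------------------------------------------------------------
# report rendering

_VOLUME_ROWS = [
    ("FIT screens", "fit_screens"),
    ("Screening colonoscopies without FIT", "colo_screening_no_fit"),
    ("Colonoscopies after a positive FIT", "colo_after_positive_fit"),
    ("Colonoscopies for symptomatic patients", "colo_symptomatic_diagnostic"),
    (
        "Surveillance colonoscopies after adenoma detection",
        "colo_surveillance_after_adenoma",
    ),
    (
        "Surveillance colonoscopies after cancer detection",
        "colo_surveillance_after_cancer",
    ),
    ("Total number of colonoscopies", "total_colonoscopies"),
]

_COST_ROWS = [
    ("Cost of screening", "cost_screening"),
    ("Cost of clinical diagnosis", "cost_clinical_diagnosis"),
    ("Cost of cancer management", "cost_cancer_management"),
    ("Total cost (screening and diagnostics)", "cost_screening_diagnostics"),
    ("Total cost (all categories)", "cost_total"),
]


def _display_table(
    table: pd.DataFrame, rows: list[tuple[str, str]]
) -> pd.DataFrame:
    out = []
    for label, col in rows:
        r = table.loc[col]
        out.append(
            {
                "outcome": label,
                "status_quo": round_half_away(r["status_quo"]),
                "new_strategy": round_half_away(r["new_strategy"]),
                "diff": round_half_away(r["diff"]),
                "pct_change": round(r["pct_change"], 1),
            }
        )
    return pd.DataFrame(out).set_index("outcome")


def write_reports(report: IncrementalReport, outdir: str | Path) -> dict:
    """Write the three incremental tables plus the per-year series as CSV.

    Verifies the structural identities before writing: the five colonoscopy
    category rows sum to the total, and the three cost groups sum to the
    all-categories total. Returns the written frames keyed by file stem.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = report.table

    # partition identity: categories sum to the total, exactly
    for col in ("status_quo", "new_strategy", "diff"):
        cat_sum = sum(
            table.loc[f"colo_{c}", col] for c in CATEGORIES
        )
        assert math.isclose(
            cat_sum, table.loc["total_colonoscopies", col], abs_tol=1e-6
        ), "colonoscopy categories do not sum to the total"
        group_sum = (
            table.loc["cost_screening", col]
            + table.loc["cost_clinical_diagnosis", col]
            + table.loc["cost_cancer_management", col]
        )
        assert math.isclose(
            group_sum, table.loc["cost_total", col], abs_tol=1e-4
        ), "cost groups do not sum to the total"

    incs = report.complication_increments
    outcomes = pd.DataFrame(
        [
            {
                "outcome": "CRC cases",
                "status_quo": round_half_away(table.loc["crc_cases", "status_quo"]),
                "new_strategy": round_half_away(
                    table.loc["crc_cases", "new_strategy"]
                ),
                "diff": round_half_away(table.loc["crc_cases", "diff"]),
                "ci_low": round(table.loc["crc_cases", "ci_low"], 1),
                "ci_high": round(table.loc["crc_cases", "ci_high"], 1),
            },
            {
                "outcome": "CRC deaths",
                "status_quo": round_half_away(table.loc["crc_deaths", "status_quo"]),
                "new_strategy": round_half_away(
                    table.loc["crc_deaths", "new_strategy"]
                ),
                "diff": round_half_away(table.loc["crc_deaths", "diff"]),
                "ci_low": round(table.loc["crc_deaths", "ci_low"], 1),
                "ci_high": round(table.loc["crc_deaths", "ci_high"], 1),
            },
            {
                "outcome": "Major bleed from colonoscopy",
                "status_quo": round_half_away(
                    table.loc["major_bleeds", "status_quo"]
                ),
                "new_strategy": round_half_away(
                    table.loc["major_bleeds", "new_strategy"]
                ),
                "diff": incs["major_bleed_diff_rounded"],
                "ci_low": float("nan"),
                "ci_high": float("nan"),
            },
            {
                "outcome": "Perforation from colonoscopy",
                "status_quo": round_half_away(
                    table.loc["perforations", "status_quo"]
                ),
                "new_strategy": round_half_away(
                    table.loc["perforations", "new_strategy"]
                ),
                "diff": incs["perforation_diff_rounded"],
                "ci_low": float("nan"),
                "ci_high": float("nan"),
            },
        ]
    ).set_index("outcome")

    volumes = _display_table(table, _VOLUME_ROWS)
    costs = _display_table(table, _COST_ROWS)

    frames = {
        "outcomes": outcomes,
        "volumes": volumes,
        "costs": costs,
        "timeseries": report.timeseries,
        "incremental_raw": table,
    }
    for stem, frame in frames.items():
        frame.to_csv(outdir / f"{stem}.csv")
    return frames
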