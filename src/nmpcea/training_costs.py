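"""Cost of training one professional in non-medical prescribing.

Components: course fee, employer-paid additional study days, the opportunity
cost of time off work for the 26 taught + 12 supervised course days (costed
at 50% of work time -- staff backfill), personal study time, and itemized
out-of-pocket (OOP) expenses.  Two costing scenarios are supported:
scenario 1 includes OOP expenses and personal study time (assumed
reimbursable by the employer), scenario 2 excludes both.  Supervised-day
costs are part of the course fee and are never added separately.

The daily salary rate convention is annual salary / 365, which reproduces
the published component costs (e.g. backfill 48,456/365 x 38 x 0.5 = 2,522).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .params_io import Param, round_pounds

__all__ = [
    "TrainingCostInputs",
    "TrainingCostBreakdown",
    "daily_rate",
    "employer_study_cost",
    "time_off_cost",
    "personal_study_cost",
    "total_training_cost",
    "training_cost_per_contact",
]

DAYS_PER_YEAR = 365.0


@dataclass(frozen=True)
class TrainingCostInputs:
    course_fee: float
    annual_salary: float
    employer_paid_days: float
    taught_days: float = 26.0
    supervised_days: float = 12.0
    work_time_fraction: float = 0.5
    personal_study_days: float = 0.0
    oop_travel: float = 0.0
    oop_materials: float = 0.0
    oop_other: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "course_fee",
            "annual_salary",
            "employer_paid_days",
            "taught_days",
            "supervised_days",
            "personal_study_days",
            "oop_travel",
            "oop_materials",
            "oop_other",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not (0.0 <= self.work_time_fraction <= 1.0):
            raise ValueError("work_time_fraction must be in [0, 1]")

    @classmethod
    def from_params(cls, training: Mapping[str, Param]) -> "TrainingCostInputs":
        return cls(**{k: p.point for k, p in training.items()})


@dataclass(frozen=True)
class TrainingCostBreakdown:
    """Unrounded component costs; round only when reporting."""

    course_fee: float
    employer_study_cost: float
    time_off_cost: float
    oop_total: float
    personal_study_cost: float

    @property
    def total_including_oop(self) -> float:
        return (
            self.course_fee
            + self.employer_study_cost
            + self.time_off_cost
            + self.oop_total
            + self.personal_study_cost
        )

    @property
    def total_excluding_oop(self) -> float:
        return self.course_fee + self.employer_study_cost + self.time_off_cost

    def total(self, scenario: str) -> float:
        if scenario == "include_oop":
            return self.total_including_oop
        if scenario == "exclude_oop":
            return self.total_excluding_oop
        raise ValueError(f"unknown scenario {scenario!r}")


def daily_rate(annual_salary: float) -> float:
    """Daily salary rate, annual salary / 365."""
    if annual_salary < 0:
        raise ValueError("annual_salary must be nonnegative")
    return annual_salary / DAYS_PER_YEAR


def employer_study_cost(annual_salary: float, paid_days: float) -> float:
    """Cost of employer-paid additional study days."""
    if paid_days < 0:
        raise ValueError("paid_days must be nonnegative")
    return daily_rate(annual_salary) * paid_days


def time_off_cost(
    annual_salary: float,
    taught_days: float,
    supervised_days: float,
    work_time_fraction: float,
) -> float:
    """Staff-backfill opportunity cost of the course days.

    Trainees spend about half their work time on the programme, so the
    taught + supervised days are costed at *work_time_fraction* of the
    daily rate.
    """
    if taught_days < 0 or supervised_days < 0:
        raise ValueError("day counts must be nonnegative")
    if not (0.0 <= work_time_fraction <= 1.0):
        raise ValueError("work_time_fraction must be in [0, 1]")
    return daily_rate(annual_salary) * (taught_days + supervised_days) * work_time_fraction


def personal_study_cost(annual_salary: float, study_days: float) -> float:
    """Cost of personal study time at the full daily rate."""
    if study_days < 0:
        raise ValueError("study_days must be nonnegative")
    return daily_rate(annual_salary) * study_days


def total_training_cost(
    inputs: TrainingCostInputs,
    scenario: str = "include_oop",
    component_overrides: Mapping[str, float] | None = None,
) -> TrainingCostBreakdown:
    """Aggregate per-prescriber training cost under one OOP scenario.

    *component_overrides* replaces derived component costs with published
    survey means where those were computed on unrounded sample data (e.g.
    a personal-study mean that is not exactly mean-days x daily-rate).
    Keys: employer_study_cost, time_off_cost, personal_study_cost.
    """
    comp = {
        "employer_study_cost": employer_study_cost(
            inputs.annual_salary, inputs.employer_paid_days
        ),
        "time_off_cost": time_off_cost(
            inputs.annual_salary,
            inputs.taught_days,
            inputs.supervised_days,
            inputs.work_time_fraction,
        ),
        "personal_study_cost": personal_study_cost(
            inputs.annual_salary, inputs.personal_study_days
        ),
    }
    if component_overrides:
        unknown = set(component_overrides) - set(comp)
        if unknown:
            raise ValueError(f"unknown component overrides: {sorted(unknown)}")
        comp.update({k: float(v) for k, v in component_overrides.items()})
    breakdown = TrainingCostBreakdown(
        course_fee=inputs.course_fee,
        employer_study_cost=comp["employer_study_cost"],
        time_off_cost=comp["time_off_cost"],
        oop_total=inputs.oop_travel + inputs.oop_materials + inputs.oop_other,
        personal_study_cost=comp["personal_study_cost"],
    )
    breakdown.total(scenario)  # validates the scenario name
    return breakdown


def training_cost_per_contact(
    total: float, contacts_per_week: float, weeks: float
) -> float:
    """Training cost spread over one year of patient contacts."""
    if contacts_per_week <= 0 or weeks <= 0:
        raise ValueError("contacts_per_week and weeks must be positive")
    return total / (contacts_per_week * weeks)


def training_table(breakdown: TrainingCostBreakdown) -> dict[str, int]:
    """Reporting view: components and totals rounded to the nearest pound."""
    return {
        "course_fee": round_pounds(breakdown.course_fee),
        "employer_study_cost": round_pounds(breakdown.employer_study_cost),
        "time_off_cost": round_pounds(breakdown.time_off_cost),
        "oop_total": round_pounds(breakdown.oop_total),
        "personal_study_cost": round_pounds(breakdown.personal_study_cost),
        "total_including_oop": round_pounds(breakdown.total_including_oop),
        "total_excluding_oop": round_pounds(breakdown.total_excluding_oop),
    }
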