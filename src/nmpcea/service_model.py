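"""Decision-tree service costs per arm and multi-year horizon totals.

Each arm (prescriber / non-prescriber) sees ``contacts_per_week x
weeks_per_year`` patient contacts a year.  A contact that requires
prescription management *and* where the professional uses their own
prescribing qualification is priced at the dearer consultation rate
(including prescribing-related activities); every other contact is priced
at the standard rate.  Independently, a fraction of contacts is referred to
another prescriber (e.g. a GP), adding a referral consultation cost on top.
The non-prescriber arm never uses prescribing rights and carries no
training cost.

Horizon totals add the (undiscounted, year-1) training cost to the annual
service cost stream; service costs in years 2..H are discounted at the
annual rate r (year t gets weight (1+r)^-(t-1)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .params_io import Param

__all__ = [
    "ActivityProfile",
    "ArmCostSummary",
    "annual_contacts",
    "expected_contact_cost",
    "expected_annual_service_cost",
    "discount_factors",
    "discounted_horizon_total",
    "arm_saving",
]


@dataclass(frozen=True)
class ActivityProfile:
    """Point-estimate activity profile for one arm."""

    contacts_per_week: float
    weeks_per_year: float
    p_require_rx: float
    p_use_rights: float
    p_refer: float
    c_consult_std: float
    c_consult_rx: float
    c_referral: float

    def __post_init__(self) -> None:
        for name in ("p_require_rx", "p_use_rights", "p_refer"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.c_consult_rx < self.c_consult_std or self.c_consult_std < 0:
            raise ValueError("require c_consult_rx >= c_consult_std >= 0")
        if self.contacts_per_week < 0 or self.weeks_per_year < 0:
            raise ValueError("contact volumes must be nonnegative")

    @classmethod
    def from_params(
        cls, activity: dict[str, Param], weeks_per_year: float = 48.0
    ) -> "ActivityProfile":
        pts = {k: p.point for k, p in activity.items()}
        return cls(weeks_per_year=weeks_per_year, **pts)


@dataclass(frozen=True)
class ArmCostSummary:
    """Expected cost of one decision-tree arm over the analysis horizon."""

    annual_service_cost: float
    training_cost: float
    years: int
    discount_rate: float
    discounted_stream: tuple[float, ...] = field(default=())

    @property
    def horizon_total(self) -> float:
        return self.training_cost + sum(self.discounted_stream)


def annual_contacts(profile: ActivityProfile) -> float:
    """Patient contacts per year for one professional."""
    return profile.contacts_per_week * profile.weeks_per_year


def expected_contact_cost(profile: ActivityProfile) -> float:
    """Expected cost per patient contact (consultation + referral add-on)."""
    p_rx = profile.p_require_rx * profile.p_use_rights
    consult = p_rx * profile.c_consult_rx + (1.0 - p_rx) * profile.c_consult_std
    return consult + profile.p_refer * profile.c_referral


def expected_annual_service_cost(profile: ActivityProfile) -> float:
    """Expected annual consultation + prescribing + referral cost."""
    return annual_contacts(profile) * expected_contact_cost(profile)


def discount_factors(years: int, r: float) -> list[float]:
    """Per-year present-value weights; year 1 undiscounted."""
    if years < 1:
        raise ValueError("years must be >= 1")
    if not (0.0 <= r < 1.0):
        raise ValueError("discount rate must be in [0, 1)")
    return [(1.0 + r) ** (-t) for t in range(years)]


def discounted_horizon_total(
    annual_cost: float, training_cost: float, years: int, r: float
) -> ArmCostSummary:
    """Horizon total: year-1 training cost plus discounted service stream."""
    weights = discount_factors(years, r)
    return ArmCostSummary(
        annual_service_cost=annual_cost,
        training_cost=training_cost,
        years=years,
        discount_rate=r,
        discounted_stream=tuple(annual_cost * w for w in weights),
    )


def arm_saving(cost_comparator: float, cost_intervention: float) -> float:
    """Comparator minus intervention; positive means the intervention saves."""
    return cost_comparator - cost_intervention
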