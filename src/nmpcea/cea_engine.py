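"""Cost-effectiveness engine: ICER, NMB, PSA with CEAC, tornado DSA.

Deterministic layer: incremental cost and effect between the prescriber
(intervention) and non-prescriber (comparator) arms, the ICER dC/dE with
its cost-effectiveness-plane quadrant, and the net monetary benefit
NMB(lambda) = lambda x dE - dC with the strict decision rule NMB > 0.

Probabilistic layer: Monte-Carlo propagation of parameter uncertainty.
Distribution families follow standard health-technology-assessment
practice -- gamma for nonnegative costs, beta for probabilities (both
moment-matched to the point estimate with SD = (high - low) / 4 when only
a range is published), normal for effect differences (SE from the
bootstrap CI width / 3.92) -- and every assignment can be overridden per
parameter.  The default PSA for the shipped fixtures samples the per-arm
per-patient cost summaries and the adjusted QALY difference, the published
uncertainty actually available at arm level.

One-way deterministic sensitivity: each ranged parameter in turn is set to
its low and high bound, holding all others at their points, and the chosen
output (NMB at the willingness-to-pay threshold by default) is recomputed
through the decision tree; entries are ranked by swing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .params_io import ModelConfig, Param, ParameterFixture
from .training_costs import TrainingCostInputs, total_training_cost, training_cost_per_contact

__all__ = [
    "incremental",
    "quadrant",
    "ICERResult",
    "icer",
    "nmb",
    "ParameterDistribution",
    "PSASpec",
    "sample_parameters",
    "default_psa_spec",
    "ceac_from_cloud",
    "CEResult",
    "deterministic_ce",
    "run_psa",
    "per_patient_arm_cost",
    "TornadoEntry",
    "tornado_one_way",
    "DEFAULT_LAMBDA_GRID",
]

#: willingness-to-pay grid for CEACs: 0..50,000 in steps of 1,000 (always
#: includes the 30,000/QALY threshold)
DEFAULT_LAMBDA_GRID = tuple(float(v) for v in range(0, 50_001, 1_000))


def incremental(
    cost_p: float, cost_np: float, eff_p: float, eff_np: float
) -> tuple[float, float]:
    """(dC, dE) of the prescriber arm relative to the non-prescriber arm."""
    return cost_p - cost_np, eff_p - eff_np


def quadrant(d_cost: float, d_effect: float) -> str:
    """Cost-effectiveness-plane quadrant of (dC, dE); 'on-axis' at zero."""
    if d_cost == 0.0 or d_effect == 0.0:
        return "on-axis"
    if d_cost > 0.0:
        return "NE" if d_effect > 0.0 else "NW"
    return "SE" if d_effect > 0.0 else "SW"


@dataclass(frozen=True)
class ICERResult:
    """ICER with its quadrant; value is None when dE = 0 (undefined)."""

    value: float | None
    quadrant: str
    d_cost: float
    d_effect: float

    @property
    def label(self) -> str:
        if self.value is None:
            return "undefined (zero effect difference)"
        unit = "per QALY gained" if self.d_effect > 0 else "per QALY lost"
        return f"{self.value:,.0f} {unit} ({self.quadrant})"


def icer(d_cost: float, d_effect: float) -> ICERResult:
    """Incremental cost-effectiveness ratio, quadrant-qualified."""
    value = None if d_effect == 0.0 else d_cost / d_effect
    return ICERResult(value=value, quadrant=quadrant(d_cost, d_effect),
                      d_cost=d_cost, d_effect=d_effect)


def nmb(wtp: float, d_effect: float, d_cost: float) -> float:
    """Net monetary benefit lambda x dE - dC (cost-effective iff > 0)."""
    if wtp < 0:
        raise ValueError("willingness to pay must be nonnegative")
    return wtp * d_effect - d_cost


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


@dataclass(frozen=True)
class ParameterDistribution:
    """Sampling assignment for one parameter (moment-matched to mean/sd)."""

    name: str
    family: str  # fixed | gamma | beta | normal
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.family not in ("fixed", "gamma", "beta", "normal"):
            raise ValueError(f"unsupported distribution family {self.family!r}")
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")
        if self.family == "beta" and not (0.0 <= self.mean <= 1.0):
            raise ValueError("beta-assigned parameter must have mean in [0, 1]")
        if self.family == "gamma" and self.mean < 0:
            raise ValueError("gamma-assigned parameter must have mean >= 0")

    @classmethod
    def from_param(cls, name: str, p: Param) -> "ParameterDistribution":
        sd = p.width / 4.0
        family = p.dist if (p.dist != "fixed" and sd > 0) else "fixed"
        return cls(name=name, family=family, mean=p.point, sd=0.0 if family == "fixed" else sd)

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "fixed" or self.sd == 0.0:
            return np.full(n, self.mean)
        if self.family == "normal":
            return rng.normal(self.mean, self.sd, n)
        if self.family == "gamma":
            if self.mean == 0.0:
                return np.zeros(n)
            shape = (self.mean / self.sd) ** 2
            scale = self.sd**2 / self.mean
            return rng.gamma(shape, scale, n)
        # beta, method of moments; cap sd at the feasible maximum
        m = self.mean
        if m in (0.0, 1.0):
            return np.full(n, m)
        var = min(self.sd**2, 0.999 * m * (1.0 - m))
        nu = m * (1.0 - m) / var - 1.0
        return rng.beta(m * nu, (1.0 - m) * nu, n)


@dataclass(frozen=True)
class PSASpec:
    """Full distribution assignment for one Monte-Carlo run."""

    distributions: tuple[ParameterDistribution, ...]
    iterations: int = 5_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        names = [d.name for d in self.distributions]
        if len(names) != len(set(names)):
            raise ValueError("duplicate parameter names in PSA spec")


def sample_parameters(spec: PSASpec) -> pd.DataFrame:
    """Draw the full (iterations x parameters) matrix, reproducibly."""
    rng = np.random.default_rng(spec.seed)
    return pd.DataFrame(
        {d.name: d.draw(spec.iterations, rng) for d in spec.distributions}
    )


def default_psa_spec(
    fixture: ParameterFixture, config: ModelConfig, outcome: str = "qaly"
) -> PSASpec:
    """Arm-level PSA: gamma per-arm patient costs, normal effect difference.

    Uses the published per-patient cost means/SDs per arm and the bootstrap
    CI of the adjusted difference (SE = CI width / 3.92).
    """
    ppc = fixture.reported["per_patient_cost"]
    eff = fixture.effects[outcome]
    se = (eff.ci_high - eff.ci_low) / 3.92
    dists = (
        ParameterDistribution("cost_prescriber", "gamma",
                              float(ppc["prescriber"]["mean"]),
                              float(ppc["prescriber"]["sd"])),
        ParameterDistribution("cost_non_prescriber", "gamma",
                              float(ppc["non_prescriber"]["mean"]),
                              float(ppc["non_prescriber"]["sd"])),
        ParameterDistribution("effect_difference", "normal", eff.difference, se),
    )
    return PSASpec(distributions=dists, iterations=config.psa_iterations,
                   seed=config.rng_seed)


def ceac_from_cloud(
    d_cost: np.ndarray, d_effect: np.ndarray, lambdas: Sequence[float]
) -> pd.DataFrame:
    """P(cost-effective) over a WTP grid: fraction with lambda x dE - dC > 0."""
    d_cost = np.asarray(d_cost, float)
    d_effect = np.asarray(d_effect, float)
    rows = [
        (lam, float(np.mean(lam * d_effect - d_cost > 0.0))) for lam in lambdas
    ]
    return pd.DataFrame(rows, columns=["wtp", "p_cost_effective"])


@dataclass(frozen=True)
class CEResult:
    """Deterministic CEA result, optionally with a PSA cloud attached."""

    outcome: str
    delta_cost: float
    delta_effect: float
    icer: ICERResult
    wtp: float
    nmb: float
    p_cost_effective: float | None = None
    ceac: pd.DataFrame | None = None
    psa_cloud: pd.DataFrame | None = None
    quadrant_shares: dict[str, float] = field(default_factory=dict)

    @property
    def quadrant(self) -> str:
        return self.icer.quadrant


def deterministic_ce(
    fixture: ParameterFixture, config: ModelConfig, outcome: str = "qaly"
) -> CEResult:
    """Base-case CEA from the fixture's per-patient arm summaries."""
    ppc = fixture.reported["per_patient_cost"]
    eff = fixture.effects[outcome]
    d_cost, d_effect = incremental(
        float(ppc["prescriber"]["mean"]), float(ppc["non_prescriber"]["mean"]),
        eff.mean_prescriber, eff.mean_non_prescriber,
    )
    # the published difference is quoted directly where available (it was
    # computed on unrounded arm summaries)
    d_effect = eff.difference
    return CEResult(
        outcome=outcome,
        delta_cost=d_cost,
        delta_effect=d_effect,
        icer=icer(d_cost, d_effect),
        wtp=config.wtp_threshold,
        nmb=nmb(config.wtp_threshold, d_effect, d_cost),
    )


def run_psa(
    fixture: ParameterFixture,
    config: ModelConfig,
    spec: PSASpec | None = None,
    outcome: str = "qaly",
    lambdas: Sequence[float] = DEFAULT_LAMBDA_GRID,
) -> CEResult:
    """Monte-Carlo PSA: sample all distributions simultaneously, build the
    (dC, dE) cloud, the CEAC and quadrant occupancy."""
    spec = spec or default_psa_spec(fixture, config, outcome)
    draws = sample_parameters(spec)
    d_cost = (draws["cost_prescriber"] - draws["cost_non_prescriber"]).to_numpy()
    d_effect = draws["effect_difference"].to_numpy()

    base = deterministic_ce(fixture, config, outcome)
    lambdas = list(lambdas)
    if config.wtp_threshold not in lambdas:
        lambdas = sorted(lambdas + [config.wtp_threshold])
    curve = ceac_from_cloud(d_cost, d_effect, lambdas)
    p_ce = float(
        curve.loc[curve["wtp"] == config.wtp_threshold, "p_cost_effective"].iloc[0]
    )
    labels = np.where(
        (d_cost == 0) | (d_effect == 0), "on-axis",
        np.where(d_cost > 0, np.where(d_effect > 0, "NE", "NW"),
                 np.where(d_effect > 0, "SE", "SW")),
    )
    shares = {q: float(np.mean(labels == q)) for q in ("NE", "NW", "SE", "SW")}
    return replace(
        base,
        p_cost_effective=p_ce,
        ceac=curve,
        psa_cloud=pd.DataFrame({"delta_cost": d_cost, "delta_effect": d_effect}),
        quadrant_shares=shares,
    )


# ---------------------------------------------------------------------------
# de-novo decision-tree output and one-way DSA


def per_patient_arm_cost(
    fixture: ParameterFixture,
    config: ModelConfig,
    arm: str,
    overrides: dict[str, float] | None = None,
) -> float:
    """Per-patient annual cost of one arm from the decision tree.

    Expected consultation + referral cost per contact, plus (prescriber arm
    only) the training cost spread over the year's contacts.  *overrides*
    maps flat parameter paths (``activity.<arm>.<name>`` or
    ``training.<name>``) to replacement values, used by the tornado DSA.
    The branch expectation is computed directly (not through
    :class:`ActivityProfile`) so that one-way excursions may transiently
    cross the point-estimate ordering of the two consultation rates.
    """
    overrides = overrides or {}
    act = {
        k: float(overrides.get(f"activity.{arm}.{k}", p.point))
        for k, p in fixture.activity[arm].items()
    }
    p_rx = act["p_require_rx"] * act["p_use_rights"]
    cost = (
        p_rx * act["c_consult_rx"]
        + (1.0 - p_rx) * act["c_consult_std"]
        + act["p_refer"] * act["c_referral"]
    )
    if arm == "prescriber":
        tr = {
            k: float(overrides.get(f"training.{k}", p.point))
            for k, p in fixture.training.items()
        }
        total = total_training_cost(
            TrainingCostInputs(**tr), config.oop_scenario
        ).total(config.oop_scenario)
        cost += training_cost_per_contact(
            total, act["contacts_per_week"], config.weeks_per_year
        )
    return cost


def _denovo_nmb(
    fixture: ParameterFixture,
    config: ModelConfig,
    outcome: str,
    overrides: dict[str, float],
) -> float:
    cost_p = per_patient_arm_cost(fixture, config, "prescriber", overrides)
    cost_np = per_patient_arm_cost(fixture, config, "non_prescriber", overrides)
    d_effect = float(
        overrides.get("effects.difference", fixture.effects[outcome].difference)
    )
    return nmb(config.wtp_threshold, d_effect, cost_p - cost_np)


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low: float
    high: float
    output_at_low: float
    output_at_high: float
    base_output: float

    @property
    def swing(self) -> float:
        return abs(self.output_at_high - self.output_at_low)


def tornado_parameters(fixture: ParameterFixture, outcome: str = "qaly"):
    """Flat (path, Param) list of every ranged input varied by the DSA."""
    params: list[tuple[str, Param]] = []
    for name, p in fixture.training.items():
        params.append((f"training.{name}", p))
    for arm in fixture.activity:
        for name, p in fixture.activity[arm].items():
            params.append((f"activity.{arm}.{name}", p))
    eff = fixture.effects[outcome]
    params.append(
        ("effects.difference",
         Param(eff.difference, eff.ci_low, eff.ci_high, "normal"))
    )
    return params


def tornado_one_way(
    fixture: ParameterFixture,
    config: ModelConfig,
    outcome: str = "qaly",
    output: Callable[[ParameterFixture, ModelConfig, str, dict], float] | None = None,
) -> list[TornadoEntry]:
    """One-way DSA: vary each ranged parameter over (low, high), others at
    points; entries sorted by swing, descending (stable for ties)."""
    out_fn = output or _denovo_nmb
    base = out_fn(fixture, config, outcome, {})
    entries = []
    for path, p in tornado_parameters(fixture, outcome):
        at_low = out_fn(fixture, config, outcome, {path: p.low})
        at_high = out_fn(fixture, config, outcome, {path: p.high})
        entries.append(
            TornadoEntry(parameter=path, low=p.low, high=p.high,
                         output_at_low=at_low, output_at_high=at_high,
                         base_output=base)
        )
    entries.sort(key=lambda e: -e.swing)
    return entries


def tornado_table(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "low": e.low,
                "high": e.high,
                "output_at_low": e.output_at_low,
                "output_at_high": e.output_at_high,
                "base_output": e.base_output,
                "swing": e.swing,
            }
            for e in entries
        ]
    )
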