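"""End-to-end pipeline: training costs -> arm costs -> effects -> CEA.

Single entry point (:func:`run_pipeline`) that executes every stage for one
profession and writes delimited-text tables, plot files and a run manifest.
Two runs with the same config, fixture and seed produce identical numeric
outputs.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import cea_engine, effectiveness, service_model, training_costs
from .params_io import (
    ModelConfig,
    ParameterFixture,
    load_fixture,
    packaged_fixture_path,
    round_pounds,
    write_results,
)
from .training_costs import TrainingCostInputs

__all__ = ["RunManifest", "run_pipeline"]

log = logging.getLogger("nmpcea")


@dataclass(frozen=True)
class RunManifest:
    config: ModelConfig
    fixture_sha256: str
    seed: int
    out_dir: Path
    files: tuple[str, ...]


def _training_table(fixture: ParameterFixture, config: ModelConfig) -> pd.DataFrame:
    inputs = TrainingCostInputs.from_params(fixture.training)
    overrides = fixture.reported.get("training_components", {})
    rows = []
    for scenario in ("include_oop", "exclude_oop"):
        bd = training_costs.total_training_cost(inputs, scenario, overrides)
        row = training_costs.training_table(bd)
        total = bd.total(scenario)
        contacts = fixture.activity["prescriber"]["contacts_per_week"].point
        rx_contacts = contacts * fixture.activity["prescriber"]["p_require_rx"].point
        row.update(
            scenario=scenario,
            total=round_pounds(total),
            per_contact=round_pounds(
                training_costs.training_cost_per_contact(
                    total, contacts, config.weeks_per_year
                )
            ),
            per_rx_contact=round_pounds(
                training_costs.training_cost_per_contact(
                    total, rx_contacts, config.weeks_per_year
                )
            ),
        )
        rows.append(row)
    return pd.DataFrame(rows)


def _arm_cost_table(fixture: ParameterFixture, config: ModelConfig) -> pd.DataFrame:
    """De-novo decision-tree arm costs plus published arm totals."""
    inputs = TrainingCostInputs.from_params(fixture.training)
    overrides = fixture.reported.get("training_components", {})
    training_total = training_costs.total_training_cost(
        inputs, config.oop_scenario, overrides
    ).total(config.oop_scenario)
    rows = []
    for arm in ("prescriber", "non_prescriber"):
        profile = service_model.ActivityProfile.from_params(
            fixture.activity[arm], config.weeks_per_year
        )
        annual = service_model.expected_annual_service_cost(profile)
        tc = training_total if arm == "prescriber" else 0.0
        summary = service_model.discounted_horizon_total(
            annual, tc, config.horizon_years, config.discount_rate
        )
        rows.append(
            {
                "arm": arm,
                "annual_contacts": service_model.annual_contacts(profile),
                "annual_service_cost": annual,
                "training_cost": tc,
                "horizon_years": config.horizon_years,
                "horizon_total": summary.horizon_total,
            }
        )
    df = pd.DataFrame(rows)
    saving = service_model.arm_saving(
        df.loc[df["arm"] == "non_prescriber", "horizon_total"].iloc[0],
        df.loc[df["arm"] == "prescriber", "horizon_total"].iloc[0],
    )
    df["horizon_saving_vs_non_prescriber"] = [saving, 0.0]
    return df


def _effects_table(fixture: ParameterFixture) -> pd.DataFrame:
    rows = []
    for name, eff in fixture.effects.items():
        rows.append(
            {
                "outcome": name,
                "mean_prescriber": eff.mean_prescriber,
                "sd_prescriber": eff.sd_prescriber,
                "mean_non_prescriber": eff.mean_non_prescriber,
                "sd_non_prescriber": eff.sd_non_prescriber,
                "difference": eff.difference,
                "ci_low": eff.ci_low,
                "ci_high": eff.ci_high,
            }
        )
    return pd.DataFrame(rows)


def _plots(result: cea_engine.CEResult, tornado: pd.DataFrame, out_dir: Path) -> list[str]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    cloud = result.psa_cloud
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    ax.scatter(cloud["delta_effect"], cloud["delta_cost"], s=4, alpha=0.25)
    ax.axhline(0, color="k", lw=0.8)
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (£)")
    ax.set_title("Cost-effectiveness plane")
    fig.tight_layout()
    fig.savefig(out_dir / "ce_plane.png", dpi=120)
    plt.close(fig)
    written.append("ce_plane.png")

    fig, ax = plt.subplots(figsize=(5.5, 4))
    ax.plot(result.ceac["wtp"], result.ceac["p_cost_effective"])
    ax.axvline(result.wtp, color="grey", ls="--", lw=0.8)
    ax.set_ylim(0, 1)
    ax.set_xlabel("Willingness to pay (£/QALY)")
    ax.set_ylabel("P(cost-effective)")
    ax.set_title("Cost-effectiveness acceptability curve")
    fig.tight_layout()
    fig.savefig(out_dir / "ceac.png", dpi=120)
    plt.close(fig)
    written.append("ceac.png")

    top = tornado.head(12).iloc[::-1]
    fig, ax = plt.subplots(figsize=(6.5, 5))
    ax.barh(top["parameter"], top["output_at_high"] - top["base_output"],
            left=top["base_output"], color="steelblue", label="high")
    ax.barh(top["parameter"], top["output_at_low"] - top["base_output"],
            left=top["base_output"], color="indianred", label="low")
    ax.axvline(float(top["base_output"].iloc[0]), color="k", lw=0.8)
    ax.set_xlabel("NMB at threshold (£)")
    ax.set_title("One-way sensitivity (tornado)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_dir / "tornado.png", dpi=120)
    plt.close(fig)
    written.append("tornado.png")
    return written


def run_pipeline(
    config: ModelConfig,
    fixture_path: str | Path | None = None,
    patients: pd.DataFrame | None = None,
    out_dir: str | Path = "results",
    make_plots: bool = True,
) -> RunManifest:
    """Run every stage for one profession and write the output set.

    If *patients* (a patient-level table) is supplied, effectiveness is
    re-estimated from it (mixed-model adjustment + bootstrap CI) and
    reported alongside the fixture's published summaries.
    """
    fixture_path = Path(fixture_path or packaged_fixture_path(config.profession))
    fixture = load_fixture(fixture_path)
    if fixture.profession != config.profession:
        raise ValueError(
            f"fixture is for {fixture.profession!r}, config wants {config.profession!r}"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    log.info("stage 1/5 training costs: scenario=%s", config.oop_scenario)
    tables: dict[str, pd.DataFrame] = {"training_costs": _training_table(fixture, config)}

    log.info(
        "stage 2/5 arm costs: horizon=%dy discount=%.1f%% weeks=%d",
        config.horizon_years, 100 * config.discount_rate, config.weeks_per_year,
    )
    tables["arm_costs"] = _arm_cost_table(fixture, config)

    log.info("stage 3/5 effectiveness summaries")
    tables["effects"] = _effects_table(fixture)
    if patients is not None:
        scored = effectiveness.add_scores(patients)
        est_rows = []
        for outcome in ("qaly", "satisfaction", "experience"):
            if outcome not in scored.columns:
                continue
            boot = effectiveness.bootstrap_mean_difference(
                scored, outcome, n_reps=config.bootstrap_reps, seed=config.rng_seed
            )
            eff = effectiveness.adjust_group_means(
                scored, outcome, ci=(boot.ci_low, boot.ci_high)
            )
            est_rows.append(
                {
                    "outcome": outcome,
                    "mean_prescriber": eff.mean_prescriber,
                    "mean_non_prescriber": eff.mean_non_prescriber,
                    "difference": eff.difference,
                    "ci_low": eff.ci_low,
                    "ci_high": eff.ci_high,
                    "n_patients": len(scored),
                }
            )
        tables["effects_estimated"] = pd.DataFrame(est_rows)

    log.info("stage 4/5 CEA + PSA: wtp=%.0f iterations=%d seed=%d",
             config.wtp_threshold, config.psa_iterations, config.rng_seed)
    result = cea_engine.run_psa(fixture, config)
    tables["ce_summary"] = pd.DataFrame(
        [
            {
                "outcome": result.outcome,
                "delta_cost": result.delta_cost,
                "delta_effect": result.delta_effect,
                "icer": result.icer.value,
                "quadrant": result.quadrant,
                "wtp": result.wtp,
                "nmb": result.nmb,
                "p_cost_effective_at_wtp": result.p_cost_effective,
                **{f"share_{q}": v for q, v in result.quadrant_shares.items()},
            }
        ]
    )
    tables["psa_samples"] = result.psa_cloud
    tables["ceac"] = result.ceac

    log.info("stage 5/5 tornado DSA")
    entries = cea_engine.tornado_one_way(fixture, config)
    tables["tornado"] = cea_engine.tornado_table(entries)

    write_results(tables, out_dir, config=config, seed=config.rng_seed)
    files = [f"{name}.csv" for name in tables] + ["manifest.json"]
    if make_plots:
        files += _plots(result, tables["tornado"], out_dir)

    return RunManifest(
        config=config,
        fixture_sha256=hashlib.sha256(fixture_path.read_bytes()).hexdigest(),
        seed=config.rng_seed,
        out_dir=out_dir,
        files=tuple(files),
    )
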