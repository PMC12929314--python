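"""Per-prescriber and per-contact training costs for both professions.

Aggregates course fee, employer-paid study days, staff-backfill time off,
personal study time and out-of-pocket (OOP) expenses under the two costing
scenarios (including / excluding OOP + personal study), and spreads the
total over a year of patient contacts.

Writes results/training_costs.csv.
"""

from pathlib import Path

import pandas as pd

from nmpcea.params_io import ModelConfig, round_pounds, write_results
from nmpcea.synthetic_data import make_paper_fixture
from nmpcea.training_costs import (
    TrainingCostInputs,
    total_training_cost,
    training_cost_per_contact,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "01_training_costs"


def main() -> None:
    rows = []
    for prof in ("dietitian", "therapeutic_radiographer"):
        fx = make_paper_fixture(prof)
        inputs = TrainingCostInputs.from_params(fx.training)
        overrides = fx.reported["training_components"]
        cpw = fx.activity["prescriber"]["contacts_per_week"].point
        p_req = fx.activity["prescriber"]["p_require_rx"].point
        for scenario in ("include_oop", "exclude_oop"):
            bd = total_training_cost(inputs, scenario, overrides)
            total = bd.total(scenario)
            rows.append(
                {
                    "profession": prof,
                    "scenario": scenario,
                    "course_fee": round_pounds(bd.course_fee),
                    "employer_study_cost": round_pounds(bd.employer_study_cost),
                    "time_off_cost": round_pounds(bd.time_off_cost),
                    "oop_total": round_pounds(bd.oop_total),
                    "personal_study_cost": round_pounds(bd.personal_study_cost),
                    "total_per_prescriber": round_pounds(total),
                    "per_contact": round_pounds(
                        training_cost_per_contact(total, cpw, 48)
                    ),
                    "per_rx_contact": round_pounds(
                        training_cost_per_contact(total, cpw * p_req, 48)
                    ),
                }
            )
    table = pd.DataFrame(rows)
    write_results({"training_costs": table}, OUT, config=ModelConfig())
    print(table.to_string(index=False))
    d = table[(table.profession == "dietitian")]
    print(
        f"\nTraining one dietitian prescriber costs "
        f"£{int(d[d.scenario == 'include_oop'].total_per_prescriber.iloc[0]):,} "
        f"including OOP/personal-study expenses and "
        f"£{int(d[d.scenario == 'exclude_oop'].total_per_prescriber.iloc[0]):,} "
        f"excluding them."
    )


if __name__ == "__main__":
    main()
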