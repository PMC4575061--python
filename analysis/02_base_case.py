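#!/usr/bin/env python
"""Base-case cost-effectiveness analysis of teleglaucoma vs in-person care.

Loads the shipped reference configuration, evaluates both screening
strategies over the 30-year horizon, and writes the incremental
cost-effectiveness league table, the JSON CEA report, and the headline
service-efficiency figures (per-patient program costs, visit-time savings).
"""

import json
from pathlib import Path

import pandas as pd

from glaucoma_cea import (
    per_patient_cost,
    percent_cost_reduction,
    reference_config,
    run_base_case,
    time_savings_report,
)

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "base_case"

# Published visit durations (minutes, wait + assessment) for the efficiency report.
TELE_VISIT_MIN, INPERSON_VISIT_MIN = 78.0, 115.0


def main() -> None:
    config = reference_config()
    base = run_base_case(config)
    OUT.mkdir(parents=True, exist_ok=True)

    rows = []
    for name, o in base.outcomes.items():
        rows.append(
            {
                "strategy": name,
                "cost": o.expected_cost,
                "effect": o.expected_qaly,
                "cost_per_effect": o.expected_cost / o.expected_qaly,
                "nmb_at_wtp": base.nmb(name),
            }
        )
    league = pd.DataFrame(rows).set_index("strategy")
    league.to_csv(OUT / "league_table.csv")

    report = base.to_report()
    with open(OUT / "cea_report.json", "w") as fh:
        json.dump(report, fh, indent=2)

    saving = time_savings_report(TELE_VISIT_MIN, INPERSON_VISIT_MIN)
    tele = config.strategies["teleglaucoma"].test
    inp = config.strategies["in_person"].test
    efficiency = {
        "tele_cost_per_screen": per_patient_cost(tele.fixed_program_cost, tele.capacity),
        "inperson_cost_per_screen": per_patient_cost(inp.fixed_program_cost, inp.capacity),
        "per_patient_cost_reduction_percent": percent_cost_reduction(
            base.outcomes["teleglaucoma"].expected_cost,
            base.outcomes["in_person"].expected_cost,
        ),
        "visit_time_saving_minutes": saving.absolute_minutes,
        "visit_time_saving_percent": saving.relative_percent,
    }
    with open(OUT / "efficiency.json", "w") as fh:
        json.dump(efficiency, fh, indent=2)

    cea = base.cea
    print(league.round(2).to_string())
    print(
        f"\nincremental cost (comparator - reference): {cea.incremental_cost:,.2f} CAD"
        f"\nincremental effect: {cea.incremental_effect:.4f} QALY"
        f"\nheadline ICER (reference perspective): {cea.icer:,.0f} CAD/QALY"
        f" — comparator is {cea.dominance}"
        f"\nper-patient cost reduction: "
        f"{efficiency['per_patient_cost_reduction_percent']:.1f}%"
        f"\nvisit time saved: {saving.absolute_minutes:.0f} min "
        f"({saving.relative_percent:.1f}%)"
    )


if __name__ == "__main__":
    main()
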