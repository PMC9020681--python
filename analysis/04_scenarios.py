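"""Scenario analyses: older cohort, shorter horizons, alternative effects.

Re-runs the model with entry at age 77, with 10- and 20-year horizons, and —
when a hazard-ratio YAML is supplied — with an alternative treatment-effect
table (the published alternative effect sizes are not printed, so that
scenario needs user input).  Shorter horizons raise every ICER because drug
spending is front-loaded while health benefits accrue late; an older cohort
raises ICERs through shorter remaining life expectancy.  Writes
results/scenarios.csv.

Run from the repository root:  python analysis/04_scenarios.py [hr_table.yaml]
"""

import sys
from pathlib import Path

import yaml

from nvaf_cea.parameters import load_parameters
from nvaf_cea.reporting import scenario_table
from nvaf_cea.sensitivity import run_scenario

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main(hr_file: str | None = None):
    params = load_parameters()
    hr_table = yaml.safe_load(open(hr_file)) if hr_file else None
    names = ["base", "older_population", "horizon_10", "horizon_20"]
    if hr_table:
        names.append("alternative_hr")
    results = {n: run_scenario(params, n, hr_table=hr_table) for n in names}
    table = scenario_table(results)
    print("ICER vs VKA (€/QALY) by scenario:")
    print(table.to_string(float_format=lambda v: f"{v:,.0f}"))
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "scenarios.csv")
    print(f"wrote {RESULTS / 'scenarios.csv'}")


if __name__ == "__main__":
    main(*sys.argv[1:2])
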