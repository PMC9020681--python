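"""Base case: lifetime costs, QALYs, life-years and events for each arm.

Runs the four treatment strategies (VKA, rivaroxaban, dabigatran, apixaban)
over the 30-year horizon with the packaged inputs and the calibrated
synthetic life table, prints the results table in the published layout and
writes the tidy version to results/base_case.csv.

Headline finding with the packaged inputs: all three NOACs gain QALYs versus
VKA; rivaroxaban has the lowest ICER, apixaban by far the highest (its
stroke hazard ratio is ~1, so its benefit rests on avoided bleeds alone).

Run from the repository root:  python analysis/01_base_case.py
"""

from pathlib import Path

from nvaf_cea.engine import compare_arms, run_base_case
from nvaf_cea.parameters import load_parameters
from nvaf_cea.reporting import base_case_table, format_base_case_table

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    params = load_parameters()
    results = run_base_case(params)
    table = base_case_table(results)
    print(format_base_case_table(table))
    ref = results["vka"]
    print()
    for arm in params.comparator_names:
        inc = compare_arms(ref, results[arm])
        print(f"{arm:12s} ICER {inc.icer_qaly:>9,.0f} €/QALY   "
              f"{inc.icer_lyg:>9,.0f} €/LYG")
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "base_case.csv")
    print(f"\nwrote {RESULTS / 'base_case.csv'}")


if __name__ == "__main__":
    main()
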