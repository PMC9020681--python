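"""Probabilistic sensitivity analysis: CE-plane scatter and CEAC.

Draws every tagged input from its fitted distribution (beta for
probabilities and utilities, gamma for costs, lognormal for hazard ratios),
re-runs all four arms per draw, and writes the incremental cost-effectiveness
plane scatter (results/psa_scatter.csv) and the cost-effectiveness
acceptability curves (results/ceac.csv).  Prints the probability each NOAC is
cost-effective versus VKA at the 22,000 euros/QALY willingness-to-pay
threshold used for the Spanish NHS.

Run from the repository root:  python analysis/03_psa.py [n_draws] [seed]
"""

import sys
from pathlib import Path

from nvaf_cea.parameters import load_parameters
from nvaf_cea.sensitivity import run_psa

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main(n_draws: int = 1000, seed: int = 20220420):
    params = load_parameters()
    res = run_psa(params, n_draws=n_draws, seed=seed)
    RESULTS.mkdir(exist_ok=True)
    res.scatter_frame().to_csv(RESULTS / "psa_scatter.csv", index=False)
    res.ceac.to_frame().to_csv(RESULTS / "ceac.csv", index=False)
    wtp = params.settings.wtp_threshold
    print(f"{n_draws} draws, seed {seed}")
    headline = " ".join(f"{arm}={res.ceac.at(arm, wtp):.2f}" for arm in res.arms)
    print(f"P(CE at €{wtp:.0f}): {headline}")
    print(f"wrote {RESULTS / 'psa_scatter.csv'} and {RESULTS / 'ceac.csv'}")


if __name__ == "__main__":
    main(*(int(a) for a in sys.argv[1:3]))
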