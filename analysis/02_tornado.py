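"""One-way deterministic sensitivity analysis (tornado) per comparator.

Every input with a printed range is set to its low and high bound in turn and
both arms re-run; the ICER spread measures each input's leverage.  Writes
plot-ready results/tornado_<arm>.csv (sorted by spread) and prints the top
drivers.  With the packaged inputs the dominant drivers are the major-stroke
follow-up cost, major-stroke and post-major-stroke mortality, and each
comparator's own discontinuation and stroke hazard ratios.

Run from the repository root:  python analysis/02_tornado.py
"""

from pathlib import Path

from nvaf_cea.parameters import load_parameters
from nvaf_cea.sensitivity import tornado, tornado_frame

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    params = load_parameters()
    RESULTS.mkdir(exist_ok=True)
    for arm in params.comparator_names:
        entries, base_icer = tornado(params, arm)
        frame = tornado_frame(entries, base_icer)
        out = RESULTS / f"tornado_{arm}.csv"
        frame.to_csv(out, index=False)
        print(f"{arm}: base ICER {base_icer:,.0f} €/QALY; top drivers:")
        for e in entries[:6]:
            print(f"   {e.parameter:45s} spread {e.spread:>10,.0f}")
        print(f"   -> {out}")


if __name__ == "__main__":
    main()
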