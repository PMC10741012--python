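#!/usr/bin/env python
"""Stage 3 — pseudo-first-order rate constants and class fold changes.

Fits ln(1 - F) against exposure time per cysteine (saturated points
excluded), then compares bond classes by geometric-mean rate ratios: the
headline expectation is interchain/hinge cysteines reducing ~100-1000x
faster than intrachain ones.

Reads:  results/fractions.tsv
Writes: results/rates.tsv
"""

from pathlib import Path

from cysred.kinetics import class_fold_change, fit_rate_table
from cysred.quantitation import read_fraction_table, write_fraction_table

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    fractions = read_fraction_table(OUT / "fractions.tsv")
    rates, fits = fit_rate_table(fractions)
    write_fraction_table(rates, OUT / "rates.tsv")

    n_fail = int((rates["error"] != "").sum())
    print(f"fitted {len(fits)} series ({n_fail} failures)")
    for cls in ("interchain", "hinge", "SEFL", "intrachain"):
        ks = sorted(f.k for f in fits if f.bond_class == cls)
        if ks:
            print(f"  {cls:10s} k range {ks[0]:.2e} .. {ks[-1]:.2e} /min "
                  f"(n={len(ks)})")
    for cls in ("interchain", "hinge"):
        fc = class_fold_change(fits, cls, "intrachain")
        print(f"{cls}/intrachain geometric-mean fold change: {fc.ratio:,.0f}")


if __name__ == "__main__":
    main()
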