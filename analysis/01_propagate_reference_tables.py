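#!/usr/bin/env python
"""Predict the reference tally tables by closed-form error propagation.

Starting from the two reference baselines — the type-I study's null totals
(374,502 transmitted / 427,972 non-transmitted over 182,799 rare variants in
100 trios) and the power study's error-free totals (17,225 / 11,112 over
19,103 rarer variants in 100 affected trios) — this script applies the
first-order propagation operator for the het->hom-ref scenarios (parents and
offspring) and the offspring false-het scenario at every rate in the study
grid, and prints the predicted post-error tallies in the two-row tally
format. The parental false-het scenario needs a cohort-level exposure count
and is handled by the simulation driver (03) instead.

Key finding: offspring het miscalls tip the transmitted share downward
(47% -> 46/44/42% at r1 = 1/5/10% on the null baseline; 61% -> 60/58/55% on
the power baseline), parental het miscalls leave the share untouched at any
rate, and offspring false hets barely move it — exactly the pattern of the
reference tables.

Output: results/reference_tally_predictions.tsv
"""

import pathlib

import pandas as pd

import triotdt as tdt
from triotdt import datasets, io

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rows = []
    for name, (T, U) in [
        ("type1_null", datasets.TYPE1_NULL_TOTALS),
        ("power_baseline", datasets.POWER_BASELINE_TOTALS),
    ]:
        columns = {"baseline": (T, U)}
        for scenario in (1, 2, 4):
            for rate in datasets.RATE_GRID[scenario]:
                spec = tdt.ErrorSpec.make(scenario, rate)
                res = tdt.propagate(T, U, spec)
                columns[spec.label()] = (res.T_out, res.U_out)
                rows.append(
                    dict(
                        baseline=name, scenario=scenario, rate=rate,
                        T_out=round(res.T_out, 1), U_out=round(res.U_out, 1),
                        pct_transmitted=res.pct_transmitted,
                    )
                )
        print(f"\n== {name} ==")
        print(io.write_tally_table(columns))
    pd.DataFrame(rows).to_csv(OUT / "reference_tally_predictions.tsv", sep="\t", index=False)
    print(f"\nwrote {OUT / 'reference_tally_predictions.tsv'}")


if __name__ == "__main__":
    main()
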