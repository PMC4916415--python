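"""Reference inputs for the canonical error-propagation analyses.

Aggregate transmitted / non-transmitted baselines from the reference
single-marker TDT tallies of two large trio-sequencing simulation studies:

* ``TYPE1_NULL_TOTALS`` — the null (error-free) totals over 182,799 rare
  variants (MAF < 0.05) in 100 trios, used by the type-I-error study;
* ``POWER_BASELINE_TOTALS`` — the error-free totals over 19,103 rare
  variants (MAF < 0.01) in 100 affected trios with 30% causal variants at
  per-allele log-odds log(4), used by the power study.

These totals are *inputs*: the propagation operator predicts how each error
scenario shifts them, and those predictions are what the canonical analyses
report.
"""

from __future__ import annotations

import math

from .errors import ErrorSpec

__all__ = [
    "TYPE1_NULL_TOTALS",
    "POWER_BASELINE_TOTALS",
    "RATE_GRID",
    "SCENARIO_GRID",
    "POWER_BETA",
    "POWER_CAUSAL_FRACTION",
    "N_TRIOS",
]

TYPE1_NULL_TOTALS = (374_502, 427_972)
POWER_BASELINE_TOTALS = (17_225, 11_112)

# The studies' error-rate grids: r1 for scenarios 1-2, r2 for scenarios 3-4.
RATE_GRID = {
    1: (0.01, 0.05, 0.10),
    2: (0.01, 0.05, 0.10),
    3: (0.001, 0.005, 0.01),
    4: (0.001, 0.005, 0.01),
}

SCENARIO_GRID = tuple(
    ErrorSpec.make(s, r) for s in sorted(RATE_GRID) for r in RATE_GRID[s]
)

# Disease model of the power study.
POWER_BETA = math.log(4.0)
POWER_CAUSAL_FRACTION = 0.30
N_TRIOS = 100
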