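"""First-order error propagation for aggregate transmission tallies.

Each error scenario shifts the aggregate transmitted (T) and non-transmitted
(U) counts in a characteristic, analytically predictable direction. To first
order in the error rate and the rare-allele frequency:

* scenario 1 (het parents -> hom-ref): a flipped het parent is simply no
  longer informative — its transmission becomes a Mendelian exclusion, its
  non-transmission becomes invisible — so both tallies thin proportionally:
  T' = (1-r1) T, U' = (1-r1) U. The transmitted *percentage* is unchanged.
* scenario 2 (het offspring -> hom-ref): a transmitted rare allele vanishes
  from the child and reappears as an apparent non-transmission:
  T' = (1-r1) T, U' = U + r1 T. The total stays put while the balance tips
  toward under-transmission — the inflation-prone case.
* scenario 3 (hom-ref parents -> het): every false-het parent is a new
  "informative" parent that did not transmit: T' = T (exactly invariant),
  U' = U + r2 * homref_exposures, where the exposure count is the number of
  targeted parent hom-ref cells (a true hom-ref parent cannot have a hom-alt
  child, so each flip adds exactly one spurious non-transmission).
* scenario 4 (hom-ref offspring -> het): a child that did not receive a het
  parent's rare allele now appears to have: T' = T + r2 U, U' = (1-r2) U.
  Flips in double-hom-ref trios only create exclusions and move no counts.

Interactions (both parents heterozygous, double flips, hom-alt offspring)
are second order in the rates and frequencies and are neglected; the
simulation suite checks the approximation directly.
"""

from __future__ import annotations

import dataclasses
import math

from .errors import ErrorSpec

__all__ = ["PropagationResult", "propagate", "percent_transmitted"]


def percent_transmitted(T: float, U: float) -> int:
    """Transmitted share as a whole percentage: round(100*T/(T+U)),
    ties away from zero (so 46.5% prints as 47)."""
    if T + U <= 0:
        raise ValueError("T + U must be positive")
    x = 100.0 * T / (T + U)
    return int(math.floor(x + 0.5))


@dataclasses.dataclass(frozen=True)
class PropagationResult:
    spec: ErrorSpec
    T_in: float
    U_in: float
    T_out: float
    U_out: float

    @property
    def pct_transmitted(self) -> int:
        return percent_transmitted(self.T_out, self.U_out)

    @property
    def pct_non_transmitted(self) -> int:
        return percent_transmitted(self.U_out, self.T_out)


def propagate(
    T: float,
    U: float,
    spec: ErrorSpec,
    homref_exposures: float | None = None,
) -> PropagationResult:
    """Expected post-error tallies from baseline (T, U) under a scenario.

    ``homref_exposures`` — required for scenario 3 only — is the number of
    (targeted parent, variant) cells whose true genotype is hom-ref; each
    one is a chance for a false het that adds a spurious non-transmission.
    Obtain it from a cohort as ``(cohort.genotypes_true[:, :2, :] == 0).sum()``
    or supply the aggregate directly.
    """
    if T < 0 or U < 0:
        raise ValueError("baseline counts must be non-negative")
    s = spec.scenario
    if s == 1:
        T_out, U_out = (1.0 - spec.r1) * T, (1.0 - spec.r1) * U
    elif s == 2:
        T_out, U_out = (1.0 - spec.r1) * T, U + spec.r1 * T
    elif s == 3:
        if homref_exposures is None:
            raise ValueError("scenario 3 requires homref_exposures")
        if homref_exposures < 0:
            raise ValueError("homref_exposures must be non-negative")
        T_out, U_out = float(T), U + spec.r2 * homref_exposures
    elif s == 4:
        T_out, U_out = T + spec.r2 * U, (1.0 - spec.r2) * U
    else:  # unreachable: ErrorSpec validates
        raise ValueError(f"unknown scenario {s}")
    return PropagationResult(spec, float(T), float(U), float(T_out), float(U_out))
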