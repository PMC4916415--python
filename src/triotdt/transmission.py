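"""Mendelian screening, transmission counting, and the single-marker TDT.

The transmission disequilibrium test compares, over heterozygous parents of
affected children, the number of rare alleles transmitted (p) against not
transmitted (q): TDT = (p - q)^2 / (p + q), chi-square with 1 df under the
null of no association. Only heterozygous parents are informative; a
homozygous parent transmits the same allele either way.

Counting rules for a consistent trio (father, mother, child dosages):
with ``h`` heterozygous parents and ``a`` hom-alt parents, the het parents
jointly transmitted ``t = child - a`` rare alleles and withheld ``h - t``.
A trio whose child dosage is unattainable from one allele of each parent is
a Mendelian inconsistency and is excluded at that variant.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import TrioCohort

__all__ = [
    "mendelian_consistent",
    "count_transmissions",
    "tally",
    "tdt_test",
    "TransmissionCounts",
]


def mendelian_consistent(father: int, mother: int, child: int) -> bool:
    """True iff the child dosage is attainable from one allele of each parent.

    Dosages must be 0/1/2; missing values are the caller's responsibility.
    """
    for d in (father, mother, child):
        if d not in (0, 1, 2):
            raise ValueError(f"dosages must be 0/1/2, got ({father}, {mother}, {child})")
    lo = (father == 2) + (mother == 2)          # rare alleles forced in
    hi = 2 - (father == 0) - (mother == 0)      # rare alleles attainable
    return lo <= child <= hi


def count_transmissions(father: int, mother: int, child: int) -> tuple[int, int]:
    """(transmitted, non-transmitted) rare-allele counts from het parents.

    Requires a Mendelian-consistent triple. Symmetric in the parents; triples
    with no heterozygous parent contribute (0, 0). With both parents
    heterozygous and a heterozygous child, which parent transmitted is
    ambiguous but the aggregate contribution (1, 1) is not.
    """
    if not mendelian_consistent(father, mother, child):
        raise ValueError(
            f"inconsistent triple ({father}, {mother}, {child}); screen with "
            "mendelian_consistent first"
        )
    n_het = (father == 1) + (mother == 1)
    n_homalt = (father == 2) + (mother == 2)
    t = child - n_homalt
    return t, n_het - t


def _build_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    consistent = np.zeros(27, dtype=bool)
    t_tab = np.zeros(27, dtype=np.int8)
    u_tab = np.zeros(27, dtype=np.int8)
    for f in range(3):
        for m in range(3):
            for c in range(3):
                code = f * 9 + m * 3 + c
                if mendelian_consistent(f, m, c):
                    consistent[code] = True
                    t_tab[code], u_tab[code] = count_transmissions(f, m, c)
    return consistent, t_tab, u_tab


_CONSISTENT, _T_TAB, _U_TAB = _build_tables()


@dataclasses.dataclass
class TransmissionCounts:
    """Per-variant and aggregate transmitted/non-transmitted tallies."""

    per_variant: pd.DataFrame  # index variant_id; columns p, q, n_excluded
    n_missing: int = 0

    @property
    def totals(self) -> tuple[int, int]:
        return int(self.per_variant["p"].sum()), int(self.per_variant["q"].sum())

    @property
    def P(self) -> int:
        return self.totals[0]

    @property
    def Q(self) -> int:
        return self.totals[1]

    @property
    def n_excluded(self) -> int:
        """Trio-variant combinations removed as Mendelian-inconsistent."""
        return int(self.per_variant["n_excluded"].sum())

    def with_tests(self) -> pd.DataFrame:
        """Per-variant table extended with the TDT statistic and p-value."""
        out = self.per_variant.copy()
        stat, pval = tdt_test(out["p"].to_numpy(), out["q"].to_numpy())
        out["statistic"] = stat
        out["p_value"] = pval
        return out


def tally(cohort: TrioCohort, layer: str = "observed") -> TransmissionCounts:
    """Count transmitted/non-transmitted rare alleles per variant.

    Trio-variant combinations with any missing member are dropped;
    Mendelian-inconsistent combinations are dropped and counted in
    ``n_excluded`` for that variant. Exclusion is per trio-variant cell, not
    per trio genome-wide.
    """
    geno = cohort.layer(layer)
    complete = (geno >= 0).all(axis=1)  # (n_trios, n_variants)
    code = (geno[:, 0, :] * 9 + geno[:, 1, :] * 3 + geno[:, 2, :]).clip(0)
    ok = complete & _CONSISTENT[code]
    t = np.where(ok, _T_TAB[code], 0)
    u = np.where(ok, _U_TAB[code], 0)
    excluded = complete & ~_CONSISTENT[code]
    per_variant = pd.DataFrame(
        {
            "p": t.sum(axis=0, dtype=np.int64),
            "q": u.sum(axis=0, dtype=np.int64),
            "n_excluded": excluded.sum(axis=0, dtype=np.int64),
        },
        index=cohort.panel.variant_ids,
    )
    n_missing = int((~complete).sum())
    return TransmissionCounts(per_variant, n_missing=n_missing)


def tdt_test(p, q):
    """TDT statistic (p - q)^2 / (p + q) and its chi-square(1) upper-tail
    p-value. Scalar or array inputs; an uninformative pair (p + q = 0) gets
    statistic NaN and p-value 1.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if (p < 0).any() or (q < 0).any():
        raise ValueError("counts must be non-negative")
    n = p + q
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(n > 0, (p - q) ** 2 / np.where(n > 0, n, 1.0), np.nan)
    pval = np.where(n > 0, stats.chi2.sf(stat, df=1), 1.0)
    if pval.ndim == 0:
        return float(stat), float(pval)
    return stat, pval
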