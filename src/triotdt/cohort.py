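"""Trio cohorts: true and observed genotype layers plus transmission records.

Genotypes are rare-allele dosages (0/1/2) in an int8 array of shape
``(n_trios, 3, n_variants)`` with the member axis ordered father, mother,
child; -1 marks a missing call in the observed layer. The true layer is the
error-free ground truth; the observed layer starts as a copy of it and is
the only layer error injection may touch.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .panel import DiseaseModel, VariantPanel

__all__ = ["TrioCohort", "FATHER", "MOTHER", "CHILD", "MEMBERS",
           "simulate_trios", "simulate_affected_trios"]

FATHER, MOTHER, CHILD = 0, 1, 2
MEMBERS = ("father", "mother", "child")
MISSING = -1


@dataclasses.dataclass
class TrioCohort:
    panel: VariantPanel
    genotypes_true: np.ndarray       # (n_trios, 3, n_variants) int8, 0/1/2
    genotypes_observed: np.ndarray   # same shape; -1 = missing
    transmission_record: np.ndarray | None = None  # (n_trios, 2, n_variants) int8 in {0,1}
    child_affected: bool = False
    perturbed: bool = False          # True once errors were injected

    def __post_init__(self) -> None:
        if self.genotypes_true.shape != self.genotypes_observed.shape:
            raise ValueError("true and observed layers must share a shape")
        if self.genotypes_true.ndim != 3 or self.genotypes_true.shape[1] != 3:
            raise ValueError("genotype arrays must have shape (n_trios, 3, n_variants)")
        if self.n_trios < 1:
            raise ValueError("n_trios must be >= 1")

    @property
    def n_trios(self) -> int:
        return self.genotypes_true.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes_true.shape[2]

    def layer(self, which: str) -> np.ndarray:
        if which == "true":
            return self.genotypes_true
        if which == "observed":
            return self.genotypes_observed
        raise ValueError(f"unknown layer {which!r}; use 'true' or 'observed'")


def _draw_trios(freqs: np.ndarray, n_trios: int, rng: np.random.Generator):
    """Parents under Hardy-Weinberg; one allele transmitted uniformly at
    random from each parent (a het parent transmits the rare allele with
    probability 1/2, homozygotes transmit deterministically)."""
    m = freqs.shape[0]
    geno = np.empty((n_trios, 3, m), dtype=np.int8)
    geno[:, FATHER, :] = rng.binomial(2, freqs, size=(n_trios, m))
    geno[:, MOTHER, :] = rng.binomial(2, freqs, size=(n_trios, m))
    # transmitted allele ~ Bernoulli(dosage / 2)
    record = np.empty((n_trios, 2, m), dtype=np.int8)
    record[:, 0, :] = rng.random((n_trios, m)) < geno[:, FATHER, :] / 2.0
    record[:, 1, :] = rng.random((n_trios, m)) < geno[:, MOTHER, :] / 2.0
    geno[:, CHILD, :] = record.sum(axis=1, dtype=np.int8)
    return geno, record


def simulate_trios(panel: VariantPanel, n_trios: int, seed: int = 0) -> TrioCohort:
    """Simulate ``n_trios`` random trios over the panel.

    Parental dosages are Binomial(2, f) per variant (Hardy-Weinberg at the
    panel's rare-allele frequency); the child receives one uniformly chosen
    allele from each parent, so the true layer is Mendelian-consistent by
    construction. Variants are independent (no linkage). Deterministic given
    ``seed``.
    """
    if n_trios < 1:
        raise ValueError("n_trios must be >= 1")
    rng = np.random.default_rng(seed)
    geno, record = _draw_trios(panel.freqs, n_trios, rng)
    return TrioCohort(panel, geno, geno.copy(), transmission_record=record)


def simulate_affected_trios(
    panel: VariantPanel,
    model: DiseaseModel,
    n_trios: int,
    seed: int = 0,
    batch_size: int = 1000,
    max_candidates: int = 2_000_000,
) -> TrioCohort:
    """Rejection-sample trios whose child is affected under the disease model.

    Candidate trios are simulated as in :func:`simulate_trios`; each child is
    retained with probability ``model.affected_probability(k)`` where ``k``
    is its causal rare-allele count over the panel's causal variants. Under
    random transmission plus this ascertainment, causal alleles of
    heterozygous parents are over-transmitted to the retained children — the
    association signal the transmission tests detect.

    Raises ``RuntimeError`` if ``max_candidates`` candidates are exhausted
    before ``n_trios`` affected trios are found (pathologically low
    acceptance probability).
    """
    if not panel.causal_mask.any() and model.causal_fraction > 0:
        raise ValueError("panel has no causal flags; attach the disease model first")
    rng = np.random.default_rng(seed)
    causal = panel.causal_mask
    kept_g, kept_r = [], []
    n_kept = 0
    n_seen = 0
    while n_kept < n_trios:
        if n_seen >= max_candidates:
            raise RuntimeError(
                f"exhausted {max_candidates} candidate trios with only "
                f"{n_kept}/{n_trios} affected; acceptance probability too low"
            )
        geno, record = _draw_trios(panel.freqs, batch_size, rng)
        n_seen += batch_size
        k = geno[:, CHILD, causal].sum(axis=1)
        accept = rng.random(batch_size) < model.affected_probability(k)
        kept_g.append(geno[accept])
        kept_r.append(record[accept])
        n_kept += int(accept.sum())
    geno = np.concatenate(kept_g)[:n_trios]
    record = np.concatenate(kept_r)[:n_trios]
    return TrioCohort(
        panel, geno, geno.copy(), transmission_record=record, child_affected=True
    )
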