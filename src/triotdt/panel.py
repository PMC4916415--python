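"""Rare-variant panels and the disease model used to ascertain affected trios.

A panel is the fixed genomic "map" of a simulation study: a set of biallelic
sites, each with a rare-allele population frequency and a gene assignment.
The rare allele is fixed here, once, and is the allele whose transmission is
counted everywhere downstream; it is never re-polarised from sample
frequencies.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from typing import Callable, Union

import numpy as np
import pandas as pd

__all__ = [
    "VariantPanel",
    "DiseaseModel",
    "sample_panel",
    "reciprocal_spectrum",
    "TYPE1_PANEL",
    "POWER_PANEL",
]

# Study-scale panel presets: the type-I panel mirrors a rare-variant exome
# panel of 541 genes / ~182,799 sites with MAF < 0.05; the power panel
# mirrors 1,000 genes / ~19,103 sites with MAF < 0.01.
TYPE1_PANEL = dict(n_genes=541, variants_per_gene=("poisson", 338.0), maf_cap=0.05)
POWER_PANEL = dict(n_genes=1000, variants_per_gene=("poisson", 19.1), maf_cap=0.01)

# Spec for "how many variants per gene" / "which frequency": either a scalar
# (point mass), a ("poisson", mean) tuple, or a callable (rng, size) -> array.
DistSpec = Union[int, float, tuple, Callable]


@dataclasses.dataclass(frozen=True)
class DiseaseModel:
    """Logistic disease model on the count of carried causal rare alleles.

    The log-odds of being affected is ``logit(baseline_prevalence) +
    beta * k`` for a child carrying ``k`` causal alleles, so a non-carrier
    is affected with probability ``baseline_prevalence`` exactly and each
    causal allele multiplies the odds by ``exp(beta)``.
    """

    causal_fraction: float
    beta: float
    baseline_prevalence: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.causal_fraction <= 1.0:
            raise ValueError(f"causal_fraction must be in [0, 1], got {self.causal_fraction}")
        if not np.isfinite(self.beta):
            raise ValueError("beta must be finite")
        if not 0.0 < self.baseline_prevalence < 1.0:
            raise ValueError("baseline_prevalence must be in (0, 1)")

    @property
    def intercept(self) -> float:
        """Logistic intercept solved so a causal-allele-free child has
        affection probability equal to the baseline prevalence."""
        p = self.baseline_prevalence
        return float(np.log(p / (1.0 - p)))

    def affected_probability(self, causal_count) -> np.ndarray:
        """P(affected | k causal rare alleles), elementwise."""
        logodds = self.intercept + self.beta * np.asarray(causal_count, dtype=float)
        return 1.0 / (1.0 + np.exp(-logodds))


class VariantPanel:
    """Variant/gene structure with per-variant rare-allele frequencies.

    Thin wrapper around a DataFrame with columns ``variant_id``, ``gene_id``,
    ``position``, ``rare_allele_freq``, ``is_causal``; validates frequency
    bounds and uniqueness on construction.
    """

    def __init__(self, table: pd.DataFrame, maf_cap: float):
        required = {"variant_id", "gene_id", "position", "rare_allele_freq", "is_causal"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"panel table missing columns: {sorted(missing)}")
        if table["variant_id"].duplicated().any():
            raise ValueError("duplicate variant_id: each variant belongs to exactly one record")
        freqs = table["rare_allele_freq"].to_numpy()
        if len(freqs) and (freqs.min() <= 0.0 or freqs.max() > maf_cap):
            raise ValueError(f"rare_allele_freq must lie in (0, {maf_cap}]")
        self.table = table.reset_index(drop=True)
        self.maf_cap = float(maf_cap)

    @property
    def n_variants(self) -> int:
        return len(self.table)

    @property
    def n_genes(self) -> int:
        return self.table["gene_id"].nunique()

    @property
    def freqs(self) -> np.ndarray:
        return self.table["rare_allele_freq"].to_numpy(dtype=float)

    @property
    def variant_ids(self) -> pd.Index:
        return pd.Index(self.table["variant_id"])

    @property
    def gene_map(self) -> pd.Series:
        """Series variant_id -> gene_id."""
        return self.table.set_index("variant_id")["gene_id"]

    @property
    def causal_mask(self) -> np.ndarray:
        return self.table["is_causal"].to_numpy(dtype=bool)

    def attach_disease_model(self, model: DiseaseModel, seed: int) -> "VariantPanel":
        """Return a copy with ``round(causal_fraction * n_variants)`` variants
        flagged causal, chosen uniformly at random."""
        rng = np.random.default_rng(seed)
        n_causal = int(round(model.causal_fraction * self.n_variants))
        idx = rng.choice(self.n_variants, size=n_causal, replace=False)
        table = self.table.copy()
        table["is_causal"] = False
        table.loc[table.index[idx], "is_causal"] = True
        return VariantPanel(table, self.maf_cap)

    def config_digest(self, extra: dict | None = None) -> str:
        """Short provenance digest over panel shape and any extra config."""
        payload = {
            "n_variants": self.n_variants,
            "n_genes": self.n_genes,
            "maf_cap": self.maf_cap,
            **(extra or {}),
        }
        return hashlib.md5(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def reciprocal_spectrum(maf_cap: float, n_eff: int = 1000) -> Callable:
    """Frequency spectrum with density proportional to 1/f, truncated to
    [1/(2*n_eff), maf_cap].

    This mimics the neutral site-frequency spectrum in which rare sites
    dominate a sequencing panel. Sampling uses the closed-form inverse CDF
    ``a * (b/a)**u`` for u uniform on [0, 1).
    """
    lo = 1.0 / (2.0 * n_eff)
    if lo >= maf_cap:
        raise ValueError(f"n_eff={n_eff} leaves an empty support below maf_cap={maf_cap}")

    def draw(rng: np.random.Generator, size: int) -> np.ndarray:
        return lo * (maf_cap / lo) ** rng.random(size)

    return draw


def _draw(spec: DistSpec, rng: np.random.Generator, size: int, what: str) -> np.ndarray:
    if callable(spec):
        return np.asarray(spec(rng, size))
    if isinstance(spec, tuple):
        name, *params = spec
        if name == "poisson":
            return rng.poisson(params[0], size)
        if name == "uniform_int":
            lo, hi = params
            return rng.integers(lo, hi + 1, size)
        raise ValueError(f"unknown {what} spec {spec!r}")
    return np.full(size, spec)


def sample_panel(
    n_genes: int,
    variants_per_gene: DistSpec,
    maf_spectrum: DistSpec | None = None,
    maf_cap: float = 0.05,
    seed: int = 0,
    n_eff: int = 1000,
) -> VariantPanel:
    """Draw a rare-variant panel: per-gene variant counts from
    ``variants_per_gene`` and frequencies from ``maf_spectrum``.

    Parameters
    ----------
    variants_per_gene
        Integer (fixed count), ``("poisson", mean)`` / ``("uniform_int", lo,
        hi)`` tuple, or callable ``(rng, size) -> counts``. Genes that draw a
        zero count are redrawn to at least one variant, so every gene is
        represented.
    maf_spectrum
        Scalar (point-mass frequency), callable ``(rng, size) -> freqs``, or
        None for the default 1/f spectrum on [1/(2*n_eff), maf_cap].

    Deterministic given ``seed``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 0.0 < maf_cap <= 0.5:
        raise ValueError(f"maf_cap must lie in (0, 0.5], got {maf_cap}")
    rng = np.random.default_rng(seed)
    if maf_spectrum is None:
        maf_spectrum = reciprocal_spectrum(maf_cap, n_eff=n_eff)

    raw = np.asarray(_draw(variants_per_gene, rng, n_genes, "variants_per_gene"))
    if raw.max() < 1:
        raise ValueError("variants_per_gene spec has no mass above zero (empty panel)")
    counts = np.maximum(raw, 1).astype(int)  # random zero draws bumped so every gene exists
    total = int(counts.sum())

    freqs = np.asarray(_draw(maf_spectrum, rng, total, "maf_spectrum"), dtype=float)
    if freqs.min() <= 0.0 or freqs.max() > maf_cap:
        raise ValueError("maf_spectrum produced frequencies outside (0, maf_cap]")

    gene_idx = np.repeat(np.arange(n_genes), counts)
    within = np.concatenate([np.arange(c) for c in counts])
    gene_ids = np.char.add("g", np.char.zfill((gene_idx + 1).astype(str), 4))
    variant_ids = np.array(
        [f"{g}_v{w + 1:04d}" for g, w in zip(gene_ids, within)], dtype=object
    )
    # positions: variants 100 bp apart within a gene, genes 10 kb apart
    positions = gene_idx * 10_000 + within * 100 + 1

    table = pd.DataFrame(
        {
            "variant_id": variant_ids,
            "gene_id": gene_ids,
            "position": positions.astype(int),
            "rare_allele_freq": freqs,
            "is_causal": False,
        }
    )
    return VariantPanel(table, maf_cap)
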