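"""Gene-level transmission test by collapsing rare-variant counts.

Rare variants are individually underpowered, so they are grouped into genes
and tested jointly: the gene-level test sums transmitted and non-transmitted
counts over a gene's member variants and applies the same
(P - Q)^2 / (P + Q) chi-square(1) statistic to the sums. Because counts add,
calling errors that bias individual variants accumulate over a gene — long
genes are hit hardest.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .transmission import TransmissionCounts, tdt_test

__all__ = ["gene_tdt", "stratify_by_size"]


def gene_tdt(counts: TransmissionCounts, gene_map) -> pd.DataFrame:
    """Collapse per-variant counts into per-gene tests.

    Parameters
    ----------
    counts
        Per-variant transmission counts.
    gene_map
        variant_id -> gene_id mapping: a dict, a Series indexed by
        variant_id, or a VariantPanel.

    Returns a DataFrame with columns ``gene_id``, ``n_variants``, ``P_g``,
    ``Q_g``, ``statistic``, ``p_value`` (one row per gene; genes whose
    collapsed counts are empty get p-value 1). Variants missing from the map
    raise rather than being silently dropped.
    """
    if hasattr(gene_map, "gene_map"):
        gene_map = gene_map.gene_map
    gene_map = pd.Series(gene_map)
    table = counts.per_variant
    unmapped = table.index.difference(gene_map.index)
    if len(unmapped):
        preview = ", ".join(map(str, unmapped[:5]))
        raise ValueError(f"{len(unmapped)} variant(s) missing from gene map: {preview}")

    grouped = table.groupby(gene_map.reindex(table.index))
    out = grouped.agg(n_variants=("p", "size"), P_g=("p", "sum"), Q_g=("q", "sum"))
    stat, pval = tdt_test(out["P_g"].to_numpy(), out["Q_g"].to_numpy())
    out["statistic"] = np.atleast_1d(stat)
    out["p_value"] = np.atleast_1d(pval)
    out.index.name = "gene_id"
    return out.reset_index()


def stratify_by_size(results: pd.DataFrame, thresholds: tuple[int, int] = (50, 100)):
    """Partition gene results by gene length (variant count).

    Returns ``{"small": ..., "middle": ..., "large": ...}`` with small genes
    holding fewer than ``thresholds[0]`` variants, large genes more than
    ``thresholds[1]``, and everything else in the middle. The three parts are
    disjoint and jointly exhaust the input.
    """
    low, high = thresholds
    if not low < high:
        raise ValueError(f"thresholds must satisfy low < high, got {thresholds}")
    n = results["n_variants"]
    return {
        "small": results[n < low],
        "middle": results[(n >= low) & (n <= high)],
        "large": results[n > high],
    }
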