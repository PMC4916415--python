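"""Standard-format readers and writers: VCF v4.2, 6-column PED, gene maps.

Cohorts are stored as one VCF sample per individual with a GT-only FORMAT
(unphased ``0/1`` notation; ``./.`` for missing), a PLINK-compatible PED
describing the trio structure, and a two-column gene map (gene_id,
variant_id). Every VCF written here embeds a digest of the generating
configuration in its header for provenance.
"""

from __future__ import annotations


import numpy as np
import pandas as pd
import pysam

from .cohort import CHILD, FATHER, MISSING, MOTHER, TrioCohort
from .panel import VariantPanel
from .propagation import percent_transmitted
from .transmission import TransmissionCounts

__all__ = [
    "write_trio_vcf",
    "read_trio_vcf",
    "write_ped",
    "read_ped_trios",
    "write_gene_map",
    "read_gene_map",
    "bed_to_gene_map",
    "write_tally_table",
]

_SUFFIX = {FATHER: "fa", MOTHER: "mo", CHILD: "ch"}
_GT = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}


def _sample_names(n_trios: int) -> list[str]:
    return [
        f"fam{t + 1:04d}_{_SUFFIX[m]}" for t in range(n_trios) for m in (FATHER, MOTHER, CHILD)
    ]


def write_trio_vcf(
    cohort: TrioCohort,
    vcf_path,
    layer: str = "observed",
    config_digest: str | None = None,
) -> None:
    """Write one genotype layer of a cohort as an uncompressed VCF v4.2."""
    panel = cohort.panel
    geno = cohort.layer(layer)
    header = pysam.VariantHeader()
    header.add_line("##source=triotdt")
    digest = config_digest or panel.config_digest({"n_trios": cohort.n_trios})
    header.add_line(f"##triotdt_config_digest={digest}")
    header.contigs.add("1", length=int(panel.table["position"].max()) + 1000)
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    samples = _sample_names(cohort.n_trios)
    for s in samples:
        header.add_sample(s)

    flat = geno.reshape(cohort.n_trios * 3, cohort.n_variants)
    with pysam.VariantFile(str(vcf_path), "w", header=header) as out:
        for j, row in panel.table.iterrows():
            rec = out.new_record(
                contig="1",
                start=int(row["position"]) - 1,
                alleles=("A", "C"),
                id=str(row["variant_id"]),
            )
            for k, s in enumerate(samples):
                rec.samples[s]["GT"] = _GT[int(flat[k, j])]
                rec.samples[s].phased = False
            out.write(rec)


def write_ped(cohort: TrioCohort, ped_path) -> None:
    """6-column whitespace-separated PED: children carry the affection flag."""
    rows = []
    aff_child = 2 if cohort.child_affected else 1
    for t in range(cohort.n_trios):
        fam = f"fam{t + 1:04d}"
        fa, mo, ch = (f"{fam}_{_SUFFIX[m]}" for m in (FATHER, MOTHER, CHILD))
        rows.append((fam, fa, "0", "0", 1, 1))
        rows.append((fam, mo, "0", "0", 2, 1))
        rows.append((fam, ch, fa, mo, 0, aff_child))
    pd.DataFrame(rows).to_csv(ped_path, sep="\t", header=False, index=False)


def read_ped_trios(ped_path) -> pd.DataFrame:
    """Parse a trios-only PED into one row per trio.

    Each family must contain exactly one child whose father and mother ids
    both appear in the same family; anything else is rejected.
    """
    ped = pd.read_csv(
        ped_path,
        sep=r"\s+",
        header=None,
        names=["family_id", "individual_id", "father_id", "mother_id", "sex", "affection"],
        dtype=str,
    )
    if ped["individual_id"].duplicated().any():
        raise ValueError("duplicate individual ids in PED")
    trios = []
    for fam, grp in ped.groupby("family_id", sort=False):
        members = set(grp["individual_id"])
        children = grp[(grp["father_id"] != "0") | (grp["mother_id"] != "0")]
        if len(children) != 1 or len(grp) != 3:
            raise ValueError(f"family {fam} is not a trio (one child, two founders)")
        child = children.iloc[0]
        if child["father_id"] not in members or child["mother_id"] not in members:
            raise ValueError(f"family {fam}: child's parents not present in the family")
        if child["individual_id"] in (child["father_id"], child["mother_id"]):
            raise ValueError(f"family {fam}: individual listed as its own parent")
        trios.append(
            dict(
                family_id=fam,
                father=child["father_id"],
                mother=child["mother_id"],
                child=child["individual_id"],
                affection=int(child["affection"]),
            )
        )
    return pd.DataFrame(trios)


def read_trio_vcf(vcf_path, ped_path, gene_map=None) -> TrioCohort:
    """Read a trio cohort from VCF + PED.

    Records must be biallelic; multiallelic sites are rejected with their
    positions listed. Sample sets must match the PED exactly, and both
    mismatch directions are reported by name. The returned cohort's true and
    observed layers both hold the file's genotypes (a file records one call
    set); rare-allele frequencies are left unknown (NaN) in the panel
    skeleton unless estimated downstream.
    """
    trios = read_ped_trios(ped_path)
    with pysam.VariantFile(str(vcf_path)) as vf:
        vcf_samples = list(vf.header.samples)
        ped_people = set(trios["father"]) | set(trios["mother"]) | set(trios["child"])
        missing_in_vcf = sorted(ped_people - set(vcf_samples))
        if missing_in_vcf:
            raise ValueError(f"PED individuals absent from VCF: {missing_in_vcf}")
        extra = sorted(set(vcf_samples) - ped_people)
        if extra:
            raise ValueError(f"VCF samples absent from PED: {extra}")

        order = [
            trios.iloc[t][m] for t in range(len(trios)) for m in ("father", "mother", "child")
        ]
        dosages, vids, positions, bad = [], [], [], []
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                bad.append(f"{rec.chrom}:{rec.pos}")
                continue
            row = np.empty(len(order), dtype=np.int8)
            for k, s in enumerate(order):
                gt = rec.samples[s]["GT"]
                if gt is None or any(a is None for a in gt):
                    row[k] = MISSING
                else:
                    if any(a not in (0, 1) for a in gt):
                        raise ValueError(f"malformed GT {gt} at {rec.chrom}:{rec.pos}")
                    row[k] = sum(gt)
            dosages.append(row)
            vids.append(rec.id or f"{rec.chrom}:{rec.pos}")
            positions.append(rec.pos)
        if bad:
            raise ValueError(f"multiallelic records not supported: {bad}")

    geno = np.stack(dosages, axis=1).reshape(len(trios), 3, -1) if dosages else np.empty(
        (len(trios), 3, 0), dtype=np.int8
    )
    if gene_map is not None:
        gene_map = pd.Series(gene_map)
        gene_ids = [gene_map.get(v, v) for v in vids]
    else:
        gene_ids = vids  # no map: every variant is its own group
    table = pd.DataFrame(
        {
            "variant_id": vids,
            "gene_id": gene_ids,
            "position": positions,
            "rare_allele_freq": np.nan,
            "is_causal": False,
        }
    )
    panel = VariantPanel(table, maf_cap=0.5)
    affected = bool(len(trios)) and bool((trios["affection"] == 2).all())
    return TrioCohort(panel, geno, geno.copy(), child_affected=affected)


def write_gene_map(panel: VariantPanel, path) -> None:
    panel.table[["gene_id", "variant_id"]].to_csv(path, sep="\t", index=False)


def read_gene_map(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "variant_id"} <= set(df.columns):
        raise ValueError("gene map needs 'gene_id' and 'variant_id' columns")
    return df.set_index("variant_id")["gene_id"]


def bed_to_gene_map(bed_path, panel: VariantPanel, chrom: str = "1") -> pd.Series:
    """Assign panel variants to genes by BED interval overlap.

    BED intervals are half-open and 0-based; a variant at 1-based position p
    belongs to the interval containing p - 1. Variants outside every
    interval are omitted from the map.
    """
    bed = pd.read_csv(
        bed_path, sep="\t", header=None, usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "name"],
    )
    bed = bed[bed["chrom"].astype(str) == chrom]
    ii = pd.IntervalIndex.from_arrays(bed["start"], bed["end"], closed="left")
    pos0 = panel.table["position"].to_numpy() - 1
    idx = ii.get_indexer(pos0)
    hit = idx >= 0
    return pd.Series(
        bed["name"].to_numpy()[idx[hit]],
        index=panel.table["variant_id"].to_numpy()[hit],
    )


def write_tally_table(columns: dict, counts_are_totals: bool = True) -> str:
    """Format per-condition totals as a two-row tally table.

    ``columns`` maps a condition label to either an (T, U) pair or a
    TransmissionCounts. Cells read ``374,502 (47%)``: thousands-separated
    counts with nearest-integer percentages.
    """

    def pair(v):
        if isinstance(v, TransmissionCounts):
            return v.totals
        return v

    labels = list(columns)
    widths = {}
    cells_t, cells_u = {}, {}
    for lab in labels:
        T, U = pair(columns[lab])
        cells_t[lab] = f"{round(T):,} ({percent_transmitted(T, U)}%)"
        cells_u[lab] = f"{round(U):,} ({percent_transmitted(U, T)}%)"
        widths[lab] = max(len(lab), len(cells_t[lab]), len(cells_u[lab]))
    head = "\t".join([""] + [lab.ljust(widths[lab]) for lab in labels])
    row_t = "\t".join(["Transmitted"] + [cells_t[lab].ljust(widths[lab]) for lab in labels])
    row_u = "\t".join(["Non-transmitted"] + [cells_u[lab].ljust(widths[lab]) for lab in labels])
    return "\n".join([head, row_t, row_u])
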