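"""Gene annotation of outlier windows and run summaries.

A gene shows evidence of selection in a breed when its interval overlaps
(>= 1 bp) any of that breed's putative-selection windows. GFF3 gene
coordinates (1-based inclusive) are converted to 0-based half-open before
the overlap test against the window grid; strand is ignored, since
selection windows are unstranded.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import DataError
from .filtering import FilterResult
from .hp import snp_hp_values
from .io import CountsTable, GeneFeature
from .outliers import STATUS_BOTH, STATUS_FST, STATUS_HP

GENE_TABLE_COLUMNS = [
    "breed", "gene_id", "chrom", "gene_start", "gene_end",
    "window_start", "window_end",
]


def genes_in_windows(
    calls: pd.DataFrame,
    genes: Sequence[GeneFeature],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Map putative-selection windows to overlapping genes.

    Returns ``(gene_table, window_annotations)``. ``gene_table`` has one
    row per (breed, gene, window) overlap, sorted by (breed, chrom,
    gene_start, gene_id). ``window_annotations`` carries every putative
    window with its gene count — windows with ``n_genes == 0`` are the
    unannotated regions. Raises ``DataError`` when the chromosome name
    sets of the windows and the annotation are disjoint (a naming-scheme
    mismatch rather than genuinely gene-free chromosomes).
    """
    put = calls[calls["status"] == STATUS_BOTH].copy()
    win_chroms = set(put["chrom"].unique())
    gene_chroms = {g.chrom for g in genes}
    if put.shape[0] and genes and win_chroms.isdisjoint(gene_chroms):
        raise DataError(
            "no chromosome name shared between outlier windows and annotation; "
            f"window chroms: {sorted(win_chroms)}; "
            f"annotation chroms: {sorted(gene_chroms)}"
        )
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        # GFF3 1-based inclusive -> 0-based half-open
        trees.setdefault(g.chrom, IntervalTree())[g.start - 1 : g.end] = g
    rows = []
    n_genes_col = []
    for rec in put.itertuples():
        hits = trees[rec.chrom][rec.start : rec.end] if rec.chrom in trees else set()
        n_genes_col.append(len(hits))
        for hit in hits:
            g = hit.data
            rows.append(
                (rec.breed, g.gene_id, g.chrom, g.start, g.end, rec.start, rec.end)
            )
    gene_table = pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS)
    gene_table = gene_table.sort_values(
        ["breed", "chrom", "gene_start", "gene_id", "window_start"], kind="stable"
    ).reset_index(drop=True)
    put["n_genes"] = n_genes_col
    return gene_table, put.reset_index(drop=True)


def breed_gene_lists(gene_table: pd.DataFrame) -> dict[str, list[str]]:
    """Per-breed sorted unique candidate gene IDs."""
    return {
        breed: sorted(grp["gene_id"].unique())
        for breed, grp in gene_table.groupby("breed")
    }


def summarize_run(
    counts: CountsTable,
    filt: FilterResult,
    calls: pd.DataFrame,
    gene_table: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
) -> pd.DataFrame:
    """One summary row per breed: SNP yield, diversity, and outlier counts.

    ``snps_per_kb`` is the breed's retained SNP count over the genome
    length in kb; ``mean_maf`` and ``mean_hp`` are means over the breed's
    retained SNPs of the per-SNP read MAF and pooled heterozygosity.
    ``n_fst_outliers``/``n_hp_outliers`` count each tail in full (windows
    in both tails are in both counts); ``n_putative`` counts the
    intersection and ``n_genes`` the breed's distinct candidate genes.
    """
    genome_kb = sum(chrom_lengths.values()) / 1000.0
    maf = counts.maf()
    rows = []
    for j, breed in enumerate(counts.breeds):
        sel = filt.passed[:, j]
        n_snps = int(sel.sum())
        n_maj = np.maximum(counts.n_ref[sel, j], counts.n_alt[sel, j])
        n_min = np.minimum(counts.n_ref[sel, j], counts.n_alt[sel, j])
        mean_hp = float(snp_hp_values(n_maj, n_min).mean()) if n_snps else np.nan
        mean_maf = float(np.nanmean(maf[sel, j])) if n_snps else np.nan
        bc = calls[calls["breed"] == breed]
        n_both = int((bc["status"] == STATUS_BOTH).sum())
        n_fst = int((bc["status"] == STATUS_FST).sum()) + n_both
        n_hp = int((bc["status"] == STATUS_HP).sum()) + n_both
        n_genes = (
            gene_table.loc[gene_table["breed"] == breed, "gene_id"].nunique()
            if len(gene_table)
            else 0
        )
        rows.append(
            (breed, n_snps, n_snps / genome_kb, mean_maf, mean_hp,
             n_fst, n_hp, n_both, int(n_genes))
        )
    return pd.DataFrame(
        rows,
        columns=[
            "breed", "n_snps", "snps_per_kb", "mean_maf", "mean_hp",
            "n_fst_outliers", "n_hp_outliers", "n_putative", "n_genes",
        ],
    )
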