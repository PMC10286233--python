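"""Colocalization of candidate-gene SNPs with QTL intervals by trait category.

A candidate gene is colocalized with a QTL region when at least one of the
SNPs that contributed to its F_ST aggregate falls inside the region. VCF
1-based SNP positions are converted to BED coordinates by the single owner
of that mapping (:func:`divase.variant_io.vcf_to_bed_pos`); containment is
then the half-open test start <= pos0 < end on the same contig. Genes whose
SNPs overlap no region are emitted once with category "none" so the output
partitions the candidate set.
"""

from __future__ import annotations

import pandas as pd
from intervaltree import IntervalTree

from .variant_io import QtlRegion, vcf_to_bed_pos


def _region_trees(regions: list[QtlRegion]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for r in regions:
        trees.setdefault(r.contig, IntervalTree()).addi(r.start, r.end, r)
    return trees


def overlap_snps_regions(
    snps: pd.DataFrame, regions: list[QtlRegion], comparison: str = ""
) -> pd.DataFrame:
    """One record per (candidate-gene SNP, overlapping QTL region).

    Parameters
    ----------
    snps : DataFrame
        Columns gene_id, contig, pos (VCF 1-based) — the SNPs of candidate
        genes.
    regions : list of QtlRegion
        BED-convention intervals.

    Returns a table (comparison, gene_id, contig, pos, qtl_id, category,
    overlap) where genes with no overlapping region anywhere appear once
    with qtl_id "." and category "none". Output order is deterministic and
    independent of input order.
    """
    trees = _region_trees(regions)
    rows = []
    genes_hit: set[str] = set()
    for snp in snps.itertuples(index=False):
        tree = trees.get(str(snp.contig))
        pos0 = vcf_to_bed_pos(int(snp.pos))
        hits = tree.at(pos0) if tree is not None else ()
        for iv in hits:
            r: QtlRegion = iv.data
            rows.append(
                (comparison, snp.gene_id, str(snp.contig), int(snp.pos),
                 r.source_id, r.category, True)
            )
            genes_hit.add(snp.gene_id)
    for gene_id in sorted(set(snps["gene_id"]) - genes_hit):
        rows.append((comparison, gene_id, ".", 0, ".", "none", False))
    out = pd.DataFrame(
        rows,
        columns=["comparison", "gene_id", "contig", "pos", "qtl_id", "category",
                 "overlap"],
    )
    return out.sort_values(
        ["gene_id", "contig", "pos", "qtl_id", "category"], kind="mergesort"
    ).reset_index(drop=True)


def summarize_by_category(records: pd.DataFrame) -> pd.DataFrame:
    """Gene counts per (comparison, category); a gene counts once per category.

    Genes overlapping regions of several categories count in each; the
    "none" pseudo-category carries the non-colocalized genes.
    """
    dedup = records[["comparison", "category", "gene_id"]].drop_duplicates()
    counts = (
        dedup.groupby(["comparison", "category"])["gene_id"]
        .nunique()
        .reset_index(name="n_genes")
    )
    return counts.sort_values(["comparison", "category"], kind="mergesort").reset_index(
        drop=True
    )
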