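"""Intersection layer: strain-specific ASE sets and their F_ST overlap.

From the ASE results (04) and the LB-vs-LSL gene screen (02): per-week
strain-specific ASE genes (significant in one strain, not the other, at the
same week), genes shared across all weeks within and between strains, and
the overlap of each strain-specific set with the top-1% Z(F_ST) genes,
printed as k/n ratios.
"""

import pandas as pd
from common import OUT, run_config

from divase import pipeline as pl
from divase import variant_io as vio


def main() -> None:
    cfg = run_config()
    results = pd.read_csv(OUT / "ase_results.tsv", sep="\t")
    strains = tuple(sorted(results["strain"].unique()))
    weeks = tuple(sorted(results["week"].unique()))
    membership = pl.classify_membership(results, strains, weeks, cfg.alpha)
    summary = pl.membership_summary(membership, strains, weeks)
    gene_tab = pd.read_csv(OUT / "gene_fst_LB_vs_LSL.tsv", sep="\t")
    top = set(gene_tab.loc[gene_tab["in_top_fraction"], "gene_id"])
    overlap = pl.fst_ase_overlap(membership, top, strains, weeks)

    vio.write_table(membership, OUT / "ase_membership.tsv", ["gene_id"])
    vio.write_table(summary, OUT / "ase_summary.tsv", ["strain"])
    vio.write_table(overlap, OUT / "fst_ase_overlap.tsv", ["strain", "week"])

    for row in summary.itertuples(index=False):
        per_week = [getattr(row, f"specific_w{w}") for w in weeks]
        print(
            f"{row.strain}: specific per week {per_week} -> total "
            f"{row.specific_total} (distinct {row.specific_distinct}); "
            f"common across weeks {row.common_across_weeks}"
        )
    print(f"common in both strains across all weeks: "
          f"{summary['common_both_strains'].iloc[0]}")
    print("overlap with top-1% Z(F_ST) genes (LB vs LSL):")
    for row in overlap.itertuples(index=False):
        print(f"  {row.strain} week {row.week}: {row.ratio}")


if __name__ == "__main__":
    main()
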