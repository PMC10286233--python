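"""Summarize candidate-gene / QTL colocalization by trait category.

Reads the per-comparison colocalization tables written by 02_fst_screen.py
and prints, for each comparison, how many candidate genes have at least one
SNP inside a QTL region of each trait category ("none" = not colocalized
with any region, the gray-line set).
"""

import pandas as pd
from common import OUT, run_config

from divase import qtl_coloc as qc


def main() -> None:
    cfg = run_config()
    for p1, p2 in cfg.comparisons:
        name = f"{p1}_vs_{p2}"
        records = pd.read_csv(OUT / f"coloc_{name}.tsv", sep="\t")
        if records.empty:
            print(f"{name}: no candidate genes")
            continue
        summary = qc.summarize_by_category(records)
        print(f"{name}: candidate genes by QTL category")
        for row in summary.itertuples(index=False):
            print(f"  {row.category:15s} {row.n_genes}")


if __name__ == "__main__":
    main()
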