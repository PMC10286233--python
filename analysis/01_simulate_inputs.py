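"""Simulate the study inputs: genotypes, gene map, QTL regions, ASE counts.

Emulates three chicken cohorts (two layer strains, LB and LSL, and a
broiler, BR; 90/89/21 diploid individuals) genotyped at ~2,600 SNPs tiling
300 genes, a QTL map with six trait categories, and per-SNP allele read
counts for 10 individuals per strain and laying age. Writes the standard
file formats under results/analysis/inputs/ and reports what was planted.
"""

import pandas as pd
from common import ASE_PI_ALT, ASE_TAU, ASE_TRUE_FRACTION, DATA, run_config

from divase import synthetic_data as sd
from divase import variant_io as vio


def main() -> None:
    cfg = run_config()
    DATA.mkdir(parents=True, exist_ok=True)

    sim = sd.CohortSimConfig(seed=cfg.seed, **cfg.cohort)
    gm, gene_map, truth = sd.simulate_cohort(sim)
    vio.write_vcf(gm, DATA / "genotypes.vcf")
    vio.write_gene_map(gene_map, DATA / "gene_map.tsv")
    vio.write_table(truth.gene_truth, DATA / "truth_genes.tsv", ["gene_id"])

    layout = {str(i): 2_000_000 for i in range(1, sim.n_autosomes + 1)}
    regions = sd.simulate_qtl_regions(
        layout, cfg.n_qtl_regions, mean_length=cfg.qtl_mean_length, seed=cfg.seed
    )
    vio.write_bed(regions, DATA / "qtl.bed")

    # ASE layer: a balanced majority plus a cis-regulated minority of genes
    n_ase = int(len(gene_map.table) * ASE_TRUE_FRACTION)
    ase_genes = sd.GeneMap(gene_map.table.tail(n_ase).reset_index(drop=True))
    null_genes = sd.GeneMap(gene_map.table.head(len(gene_map.table) - n_ase)
                            .reset_index(drop=True))
    null_cfg = sd.AseSimConfig(seed=cfg.seed, **cfg.ase)
    alt_kw = {**cfg.ase, "pi_truth": ASE_PI_ALT, "tau": ASE_TAU}
    alt_cfg = sd.AseSimConfig(seed=cfg.seed, **alt_kw)
    counts_null, truth_null = sd.simulate_ase_counts(null_genes, null_cfg)
    counts_alt, truth_alt = sd.simulate_ase_counts(ase_genes, alt_cfg)
    counts = pd.concat([counts_null, counts_alt], ignore_index=True)
    vio.write_table(
        counts, DATA / "ase_counts.tsv",
        ["strain", "week", "gene_id", "pos", "individual"],
    )
    ase_truth = pd.concat(
        [truth_null.gene_truth, truth_alt.gene_truth], ignore_index=True
    )
    vio.write_table(ase_truth, DATA / "truth_ase.tsv", ["gene_id"])

    planted = truth.gene_truth["is_divergent"].sum()
    print(f"cohort: {gm.n_snps} SNPs x {gm.n_individuals} individuals "
          f"({dict(zip(sim.pop_labels, sim.pop_sizes))})")
    print(f"planted divergent genes (F={sim.divergent_F} vs "
          f"baseline {sim.baseline_F}): {planted} of {sim.n_genes}")
    print(f"QTL regions: {len(regions)}; ASE rows: {len(counts)} "
          f"({n_ase} genes with true imbalance pi={ASE_PI_ALT})")
    print(f"inputs written to {DATA}")


if __name__ == "__main__":
    main()
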