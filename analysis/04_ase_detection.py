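"""Population-level ASE detection per strain and laying age.

Reads the simulated allele counts (01_simulate_inputs.py), applies the
per-SNP-per-sample count filter, and runs the folded-deviance resampling
test for every (strain, week, gene). Writes ase_results.tsv and prints the
per-group counts of significant genes (p < 0.05, and p < 0.01 with
FDR < 5%).
"""

from common import DATA, OUT, run_config

from divase import ase_detect as ad
from divase import variant_io as vio


def main() -> None:
    cfg = run_config()
    counts = vio.read_ase_counts(DATA / "ase_counts.tsv")
    results = ad.detect_ase(
        counts, r_max=cfg.ase_r_max, batch=cfg.ase_batch,
        stop_hits=cfg.ase_stop_hits, seed=cfg.seed,
        alpha=cfg.alpha, alpha_strict=cfg.alpha_strict,
    )
    vio.write_table(results, OUT / "ase_results.tsv", ["strain", "week", "gene_id"])
    print(f"tested {len(results)} gene x group combinations")
    for (strain, week), grp in results.groupby(["strain", "week"]):
        print(
            f"  {strain} week {week}: {grp['significant_05'].sum():4d} genes "
            f"p<0.05, {grp['significant_01'].sum():4d} genes p<0.01 (FDR<5%) "
            f"of {len(grp)}"
        )
    print(f"results written to {OUT / 'ase_results.tsv'}")


if __name__ == "__main__":
    main()
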