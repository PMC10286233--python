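"""Shared run configuration for the numbered analysis scripts.

One seed drives every stage; outputs accumulate under results/analysis so
the scripts can be run in order (01 .. 05) or individually re-run.
"""

from pathlib import Path

from divase import pipeline as pl

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "analysis"
DATA = OUT / "inputs"
SEED = 17


def run_config() -> pl.RunConfig:
    return pl.RunConfig(
        seed=SEED,
        out_dir=str(OUT),
        comparisons=(("LB", "LSL"), ("LB", "BR"), ("LSL", "BR")),
        cohort=dict(
            n_genes=300, snps_per_gene=8, intergenic_snps=200,
            divergent_gene_fraction=0.01,
        ),
        ase=dict(
            n_individuals=10, snps_per_gene=3, depth_mean=50.0,
            pi_truth=0.5, tau=0.0,
        ),
        ase_r_max=2_000,
        n_qtl_regions=200,
    )


# the analysis simulates a mixture: most genes balanced, a subset with true
# allelic imbalance (the cis-regulated fraction)
ASE_TRUE_FRACTION = 0.25
ASE_PI_ALT = 0.7
ASE_TAU = 0.2
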