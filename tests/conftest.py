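import numpy as np
import pandas as pd
import pytest

from divase import synthetic_data as sd
from divase.variant_io import GeneMap, GenotypeMatrix


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """Two populations x 30 diploids, 60 genes x 5 SNPs, some missingness."""
    cfg = sd.CohortSimConfig(
        n_populations=2,
        pop_sizes=(30, 30),
        pop_labels=("A", "B"),
        n_genes=60,
        snps_per_gene=5,
        intergenic_snps=50,
        baseline_F=0.1,
        divergent_gene_fraction=0.05,
        divergent_F=0.5,
        missing_rate=0.05,
        nonautosomal_fraction=0.1,
        seed=42,
    )
    return sd.simulate_cohort(cfg)


@pytest.fixture()
def tiny_gene_map():
    return GeneMap(
        pd.DataFrame(
            {
                "gene_id": ["gA", "gB", "gC"],
                "contig": ["1", "1", "2"],
                "start": [100, 150, 100],
                "end": [200, 300, 200],
            }
        )
    )


def make_matrix(dosage, contigs=None, populations=None):
    """Hand-build a GenotypeMatrix from a dosage array."""
    dosage = np.asarray(dosage, dtype=float)
    n_snps, n_ind = dosage.shape
    contigs = contigs if contigs is not None else ["1"] * n_snps
    populations = (
        np.asarray(populations, dtype=object)
        if populations is not None
        else np.array(["A"] * (n_ind // 2) + ["B"] * (n_ind - n_ind // 2), dtype=object)
    )
    snps = pd.DataFrame(
        {
            "contig": contigs,
            "pos": np.arange(1, n_snps + 1) * 10,
            "id": [f"s{i}" for i in range(n_snps)],
            "ref": "A",
            "alt": "C",
        }
    )
    return GenotypeMatrix(
        snps=snps,
        dosage=dosage,
        individuals=[f"i{j}" for j in range(n_ind)],
        populations=populations,
    )
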