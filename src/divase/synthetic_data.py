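"""Synthetic cohorts with known ground truth.

Three generators cover the inputs of the pipeline:

* :func:`simulate_cohort` — diploid SNP genotypes for two or three
  populations under the Balding–Nichols model. Each population's allele
  frequency at a SNP is a Beta draw around a shared ancestral frequency with
  dispersion set by a divergence parameter F; F is the expectation of the
  Weir–Cockerham theta, which gives downstream estimators a closed-form
  recovery target. A chosen fraction of genes is planted with elevated F.
* :func:`simulate_qtl_regions` — QTL intervals by trait category.
* :func:`simulate_ase_counts` — per-SNP allele read counts per individual
  with a per-gene true allelic fraction, per-individual overdispersion on
  the log-odds scale, and random ref/alt label swaps emulating unphased
  data.

All randomness flows from one integer seed through named substreams
("cohort", "qtl", "ase") so each generator can be re-run independently and
reproducibly.

Default parameters emulate the study design the pipeline targets: three
chicken cohorts (two commercial layer strains and one broiler) of 90, 89
and 21 diploid individuals, and ASE groups of 10 individuals per strain and
age (weeks 10, 16, 24, 30, 60).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .errors import ConfigError
from .variant_io import QTL_CATEGORIES, GeneMap, GenotypeMatrix, QtlRegion

DEFAULT_POP_LABELS = ("LB", "LSL", "BR")
DEFAULT_WEEKS = (10, 16, 24, 30, 60)


def substream(seed: int, name: str, *extra: str | int) -> np.random.Generator:
    """Named, order-independent child RNG stream of a single master seed."""
    keys = [zlib.crc32(str(k).encode()) for k in (name, *extra)]
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, *keys]))


@dataclass(frozen=True)
class CohortSimConfig:
    """Settings for the genotype cohort generator.

    ``baseline_F`` is the background between-population divergence;
    ``divergent_F`` applies to the planted fraction of genes. Proportions are
    checked at construction; degenerate Beta shapes (F = 0 or 1) are rejected
    because the Balding–Nichols Beta distribution is undefined there.
    """

    n_populations: int = 3
    pop_sizes: tuple[int, ...] = (90, 89, 21)
    pop_labels: tuple[str, ...] = DEFAULT_POP_LABELS
    n_genes: int = 300
    snps_per_gene: int = 8
    intergenic_snps: int = 200
    baseline_F: float = 0.05
    divergent_gene_fraction: float = 0.005
    divergent_F: float = 0.5
    missing_rate: float = 0.05
    nonautosomal_fraction: float = 0.0265
    n_autosomes: int = 10
    gene_length: int = 10_000
    gene_spacing: int = 5_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_populations not in (2, 3):
            raise ConfigError("n_populations must be 2 or 3")
        if len(self.pop_sizes) != self.n_populations:
            raise ConfigError("pop_sizes length must equal n_populations")
        if any(n < 2 for n in self.pop_sizes):
            raise ConfigError("each population needs at least 2 individuals")
        for name in ("baseline_F", "divergent_F"):
            f = getattr(self, name)
            if not 0.0 < f < 1.0:
                raise ConfigError(f"{name} must lie strictly in (0, 1), got {f}")
        if self.divergent_F <= self.baseline_F:
            raise ConfigError("divergent_F must exceed baseline_F")
        if not 0.0 <= self.divergent_gene_fraction <= 1.0:
            raise ConfigError("divergent_gene_fraction must lie in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must lie in [0, 1)")
        if not 0.0 <= self.nonautosomal_fraction <= 1.0:
            raise ConfigError("nonautosomal_fraction must lie in [0, 1]")
        if self.n_genes < 1 or self.snps_per_gene < 1:
            raise ConfigError("n_genes and snps_per_gene must be positive")


@dataclass(frozen=True)
class AseSimConfig:
    """Settings for the allele-count generator.

    ``pi_truth`` is the true allelic fraction shared by all simulated genes
    (0.5 is the null of no imbalance); ``tau`` is the standard deviation of a
    per-individual random effect on the log-odds scale, the overdispersion
    channel. Depth is Poisson with mean ``depth_mean`` (floored at one read).
    """

    n_individuals: int = 10
    groups: tuple[tuple[str, int], ...] = tuple(
        (s, w) for s in ("LB", "LSL") for w in DEFAULT_WEEKS
    )
    snps_per_gene: int = 3
    depth_mean: float = 50.0
    pi_truth: float = 0.5
    tau: float = 0.0
    swap_labels: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth_mean <= 0:
            raise ConfigError("depth_mean must be positive")
        if not 0.0 < self.pi_truth < 1.0:
            raise ConfigError("pi_truth must lie strictly in (0, 1)")
        if self.tau < 0:
            raise ConfigError("tau must be nonnegative")
        if self.n_individuals < 1 or self.snps_per_gene < 1:
            raise ConfigError("n_individuals and snps_per_gene must be positive")


@dataclass
class TruthLabels:
    """Ground truth attached to a simulated dataset.

    ``gene_truth`` has one row per gene (true divergence parameter and/or
    true allelic fraction); ``snp_truth`` has one row per SNP (contig class).
    """

    gene_truth: pd.DataFrame = field(default_factory=pd.DataFrame)
    snp_truth: pd.DataFrame = field(default_factory=pd.DataFrame)


def _tile_gene_map(cfg: CohortSimConfig) -> GeneMap:
    """Lay genes end to end across the autosomes, round-robin."""
    rows = []
    offsets = dict.fromkeys(range(1, cfg.n_autosomes + 1), 0)
    for g in range(cfg.n_genes):
        contig = g % cfg.n_autosomes + 1
        start = offsets[contig] + cfg.gene_spacing + 1
        end = start + cfg.gene_length - 1
        offsets[contig] = end
        rows.append((f"G{g:05d}", str(contig), start, end))
    return GeneMap(pd.DataFrame(rows, columns=["gene_id", "contig", "start", "end"]))


def simulate_cohort(cfg: CohortSimConfig) -> tuple[GenotypeMatrix, GeneMap, TruthLabels]:
    """Draw a multi-population diploid genotype matrix with planted divergence.

    Per SNP: ancestral frequency ~ Uniform[0.05, 0.95]; per population,
    frequency ~ Beta(p(1-F)/F, (1-p)(1-F)/F) where F is the gene's divergence
    parameter (intergenic SNPs use the baseline); per individual, dosage ~
    Binomial(2, population frequency). Calls are masked missing independently
    at ``missing_rate``. A Bernoulli(``nonautosomal_fraction``) subset of SNPs
    is relocated to contigs "Z"/"W" (and therefore falls outside every gene).

    Returns the genotype matrix, the gene map, and truth labels. Deterministic
    for a fixed config.
    """
    rng = substream(cfg.seed, "cohort")
    gene_map = _tile_gene_map(cfg)

    n_div = int(round(cfg.n_genes * cfg.divergent_gene_fraction))
    div_idx = rng.choice(cfg.n_genes, size=n_div, replace=False) if n_div else np.array([], int)
    gene_F = np.full(cfg.n_genes, cfg.baseline_F)
    gene_F[div_idx] = cfg.divergent_F

    # SNP layout: snps_per_gene evenly spaced inside each gene, then
    # intergenic SNPs on a dedicated stretch past the genes.
    snp_rows = []
    snp_F = []
    for g, gene in enumerate(gene_map.table.itertuples(index=False)):
        positions = np.linspace(gene.start, gene.end, cfg.snps_per_gene, dtype=int)
        positions = np.unique(positions)
        for p in positions:
            snp_rows.append((gene.contig, int(p)))
            snp_F.append(gene_F[g])
    tail = gene_map.table.groupby("contig")["end"].max().to_dict()
    for k in range(cfg.intergenic_snps):
        contig = str(k % cfg.n_autosomes + 1)
        pos = tail.get(contig, 0) + 50_000 + 1_000 * (k // cfg.n_autosomes + 1)
        snp_rows.append((contig, int(pos)))
        snp_F.append(cfg.baseline_F)

    n_snps = len(snp_rows)
    snp_F = np.asarray(snp_F)

    # Relocate a Bernoulli subset to the sex chromosomes.
    nonauto = rng.random(n_snps) < cfg.nonautosomal_fraction
    za = rng.integers(0, 2, size=n_snps)  # Z or W
    contigs = np.array([c for c, _ in snp_rows], dtype=object)
    positions = np.array([p for _, p in snp_rows], dtype=int)
    contigs[nonauto] = np.where(za[nonauto] == 0, "Z", "W")
    positions[nonauto] = 1_000 + 500 * np.flatnonzero(nonauto)

    p_anc = rng.uniform(0.05, 0.95, size=n_snps)
    shape = (1.0 - snp_F) / snp_F
    sizes = np.asarray(cfg.pop_sizes)
    dosage = np.empty((n_snps, int(sizes.sum())), dtype=float)
    col = 0
    for k in range(cfg.n_populations):
        p_pop = rng.beta(p_anc * shape, (1.0 - p_anc) * shape)
        dosage[:, col : col + sizes[k]] = rng.binomial(
            2, p_pop[:, None], size=(n_snps, sizes[k])
        )
        col += sizes[k]
    if cfg.missing_rate > 0:
        dosage[rng.random(dosage.shape) < cfg.missing_rate] = np.nan

    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, n_snps)]
    alt_shift = rng.integers(1, 4, n_snps)
    alt = bases[(np.searchsorted(bases, ref) + alt_shift) % 4]
    snps = pd.DataFrame(
        {
            "contig": contigs,
            "pos": positions,
            "id": [f"snp{i:06d}" for i in range(n_snps)],
            "ref": ref,
            "alt": alt,
        }
    )
    individuals, populations = [], []
    for k in range(cfg.n_populations):
        label = cfg.pop_labels[k]
        individuals += [f"{label}_{j:03d}" for j in range(cfg.pop_sizes[k])]
        populations += [label] * cfg.pop_sizes[k]

    gm = GenotypeMatrix(
        snps=snps,
        dosage=dosage,
        individuals=individuals,
        populations=np.array(populations, dtype=object),
    )
    truth = TruthLabels(
        gene_truth=pd.DataFrame(
            {
                "gene_id": gene_map.table["gene_id"],
                "true_F": gene_F,
                "is_divergent": gene_F > cfg.baseline_F,
            }
        ),
        snp_truth=pd.DataFrame(
            {
                "id": snps["id"],
                "contig_class": np.where(nonauto, "nonautosome", "autosome"),
                "true_F": snp_F,
            }
        ),
    )
    return gm, gene_map, truth


def simulate_qtl_regions(
    genome_layout: dict[str, int],
    n_regions: int,
    categories: tuple[str, ...] = QTL_CATEGORIES,
    mean_length: float = 200_000.0,
    seed: int = 0,
) -> list[QtlRegion]:
    """Place QTL intervals uniformly on the genome with exponential lengths.

    Contigs are chosen proportionally to their length; each region's length
    is Exponential(``mean_length``) clipped to the contig end and floored at
    one base; categories are drawn uniformly from ``categories``.
    """
    if not genome_layout:
        raise ConfigError("genome layout is empty")
    if n_regions < 1:
        raise ConfigError("n_regions must be >= 1")
    if not categories:
        raise ConfigError("categories must be non-empty")
    rng = substream(seed, "qtl")
    names = list(genome_layout)
    lengths = np.array([genome_layout[c] for c in names], dtype=float)
    probs = lengths / lengths.sum()
    regions = []
    for i in range(n_regions):
        ci = rng.choice(len(names), p=probs)
        contig, clen = names[ci], int(lengths[ci])
        start = int(rng.integers(0, clen))
        length = max(1, int(rng.exponential(mean_length)))
        end = min(clen, start + length)
        if end <= start:
            end = start + 1
        category = categories[rng.integers(0, len(categories))]
        regions.append(QtlRegion(contig, start, end, category, f"QTL{i:05d}"))
    return regions


def simulate_ase_counts(
    gene_map: GeneMap, cfg: AseSimConfig
) -> tuple[pd.DataFrame, TruthLabels]:
    """Draw per-SNP allele read counts for every (strain, week) group.

    Per gene, group and individual j: the individual allelic fraction is
    logistic(logit(pi_truth) + Normal(0, tau^2)). Per SNP: depth ~
    Poisson(depth_mean) floored at 1 and alt reads ~ Binomial(depth,
    individual fraction). With ``swap_labels`` each (SNP, individual) cell's
    ref/alt labels are independently swapped with probability 0.5, emulating
    unphased data in which the orientation of the imbalance is unknown.

    Returns a long-format count table (schema of
    :data:`divase.variant_io.ASE_COLUMNS`) and truth labels. Deterministic
    for a fixed config; each (group, gene) uses its own substream.
    """
    rows = []
    genes = gene_map.table
    for strain, week in cfg.groups:
        for gene in genes.itertuples(index=False):
            rng = substream(cfg.seed, "ase", strain, week, gene.gene_id)
            frac = expit(
                logit(cfg.pi_truth)
                + rng.normal(0.0, cfg.tau, size=cfg.n_individuals)
            )
            span = max(gene.end - gene.start, cfg.snps_per_gene)
            pos = gene.start + (
                np.arange(cfg.snps_per_gene) * span // cfg.snps_per_gene
            )
            depth = np.maximum(
                rng.poisson(cfg.depth_mean, size=(cfg.n_individuals, cfg.snps_per_gene)),
                1,
            )
            alt = rng.binomial(depth, frac[:, None])
            ref = depth - alt
            if cfg.swap_labels:
                swap = rng.random((cfg.n_individuals, cfg.snps_per_gene)) < 0.5
                ref, alt = np.where(swap, alt, ref), np.where(swap, ref, alt)
            for j in range(cfg.n_individuals):
                ind = f"{strain}_w{week}_i{j:02d}"
                for s in range(cfg.snps_per_gene):
                    rows.append(
                        (
                            ind,
                            strain,
                            week,
                            gene.gene_id,
                            gene.contig,
                            int(pos[s]),
                            int(ref[j, s]),
                            int(alt[j, s]),
                        )
                    )
    table = pd.DataFrame(
        rows,
        columns=[
            "individual",
            "strain",
            "week",
            "gene_id",
            "contig",
            "pos",
            "ref_reads",
            "alt_reads",
        ],
    )
    truth = TruthLabels(
        gene_truth=pd.DataFrame(
            {"gene_id": genes["gene_id"], "true_pi": cfg.pi_truth}
        )
    )
    return table, truth
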