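"""Per-SNP Weir–Cockerham theta and the gene-level Z(F_ST) screen.

The method-of-moments estimator partitions allelic variance into three
components per SNP — among populations (a), among individuals within
populations (b), and within individuals (c) — and estimates the fixation
index as theta = a / (a + b + c). For a pair of populations with non-missing
diploid sample sizes n_i, alt-allele frequencies p_i and observed
heterozygote proportions h_i (r = 2):

    n_bar = (n_1 + n_2) / r
    n_c   = (r n_bar - sum n_i^2 / (r n_bar)) / (r - 1)
    p_bar = sum n_i p_i / (r n_bar)
    s2    = sum n_i (p_i - p_bar)^2 / ((r - 1) n_bar)
    h_bar = sum n_i h_i / (r n_bar)
    a = (n_bar / n_c) [s2 - (p_bar(1-p_bar) - s2 (r-1)/r - h_bar/4)/(n_bar-1)]
    b = (n_bar / (n_bar-1)) [p_bar(1-p_bar) - s2 (r-1)/r - h_bar (2n_bar-1)/(4n_bar)]
    c = h_bar / 2

theta is undefined when a + b + c = 0 (e.g. a SNP monomorphic in the pooled
pair); negative values are retained, not truncated, because truncation would
bias the gene means upward.

Gene aggregation averages the defined per-SNP thetas of the SNPs whose
position falls inside the gene interval (1-based inclusive; SNPs in
overlapping genes count in each), drops genes with fewer than ``min_snps``
SNPs, standardizes the gene means to Z scores, and flags candidates at
Z >= 4 and the top 1% of the ranking. A multi-locus ratio-of-sums estimate
sum(a)/sum(a+b+c) is provided both genome-wide and as an optional gene
aggregation mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import ConfigError, DataError
from .variant_io import GeneMap, GenotypeMatrix

R_POPS = 2  # the screen is pairwise


@dataclass(frozen=True)
class WcComponents:
    """Weir–Cockerham intermediates and variance components for one SNP."""

    n_i: tuple[float, float]
    p_i: tuple[float, float]
    h_i: tuple[float, float]
    n_bar: float
    n_c: float
    p_bar: float
    s2: float
    h_bar: float
    a: float
    b: float
    c: float
    theta: float  # NaN when undefined

    @property
    def defined(self) -> bool:
        return not math.isnan(self.theta)


def _pop_summaries(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP (n, p, h) for one population's dosage block (NaN = missing)."""
    called = ~np.isnan(dosage)
    n = called.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore"):
        p = np.nansum(dosage, axis=1) / (2.0 * n)
        h = np.nansum(dosage == 1.0, axis=1) / n
    return n, p, h


def wc_from_summaries(
    n1: np.ndarray, p1: np.ndarray, h1: np.ndarray,
    n2: np.ndarray, p2: np.ndarray, h2: np.ndarray,
) -> pd.DataFrame:
    """Variance components from per-population summaries (n_i, p_i, h_i).

    Accepts scalars or aligned arrays; theta is NaN where a + b + c = 0.
    """
    n1, p1, h1, n2, p2, h2 = (
        np.asarray(x, dtype=float) for x in (n1, p1, h1, n2, p2, h2)
    )
    r = float(R_POPS)
    n_bar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1.0)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        inner = p_bar * (1.0 - p_bar) - s2 * (r - 1.0) / r
        a = (n_bar / n_c) * (s2 - (inner - h_bar / 4.0) / (n_bar - 1.0))
        b = (n_bar / (n_bar - 1.0)) * (
            inner - h_bar * (2.0 * n_bar - 1.0) / (4.0 * n_bar)
        )
        c = h_bar / 2.0
        denom = a + b + c
        theta = np.where(denom != 0.0, a / np.where(denom != 0.0, denom, 1.0), np.nan)
    return pd.DataFrame(
        {
            "n1": np.atleast_1d(n1), "n2": np.atleast_1d(n2),
            "p1": np.atleast_1d(p1), "p2": np.atleast_1d(p2),
            "h1": np.atleast_1d(h1), "h2": np.atleast_1d(h2),
            "n_bar": np.atleast_1d(n_bar), "n_c": np.atleast_1d(n_c),
            "p_bar": np.atleast_1d(p_bar), "s2": np.atleast_1d(s2),
            "h_bar": np.atleast_1d(h_bar), "a": np.atleast_1d(a),
            "b": np.atleast_1d(b), "c": np.atleast_1d(c),
            "theta": np.atleast_1d(theta),
        }
    )


def wc_components_matrix(dosage1: np.ndarray, dosage2: np.ndarray) -> pd.DataFrame:
    """Vectorized Weir–Cockerham components for a SNP x individual pair split.

    Rows where a population has no non-missing call, or where n_bar <= 1,
    yield undefined (NaN) components; so does theta when a + b + c = 0.
    """
    n1, p1, h1 = _pop_summaries(np.atleast_2d(dosage1))
    n2, p2, h2 = _pop_summaries(np.atleast_2d(dosage2))
    out = wc_from_summaries(n1, p1, h1, n2, p2, h2)
    invalid = (n1 == 0) | (n2 == 0) | ((n1 + n2) / 2.0 <= 1.0)
    out.loc[invalid, ["a", "b", "c", "theta"]] = np.nan
    return out


def wc_theta_snp(dosage1: np.ndarray, dosage2: np.ndarray) -> WcComponents:
    """Weir–Cockerham components for a single SNP (scalar interface).

    Raises :class:`DataError` when a population has all calls missing or the
    mean sample size n_bar is <= 1; a defined-denominator SNP returns theta,
    otherwise theta is NaN.
    """
    d1 = np.asarray(dosage1, dtype=float).reshape(1, -1)
    d2 = np.asarray(dosage2, dtype=float).reshape(1, -1)
    if np.all(np.isnan(d1)) or np.all(np.isnan(d2)):
        raise DataError("a population has no non-missing calls at this SNP")
    row = wc_components_matrix(d1, d2).iloc[0]
    if (row["n1"] + row["n2"]) / 2.0 <= 1.0:
        raise DataError("mean sample size n_bar <= 1")
    return WcComponents(
        n_i=(row["n1"], row["n2"]),
        p_i=(row["p1"], row["p2"]),
        h_i=(row["h1"], row["h2"]),
        n_bar=row["n_bar"],
        n_c=row["n_c"],
        p_bar=row["p_bar"],
        s2=row["s2"],
        h_bar=row["h_bar"],
        a=row["a"],
        b=row["b"],
        c=row["c"],
        theta=row["theta"],
    )


def per_snp_fst(gm: GenotypeMatrix, pops: tuple[str, str]) -> pd.DataFrame:
    """Per-SNP components and theta for one population pair.

    Returns the SNP table (contig, pos, id) joined with the component
    columns; undefined thetas are NaN and excluded downstream.
    """
    cols1 = gm.pop_columns(pops[0])
    cols2 = gm.pop_columns(pops[1])
    comp = wc_components_matrix(gm.dosage[:, cols1], gm.dosage[:, cols2])
    return pd.concat(
        [gm.snps[["contig", "pos", "id"]].reset_index(drop=True), comp], axis=1
    )


def multilocus_fst(components: pd.DataFrame) -> float:
    """Ratio-of-sums multi-locus estimate sum(a) / sum(a+b+c)."""
    ok = components[["a", "b", "c"]].dropna()
    denom = float((ok["a"] + ok["b"] + ok["c"]).sum())
    if denom == 0.0:
        raise DataError("all loci have zero total variance")
    return float(ok["a"].sum()) / denom


def _gene_trees(genes: GeneMap) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for row in genes.table.itertuples(index=False):
        # 1-based inclusive [start, end] -> half-open [start, end+1)
        trees.setdefault(str(row.contig), IntervalTree()).addi(
            int(row.start), int(row.end) + 1, row.gene_id
        )
    return trees


def assign_snps_to_genes(snps: pd.DataFrame, genes: GeneMap) -> pd.DataFrame:
    """(snp index, gene_id) pairs for every SNP inside a gene interval.

    A SNP belongs to a gene iff its 1-based position lies in [start, end]
    inclusive on the same contig; SNPs under overlapping genes are paired
    with each of them.
    """
    trees = _gene_trees(genes)
    pairs: list[tuple[int, str]] = []
    contigs = snps["contig"].to_numpy()
    positions = snps["pos"].to_numpy()
    for i in range(len(snps)):
        tree = trees.get(str(contigs[i]))
        if tree is None:
            continue
        for iv in tree.at(int(positions[i])):
            pairs.append((i, iv.data))
    return pd.DataFrame(pairs, columns=["snp_index", "gene_id"])


def aggregate_gene_fst(
    per_snp: pd.DataFrame,
    genes: GeneMap,
    min_snps: int = 3,
    mode: str = "mean",
) -> pd.DataFrame:
    """Aggregate per-SNP theta to gene level.

    Parameters
    ----------
    per_snp : DataFrame
        Output of :func:`per_snp_fst` (needs contig, pos, a, b, c, theta).
    min_snps : int
        Genes with fewer defined-theta SNPs are dropped.
    mode : {"mean", "ratio"}
        "mean" averages per-SNP theta (the conventional gene aggregate);
        "ratio" computes the ratio-of-sums estimate within the gene.

    Returns a table (gene_id, contig, start, end, n_snps, mean_fst).
    """
    if len(genes) == 0:
        raise DataError("gene map is empty")
    if mode not in ("mean", "ratio"):
        raise ConfigError(f"unknown aggregation mode {mode!r}")
    pairs = assign_snps_to_genes(per_snp, genes)
    if pairs.empty:
        return pd.DataFrame(
            columns=["gene_id", "contig", "start", "end", "n_snps", "mean_fst"]
        )
    joined = pairs.join(per_snp[["a", "b", "c", "theta"]], on="snp_index")
    joined = joined.dropna(subset=["theta"])
    grouped = joined.groupby("gene_id")
    n_snps = grouped.size()
    if mode == "mean":
        agg = grouped["theta"].mean()
    else:
        sums = grouped[["a", "b", "c"]].sum()
        agg = sums["a"] / (sums["a"] + sums["b"] + sums["c"])
    out = pd.DataFrame({"n_snps": n_snps, "mean_fst": agg})
    out = out[out["n_snps"] >= min_snps].reset_index()
    out = out.merge(genes.table, on="gene_id", how="left")
    return out[["gene_id", "contig", "start", "end", "n_snps", "mean_fst"]].sort_values(
        "gene_id", kind="mergesort"
    ).reset_index(drop=True)


def z_transform(gene_means: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Standardize gene-level F_ST: Z = (F_ST - mu) / sigma.

    ``mu`` is the mean and ``sigma`` the sample (n-1) standard deviation over
    the gene-level values. Raises on fewer than two genes or sigma = 0.
    """
    vals = np.asarray(gene_means, dtype=float)
    if vals.size < 2:
        raise DataError("Z transform needs at least two genes")
    mu = float(vals.mean())
    sigma = float(vals.std(ddof=1))
    if sigma == 0.0:
        raise DataError("degenerate screen: all gene means equal (sigma = 0)")
    return (vals - mu) / sigma, mu, sigma


def select_candidates(results: pd.DataFrame, z_threshold: float = 4.0) -> pd.DataFrame:
    """Flag genes with z_fst >= z_threshold (boundary inclusive)."""
    out = results.copy()
    out["is_candidate"] = out["z_fst"] >= z_threshold
    return out


def select_top_fraction(results: pd.DataFrame, fraction: float = 0.01) -> pd.DataFrame:
    """Flag the top ``ceil(fraction * n_genes)`` genes by Z score.

    Ranking is by z_fst descending with ties broken by gene_id ascending so
    the boundary is deterministic.
    """
    if not 0.0 < fraction <= 1.0:
        raise ConfigError(f"fraction must lie in (0, 1], got {fraction}")
    out = results.copy()
    k = math.ceil(fraction * len(out))
    ranked = out.sort_values(
        ["z_fst", "gene_id"], ascending=[False, True], kind="mergesort"
    )
    top = set(ranked["gene_id"].head(k))
    out["in_top_fraction"] = out["gene_id"].isin(top)
    return out


def gene_fst_screen(
    gm: GenotypeMatrix,
    genes: GeneMap,
    pops: tuple[str, str],
    min_snps: int = 3,
    z_threshold: float = 4.0,
    top_fraction: float = 0.01,
    mode: str = "mean",
) -> tuple[pd.DataFrame, dict]:
    """Full screen for one comparison: per-SNP theta -> gene table with flags.

    Returns the gene table and a summary dict (mu, sigma, multi-locus
    estimate, counts) for the run manifest.
    """
    per_snp = per_snp_fst(gm, pops)
    gene_tab = aggregate_gene_fst(per_snp, genes, min_snps=min_snps, mode=mode)
    if len(gene_tab) < 2:
        raise DataError("fewer than two genes survived aggregation")
    z, mu, sigma = z_transform(gene_tab["mean_fst"].to_numpy())
    gene_tab["z_fst"] = z
    gene_tab = select_candidates(gene_tab, z_threshold)
    gene_tab = select_top_fraction(gene_tab, top_fraction)
    summary = {
        "comparison": f"{pops[0]}_vs_{pops[1]}",
        "n_snps_defined_theta": int(per_snp["theta"].notna().sum()),
        "n_genes": int(len(gene_tab)),
        "mu_fst": mu,
        "sigma_fst": sigma,
        "multilocus_fst": multilocus_fst(per_snp),
        "n_candidates": int(gene_tab["is_candidate"].sum()),
        "n_top_fraction": int(gene_tab["in_top_fraction"].sum()),
    }
    return gene_tab, summary
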