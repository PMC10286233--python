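"""Population-level allele-specific-expression detection per strain x age group.

Given per-SNP (ref, alt) read counts for the individuals of one group, the
detector asks whether a gene shows consistent allelic imbalance across the
population even though the data are unphased — the direction of the
imbalance is unknown and may differ between individuals.

Procedure per gene and group:

1. Per-SNP-per-sample count filter: minor allele count >= 3 reads, total
   depth >= 30 reads, minor allele ratio >= 1%.
2. Folding: each accepted SNP's counts are replaced by the major count
   m = max(ref, alt) and the depth d = ref + alt, making everything
   label-symmetric (the unphased treatment).
3. Statistic: each individual j gets a pooled major fraction
   p_hat_j = sum_s m_s / sum_s d_s (>= 1/2 by folding) and contributes the
   binomial deviance against the balanced null,
   2 * [sum m ln p_hat_j + sum (d - m) ln(1 - p_hat_j) + sum d ln 2];
   the gene statistic T is the sum over individuals and is nonnegative.
4. Null: read counts are resampled as Binomial(d, 1/2) and folded the same
   way; T* is recomputed. Resampling proceeds in batches with a fixed-hits
   early stop (stop once ``stop_hits`` resampled statistics reach T_obs),
   and the empirical p-value is (1 + k) / (1 + resamples used), valid by
   construction.
5. Benjamini–Hochberg adjustment across the genes of the group.

The statistic deliberately uses only the folded counts; any systematic
reference bias must have been removed upstream (the read counting this
emulates uses an N-masked reference), otherwise the balanced null is wrong.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import xlogy
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DataError
from .synthetic_data import substream

LN2 = math.log(2.0)
_TIE_EPS = 1e-9  # absorb float noise in the T* >= T_obs comparison


@dataclass(frozen=True)
class AseSnpFilterRule:
    """Per-SNP-per-sample acceptance thresholds for allele counts."""

    min_minor_count: int = 3
    min_total: int = 30
    min_minor_ratio: float = 0.01

    def __post_init__(self) -> None:
        if self.min_minor_count <= 0 or self.min_total <= 0 or self.min_minor_ratio <= 0:
            raise ConfigError("ASE filter thresholds must be positive")


def filter_ase_snp(
    ref_reads: np.ndarray, alt_reads: np.ndarray, rule: AseSnpFilterRule | None = None
) -> np.ndarray:
    """Vectorized accept flags for per-sample SNP counts.

    Accept iff min(ref, alt) >= min_minor_count AND ref + alt >= min_total
    AND min(ref, alt) / (ref + alt) >= min_minor_ratio.
    """
    rule = rule or AseSnpFilterRule()
    ref = np.asarray(ref_reads)
    alt = np.asarray(alt_reads)
    if (ref < 0).any() or (alt < 0).any():
        raise DataError("negative read counts")
    minor = np.minimum(ref, alt)
    total = ref + alt
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 0, minor / total, 0.0)
    return (minor >= rule.min_minor_count) & (total >= rule.min_total) & (
        ratio >= rule.min_minor_ratio
    )


def fold_counts(ref_reads: np.ndarray, alt_reads: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fold (ref, alt) to (major count m, depth d); m >= d/2 by construction."""
    ref = np.asarray(ref_reads)
    alt = np.asarray(alt_reads)
    return np.maximum(ref, alt), ref + alt


def _deviance_from_sums(sum_m: np.ndarray, sum_d: np.ndarray) -> np.ndarray:
    """Per-individual deviance from pooled folded sums (vectorized, safe at p=1)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        p_hat = np.where(sum_d > 0, sum_m / np.maximum(sum_d, 1), 0.5)
    return 2.0 * (
        xlogy(sum_m, p_hat) + xlogy(sum_d - sum_m, 1.0 - p_hat) + sum_d * LN2
    )


def ase_statistic(m: np.ndarray, d: np.ndarray, individual_idx: np.ndarray) -> float:
    """Gene statistic T for one group: summed per-individual folded deviance.

    Parameters
    ----------
    m, d : arrays over accepted (individual, SNP) cells
        Folded major counts and depths.
    individual_idx : int array
        Index of the individual owning each cell (0..J-1).
    """
    m = np.asarray(m, dtype=float)
    d = np.asarray(d, dtype=float)
    if m.size == 0:
        raise DataError("no accepted SNPs for this gene/group")
    j = np.asarray(individual_idx)
    n_ind = int(j.max()) + 1
    sum_m = np.bincount(j, weights=m, minlength=n_ind)
    sum_d = np.bincount(j, weights=d, minlength=n_ind)
    t = float(_deviance_from_sums(sum_m, sum_d).sum())
    return max(t, 0.0)


@dataclass(frozen=True)
class AseGeneResult:
    """Resampling-test outcome for one gene in one (strain, week) group."""

    gene_id: str
    strain: str
    week: int
    n_individuals_used: int
    n_snps_used: int
    statistic_T: float
    resamples_used: int
    p_empirical: float


def ase_test(
    m: np.ndarray,
    d: np.ndarray,
    individual_idx: np.ndarray,
    rng: np.random.Generator,
    r_max: int = 10_000,
    batch: int = 1_000,
    stop_hits: int = 50,
) -> tuple[float, int, float]:
    """Adaptive resampling p-value for one gene/group.

    Null resamples redraw each accepted cell as Binomial(d, 1/2), fold, and
    recompute T; batches of ``batch`` resamples are consumed until
    ``stop_hits`` exceedances (T* >= T_obs) accumulate or ``r_max`` resamples
    are spent. Returns (T_obs, resamples_used, p) with
    p = (1 + hits) / (1 + resamples_used).
    """
    if r_max < batch:
        raise ConfigError("r_max must be at least one batch")
    t_obs = ase_statistic(m, d, individual_idx)
    d_arr = np.asarray(d, dtype=np.int64)
    j = np.asarray(individual_idx)
    n_ind = int(j.max()) + 1
    onehot = np.zeros((d_arr.size, n_ind))
    onehot[np.arange(d_arr.size), j] = 1.0
    sum_d = d_arr.astype(float) @ onehot

    used = 0
    hits = 0
    while used < r_max and hits < stop_hits:
        b = min(batch, r_max - used)
        x = rng.binomial(d_arr, 0.5, size=(b, d_arr.size))
        m_star = np.maximum(x, d_arr - x).astype(float)
        sum_m = m_star @ onehot
        t_star = _deviance_from_sums(sum_m, sum_d[None, :]).sum(axis=1)
        hits += int((t_star >= t_obs - _TIE_EPS).sum())
        used += b
    p = (1.0 + hits) / (1.0 + used)
    return t_obs, used, min(p, 1.0)


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values (monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise DataError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def detect_ase(
    counts: pd.DataFrame,
    rule: AseSnpFilterRule | None = None,
    r_max: int = 10_000,
    batch: int = 1_000,
    stop_hits: int = 50,
    seed: int = 0,
    alpha: float = 0.05,
    alpha_strict: float = 0.01,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Run the full ASE scan over every (strain, week, gene) in a count table.

    ``counts`` follows the schema of :data:`divase.variant_io.ASE_COLUMNS`.
    Each gene/group gets its own RNG substream derived from ``seed`` so the
    p-values do not depend on evaluation order. Genes with no accepted SNP
    in a group are skipped (not rows in the output). Benjamini–Hochberg
    q-values are computed within each (strain, week) group.

    Output columns: gene_id, strain, week, n_individuals_used, n_snps_used,
    statistic_T, resamples_used, p_empirical, q_bh, significant_05,
    significant_01. significant_05 means p < alpha; significant_01 means
    p < alpha_strict with q_bh < fdr.
    """
    rule = rule or AseSnpFilterRule()
    accept = filter_ase_snp(
        counts["ref_reads"].to_numpy(), counts["alt_reads"].to_numpy(), rule
    )
    kept = counts.loc[accept].copy()
    m, d = fold_counts(kept["ref_reads"].to_numpy(), kept["alt_reads"].to_numpy())
    kept["m"] = m
    kept["d"] = d

    results: list[AseGeneResult] = []
    for (strain, week, gene_id), sub in kept.groupby(
        ["strain", "week", "gene_id"], sort=True
    ):
        # canonical cell order so the resampling stream is independent of
        # input row order
        sub = sub.sort_values(["individual", "contig", "pos"], kind="mergesort")
        codes, uniques = pd.factorize(sub["individual"], sort=True)
        rng = substream(seed, "ase_test", strain, week, gene_id)
        t_obs, used, p = ase_test(
            sub["m"].to_numpy(),
            sub["d"].to_numpy(),
            codes,
            rng,
            r_max=r_max,
            batch=batch,
            stop_hits=stop_hits,
        )
        results.append(
            AseGeneResult(
                gene_id=str(gene_id),
                strain=str(strain),
                week=int(week),
                n_individuals_used=len(uniques),
                n_snps_used=int(sub["pos"].nunique()),
                statistic_T=t_obs,
                resamples_used=used,
                p_empirical=p,
            )
        )
    if not results:
        return pd.DataFrame(
            columns=[
                "gene_id", "strain", "week", "n_individuals_used", "n_snps_used",
                "statistic_T", "resamples_used", "p_empirical", "q_bh",
                "significant_05", "significant_01",
            ]
        )
    out = pd.DataFrame([vars(r) for r in results])
    out["q_bh"] = np.nan
    for _, idx in out.groupby(["strain", "week"]).groups.items():
        out.loc[idx, "q_bh"] = bh_adjust(out.loc[idx, "p_empirical"].to_numpy())
    out["significant_05"] = out["p_empirical"] < alpha
    out["significant_01"] = (out["p_empirical"] < alpha_strict) & (out["q_bh"] < fdr)
    return out.sort_values(["strain", "week", "gene_id"], kind="mergesort").reset_index(
        drop=True
    )
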