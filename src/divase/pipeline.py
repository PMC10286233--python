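"""Orchestration: configuration, the two workflows, and the reporting layer.

The reporting layer reproduces the bookkeeping of the study design this
package targets: per-(strain, week) counts of ASE genes, strain-specific
sets (significant in one strain and not the other at the same week),
genes shared across all five weeks within a strain and across both strains,
and the intersection of strain-specific ASE genes with the top-1% Z(F_ST)
set. Per-strain "specific totals" follow the row-sum convention (the sum of
the five per-week counts, so genes recurring at several weeks count each
time); a distinct-gene count is emitted alongside.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import ase_detect, fst_scan, qtl_coloc, snp_filter, synthetic_data, variant_io
from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Thresholds, comparisons and simulation settings for one full run.

    Exactly one input mode is supported per run: a synthetic-simulation
    block (the default) or paths to real inputs (VCF + gene map + BED +
    ASE counts).
    """

    seed: int = 0
    out_dir: str = "results/run"
    comparisons: tuple[tuple[str, str], ...] = (
        ("LB", "LSL"), ("LB", "BR"), ("LSL", "BR"),
    )
    min_rate: float = 0.80
    min_maf: float = 0.05
    min_snps: int = 3
    z_threshold: float = 4.0
    top_fraction: float = 0.01
    agg_mode: str = "mean"
    ase_r_max: int = 10_000
    ase_batch: int = 1_000
    ase_stop_hits: int = 50
    alpha: float = 0.05
    alpha_strict: float = 0.01
    # synthetic block (used when input paths are absent)
    cohort: dict = field(default_factory=dict)
    ase: dict = field(default_factory=dict)
    n_qtl_regions: int = 200
    qtl_mean_length: float = 200_000.0
    # real-input block
    vcf_path: str | None = None
    gene_map_path: str | None = None
    qtl_bed_path: str | None = None
    ase_counts_path: str | None = None
    populations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        paths = [self.vcf_path, self.gene_map_path, self.ase_counts_path]
        if any(paths) and not all(paths[:2]):
            raise ConfigError("real-input mode needs vcf_path and gene_map_path")
        for name, lo, hi in (
            ("min_rate", 0.0, 1.0),
            ("top_fraction", 0.0, 1.0),
            ("alpha", 0.0, 1.0),
            ("alpha_strict", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not lo < v <= hi:
                raise ConfigError(f"{name} must lie in ({lo}, {hi}], got {v}")
        if not 0.0 <= self.min_maf < 0.5:
            raise ConfigError("min_maf must lie in [0, 0.5)")
        if self.min_snps < 1:
            raise ConfigError("min_snps must be >= 1")

    @property
    def synthetic(self) -> bool:
        return self.vcf_path is None

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            known = {f.name for f in dataclasses.fields(cls)}
            unknown = set(raw) - known
            if unknown:
                raise ConfigError(f"unknown config keys: {sorted(unknown)}")
            if "comparisons" in raw:
                raw["comparisons"] = tuple(tuple(c) for c in raw["comparisons"])
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path: str) -> None:
        data = dataclasses.asdict(self)
        data["comparisons"] = [list(c) for c in self.comparisons]
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _load_inputs(cfg: RunConfig):
    """Simulate or read the four inputs, honoring the config's mode."""
    if cfg.synthetic:
        sim = synthetic_data.CohortSimConfig(seed=cfg.seed, **cfg.cohort)
        gm, gene_map, truth = synthetic_data.simulate_cohort(sim)
        layout = {str(i): 2_000_000 for i in range(1, sim.n_autosomes + 1)}
        regions = synthetic_data.simulate_qtl_regions(
            layout, cfg.n_qtl_regions, mean_length=cfg.qtl_mean_length, seed=cfg.seed
        )
        ase_cfg = synthetic_data.AseSimConfig(seed=cfg.seed, **cfg.ase)
        ase_counts, ase_truth = synthetic_data.simulate_ase_counts(gene_map, ase_cfg)
        return gm, gene_map, regions, ase_counts, truth
    gm = variant_io.read_vcf(cfg.vcf_path, cfg.populations or None)
    gene_map = variant_io.read_gene_map(cfg.gene_map_path)
    regions = variant_io.read_bed(cfg.qtl_bed_path) if cfg.qtl_bed_path else []
    ase_counts = (
        variant_io.read_ase_counts(cfg.ase_counts_path)
        if cfg.ase_counts_path
        else pd.DataFrame(columns=variant_io.ASE_COLUMNS)
    )
    return gm, gene_map, regions, ase_counts, None


def run_fst_workflow(cfg: RunConfig, out_dir: Path | None = None) -> dict:
    """Filters -> per-SNP theta -> gene screen -> QTL colocalization.

    Executes every configured comparison, writes the gene tables, filter
    ledgers and colocalization tables under ``out_dir`` and returns the run
    manifest (thresholds, seed, per-comparison counts).
    """
    out = Path(out_dir or cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gm, gene_map, regions, _, truth = _load_inputs(cfg)
    manifest: dict = {
        "seed": cfg.seed,
        "thresholds": {
            "min_rate": cfg.min_rate, "min_maf": cfg.min_maf,
            "min_snps": cfg.min_snps, "z_threshold": cfg.z_threshold,
            "top_fraction": cfg.top_fraction,
        },
        "comparisons": {},
    }
    present = set(gm.populations)
    for pops in cfg.comparisons:
        if not set(pops) <= present:
            raise DataError(f"comparison {pops} references unknown population")
        name = f"{pops[0]}_vs_{pops[1]}"
        try:
            filtered, ledger = snp_filter.apply_filters(
                gm, pops, min_rate=cfg.min_rate, min_maf=cfg.min_maf
            )
            gene_tab, summary = fst_scan.gene_fst_screen(
                filtered, gene_map, pops,
                min_snps=cfg.min_snps, z_threshold=cfg.z_threshold,
                top_fraction=cfg.top_fraction, mode=cfg.agg_mode,
            )
            per_snp = fst_scan.per_snp_fst(filtered, pops)
            cand_genes = set(gene_tab.loc[gene_tab["is_candidate"], "gene_id"])
            pairs = fst_scan.assign_snps_to_genes(per_snp, gene_map)
            cand_pairs = pairs[pairs["gene_id"].isin(cand_genes)]
            cand_snps = per_snp.loc[cand_pairs["snp_index"], ["contig", "pos"]]
            cand_snps = cand_snps.assign(
                gene_id=cand_pairs["gene_id"].to_numpy()
            ).reset_index(drop=True)
            coloc = qtl_coloc.overlap_snps_regions(cand_snps, regions, comparison=name)
            coloc_summary = qtl_coloc.summarize_by_category(coloc)
        except DataError as exc:
            raise DataError(f"[{name}] {exc}") from exc
        variant_io.write_table(ledger.to_frame(), out / f"ledger_{name}.tsv")
        variant_io.write_table(gene_tab, out / f"gene_fst_{name}.tsv", ["gene_id"])
        variant_io.write_table(
            coloc, out / f"coloc_{name}.tsv", ["gene_id", "contig", "pos", "qtl_id"]
        )
        variant_io.write_table(
            coloc_summary, out / f"coloc_summary_{name}.tsv", ["comparison", "category"]
        )
        manifest["comparisons"][name] = {
            "ledger": dataclasses.asdict(ledger), **summary
        }
        if truth is not None:
            planted = set(truth.gene_truth.loc[truth.gene_truth["is_divergent"], "gene_id"])
            top = set(gene_tab.loc[gene_tab["in_top_fraction"], "gene_id"])
            manifest["comparisons"][name]["planted_in_top_fraction"] = len(planted & top)
            manifest["comparisons"][name]["planted_total"] = len(planted)
    return manifest


def classify_membership(
    ase_results: pd.DataFrame,
    strains: tuple[str, str] = ("LB", "LSL"),
    weeks: tuple[int, ...] = synthetic_data.DEFAULT_WEEKS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene significance flags and derived membership labels.

    Returns one row per gene with a boolean column ``sig_{strain}_{week}``
    per cell, per-cell specific flags ``specific_{strain}_{week}`` (significant
    in that strain and not the other at the same week), per-strain
    ``common_across_weeks_{strain}`` and the joint ``common_both_strains``.
    Raises when a (strain, week) group is entirely absent from the results.
    """
    have = set(map(tuple, ase_results[["strain", "week"]].drop_duplicates().to_numpy()))
    for s in strains:
        for w in weeks:
            if (s, w) not in have:
                raise DataError(f"missing ASE results for group ({s}, week {w})")
    sig = ase_results["p_empirical"] < alpha
    pivot = (
        ase_results.assign(sig=sig)
        .pivot_table(index="gene_id", columns=["strain", "week"], values="sig",
                     aggfunc="any", fill_value=False)
        .astype(bool)
    )
    out = pd.DataFrame(index=pivot.index)
    for s in strains:
        for w in weeks:
            out[f"sig_{s}_{w}"] = pivot.get((s, w), False)
    s1, s2 = strains
    for w in weeks:
        out[f"specific_{s1}_{w}"] = out[f"sig_{s1}_{w}"] & ~out[f"sig_{s2}_{w}"]
        out[f"specific_{s2}_{w}"] = out[f"sig_{s2}_{w}"] & ~out[f"sig_{s1}_{w}"]
    for s in strains:
        out[f"common_across_weeks_{s}"] = pd.concat(
            [out[f"sig_{s}_{w}"] for w in weeks], axis=1
        ).all(axis=1)
    out["common_both_strains"] = (
        out[f"common_across_weeks_{s1}"] & out[f"common_across_weeks_{s2}"]
    )
    return out.reset_index()


def membership_summary(
    membership: pd.DataFrame,
    strains: tuple[str, str] = ("LB", "LSL"),
    weeks: tuple[int, ...] = synthetic_data.DEFAULT_WEEKS,
) -> pd.DataFrame:
    """Accounting table: ASE and strain-specific gene counts per cell.

    The per-strain specific total is the row sum of the five per-week
    specific counts (a gene specific at several weeks counts once per week);
    ``n_distinct`` counts each gene once.
    """
    rows = []
    for s in strains:
        sig_counts = {w: int(membership[f"sig_{s}_{w}"].sum()) for w in weeks}
        spec_counts = {w: int(membership[f"specific_{s}_{w}"].sum()) for w in weeks}
        spec_any = membership[[f"specific_{s}_{w}" for w in weeks]].any(axis=1)
        sig_any = membership[[f"sig_{s}_{w}" for w in weeks]].any(axis=1)
        rows.append(
            {
                "strain": s,
                **{f"ase_w{w}": sig_counts[w] for w in weeks},
                "ase_distinct": int(sig_any.sum()),
                **{f"specific_w{w}": spec_counts[w] for w in weeks},
                "specific_total": sum(spec_counts.values()),
                "specific_distinct": int(spec_any.sum()),
                "common_across_weeks": int(membership[f"common_across_weeks_{s}"].sum()),
            }
        )
    summary = pd.DataFrame(rows)
    summary["common_both_strains"] = int(membership["common_both_strains"].sum())
    # row-sum convention must hold by construction
    for row in summary.itertuples(index=False):
        assert row.specific_total == sum(
            getattr(row, f"specific_w{w}") for w in weeks
        )
    return summary


def fst_ase_overlap(
    membership: pd.DataFrame,
    top_fraction_genes: set[str],
    strains: tuple[str, str] = ("LB", "LSL"),
    weeks: tuple[int, ...] = synthetic_data.DEFAULT_WEEKS,
) -> pd.DataFrame:
    """Overlap of per-cell strain-specific ASE genes with the top-1% F_ST set.

    One row per (strain, week) with the intersection size ``k``, the specific
    count ``n`` and the printed-style ratio "k/n".
    """
    rows = []
    genes = membership.set_index("gene_id")
    for s in strains:
        for w in weeks:
            specific = set(genes.index[genes[f"specific_{s}_{w}"]])
            k = len(specific & top_fraction_genes)
            rows.append(
                {"strain": s, "week": w, "overlap": k, "specific": len(specific),
                 "ratio": f"{k}/{len(specific)}"}
            )
    return pd.DataFrame(rows)


def run_all(cfg: RunConfig) -> dict:
    """Full pipeline: F_ST workflow + ASE scan + membership/overlap reports.

    Writes every table plus ``manifest.json`` under ``cfg.out_dir``; one seed
    reproduces the whole output tree byte for byte.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = run_fst_workflow(cfg, out)
    _, gene_map, _, ase_counts, _ = _load_inputs(cfg)

    ase_results = ase_detect.detect_ase(
        ase_counts,
        r_max=cfg.ase_r_max, batch=cfg.ase_batch, stop_hits=cfg.ase_stop_hits,
        seed=cfg.seed, alpha=cfg.alpha, alpha_strict=cfg.alpha_strict,
    )
    variant_io.write_table(
        ase_results, out / "ase_results.tsv", ["strain", "week", "gene_id"]
    )
    strains = tuple(dict.fromkeys(s for s, _ in _ase_groups(cfg, ase_counts)))[:2]
    weeks = tuple(sorted(ase_counts["week"].unique())) if len(ase_counts) else ()
    if len(strains) == 2 and weeks:
        membership = classify_membership(
            ase_results, strains=strains, weeks=weeks, alpha=cfg.alpha
        )
        summary = membership_summary(membership, strains=strains, weeks=weeks)
        first = f"{cfg.comparisons[0][0]}_vs_{cfg.comparisons[0][1]}"
        gene_tab = pd.read_csv(out / f"gene_fst_{first}.tsv", sep="\t")
        top = set(gene_tab.loc[gene_tab["in_top_fraction"], "gene_id"])
        overlap = fst_ase_overlap(membership, top, strains=strains, weeks=weeks)
        variant_io.write_table(membership, out / "ase_membership.tsv", ["gene_id"])
        variant_io.write_table(summary, out / "ase_summary.tsv", ["strain"])
        variant_io.write_table(overlap, out / "fst_ase_overlap.tsv", ["strain", "week"])
        manifest["ase"] = {
            "n_tests": int(len(ase_results)),
            "n_significant_05": int(ase_results["significant_05"].sum()),
            "n_significant_01": int(ase_results["significant_01"].sum()),
            "specific_totals": {
                r["strain"]: int(r["specific_total"])
                for _, r in summary.iterrows()
            },
        }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _ase_groups(cfg: RunConfig, ase_counts: pd.DataFrame):
    if len(ase_counts) == 0:
        return []
    return list(map(tuple, ase_counts[["strain", "week"]].drop_duplicates().to_numpy()))
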