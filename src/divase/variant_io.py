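"""Readers and writers for the standard formats the pipeline touches.

In-memory model
---------------
``GenotypeMatrix``
    Biallelic SNP sites x diploid individuals, stored as an alt-allele dosage
    matrix (0/1/2, NaN = missing call) plus per-individual population labels.
``GeneMap``
    Gene intervals, 1-based inclusive, unique gene ids.
``QtlRegion``
    QTL intervals, 0-based half-open (BED convention), labelled with one of
    the six layer/broiler trait categories.

Coordinate conventions are owned by exactly two functions,
:func:`vcf_to_bed_pos` and :func:`bed_to_vcf_pos`; everything else calls them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .errors import DataError

logger = logging.getLogger(__name__)

#: The closed set of QTL trait categories considered in the colocalization layer.
QTL_CATEGORIES = (
    "egg production",
    "egg quality",
    "fat content",
    "growth",
    "meat quality",
    "feeding",
)

MISSING = np.nan


def vcf_to_bed_pos(pos: int) -> int:
    """Map a 1-based VCF position to its 0-based BED coordinate."""
    return pos - 1


def bed_to_vcf_pos(coord: int) -> int:
    """Map a 0-based BED coordinate back to a 1-based VCF position."""
    return coord + 1


@dataclass
class GenotypeMatrix:
    """Diploid genotype dosages for biallelic SNPs across labelled populations.

    Attributes
    ----------
    snps : pandas.DataFrame
        One row per SNP with columns ``contig, pos, id, ref, alt``
        (``pos`` 1-based).
    dosage : numpy.ndarray, shape (n_snps, n_individuals)
        Alt-allele dosage per call: 0.0, 1.0, 2.0 or NaN for missing.
    individuals : list of str
    populations : numpy.ndarray of str, one label per individual
    """

    snps: pd.DataFrame
    dosage: np.ndarray
    individuals: list[str]
    populations: np.ndarray

    def __post_init__(self) -> None:
        if self.dosage.shape != (len(self.snps), len(self.individuals)):
            raise DataError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.snps)} SNPs x {len(self.individuals)} individuals"
            )
        if len(self.populations) != len(self.individuals):
            raise DataError("every individual needs a population label")

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def pop_columns(self, population: str) -> np.ndarray:
        """Column indices of the individuals belonging to ``population``."""
        idx = np.flatnonzero(self.populations == population)
        if idx.size == 0:
            raise DataError(f"population {population!r} not present")
        return idx

    def subset_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        """New matrix keeping the SNP rows where ``mask`` is True."""
        return GenotypeMatrix(
            snps=self.snps.loc[mask].reset_index(drop=True),
            dosage=self.dosage[np.asarray(mask)],
            individuals=list(self.individuals),
            populations=self.populations,
        )


@dataclass
class GeneMap:
    """Gene intervals with 1-based inclusive coordinates and unique ids."""

    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["gene_id", "contig", "start", "end"]
        )
    )

    def __post_init__(self) -> None:
        t = self.table
        if len(t) and (t["start"] > t["end"]).any():
            bad = t.index[t["start"] > t["end"]][0]
            raise DataError(f"gene map row {bad}: start > end")
        if t["gene_id"].duplicated().any():
            dup = t.loc[t["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise DataError(f"duplicate gene_id {dup!r}")

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class QtlRegion:
    """A QTL interval in BED coordinates (0-based, half-open)."""

    contig: str
    start: int
    end: int
    category: str
    source_id: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise DataError(
                f"QTL {self.source_id}: empty interval [{self.start},{self.end})"
            )
        if self.category not in QTL_CATEGORIES:
            raise DataError(f"QTL {self.source_id}: unknown category {self.category!r}")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_GT_CODE = {0: 0.0, 1: 1.0, 3: 2.0, 2: MISSING}  # cyvcf2 gt_types


def read_vcf(path: str, populations: dict[str, str] | None = None) -> GenotypeMatrix:
    """Read a GT-only VCF into a :class:`GenotypeMatrix`.

    Multiallelic records and indels (REF or ALT length != 1) are skipped with
    a logged count. Phased separators are accepted and treated as unphased;
    half-missing calls are treated as missing.

    Parameters
    ----------
    path : str
        Uncompressed or bgzipped VCF v4.x file.
    populations : dict, optional
        Sample name -> population label. Samples absent from the mapping get
        the label ``"?"``.
    """
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # malformed header
        raise DataError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise DataError(f"{path}: VCF has no sample columns")
    rows, dosages = [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        rows.append((str(var.CHROM), int(var.POS), var.ID or ".", var.REF, var.ALT[0]))
        dosages.append([_GT_CODE[g] for g in var.gt_types])
    vcf.close()
    if n_skipped:
        logger.info("read_vcf: skipped %d multiallelic/indel records", n_skipped)
    snps = pd.DataFrame(rows, columns=["contig", "pos", "id", "ref", "alt"])
    pops = np.array([(populations or {}).get(s, "?") for s in samples], dtype=object)
    dosage = (
        np.array(dosages, dtype=float)
        if dosages
        else np.empty((0, len(samples)), dtype=float)
    )
    gm = GenotypeMatrix(snps=snps, dosage=dosage, individuals=samples, populations=pops)
    gm.n_skipped_records = n_skipped  # type: ignore[attr-defined]
    return gm


def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Write a :class:`GenotypeMatrix` as a minimal VCF v4.2 (GT-only)."""
    code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        contigs = pd.unique(gm.snps["contig"])
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.individuals)
            + "\n"
        )
        for i, snp in enumerate(gm.snps.itertuples(index=False)):
            gts = "\t".join(
                code.get(d, "./.") if not np.isnan(d) else "./."
                for d in gm.dosage[i]
            )
            fh.write(
                f"{snp.contig}\t{snp.pos}\t{snp.id}\t{snp.ref}\t{snp.alt}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# BED (QTL regions)
# ---------------------------------------------------------------------------

def _normalize_category(name: str) -> str | None:
    key = name.strip().lower().replace("_", " ")
    return key if key in QTL_CATEGORIES else None


def read_bed(path: str, categories: tuple[str, ...] = QTL_CATEGORIES) -> list[QtlRegion]:
    """Read QTL regions from a BED file (>= 4 columns: contig start end name).

    Coordinates are kept 0-based half-open. Rows whose name column does not
    map (case-insensitively) to a known trait category are dropped with a
    logged count, as are empty intervals.
    """
    regions: list[QtlRegion] = []
    n_dropped = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(f"{path}:{lineno}: fewer than 3 BED columns")
            contig, start_s, end_s = parts[0], parts[1], parts[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                n_dropped += 1
                logger.info("read_bed: %s:%d empty interval dropped", path, lineno)
                continue
            name = parts[3] if len(parts) > 3 else ""
            cat = _normalize_category(name)
            if cat is None or cat not in categories:
                n_dropped += 1
                continue
            source_id = parts[6] if len(parts) > 6 else f"{path}:{lineno}"
            regions.append(QtlRegion(contig, start, end, cat, source_id))
    if n_dropped:
        logger.info("read_bed: dropped %d rows (unknown category or empty)", n_dropped)
    return regions


def write_bed(regions: list[QtlRegion], path: str) -> None:
    """Write QTL regions as BED6 (name = category, score 0, strand '.')."""
    with open(path, "w", encoding="utf-8") as fh:
        for r in regions:
            fh.write(f"{r.contig}\t{r.start}\t{r.end}\t{r.category}\t0\t.\t{r.source_id}\n")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def read_gene_map(path: str) -> GeneMap:
    """Read the gene map TSV (gene_id, contig, start, end; 1-based inclusive)."""
    table = pd.read_csv(path, sep="\t", dtype={"contig": str})
    required = {"gene_id", "contig", "start", "end"}
    missing = required - set(table.columns)
    if missing:
        raise DataError(f"{path}: gene map missing columns {sorted(missing)}")
    if table.empty:
        logger.warning("read_gene_map: %s is empty", path)
    return GeneMap(table.reset_index(drop=True))


def write_gene_map(gene_map: GeneMap, path: str) -> None:
    gene_map.table.sort_values("gene_id").to_csv(path, sep="\t", index=False)


ASE_COLUMNS = [
    "individual",
    "strain",
    "week",
    "gene_id",
    "contig",
    "pos",
    "ref_reads",
    "alt_reads",
]


def read_ase_counts(path: str) -> pd.DataFrame:
    """Read the per-SNP allele-count TSV used by the ASE layer.

    Schema: individual, strain, week, gene_id, contig, pos, ref_reads,
    alt_reads. Negative read counts are rejected with the offending row
    number.
    """
    table = pd.read_csv(path, sep="\t", dtype={"contig": str, "strain": str})
    missing = set(ASE_COLUMNS) - set(table.columns)
    if missing:
        raise DataError(f"{path}: ASE table missing columns {sorted(missing)}")
    neg = (table["ref_reads"] < 0) | (table["alt_reads"] < 0)
    if neg.any():
        row = int(table.index[neg][0]) + 2  # +1 header, +1 1-based
        raise DataError(f"{path}: negative read count at line {row}")
    return table


def write_table(table: pd.DataFrame, path: str, sort_by: list[str] | None = None) -> None:
    """Write a results table as deterministic, UTF-8, tab-separated text.

    Rows are sorted by ``sort_by`` (default: all columns, left to right) so
    repeated runs produce byte-identical files; floats use a fixed 10
    significant-digit format.
    """
    out = table.sort_values(sort_by or list(table.columns), kind="mergesort")
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")
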