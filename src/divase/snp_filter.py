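"""SNP retention rules with a complete accounting ledger.

The screen keeps, in order: SNPs called in at least ``min_rate`` of all
individuals, autosomal SNPs, and SNPs whose minor allele frequency in the
two populations of the comparison (pooled) is at least ``min_maf``. The
pooled-MAF rule subsumes monomorphic sites. Each stage reports how many SNPs
it removed; the :class:`FilterLedger` enforces exact integer conservation
(input = removed + retained).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .variant_io import GenotypeMatrix

logger = logging.getLogger(__name__)

#: Chicken autosomes: GRCg6a has autosomes 1..33 plus the Z/W sex chromosomes.
DEFAULT_AUTOSOMES = frozenset(str(i) for i in range(1, 34))


@dataclass(frozen=True)
class FilterLedger:
    """Integer accounting of one filtering pass.

    Invariant: ``total_input - removed_call_rate - removed_nonautosomal -
    removed_monomorphic_or_low_maf == retained``; checked at construction.
    """

    total_input: int
    removed_call_rate: int
    removed_nonautosomal: int
    removed_monomorphic_or_low_maf: int
    retained: int

    def __post_init__(self) -> None:
        counts = (
            self.total_input,
            self.removed_call_rate,
            self.removed_nonautosomal,
            self.removed_monomorphic_or_low_maf,
            self.retained,
        )
        if any(c < 0 for c in counts):
            raise DataError("ledger counts must be nonnegative")
        expected = (
            self.total_input
            - self.removed_call_rate
            - self.removed_nonautosomal
            - self.removed_monomorphic_or_low_maf
        )
        if expected != self.retained:
            raise DataError(
                f"ledger does not balance: {self.total_input} - "
                f"{self.removed_call_rate} - {self.removed_nonautosomal} - "
                f"{self.removed_monomorphic_or_low_maf} != {self.retained}"
            )

    @classmethod
    def from_removals(
        cls, total_input: int, call_rate: int, nonautosomal: int, maf: int
    ) -> "FilterLedger":
        """Build a balanced ledger from the per-stage removal counts."""
        return cls(
            total_input=total_input,
            removed_call_rate=call_rate,
            removed_nonautosomal=nonautosomal,
            removed_monomorphic_or_low_maf=maf,
            retained=total_input - call_rate - nonautosomal - maf,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def filter_call_rate(
    gm: GenotypeMatrix, min_rate: float = 0.80
) -> tuple[GenotypeMatrix, int]:
    """Keep SNPs whose fraction of non-missing calls is >= ``min_rate``.

    The rate is computed across all individuals regardless of population;
    the boundary is inclusive (exactly ``min_rate`` is kept). Floating
    comparison uses a half-call margin so 80/100 calls pass at 0.80 exactly.
    """
    if not 0.0 < min_rate <= 1.0:
        raise ConfigError(f"min_rate must lie in (0, 1], got {min_rate}")
    n_called = np.sum(~np.isnan(gm.dosage), axis=1)
    keep = n_called + 0.5 >= min_rate * gm.n_individuals
    removed = int((~keep).sum())
    return gm.subset_snps(keep), removed


def filter_autosomal(
    gm: GenotypeMatrix, autosomes: frozenset[str] = DEFAULT_AUTOSOMES
) -> tuple[GenotypeMatrix, int]:
    """Remove SNPs on contigs outside the autosome set (e.g. Z, W, MT)."""
    if not autosomes:
        raise ConfigError("autosome set must be non-empty")
    keep = gm.snps["contig"].isin(autosomes).to_numpy()
    removed = int((~keep).sum())
    return gm.subset_snps(keep), removed


def filter_maf(
    gm: GenotypeMatrix, pops: tuple[str, str], min_maf: float = 0.05
) -> tuple[GenotypeMatrix, int]:
    """Remove SNPs with pooled minor allele frequency below ``min_maf``.

    The alt-allele frequency is computed from non-missing dosages pooled over
    the two populations of the comparison; ``min(freq, 1-freq) < min_maf``
    removes the SNP. Monomorphic SNPs (freq 0 or 1) and SNPs with no
    non-missing call in the pooled pair are removed and counted here. The
    boundary is inclusive: MAF exactly ``min_maf`` is kept (tested with a
    margin of half a chromosome count to absorb float division).
    """
    if not 0.0 <= min_maf < 0.5:
        raise ConfigError(f"min_maf must lie in [0, 0.5), got {min_maf}")
    cols = np.concatenate([gm.pop_columns(pops[0]), gm.pop_columns(pops[1])])
    sub = gm.dosage[:, cols]
    n_called = np.sum(~np.isnan(sub), axis=1)
    alt = np.nansum(sub, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = alt / (2.0 * n_called)
    minor = np.minimum(freq, 1.0 - freq)
    # keep iff minor count >= min_maf * chromosomes, inclusive at the boundary
    keep = (n_called > 0) & (minor * 2.0 * n_called + 0.5 >= min_maf * 2.0 * n_called)
    keep &= minor > 0
    removed = int((~keep).sum())
    return gm.subset_snps(keep), removed


def apply_filters(
    gm: GenotypeMatrix,
    pops: tuple[str, str],
    min_rate: float = 0.80,
    autosomes: frozenset[str] = DEFAULT_AUTOSOMES,
    min_maf: float = 0.05,
) -> tuple[GenotypeMatrix, FilterLedger]:
    """Run the full retention sequence call-rate -> autosome -> MAF."""
    total = gm.n_snps
    gm1, n_rate = filter_call_rate(gm, min_rate)
    gm2, n_auto = filter_autosomal(gm1, autosomes)
    gm3, n_maf = filter_maf(gm2, pops, min_maf)
    ledger = FilterLedger.from_removals(total, n_rate, n_auto, n_maf)
    logger.info(
        "snp_filter %s vs %s: %d -> %d (call-rate -%d, nonautosomal -%d, "
        "monomorphic/low-MAF -%d)",
        pops[0], pops[1], total, ledger.retained, n_rate, n_auto, n_maf,
    )
    return gm3, ledger
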