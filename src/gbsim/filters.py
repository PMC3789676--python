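"""Per-call masking and per-site retention filters for genotype tables.

Two criteria sets are used at different stages of the pipeline:

* ``FilterCriteria`` — the map-building set: homozygous calls need depth
  >= 1 and GQ >= 3, heterozygous calls depth >= 3 and GQ >= 5 (low-quality
  calls are set to missing, not removed); sites are kept with at most 90%
  missing calls, minor allele frequency >= 5% and fewer than 10%
  heterozygous calls.  The loose thresholds suit a nearly homozygous RIL
  population whose true MAF is ~50%.
* ``ComparisonCriteria`` — the stricter set used before cross-dataset
  comparison: missing fraction <= 50% and MAF >= 30%.

MAF is computed over non-missing calls with heterozygotes contributing half
an allele to each side; the het-fraction cut is strict (<).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from gbsim.config import ConfigurationError
from gbsim.tables import (GT_HET, GT_HOM_ALT, GT_HOM_REF, GT_MISSING,
                          GenotypeTable)


@dataclass(frozen=True)
class FilterCriteria:
    min_depth_hom: int = 1
    min_depth_het: int = 3
    min_gq_hom: int = 3
    min_gq_het: int = 5
    max_missing_frac: float = 0.90
    min_maf: float = 0.05
    max_het_frac: float | None = 0.10

    def __post_init__(self) -> None:
        for f in (self.max_missing_frac, self.min_maf):
            if not (0.0 <= f <= 1.0):
                raise ConfigurationError("fractions must lie in [0, 1]")
        if self.min_depth_het < self.min_depth_hom or \
                self.min_gq_het < self.min_gq_hom:
            raise ConfigurationError(
                "het thresholds must be at least the hom thresholds")


@dataclass(frozen=True)
class ComparisonCriteria:
    max_missing_frac: float = 0.50
    min_maf: float = 0.30
    max_het_frac: float | None = None

    def __post_init__(self) -> None:
        for f in (self.max_missing_frac, self.min_maf):
            if not (0.0 <= f <= 1.0):
                raise ConfigurationError("fractions must lie in [0, 1]")


def mask_low_confidence(table: GenotypeTable,
                        c: FilterCriteria) -> GenotypeTable:
    """Set calls failing their genotype-class depth/GQ threshold to missing.

    Site and sample dimensions are unchanged; the operation is idempotent.
    """
    out = table.copy()
    het = out.gt == GT_HET
    hom = (out.gt == GT_HOM_REF) | (out.gt == GT_HOM_ALT)
    bad = (het & ((out.dp < c.min_depth_het) | (out.gq < c.min_gq_het))) | \
          (hom & ((out.dp < c.min_depth_hom) | (out.gq < c.min_gq_hom)))
    out.gt[bad] = GT_MISSING
    return out


def site_statistics(table: GenotypeTable) -> pd.DataFrame:
    """Per-site missing fraction, minor allele frequency and het fraction.

    MAF and het fraction are NaN where every call is missing.
    """
    gt = table.gt
    n_samples = gt.shape[1]
    missing = (gt == GT_MISSING).sum(axis=1)
    present = n_samples - missing
    het = (gt == GT_HET).sum(axis=1)
    hom_alt = (gt == GT_HOM_ALT).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = (hom_alt + 0.5 * het) / present
        maf = np.minimum(alt_freq, 1.0 - alt_freq)
        het_frac = het / present
    maf = np.where(present == 0, np.nan, maf)
    het_frac = np.where(present == 0, np.nan, het_frac)
    return pd.DataFrame({
        "missing_frac": missing / n_samples,
        "maf": maf,
        "het_frac": het_frac,
    })


def filter_sites(table: GenotypeTable, criteria) -> GenotypeTable:
    """Retain sites passing missing-data, MAF and (optionally) het cuts.

    Sites where every call is missing have undefined MAF and are removed.
    Site order is preserved.
    """
    stats = site_statistics(table)
    keep = (stats["missing_frac"].to_numpy() <= criteria.max_missing_frac)
    maf = stats["maf"].to_numpy()
    keep &= ~np.isnan(maf)
    keep &= np.nan_to_num(maf) >= criteria.min_maf
    max_het = getattr(criteria, "max_het_frac", None)
    if max_het is not None:
        keep &= np.nan_to_num(stats["het_frac"].to_numpy()) < max_het
    return table.subset_sites(keep)
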