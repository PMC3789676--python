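"""Core in-memory containers passed between pipeline stages.

Two matrix conventions are used throughout:

* ``GenotypeTable`` holds diploid calls relative to a site's ref/alt alleles:
  0 = hom-ref, 1 = het, 2 = hom-alt, -1 = missing.
* ``MarkerMatrix`` holds parentally encoded calls for map construction:
  0 = parent A, 1 = parent B, 2 = heterozygous, -1 = missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

# GenotypeTable call codes
GT_HOM_REF = 0
GT_HET = 1
GT_HOM_ALT = 2
GT_MISSING = -1

# MarkerMatrix / RIL call codes
CODE_A = 0
CODE_B = 1
CODE_H = 2
CODE_MISSING = -1

ABH_CHARS = {CODE_A: "A", CODE_B: "B", CODE_H: "H", CODE_MISSING: "-"}
ABH_CODES = {v: k for k, v in ABH_CHARS.items()}


@dataclass
class GenotypeTable:
    """Per-site, per-sample genotype calls with depth and quality.

    ``sites`` is a DataFrame with columns ``contig``, ``pos`` (0-based),
    ``ref`` and ``alt``; ``gt``/``dp``/``gq`` are (n_sites, n_samples)
    arrays.
    """

    sites: pd.DataFrame
    samples: list[str]
    gt: np.ndarray
    dp: np.ndarray
    gq: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        n_sites = len(self.sites)
        n_samp = len(self.samples)
        for name in ("gt", "dp", "gq"):
            arr = getattr(self, name)
            if arr.shape != (n_sites, n_samp):
                raise ValueError(
                    f"{name} shape {arr.shape} != ({n_sites}, {n_samp})")
        keys = list(zip(self.sites["contig"], self.sites["pos"]))
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (contig, pos) site keys")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_keys(self) -> list[tuple[str, int]]:
        return list(zip(self.sites["contig"], self.sites["pos"]))

    def copy(self) -> "GenotypeTable":
        return GenotypeTable(self.sites.copy(), list(self.samples),
                             self.gt.copy(), self.dp.copy(), self.gq.copy(),
                             self.provenance)

    def subset_sites(self, mask: np.ndarray) -> "GenotypeTable":
        return GenotypeTable(self.sites.loc[mask].reset_index(drop=True),
                             list(self.samples), self.gt[mask],
                             self.dp[mask], self.gq[mask], self.provenance)

    def subset_samples(self, names: list[str]) -> "GenotypeTable":
        idx = [self.samples.index(s) for s in names]
        return GenotypeTable(self.sites.copy(), list(names),
                             self.gt[:, idx], self.dp[:, idx],
                             self.gq[:, idx], self.provenance)


@dataclass
class MarkerMatrix:
    """Markers x individuals matrix of parentally encoded calls (A/B/H)."""

    ids: np.ndarray           # marker identifiers (str)
    calls: np.ndarray         # int8 (n_markers, n_individuals)
    samples: list[str]
    contig: np.ndarray | None = None   # originating contig per marker
    pos: np.ndarray | None = None      # 0-based position on the contig

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        if self.calls.shape != (len(self.ids), len(self.samples)):
            raise ValueError("calls shape does not match ids x samples")

    @property
    def n_markers(self) -> int:
        return len(self.ids)

    def subset(self, index: np.ndarray) -> "MarkerMatrix":
        return MarkerMatrix(
            self.ids[index], self.calls[index], list(self.samples),
            None if self.contig is None else np.asarray(self.contig)[index],
            None if self.pos is None else np.asarray(self.pos)[index],
        )
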