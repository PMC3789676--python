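"""Simulated reference genome with anchored contigs, and parental variants.

The reference plays the role of a whole-genome shotgun assembly of the
first parent: at every variant locus the reference base equals the parent-A
allele and the second parent carries the alternative allele.  Chromosomes
are tiled into fixed-length contigs, each carrying a genetic (cM) anchor
obtained by linearly scaling physical position to the chromosome's map
length — the "reference framework" against which de novo maps are compared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from gbsim.config import ConfigurationError, SimConfig
from gbsim.seqs import BASES, find_sites, random_sequence


@dataclass(frozen=True)
class Contig:
    contig_id: str
    chrom: str
    start: int        # 0-based, half-open
    end: int
    cM: float


@dataclass
class ReferenceGenome:
    """Chromosome sequences plus anchored contig intervals."""

    chromosomes: dict[str, str]
    contigs: list[Contig]

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[Contig]] = {}
        for c in self.contigs:
            if c.chrom not in self.chromosomes:
                raise ConfigurationError(f"contig {c.contig_id} on unknown "
                                         f"chromosome {c.chrom}")
            if not (0 <= c.start < c.end <= len(self.chromosomes[c.chrom])):
                raise ConfigurationError(
                    f"contig {c.contig_id} outside chromosome bounds")
            by_chrom.setdefault(c.chrom, []).append(c)
        for cs in by_chrom.values():
            cs.sort(key=lambda c: c.start)
            for a, b in zip(cs, cs[1:]):
                if a.end > b.start:
                    raise ConfigurationError("overlapping contigs")
                if a.cM > b.cM:
                    raise ConfigurationError("cM positions must be "
                                             "non-decreasing along chromosome")

    def contig_sequence(self, contig_id: str) -> str:
        c = self.contig_by_id(contig_id)
        return self.chromosomes[c.chrom][c.start:c.end]

    def contig_by_id(self, contig_id: str) -> Contig:
        for c in self.contigs:
            if c.contig_id == contig_id:
                return c
        raise KeyError(contig_id)

    def contig_map(self) -> dict[str, Contig]:
        return {c.contig_id: c for c in self.contigs}

    def anchor_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c.contig_id, c.chrom, c.start, c.end, c.cM)
             for c in self.contigs],
            columns=["contig_id", "chrom", "start", "end", "cM"])


@dataclass
class ParentalVariants:
    """Biallelic loci distinguishing the two inbred parents.

    ``loci`` has columns ``chrom``, ``pos`` (0-based), ``allele_a``
    (= reference base) and ``allele_b``.
    """

    loci: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.loci):
            dup = self.loci.duplicated(subset=["chrom", "pos"]).any()
            if dup:
                raise ConfigurationError("duplicate variant positions")
            if (self.loci["allele_a"] == self.loci["allele_b"]).any():
                raise ConfigurationError("parental alleles must differ")

    def __len__(self) -> int:
        return len(self.loci)

    def by_chrom(self) -> dict[str, pd.DataFrame]:
        return {str(c): g.sort_values("pos").reset_index(drop=True)
                for c, g in self.loci.groupby("chrom")}


def _recognition_site_mask(seq: str, motifs: list[str]) -> np.ndarray:
    """Boolean mask over positions lying inside any recognition-site hit."""
    mask = np.zeros(len(seq), dtype=bool)
    for motif in motifs:
        for start in find_sites(seq, motif):
            mask[start:start + len(motif)] = True
    return mask


def simulate_reference(
    config: SimConfig, rng: np.random.Generator | None = None,
) -> tuple[ReferenceGenome, ParentalVariants]:
    """Draw a random genome, anchored contig frame and parental SNP set.

    Bases are i.i.d. uniform; SNP loci are Bernoulli(``snp_density``) per
    position, excluding positions inside PstI/MspI recognition sites so that
    both parents share all fragment boundaries.  The parent-B allele at each
    locus is drawn uniformly from the three non-reference bases.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    motifs = [config.enzyme_rare.recognition,
              config.enzyme_frequent.recognition]

    chromosomes: dict[str, str] = {}
    contigs: list[Contig] = []
    rows: list[tuple[str, int, str, str]] = []
    for ci in range(config.n_chromosomes):
        name = f"chr{ci + 1}"
        seq = random_sequence(config.chrom_length_bp, rng)
        chromosomes[name] = seq
        length = len(seq)
        for j, start in enumerate(range(0, length, config.contig_length_bp)):
            end = min(start + config.contig_length_bp, length)
            cm = config.map_length_cM * start / length
            contigs.append(Contig(f"{name}_ctg{j:04d}", name, start, end, cm))
        if config.snp_density > 0:
            hit = rng.random(length) < config.snp_density
            hit &= ~_recognition_site_mask(seq, motifs)
            positions = np.nonzero(hit)[0]
            for pos in positions:
                ref = seq[pos]
                others = [b for b in BASES if b != ref]
                alt = others[rng.integers(0, 3)]
                rows.append((name, int(pos), ref, alt))
    loci = pd.DataFrame(rows, columns=["chrom", "pos", "allele_a", "allele_b"])
    return ReferenceGenome(chromosomes, contigs), ParentalVariants(loci)
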