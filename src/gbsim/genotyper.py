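"""Read placement and genotype calling.

Placement is exact-k-mer seed-and-extend: a read is seeded with its first
non-ambiguous k-mer (both strands tried), extended without gaps against the
contig, and accepted only when the mismatch fraction over the compared
bases is below threshold and the placement is unique.  There is no gapped
alignment; indel-rich reads simply fail to place, which lowers the
placement rate rather than producing shifted calls.

Genotypes are called per site and sample from the counts of the two site
alleles with a binomial likelihood model: with per-base error rate ``e``
and counts (n_r, n_a),

    L(hom_ref) = (1-e)^n_r * e^n_a
    L(hom_alt) = e^n_r * (1-e)^n_a
    L(het)     = 0.5^(n_r + n_a)

The posterior over the three genotypes (default uniform prior; an optional
RIL-informed prior down-weights hets) gives the call and a Phred-scaled
genotype quality GQ = -10*log10(1 - max posterior), capped at 99.

A second, tag-based calling path mirrors reference-free pipelines that
collapse reads to fixed-length tags before alignment: reads are truncated
to ``tag_length``, collapsed to unique tags with per-sample counts, placed
like reads, and SNPs are found between co-placed tags; the tag-relative SNP
offset is converted to contig coordinates by adding the placement offset
(the degenerate, ungapped CIGAR case).
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from gbsim.config import ConfigurationError
from gbsim.seqs import decode, encode, revcomp
from gbsim.sim.reads import FastqRead
from gbsim.sim.reference import ReferenceGenome
from gbsim.tables import (GT_HET, GT_HOM_ALT, GT_HOM_REF, GT_MISSING,
                          GenotypeTable)

UNIFORM_PRIOR = (1 / 3, 1 / 3, 1 / 3)
#: Prior reflecting the ~1-2% residual heterozygosity of an inbred RIL
#: population (hom-ref, het, hom-alt).
RIL_PRIOR = (0.49, 0.02, 0.49)


@dataclass(frozen=True)
class Placement:
    contig: str
    offset: int          # 0-based start of the (clipped) read on the contig
    strand: str          # "+" or "-"
    n_mismatches: int
    n_compared: int
    read_clip: int = 0   # bases of the oriented read clipped on the left


class KmerIndex:
    """Exact k-mer -> (contig, offset) lookup over all contigs.

    K-mers occurring at more than one position are flagged ambiguous and
    never used as seeds.
    """

    def __init__(self, ref: ReferenceGenome, k: int = 21) -> None:
        if k < 11:
            raise ConfigurationError("k must be >= 11")
        self.k = k
        self.contig_names: list[str] = []
        self.contig_seqs: dict[str, str] = {}
        self._lookup: dict[str, tuple[str, int] | None] = {}
        for contig in ref.contigs:
            seq = ref.chromosomes[contig.chrom][contig.start:contig.end]
            self.contig_names.append(contig.contig_id)
            self.contig_seqs[contig.contig_id] = seq
            for i in range(len(seq) - k + 1):
                kmer = seq[i:i + k]
                if kmer in self._lookup:
                    self._lookup[kmer] = None
                else:
                    self._lookup[kmer] = (contig.contig_id, i)

    def get(self, kmer: str) -> tuple[str, int] | None:
        return self._lookup.get(kmer)

    def is_ambiguous(self, kmer: str) -> bool:
        return kmer in self._lookup and self._lookup[kmer] is None

    def ambiguous_fraction(self) -> float:
        n_amb = sum(1 for v in self._lookup.values() if v is None)
        return n_amb / max(1, len(self._lookup))


def build_index(ref: ReferenceGenome, k: int = 21) -> KmerIndex:
    return KmerIndex(ref, k)


def _extend(seq: str, contig_seq: str, offset: int) -> tuple[int, int, int]:
    """Ungapped comparison of ``seq`` against the contig at ``offset``.

    Returns (clipped offset, mismatches, compared length); the read may
    overhang the contig on either side, only the overlap is compared.
    """
    start = max(0, offset)
    end = min(len(contig_seq), offset + len(seq))
    if end <= start:
        return start, 0, 0
    sub_read = seq[start - offset:end - offset]
    sub_ref = contig_seq[start:end]
    mism = sum(1 for a, b in zip(sub_read, sub_ref) if a != b)
    return start, mism, end - start


def place_read(
    seq: str, index: KmerIndex, max_mismatch_frac: float = 0.1,
) -> Placement | None:
    """Seed-and-extend placement; None when unplaced or ambiguous."""
    k = index.k
    if len(seq) < k:
        return None
    candidates: list[Placement] = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for i in range(len(s) - k + 1):
            kmer = s[i:i + k]
            hit = index.get(kmer)
            if hit is None:
                # ambiguous k-mers and k-mers hit by sequencing errors are
                # both skipped; the next offset may still seed
                continue
            contig, pos = hit
            offset = pos - i
            cseq = index.contig_seqs[contig]
            start, mism, compared = _extend(s, cseq, offset)
            if compared >= k and mism / compared <= max_mismatch_frac:
                candidates.append(
                    Placement(contig, start, strand, mism, compared,
                              read_clip=start - offset))
            break  # one seed per strand
    if not candidates:
        return None
    distinct = {(p.contig, p.offset, p.strand) for p in candidates}
    if len(distinct) > 1:
        return None  # ambiguous across strands
    return candidates[0]


def call_genotype(
    n_ref: int, n_alt: int, error_rate: float,
    prior: tuple[float, float, float] = UNIFORM_PRIOR,
) -> tuple[int, int]:
    """Posterior genotype and GQ from allele counts; missing at depth 0."""
    if not (0.0 < error_rate < 0.5):
        raise ConfigurationError("error_rate must lie in (0, 0.5)")
    depth = n_ref + n_alt
    if depth == 0:
        return GT_MISSING, 0
    log_e = math.log(error_rate)
    log_1e = math.log1p(-error_rate)
    ll = np.array([
        n_ref * log_1e + n_alt * log_e,
        depth * math.log(0.5),
        n_ref * log_e + n_alt * log_1e,
    ])
    ll += np.log(prior)
    ll -= ll.max()
    post = np.exp(ll)
    post /= post.sum()
    g = int(np.argmax(post))
    p_err = 1.0 - post[g]
    if p_err < 1e-10:
        gq = 99
    else:
        gq = min(99, int(round(-10 * math.log10(p_err))))
    genotype = (GT_HOM_REF, GT_HET, GT_HOM_ALT)[g]
    return genotype, gq


def _accumulate_counts(
    sample_reads: Mapping[str, Sequence[FastqRead]],
    index: KmerIndex,
    max_mismatch_frac: float,
) -> dict[str, np.ndarray]:
    """Per-contig base-count arrays of shape (n_samples, contig_len, 4)."""
    samples = list(sample_reads)
    counts: dict[str, np.ndarray] = {}
    buffers: dict[str, list[tuple[np.ndarray, np.ndarray, np.ndarray]]] = \
        defaultdict(list)
    for si, sample in enumerate(samples):
        for read in sample_reads[sample]:
            p = place_read(read.seq, index, max_mismatch_frac)
            if p is None:
                continue
            s = read.seq if p.strand == "+" else revcomp(read.seq)
            aligned = s[p.read_clip:p.read_clip + p.n_compared]
            codes = encode(aligned)
            positions = np.arange(p.offset, p.offset + p.n_compared)
            buffers[p.contig].append(
                (np.full(p.n_compared, si), positions, codes))
    for contig, items in buffers.items():
        arr = np.zeros((len(samples), len(index.contig_seqs[contig]), 4),
                       dtype=np.int32)
        sidx = np.concatenate([it[0] for it in items])
        pos = np.concatenate([it[1] for it in items])
        base = np.concatenate([it[2] for it in items])
        ok = base < 4
        np.add.at(arr, (sidx[ok], pos[ok], base[ok]), 1)
        counts[contig] = arr
    return counts


def pileup_and_call(
    sample_reads: Mapping[str, Sequence[FastqRead]],
    index: KmerIndex,
    error_rate: float = 0.01,
    prior: tuple[float, float, float] = UNIFORM_PRIOR,
    max_mismatch_frac: float = 0.1,
    max_third_allele_frac: float = 0.1,
    provenance: str = "",
) -> GenotypeTable:
    """Place all reads, pile up bases and call genotypes at variant sites.

    A site is emitted where at least one non-reference base is observed.
    The site alleles are the reference base and the most frequent
    non-reference base; sites where a third allele exceeds
    ``max_third_allele_frac`` of total depth (with count >= 2) are dropped
    as putatively multi-allelic or repetitive.
    """
    samples = list(sample_reads)
    counts = _accumulate_counts(sample_reads, index, max_mismatch_frac)

    rows = []
    gt_rows, dp_rows, gq_rows = [], [], []
    for contig in sorted(counts):
        arr = counts[contig]
        cseq = index.contig_seqs[contig]
        ref_codes = encode(cseq)
        total = arr.sum(axis=0)                        # (L, 4)
        depth = total.sum(axis=1)
        ref_count = total[np.arange(len(cseq)), ref_codes]
        cand = np.nonzero(depth > ref_count)[0]
        for pos in cand:
            by_allele = total[pos].copy()
            ref_code = ref_codes[pos]
            nonref = by_allele.copy()
            nonref[ref_code] = -1
            alt_code = int(np.argmax(nonref))
            other = int(depth[pos] - by_allele[ref_code]
                        - by_allele[alt_code])
            if other >= 2 and other / depth[pos] > max_third_allele_frac:
                continue
            gts, dps, gqs = [], [], []
            for si in range(len(samples)):
                n_r = int(arr[si, pos, ref_code])
                n_a = int(arr[si, pos, alt_code])
                g, q = call_genotype(n_r, n_a, error_rate, prior)
                gts.append(g)
                dps.append(n_r + n_a)
                gqs.append(q)
            rows.append((contig, int(pos), decode(np.array([ref_code])),
                         decode(np.array([alt_code]))))
            gt_rows.append(gts)
            dp_rows.append(dps)
            gq_rows.append(gqs)
    sites = pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt"])
    shape = (len(rows), len(samples))
    return GenotypeTable(
        sites, samples,
        np.array(gt_rows, dtype=np.int8).reshape(shape),
        np.array(dp_rows, dtype=np.int32).reshape(shape),
        np.array(gq_rows, dtype=np.int16).reshape(shape),
        provenance=provenance,
    )


def tag_based_call(
    sample_reads: Mapping[str, Sequence[FastqRead]],
    index: KmerIndex,
    tag_length: int = 64,
    error_rate: float = 0.01,
    prior: tuple[float, float, float] = UNIFORM_PRIOR,
    max_mismatch_frac: float = 0.1,
    provenance: str = "tags",
) -> GenotypeTable:
    """Collapse reads to fixed-length tags and call SNPs between tags.

    Reads shorter than ``tag_length`` are dropped; only uniquely placed
    tags contribute.  Within each group of tags sharing a placement,
    biallelic variant columns become sites; per-sample allele counts are
    the summed tag counts.
    """
    if tag_length < index.k:
        raise ConfigurationError("tag_length must be >= index k")
    samples = list(sample_reads)
    tag_counts: dict[str, np.ndarray] = defaultdict(
        lambda: np.zeros(len(samples), dtype=np.int64))
    for si, sample in enumerate(samples):
        for read in sample_reads[sample]:
            if len(read.seq) < tag_length:
                continue
            tag_counts[read.seq[:tag_length]][si] += 1

    groups: dict[tuple[str, int, str], list[tuple[str, np.ndarray]]] = \
        defaultdict(list)
    for tag, cnts in tag_counts.items():
        p = place_read(tag, index, max_mismatch_frac)
        if p is None:
            continue
        oriented = tag if p.strand == "+" else revcomp(tag)
        groups[(p.contig, p.offset, p.strand)].append((oriented, cnts))

    # per-site accumulated (ref_counts, alt_counts) keyed by coordinate
    site_alleles: dict[tuple[str, int], tuple[str, str]] = {}
    site_counts: dict[tuple[str, int], np.ndarray] = {}
    for (contig, offset, _strand), members in groups.items():
        cseq = index.contig_seqs[contig]
        usable = min(len(cseq) - offset, *(len(t) for t, _ in members))
        mat = np.stack([encode(t[:usable]) for t, _ in members])
        weights = np.stack([c for _, c in members])       # (n_tags, n_samp)
        ref_codes = encode(cseq[offset:offset + usable])
        for col in range(usable):
            col_bases = mat[:, col]
            uniq = np.unique(col_bases)
            if len(uniq) < 2:
                continue
            if len(uniq) > 2:
                continue
            ref_code = ref_codes[col]
            if ref_code not in uniq:
                continue
            alt_code = int(uniq[uniq != ref_code][0])
            key = (contig, offset + col)
            alleles = (decode(np.array([ref_code])),
                       decode(np.array([alt_code])))
            if key in site_alleles and site_alleles[key] != alleles:
                # conflicting allele pairs from overlapping groups
                site_counts.pop(key, None)
                site_alleles[key] = ("!", "!")
                continue
            if site_alleles.get(key) == ("!", "!"):
                continue
            site_alleles[key] = alleles
            acc = site_counts.setdefault(key,
                                         np.zeros((2, len(samples)),
                                                  dtype=np.int64))
            acc[0] += weights[col_bases == ref_code].sum(axis=0)
            acc[1] += weights[col_bases == alt_code].sum(axis=0)

    rows, gt_rows, dp_rows, gq_rows = [], [], [], []
    for key in sorted(site_counts):
        contig, pos = key
        ref, alt = site_alleles[key]
        acc = site_counts[key]
        gts, dps, gqs = [], [], []
        for si in range(len(samples)):
            g, q = call_genotype(int(acc[0, si]), int(acc[1, si]),
                                 error_rate, prior)
            gts.append(g)
            dps.append(int(acc[0, si] + acc[1, si]))
            gqs.append(q)
        rows.append((contig, pos, ref, alt))
        gt_rows.append(gts)
        dp_rows.append(dps)
        gq_rows.append(gqs)
    sites = pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt"])
    shape = (len(rows), len(samples))
    return GenotypeTable(
        sites, samples,
        np.array(gt_rows, dtype=np.int8).reshape(shape),
        np.array(dp_rows, dtype=np.int32).reshape(shape),
        np.array(gq_rows, dtype=np.int16).reshape(shape),
        provenance=provenance,
    )
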