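"""Barcoded sequencing reads from amplifiable fragments.

Every read models the sequenced strand of an amplified PstI-MspI fragment,
read from the PstI end:

    barcode + spacer + TGCAG... genomic ... [+ reverse adapter if read-through]

The leading ``TGCAG`` is the filled-in PstI overhang plus first post-cut
base and is genomic sequence, so it is retained after demultiplexing.  For a
fragment whose *left* end is the PstI cut the read follows the top strand
(and also carries the filled MspI overhang ``CG`` at its far end); for a
*right* PstI end it is the reverse complement of the fragment.

Platform error models:

* ``illumina`` — fixed-length reads, i.i.d. substitutions at
  ``sub_error_rate`` per base.
* ``ion`` — variable-length reads (truncated normal) with, per homopolymer
  run, a one-unit insertion or deletion at ``hp_indel_rate``, plus
  substitutions.

Quality strings are flat Phred+33 encodings of the configured substitution
rate; the caller consumes depth and allele counts, not per-base quality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import groupby

import numpy as np

from gbsim.config import ConfigurationError, SimConfig
from gbsim.seqs import BASES, revcomp
from gbsim.sim.digest import Fragment
from gbsim.sim.population import RILGenotypes
from gbsim.sim.reference import ReferenceGenome
from gbsim.tables import CODE_A, CODE_B, CODE_H


@dataclass
class FastqRead:
    id: str
    seq: str
    qual: str

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError("sequence and quality lengths differ")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ReadTruth:
    """Hidden provenance of a simulated read, for evaluation only."""

    sample: str
    chrom: str
    start: int          # genomic span of the error-free read template
    end: int
    strand: str         # "+" or "-"
    fragment_index: int


@dataclass
class ReadSet:
    reads: list[FastqRead]
    truth: list[ReadTruth] | None = None

    def __len__(self) -> int:
        return len(self.reads)


def generate_barcodes(
    samples: list[str], length: int, rng: np.random.Generator,
) -> dict[str, str]:
    """Distinct fixed-length barcodes, one per sample."""
    barcodes: dict[str, str] = {}
    seen: set[str] = set()
    for sample in samples:
        while True:
            bc = "".join(BASES[i] for i in rng.integers(0, 4, size=length))
            if bc not in seen:
                break
        seen.add(bc)
        barcodes[sample] = bc
    return barcodes


def _phred_char(error_rate: float) -> str:
    q = 40 if error_rate <= 0 else min(40, round(-10 * math.log10(error_rate)))
    return chr(33 + q)


def _apply_substitutions(seq: str, rate: float,
                         rng: np.random.Generator) -> str:
    if rate <= 0 or not seq:
        return seq
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    if len(hits) == 0:
        return seq
    chars = list(seq)
    for i in hits:
        alternatives = [b for b in BASES if b != chars[i]]
        chars[i] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def _apply_homopolymer_indels(seq: str, rate: float,
                              rng: np.random.Generator) -> str:
    """Per homopolymer run, insert or delete one unit with probability ``rate``."""
    if rate <= 0:
        return seq
    parts = []
    for base, run in groupby(seq):
        n = len(list(run))
        if rng.random() < rate:
            if n == 1 or rng.random() < 0.5:
                n += 1
            else:
                n -= 1
        parts.append(base * n)
    return "".join(parts)


def _fragment_layout(frag: Fragment, rare_name: str) -> tuple[int, int, str]:
    """Genomic span and strand of the read template for one fragment.

    Forward reads (left end PstI) include the four overhang bases upstream
    of the cut and the two filled frequent-cutter overhang bases downstream;
    reverse reads cover exactly the fragment on the bottom strand.
    """
    if frag.left_end == rare_name:
        return frag.start - 4, frag.end + 2, "+"
    if frag.right_end == rare_name:
        return frag.start, frag.end, "-"
    raise ConfigurationError("fragment has no rare-cutter end; "
                             "run select_amplifiable first")


def generate_reads(
    ref: ReferenceGenome,
    fragments: list[Fragment],
    genotypes: RILGenotypes,
    barcodes: dict[str, str],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> ReadSet:
    """Simulate a multiplexed FASTQ pool for all samples in ``barcodes``.

    Per-sample read totals are lognormal (uneven pooling); fragments are
    sampled uniformly.  At heterozygous loci each read samples one allele
    with probability 0.5 — the mechanism by which shallow coverage turns
    true hets into homozygous calls downstream.
    """
    if len(set(barcodes.values())) != len(barcodes):
        raise ConfigurationError("duplicate barcodes")
    for bc in barcodes.values():
        if len(bc) != config.barcode_length:
            raise ConfigurationError("barcode length mismatch")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed + 2)

    rare = config.enzyme_rare.name
    layouts = [(_fragment_layout(f, rare), f) for f in fragments]

    # variant lookup per chromosome: sorted positions and parent-B alleles
    per_chrom = genotypes.loci.groupby("chrom").indices
    sample_index = {s: i for i, s in enumerate(genotypes.samples)}
    var_pos: dict[str, np.ndarray] = {}
    var_row: dict[str, np.ndarray] = {}
    for chrom, idx in per_chrom.items():
        pos = genotypes.loci["pos"].to_numpy()[idx]
        order = np.argsort(pos)
        var_pos[chrom] = pos[order]
        var_row[chrom] = np.asarray(idx)[order]
    # allele_b is carried on the loci frame (attached when the population is
    # simulated from ParentalVariants); without it the parent-B base at a
    # locus is unknown and reads cannot be synthesised.
    if "allele_b" not in genotypes.loci.columns:
        raise ConfigurationError(
            "genotypes.loci must carry an allele_b column for read "
            "simulation (attach it from ParentalVariants)")
    allele_b_all = genotypes.loci["allele_b"].to_numpy()

    median, sigma = config.per_sample_depth_params
    qchar = _phred_char(config.sub_error_rate)
    reads: list[FastqRead] = []
    truth: list[ReadTruth] = []
    counter = 0

    for sample, barcode in barcodes.items():
        if sample not in sample_index:
            raise ConfigurationError(f"no genotypes for sample {sample!r}")
        si = sample_index[sample]
        n_reads = int(round(rng.lognormal(math.log(median), sigma)))
        frag_choice = rng.integers(0, len(layouts), size=n_reads)
        for fi in frag_choice:
            (gstart, gend, strand), frag = layouts[fi]
            chrom_seq = ref.chromosomes[frag.chrom]
            gstart_c = max(0, gstart)
            gend_c = min(len(chrom_seq), gend)
            template = chrom_seq[gstart_c:gend_c]

            # substitute this individual's alleles (forward coordinates)
            pos_arr = var_pos.get(frag.chrom)
            if pos_arr is not None and len(pos_arr):
                lo = np.searchsorted(pos_arr, gstart_c)
                hi = np.searchsorted(pos_arr, gend_c)
                if hi > lo:
                    chars = list(template)
                    for k in range(lo, hi):
                        row = var_row[frag.chrom][k]
                        call = genotypes.calls[row, si]
                        if call == CODE_A:
                            continue
                        if call == CODE_H and rng.random() < 0.5:
                            continue
                        if call in (CODE_B, CODE_H):
                            chars[pos_arr[k] - gstart_c] = allele_b_all[row]
                    template = "".join(chars)
            if strand == "-":
                template = revcomp(template)

            full = barcode + config.spacer + template + config.reverse_adapter
            if config.platform == "ion":
                full = _apply_homopolymer_indels(full, config.hp_indel_rate,
                                                 rng)
                full = _apply_substitutions(full, config.sub_error_rate, rng)
                length = int(round(rng.normal(config.ion_length_mean,
                                              config.ion_length_sd)))
                length = max(config.ion_length_min, length)
                seq = full[:length]
            else:
                seq = full[:config.read_length_bp]
                if len(seq) < config.read_length_bp:
                    pad = config.read_length_bp - len(seq)
                    seq += "".join(BASES[i]
                                   for i in rng.integers(0, 4, size=pad))
                seq = _apply_substitutions(seq, config.sub_error_rate, rng)

            counter += 1
            reads.append(FastqRead(f"read{counter:08d}", seq,
                                   qchar * len(seq)))
            truth.append(ReadTruth(sample, frag.chrom, gstart_c, gend_c,
                                   strand, int(fi)))
    return ReadSet(reads, truth)
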