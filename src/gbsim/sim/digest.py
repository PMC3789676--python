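"""In-silico restriction digestion and fragment selection.

Co-digestion with a rare cutter (PstI, CTGCA^G) and a frequent cutter
(MspI, C^CGG) partitions each chromosome into fragments whose ends are
labelled by the enzyme that produced them (or ``chrom_end``).  Only
fragments with one PstI and one MspI end carry the barcoded forward adapter
and the Y-adapter on opposite ends and therefore amplify; MspI-MspI
fragments carry the Y-adapter on both ends and lack a priming site, and
PstI-PstI fragments lack the reverse site.
"""

from __future__ import annotations

from dataclasses import dataclass

from gbsim.config import Enzyme, InputError, SimConfig
from gbsim.seqs import find_sites
from gbsim.sim.reference import ReferenceGenome

CHROM_END = "chrom_end"


@dataclass(frozen=True)
class Fragment:
    chrom: str
    start: int          # 0-based half-open, post-cut boundaries
    end: int
    left_end: str       # enzyme name or "chrom_end"
    right_end: str

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def end_types(self) -> frozenset:
        return frozenset((self.left_end, self.right_end))


def digest_sequence(
    seq: str, chrom: str, enzymes: tuple[Enzyme, ...],
) -> list[Fragment]:
    """Cut one chromosome sequence; fragments partition it exactly."""
    if set(seq) - set("ACGT"):
        bad = sorted(set(seq) - set("ACGT"))
        raise InputError(f"sequence contains non-ACGT characters: {bad}")
    cuts: list[tuple[int, str]] = []
    for enz in enzymes:
        for start in find_sites(seq, enz.recognition):
            cuts.append((start + enz.cut_offset, enz.name))
    cuts.sort()
    fragments = []
    prev_pos, prev_label = 0, CHROM_END
    for pos, label in cuts:
        fragments.append(Fragment(chrom, prev_pos, pos, prev_label, label))
        prev_pos, prev_label = pos, label
    fragments.append(Fragment(chrom, prev_pos, len(seq), prev_label,
                              CHROM_END))
    return fragments


def digest_and_classify(
    ref: ReferenceGenome, config: SimConfig,
    haplotype: dict[str, str] | None = None,
) -> list[Fragment]:
    """Digest every chromosome of the reference (or a given haplotype).

    Variants are never planted inside recognition sites, so digesting the
    reference yields the fragment set shared by both parents and all
    offspring; ``haplotype`` exists for completeness.
    """
    seqs = haplotype if haplotype is not None else ref.chromosomes
    enzymes = (config.enzyme_rare, config.enzyme_frequent)
    fragments: list[Fragment] = []
    for chrom, seq in seqs.items():
        fragments.extend(digest_sequence(seq, chrom, enzymes))
    return fragments


def select_amplifiable(
    fragments: list[Fragment], config: SimConfig,
) -> list[Fragment]:
    """Keep rare-frequent fragments within the amplifiable size window."""
    lo, hi = config.amplifiable_size_range
    wanted = frozenset((config.enzyme_rare.name, config.enzyme_frequent.name))
    return [f for f in fragments
            if f.end_types == wanted and lo <= f.length <= hi]
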