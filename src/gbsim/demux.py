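"""Demultiplexing by exact barcode match and reverse-adapter trimming.

A read is assigned to a sample iff its first ``L`` bases equal that sample's
barcode *and* the following bases equal the expected prefix (spacer plus
PstI cut-site remnant).  No mismatches are tolerated anywhere; reads failing
either check are counted as unassigned and dropped.  The barcode and spacer
are removed from assigned reads but the cut-site remnant is kept — it is
genomic sequence and is needed for mapping.

Adapter trimming removes the best semi-global occurrence of the common
(reverse) adapter at the 3' end of a read; reads shorter than
``min_length`` (default 30 bp) after trimming are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from gbsim.config import ConfigurationError, SimConfig
from gbsim.sim.reads import FastqRead, ReadSet

DEFAULT_MIN_LENGTH = 30


@dataclass
class BarcodeSet:
    """Sample barcodes plus the invariant read layout after the barcode.

    ``spacer`` (non-genomic, removed with the barcode) and ``remnant``
    (the genomic cut-site remnant, retained) together form the expected
    prefix that must follow the barcode exactly.
    """

    entries: dict[str, str]          # sample_id -> barcode
    spacer: str = ""
    remnant: str = "TGCAG"

    def __post_init__(self) -> None:
        if not self.entries:
            raise ConfigurationError("empty barcode set")
        barcodes = list(self.entries.values())
        if len(set(barcodes)) != len(barcodes):
            raise ConfigurationError("barcodes are not unique")
        if len({len(b) for b in barcodes}) != 1:
            raise ConfigurationError("barcodes must have equal length")

    @classmethod
    def from_config(cls, barcodes: dict[str, str],
                    config: SimConfig) -> "BarcodeSet":
        return cls(dict(barcodes), config.spacer, config.cutsite_remnant)

    @property
    def expected_prefix(self) -> str:
        return self.spacer + self.remnant

    @property
    def barcode_length(self) -> int:
        return len(next(iter(self.entries.values())))


@dataclass
class DemuxStats:
    total_reads: int = 0
    assigned_reads: int = 0
    per_sample_counts: dict[str, int] = field(default_factory=dict)
    discarded_short: int = 0

    @property
    def unassigned_reads(self) -> int:
        return self.total_reads - self.assigned_reads

    def as_dict(self) -> dict:
        return {
            "total_reads": self.total_reads,
            "assigned_reads": self.assigned_reads,
            "unassigned_reads": self.unassigned_reads,
            "per_sample_counts": dict(self.per_sample_counts),
            "discarded_short": self.discarded_short,
        }


def demultiplex(
    reads: ReadSet, barcodes: BarcodeSet,
) -> tuple[dict[str, ReadSet], DemuxStats]:
    """Assign reads to samples by exact barcode + prefix match.

    Returns per-sample read sets (with truth labels carried along when
    present) and assignment statistics.
    """
    lookup = {bc: sample for sample, bc in barcodes.entries.items()}
    bl = barcodes.barcode_length
    prefix = barcodes.expected_prefix
    pl = len(prefix)
    spacer_len = len(barcodes.spacer)

    out = {s: ReadSet([], [] if reads.truth is not None else None)
           for s in barcodes.entries}
    stats = DemuxStats(per_sample_counts={s: 0 for s in barcodes.entries})
    for i, read in enumerate(reads.reads):
        stats.total_reads += 1
        sample = lookup.get(read.seq[:bl])
        if sample is None or read.seq[bl:bl + pl] != prefix:
            continue
        cut = bl + spacer_len
        trimmed = FastqRead(read.id, read.seq[cut:], read.qual[cut:])
        out[sample].reads.append(trimmed)
        if reads.truth is not None:
            out[sample].truth.append(reads.truth[i])
        stats.assigned_reads += 1
        stats.per_sample_counts[sample] += 1
    return out, stats


def trim_reverse_adapter(
    read: FastqRead, adapter_seq: str, min_overlap: int = 3,
    max_error_rate: float = 0.1, min_length: int = DEFAULT_MIN_LENGTH,
) -> FastqRead | None:
    """Trim the 3' adapter; return None when the trimmed read is too short.

    The best match is the alignment of a prefix of ``adapter_seq`` against
    the read's 3' end (any overlap >= ``min_overlap``) with mismatch
    fraction <= ``max_error_rate``, maximising the number of matching
    bases; ties prefer the earlier (longer-overlap) position.  Matching
    and truncation repeat until no further match remains, which makes the
    operation idempotent.  Quality is trimmed in lockstep with sequence.
    """
    if min_overlap < 1:
        raise ConfigurationError("min_overlap must be >= 1")
    seq, qual = read.seq, read.qual
    while True:
        best_pos: int | None = None
        best_matches = -1
        for j in range(0, len(seq) - min_overlap + 1):
            overlap = min(len(adapter_seq), len(seq) - j)
            if overlap < min_overlap:
                break
            mism = sum(1 for a, b in zip(seq[j:j + overlap], adapter_seq)
                       if a != b)
            if mism / overlap <= max_error_rate:
                matches = overlap - mism
                if matches > best_matches:
                    best_matches = matches
                    best_pos = j
        if best_pos is None:
            break
        seq, qual = seq[:best_pos], qual[:best_pos]
    if len(seq) < min_length:
        return None
    return FastqRead(read.id, seq, qual)


def demultiplex_and_trim(
    reads: ReadSet, barcodes: BarcodeSet, adapter_seq: str,
    min_overlap: int = 3, max_error_rate: float = 0.1,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> tuple[dict[str, ReadSet], DemuxStats]:
    """Demultiplex, then adapter-trim and length-filter each assigned read."""
    per_sample, stats = demultiplex(reads, barcodes)
    for sample, rs in per_sample.items():
        kept_reads, kept_truth = [], [] if rs.truth is not None else None
        for i, read in enumerate(rs.reads):
            trimmed = trim_reverse_adapter(read, adapter_seq, min_overlap,
                                           max_error_rate, min_length)
            if trimmed is None:
                stats.discarded_short += 1
                continue
            kept_reads.append(trimmed)
            if kept_truth is not None:
                kept_truth.append(rs.truth[i])
        rs.reads = kept_reads
        rs.truth = kept_truth
    return per_sample, stats
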