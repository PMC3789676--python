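"""Configuration objects for the GBS simulation and analysis pipeline.

The defaults describe a two-enzyme (PstI/MspI) genotyping-by-sequencing
experiment on a biparental recombinant inbred line (RIL) population:
F8-derived lines (seven generations of selfing after the F1) genotyped by
sequencing barcoded restriction fragments on either a fixed-length,
substitution-error platform ("illumina") or a variable-length platform with
homopolymer indel errors ("ion").
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path


class ConfigurationError(ValueError):
    """Raised when a configuration object is internally inconsistent."""


class InputError(ValueError):
    """Raised for malformed input data (sequences, tables, identifiers)."""


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme as a recognition motif plus top-strand cut offset.

    ``cut_offset`` is the number of recognition-site bases left of the cut on
    the top strand.  PstI (CTGCA^G) cuts after base 5, MspI (C^CGG) after
    base 1; both motifs are palindromic so a top-strand scan finds every site.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not (0 < self.cut_offset < len(self.recognition)):
            raise ConfigurationError(
                f"cut offset {self.cut_offset} outside recognition site "
                f"{self.recognition!r}"
            )


PSTI = Enzyme("PstI", "CTGCAG", 5)
MSPI = Enzyme("MspI", "CCGG", 1)

#: Invariant bases at the start of every genomic read: the filled-in PstI
#: overhang (TGCA) plus the first base after the cut (G).
PSTI_REMNANT = "TGCAG"

#: Stand-in for the common (reverse/Y) adapter as it appears at the 3' end of
#: reads that sequence through a short insert.  The exact sequence is
#: arbitrary; it only needs to be recognisable by the adapter trimmer.
DEFAULT_REVERSE_ADAPTER = "AGATCGGAAGAGCGGTTCAGCAGGAATGCCGAG"


@dataclass
class SimConfig:
    """Parameters of the synthetic GBS experiment.

    Attributes
    ----------
    n_chromosomes, chrom_length_bp
        Genome shape.  Chromosome sequences are i.i.d. uniform over ACGT.
    contig_length_bp
        Chromosomes are tiled into anchored contigs of this length; the
        contig table plays the role of a physical/genetic framework map.
    snp_density
        Per-bp probability that the two parents differ at a position
        (positions inside restriction sites are excluded so that digestion
        is genotype independent).
    n_rils, selfing_generations
        Population size and number of selfing rounds after the F1.
        ``selfing_generations=7`` corresponds to F8-derived lines by single
        seed descent; residual heterozygosity is 0.5**7 in expectation.
    map_length_cM
        Genetic length per chromosome; crossovers per meiosis are
        Poisson(map_length_cM / 100) with uniform placement (no
        interference).
    enzyme_rare, enzyme_frequent
        The rare (barcoded-adapter) and frequent (Y-adapter) cutters.
    amplifiable_size_range
        Inclusive fragment-length window retained by the PCR/size step;
        only rare-frequent (PstI-MspI) fragments amplify at all.
    barcode_length, cutsite_remnant, spacer
        Read layout: barcode (9 bp), optional spacer, then the invariant
        cut-site remnant, then genomic sequence.
    platform
        "illumina": fixed ``read_length_bp`` reads with substitution errors.
        "ion": variable-length reads (truncated normal) with homopolymer
        indels in addition to substitutions.
    per_sample_depth_params
        (median_reads, sigma) of a lognormal distribution of reads per
        sample, emulating uneven pooling.
    """

    n_chromosomes: int = 7
    chrom_length_bp: int = 200_000
    contig_length_bp: int = 10_000
    snp_density: float = 0.002
    n_rils: int = 94
    selfing_generations: int = 7
    map_length_cM: float = 150.0
    enzyme_rare: Enzyme = PSTI
    enzyme_frequent: Enzyme = MSPI
    amplifiable_size_range: tuple[int, int] = (50, 400)
    barcode_length: int = 9
    cutsite_remnant: str = PSTI_REMNANT
    spacer: str = ""
    reverse_adapter: str = DEFAULT_REVERSE_ADAPTER
    platform: str = "illumina"
    read_length_bp: int = 100
    ion_length_mean: float = 160.0
    ion_length_sd: float = 40.0
    ion_length_min: int = 30
    sub_error_rate: float = 0.002
    hp_indel_rate: float = 0.005
    per_sample_depth_params: tuple[float, float] = (2000.0, 0.7)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.platform not in ("illumina", "ion"):
            raise ConfigurationError(f"unknown platform {self.platform!r}")
        if self.selfing_generations < 1:
            raise ConfigurationError("selfing_generations must be >= 1")
        if not (0.0 <= self.snp_density < 1.0):
            raise ConfigurationError("snp_density must lie in [0, 1)")
        for name in ("n_chromosomes", "chrom_length_bp", "contig_length_bp",
                     "n_rils", "barcode_length", "read_length_bp"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.contig_length_bp > self.chrom_length_bp:
            raise ConfigurationError(
                "contig_length_bp exceeds chrom_length_bp")
        lo, hi = self.amplifiable_size_range
        if lo < 0 or hi < lo:
            raise ConfigurationError("invalid amplifiable_size_range")
        if not (0.0 <= self.sub_error_rate < 0.5):
            raise ConfigurationError("sub_error_rate must lie in [0, 0.5)")
        if isinstance(self.enzyme_rare, (tuple, list)):
            self.enzyme_rare = Enzyme("rare", *self.enzyme_rare)
        if isinstance(self.enzyme_frequent, (tuple, list)):
            self.enzyme_frequent = Enzyme("frequent", *self.enzyme_frequent)

    @property
    def expected_read_prefix(self) -> str:
        """Spacer + cut-site remnant expected right after the barcode."""
        return self.spacer + self.cutsite_remnant

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["enzyme_rare"] = [self.enzyme_rare.name, self.enzyme_rare.recognition,
                            self.enzyme_rare.cut_offset]
        d["enzyme_frequent"] = [self.enzyme_frequent.name,
                                self.enzyme_frequent.recognition,
                                self.enzyme_frequent.cut_offset]
        Path(path).write_text(json.dumps(d, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimConfig":
        d = json.loads(Path(path).read_text())
        known = {f.name for f in fields(cls)}
        d = {k: v for k, v in d.items() if k in known}
        for key in ("enzyme_rare", "enzyme_frequent"):
            if key in d and isinstance(d[key], (list, tuple)):
                d[key] = Enzyme(*d[key])
        for key in ("amplifiable_size_range", "per_sample_depth_params"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)
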