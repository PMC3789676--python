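# Methods

This note documents the models behind `gbsim`, the parameter choices that
matter, and what the simulations do and do not demonstrate.

## Simulated experiment

### Reference genome and anchors

Chromosome sequences are i.i.d. uniform over ACGT. Chromosomes are tiled
into fixed-length contigs (default 10 kb), each anchored at a genetic
position obtained by linearly scaling physical position to the
chromosome's map length. This contig frame plays the role of an anchored
whole-genome assembly; read placement and variant coordinates are
contig-relative, as they would be against a fragmented assembly.
Coordinates are 0-based half-open everywhere internally; only VCF output
is 1-based.

Parental variants are planted per-position Bernoulli (`snp_density`,
default 0.002/bp) with the reference carrying the parent-A allele.
Positions inside PstI/MspI recognition sites are excluded so that both
parents share every fragment boundary and truth coverage per locus is
well defined. Real populations can segregate for restriction-site
polymorphisms (presence/absence markers); this class of marker is not
modelled.

### Population

Each RIL descends from an independent F1 and is advanced by
`selfing_generations = 7` rounds of single seed descent (F8-derived
lines). Meioses place Poisson(`map_length_cM`/100) crossovers uniformly
on the genetic map — no crossover interference; the Kosambi function is
used only downstream for distance estimation, not in the generative
model. Expected residual heterozygosity is `0.5^7 ≈ 0.78%`, inside the
1–2% range expected of such populations; the per-locus selfing Markov
chain is the test oracle for this decay.

### Digestion, amplification, reads

Digestion is a top-strand scan for `CTGCAG` (cut after base 5) and `CCGG`
(cut after base 1); both motifs are palindromic so a single-strand scan
finds every site, and fragments exactly partition each chromosome. Only
fragments with one PstI and one MspI end within the amplifiable size
window (default 50–400 bp, a typical size-selection window; the protocol
itself states none) are retained — PstI–PstI, MspI–MspI and chromosome-end
fragments do not amplify under the Y-adapter design.

Reads run from the PstI end: `barcode (9 bp) + spacer (default empty,
optionally CGAT) + TGCAG + genomic sequence`, continuing into the common
reverse adapter when the insert is shorter than the read. Whether the
sequenced read contains the `CGAT` spacer is ambiguous in the original
adapter design, so the simulator and demultiplexer share one configurable
layout. For a fragment read on the forward strand the template includes
the four genomic overhang bases upstream of the PstI cut and the two
filled MspI overhang bases at the far end; the reverse-strand template is
the reverse complement of the fragment. At heterozygous loci each read
samples one allele with probability 0.5 — the mechanism that converts
shallow-covered hets into homozygous calls downstream.

Per-sample read totals are lognormal (`median, sigma`; default 2,000 and
0.7) to emulate uneven pooling; a sigma of ~1.5 reproduces the >10× spread
seen in badly balanced pools. Platform error models: *illumina* — fixed
100 bp, i.i.d. substitutions (default 0.002/base); *ion* — read length
truncated-normal (mean 160, SD 40, min 30) and, per homopolymer run, a
one-unit insertion or deletion with probability `hp_indel_rate` (default
0.005), plus substitutions. Quality strings are flat Phred+33 encodings
of the substitution rate: the caller consumes depth and allele counts,
not per-base quality, so modelling quality profiles would add nothing
testable. PCR duplicates, chimeras and instrument-specific artefacts are
out of scope.

## Analysis pipeline

### Demultiplexing and trimming

Assignment requires an exact match of the 9-bp barcode *and* the expected
prefix (spacer + `TGCAG`); there is no 1-mismatch rescue, mirroring
exact-match demultiplexers used for GBS. Barcode and spacer are removed;
the remnant is genomic and kept. Adapter trimming finds the best
semi-global match of the adapter prefix at the 3' end (min overlap 3,
max error rate 0.1 — conventional trimmer defaults) and iterates to a
fixpoint so that trimming is idempotent; reads under 30 bp after trimming
are discarded.

### Placement and calling

Placement seeds with the first non-ambiguous k-mer (k = 21, both
strands), extends ungapped, and accepts a unique placement with mismatch
fraction ≤ 0.1. There is no gapped alignment: ion homopolymer indels
lower the placement rate instead of producing shifted alignments, which
keeps the mapper exactly testable; the cost is a higher false-site rate
in ion data near indels (visible in the pipeline's truth evaluation).

The caller is a binomial-likelihood genotyper over the two site alleles
with uniform prior by default (a RIL-informed prior with het weight 0.02
is available). GQ is the Phred-scaled complement of the maximum
posterior, capped at 99. Sites are emitted where any non-reference base
is observed; a site is dropped as multi-allelic when a third allele
reaches count ≥ 2 *and* more than 10% of site depth — a strict "any third
allele" rule would discard nearly every true site once sequencing errors
exist at realistic depths, while the thresholded rule reduces to the
strict one on error-free data.

Base quality is ignored in counting (simulated qualities are flat);
the error rate is a caller parameter. Read-level quality trimming has no
analog under flat qualities and is omitted.

The tag path truncates reads to 64 bp tags, collapses them with
per-sample counts, places unique tags, and derives SNPs from co-placed
tags differing at single columns; tag-relative offsets convert to contig
coordinates by adding the placement offset (the degenerate CIGAR case,
since placements are ungapped). Only uniquely placed tags contribute. On
error-free data the tag path's sites are a subset of the full-read path's
(tags reach at most 59 bp past the cut site) and genotypes agree where
both call.

### Filters

Two criteria sets: the RIL map-building set (mask calls below depth 1/3
or GQ 3/5 for hom/het; keep sites with ≤ 90% missing, MAF ≥ 5%, < 10%
het — strict `<` on the het fraction) and the stricter comparison set
(≤ 50% missing, MAF ≥ 30%). MAF counts a heterozygote as half an allele
on each side, the standard allele-frequency definition; sites with all
calls missing have undefined MAF and are removed.

### Concordance

Tables are merged on (contig, position). Sites whose ref/alt pair
differs between datasets are excluded from genotype comparison (and
counted) rather than re-oriented — the datasets disagree about the
alleles themselves. Discordance is computed over call pairs non-missing
in both datasets; het-vs-hom differences count as discordant. Under
independent per-dataset error rates e1, e2 on homozygous truth the
expected discordance is ≈ e1 + e2 (exactly 2e(1−e) for equal rates),
which is the basis of the "platform error rates sum" interpretation of
cross-platform discordance.

### Map construction

Pre-filters: drop markers > 20% missing; keep one marker per contig
(least missing, ties by position); drop markers with missing + het
fraction > 10%; set remaining hets to missing. The population is then
treated as doubled haploids — the observed two-point disagreement
fraction is used directly, without the RIL selfing correction
`R = 2r/(1+2r)`, mirroring the standard MSTmap invocation for advanced
RILs. Consequently de novo cM distances are map-expanded relative to the
single-meiosis scale; rank-based comparisons are unaffected.

Grouping is single-linkage over pairs with chi-square (1 df) independence
p ≤ 1e−5. With ~1,800 markers there are ~1.6 M between-chromosome pairs,
so one or two spurious significances at the 1e−5 tail occasionally merge
two chromosomes into one linkage group. Merged groups keep their
majority-chromosome identity for order comparison, and the per-group rank
correlations are unaffected; exact group-count recovery should only be
expected at smaller marker counts.

Ordering collapses identical genotype vectors into bins (ordered by
marker id for determinism), seeds an order by depth-first traversal of
the minimum spanning tree of the bin-level recombination graph from one
end of its diameter, and refines with 2-opt segment reversals plus or-opt
relocations of segments of length 1–3. Both moves minimise the same
objective — the sum of adjacent recombination fractions — and are applied
only when strictly improving, so refinement is monotone; or-opt was added
because reversals alone left occasional misplaced segments in dense
groups. Group orientation is arbitrary; distances are cumulative Kosambi
transforms of adjacent fractions (capped at 0.4999). The isolated-marker
discard (`no_map_size`/`no_map_dist`) is implemented but inert by
default, as it has no effect when all markers group.

With finite populations the true order need not minimise the noisy
objective: markers closer than ~1/(2N) in recombination units (N
informative individuals) can be locally permuted by a single sampled
recombinant. The test suite therefore checks exact recovery only at
resolvable spacing (evenly spaced markers ≫ 1/N apart), and otherwise
checks that the found order scores no worse than the truth plus high
rank agreement.

### Order comparison

Per linkage group: absolute Spearman correlation (average ranks for
cosegregating bins) between de novo cM and reference cM over markers
anchored to the group's majority chromosome; groups under 3 anchored
markers are skipped. Chromosome concordance counts markers anchored to a
different chromosome than their group's majority. Displacement fits a
tricube-weighted local linear regression (loess, span 0.75 — the
canonical default; the source procedure names loess without parameters)
of reference cM on orientation-aligned de novo cM and flags markers whose
residual exceeds 5 cM; groups too small for the local fit fall back to a
global linear fit. The displacement criterion is residual-based rather
than projection-based, one of two defensible readings of "farther than
5 cM apart".

## Reference experiments and their scope

`gbsim.experiments` fixes the study conditions used by the test suite and
`scripts/acceptance.py`:

* mean MAF: 200 RILs × ~2,000 loci, no error/missingness. With n lines,
  per-locus allele frequencies have SD ≈ 0.5/√n, and folding at 0.5 gives
  E[MAF] = 50 − 100·√(2/π)·0.5/√n percent ≈ 47.2% at n = 200 — the mean
  MAF approaches 50% only as n grows.
* summed-error discordance: 96 × 5,000 homozygous truth, two copies each
  corrupted at 0.5%; expectation 2e(1−e) ≈ 0.995%.
* map order: 94 RILs × ~1,800 markers × 7 chromosomes (150 cM each), 10%
  missing and 0.5% error injected at the matrix level (markers stand for
  already-selected one-per-contig tags); marker-weighted mean per-group
  |Spearman ρ| ≥ 0.99 across seeds, typically ≈ 0.999.

These matrix-level conditions deliberately bypass read simulation: a
desk-scale genome cannot yield ~1,800 *callable* GBS markers, so read-level
behaviour (demultiplexing rates, caller accuracy, platform concordance)
is validated separately on smaller genomes by the pipeline tests. What
passing these experiments shows is that the analysis chain is correct
under its own generative assumptions — uniform base composition, linear
cM/bp scaling, no interference, genotype-independent digestion,
independent errors. It does not show robustness to properties of real
data absent from the generator: repeat structure and mapping ambiguity,
GC- and fragment-size-dependent coverage, PCR duplicates, segregation
distortion, or restriction-site polymorphism between parents.

## Numerical and degenerate-case choices

* One global seed spawns per-stage substreams (`numpy` SeedSequence);
  identical configs are byte-reproducible, including FASTQ output.
* Two-point tables with an empty margin get p = 1 (no evidence either
  way); pairs with zero informative individuals get r = NaN and weight
  0.5 in ordering.
* Tie-breaks: identical-genotype bins order by marker id; per-contig
  marker selection breaks ties by lowest position.
* `kosambi` raises on r ≥ 0.5; adjacent fractions are capped at 0.4999
  before transformation.
* All-missing sites fail MAF filtering by definition; zero shared
  samples yield a discordance report with 0 compared calls and an
  undefined percentage rather than an error.
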