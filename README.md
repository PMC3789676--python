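# gbsim — two-enzyme genotyping-by-sequencing, simulated end to end

`gbsim` models and analyses a **two-enzyme GBS experiment** on a biparental
recombinant inbred line (RIL) population, the design used to genotype large
cereal mapping populations at low cost: genomic DNA is co-digested with a
rare cutter (PstI, `CTGCAG`) and a frequent cutter (MspI, `CCGG`); a
barcoded adapter ligates to the PstI overhang and a Y-adapter to the MspI
overhang, so that only PstI–MspI fragments amplify; pooled fragments are
sequenced, reads are demultiplexed by an exact 9-bp barcode plus the
invariant `TGCAG` cut-site remnant, placed on an anchored reference
assembly, and genotyped.

The package is aimed at people developing or teaching GBS analysis
pipelines: every stage of the wet-lab design has a faithful in-silico
counterpart, so the complete analysis chain — demultiplexing, mapping,
genotype calling, filtering, cross-platform concordance and genetic map
construction — can be exercised and validated against known truth without
any external data.

## What is modelled

**Population.** F8-derived RILs by single seed descent: each line descends
from an independent F1 and is selfed for `g = 7` generations, so residual
heterozygosity is `0.5^g ≈ 0.78%` in expectation and the minor allele
frequency at segregating loci is ~50%. Crossovers are Poisson
(`map_length_cM / 100` per meiosis) with uniform placement (no
interference).

**Sequencing.** Reads are `barcode + spacer + TGCAG + genomic fragment`
from the PstI end, with per-sample read totals drawn lognormally (uneven
pooling). Two platform error models: fixed-length reads with substitution
errors ("illumina") and variable-length reads with homopolymer-run
insertions/deletions ("ion").

**Genotyping.** Reads are placed by exact k-mer seeding with ungapped
extension, and genotypes called per site and sample from allele counts
`(n_r, n_a)` with a binomial likelihood,

```
L(hom_ref) = (1−e)^n_r · e^n_a      L(het) = 0.5^(n_r+n_a)
L(hom_alt) = e^n_r · (1−e)^n_a      GQ = −10·log10(1 − max posterior)
```

followed by the RIL filter set (depth ≥ 1/3 and GQ ≥ 3/5 for hom/het
calls, ≤ 90% missing, MAF ≥ 5%, < 10% het). A second, tag-based calling
path truncates reads to fixed-length tags before placement, mirroring
reference-free GBS pipelines.

**Mapping.** De novo genetic maps are built from A/B parental encodings:
markers are clustered into linkage groups by two-point chi-square linkage
(single linkage at p ≤ 1e−5), ordered within groups by a minimum spanning
tree backbone refined with 2-opt/or-opt moves that minimise the sum of
adjacent recombination fractions, and spaced with the Kosambi map function
`d = 25·ln((1+2r)/(1−2r))` cM. Estimated orders are compared with the
anchored reference frame by per-group absolute Spearman rank correlation
and loess displacement.

## Worked example

The headline experiment — a 94-line RIL population genotyped at ~1,800
markers over 7 chromosomes, with 10% missing data and 0.5% genotype error
injected — builds a de novo map and compares it with the true marker
positions:

```python
from gbsim.experiments import map_order_experiment

res = map_order_experiment(seed=404)
print(res.n_markers_mapped, res.n_groups, round(res.mean_spearman_abs, 4))
print(res.comparison.per_group)
```

```
869 6 0.9993
   group chrom  n_markers  spearman_abs
0      1  chr4        145      0.999479
1      2  chr6        137      0.999663
2      3  chr1        119      0.998980
3      4  chr5        117      0.999365
4      5  chr3        115      0.998917
5      6  chr7        115      0.999479
```

Of the 1,800 simulated markers, 869 survive the pre-mapping filters (the
10% injected missingness interacts with the 10% missing+het threshold);
each linkage group is dominated by a single chromosome and its marker
order agrees with the true order at |Spearman ρ| ≈ 0.999 — the de novo and
reference-based orderings are effectively interchangeable, which is the
property that justifies reference-frame genotyping of new populations.

The full read-level pipeline (simulate → demultiplex → call → filter →
compare platforms → map → evaluate) runs from one config:

```python
from gbsim.config import SimConfig
from gbsim.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    sim=SimConfig(n_chromosomes=3, chrom_length_bp=200_000,
                  snp_density=0.004, n_rils=48, map_length_cM=60.0,
                  per_sample_depth_params=(1500.0, 0.5),
                  sub_error_rate=0.001),
    platforms=["illumina", "ion"], seed=11)
summary = run_pipeline(cfg, "out/")
```

which on this configuration reports, per stage: 75,505 of 76,550 illumina
reads assigned (98.6%; ion: 93.5%, homopolymer indels corrupt more
barcodes), zero genotype errors at filtered illumina sites, a 0.6% ion
genotype error rate driven by indel mis-placements, and 0.49% discordance
between the two platforms over 2,867 compared calls at 59 shared SNPs —
consistent with per-platform error rates summing. The same stages are
available as a CLI (`gbsim simulate|demux|call|filter|compare|map|
evaluate-map|run-all`).

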