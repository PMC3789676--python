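"""End-to-end orchestration: simulate -> demux -> call -> filter -> compare
-> map -> evaluate.

One global seed spawns independent substreams per stage (via
``numpy.random.SeedSequence``) so that each stage is reproducible on its
own and the whole run is byte-deterministic.  The truth population is
shared by all platforms, emulating one experiment sequenced on several
instruments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from gbsim import io
from gbsim.comparison import compare_orders
from gbsim.concordance import (all_pairwise_discordance, encode_parental,
                               merge_by_position, venn_counts)
from gbsim.config import ConfigurationError, SimConfig
from gbsim.demux import BarcodeSet, demultiplex_and_trim
from gbsim.filters import (ComparisonCriteria, FilterCriteria, filter_sites,
                           mask_low_confidence)
from gbsim.genotyper import (RIL_PRIOR, build_index, pileup_and_call,
                             tag_based_call)
from gbsim.mapbuilder import MapBuildParams, build_map
from gbsim.sim import (RILGenotypes, digest_and_classify, generate_barcodes,
                       generate_reads, select_amplifiable,
                       simulate_reference, simulate_ril_population)
from gbsim.tables import (CODE_A, CODE_B, CODE_H, CODE_MISSING, GT_HET,
                          GT_HOM_ALT, GT_HOM_REF, GT_MISSING, GenotypeTable)

logger = logging.getLogger("gbsim")

PARENT_A = "PARENT_A"
PARENT_B = "PARENT_B"


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    platforms: list[str] = field(default_factory=lambda: ["illumina", "ion"])
    run_tag_path: bool = False
    tag_length: int = 64
    kmer_size: int = 21
    caller_error_rate: float = 0.01
    use_ril_prior: bool = False
    filter_criteria: FilterCriteria = field(default_factory=FilterCriteria)
    comparison_criteria: ComparisonCriteria = field(
        default_factory=ComparisonCriteria)
    map_params: MapBuildParams = field(default_factory=MapBuildParams)
    seed: int = 0


def with_parents(ril: RILGenotypes) -> RILGenotypes:
    """Append the two inbred parents as samples (all-A and all-B calls)."""
    n = len(ril.loci)
    calls = np.concatenate([
        ril.calls,
        np.full((n, 1), CODE_A, dtype=np.int8),
        np.full((n, 1), CODE_B, dtype=np.int8),
    ], axis=1)
    xov = dict(ril.truth_crossovers)
    xov[PARENT_A] = {}
    xov[PARENT_B] = {}
    return RILGenotypes(ril.samples + [PARENT_A, PARENT_B],
                        ril.loci, calls, xov)


@dataclass
class TruthEvaluation:
    """Confusion of called genotypes against simulation truth."""

    confusion: dict[tuple[int, int], int]
    n_sites_matched: int
    n_sites_false: int          # called sites with no truth locus

    def _total(self, truth_codes, call_codes) -> int:
        return sum(v for (t, c), v in self.confusion.items()
                   if t in truth_codes and c in call_codes)

    @property
    def n_compared(self) -> int:
        return self._total((CODE_A, CODE_B, CODE_H),
                           (GT_HOM_REF, GT_HET, GT_HOM_ALT))

    @property
    def n_errors(self) -> int:
        wrong = 0
        match = {CODE_A: GT_HOM_REF, CODE_B: GT_HOM_ALT, CODE_H: GT_HET}
        for (t, c), v in self.confusion.items():
            if c == GT_MISSING:
                continue
            if match.get(t) != c:
                wrong += v
        return wrong

    @property
    def error_rate(self) -> float | None:
        n = self.n_compared
        return None if n == 0 else self.n_errors / n

    @property
    def het_called_hom_rate(self) -> float | None:
        """Among true hets with a non-missing call, fraction called hom."""
        n = self._total((CODE_H,), (GT_HOM_REF, GT_HET, GT_HOM_ALT))
        if n == 0:
            return None
        return self._total((CODE_H,), (GT_HOM_REF, GT_HOM_ALT)) / n

    @property
    def het_called_hom_ref_fraction(self) -> float | None:
        """Among true hets called hom, fraction called hom-ref (~0.5)."""
        n = self._total((CODE_H,), (GT_HOM_REF, GT_HOM_ALT))
        if n == 0:
            return None
        return self._total((CODE_H,), (GT_HOM_REF,)) / n

    def as_dict(self) -> dict:
        return {
            "n_sites_matched": self.n_sites_matched,
            "n_sites_false": self.n_sites_false,
            "n_compared": self.n_compared,
            "n_errors": self.n_errors,
            "error_rate": self.error_rate,
            "het_called_hom_rate": self.het_called_hom_rate,
        }


def evaluate_against_truth(
    table: GenotypeTable, truth: RILGenotypes, ref,
) -> TruthEvaluation:
    """Compare called genotypes with the simulated truth matrix.

    Called sites are translated from contig to chromosome coordinates via
    the anchor frame; a site whose (chrom, pos) has no truth locus, or
    whose alleles disagree with the parental alleles, counts as a false
    site.  Truth A maps to hom-ref because the reference carries the
    parent-A allele.
    """
    contig_map = ref.contig_map()
    truth_index: dict[tuple[str, int], int] = {
        (c, int(p)): i for i, (c, p) in
        enumerate(zip(truth.loci["chrom"], truth.loci["pos"]))}
    sample_cols = [truth.samples.index(s) if s in truth.samples else None
                   for s in table.samples]

    confusion: dict[tuple[int, int], int] = {}
    matched = 0
    false_sites = 0
    has_alleles = "allele_b" in truth.loci.columns
    for i in range(table.n_sites):
        contig = table.sites["contig"].iat[i]
        c = contig_map.get(contig)
        if c is None:
            false_sites += 1
            continue
        key = (c.chrom, c.start + int(table.sites["pos"].iat[i]))
        row = truth_index.get(key)
        if row is None:
            false_sites += 1
            continue
        if has_alleles:
            ra = truth.loci["allele_a"].iat[row]
            rb = truth.loci["allele_b"].iat[row]
            if (table.sites["ref"].iat[i], table.sites["alt"].iat[i]) != \
                    (ra, rb):
                false_sites += 1
                continue
        matched += 1
        for j, tc in enumerate(sample_cols):
            if tc is None:
                continue
            t = int(truth.calls[row, tc])
            g = int(table.gt[i, j])
            confusion[(t, g)] = confusion.get((t, g), 0) + 1
    return TruthEvaluation(confusion, matched, false_sites)


def truth_genotype_table(truth: RILGenotypes,
                         provenance: str = "truth") -> GenotypeTable:
    """Express the truth matrix as a GenotypeTable on chromosome coordinates."""
    code_map = {CODE_A: GT_HOM_REF, CODE_B: GT_HOM_ALT, CODE_H: GT_HET,
                CODE_MISSING: GT_MISSING}
    gt = np.vectorize(code_map.get)(truth.calls).astype(np.int8)
    sites = pd.DataFrame({
        "contig": truth.loci["chrom"],
        "pos": truth.loci["pos"],
        "ref": truth.loci.get("allele_a", "N"),
        "alt": truth.loci.get("allele_b", "N"),
    })
    shape = gt.shape
    return GenotypeTable(sites, list(truth.samples), gt,
                         np.zeros(shape, dtype=np.int32),
                         np.zeros(shape, dtype=np.int16), provenance)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage and write artifacts; returns the summary dict."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    streams = ss.spawn(3 + len(config.platforms))
    rng_ref = np.random.default_rng(streams[0])
    rng_pop = np.random.default_rng(streams[1])
    rng_bc = np.random.default_rng(streams[2])

    summary: dict = {"seed": config.seed, "platforms": config.platforms,
                     "stages": {}}

    def stage(name):
        logger.info("stage: %s", name)
        return summary["stages"].setdefault(name, {})

    try:
        # ------------------------------------------------------- simulate
        s = stage("simulate")
        ref, variants = simulate_reference(config.sim, rng_ref)
        ril = simulate_ril_population(ref, variants, config.sim, rng_pop)
        population = with_parents(ril)
        fragments = select_amplifiable(
            digest_and_classify(ref, config.sim), config.sim)
        if not fragments:
            raise ConfigurationError("no amplifiable fragments simulated")
        barcodes = generate_barcodes(population.samples,
                                     config.sim.barcode_length, rng_bc)
        io.write_fasta(ref.chromosomes, out / "reference.fa")
        io.write_anchors(ref, out / "anchors.tsv")
        io.write_barcodes(barcodes, out / "barcodes.tsv")
        io.write_vcf(truth_genotype_table(population),
                     out / "truth.vcf",
                     {c: len(seq) for c, seq in ref.chromosomes.items()})
        s.update(n_variant_loci=len(variants),
                 n_amplifiable_fragments=len(fragments),
                 het_fraction=ril.het_fraction())

        index = build_index(ref, config.kmer_size)
        prior = RIL_PRIOR if config.use_ril_prior else None

        filtered_tables: dict[str, GenotypeTable] = {}
        comparison_tables: list[GenotypeTable] = []
        for pi, platform in enumerate(config.platforms):
            label = f"{platform}{pi + 1}" \
                if config.platforms.count(platform) > 1 else platform
            sim_p = replace(config.sim, platform=platform)
            rng_reads = np.random.default_rng(streams[3 + pi])

            s = stage(f"reads[{label}]")
            pool = generate_reads(ref, fragments, population, barcodes,
                                  sim_p, rng_reads)
            io.write_fastq(pool, out / f"reads_{label}.fastq.gz")
            s.update(n_reads=len(pool))

            s = stage(f"demux[{label}]")
            per_sample, stats = demultiplex_and_trim(
                pool, BarcodeSet.from_config(barcodes, sim_p),
                sim_p.reverse_adapter)
            s.update(stats.as_dict())

            s = stage(f"call[{label}]")
            reads_by_sample = {name: rs.reads
                               for name, rs in per_sample.items()}
            kwargs = {} if prior is None else {"prior": prior}
            table = pileup_and_call(reads_by_sample, index,
                                    error_rate=config.caller_error_rate,
                                    provenance=label, **kwargs)
            io.write_vcf(table, out / f"calls_{label}.vcf")
            masked = mask_low_confidence(table, config.filter_criteria)
            filtered = filter_sites(masked, config.filter_criteria)
            io.write_vcf(filtered, out / f"calls_{label}.filtered.vcf")
            filtered_tables[label] = filtered
            comp = filter_sites(masked, config.comparison_criteria)
            comp.provenance = label
            comparison_tables.append(comp)
            s.update(n_sites_called=table.n_sites,
                     n_sites_filtered=filtered.n_sites,
                     n_sites_comparison=comp.n_sites)

            if config.run_tag_path:
                s = stage(f"tags[{label}]")
                tag_table = tag_based_call(
                    reads_by_sample, index, tag_length=config.tag_length,
                    error_rate=config.caller_error_rate,
                    provenance=f"{label}-tags", **kwargs)
                tag_masked = mask_low_confidence(tag_table,
                                                 config.filter_criteria)
                tag_comp = filter_sites(tag_masked,
                                        config.comparison_criteria)
                tag_comp.provenance = f"{label}-tags"
                comparison_tables.append(tag_comp)
                io.write_vcf(tag_table, out / f"calls_{label}.tags.vcf")
                s.update(n_sites_called=tag_table.n_sites,
                         n_sites_comparison=tag_comp.n_sites)

            s = stage(f"evaluate[{label}]")
            ev = evaluate_against_truth(filtered, population, ref)
            s.update(ev.as_dict())

        # -------------------------------------------------------- compare
        if len(comparison_tables) >= 2:
            s = stage("concordance")
            merged = merge_by_position(comparison_tables[:3])
            s["venn"] = {"+".join(l for l, f in zip(merged.labels, key) if f):
                         v for key, v in venn_counts(merged).items()}
            s["discordance"] = [r.as_dict()
                                for r in all_pairwise_discordance(merged)]
            s["allele_conflicts"] = int(merged.allele_conflict.sum())

        # ------------------------------------------------------------ map
        s = stage("map")
        primary = filtered_tables[next(iter(filtered_tables))]
        markers = encode_parental(primary, PARENT_A, PARENT_B)
        gmap = build_map(markers, config.map_params)
        io.write_map(gmap, out / "map.tsv")
        s.update(n_markers=len(gmap.table),
                 n_groups=len(gmap.groups),
                 group_sizes=list(gmap.group_sizes().values()))

        s = stage("evaluate_map")
        contig_map = ref.contig_map()
        anchors = pd.DataFrame({
            "marker_id": markers.ids,
            "chrom": [contig_map[c].chrom for c in markers.contig],
            "ref_cM": [contig_map[c].cM for c in markers.contig],
        })
        oc = compare_orders(gmap, anchors)
        s.update(oc.as_dict())
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {list(summary['stages'])[-1] if summary['stages'] else 'init'!r} "
            f"failed: {exc}") from exc

    io.write_json(summary, out / "summary.json")
    return summary
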