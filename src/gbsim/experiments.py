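"""Reference in-silico experiments emulating the study conditions.

Each function runs one self-contained simulated experiment at the scale a
single workstation handles comfortably and returns summary statistics:

* ``mean_maf_experiment`` — allele balance of an unselected biparental RIL
  population (expected: minor allele frequency near 50%).
* ``residual_heterozygosity_experiment`` — heterozygosity left after seven
  selfing generations (expected: 0.5**7 ~ 0.78%, within the 1-2% range
  typical of F8-derived lines).
* ``platform_discordance_experiment`` — two observed copies of one
  homozygous truth matrix, each corrupted independently; with per-copy
  error rate e the expected discordance is 2 e (1 - e), i.e. two imperfect
  platforms' error rates approximately sum.
* ``map_order_experiment`` — a 94-line RIL population genotyped at ~1,800
  markers on 7 chromosomes with missing data and genotype error; a de novo
  genetic map is built and its marker order compared with the true
  positions (expected: per-group |Spearman rho| at or above 0.99).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from gbsim.comparison import OrderComparison, compare_orders
from gbsim.concordance import merge_by_position, percent_discordant
from gbsim.config import SimConfig
from gbsim.mapbuilder import MapBuildParams, build_map
from gbsim.sim import inject_noise, simulate_reference, \
    simulate_ril_population
from gbsim.tables import (CODE_H, GT_HOM_ALT, GT_HOM_REF, GenotypeTable,
                          MarkerMatrix)


def _population(n_rils: int, n_loci_target: int, n_chromosomes: int,
                chrom_length_bp: int, map_length_cM: float, seed: int,
                selfing_generations: int = 7):
    density = n_loci_target / (n_chromosomes * chrom_length_bp)
    cfg = SimConfig(
        n_chromosomes=n_chromosomes, chrom_length_bp=chrom_length_bp,
        contig_length_bp=10_000, snp_density=density, n_rils=n_rils,
        selfing_generations=selfing_generations,
        map_length_cM=map_length_cM, rng_seed=seed)
    ss = np.random.SeedSequence(seed).spawn(2)
    ref, variants = simulate_reference(cfg, np.random.default_rng(ss[0]))
    ril = simulate_ril_population(ref, variants, cfg,
                                  np.random.default_rng(ss[1]))
    return cfg, ref, ril


def mean_maf_experiment(seed: int, n_rils: int = 200,
                        n_loci: int = 2000) -> dict:
    """Mean per-locus minor allele frequency (%) of an unselected RIL set.

    No genotyping error, no missing data; heterozygotes contribute half an
    allele to each side.  The folded sampling distribution pulls the mean
    slightly below 50%: E[MAF] = 0.5 - E|f - 0.5| with
    SD(f) ~ 0.5 / sqrt(n_rils).
    """
    _cfg, _ref, ril = _population(
        n_rils=n_rils, n_loci_target=n_loci, n_chromosomes=7,
        chrom_length_bp=150_000, map_length_cM=150.0, seed=seed)
    freqs = ril.allele_a_frequency()
    maf = np.minimum(freqs, 1.0 - freqs)
    return {"mean_maf_percent": float(100.0 * np.nanmean(maf)),
            "n_loci": int(len(maf)), "n_rils": n_rils}


def residual_heterozygosity_experiment(seed: int, n_rils: int = 300,
                                       n_loci: int = 1500,
                                       selfing_generations: int = 7) -> dict:
    """Het fraction of an F(1+g)-derived population vs the 0.5**g law."""
    _cfg, _ref, ril = _population(
        n_rils=n_rils, n_loci_target=n_loci, n_chromosomes=7,
        chrom_length_bp=150_000, map_length_cM=150.0, seed=seed,
        selfing_generations=selfing_generations)
    per_individual = (ril.calls == CODE_H).mean(axis=0)
    return {
        "het_percent": float(100.0 * per_individual.mean()),
        "expected_percent": 100.0 * 0.5 ** selfing_generations,
        "sem_percent": float(100.0 * per_individual.std(ddof=1)
                             / np.sqrt(n_rils)),
        "n_rils": n_rils, "n_loci": len(ril.loci),
    }


def platform_discordance_experiment(seed: int, n_samples: int = 96,
                                    n_markers: int = 5000,
                                    error_rate: float = 0.005) -> dict:
    """Percent discordant calls between two independently corrupted copies
    of one homozygous truth matrix."""
    rng = np.random.default_rng(seed)
    truth = rng.choice([GT_HOM_REF, GT_HOM_ALT],
                       size=(n_markers, n_samples)).astype(np.int8)
    samples = [f"s{j}" for j in range(n_samples)]
    sites = pd.DataFrame({"contig": "c", "pos": range(n_markers),
                          "ref": "A", "alt": "G"})
    tables = []
    for label in ("platform_x", "platform_y"):
        flip = rng.random(truth.shape) < error_rate
        observed = np.where(flip, GT_HOM_ALT + GT_HOM_REF - truth,
                            truth).astype(np.int8)
        tables.append(GenotypeTable(
            sites.copy(), samples, observed,
            np.full(truth.shape, 1, dtype=np.int32),
            np.full(truth.shape, 99, dtype=np.int16), label))
    report = percent_discordant(merge_by_position(tables))
    return {"percent_discordant": float(report.percent_discordant),
            "expected_percent": 100.0 * 2 * error_rate * (1 - error_rate),
            "compared_calls": report.compared_calls}


@dataclass
class MapOrderResult:
    comparison: OrderComparison
    n_markers_mapped: int
    n_groups: int

    @property
    def mean_spearman_abs(self) -> float:
        return self.comparison.mean_spearman_abs


def map_order_experiment(seed: int, n_rils: int = 94,
                         n_markers: int = 1800, n_chromosomes: int = 7,
                         map_length_cM: float = 150.0,
                         missing_frac: float = 0.10,
                         error_rate: float = 0.005) -> MapOrderResult:
    """De novo map construction under missing data and genotype error.

    Markers are the parental variant loci themselves (as if one marker per
    assembly contig had already been chosen), corrupted by ``error_rate``
    A/B flips and ``missing_frac`` dropout, then run through the standard
    map-building parameters.  The comparison reference is the true
    simulated position of each marker.
    """
    _cfg, _ref, ril = _population(
        n_rils=n_rils, n_loci_target=n_markers,
        n_chromosomes=n_chromosomes, chrom_length_bp=200_000,
        map_length_cM=map_length_cM, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[2])
    noisy = inject_noise(ril.calls, missing_frac, error_rate, rng)
    ids = np.array([f"{c}_{p}" for c, p in
                    zip(ril.loci["chrom"], ril.loci["pos"])])
    matrix = MarkerMatrix(ids, noisy, ril.samples)
    params = MapBuildParams(one_marker_per_contig=False)
    gmap = build_map(matrix, params)

    chrom_len = 200_000
    truth = {i: (c, map_length_cM * p / chrom_len) for i, c, p in
             zip(ids, ril.loci["chrom"], ril.loci["pos"])}
    anchors = pd.DataFrame({
        "marker_id": gmap.table["marker_id"],
        "chrom": [truth[i][0] for i in gmap.table["marker_id"]],
        "ref_cM": [truth[i][1] for i in gmap.table["marker_id"]],
    })
    oc = compare_orders(gmap, anchors)
    return MapOrderResult(oc, len(gmap.table), len(gmap.groups))
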