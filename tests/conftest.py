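"""Shared fixtures: one small, error-free simulated GBS experiment.

Everything is generated at test time from fixed seeds; the dataset is
session-scoped because the read-level stages (demux, placement, calling)
are reused by several test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from gbsim.config import SimConfig
from gbsim.demux import BarcodeSet, demultiplex_and_trim
from gbsim.genotyper import build_index, pileup_and_call
from gbsim.sim import (digest_and_classify, generate_barcodes, generate_reads,
                       select_amplifiable, simulate_reference,
                       simulate_ril_population)


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    """Small, error-free experiment for truth-based round-trip tests."""
    return SimConfig(
        n_chromosomes=2, chrom_length_bp=60_000, contig_length_bp=6_000,
        snp_density=0.003, n_rils=12, selfing_generations=7,
        map_length_cM=120.0, per_sample_depth_params=(600.0, 0.4),
        sub_error_rate=0.0, rng_seed=33)


@pytest.fixture(scope="session")
def sim_dataset(tiny_config):
    cfg = tiny_config
    ref, variants = simulate_reference(cfg)
    ril = simulate_ril_population(ref, variants, cfg)
    fragments = select_amplifiable(digest_and_classify(ref, cfg), cfg)
    barcodes = generate_barcodes(ril.samples, cfg.barcode_length,
                                 np.random.default_rng(99))
    reads = generate_reads(ref, fragments, ril, barcodes, cfg)
    return {"config": cfg, "ref": ref, "variants": variants, "ril": ril,
            "fragments": fragments, "barcodes": barcodes, "reads": reads}


@pytest.fixture(scope="session")
def demuxed(sim_dataset):
    cfg = sim_dataset["config"]
    per_sample, stats = demultiplex_and_trim(
        sim_dataset["reads"],
        BarcodeSet.from_config(sim_dataset["barcodes"], cfg),
        cfg.reverse_adapter)
    return per_sample, stats


@pytest.fixture(scope="session")
def kmer_index(sim_dataset):
    return build_index(sim_dataset["ref"], 21)


@pytest.fixture(scope="session")
def called_table(demuxed, kmer_index):
    per_sample, _ = demuxed
    sample_reads = {s: rs.reads for s, rs in per_sample.items()}
    return pileup_and_call(sample_reads, kmer_index, error_rate=0.01)
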