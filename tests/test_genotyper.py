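"""Read placement and genotype calling against independent oracles."""

import math
from fractions import Fraction

import numpy as np
import pytest

from gbsim.config import SimConfig
from gbsim.genotyper import (build_index, call_genotype, place_read,
                             pileup_and_call, tag_based_call)
from gbsim.seqs import revcomp
from gbsim.sim.reference import Contig, ReferenceGenome
from gbsim.tables import GT_HET, GT_HOM_ALT, GT_HOM_REF, GT_MISSING


def _single_contig_ref(seq: str) -> ReferenceGenome:
    return ReferenceGenome({"chr1": seq},
                           [Contig("ctg1", "chr1", 0, len(seq), 0.0)])


class TestIndex:
    def test_interior_kmers_map_to_their_positions(self):
        rng = np.random.default_rng(1)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 500))
        index = build_index(_single_contig_ref(seq), k=21)
        for i in (0, 100, 479):
            assert index.get(seq[i:i + 21]) == ("ctg1", i)

    def test_duplicated_contig_marks_all_kmers_ambiguous(self):
        rng = np.random.default_rng(2)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        ref = ReferenceGenome(
            {"chr1": seq + seq},
            [Contig("a", "chr1", 0, 300, 0.0),
             Contig("b", "chr1", 300, 600, 0.0)])
        index = build_index(ref, k=21)
        assert index.ambiguous_fraction() == pytest.approx(1.0)

    def test_random_genome_nearly_collision_free(self):
        # expected k-mer collisions for L=100kb, k=21: ~L^2 / 4^k << 1%
        rng = np.random.default_rng(3)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 100_000))
        index = build_index(_single_contig_ref(seq), k=21)
        assert index.ambiguous_fraction() < 0.01

    def test_small_k_rejected(self):
        from gbsim.config import ConfigurationError
        with pytest.raises(ConfigurationError):
            build_index(_single_contig_ref("ACGT" * 100), k=5)


class TestPlacement:
    def test_error_free_reads_place_at_truth_origin(self, sim_dataset,
                                                    demuxed, kmer_index):
        per_sample, _ = demuxed
        contig_map = sim_dataset["ref"].contig_map()
        checked = exact = 0
        for sample, rs in list(per_sample.items())[:4]:
            for read, truth in list(zip(rs.reads, rs.truth))[:100]:
                p = place_read(read.seq, kmer_index)
                if p is None:
                    continue  # e.g. spans a contig boundary ambiguously
                c = contig_map[p.contig]
                assert c.chrom == truth.chrom
                # aligned segment must lie within the truth span (clipping
                # at contig boundaries can shrink it)
                gstart = c.start + p.offset
                assert truth.start <= gstart
                assert gstart + p.n_compared <= truth.end
                if p.strand == "+" and p.read_clip == 0 and \
                        p.n_compared == len(read.seq):
                    assert gstart == truth.start
                    exact += 1
                checked += 1
        assert checked > 100 and exact > 20

    def test_foreign_read_unplaced(self, kmer_index):
        assert place_read("A" * 60, kmer_index) is None

    def test_mismatch_fraction_gate(self):
        rng = np.random.default_rng(4)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
        index = build_index(_single_contig_ref(seq), k=21)
        read = seq[50:150]
        # corrupt the tail heavily but keep the first 21-mer intact
        bad = read[:21] + "".join(
            {"A": "C", "C": "G", "G": "T", "T": "A"}[b] for b in read[21:])
        assert place_read(read, index) is not None
        assert place_read(bad, index, max_mismatch_frac=0.1) is None

    def test_reverse_strand_read_places(self):
        rng = np.random.default_rng(5)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
        index = build_index(_single_contig_ref(seq), k=21)
        p = place_read(revcomp(seq[100:180]), index)
        assert p is not None and p.strand == "-" and p.offset == 100


def oracle_call(n_ref: int, n_alt: int, e: Fraction, prior):
    """Exact-arithmetic posterior over {hom_ref, het, hom_alt}."""
    like = [
        (1 - e) ** n_ref * e ** n_alt,
        Fraction(1, 2) ** (n_ref + n_alt),
        e ** n_ref * (1 - e) ** n_alt,
    ]
    post = [p * l for p, l in zip(prior, like)]
    total = sum(post)
    post = [p / total for p in post]
    best = max(range(3), key=lambda i: post[i])
    p_err = float(1 - post[best])
    gq = 99 if p_err < 1e-10 else min(99, round(-10 * math.log10(p_err)))
    return (GT_HOM_REF, GT_HET, GT_HOM_ALT)[best], gq


class TestCaller:
    @pytest.mark.parametrize("e", [0.01, 0.05, 0.002])
    def test_equals_enumeration_oracle_up_to_depth_ten(self, e):
        prior = (Fraction(1, 3),) * 3
        ef = Fraction(e).limit_denominator(10**6)
        for depth in range(0, 11):
            for n_ref in range(depth + 1):
                n_alt = depth - n_ref
                got = call_genotype(n_ref, n_alt, e)
                if depth == 0:
                    assert got == (GT_MISSING, 0)
                    continue
                want = oracle_call(n_ref, n_alt, ef, prior)
                assert got[0] == want[0], (n_ref, n_alt, e)
                assert abs(got[1] - want[1]) <= 1, (n_ref, n_alt, e)

    def test_clean_homozygote_example(self):
        # n_ref=5, n_alt=0, e=0.01, uniform prior: hom_ref wins with
        # posterior 0.9511/(0.9511 + 0.03125 + 1e-10) -> GQ 15
        g, gq = call_genotype(5, 0, 0.01)
        assert g == GT_HOM_REF
        want_g, want_gq = oracle_call(5, 0, Fraction(1, 100),
                                      (Fraction(1, 3),) * 3)
        assert (g, gq) == (want_g, want_gq)

    def test_balanced_counts_call_het(self):
        g, _ = call_genotype(3, 3, 0.01)
        assert g == GT_HET

    def test_zero_depth_missing(self):
        assert call_genotype(0, 0, 0.01) == (GT_MISSING, 0)


class TestPileupCalling:
    def test_error_free_calls_match_truth(self, sim_dataset, called_table):
        # every called site that corresponds to a truth locus must agree
        # with the truth matrix wherever the call is non-missing
        from gbsim.pipeline import evaluate_against_truth

        ev = evaluate_against_truth(called_table, sim_dataset["ril"],
                                    sim_dataset["ref"])
        assert ev.n_sites_matched > 10
        assert ev.n_sites_false == 0
        assert ev.n_compared > 100
        # hets sampled at depth >=1 can legitimately be called hom; all
        # other disagreements are true errors and must be absent
        non_het_errors = sum(
            v for (t, c), v in ev.confusion.items()
            if t in (0, 1) and c != GT_MISSING
            and {0: GT_HOM_REF, 1: GT_HOM_ALT}[t] != c)
        assert non_het_errors == 0

    def test_depth_zero_samples_missing(self, called_table):
        zero = called_table.dp == 0
        assert (called_table.gt[zero] == GT_MISSING).all()
        assert (called_table.dp == (called_table.gt != GT_MISSING) *
                called_table.dp).all()


class TestTagPath:
    def test_two_tags_one_mismatch_define_snp(self):
        rng = np.random.default_rng(6)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        index = build_index(_single_contig_ref(seq), k=21)
        tag = seq[40:104]                       # 64 bp, offset 40
        var_off = 30
        alt_base = {"A": "C", "C": "G", "G": "T", "T": "A"}[tag[var_off]]
        tag_alt = tag[:var_off] + alt_base + tag[var_off + 1:]
        reads = {
            "s1": [type("R", (), {"seq": tag})() for _ in range(5)],
            "s2": [type("R", (), {"seq": tag_alt})() for _ in range(5)],
        }
        table = tag_based_call(reads, index, tag_length=64, error_rate=0.01)
        assert table.n_sites == 1
        assert int(table.sites["pos"].iloc[0]) == 40 + var_off
        assert table.gt[0, 0] == GT_HOM_REF
        assert table.gt[0, 1] == GT_HOM_ALT

    def test_tag_sites_subset_of_full_read_sites(self, demuxed, kmer_index,
                                                 called_table):
        per_sample, _ = demuxed
        sample_reads = {s: rs.reads for s, rs in per_sample.items()}
        tag_table = tag_based_call(sample_reads, kmer_index, tag_length=64,
                                   error_rate=0.01)
        assert set(tag_table.site_keys()) <= set(called_table.site_keys())

    def test_paths_agree_on_joint_sites(self, demuxed, kmer_index,
                                        called_table):
        per_sample, _ = demuxed
        sample_reads = {s: rs.reads for s, rs in per_sample.items()}
        tag_table = tag_based_call(sample_reads, kmer_index, tag_length=64,
                                   error_rate=0.01)
        full_keys = {k: i for i, k in enumerate(called_table.site_keys())}
        mismatched = total = 0
        for ti, key in enumerate(tag_table.site_keys()):
            fi = full_keys[key]
            for si in range(len(tag_table.samples)):
                a = tag_table.gt[ti, si]
                b = called_table.gt[fi, si]
                if a == GT_MISSING or b == GT_MISSING:
                    continue
                total += 1
                # truncation to 64 bp lowers tag depth, so hets may be
                # sampled differently; homozygous calls must agree
                if GT_HET not in (a, b):
                    mismatched += a != b
        assert total > 50
        assert mismatched == 0
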