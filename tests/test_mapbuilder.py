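"""Linkage estimation, grouping, ordering and the Kosambi map function."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gbsim.config import InputError, SimConfig
from gbsim.mapbuilder import (GeneticMap, MapBuildParams, build_map,
                              group_markers, kosambi, kosambi_inverse,
                              order_markers, pairwise_linkage,
                              preprocess_markers, recombination_fraction)
from gbsim.sim import simulate_reference, simulate_ril_population
from gbsim.tables import CODE_A, CODE_B, CODE_H, CODE_MISSING, MarkerMatrix

PARAMS = MapBuildParams(one_marker_per_contig=False)


def matrix_from(calls, ids=None, **kw):
    calls = np.asarray(calls, dtype=np.int8)
    ids = ids or [f"m{i}" for i in range(calls.shape[0])]
    samples = [f"s{j}" for j in range(calls.shape[1])]
    return MarkerMatrix(np.array(ids), calls, samples, **kw)


def ril_matrix(n_rils=60, n_chrom=3, seed=7, chrom_len=120_000,
               density=0.0005, map_cm=100.0):
    cfg = SimConfig(n_chromosomes=n_chrom, chrom_length_bp=chrom_len,
                    contig_length_bp=10_000, snp_density=density,
                    n_rils=n_rils, map_length_cM=map_cm, rng_seed=seed)
    ref, variants = simulate_reference(cfg)
    ril = simulate_ril_population(ref, variants, cfg)
    ids = np.array([f"{c}_{p}" for c, p in
                    zip(ril.loci["chrom"], ril.loci["pos"])])
    truth = {i: (c, p) for i, c, p in
             zip(ids, ril.loci["chrom"], ril.loci["pos"])}
    return MarkerMatrix(ids, ril.calls, ril.samples), truth


class TestKosambi:
    def test_closed_form_values(self):
        assert kosambi(0.0) == 0.0
        assert kosambi(0.25) == pytest.approx(25 * np.log(3), rel=1e-12)

    def test_small_r_linear_limit(self):
        r = 1e-4
        assert kosambi(r) == pytest.approx(100 * r, rel=1e-4)

    def test_domain_error(self):
        with pytest.raises(InputError):
            kosambi(0.5)
        with pytest.raises(InputError):
            kosambi(-0.01)

    @settings(max_examples=200, deadline=None)
    @given(st.floats(min_value=1e-6, max_value=0.4999))
    def test_monotone_and_dominates_linear(self, r):
        assert kosambi(r) >= 100 * r - 1e-9
        assert kosambi(r) > kosambi(r * 0.99)
        assert kosambi_inverse(kosambi(r)) == pytest.approx(r, rel=1e-9)


class TestRecombinationFraction:
    def test_identical_markers_fully_linked(self):
        x = np.array([CODE_A] * 40 + [CODE_B] * 40, dtype=np.int8)
        r, p, n = recombination_fraction(x, x)
        assert r == 0.0 and n == 80
        assert p < 1e-15

    def test_balanced_table_is_independent(self):
        # 94 individuals, 47 recombinant, all four classes balanced:
        # r_hat = 0.5, chi-square p = 1 (no linkage signal)
        x = np.array([CODE_A] * 47 + [CODE_B] * 47, dtype=np.int8)
        y = np.array(([CODE_A] * 24 + [CODE_B] * 23) +
                     ([CODE_A] * 24 + [CODE_B] * 23), dtype=np.int8)
        r, p, n = recombination_fraction(x, y)
        assert n == 94
        assert r == pytest.approx(0.5)
        assert p == pytest.approx(1.0)

    def test_missing_individuals_excluded(self):
        x = np.array([CODE_A, CODE_B, CODE_MISSING, CODE_A], dtype=np.int8)
        y = np.array([CODE_A, CODE_MISSING, CODE_B, CODE_B], dtype=np.int8)
        r, _p, n = recombination_fraction(x, y)
        assert n == 2 and r == 0.5 * 1.0

    def test_no_informative_individuals_flagged(self):
        x = np.array([CODE_MISSING, CODE_A], dtype=np.int8)
        y = np.array([CODE_A, CODE_MISSING], dtype=np.int8)
        r, p, n = recombination_fraction(x, y)
        assert n == 0 and np.isnan(r) and p == 1.0

    def test_gamete_level_fraction_matches_haldane(self):
        # single-meiosis gametes at 10 cM separation: expected r =
        # (1 - exp(-0.2)) / 2 = 0.0906 under no interference
        from gbsim.sim import meiosis
        rng = np.random.default_rng(15)
        pos = np.array([20_000, 40_000])      # 10 cM at 200kb / 100 cM
        h0 = np.zeros(2, dtype=np.int8)
        h1 = np.ones(2, dtype=np.int8)
        n = 6000
        gametes = np.array([meiosis(h0, h1, pos, 200_000, 100.0, rng)[0]
                            for _ in range(n)])
        r, _p, _n = recombination_fraction(gametes[:, 0], gametes[:, 1])
        expected = 0.5 * (1 - np.exp(-0.2))
        sd = np.sqrt(expected * (1 - expected) / n)
        assert abs(r - expected) < 3 * sd

    def test_pairwise_matrix_matches_scalar_path(self):
        rng = np.random.default_rng(2)
        calls = rng.choice([CODE_A, CODE_B, CODE_MISSING], size=(8, 40),
                           p=[0.45, 0.45, 0.1]).astype(np.int8)
        r_m, p_m, n_m = pairwise_linkage(calls)
        for i in range(8):
            for j in range(8):
                r, p, n = recombination_fraction(calls[i], calls[j])
                assert n_m[i, j] == n
                if n:
                    assert r_m[i, j] == pytest.approx(r, abs=1e-12)
                    assert p_m[i, j] == pytest.approx(p, abs=1e-9)


class TestPreprocess:
    def test_missing_fraction_filter(self):
        good = [CODE_A] * 10
        bad = [CODE_MISSING] * 3 + [CODE_A] * 7     # 30% missing
        m = matrix_from([good, bad])
        out = preprocess_markers(m, PARAMS)
        assert list(out.ids) == ["m0"]

    def test_one_marker_per_contig_least_missing(self):
        rows = [[CODE_A] * 9 + [CODE_MISSING],      # 10% missing
                [CODE_A] * 10,                      # complete -> chosen
                [CODE_B] * 10]
        m = matrix_from(rows, contig=np.array(["c1", "c1", "c2"]),
                        pos=np.array([100, 200, 50]))
        out = preprocess_markers(m, MapBuildParams())
        assert sorted(out.ids) == ["m1", "m2"]

    def test_het_plus_missing_threshold_and_dh_conversion(self):
        # 2 hets of 10 = 20% > missing_threshold 10% -> dropped
        borderline = [CODE_H, CODE_H] + [CODE_A] * 8
        kept = [CODE_H] + [CODE_A] * 9              # exactly 10%
        m = matrix_from([borderline, kept])
        out = preprocess_markers(m, PARAMS)
        assert list(out.ids) == ["m1"]
        assert out.calls[0, 0] == CODE_MISSING      # H -> missing
        assert (out.calls != CODE_H).all()

    def test_overfiltering_raises(self):
        m = matrix_from([[CODE_MISSING] * 10])
        with pytest.raises(InputError):
            preprocess_markers(m, PARAMS)

    def test_random_matrix_matches_predicate_scan(self):
        rng = np.random.default_rng(4)
        calls = rng.choice([CODE_A, CODE_B, CODE_H, CODE_MISSING],
                           size=(40, 30),
                           p=[0.4, 0.4, 0.05, 0.15]).astype(np.int8)
        m = matrix_from(calls)
        out = preprocess_markers(m, PARAMS)
        want = []
        for i in range(40):
            row = calls[i]
            miss = (row == CODE_MISSING).mean()
            bad = ((row == CODE_MISSING) | (row == CODE_H)).mean()
            if miss <= 0.20 and bad <= 0.10:
                want.append(f"m{i}")
        assert list(out.ids) == want


class TestGrouping:
    def test_simulated_chromosomes_recovered(self):
        m, truth = ril_matrix(n_rils=80, n_chrom=3, seed=21)
        pre = preprocess_markers(m, PARAMS)
        groups = group_markers(pre, PARAMS)
        assert len(groups) == 3
        for idx in groups:
            chroms = {truth[i][0] for i in pre.ids[idx]}
            assert len(chroms) == 1

    def test_unlinked_markers_stay_singletons(self):
        rng = np.random.default_rng(8)
        calls = rng.choice([CODE_A, CODE_B], size=(5, 30)).astype(np.int8)
        m = matrix_from(calls)
        groups = group_markers(m, PARAMS)
        # independent random markers essentially never reach p <= 1e-5
        assert len(groups) == 5

    def test_matches_brute_force_components(self):
        m, _ = ril_matrix(n_rils=50, n_chrom=2, seed=3, density=0.0003)
        pre = preprocess_markers(m, PARAMS)
        groups = group_markers(pre, PARAMS)
        _r, p, n = pairwise_linkage(pre.calls)
        # brute-force union-find over the significant-pair graph
        parent = list(range(pre.n_markers))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(pre.n_markers):
            for j in range(i + 1, pre.n_markers):
                if n[i, j] > 0 and p[i, j] <= PARAMS.cut_off_p:
                    parent[find(i)] = find(j)
        want = {}
        for i in range(pre.n_markers):
            want.setdefault(find(i), set()).add(i)
        got = {frozenset(g.tolist()) for g in groups}
        assert got == {frozenset(v) for v in want.values()}


class TestOrdering:
    def test_two_marker_group(self):
        x = [CODE_A] * 30 + [CODE_B] * 30
        y = [CODE_A] * 33 + [CODE_B] * 27
        m = matrix_from([x, y])
        out = order_markers(m, PARAMS)
        r = 3 / 60
        assert sorted(out["cM"]) == pytest.approx([0.0, kosambi(r)])

    def test_identical_markers_share_a_bin(self):
        x = [CODE_A] * 20 + [CODE_B] * 20
        m = matrix_from([x, x, x])
        out = order_markers(m, PARAMS)
        assert set(out["cM"]) == {0.0}
        assert sorted(out["marker_id"]) == ["m0", "m1", "m2"]

    @pytest.mark.parametrize("seed", [0, 4, 9])
    def test_error_free_group_recovers_true_order(self, seed):
        # evenly spaced markers (10 kb ~ 8.3 cM apart) are resolvable by
        # 100 meiotic samples, so error-free recovery must be exact up to
        # whole-group reversal
        from gbsim.sim.reference import ParentalVariants

        cfg = SimConfig(n_chromosomes=1, chrom_length_bp=120_000,
                        contig_length_bp=10_000, snp_density=0.0,
                        n_rils=100, map_length_cM=100.0, rng_seed=seed)
        ref, _ = simulate_reference(cfg)
        seq = ref.chromosomes["chr1"]
        rows = []
        for p in range(5_000, 120_000, 10_000):
            alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[p]]
            rows.append(("chr1", p, seq[p], alt))
        var = ParentalVariants(pd.DataFrame(
            rows, columns=["chrom", "pos", "allele_a", "allele_b"]))
        ril = simulate_ril_population(ref, var, cfg)
        ids = np.array([f"{p:06d}" for p in ril.loci["pos"]])
        pre = preprocess_markers(
            MarkerMatrix(ids, ril.calls, ril.samples), PARAMS)
        out = order_markers(pre, PARAMS).sort_values("order_index")
        pos = np.array([int(i) for i in out["marker_id"]])
        binned = pd.DataFrame({"cM": out["cM"].to_numpy(), "pos": pos}) \
            .groupby("cM", sort=True)["pos"].mean().to_numpy()
        diffs = np.diff(binned)
        assert (diffs >= 0).all() or (diffs <= 0).all()

    def test_found_order_at_least_as_good_as_truth(self):
        # with randomly placed (sub-cM clustered) markers the truth order
        # need not minimise the noisy objective, but the search must find
        # an order no worse than it
        m, truth = ril_matrix(n_rils=80, n_chrom=1, seed=31, density=0.0004)
        pre = preprocess_markers(m, PARAMS)
        uniq, inverse = np.unique(pre.calls, axis=0, return_inverse=True)
        r, _p, _n = pairwise_linkage(uniq)
        np.fill_diagonal(r, 0.0)
        pos = np.array([truth[i][1] for i in pre.ids])
        binpos = np.array([pos[inverse == b].mean()
                           for b in range(uniq.shape[0])])
        true_order = list(np.argsort(binpos))

        def objective(order):
            return sum(r[order[k], order[k + 1]]
                       for k in range(len(order) - 1))

        out = order_markers(pre, PARAMS).sort_values("order_index")
        id_to_bin = dict(zip(pre.ids, inverse))
        found = []
        for mid in out["marker_id"]:
            b = id_to_bin[mid]
            if not found or found[-1] != b:
                found.append(b)
        assert objective(found) <= objective(true_order) + 1e-9
        rho = stats.spearmanr(out["cM"],
                              [truth[i][1] for i in out["marker_id"]])
        assert abs(rho.statistic) > 0.995


def test_build_map_assigns_every_marker_once():
    m, truth = ril_matrix(n_rils=80, n_chrom=3, seed=11)
    gmap = build_map(m, PARAMS)
    assert len(gmap.groups) == 3
    ids = gmap.table["marker_id"]
    assert ids.is_unique
    pre = preprocess_markers(m, PARAMS)
    assert set(ids) == set(pre.ids)
    # cM non-decreasing within groups is asserted by the GeneticMap
    # constructor; group sizes must sum to the marker count
    assert sum(gmap.group_sizes().values()) == len(ids)
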