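"""Genetic distances, F_ST, permutation tests and AMOVA."""

import numpy as np
import pytest

from gravnet.popgen import (
    MISSING,
    GenotypeMatrix,
    amova,
    euclidean_genetic_distance,
    fst_permutation_test,
    gene_flow,
    pairwise_fst,
    weir_cockerham_fst,
)
from gravnet.simulate import SimulationConfig, generate_genotypes_bn


def gm(dosages, pops=None):
    d = np.asarray(dosages)
    n = d.shape[0]
    pops = pops or ["A"] * n
    return GenotypeMatrix(d, [f"i{k}" for k in range(n)], list(pops))


def panmictic(seed, n=30, loci=300):
    """Two labelled halves of one panmictic pool (true F_ST = 0)."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.05, 0.95, loci)
    d = rng.binomial(2, p, size=(n, loci))
    return gm(d, ["A"] * (n // 2) + ["B"] * (n - n // 2))


class TestEuclideanDistance:
    def test_identical_rows_zero(self):
        g = gm([[0, 1, 2], [0, 1, 2]])
        assert euclidean_genetic_distance(g).values[0, 1] == 0.0

    def test_closed_form(self):
        g = gm([[0, 0, 0, 0], [2, 2, 2, 2]])
        assert euclidean_genetic_distance(g).values[0, 1] == pytest.approx(4.0)

    def test_matches_bruteforce_with_missing(self):
        rng = np.random.default_rng(11)
        d = rng.integers(0, 3, (10, 50))
        d[rng.random(d.shape) < 0.1] = MISSING
        d[:, (d == MISSING).all(axis=0)] = 0
        g = gm(d)
        got = euclidean_genetic_distance(g).values
        L = d.shape[1]
        for i in range(10):
            for j in range(10):
                both = (d[i] != MISSING) & (d[j] != MISSING)
                raw = float(((d[i, both] - d[j, both]) ** 2).sum())
                expect = np.sqrt(raw * L / both.sum())
                assert got[i, j] == pytest.approx(expect, abs=1e-10)

    def test_symmetry_and_triangle_inequality(self):
        rng = np.random.default_rng(12)
        g = gm(rng.integers(0, 3, (8, 40)))
        D = euclidean_genetic_distance(g).values
        assert np.allclose(D, D.T)
        for i in range(8):
            for j in range(8):
                for k in range(8):
                    assert D[i, j] <= D[i, k] + D[k, j] + 1e-9

    def test_zero_shared_loci_rejected(self):
        d = np.array([[0, MISSING], [MISSING, 2]])
        with pytest.raises(ValueError):
            euclidean_genetic_distance(gm(d))


class TestGeneFlow:
    def test_anchors_and_monotonicity(self):
        g = gm([[0, 0, 0], [2, 2, 2], [1, 1, 1], [0, 0, 1]])
        dist = euclidean_genetic_distance(g)
        flow = gene_flow(dist)
        assert np.allclose(np.diag(flow.values), 1.0)
        assert flow.values.min() == 0.0  # maximal-distance pair
        d = dist.values[np.triu_indices(4, 1)]
        f = flow.values[np.triu_indices(4, 1)]
        order = np.argsort(d)
        assert np.all(np.diff(f[order]) <= 1e-12)

    def test_all_zero_distances_warns(self):
        g = gm([[1, 1], [1, 1]])
        with pytest.warns(UserWarning):
            flow = gene_flow(euclidean_genetic_distance(g))
        assert np.allclose(flow.values, 1.0)

    def test_requires_genotype_metric(self):
        g = gm([[0, 2], [2, 0]])
        flow = gene_flow(euclidean_genetic_distance(g))
        with pytest.raises(ValueError):
            gene_flow(flow)


class TestPairwiseFst:
    def test_panmictic_near_zero(self):
        g = panmictic(1, n=60, loci=2000)
        assert abs(pairwise_fst(g, ("A", "B"))) < 0.01

    def test_fixed_differences_are_one(self):
        d = np.vstack([np.zeros((5, 20), int), np.full((5, 20), 2)])
        g = gm(d, ["A"] * 5 + ["B"] * 5)
        assert pairwise_fst(g, ("A", "B")) == pytest.approx(1.0)

    def test_balding_nichols_calibration(self):
        cfg = SimulationConfig(seed=13, n_sites=2, inds_per_site=30, n_loci=2000,
                               fst_target=0.2, missing_rate=0.0)
        g, _ = generate_genotypes_bn(cfg)
        assert pairwise_fst(g, ("S01", "S02")) == pytest.approx(0.2, abs=0.03)

    def test_monomorphic_pair_warns_zero(self):
        g = gm(np.zeros((6, 10), int), ["A"] * 3 + ["B"] * 3)
        with pytest.warns(UserWarning):
            assert pairwise_fst(g, ("A", "B")) == 0.0

    def test_weir_cockerham_variant_agrees(self):
        cfg = SimulationConfig(seed=14, n_sites=2, inds_per_site=25, n_loci=1000,
                               fst_target=0.15, missing_rate=0.05)
        g, _ = generate_genotypes_bn(cfg)
        assert weir_cockerham_fst(g, ("S01", "S02")) == pytest.approx(
            pairwise_fst(g, ("S01", "S02")), abs=0.02)


class TestFstPermutationTest:
    def test_fixed_differences_minimal_p(self):
        d = np.vstack([np.zeros((5, 20), int), np.full((5, 20), 2)])
        g = gm(d, ["A"] * 5 + ["B"] * 5)
        p = fst_permutation_test(g, ("A", "B"), n_perm=99, seed=1)
        assert p == pytest.approx(1 / 100)

    def test_single_permutation_boundary(self):
        g = panmictic(2)
        p = fst_permutation_test(g, ("A", "B"), n_perm=1, seed=3)
        assert p in (0.5, 1.0)

    def test_seeded_reproducibility_and_label_order(self):
        g = panmictic(3)
        p1 = fst_permutation_test(g, ("A", "B"), n_perm=49, seed=5)
        p2 = fst_permutation_test(g, ("A", "B"), n_perm=49, seed=5)
        assert p1 == p2
        # swapping population order permutes the same individuals
        p3 = fst_permutation_test(g, ("B", "A"), n_perm=49, seed=5)
        assert abs(p3 - p1) < 0.3  # same statistic; stream order may differ


def naive_amova_components(dosages, pop_idx):
    """Independent sums-of-squares oracle: explicit allele lists and double loops."""
    n_pops = pop_idx.max() + 1
    sw_sum = si_sum = sp_sum = 0.0
    for locus in range(dosages.shape[1]):
        alleles = []  # (pop, ind, value)
        for ind in range(dosages.shape[0]):
            dv = dosages[ind, locus]
            if dv == MISSING:
                continue
            a, b = (1, 1) if dv == 2 else (0, 0) if dv == 0 else (0, 1)
            alleles.append((pop_idx[ind], ind, a))
            alleles.append((pop_idx[ind], ind, b))
        vals = np.array([v for _, _, v in alleles], float)
        pops = np.array([p for p, _, _ in alleles])
        inds = np.array([i for _, i, _ in alleles])
        M = len(vals)
        if M == 0:
            continue
        grand = vals.mean()
        ss_total = ((vals - grand) ** 2).sum()
        ss_wp = 0.0
        for p in range(n_pops):
            sel = pops == p
            if sel.sum() > 0:
                ss_wp += ((vals[sel] - vals[sel].mean()) ** 2).sum()
        ss_wi = 0.0
        for i in np.unique(inds):
            sel = inds == i
            ss_wi += ((vals[sel] - vals[sel].mean()) ** 2).sum()
        ss_ap = ss_total - ss_wp
        ss_ai = ss_wp - ss_wi
        n_present = len(np.unique(inds))
        pops_present = len(np.unique(pops))
        m_p = np.array([(pops == p).sum() for p in np.unique(pops)], float)
        df_wi, df_ai, df_ap = n_present, n_present - pops_present, pops_present - 1
        if df_ai <= 0 or df_ap <= 0:
            continue
        n_c = (M - (m_p ** 2).sum() / M) / df_ap
        if n_c <= 0:
            continue
        ms_wi, ms_ai, ms_ap = ss_wi / df_wi, ss_ai / df_ai, ss_ap / df_ap
        sw_sum += ms_wi
        si_sum += (ms_ai - ms_wi) / 2
        sp_sum += (ms_ap - ms_ai) / n_c
    return sw_sum, si_sum, sp_sum


class TestAmova:
    def test_degenerate_identical_homozygotes(self):
        g = gm(np.zeros((8, 10), int), ["A"] * 4 + ["B"] * 4)
        res = amova(g, n_perm=0)
        assert res.f_it == res.f_is == res.f_st == 0.0
        assert sum(res.percent.values()) == pytest.approx(100.0)

    def test_fixed_differences_hardy_weinberg(self):
        d = np.vstack([np.zeros((6, 30), int), np.full((6, 30), 2)])
        g = gm(d, ["A"] * 6 + ["B"] * 6)
        res = amova(g, n_perm=0)
        assert res.f_st == pytest.approx(1.0)
        assert res.f_is == pytest.approx(0.0, abs=1e-12)
        assert res.f_st_prime == pytest.approx(1.0)  # no shared alleles

    def test_f_statistic_identity_and_percent_sum(self):
        cfg = SimulationConfig(seed=15, n_loci=300, missing_rate=0.05)
        g, _ = generate_genotypes_bn(cfg)
        res = amova(g, n_perm=0)
        assert (1 - res.f_it) == pytest.approx((1 - res.f_is) * (1 - res.f_st), abs=1e-8)
        assert sum(res.percent.values()) == pytest.approx(100.0, abs=1e-6)
        assert res.f_st_prime >= res.f_st

    def test_matches_naive_ss_oracle_on_subset(self):
        cfg = SimulationConfig(seed=16, n_sites=3, inds_per_site=10, n_loci=60,
                               missing_rate=0.1)
        g, _ = generate_genotypes_bn(cfg)
        res = amova(g, n_perm=0)
        pop_idx = np.array([{"S01": 0, "S02": 1, "S03": 2}[p] for p in g.population_labels])
        sw, si, sp = naive_amova_components(g.dosages, pop_idx)
        total = sw + si + sp
        naive_pct_ap = 100 * max(sp, 0) / (max(sw, 0) + max(si, 0) + max(sp, 0))
        assert res.percent["among_population"] == pytest.approx(naive_pct_ap, abs=3.0)
        assert res.f_st == pytest.approx(sp / total, abs=1e-8)

    def test_single_individual_population_excluded(self):
        d = np.vstack([np.zeros((4, 10), int), np.full((1, 10), 2), np.ones((4, 10), int)])
        g = gm(d, ["A"] * 4 + ["lonely"] + ["B"] * 4)
        with pytest.warns(UserWarning):
            res = amova(g, n_perm=0)
        assert res is not None

    def test_permutation_pvalues_seeded(self):
        cfg = SimulationConfig(seed=17, n_sites=3, inds_per_site=8, n_loci=50,
                               missing_rate=0.0)
        g, _ = generate_genotypes_bn(cfg)
        r1 = amova(g, n_perm=29, seed=9)
        r2 = amova(g, n_perm=29, seed=9)
        assert r1.p_values == r2.p_values
        assert 0 < r1.p_values["f_st"] <= 1
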