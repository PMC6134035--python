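"""Diversity and differentiation statistics against independent oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fragdiv import (
    FragdivError,
    GenotypeMatrix,
    PopulationMeta,
    expected_heterozygosity,
    fis,
    great_circle_distances,
    linearize_fst,
    mantel_test,
    pairwise_fst,
    rarefied_allelic_richness,
    simulate_balding_nichols,
    wc_fst,
)
from fragdiv.popgen import diversity_table


def brute_force_richness(counts, g):
    """Mean distinct alleles over all size-g subsamples, by enumeration."""
    copies = [a for a, c in enumerate(counts) for _ in range(c)]
    subsets = list(itertools.combinations(range(len(copies)), g))
    return np.mean([len({copies[i] for i in sub}) for sub in subsets])


class TestRarefaction:
    def test_known_small_case(self):
        assert rarefied_allelic_richness([3, 1], 2) == pytest.approx(1.5)

    def test_matches_enumeration_for_small_samples(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            k = int(rng.integers(1, 5))
            counts = rng.integers(0, 5, size=k)
            counts[rng.integers(k)] += 1  # non-empty
            n = int(counts.sum())
            if n > 12:
                continue
            g = int(rng.integers(1, n + 1))
            assert rarefied_allelic_richness(counts, g) == pytest.approx(
                brute_force_richness(counts, g), abs=1e-10)

    def test_full_sample_returns_observed_count(self):
        assert rarefied_allelic_richness([4, 3, 2], 9) == pytest.approx(3.0)

    def test_single_copy_subsample(self):
        assert rarefied_allelic_richness([5, 5, 5], 1) == pytest.approx(1.0)

    def test_oversized_subsample_rejected(self):
        with pytest.raises(FragdivError, match="exceeds"):
            rarefied_allelic_richness([2, 2], 5)


class TestHeterozygosity:
    def test_monomorphic_is_zero(self):
        assert expected_heterozygosity([10]) == 0.0

    def test_unbiased_estimator_value(self):
        assert expected_heterozygosity([5, 5]) == pytest.approx(10 / 9 * 0.5)

    def test_large_sample_equifrequent_limit(self):
        counts = [10_000] * 4
        assert expected_heterozygosity(counts) == pytest.approx(0.75, abs=1e-4)

    def test_too_few_copies_rejected(self):
        with pytest.raises(FragdivError):
            expected_heterozygosity([1])


class TestFis:
    def _one_pop(self, genotypes):
        calls = np.array(genotypes, dtype=np.int32)[:, None, :]
        inds = [f"i{k}" for k in range(len(genotypes))]
        return GenotypeMatrix(
            individuals=inds, populations={i: "P" for i in inds},
            regions={}, loci=["L1"], marker_kinds=["ssr_id"], calls=calls)

    def test_hand_computed_example(self):
        # AA, AA, AB, BB: H_obs = 0.25, He = (8/7)(1 - 0.625^2 - 0.375^2)
        gm = self._one_pop([(0, 0), (0, 0), (0, 1), (1, 1)])
        series, mean = fis(gm, "P")
        he = (8 / 7) * (1 - 0.625 ** 2 - 0.375 ** 2)
        assert series["L1"] == pytest.approx(1 - 0.25 / he)
        assert mean == pytest.approx(1 - 0.25 / he)

    def test_all_homozygotes_give_one(self):
        gm = self._one_pop([(0, 0), (1, 1), (0, 0), (1, 1)])
        _, mean = fis(gm, "P")
        assert mean == pytest.approx(1.0)

    def test_hardy_weinberg_sample_near_zero(self):
        rng = np.random.default_rng(4)
        copies = rng.integers(0, 2, size=(2000, 10, 2))
        inds = [f"i{k}" for k in range(2000)]
        gm = GenotypeMatrix(
            individuals=inds, populations={i: "P" for i in inds},
            regions={}, loci=[f"L{j}" for j in range(10)],
            marker_kinds=["snp"] * 10, calls=copies.astype(np.int32))
        _, mean = fis(gm, "P")
        assert abs(mean) < 0.03


def wc_biallelic_oracle(geno_a, geno_b):
    """Single-locus, two-population Weir-Cockerham theta, coded directly
    from the 1984 variance-components definitions for one allele of a
    biallelic locus (independent of the package implementation)."""
    r = 2
    n = [len(geno_a), len(geno_b)]
    p = [np.mean([g.count(0) for g in geno_a]) / 2,
         np.mean([g.count(0) for g in geno_b]) / 2]
    h = [np.mean([g[0] != g[1] for g in geno_a]),
         np.mean([g[0] != g[1] for g in geno_b])]
    nbar = sum(n) / r
    nc = (r * nbar - sum(x * x for x in n) / (r * nbar)) / (r - 1)
    pbar = (n[0] * p[0] + n[1] * p[1]) / (r * nbar)
    s2 = (n[0] * (p[0] - pbar) ** 2 + n[1] * (p[1] - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n[0] * h[0] + n[1] * h[1]) / (r * nbar)
    a = (nbar / nc) * (s2 - 1 / (nbar - 1) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    # summing components over the two alleles doubles a, b and c alike
    return a / (a + b + c)


def _two_pop_matrix(geno_a, geno_b):
    calls = np.array(list(geno_a) + list(geno_b), dtype=np.int32)[:, None, :]
    inds = [f"a{k}" for k in range(len(geno_a))] + \
           [f"b{k}" for k in range(len(geno_b))]
    pops = {i: ("A" if i.startswith("a") else "B") for i in inds}
    return GenotypeMatrix(individuals=inds, populations=pops, regions={},
                          loci=["L1"], marker_kinds=["snp"], calls=calls)


class TestWcFst:
    def test_identical_pools_give_near_zero_theta(self):
        gm = simulate_balding_nichols([np.array([0.5, 0.5])] * 50,
                                      [0.0, 0.0], [500, 500], seed=6)
        res = wc_fst(gm, "global", min_maf=0.0)
        assert abs(res.theta) < 0.01

    def test_fixed_alternative_alleles_give_one(self):
        geno_a = [(0, 0)] * 10
        geno_b = [(1, 1)] * 10
        res = wc_fst(_two_pop_matrix(geno_a, geno_b), "global", min_maf=0.0)
        assert res.theta == pytest.approx(1.0)

    def test_matches_hand_oracle_on_spec_example(self):
        # counts (A:14, B:6) vs (A:6, B:14) over 10 diploids each
        geno_a = [(0, 0)] * 4 + [(0, 1)] * 6
        geno_b = [(1, 1)] * 4 + [(0, 1)] * 6
        res = wc_fst(_two_pop_matrix(geno_a, geno_b), "global", min_maf=0.0)
        assert res.theta == pytest.approx(
            wc_biallelic_oracle(geno_a, geno_b), abs=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 100_000))
    def test_matches_hand_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n_a, n_b = rng.integers(2, 11, size=2)  # up to 20 individuals total
        geno_a = [tuple(sorted(rng.integers(0, 2, 2))) for _ in range(n_a)]
        geno_b = [tuple(sorted(rng.integers(0, 2, 2))) for _ in range(n_b)]
        flat = [x for g in geno_a + geno_b for x in g]
        if len(set(flat)) < 2:
            return  # monomorphic draws carry no information
        want = wc_biallelic_oracle(geno_a, geno_b)
        if not math.isfinite(want):
            return
        res = wc_fst(_two_pop_matrix(geno_a, geno_b), "global", min_maf=0.0)
        assert res.theta == pytest.approx(want, abs=1e-12)

    def test_ratio_of_sums_reduces_to_single_locus_formula(self):
        geno_a = [(0, 0), (0, 1), (1, 1), (0, 1)]
        geno_b = [(1, 1), (1, 1), (0, 1), (0, 0)]
        res = wc_fst(_two_pop_matrix(geno_a, geno_b), "global", min_maf=0.0)
        assert res.theta == pytest.approx(res.a_sum / res.abc_sum)
        assert res.n_loci_used == 1

    def test_permutation_p_detects_structure(self):
        gm = simulate_balding_nichols(
            [np.array([0.5, 0.5])] * 30, [0.25, 0.25], [30, 30], seed=8)
        res = wc_fst(gm, "global", min_maf=0.0, n_permutations=199, seed=1)
        assert res.p_value == pytest.approx(1 / 200)

    def test_mean_pairwise_theta_tracks_generating_f(self):
        for f in (0.02, 0.1, 0.2):
            rng = np.random.default_rng(int(f * 1000))
            freqs = [rng.dirichlet([1.0] * 4) for _ in range(80)]
            gm = simulate_balding_nichols(freqs, [f] * 6, [40] * 6,
                                          seed=int(f * 100) + 1)
            mat = pairwise_fst(gm, min_maf=0.0, max_missing=1.0)
            vals = mat.to_numpy()[np.triu_indices(6, k=1)]
            # pairwise theta between two BN populations estimates their
            # shared F (variance among the two relative to total)
            assert np.nanmean(vals) == pytest.approx(f, abs=0.35 * f + 0.01)


class TestLinearizeFst:
    @pytest.mark.parametrize("fst,want", [
        (0.5, 1.0), (1.0, 0.0), (0.021, (1 - 0.021) / 0.021)])
    def test_values(self, fst, want):
        assert linearize_fst(fst) == pytest.approx(want)

    def test_scandinavian_global_fst_gives_reported_m(self):
        assert linearize_fst(0.021) == pytest.approx(46.62, abs=0.01)

    def test_nonpositive_returns_infinity(self):
        assert math.isinf(linearize_fst(0.0))
        assert math.isinf(linearize_fst(-0.01))


class TestGreatCircle:
    def _meta(self, pop, lat, lon):
        return PopulationMeta(pop, lat, lon, "10-100", region="x")

    def test_identical_coordinates_zero(self):
        d = great_circle_distances([self._meta("a", 57.0, -4.0),
                                    self._meta("b", 57.0, -4.0)])
        assert d.loc["a", "b"] == pytest.approx(0.0)

    def test_antipodal_arc(self):
        d = great_circle_distances([self._meta("a", 0.0, 0.0),
                                    self._meta("b", 0.0, 180.0)])
        assert d.loc["a", "b"] == pytest.approx(math.pi * 6371.0, abs=0.1)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        metas = [self._meta(f"p{k}", rng.uniform(-90, 90),
                            rng.uniform(-180, 180)) for k in range(4)]
        d = great_circle_distances(metas).to_numpy()
        assert np.allclose(d, d.T)
        assert (np.diag(d) == 0).all()

    def test_out_of_range_latitude_rejected(self):
        with pytest.raises(FragdivError):
            PopulationMeta("a", 91.0, 0.0, "10-100")


def brute_force_mantel(genetic, geographic, log_distance=True):
    """Exhaustive-permutation Mantel p-value by direct enumeration."""
    g = np.asarray(genetic, float)
    d = np.asarray(geographic, float)
    n = g.shape[0]
    if log_distance:
        iu = np.triu_indices(n, 1)
        dd = d.copy()
        dd[iu] = np.log(d[iu])
        dd.T[iu] = dd[iu]
        d = dd
    iu = np.triu_indices(n, 1)
    x = d[iu]

    def corr(mat):
        return np.corrcoef(x, mat[iu])[0, 1]

    r_obs = corr(g)
    count = sum(
        1 for perm in itertools.permutations(range(n))
        if corr(g[np.ix_(perm, perm)]) >= r_obs - 1e-12)
    total = math.factorial(n)
    return r_obs, (1 + count) / (1 + total)


class TestMantel:
    def _matrices(self, seed=13, n=5):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 10, size=(n, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1)) + 0.1
        np.fill_diagonal(d, 0.0)
        g = d * rng.uniform(0.5, 1.5) + rng.normal(0, 1, size=(n, n))
        g = (g + g.T) / 2
        np.fill_diagonal(g, 0.0)
        return g, d

    def test_identical_matrices_give_r_one(self):
        _, d = self._matrices()
        logd = np.zeros_like(d)
        iu = np.triu_indices(5, 1)
        logd[iu] = np.log(d[iu])
        logd.T[iu] = logd[iu]
        r, _ = mantel_test(logd, d, log_distance=True, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_negated_matrix_gives_r_minus_one(self):
        _, d = self._matrices()
        logd = np.zeros_like(d)
        iu = np.triu_indices(5, 1)
        logd[iu] = -np.log(d[iu])
        logd.T[iu] = logd[iu]
        r, _ = mantel_test(logd, d, log_distance=True, n_perm=99, seed=0)
        assert r == pytest.approx(-1.0)

    def test_exhaustive_mode_matches_enumeration(self):
        g, d = self._matrices(seed=21)
        r_want, p_want = brute_force_mantel(g, d)
        r, p = mantel_test(g, d, exhaustive=True)
        assert r == pytest.approx(r_want)
        assert p == pytest.approx(p_want)

    def test_zero_distance_under_log_rejected(self):
        g, d = self._matrices()
        d[0, 1] = d[1, 0] = 0.0
        with pytest.raises(FragdivError, match="log"):
            mantel_test(g, d, log_distance=True)

    def test_too_few_populations_rejected(self):
        m = np.zeros((3, 3))
        with pytest.raises(FragdivError, match=">= 4"):
            mantel_test(m, m + 1 - np.eye(3), log_distance=False)


class TestDiversityTable:
    def test_small_populations_excluded_from_region_rows(self):
        rng = np.random.default_rng(3)
        freqs = [rng.dirichlet([1.0] * 4) for _ in range(10)]
        gm = simulate_balding_nichols(freqs, [0.1, 0.1, 0.1], [20, 20, 2],
                                      seed=3, region="fragmented")
        table = diversity_table(gm, g_copies=10, min_individuals=5)
        flags = dict(zip(table["population"], table["excluded"]))
        assert flags["P3"] and not flags["P1"]
        region = table[table["population"] == "region:fragmented"].iloc[0]
        assert region["n_individuals"] == 40  # P3's two plants left out

    def test_richness_never_exceeds_observed_alleles(self, bn_matrix):
        table = diversity_table(bn_matrix, g_copies=10)
        pops = table[~table["population"].str.startswith("region:")]
        assert (pops["A_r"] <= pops["n_alleles"]).all()
        assert ((0 <= pops["H_e"]) & (pops["H_e"] <= 1)).all()
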