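"""SNP filtering, Weir-Cockerham FST, diversity, PCA, Mantel."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pial.popgen import (
    expected_heterozygosity,
    filter_genotypes,
    genotype_pca,
    mantel_test,
    nucleotide_diversity,
    utm_distance_matrix,
    weir_cockerham_fst,
)
from tests.conftest import island_model_matrix, make_genotype_matrix, wc_theta_oracle


class TestFilter:
    def test_locus_presence_threshold(self):
        calls = np.ones((10, 1))
        calls[:3, 0] = np.nan  # called in 7/10 < 0.8
        gm = make_genotype_matrix([calls[:5].tolist(), calls[5:].tolist()])
        with pytest.raises(ValueError, match="all loci removed"):
            filter_genotypes(gm, min_maf=0.0)

    def test_maf_threshold_recomputed(self):
        # locus 1: maf 0.01 (1 minor copy in 50 diploids); locus 2: common
        calls = np.zeros((50, 2))
        calls[0, 0] = 1.0
        calls[:25, 1] = 1.0
        gm = make_genotype_matrix([calls[:25].tolist(), calls[25:].tolist()])
        out, report = filter_genotypes(gm, min_maf=0.02)
        assert out.loci["locus_id"].tolist() == ["L2_1"]
        assert report.set_index("step").loc["maf", "n_removed"] == 1

    def test_one_snp_per_parent_locus_counts(self):
        # parents with 2, 1, 3 SNPs -> 3 kept, lowest position wins
        ids = ["A_5", "A_2", "B_1", "C_9", "C_3", "C_7"]
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 3, (12, 6)).astype(float)
        gm = make_genotype_matrix([calls[:6].tolist(), calls[6:].tolist()], locus_ids=ids)
        out, _ = filter_genotypes(gm, min_maf=0.0)
        assert sorted(out.loci["locus_id"]) == ["A_2", "B_1", "C_3"]

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        calls = rng.integers(0, 3, (30, 20)).astype(float)
        calls[rng.random(calls.shape) < 0.1] = np.nan
        gm = make_genotype_matrix([calls[:15].tolist(), calls[15:].tolist()])
        once, _ = filter_genotypes(gm)
        twice, report = filter_genotypes(once)
        assert np.array_equal(once.calls, twice.calls, equal_nan=True)
        assert report["n_removed"].sum() == 0

    def test_individual_presence_filter(self):
        calls = np.ones((6, 10))
        calls[0, :9] = np.nan
        gm = make_genotype_matrix([calls[:3].tolist(), calls[3:].tolist()])
        out, report = filter_genotypes(
            gm, min_individual_presence=0.5, min_locus_presence=0.0, min_maf=0.0
        )
        assert out.n_individuals == 5
        assert report.set_index("step").loc["individual_presence", "n_removed"] == 1


class TestFst:
    def test_hand_computed_toy(self):
        # 2 sites x 10 diploids, minor counts 4 vs 16
        popA = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        popB = [2, 2, 2, 2, 2, 2, 1, 1, 1, 1]
        res = weir_cockerham_fst(make_genotype_matrix([popA, popB]), n_boot=10, seed=0)
        assert res.theta_global == pytest.approx(wc_theta_oracle([popA, popB]), abs=1e-12)

    def test_fixed_alternate_alleles_theta_one(self):
        res = weir_cockerham_fst(make_genotype_matrix([[0] * 10, [2] * 10]), n_boot=10, seed=0)
        assert res.theta_global == pytest.approx(1.0)

    def test_identical_frequencies_theta_near_zero(self):
        rng = np.random.default_rng(3)
        calls = rng.binomial(2, 0.4, size=(200, 80)).astype(float)
        gm = make_genotype_matrix([calls[:100].tolist(), calls[100:].tolist()])
        res = weir_cockerham_fst(gm, n_boot=10, seed=0)
        assert abs(res.theta_global) < 0.01

    @pytest.mark.parametrize("seed", range(4))
    def test_single_locus_three_pop_matches_oracle(self, seed):
        # each single-locus theta must equal the scalar 1984 oracle; the
        # multi-locus aggregate is a ratio of sums, not a mean of these
        rng = np.random.default_rng(seed)
        pops = [rng.integers(0, 3, size=(8, 3)).tolist() for _ in range(3)]
        for j in range(3):
            per_pop = [[row[j] for row in p] for p in pops]
            got = weir_cockerham_fst(
                make_genotype_matrix([[[v] for v in p] for p in per_pop]),
                n_boot=10,
                seed=0,
            ).theta_global
            assert got == pytest.approx(wc_theta_oracle(per_pop), abs=1e-12)

    def test_pairwise_matrix_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(2)
        gm = island_model_matrix(rng, 0.1, n_sites=4, n_ind=8, n_loci=60)
        res = weir_cockerham_fst(gm, n_boot=10, seed=0)
        m = res.pairwise.to_numpy()
        assert np.allclose(m, m.T)
        assert np.all(np.diag(m) == 0)

    def test_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(5)
        gm = island_model_matrix(rng, 0.08, n_loci=200)
        res = weir_cockerham_fst(gm, n_boot=300, seed=1)
        assert res.ci_low <= res.theta_global <= res.ci_high


class TestDiversity:
    def test_uhe_closed_form(self):
        # p = 0.5, n = 10 -> (20/19) * 0.5
        pop = [0, 0, 0, 1, 1, 1, 1, 2, 2, 2]  # 10 copies of minor allele in 20
        gm = make_genotype_matrix([pop, [0] * 5])
        out = expected_heterozygosity(gm)
        assert out.set_index("site_id").loc["P0", "uhe"] == pytest.approx(20 / 19 * 0.5)

    def test_monomorphic_contributes_zero(self):
        gm = make_genotype_matrix([[2, 2, 2], [0, 0, 0]])
        out = expected_heterozygosity(gm)
        assert (out["uhe"] == 0.0).all()

    def test_uhe_exceeds_he_for_finite_n(self):
        rng = np.random.default_rng(1)
        pop = rng.binomial(2, 0.3, 12).tolist()
        gm = make_genotype_matrix([pop])
        uhe = expected_heterozygosity(gm).loc[0, "uhe"]
        p = np.sum(pop) / 24
        he = 1 - p**2 - (1 - p) ** 2
        if 0 < p < 1:
            assert uhe > he

    def test_pi_equals_uhe_per_site_definition(self):
        rng = np.random.default_rng(2)
        calls = rng.binomial(2, 0.35, size=(20, 15)).astype(float)
        gm = make_genotype_matrix([calls[:10].tolist(), calls[10:].tolist()])
        he = expected_heterozygosity(gm)
        pi = nucleotide_diversity(gm)
        np.testing.assert_allclose(he["uhe"], pi["pi"])


class TestPCA:
    def test_identical_individuals_zero_eigenvalues(self):
        calls = np.tile([0.0, 1.0, 2.0, 1.0], (8, 1))
        gm = make_genotype_matrix([calls[:4].tolist(), calls[4:].tolist()])
        res = genotype_pca(gm)
        assert res.percent_variance.size == 0 or np.allclose(res.percent_variance, 0)

    def test_two_clusters_single_axis(self):
        a = [0.0, 0.0, 2.0]
        b = [2.0, 2.0, 0.0]
        gm = make_genotype_matrix([[a] * 5, [b] * 5])
        res = genotype_pca(gm, n_axes=3)
        assert res.percent_variance[0] == pytest.approx(100.0)
        s = res.scores[:, 0]
        assert (s[:5] * s[5:] < 0).all()  # clusters on opposite sides

    def test_small_matrix_matches_eigendecomposition(self):
        calls = np.array([[0, 2], [1, 1], [2, 0], [1, 2.0]])
        gm = make_genotype_matrix([calls[:2].tolist(), calls[2:].tolist()])
        res = genotype_pca(gm, n_axes=2)
        X = calls - calls.mean(axis=0)
        evals, evecs = np.linalg.eigh(X.T @ X)
        order = np.argsort(evals)[::-1]
        expected_scores = X @ evecs[:, order]
        for k in range(res.scores.shape[1]):
            got, want = res.scores[:, k], expected_scores[:, k]
            assert np.allclose(got, want, atol=1e-10) or np.allclose(got, -want, atol=1e-10)

    def test_locus_order_invariance_up_to_sign(self):
        rng = np.random.default_rng(4)
        calls = rng.integers(0, 3, (12, 9)).astype(float)
        gm1 = make_genotype_matrix([calls[:6].tolist(), calls[6:].tolist()])
        perm = rng.permutation(9)
        gm2 = make_genotype_matrix(
            [calls[:6, perm].tolist(), calls[6:, perm].tolist()]
        )
        r1 = genotype_pca(gm1, n_axes=3)
        r2 = genotype_pca(gm2, n_axes=3)
        np.testing.assert_allclose(r1.percent_variance, r2.percent_variance, atol=1e-9)
        for k in range(3):
            a, b = r1.scores[:, k], r2.scores[:, k]
            assert np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8)


class TestMantel:
    def test_proportional_matrices_r_one(self):
        rng = np.random.default_rng(0)
        x = rng.random((6, 6))
        d = (x + x.T) / 2
        np.fill_diagonal(d, 0)
        r, p = mantel_test(d, 3.0 * d, n_perm=99, seed=1)
        assert r == pytest.approx(1.0)

    def test_minimum_p_with_999_permutations(self):
        pts = np.arange(8.0).reshape(-1, 1)
        d = np.abs(pts - pts.T)
        r, p = mantel_test(d, d * 2.0, n_perm=999, seed=1)
        assert p == pytest.approx(1 / 1000)

    def test_constant_matrix_errors(self):
        d = np.ones((5, 5)) - np.eye(5)
        geo = np.abs(np.arange(5.0).reshape(-1, 1) - np.arange(5.0))
        with pytest.raises(ValueError, match="constant"):
            mantel_test(d, geo, n_perm=99, seed=1)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(2)
        a = rng.random((7, 7))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        b = rng.random((7, 7))
        b = (b + b.T) / 2
        np.fill_diagonal(b, 0)
        assert mantel_test(a, b, seed=5) == mantel_test(a, b, seed=5)

    def test_agrees_with_skbio_oracle(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(3)
        a = rng.random((9, 9))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        b = a * 2 + rng.random((9, 9)) * 0.0
        r_ours, _ = mantel_test(a, b, n_perm=99, seed=1)
        r_skbio, _, _ = skbio_distance.mantel(
            skbio_distance.DistanceMatrix(a),
            skbio_distance.DistanceMatrix(b),
            permutations=0,
        )
        assert r_ours == pytest.approx(r_skbio, abs=1e-10)


def test_utm_distance_matrix():
    sites = pd.DataFrame({"site_id": ["a", "b"], "utm_e": [0.0, 3.0], "utm_n": [0.0, 4.0]})
    d = utm_distance_matrix(sites)
    assert d[0, 1] == pytest.approx(5.0)
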