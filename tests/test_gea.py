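"""Imputation, VIF forward selection, partial RDA, outliers, linkage."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pial.gea import (
    detect_outlier_loci,
    impute_most_common,
    link_scores_to_phenotype,
    partial_rda,
    rda_permutation_tests,
    vif_forward_select,
    _vifs,
)
from tests.conftest import make_genotype_matrix


class TestImpute:
    def test_mode_fill(self):
        gm = make_genotype_matrix([[0.0, 0.0, 1.0], [np.nan, 1.0, 1.0]])
        X, frac = impute_most_common(gm)
        assert X[1, 0] == 0.0  # mode of {0, 0} is 0
        assert frac == pytest.approx(1 / 6)

    def test_tie_resolves_to_lower_dosage(self):
        gm = make_genotype_matrix([[0.0], [0.0], [2.0], [2.0], [np.nan], [1.0]])
        X, _ = impute_most_common(gm)
        assert X[4, 0] == 0.0

    def test_fully_missing_locus_errors(self):
        gm = make_genotype_matrix([[np.nan], [np.nan]])
        with pytest.raises(ValueError, match="no calls"):
            impute_most_common(gm)

    def test_imputed_fraction_equals_missing_rate(self):
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 3, (20, 10)).astype(float)
        mask = rng.random(calls.shape) < 0.15
        mask[:, mask.all(axis=0)] = False
        calls[mask] = np.nan
        gm = make_genotype_matrix([calls[:10].tolist(), calls[10:].tolist()])
        _, frac = impute_most_common(gm)
        assert frac == pytest.approx(mask.mean())


class TestForwardSelection:
    def test_two_orthogonal_informative_predictors(self):
        rng = np.random.default_rng(1)
        n = 120
        a = np.repeat(rng.standard_normal(12), 10)
        b = np.repeat(rng.standard_normal(12), 10)
        Y = np.outer(a, rng.standard_normal(30)) * 0.4 + np.outer(
            b, rng.standard_normal(30)
        ) * 0.4 + rng.standard_normal((n, 30))
        sel = vif_forward_select(pd.DataFrame({"a": a, "b": b}), Y, n_perm=99, seed=0)
        assert set(sel.selected) == {"a", "b"}
        assert all(v == pytest.approx(1.0, abs=0.3) for v in sel.vifs.values())

    def test_duplicated_predictor_never_enters(self):
        rng = np.random.default_rng(2)
        n = 100
        a = rng.standard_normal(n)
        Y = np.outer(a, rng.standard_normal(20)) * 0.5 + rng.standard_normal((n, 20))
        sel = vif_forward_select(
            pd.DataFrame({"a": a, "a_copy": a.copy()}), Y, n_perm=99, seed=0
        )
        assert len(sel.selected) == 1

    def test_pure_noise_selects_nothing_usually(self):
        rng = np.random.default_rng(3)
        Y = rng.standard_normal((80, 10))
        cand = pd.DataFrame(rng.standard_normal((80, 3)), columns=list("abc"))
        sel = vif_forward_select(cand, Y, n_perm=99, seed=0)
        assert len(sel.selected) <= 1  # at most a type-I entry

    def test_vif_of_exact_copy_infinite(self):
        x = np.random.default_rng(0).standard_normal(50)
        v = _vifs(np.column_stack([x, x]))
        assert np.isinf(v).all()


class TestPartialRDA:
    def test_y_equals_x_single_axis_full_r2(self):
        x = np.random.default_rng(0).standard_normal(20)
        rda = partial_rda(x.reshape(-1, 1), pd.DataFrame({"x": x}))
        assert rda.r2 == pytest.approx(1.0)
        assert rda.r2_adj == pytest.approx(1.0)
        assert rda.n_axes == 1

    def test_x_in_span_of_z_zero_constrained_variance(self):
        rng = np.random.default_rng(1)
        Z = rng.standard_normal((15, 2))
        X = pd.DataFrame({"x": Z @ [1.5, -0.5]})
        rda = partial_rda(rng.standard_normal((15, 5)), X, Z)
        assert rda.n_axes == 0 and rda.r2 == 0.0

    def test_rank_deficient_predictors_error(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(15)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="rank-deficient"):
            partial_rda(rng.standard_normal((15, 4)), X)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_brute_force_normal_equations(self, trial):
        """Axis eigenvalues/scores equal an explicit projection + eigh oracle."""
        rng = np.random.default_rng(100 + trial)
        n, L, m, g = 12, 6, 2, 1
        Y = rng.standard_normal((n, L))
        X = rng.standard_normal((n, m))
        Z = rng.standard_normal((n, g))
        rda = partial_rda(Y, pd.DataFrame(X, columns=["a", "b"]), Z)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        Zs = (Z - Z.mean(0)) / Z.std(0, ddof=1)
        C = np.column_stack([np.ones(n), Zs])
        P = C @ np.linalg.inv(C.T @ C) @ C.T
        Yr, Xr = Y - P @ Y, Xs - P @ Xs
        F = Xr @ np.linalg.inv(Xr.T @ Xr) @ Xr.T @ Yr
        eig = np.sort(np.linalg.eigvalsh(F.T @ F / (n - 1)))[::-1][: rda.n_axes]
        np.testing.assert_allclose(rda.eigenvalues, eig, atol=1e-8)
        assert rda.eigenvalues.sum() == pytest.approx(
            np.trace(F.T @ F) / (n - 1), abs=1e-8
        )
        # non-increasing eigenvalues
        assert np.all(np.diff(rda.eigenvalues) <= 1e-12)

    def test_empty_z_equals_plain_rda(self):
        rng = np.random.default_rng(3)
        Y = rng.standard_normal((18, 5))
        X = pd.DataFrame({"x": rng.standard_normal(18)})
        a = partial_rda(Y, X, None)
        b = partial_rda(Y, X, np.zeros((18, 0)))
        np.testing.assert_allclose(a.eigenvalues, b.eigenvalues)

    def test_indicator_x_reproduces_between_group_structure(self):
        """With group-indicator predictors the fitted values are group means."""
        rng = np.random.default_rng(4)
        groups = np.repeat([0, 1, 2], 6)
        Y = rng.standard_normal((18, 4)) + groups[:, None] * 0.5
        X = pd.DataFrame({"g1": (groups == 1).astype(float), "g2": (groups == 2).astype(float)})
        rda = partial_rda(Y, X)
        Yc = Y - Y.mean(0)
        M = np.vstack([Yc[groups == g].mean(0) for g in range(3)])[groups]
        eig = np.sort(np.linalg.eigvalsh(M.T @ M / (18 - 1)))[::-1][: rda.n_axes]
        np.testing.assert_allclose(rda.eigenvalues, eig, atol=1e-8)


class TestPermutation:
    def test_strong_signal_minimum_p(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(25)
        Y = np.outer(x, rng.standard_normal(6))
        rda = rda_permutation_tests(Y, pd.DataFrame({"x": x}), n_perm=99, seed=1)
        assert rda.p_full == pytest.approx(1 / 100)
        assert rda.p_axes[0] == pytest.approx(1 / 100)

    def test_seed_reproducible(self):
        rng = np.random.default_rng(1)
        Y = rng.standard_normal((20, 5))
        X = pd.DataFrame({"x": rng.standard_normal(20)})
        a = rda_permutation_tests(Y, X, n_perm=99, seed=3)
        b = rda_permutation_tests(Y, X, n_perm=99, seed=3)
        assert a.p_full == b.p_full
        np.testing.assert_array_equal(a.p_axes, b.p_axes)
        assert a.p_terms == b.p_terms

    def test_too_few_permutations_refused(self):
        with pytest.raises(ValueError, match="n_perm"):
            rda_permutation_tests(np.zeros((10, 2)), pd.DataFrame({"x": np.arange(10.0)}), n_perm=50)


class TestOutliers:
    def _rda_with(self, Y, X, Z=None):
        return partial_rda(Y, X, Z)

    def test_planted_cwd_locus_flagged_and_assigned(self):
        rng = np.random.default_rng(5)
        n, L = 60, 40
        cwd = np.repeat(rng.standard_normal(12), 5)
        tmn = np.repeat(rng.standard_normal(12), 5)
        Y = rng.standard_normal((n, L)) * 0.3
        Y[:, 7] = 1.5 * cwd + rng.standard_normal(n) * 0.1  # strong CWD locus
        X = pd.DataFrame({"CWD": cwd, "Tmn": tmn})
        rda = self._rda_with(Y, X)
        out = detect_outlier_loci(rda, Y, X, sd_mult=3, axes=[0, 1])
        assert 7 in out.table["locus_id"].tolist()
        row = out.table[out.table["locus_id"] == 7].iloc[0]
        assert row["assigned_variable"] == "CWD"

    def test_huge_sd_mult_empty(self):
        rng = np.random.default_rng(6)
        Y = rng.standard_normal((30, 20))
        X = pd.DataFrame({"x": rng.standard_normal(30)})
        rda = self._rda_with(Y, X)
        out = detect_outlier_loci(rda, Y, X, sd_mult=1e6, axes=[0])
        assert out.table.empty

    def test_empty_axis_set_empty_result(self):
        rng = np.random.default_rng(7)
        Y = rng.standard_normal((30, 20))
        X = pd.DataFrame({"x": rng.standard_normal(30)})
        rda = self._rda_with(Y, X)
        out = detect_outlier_loci(rda, Y, X, axes=[])
        assert out.table.empty and out.axes == []


class TestPhenotypeLink:
    def test_monotone_phenotype_perfect_rs(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(30)
        Y = np.outer(x, rng.standard_normal(8)) + rng.standard_normal((30, 8)) * 0.01
        rda = partial_rda(Y, pd.DataFrame({"x": x}))
        ids = np.array([f"t{i}" for i in range(30)])
        phen = pd.Series(np.exp(rda.individual_scores[:, 0]), index=ids)
        out = link_scores_to_phenotype(rda, ids, phen)
        assert out.loc[0, "r_s"] == pytest.approx(1.0)

    def test_too_few_overlapping_errors(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(10)
        Y = np.outer(x, rng.standard_normal(4))
        rda = partial_rda(Y, pd.DataFrame({"x": x}))
        ids = np.array([f"t{i}" for i in range(10)])
        phen = pd.Series([1.0, 2.0], index=["t0", "t1"])
        with pytest.raises(ValueError, match="overlapping"):
            link_scores_to_phenotype(rda, ids, phen)
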