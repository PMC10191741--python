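"""SNP filtering and population-genomic summary statistics.

Implements the differentiation and diversity layer of the pipeline:

* genotype filtering (locus call rate, one SNP per parent locus, minor
  allele frequency, optional individual call rate), with a per-step
  attrition report;
* Weir & Cockerham (1984) theta via per-locus variance components
  (a, b, c) aggregated ratio-of-sums, globally and pairwise between
  sites, with a seeded percentile bootstrap over loci for the global CI;
* unbiased expected heterozygosity uHe = (2n/(2n-1)) (1 - p^2 - q^2)
  and per-variant-site nucleotide diversity pi (identical to uHe under
  the biallelic per-site definition used here);
* genotype PCA (mean-dosage imputation, centered SVD);
* a Mantel test of isolation by distance (seeded, vectorized over
  permutations, one-sided "greater" p).

Negative theta estimates are reported as computed, not truncated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pial.dataio import GenotypeMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def filter_genotypes(
    gm: GenotypeMatrix,
    min_locus_presence: float = 0.8,
    min_maf: float = 0.02,
    one_snp_per_locus: bool = True,
    min_individual_presence: float | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply the standard SNP filters in order and report attrition.

    Order: individual call rate (if requested) -> locus call rate ->
    one SNP per parent locus (lowest position wins) -> minor allele
    frequency recomputed on the filtered matrix.  Returns the filtered
    matrix and a table of counts removed at each step.
    """
    steps = []
    out = gm

    if min_individual_presence is not None:
        called = 1.0 - np.isnan(out.calls).mean(axis=1)
        keep = called >= min_individual_presence
        steps.append(("individual_presence", int((~keep).sum())))
        out = out.subset(rows=keep)

    called = 1.0 - np.isnan(out.calls).mean(axis=0)
    keep = called >= min_locus_presence
    steps.append(("locus_presence", int((~keep).sum())))
    out = out.subset(cols=keep)

    if one_snp_per_locus:
        if "parent_locus" not in out.loci.columns:
            raise ValueError("one_snp_per_locus requires parent_locus metadata")
        order = out.loci.reset_index().sort_values(["parent_locus", "position", "index"])
        first = order.groupby("parent_locus", sort=False)["index"].first()
        keep_idx = np.sort(first.to_numpy())
        steps.append(("one_snp_per_locus", out.n_loci - keep_idx.size))
        out = out.subset(cols=keep_idx)

    with np.errstate(invalid="ignore"):
        p = np.nanmean(out.calls, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    keep = maf >= min_maf
    keep &= ~np.isnan(maf)
    steps.append(("maf", int((~keep).sum())))
    out = out.subset(cols=keep)

    report = pd.DataFrame(steps, columns=["step", "n_removed"])
    if out.n_loci == 0:
        raise ValueError(f"all loci removed by filters:\n{report}")
    return out, report


# ---------------------------------------------------------------------------
# Weir & Cockerham theta
# ---------------------------------------------------------------------------


def _wc_components(
    calls: np.ndarray, site_codes: np.ndarray, n_sites: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus W&C (1984) variance components a (among populations),
    b (among individuals within populations), c (within individuals).

    ``calls`` is individuals x loci with NaN missing; loci with fewer
    than two populations observed yield NaN components.
    """
    L = calls.shape[1]
    obs = ~np.isnan(calls)
    # per (site, locus) sample size, allele count, het count
    n_il = np.zeros((n_sites, L))
    sum_il = np.zeros((n_sites, L))
    het_il = np.zeros((n_sites, L))
    for s in range(n_sites):
        rows = site_codes == s
        sub = calls[rows, :]
        ob = obs[rows, :]
        n_il[s] = ob.sum(axis=0)
        sum_il[s] = np.where(ob, sub, 0.0).sum(axis=0)
        het_il[s] = np.where(ob, sub == 1.0, False).sum(axis=0)

    present = n_il > 0
    r = present.sum(axis=0).astype(float)  # populations observed per locus
    with np.errstate(invalid="ignore", divide="ignore"):
        p_il = np.where(present, sum_il / (2.0 * n_il), 0.0)
        h_il = np.where(present, het_il / np.where(n_il > 0, n_il, 1.0), 0.0)
        n_tot = n_il.sum(axis=0)
        nbar = n_tot / r
        nc = (n_tot - (n_il**2).sum(axis=0) / n_tot) / (r - 1.0)
        pbar = (n_il * p_il).sum(axis=0) / n_tot
        s2 = (n_il * (p_il - pbar) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = (n_il * h_il).sum(axis=0) / n_tot

        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1.0))
            * (pbar * (1 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar)
            - ((r - 1.0) / r) * s2
            - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0

    bad = (r < 2) | (nbar <= 1) | ~np.isfinite(nc) | (nc <= 0)
    a[bad] = np.nan
    b[bad] = np.nan
    c[bad] = np.nan
    return a, b, c


def _theta_from_components(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    denom = np.sum(a[ok] + b[ok] + c[ok])
    if denom == 0:
        return np.nan
    return float(np.sum(a[ok]) / denom)


@dataclass
class FstResult:
    """Global and pairwise Weir-Cockerham theta with a bootstrap CI."""

    theta_global: float
    ci_low: float
    ci_high: float
    pairwise: pd.DataFrame  # symmetric site x site matrix
    n_loci: int
    n_boot: int
    estimator: str = "weir_cockerham_1984_ratio_of_sums"


def weir_cockerham_fst(
    gm: GenotypeMatrix,
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> FstResult:
    """Weir & Cockerham theta across the matrix's sites.

    Global theta is the ratio of summed per-locus components
    sum(a)/sum(a+b+c); the CI is a seeded percentile bootstrap over
    loci.  Pairwise theta is computed for every site pair the same way.
    Sites with fewer than two called individuals at every locus are
    excluded with a warning.  Negative estimates are reported as
    computed (flagged by sign, not truncated).
    """
    site_ids = np.array(sorted(set(gm.individuals["site_id"])))
    codes = pd.Categorical(
        gm.individuals["site_id"], categories=site_ids
    ).codes.astype(int)

    # drop sites that never reach 2 called individuals
    ok_sites = []
    for s, sid in enumerate(site_ids):
        n_called = (~np.isnan(gm.calls[codes == s, :])).sum(axis=0)
        if (n_called >= 2).any():
            ok_sites.append(s)
        else:
            logger.warning("site %s: <2 called individuals at every locus; excluded", sid)
    if len(ok_sites) < 2:
        raise ValueError("need >= 2 usable sites for FST")
    if len(ok_sites) < len(site_ids):
        keep_rows = np.isin(codes, ok_sites)
        gm = gm.subset(rows=keep_rows)
        site_ids = site_ids[ok_sites]
        codes = pd.Categorical(gm.individuals["site_id"], categories=site_ids).codes.astype(int)

    a, b, c = _wc_components(gm.calls, codes, len(site_ids))
    theta = _theta_from_components(a, b, c)

    rng = np.random.default_rng(seed)
    ok = np.isfinite(a)
    ai, bi, ci_ = a[ok], b[ok], c[ok]
    L = ai.size
    boots = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, L, size=L)
        denom = np.sum(ai[idx] + bi[idx] + ci_[idx])
        boots[i] = np.sum(ai[idx]) / denom if denom != 0 else np.nan
    alpha = 1.0 - ci
    lo, hi = np.nanpercentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])

    n_sites = len(site_ids)
    pw = np.zeros((n_sites, n_sites))
    for i in range(n_sites):
        for j in range(i + 1, n_sites):
            rows = np.isin(codes, [i, j])
            sub_codes = (codes[rows] == j).astype(int)
            aa, bb, cc = _wc_components(gm.calls[rows, :], sub_codes, 2)
            pw[i, j] = pw[j, i] = _theta_from_components(aa, bb, cc)
    pairwise = pd.DataFrame(pw, index=site_ids, columns=site_ids)

    return FstResult(
        theta_global=theta,
        ci_low=float(lo),
        ci_high=float(hi),
        pairwise=pairwise,
        n_loci=int(ok.sum()),
        n_boot=n_boot,
    )


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------


def _per_site_uhe(calls: np.ndarray, codes: np.ndarray, n_sites: int) -> np.ndarray:
    """uHe per (site, locus); NaN where fewer than 2 called individuals."""
    L = calls.shape[1]
    out = np.full((n_sites, L), np.nan)
    for s in range(n_sites):
        sub = calls[codes == s, :]
        n = (~np.isnan(sub)).sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.nansum(sub, axis=0) / (2.0 * n)
            uhe = (2.0 * n / (2.0 * n - 1.0)) * (1.0 - p**2 - (1.0 - p) ** 2)
        uhe[n < 2] = np.nan
        out[s] = uhe
    return out


def expected_heterozygosity(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-site unbiased expected heterozygosity, mean +/- SE over loci.

    uHe = (2n/(2n-1)) (1 - p^2 - q^2) per locus with n the called
    diploids at that site; monomorphic loci contribute 0.  Also reports
    the missing-adjusted mean sample size per site.
    """
    site_ids = np.array(sorted(set(gm.individuals["site_id"])))
    codes = pd.Categorical(gm.individuals["site_id"], categories=site_ids).codes.astype(int)
    uhe = _per_site_uhe(gm.calls, codes, len(site_ids))
    rows = []
    for s, sid in enumerate(site_ids):
        v = uhe[s][np.isfinite(uhe[s])]
        n_called = (~np.isnan(gm.calls[codes == s, :])).sum(axis=0)
        rows.append(
            {
                "site_id": sid,
                "uhe": float(v.mean()) if v.size else np.nan,
                "uhe_se": float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else np.nan,
                "mean_sample_size": float(n_called.mean()),
                "n_loci": int(v.size),
            }
        )
    return pd.DataFrame(rows)


def nucleotide_diversity(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-site pi over variant sites, mean +/- SE.

    With one biallelic variant per column, per-site pi at a variant
    site is (2n/(2n-1)) 2 p q — the same quantity as uHe; the two
    diverge only under haplotype-wise multi-site definitions that are
    out of scope here.
    """
    out = expected_heterozygosity(gm)
    return out.rename(columns={"uhe": "pi", "uhe_se": "pi_se"})


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    scores: np.ndarray  # individuals x axes
    percent_variance: np.ndarray
    loadings: np.ndarray  # loci x axes
    n_loci: int


def genotype_pca(gm: GenotypeMatrix, n_axes: int = 10, scale: bool = False) -> PCAResult:
    """PCA of the dosage matrix via SVD.

    Missing calls are imputed to the per-locus mean dosage; columns are
    centered (and optionally scaled to unit variance).  Percent
    variance is the eigenvalue share of total variance.
    """
    X = gm.calls.copy()
    mu = np.nanmean(X, axis=0)
    nan_r, nan_c = np.where(np.isnan(X))
    X[nan_r, nan_c] = mu[nan_c]
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(S > S[0] * 1e-12)) if S.size else 0
    if n_axes > rank:
        logger.info("requested %d axes but rank is %d; truncating", n_axes, rank)
        n_axes = rank
    ev = S**2
    pct = 100.0 * ev / ev.sum() if ev.sum() > 0 else np.zeros_like(ev)
    return PCAResult(
        scores=U[:, :n_axes] * S[:n_axes],
        percent_variance=pct[:n_axes],
        loadings=Vt[:n_axes].T,
        n_loci=gm.n_loci,
    )


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------


def mantel_test(
    d_gen: np.ndarray,
    d_geo: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices with one-sided p.

    r is the Pearson correlation over strictly-lower-triangle entries;
    the permutation null jointly permutes rows and columns of the
    genetic matrix, p = (1 + #{r_perm >= r_obs}) / (n_perm + 1).
    """
    d_gen = np.asarray(d_gen, dtype=float)
    d_geo = np.asarray(d_geo, dtype=float)
    n = d_gen.shape[0]
    if d_gen.shape != (n, n) or d_geo.shape != (n, n):
        raise ValueError("matrices must be square and same shape")
    if n < 4:
        raise ValueError("need >= 4 sites for a Mantel test")
    if not (np.allclose(d_gen, d_gen.T) and np.allclose(d_geo, d_geo.T)):
        raise ValueError("matrices must be symmetric")
    il, jl = np.tril_indices(n, k=-1)
    x = d_gen[il, jl]
    y = d_geo[il, jl]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant distance matrix; Mantel r undefined")
    yc = y - y.mean()
    y_norm = np.linalg.norm(yc)

    def corr(v: np.ndarray) -> float:
        vc = v - v.mean()
        return float(vc @ yc / (np.linalg.norm(vc) * y_norm))

    r_obs = corr(x)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        xp = d_gen[np.ix_(perm, perm)][il, jl]
        if corr(xp) >= r_obs - 1e-12:
            count += 1
    p = (1.0 + count) / (n_perm + 1.0)
    return r_obs, p


def utm_distance_matrix(sites: pd.DataFrame) -> np.ndarray:
    """Pairwise Euclidean distance (m) from site UTM easting/northing."""
    xy = sites[["utm_e", "utm_n"]].to_numpy(dtype=float)
    diff = xy[:, None, :] - xy[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))
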