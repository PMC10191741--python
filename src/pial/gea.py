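"""Genotype-environment association via partial redundancy analysis.

The association model is the two-step constrained ordination: genotype
dosages (individuals x loci) are regressed on site-level climate
normals expanded to individuals, after both sides are residualized on a
conditioning matrix of geographic coordinates (UTM northing + easting)
to control for spatial structure; a PCA (SVD) of the fitted values
yields the constrained axes.  Putatively adaptive loci are those whose
loading on a significant axis lies more than ``sd_mult`` standard
deviations from that axis's mean loading; each outlier is assigned the
climate variable with which its dosage is most strongly correlated.

Inference is by permutation: rows of the residualized genotype matrix
are shuffled (residuals-under-reduced-model scheme) and the pseudo-F
recomputed, for the full model, each sequential axis, and each marginal
term.  Predictor screening uses greedy forward selection on adjusted
R^2 with a permutation entry test and a variance inflation factor cap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pial.dataio import GenotypeMatrix
from pial.drought import correlate

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------


def impute_most_common(gm: GenotypeMatrix) -> tuple[np.ndarray, float]:
    """Replace missing calls with the locus's modal genotype.

    Ties between modes resolve to the lower dosage.  Returns the dense
    dosage matrix and the fraction of cells imputed.
    """
    X = gm.calls.copy()
    missing = np.isnan(X)
    if missing.all(axis=0).any():
        bad = gm.loci.loc[missing.all(axis=0), "locus_id"]
        raise ValueError(f"loci with no calls at all: {list(bad[:5])}")
    # counts of dosage 0/1/2 per locus; argmax returns the lowest on ties
    counts = np.stack([(X == d).sum(axis=0) for d in (0.0, 1.0, 2.0)])
    mode = counts.argmax(axis=0).astype(float)
    r, c = np.where(missing)
    X[r, c] = mode[c]
    return X, float(missing.mean())


# ---------------------------------------------------------------------------
# linear algebra helpers
# ---------------------------------------------------------------------------


def _residualize(M: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Residuals of each column of M on the column space of C."""
    coef, *_ = np.linalg.lstsq(C, M, rcond=None)
    return M - C @ coef


def _standardize(M: np.ndarray) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    sd = M.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant column cannot be standardized")
    return (M - M.mean(axis=0)) / sd


# ---------------------------------------------------------------------------
# partial RDA
# ---------------------------------------------------------------------------


@dataclass
class RDAResult:
    """Constrained ordination output.

    ``eigenvalues`` are fitted-covariance eigenvalues (non-increasing);
    ``individual_scores`` are the residualized genotypes projected on
    the axes (WA scores); ``loadings`` are axis-scaled right singular
    vectors (covariance-preserving "species" scaling by default);
    ``biplot_scores`` are correlations of the predictors with the
    constrained axes.
    """

    eigenvalues: np.ndarray
    individual_scores: np.ndarray  # n x n_axes
    loadings: np.ndarray  # loci x n_axes
    biplot_scores: pd.DataFrame  # predictors x axes
    r2: float
    r2_adj: float
    locus_ids: np.ndarray
    predictor_names: list[str]
    n_conditioning: int
    # permutation p-values, filled by rda_permutation_tests
    p_full: float | None = None
    p_axes: np.ndarray | None = None
    p_terms: dict[str, float] | None = None

    @property
    def n_axes(self) -> int:
        return int(self.eigenvalues.size)

    def significant_axes(self, alpha: float = 0.05) -> list[int]:
        """0-based indices of axes with sequential permutation p < alpha."""
        if self.p_axes is None:
            raise ValueError("run rda_permutation_tests first")
        return [i for i, p in enumerate(self.p_axes) if p < alpha]


def partial_rda(
    Y: np.ndarray,
    X: pd.DataFrame | np.ndarray,
    Z: pd.DataFrame | np.ndarray | None = None,
    locus_ids: np.ndarray | None = None,
    scaling: str = "covariance",
    scale_y: bool = False,
) -> RDAResult:
    """Partial RDA of Y on X given conditioning matrix Z.

    Y (n x loci) is the imputed dosage matrix; X holds the selected
    predictors and Z the conditioning terms (both standardized
    internally).  With Z=None this is a plain RDA.  ``scale_y`` divides
    each response column by its SD first (correlation-style RDA), which
    equalizes the sampling variance across loci of different allele
    frequency and makes the +/-3 SD outlier rule better calibrated.
    R^2 is the fitted share of the residualized response variance;
    R^2_adj uses the Ezekiel correction 1-(1-R^2)(n-g-1)/(n-g-m-1).
    """
    Y = np.asarray(Y, dtype=float)
    if scale_y:
        sd = Y.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Y = Y / sd
    n = Y.shape[0]
    x_names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"x{i}" for i in range(np.atleast_2d(X).shape[1])
    ]
    Xs = _standardize(np.asarray(X, dtype=float).reshape(n, -1))
    m = Xs.shape[1]
    if Z is not None and np.asarray(Z).size:
        Zs = _standardize(np.asarray(Z, dtype=float).reshape(n, -1))
        g = Zs.shape[1]
        C = np.column_stack([np.ones(n), Zs])
    else:
        g = 0
        C = np.ones((n, 1))

    Y_res = _residualize(Y, C)
    X_res = _residualize(Xs, C)
    if float(np.abs(X_res).max(initial=0.0)) < 1e-10 * max(1.0, float(np.abs(Xs).max())):
        # conditioning absorbed every predictor: zero constrained variance
        logger.warning("predictors lie in the span of the conditioning matrix")
        return RDAResult(
            eigenvalues=np.zeros(0),
            individual_scores=np.zeros((n, 0)),
            loadings=np.zeros((Y.shape[1], 0)),
            biplot_scores=pd.DataFrame(index=x_names),
            r2=0.0,
            r2_adj=0.0,
            locus_ids=np.asarray(locus_ids)
            if locus_ids is not None
            else np.arange(Y.shape[1]),
            predictor_names=x_names,
            n_conditioning=g,
        )
    rank_x = np.linalg.matrix_rank(X_res)
    if rank_x < m:
        raise ValueError(
            "predictors rank-deficient after conditioning "
            f"(rank {rank_x} < {m}); remove collinear terms among {x_names}"
        )

    B, *_ = np.linalg.lstsq(X_res, Y_res, rcond=None)
    fitted = X_res @ B
    U, S, Vt = np.linalg.svd(fitted, full_matrices=False)
    n_axes = min(m, int(np.sum(S > (S[0] * 1e-9 if S.size and S[0] > 0 else 1.0))))
    U, S, Vt = U[:, :n_axes], S[:n_axes], Vt[:n_axes]
    eig = S**2 / (n - 1)

    V = Vt.T  # loci x axes, unit norm
    if scaling == "covariance":
        loadings = V * (S / np.sqrt(n - 1))
    elif scaling == "unit":
        loadings = V
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    scores = Y_res @ V  # WA-style individual scores
    lc = U * S  # constrained (LC) scores

    ss_fit = float(np.sum(S**2))
    ss_tot = float(np.sum(Y_res**2))
    r2 = ss_fit / ss_tot if ss_tot > 0 else 0.0
    denom = n - g - m - 1
    r2_adj = 1.0 - (1.0 - r2) * (n - g - 1) / denom if denom > 0 else np.nan

    biplot = np.zeros((m, n_axes))
    for j in range(m):
        xj = X_res[:, j]
        for k in range(n_axes):
            sd = xj.std() * lc[:, k].std()
            biplot[j, k] = (
                np.mean((xj - xj.mean()) * (lc[:, k] - lc[:, k].mean())) / sd
                if sd > 0
                else 0.0
            )
    return RDAResult(
        eigenvalues=eig,
        individual_scores=scores,
        loadings=loadings,
        biplot_scores=pd.DataFrame(
            biplot, index=x_names, columns=[f"RDA{k + 1}" for k in range(n_axes)]
        ),
        r2=r2,
        r2_adj=r2_adj,
        locus_ids=np.asarray(locus_ids) if locus_ids is not None else np.arange(Y.shape[1]),
        predictor_names=x_names,
        n_conditioning=g,
    )


def _pseudo_f(Y_res: np.ndarray, X_res: np.ndarray, df_res: int) -> float:
    B, *_ = np.linalg.lstsq(X_res, Y_res, rcond=None)
    fitted = X_res @ B
    ss_fit = float(np.sum(fitted**2))
    ss_res = float(np.sum((Y_res - fitted) ** 2))
    m = X_res.shape[1]
    if ss_res <= 0:
        return np.inf
    return (ss_fit / m) / (ss_res / df_res)


def rda_permutation_tests(
    Y: np.ndarray,
    X: pd.DataFrame | np.ndarray,
    Z: pd.DataFrame | np.ndarray | None = None,
    n_perm: int = 999,
    seed: int = 0,
    rda: RDAResult | None = None,
    scale_y: bool = False,
) -> RDAResult:
    """Permutation significance for the full model, each axis, each term.

    The scheme permutes rows of the residualized response (reduced-model
    residual permutation): p = (1 + #{F_perm >= F_obs}) / (n_perm + 1).
    Axis k is tested sequentially with axes 1..k-1 added to the
    conditioning; term tests drop one predictor at a time.  Results are
    written onto the (possibly freshly computed) RDAResult.
    """
    if n_perm < 99:
        raise ValueError("n_perm < 99 gives too coarse a p resolution")
    if rda is None:
        rda = partial_rda(Y, X, Z, scale_y=scale_y)
    rng = np.random.default_rng(seed)
    Y = np.asarray(Y, dtype=float)
    if scale_y:
        sd = Y.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Y = Y / sd
    n = Y.shape[0]
    Xs = _standardize(np.asarray(X, dtype=float).reshape(n, -1))
    m = Xs.shape[1]
    if Z is not None and np.asarray(Z).size:
        Zs = _standardize(np.asarray(Z, dtype=float).reshape(n, -1))
        g = Zs.shape[1]
        C = np.column_stack([np.ones(n), Zs])
    else:
        g = 0
        C = np.ones((n, 1))
    Y_res = _residualize(Y, C)
    X_res = _residualize(Xs, C)
    df_res = n - g - m - 1

    # full model
    f_obs = _pseudo_f(Y_res, X_res, df_res)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _pseudo_f(Y_res[perm], X_res, df_res) >= f_obs - 1e-12:
            count += 1
    rda.p_full = (1.0 + count) / (n_perm + 1.0)

    # sequential axis tests
    B, *_ = np.linalg.lstsq(X_res, Y_res, rcond=None)
    fitted = X_res @ B
    ss_res_full = float(np.sum((Y_res - fitted) ** 2))
    U, S, Vt = np.linalg.svd(fitted, full_matrices=False)
    n_axes = rda.n_axes
    lc = U[:, :n_axes] * S[:n_axes]
    p_axes = np.empty(n_axes)
    for k in range(n_axes):
        Ck = np.column_stack([C, lc[:, :k]]) if k else C
        Yk = _residualize(Y, Ck)
        Xk = _residualize(Xs, Ck)
        dfk = n - Ck.shape[1] - m + k  # conditioning absorbed k pseudo-terms
        dfk = max(dfk, 1)

        def axis_stat(Ymat: np.ndarray) -> float:
            Bk, *_ = np.linalg.lstsq(Xk, Ymat, rcond=None)
            fit_k = Xk @ Bk
            s1 = np.linalg.svd(fit_k, compute_uv=False)
            lam1 = float(s1[0] ** 2) if s1.size else 0.0
            ss_r = float(np.sum((Ymat - fit_k) ** 2))
            return lam1 / (ss_r / dfk) if ss_r > 0 else np.inf

        f_k = axis_stat(Yk)
        cnt = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            if axis_stat(Yk[perm]) >= f_k - 1e-12:
                cnt += 1
        p_axes[k] = (1.0 + cnt) / (n_perm + 1.0)
    rda.p_axes = p_axes

    # marginal term tests: drop one term, condition on the rest
    p_terms: dict[str, float] = {}
    for j, name in enumerate(rda.predictor_names):
        others = np.delete(np.arange(m), j)
        Cj = np.column_stack([C, X_res[:, others]]) if others.size else C
        Yj = _residualize(Y, Cj)
        Xj = _residualize(X_res[:, [j]], Cj)
        dfj = n - Cj.shape[1] - 1
        f_j = _pseudo_f(Yj, Xj, dfj)
        cnt = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            if _pseudo_f(Yj[perm], Xj, dfj) >= f_j - 1e-12:
                cnt += 1
        p_terms[name] = (1.0 + cnt) / (n_perm + 1.0)
    rda.p_terms = p_terms
    return rda


# ---------------------------------------------------------------------------
# forward selection with VIF
# ---------------------------------------------------------------------------


@dataclass
class PredictorSelection:
    selected: list[str]
    trace: pd.DataFrame
    vifs: dict[str, float]


def _vifs(X: np.ndarray) -> np.ndarray:
    """VIF_j = 1 / (1 - R^2_j) of column j regressed on the others."""
    n, m = X.shape
    if m == 1:
        return np.ones(1)
    out = np.empty(m)
    for j in range(m):
        others = np.delete(np.arange(m), j)
        C = np.column_stack([np.ones(n), X[:, others]])
        res = _residualize(X[:, [j]], C)
        ss_tot = float(np.sum((X[:, j] - X[:, j].mean()) ** 2))
        r2 = 1.0 - float(np.sum(res**2)) / ss_tot if ss_tot > 0 else 1.0
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def _adj_r2(Y: np.ndarray, X: np.ndarray) -> float:
    n, m = X.shape
    C = np.ones((n, 1))
    Yc = _residualize(Y, C)
    Xc = _residualize(X, C)
    B, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    fitted = Xc @ B
    ss_tot = float(np.sum(Yc**2))
    r2 = float(np.sum(fitted**2)) / ss_tot if ss_tot > 0 else 0.0
    denom = n - m - 1
    return 1.0 - (1.0 - r2) * (n - 1) / denom if denom > 0 else np.nan


def vif_forward_select(
    candidates: pd.DataFrame,
    Y: np.ndarray,
    vif_cutoff: float = 10.0,
    p_enter: float = 0.05,
    n_perm: int = 199,
    seed: int = 0,
) -> PredictorSelection:
    """Greedy forward selection of climate predictors for the RDA.

    At each step the candidate adding the most adjusted R^2 enters,
    provided its permutation partial-F p-value is below ``p_enter`` and
    every VIF in the augmented set stays at or below ``vif_cutoff``.
    Stops when no candidate qualifies; an empty selection is returned
    with a warning (downstream RDA will refuse to run on it).
    """
    rng = np.random.default_rng(seed)
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    names = list(candidates.columns)
    Xall = _standardize(candidates.to_numpy(dtype=float))
    selected: list[int] = []
    rows = []
    current_r2 = 0.0
    while True:
        best = None
        for j in range(Xall.shape[1]):
            if j in selected:
                continue
            trial = selected + [j]
            Xt = Xall[:, trial]
            vifs = _vifs(Xt)
            if np.any(vifs > vif_cutoff):
                continue
            r2 = _adj_r2(Y, Xt)
            if best is None or r2 > best[1]:
                best = (j, r2, vifs)
        if best is None:
            break
        j, r2_new, vifs = best
        # permutation test of the added term given the already-selected set
        C = (
            np.column_stack([np.ones(n), Xall[:, selected]])
            if selected
            else np.ones((n, 1))
        )
        Yj = _residualize(Y, C)
        Xj = _residualize(Xall[:, [j]], C)
        dfj = n - C.shape[1] - 1
        f_obs = _pseudo_f(Yj, Xj, dfj)
        cnt = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            if _pseudo_f(Yj[perm], Xj, dfj) >= f_obs - 1e-12:
                cnt += 1
        p = (1.0 + cnt) / (n_perm + 1.0)
        if p >= p_enter:
            break
        selected.append(j)
        rows.append(
            {
                "step": len(selected),
                "entered": names[j],
                "adj_r2": r2_new,
                "p": p,
                "max_vif": float(np.max(vifs)),
            }
        )
        current_r2 = r2_new
    if not selected:
        logger.warning("forward selection kept no predictors")
    sel_names = [names[j] for j in selected]
    final_vifs = (
        dict(zip(sel_names, _vifs(Xall[:, selected]))) if selected else {}
    )
    return PredictorSelection(
        selected=sel_names,
        trace=pd.DataFrame(rows),
        vifs=final_vifs,
    )


# ---------------------------------------------------------------------------
# outliers and phenotype linkage
# ---------------------------------------------------------------------------


@dataclass
class OutlierSet:
    table: pd.DataFrame  # locus_id, axis, loading, assigned_variable, correlation
    sd_mult: float
    axes: list[int]

    @property
    def locus_ids(self) -> np.ndarray:
        return self.table["locus_id"].unique()


def detect_outlier_loci(
    rda: RDAResult,
    Y: np.ndarray,
    climate_by_individual: pd.DataFrame,
    sd_mult: float = 3.0,
    axes: list[int] | None = None,
) -> OutlierSet:
    """Flag loci loading beyond mean +/- sd_mult * SD on any chosen axis.

    ``axes`` are 0-based indices of the significant axes (empty set ->
    empty result).  Each outlier is assigned the climate variable with
    the largest |Pearson correlation| between its dosage column in Y
    and the individual-expanded variable.
    """
    if axes is None:
        if rda.p_axes is None:
            raise ValueError("pass axes explicitly or run rda_permutation_tests")
        axes = rda.significant_axes()
    if not axes:
        return OutlierSet(
            table=pd.DataFrame(
                columns=["locus_id", "axis", "loading", "assigned_variable", "correlation"]
            ),
            sd_mult=sd_mult,
            axes=[],
        )
    Y = np.asarray(Y, dtype=float)
    clim = climate_by_individual.to_numpy(dtype=float)
    clim_names = list(climate_by_individual.columns)
    clim_c = clim - clim.mean(axis=0)
    clim_sd = clim_c.std(axis=0)

    rows = []
    flagged: dict[int, tuple[int, float]] = {}
    for k in axes:
        load = rda.loadings[:, k]
        mu, sd = load.mean(), load.std()
        if sd == 0:
            continue
        hits = np.where(np.abs(load - mu) > sd_mult * sd)[0]
        for i in hits:
            if i not in flagged or abs(load[i] - mu) / sd > abs(flagged[i][1]):
                flagged[i] = (k, (load[i] - mu) / sd)
    for i, (k, _) in sorted(flagged.items()):
        y = Y[:, i] - Y[:, i].mean()
        ysd = y.std()
        if ysd == 0:
            corrs = np.zeros(len(clim_names))
        else:
            corrs = (clim_c.T @ y) / (len(y) * clim_sd * ysd)
        j = int(np.argmax(np.abs(corrs)))
        rows.append(
            {
                "locus_id": rda.locus_ids[i],
                "axis": f"RDA{k + 1}",
                "loading": float(rda.loadings[i, k]),
                "assigned_variable": clim_names[j],
                "correlation": float(corrs[j]),
            }
        )
    return OutlierSet(
        table=pd.DataFrame(
            rows,
            columns=["locus_id", "axis", "loading", "assigned_variable", "correlation"],
        ),
        sd_mult=sd_mult,
        axes=list(axes),
    )


def link_scores_to_phenotype(
    rda: RDAResult,
    scores_individual_ids: np.ndarray,
    phenotype: pd.Series,
) -> pd.DataFrame:
    """Spearman correlation of per-axis individual scores with R_d.

    ``phenotype`` is indexed by individual id; individuals absent from
    either side are dropped (count logged).  Requires >= 3 overlapping
    individuals.
    """
    ids = np.asarray(scores_individual_ids)
    common = [i for i, x in enumerate(ids) if x in phenotype.index and pd.notna(phenotype[x])]
    n_dropped = len(ids) - len(common)
    if n_dropped:
        logger.info("phenotype linkage: dropped %d non-overlapping individuals", n_dropped)
    if len(common) < 3:
        raise ValueError(f"only {len(common)} overlapping individuals (< 3)")
    ph = phenotype.loc[ids[common]].to_numpy(dtype=float)
    rows = []
    for k in range(rda.n_axes):
        r, p = correlate(rda.individual_scores[common, k], ph, method="spearman")
        rows.append({"axis": f"RDA{k + 1}", "r_s": r, "p": p, "n": len(common)})
    return pd.DataFrame(rows)
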