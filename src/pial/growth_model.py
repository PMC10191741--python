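"""Site-level growth-climate regression with AR1 errors and AICc.

The response is site-level mean annual sBAI on a site x water-year
panel; predictors are standardized water-year climate (Tmn, PPT) and
their one-year lags.  Errors follow a first-order autoregressive
process within each site and are independent across sites:

    y = X beta + e,   e_t = phi * e_{t-1} + u_t   (within site)

The fit is exact Gaussian maximum likelihood: for a trial phi the data
are whitened with the AR1 Cholesky factor (first in-site row scaled by
sqrt(1 - phi^2), later rows differenced as y_t - phi*y_{t-1}), OLS on
the whitened data gives the profiled beta and sigma^2, and phi is found
by maximizing the profile likelihood on (-0.99, 0.99).  ML (not REML)
is used throughout because AICc compares fixed-effect structures.

Candidate models follow the standard seven-model set: Tmn+PPT,
Tmn+PPT+PPT.lag1, Tmn+PPT+Tmn.lag1, Tmn+PPT+PPT.lag1+Tmn.lag1, Tmn,
PPT, and intercept-only; ranking is by AICc with Akaike weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

#: the standard candidate set: formula name -> predictor columns
CANDIDATE_MODELS: dict[str, tuple[str, ...]] = {
    "Tmn + PPT": ("Tmn", "PPT"),
    "Tmn + PPT + PPT.lag1": ("Tmn", "PPT", "PPT.lag1"),
    "Tmn + PPT + Tmn.lag1": ("Tmn", "PPT", "Tmn.lag1"),
    "Tmn + PPT + PPT.lag1 + Tmn.lag1": ("Tmn", "PPT", "PPT.lag1", "Tmn.lag1"),
    "Tmn": ("Tmn",),
    "PPT": ("PPT",),
    "Intercept only": (),
}


@dataclass
class ModelFit:
    """A fitted GLS-AR1 model.

    ``k`` counts the fixed effects (incl. intercept) plus phi and the
    residual variance, the conventional AICc accounting for GLS.
    """

    formula: str
    terms: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    phi: float
    sigma2: float
    loglik: float
    n_obs: int
    k: int
    aicc: float
    fitted: np.ndarray
    pseudo_r2: float


def build_design(
    site_sbai: pd.DataFrame,
    climate: pd.DataFrame,
    window: tuple[int, int] = (1971, 2011),
    predictors: tuple[str, ...] = ("Tmn", "PPT"),
) -> pd.DataFrame:
    """Assemble the (site, year) panel of response and standardized predictors.

    ``site_sbai`` has columns site_id, year, sbai (site-level mean annual
    sBAI).  Each predictor gets a one-year-lagged companion
    (``<var>.lag1``); all predictor columns are standardized (mean 0,
    SD 1, n-1) over the pooled design.  Site-years lacking sBAI are
    dropped with a logged count.
    """
    lo, hi = window
    clim = climate.rename(columns={"water_year": "year"})[
        ["site_id", "year", *predictors]
    ].copy()
    lagged = clim.copy()
    lagged["year"] = lagged["year"] + 1
    lagged = lagged.rename(columns={v: f"{v}.lag1" for v in predictors})
    design = clim.merge(lagged, on=["site_id", "year"], how="inner")
    design = design[(design["year"] >= lo) & (design["year"] <= hi)]
    n_before = design.shape[0]
    design = design.merge(site_sbai, on=["site_id", "year"], how="inner")
    n_dropped = n_before - design.shape[0]
    if n_dropped:
        logger.info("build_design: dropped %d site-years without sBAI", n_dropped)
    design = design.dropna(subset=["sbai"]).reset_index(drop=True)
    for col in design.columns:
        if col in ("site_id", "year", "sbai"):
            continue
        sd = design[col].std(ddof=1)
        if sd == 0:
            raise ValueError(f"predictor {col} has zero variance over the design")
        design[col] = (design[col] - design[col].mean()) / sd
    return design.sort_values(["site_id", "year"]).reset_index(drop=True)


def _group_starts(groups: np.ndarray) -> np.ndarray:
    """Boolean mask marking the first row of each within-site run."""
    starts = np.ones(groups.shape[0], dtype=bool)
    starts[1:] = groups[1:] != groups[:-1]
    return starts


def _whiten(y: np.ndarray, X: np.ndarray, groups: np.ndarray, phi: float):
    """Apply the AR1 Cholesky whitening transform within each group."""
    starts = _group_starts(groups)
    c = np.sqrt(1.0 - phi**2)
    yw = np.empty_like(y)
    Xw = np.empty_like(X)
    yw[starts] = y[starts] * c
    Xw[starts] = X[starts] * c
    cont = ~starts
    yw[cont] = y[cont] - phi * y[np.flatnonzero(cont) - 1]
    Xw[cont] = X[cont] - phi * X[np.flatnonzero(cont) - 1]
    return yw, Xw, int(cont.sum())


def _profile_loglik(phi: float, y: np.ndarray, X: np.ndarray, groups: np.ndarray) -> float:
    """Exact Gaussian log-likelihood profiled over beta and sigma^2 at phi.

    The whitened residuals have variance sigma^2 (1 - phi^2); the AR1
    correlation determinant is |R| = (1 - phi^2)^(T_s - 1) per site,
    i.e. (1 - phi^2)^n_cont overall.
    """
    n = y.shape[0]
    yw, Xw, n_cont = _whiten(y, X, groups, phi)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    rss = float(np.sum((yw - Xw @ beta) ** 2))
    sigma2 = max(rss / ((1.0 - phi**2) * n), 1e-300)  # guard a perfect fit
    logdet_R = n_cont * np.log(1.0 - phi**2)
    return -0.5 * (n * np.log(2 * np.pi * sigma2) + n) - 0.5 * logdet_R


def fit_gls_ar1(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    formula: str = "",
    terms: tuple[str, ...] = (),
    phi: float | None = None,
    phi_bound: float = 0.99,
    tol: float = 1e-8,
) -> ModelFit:
    """Fit y = X beta + AR1(phi) errors by exact maximum likelihood.

    Rows must be grouped by site with within-site rows time-ordered
    (consecutive years).  ``X`` must include the intercept column.  Pass
    ``phi`` to fix the autocorrelation (phi=0 reproduces OLS exactly).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    groups = np.asarray(groups)
    n, p = X.shape
    if y.shape[0] != n or groups.shape[0] != n:
        raise ValueError("y, X, groups must have equal length")

    if phi is None:
        res = optimize.minimize_scalar(
            lambda ph: -_profile_loglik(ph, y, X, groups),
            bounds=(-phi_bound, phi_bound),
            method="bounded",
            options={"xatol": tol},
        )
        if not res.success:
            raise RuntimeError(f"AR1 profile likelihood failed: {res.message}")
        phi_hat = float(res.x)
    else:
        if abs(phi) >= 1:
            raise ValueError("|phi| must be < 1")
        phi_hat = float(phi)

    yw, Xw, _ = _whiten(y, X, groups, phi_hat)
    XtX = Xw.T @ Xw
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    resid_w = yw - Xw @ beta
    rss = float(resid_w @ resid_w)
    sigma2 = rss / ((1.0 - phi_hat**2) * n)
    loglik = _profile_loglik(phi_hat, y, X, groups)
    cov = rss / (n - p) * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov))
    fitted = X @ beta
    k = p + 2
    fit = ModelFit(
        formula=formula,
        terms=terms,
        beta=beta,
        se=se,
        phi=phi_hat,
        sigma2=sigma2,
        loglik=loglik,
        n_obs=n,
        k=k,
        aicc=np.nan,
        fitted=fitted,
        pseudo_r2=np.nan,
    )
    fit.aicc = aicc(fit)
    fit.pseudo_r2 = pseudo_r2(fit, y)
    return fit


def aicc(fit: ModelFit) -> float:
    """AICc = -2 logLik + 2k + 2k(k+1)/(n - k - 1)."""
    n, k = fit.n_obs, fit.k
    if n <= k + 1:
        raise ValueError(f"AICc undefined: n_obs={n} <= k+1={k + 1}")
    return -2.0 * fit.loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def pseudo_r2(fit: ModelFit, y: np.ndarray) -> float:
    """Square of the Pearson correlation between fitted and observed."""
    fitted = fit.fitted
    if np.std(fitted) == 0:
        logger.warning("pseudo_r2: zero variance in fitted values")
        return 0.0
    r = np.corrcoef(fitted, y)[0, 1]
    return float(r**2)


def fit_candidate(
    design: pd.DataFrame, terms: tuple[str, ...], formula: str, phi: float | None = None
) -> ModelFit:
    """Fit one candidate formula on a built design panel."""
    y = design["sbai"].to_numpy(dtype=float)
    cols = [design[t].to_numpy(dtype=float) for t in terms]
    X = np.column_stack([np.ones(len(design))] + cols)
    groups = design["site_id"].to_numpy()
    return fit_gls_ar1(y, X, groups, formula=formula, terms=terms, phi=phi)


def select_growth_model(
    design: pd.DataFrame,
    candidates: dict[str, tuple[str, ...]] | None = None,
) -> tuple[pd.DataFrame, dict[str, ModelFit]]:
    """Fit all candidates on the identical rows and rank by AICc.

    Returns the ranking table (AICc, dAICc, Akaike weight, pseudo r^2,
    phi) sorted ascending by AICc, and the fits keyed by formula.
    Candidates that fail to fit are flagged and excluded.
    """
    candidates = candidates or CANDIDATE_MODELS
    fits: dict[str, ModelFit] = {}
    failed: list[str] = []
    for formula, terms in candidates.items():
        missing = [t for t in terms if t not in design.columns]
        if missing:
            raise ValueError(f"design lacks columns {missing} for {formula!r}")
        try:
            fits[formula] = fit_candidate(design, terms, formula)
        except Exception as exc:  # noqa: BLE001 - candidate failure is survivable
            logger.warning("candidate %r failed: %s", formula, exc)
            failed.append(formula)
    if not fits:
        raise RuntimeError("every candidate model failed")
    tab = pd.DataFrame(
        {
            "model": list(fits.keys()),
            "AICc": [f.aicc for f in fits.values()],
            "logLik": [f.loglik for f in fits.values()],
            "k": [f.k for f in fits.values()],
            "phi": [f.phi for f in fits.values()],
            "pseudo_r2": [f.pseudo_r2 for f in fits.values()],
        }
    )
    tab["dAICc"] = tab["AICc"] - tab["AICc"].min()
    rel = np.exp(-0.5 * tab["dAICc"])
    tab["weight"] = rel / rel.sum()
    tab = tab.sort_values("AICc").reset_index(drop=True)
    if failed:
        tab.attrs["failed_candidates"] = failed
    return tab, fits


def best_supported_model(ranking: pd.DataFrame, delta_threshold: float = 4.0) -> str:
    """Most parsimonious model among those with similar support.

    Models within ``delta_threshold`` AICc of the minimum are treated as
    equivalently supported; among them the one with the fewest
    parameters wins (ties broken by lower AICc).  This guards against
    the fixed overfitting probability of strict argmin-AICc selection,
    which admits a superset of the true terms in a substantial fraction
    of samples no matter how strong the true effects are.
    """
    close = ranking[ranking["dAICc"] < delta_threshold]
    best = close.sort_values(["k", "AICc"]).iloc[0]
    return str(best["model"])
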