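"""Seeded synthetic climate, ring-width and genotype generators.

The generators emulate the statistical structure of a subalpine pine
study network: 27 sites on a latitudinal gradient whose water-year
climate shows a warming minimum-temperature trend and a 2012-2015
precipitation deficit forced more than 1 SD below each site's
WY1970-1999 mean; per-tree growth on the log-BAI scale with weak
positive standardized Tmn and PPT effects and AR1(0.6) noise; and
stepping-stone genetic structure (logit allele-frequency field with
spatially decaying covariance -> low global FST with isolation by
distance) plus a minority of adaptive loci whose site frequencies track
a climate variable.

Every stochastic choice a recovery test needs is recorded in the
returned :class:`SyntheticTruth`.  Each generator draws from its own
RNG stream, seeded from the master seed by a fixed offset, so
regenerating one input never perturbs the others.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pial.dataio import GenotypeMatrix, RingWidthSeries

logger = logging.getLogger(__name__)

_STREAM_OFFSETS = {"climate": 0, "treering": 1, "genotype": 2, "missing": 3}


def derive_seed(master: int, stream: str) -> int:
    """Fixed-offset child seed for a named generator stream (< 2^31)."""
    return (int(master) * 1000003 + _STREAM_OFFSETS[stream]) % (2**31 - 1)


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generators for recovery tests."""

    site_table: pd.DataFrame | None = None
    climate_params: dict | None = None
    tree_params: pd.DataFrame | None = None  # tree_id, site_id, mu, slope
    phi_sim: float | None = None
    b_tmn: float | None = None
    b_ppt: float | None = None
    adaptive_loci: pd.DataFrame | None = None  # locus_id, variable, gamma
    stepping_stone_range_m: float | None = None

    def merge(self, other: "SyntheticTruth") -> "SyntheticTruth":
        for f in self.__dataclass_fields__:
            if getattr(self, f) is None:
                setattr(self, f, getattr(other, f))
        return self


# ---------------------------------------------------------------------------
# climate
# ---------------------------------------------------------------------------


def simulate_climate(
    n_sites: int = 27,
    years: tuple[int, int] = (1970, 2020),
    drought_years: tuple[int, ...] = (2012, 2013, 2014, 2015),
    seed: int = 1,
    noise_scale: float = 1.0,
    tmn_trend: float = 0.03,
    deficit_sd: float = 1.5,
    deficit_frac: float = 0.3,
    normals_span: tuple[int, int] = (1970, 1999),
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate per-site water-year climate with a forced drought.

    Sites sit on a latitude gradient (39 N -> 36 N); Tmn rises linearly
    at ``tmn_trend`` deg C/yr with Gaussian noise, PPT is lognormal with
    a shared regional year effect, and PET/AET/CWD close the water
    balance with PET increasing in Tmn and AET increasing in PPT.
    Drought-year PPT is rescaled per site so its mean sits
    ``deficit_sd`` reference SDs below the WY normals mean (or
    ``deficit_frac`` of the mean when the reference variance is zero),
    guaranteeing the >1 SD deficit.
    """
    if n_sites < 2:
        raise ValueError("need >= 2 sites")
    ylo, yhi = years
    wy = np.arange(ylo, yhi + 1)
    bad = [y for y in drought_years if y < ylo or y > yhi]
    if bad:
        raise ValueError(f"drought years outside simulated span: {bad}")
    rng = np.random.default_rng(derive_seed(seed, "climate"))

    lat = np.linspace(39.0, 36.0, n_sites)
    site_ids = [f"S{i + 1:02d}" for i in range(n_sites)]
    utm_n = lat * 111_000.0
    utm_e = 250_000.0 + 15_000.0 * np.sin(np.linspace(0, 3 * np.pi, n_sites)) + rng.normal(
        0, 3_000.0, n_sites
    )
    elev = 2600.0 + 250.0 * (lat - 36.0) / 3.0 + rng.normal(0, 150.0, n_sites)

    # microclimate offsets (aspect, cold-air pooling, rain shadow) leave each
    # site with climate variation orthogonal to the geographic gradient
    tmn_base = (
        1.5
        - 1.2 * (lat - 36.0) / 3.0
        - 0.004 * (elev - 2600.0)
        + rng.normal(0.0, 0.5, n_sites)
    )
    log_ppt_mean = (
        np.log(1100.0) + 0.20 * (lat - 36.0) / 3.0 + rng.normal(0.0, 0.15, n_sites)
    )

    year_effect = rng.normal(0.0, 0.25 * noise_scale, wy.size)
    rows = []
    for s in range(n_sites):
        tmn = (
            tmn_base[s]
            + tmn_trend * (wy - ylo)
            + rng.normal(0.0, 0.7 * noise_scale, wy.size)
        )
        ppt = np.exp(
            log_ppt_mean[s] + year_effect + rng.normal(0.0, 0.12 * noise_scale, wy.size)
        )
        rows.append(
            pd.DataFrame(
                {"site_id": site_ids[s], "water_year": wy, "Tmn": tmn, "PPT": ppt}
            )
        )
    clim = pd.concat(rows, ignore_index=True)

    # force the drought deficit per site
    nlo, nhi = normals_span
    dmask = clim["water_year"].isin(drought_years)
    for sid in site_ids:
        smask = clim["site_id"] == sid
        ref = clim.loc[
            smask & clim["water_year"].between(nlo, nhi), "PPT"
        ]
        ref_mean, ref_sd = ref.mean(), ref.std(ddof=1)
        target = ref_mean - deficit_sd * ref_sd
        if not ref_sd > 0:
            target = (1.0 - deficit_frac) * ref_mean
        if target <= 0:
            raise ValueError(
                f"site {sid}: drought target PPT <= 0; variance too large for "
                f"deficit_sd={deficit_sd} — lower deficit_sd or noise, or raise "
                "the deficit multiplier on the mean"
            )
        cur = clim.loc[smask & dmask, "PPT"].mean()
        clim.loc[smask & dmask, "PPT"] *= target / cur

    tmn_noise = 20.0 * noise_scale
    clim["Tmx"] = clim["Tmn"] + 12.0 + rng.normal(0.0, 0.5 * noise_scale, len(clim))
    clim["PET"] = np.maximum(
        700.0 + 45.0 * clim["Tmn"] + rng.normal(0.0, tmn_noise, len(clim)), 50.0
    )
    clim["AET"] = clim["PET"] * (1.0 - np.exp(-clim["PPT"] / 1000.0))
    clim["CWD"] = clim["PET"] - clim["AET"]

    site_table = pd.DataFrame(
        {
            "site_id": site_ids,
            "latitude": lat,
            "utm_e": utm_e,
            "utm_n": utm_n,
            "elevation_m": elev,
        }
    )
    truth = SyntheticTruth(
        site_table=site_table,
        climate_params={
            "tmn_trend": tmn_trend,
            "tmn_base": tmn_base.tolist(),
            "log_ppt_mean": log_ppt_mean.tolist(),
            "deficit_sd": deficit_sd,
            "noise_scale": noise_scale,
            "drought_years": list(drought_years),
        },
    )
    return clim.sort_values(["site_id", "water_year"]).reset_index(drop=True), truth


# ---------------------------------------------------------------------------
# ring widths
# ---------------------------------------------------------------------------


@dataclass
class GrowthParams:
    """Tree-growth generator parameters (log-BAI scale).

    ``b_tmn``/``b_ppt`` multiply within-site z-scores of the annual
    climate; ``site_slopes`` (sBAI-free log slope per site, per year)
    defaults to zero everywhere; ``phi`` and ``sigma`` set the AR1
    noise; drought_boost multiplies BAI in the drought years (1.0 = no
    planted response).
    """

    mu_log_bai: float = 1.6  # log cm^2, about 5 cm^2/yr
    sd_mu: float = 0.3
    site_slopes: dict[str, float] | float = 0.0
    slope_sd: float = 0.0
    b_tmn: float = 0.15
    b_ppt: float = 0.05
    phi: float = 0.6
    sigma: float = 0.32  # AR1 innovation SD
    pith_radius_cm: float = 0.2
    drought_boost: float = 1.0
    drought_boost_cv: float = 0.0
    drought_years: tuple[int, ...] = (2012, 2013, 2014, 2015)


def simulate_ring_widths(
    climate: pd.DataFrame,
    n_trees_per_site: int = 28,
    growth_params: GrowthParams | None = None,
    seed: int = 1,
) -> tuple[list[RingWidthSeries], SyntheticTruth]:
    """Simulate ring-width series from climate via log-BAI dynamics.

    log BAI_{i,t} = mu_i + s_i (t - t0) + b_T z(Tmn_{site,t})
                  + b_P z(PPT_{site,t}) + eps_{i,t},  eps ~ AR1(phi)

    BAI is converted to ring widths by inverse annulus geometry from a
    pith radius, and the final DBH recorded as twice the final radius.
    Widths are strictly positive by construction.
    """
    gp = growth_params or GrowthParams()
    if not -1.0 < gp.phi < 1.0:
        raise ValueError("phi must be in (-1, 1)")
    rng = np.random.default_rng(derive_seed(seed, "treering"))
    sites = sorted(climate["site_id"].unique())
    t0 = int(climate["water_year"].min())
    series: list[RingWidthSeries] = []
    truth_rows = []
    for sid in sites:
        sc = climate[climate["site_id"] == sid].sort_values("water_year")
        yrs = sc["water_year"].to_numpy()
        z_t = _zscore(sc["Tmn"].to_numpy())
        z_p = _zscore(sc["PPT"].to_numpy())
        s_mean = (
            gp.site_slopes.get(sid, 0.0)
            if isinstance(gp.site_slopes, dict)
            else float(gp.site_slopes)
        )
        in_drought = np.isin(yrs, gp.drought_years)
        for i in range(n_trees_per_site):
            tree_id = f"{sid}T{i + 1:02d}"
            mu = gp.mu_log_bai + rng.normal(0.0, gp.sd_mu)
            s_i = s_mean + rng.normal(0.0, gp.slope_sd) if gp.slope_sd > 0 else s_mean
            eps = _ar1(rng, gp.phi, gp.sigma, yrs.size)
            log_bai = mu + s_i * (yrs - t0) + gp.b_tmn * z_t + gp.b_ppt * z_p + eps
            bai = np.exp(log_bai)
            boost = gp.drought_boost
            if gp.drought_boost_cv > 0:
                boost = max(
                    gp.drought_boost
                    * (1.0 + rng.normal(0.0, gp.drought_boost_cv)),
                    0.05,
                )
            if boost != 1.0:
                bai = np.where(in_drought, bai * boost, bai)
            widths_mm, dbh_cm = _bai_to_widths(bai, gp.pith_radius_cm)
            if np.any(widths_mm <= 0):
                raise ValueError(f"tree {tree_id}: non-positive width generated")
            series.append(
                RingWidthSeries(
                    tree_id=tree_id,
                    site_id=sid,
                    years=yrs.copy(),
                    widths=widths_mm,
                    dbh_cm=dbh_cm,
                )
            )
            truth_rows.append(
                {"tree_id": tree_id, "site_id": sid, "mu": mu, "slope": s_i, "boost": boost}
            )
    truth = SyntheticTruth(
        tree_params=pd.DataFrame(truth_rows),
        phi_sim=gp.phi,
        b_tmn=gp.b_tmn,
        b_ppt=gp.b_ppt,
    )
    return series, truth


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _ar1(rng: np.random.Generator, phi: float, sigma: float, n: int) -> np.ndarray:
    if sigma == 0:
        return np.zeros(n)
    marginal = sigma / np.sqrt(1.0 - phi**2)
    eps = np.empty(n)
    eps[0] = rng.normal(0.0, marginal)
    innov = rng.normal(0.0, sigma, n - 1)
    for t in range(1, n):
        eps[t] = phi * eps[t - 1] + innov[t - 1]
    return eps


def _bai_to_widths(bai: np.ndarray, pith_radius_cm: float) -> tuple[np.ndarray, float]:
    """Equal-area inverse: widths (mm) whose annuli reproduce the BAI series."""
    areas = np.pi * pith_radius_cm**2 + np.cumsum(bai)
    radii = np.sqrt(areas / np.pi)
    widths_cm = np.diff(np.concatenate([[pith_radius_cm], radii]))
    return widths_cm * 10.0, float(2.0 * radii[-1])


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def simulate_genotypes(
    sites: pd.DataFrame,
    n_per_site: int = 15,
    n_loci: int = 5000,
    n_adaptive: int = 50,
    gamma: float = 1.5,
    missing_rate: float = 0.2,
    seed: int = 1,
    env: pd.DataFrame | None = None,
    sigma_logit: float = 0.5,
    autocorr_range_m: float = 150_000.0,
    p_clip: tuple[float, float] = (0.001, 0.999),
) -> tuple[GenotypeMatrix, SyntheticTruth]:
    """Simulate stepping-stone genotypes with planted adaptive loci.

    Neutral loci: an ancestral frequency is Beta-drawn, then per-site
    logit deviations come from a Gaussian field whose covariance decays
    exponentially with UTM distance (sigma_logit^2 exp(-d/range)),
    producing low global FST with isolation by distance.  Adaptive
    loci: logit p_site = logit(p0) + gamma * z(climate variable); the
    driving variable for each planted locus is drawn from the columns
    of ``env`` (site x variable 30-year normals; required when
    n_adaptive > 0).  Genotypes are Binomial(2, p_site), then masked
    missing at ``missing_rate``.
    """
    if n_adaptive >= n_loci:
        raise ValueError("n_adaptive must be < n_loci")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    if n_adaptive > 0 and env is None:
        raise ValueError("env (site x climate normals) required for adaptive loci")
    rng = np.random.default_rng(derive_seed(seed, "genotype"))
    site_ids = sites["site_id"].to_numpy()
    S = site_ids.size
    xy = sites[["utm_e", "utm_n"]].to_numpy(dtype=float)
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    if np.isinf(autocorr_range_m):
        cov = np.ones((S, S)) * sigma_logit**2
    else:
        cov = sigma_logit**2 * np.exp(-d / autocorr_range_m)
    chol = np.linalg.cholesky(cov + 1e-10 * np.eye(S))

    n_neutral = n_loci - n_adaptive
    p0 = rng.beta(0.8, 0.8, n_loci).clip(0.05, 0.95)
    logit0 = np.log(p0 / (1.0 - p0))

    field = rng.standard_normal((n_neutral, S)) @ chol.T
    logit_neutral = logit0[:n_neutral, None] + field

    if n_adaptive:
        env_aligned = env.set_index("site_id") if "site_id" in env.columns else env
        env_aligned = env_aligned.loc[pd.Index(site_ids)]
        env_vars = list(env_aligned.columns)
        Z = np.column_stack([_zscore(env_aligned[v].to_numpy(dtype=float)) for v in env_vars])
        var_idx = rng.integers(0, len(env_vars), n_adaptive)
        logit_adapt = logit0[n_neutral:, None] + gamma * Z[:, var_idx].T
        logit = np.vstack([logit_neutral, logit_adapt])
    else:
        env_vars, var_idx = [], np.array([], dtype=int)
        logit = logit_neutral

    p = 1.0 / (1.0 + np.exp(-logit))  # loci x sites
    lo, hi = p_clip
    n_clip = int(((p < lo) | (p > hi)).sum())
    if n_clip:
        logger.warning("clipping %d site frequencies to (%g, %g)", n_clip, lo, hi)
        p = p.clip(lo, hi)

    n_ind = S * n_per_site
    site_of = np.repeat(np.arange(S), n_per_site)
    calls = rng.binomial(2, p[:, site_of].T).astype(float)  # individuals x loci

    if missing_rate > 0:
        mrng = np.random.default_rng(derive_seed(seed, "missing"))
        mask = mrng.random(calls.shape) < missing_rate
        calls[mask] = np.nan

    locus_ids = np.array(
        [f"L{i + 1:05d}_1" for i in range(n_neutral)]
        + [f"A{i + 1:05d}_1" for i in range(n_adaptive)]
    )
    loci = pd.DataFrame(
        {
            "locus_id": locus_ids,
            "parent_locus": [lid.rsplit("_", 1)[0] for lid in locus_ids],
            "position": 1,
        }
    )
    individuals = pd.DataFrame(
        {
            # ids follow the tree-core naming so genotyped individuals are a
            # subset of cored trees when both generators share a site table
            "individual_id": [
                f"{site_ids[s]}T{i % n_per_site + 1:02d}" for i, s in enumerate(site_of)
            ],
            "site_id": site_ids[site_of],
        }
    )
    gm = GenotypeMatrix(
        calls=calls,
        individuals=individuals,
        loci=loci,
        sites=sites[["site_id", "utm_e", "utm_n", "latitude"]].copy()
        if "latitude" in sites.columns
        else sites.copy(),
    )
    adaptive = pd.DataFrame(
        {
            "locus_id": locus_ids[n_neutral:],
            "variable": [env_vars[j] for j in var_idx],
            "gamma": gamma,
        }
    )
    truth = SyntheticTruth(
        site_table=sites,
        adaptive_loci=adaptive,
        stepping_stone_range_m=autocorr_range_m,
    )
    return gm, truth
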