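"""Basal area increment, sBAI standardization, and growth trends.

Ring widths are converted to annual basal area increment (BAI, cm^2/yr)
by reconstructing radii outside-in: the outermost radius is anchored at
DBH/2 and each ring width is subtracted walking toward the pith, so
that measurement error accumulates in the (old, slow-grown) core rather
than the recent rings of interest.  BAI series are standardized by
their own whole-series standard deviation (sBAI), making growth
trajectories comparable between large and small stems.  Per-tree growth
trends are OLS slopes of sBAI on calendar year within an analysis
window; sites are classified positive/neutral/negative from the
t-based confidence interval of the within-site tree slopes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from pial.dataio import RingWidthSeries

logger = logging.getLogger(__name__)


@dataclass
class BAISeries:
    """Annual basal area increment for one tree, with optional sBAI.

    ``bai`` is in cm^2/yr, pith-to-bark aligned with ``years``; ``sbai``
    is bai divided by the whole-series SD (n-1) and is None until
    :func:`standardize_bai` runs.  ``clamped`` flags trees whose
    reconstructed inner radii hit zero (cumulative width exceeded
    DBH/2); ``flagged_constant`` marks zero-variance series excluded
    from trend analysis.
    """

    tree_id: str
    site_id: str
    years: np.ndarray
    bai: np.ndarray
    sbai: np.ndarray | None = None
    dbh_cm: float | None = None
    clamped: bool = False
    flagged_constant: bool = False


def ring_widths_to_bai(series: RingWidthSeries) -> BAISeries:
    """Convert ring widths (mm) to annual basal area increment (cm^2).

    The outermost radius is DBH/2; when DBH is absent the summed ring
    widths stand in for the outer radius (logged fallback).  Inner radii
    that would go negative are clamped to zero with a warning, zeroing
    the earliest increments.
    """
    w_cm = series.widths / 10.0
    if not np.any(w_cm > 0):
        raise ValueError(f"tree {series.tree_id}: all ring widths zero")
    if series.dbh_cm is not None:
        r_outer = series.dbh_cm / 2.0
    else:
        r_outer = float(w_cm.sum())
        logger.info("tree %s: no DBH, outer radius = sum of widths", series.tree_id)
    # radii outside-in: r[k] is the radius after ring k (pith-to-bark order)
    radii = r_outer - np.concatenate([[0.0], np.cumsum(w_cm[::-1])])[::-1]
    clamped = bool(radii[0] < -1e-12)
    if clamped:
        logger.warning(
            "tree %s: ring widths exceed DBH/2, clamping inner radii at 0",
            series.tree_id,
        )
        radii = np.maximum(radii, 0.0)
    bai = np.pi * (radii[1:] ** 2 - radii[:-1] ** 2)
    return BAISeries(
        tree_id=series.tree_id,
        site_id=series.site_id,
        years=series.years.copy(),
        bai=bai,
        dbh_cm=series.dbh_cm,
        clamped=clamped,
    )


def standardize_bai(bai: BAISeries) -> BAISeries:
    """Fill sBAI = BAI / SD(BAI over the full series), n-1 denominator.

    The SD is computed over the whole measured series, before any
    window filtering.  A zero-variance series is flagged (excluded from
    trend analysis downstream) rather than raising.
    """
    if len(bai.bai) < 2:
        raise ValueError(f"tree {bai.tree_id}: need >= 2 rings to standardize")
    sd = float(np.std(bai.bai, ddof=1))
    if sd == 0.0:
        logger.warning("tree %s: constant BAI, sBAI undefined", bai.tree_id)
        return BAISeries(
            tree_id=bai.tree_id,
            site_id=bai.site_id,
            years=bai.years,
            bai=bai.bai,
            sbai=None,
            dbh_cm=bai.dbh_cm,
            clamped=bai.clamped,
            flagged_constant=True,
        )
    return BAISeries(
        tree_id=bai.tree_id,
        site_id=bai.site_id,
        years=bai.years,
        bai=bai.bai,
        sbai=bai.bai / sd,
        dbh_cm=bai.dbh_cm,
        clamped=bai.clamped,
    )


def lag1_autocorrelation(x: np.ndarray) -> float:
    """Sample lag-1 autocorrelation: sum (x_t - xbar)(x_{t+1} - xbar) / sum (x_t - xbar)^2."""
    x = np.asarray(x, dtype=float)
    xc = x - x.mean()
    denom = float(np.sum(xc**2))
    if denom == 0.0:
        return np.nan
    return float(np.sum(xc[:-1] * xc[1:]) / denom)


def series_summary(
    series_by_site: dict[str, list[RingWidthSeries]],
    min_overlap: int = 10,
) -> pd.DataFrame:
    """Per-site ring-width summary statistics.

    AR1 is the sample lag-1 autocorrelation of each raw ring-width
    series; the interseries correlation is the mean pairwise Spearman
    correlation between the overlapping portions of series within a
    site, with pairs overlapping fewer than ``min_overlap`` years
    excluded.  A single-series site reports the interseries correlation
    as missing.
    """
    rows = []
    for site, series in series_by_site.items():
        if not series:
            raise ValueError(f"site {site}: no series")
        lengths = np.array([len(s) for s in series])
        ar1 = np.array([lag1_autocorrelation(s.widths) for s in series])
        pair_r = []
        for a, b in combinations(series, 2):
            lo = max(a.years[0], b.years[0])
            hi = min(a.years[-1], b.years[-1])
            if hi - lo + 1 < min_overlap:
                continue
            wa = a.widths[(a.years >= lo) & (a.years <= hi)]
            wb = b.widths[(b.years >= lo) & (b.years <= hi)]
            if np.std(wa) == 0 or np.std(wb) == 0:
                continue
            pair_r.append(stats.spearmanr(wa, wb).statistic)
        rows.append(
            {
                "site_id": site,
                "n_series": len(series),
                "n_rings": int(lengths.sum()),
                "mean_series_length": float(lengths.mean()),
                "start_year": int(min(s.years[0] for s in series)),
                "mean_ar1": float(np.nanmean(ar1)),
                "sd_ar1": float(np.nanstd(ar1, ddof=1)) if len(series) > 1 else np.nan,
                "mean_interseries_correlation": float(np.mean(pair_r)) if pair_r else np.nan,
                "sd_interseries_correlation": float(np.std(pair_r, ddof=1)) if len(pair_r) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def tree_growth_trend(
    sbai: BAISeries, window: tuple[int, int] = (1970, 2011), min_years: int = 10
) -> float | None:
    """OLS slope of sBAI on calendar year within the window (sBAI/yr).

    Returns None (with a log entry) for trees with fewer than
    ``min_years`` in-window observations or a flagged-constant series.
    """
    if sbai.flagged_constant or sbai.sbai is None:
        logger.info("tree %s: constant series, excluded from trends", sbai.tree_id)
        return None
    lo, hi = window
    mask = (sbai.years >= lo) & (sbai.years <= hi)
    if mask.sum() < min_years:
        logger.info(
            "tree %s: only %d in-window years (< %d), excluded",
            sbai.tree_id,
            int(mask.sum()),
            min_years,
        )
        return None
    yrs = sbai.years[mask].astype(float)
    y = sbai.sbai[mask]
    slope, _ = np.polyfit(yrs, y, 1)
    return float(slope)


def classify_site_trends(
    slopes_by_site: dict[str, list[float]],
    alpha: float = 0.05,
    threshold: float = 0.0,
) -> pd.DataFrame:
    """Classify each site's mean tree slope against ``threshold``.

    CI = mean +/- t_{1-alpha/2, n-1} * SE across tree slopes.  A site is
    positive when the CI's lower bound exceeds the threshold, negative
    when the upper bound is below it, neutral otherwise; single-tree
    sites are reported neutral with a flag.
    """
    rows = []
    for site, slopes in slopes_by_site.items():
        slopes = [s for s in slopes if s is not None]
        if not slopes:
            raise ValueError(f"site {site}: no usable trees")
        arr = np.asarray(slopes, dtype=float)
        n = arr.size
        mean = float(arr.mean())
        if n < 2:
            rows.append(
                {
                    "site_id": site,
                    "n_trees": n,
                    "mean": mean,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "trend_class": "neutral",
                    "flag": "single_tree",
                }
            )
            continue
        se = float(arr.std(ddof=1) / np.sqrt(n))
        tcrit = stats.t.ppf(1 - alpha / 2, n - 1)
        lo, hi = mean - tcrit * se, mean + tcrit * se
        if lo > threshold:
            cls = "positive"
        elif hi < threshold:
            cls = "negative"
        else:
            cls = "neutral"
        rows.append(
            {
                "site_id": site,
                "n_trees": n,
                "mean": mean,
                "ci_low": lo,
                "ci_high": hi,
                "trend_class": cls,
                "flag": "",
            }
        )
    return pd.DataFrame(rows)
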