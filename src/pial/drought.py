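"""BAI drought response index and site-level classification.

The drought response index R_d is a Lloret-style resistance measure:
mean raw BAI over the drought water years divided by mean BAI over an
equal-length pre-drought window (default 2012-2015 vs 2008-2011, with
2012-2016 vs 2007-2011 as the robustness alternative).  Values above 1
mean the tree grew more during the drought than just before it.  Sites
are classified against the no-change value 1 using the t-based CI of
within-site tree indices.

A note on the classification threshold: an index defined as a ratio has
its null at 1, and the site figure convention (CIs overlapping 1) is
the internally consistent reading; the threshold is therefore 1, with
the deviation recorded in output metadata by callers that care.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from pial.treering import BAISeries

logger = logging.getLogger(__name__)


def drought_response_index(
    bai: BAISeries,
    drought: tuple[int, int] = (2012, 2015),
    reference: tuple[int, int] = (2008, 2011),
) -> float | None:
    """R_d = mean(BAI over drought window) / mean(BAI over reference window).

    Uses raw BAI (the ratio is already scale-free).  Both windows must
    be covered by the series; unequal window lengths only warn.  A zero
    reference mean excludes the tree (returns None, logged).
    """
    dlo, dhi = drought
    rlo, rhi = reference
    if (dhi - dlo) != (rhi - rlo):
        logger.warning(
            "tree %s: drought window %s and reference %s differ in length",
            bai.tree_id,
            drought,
            reference,
        )
    dmask = (bai.years >= dlo) & (bai.years <= dhi)
    rmask = (bai.years >= rlo) & (bai.years <= rhi)
    if dmask.sum() != dhi - dlo + 1 or rmask.sum() != rhi - rlo + 1:
        raise ValueError(
            f"tree {bai.tree_id}: series does not cover both windows "
            f"{drought} and {reference}"
        )
    ref_mean = float(bai.bai[rmask].mean())
    if ref_mean == 0.0:
        logger.info("tree %s: zero reference-window BAI, R_d undefined", bai.tree_id)
        return None
    return float(bai.bai[dmask].mean() / ref_mean)


def classify_site_response(
    indices_by_site: dict[str, list[float]], alpha: float = 0.05
) -> pd.DataFrame:
    """Classify site mean R_d against 1 with a t-based CI.

    Positive when the CI lower bound is above 1, negative when the
    upper bound is below 1, neutral otherwise; single-tree sites are
    neutral with a flag.
    """
    from pial.treering import classify_site_trends

    tab = classify_site_trends(indices_by_site, alpha=alpha, threshold=1.0)
    return tab.rename(columns={"trend_class": "response_class"})


def correlate(
    a: np.ndarray, b: np.ndarray, method: str = "pearson", exact: bool = False
) -> tuple[float, float]:
    """Correlation between two paired site/tree vectors with two-sided p.

    Pearson gives the product-moment r with its t-test p; Spearman uses
    average ranks for ties and the t approximation, or (``exact=True``,
    n <= 8) a full-enumeration permutation p.  Pairs with a missing
    value on either side are dropped.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if a.size < 3:
        raise ValueError(f"need >= 3 paired observations, have {a.size}")
    for name, v in (("a", a), ("b", b)):
        if np.std(v) == 0:
            raise ValueError(f"zero variance in {name}; correlation undefined")
    if method == "pearson":
        res = stats.pearsonr(a, b)
    elif method == "spearman":
        res = stats.spearmanr(a, b)
        if exact:
            if a.size > 8:
                logger.warning("exact Spearman p limited to n <= 8; using t approximation")
            else:
                return float(res.statistic), _exact_spearman_p(a, b)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


def _exact_spearman_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact permutation p for Spearman's r_s by full enumeration."""
    from itertools import permutations

    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    obs = abs(np.corrcoef(ra, rb)[0, 1])
    perms = np.array(list(permutations(rb)))
    rac = ra - ra.mean()
    pc = perms - perms.mean(axis=1, keepdims=True)
    rs = pc @ rac / (np.linalg.norm(pc, axis=1) * np.linalg.norm(rac))
    return float(np.mean(np.abs(rs) >= obs - 1e-12))
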