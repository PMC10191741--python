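"""Water-year aggregation, climate normals, and drought anomalies.

The hydrological water year (WY) runs October-September and is labeled
by its ending calendar year, so October 1999 belongs to WY2000.  Fluxes
(PPT, PET, AET, CWD) are summed within a water year; temperatures (Tmn,
Tmx) are averaged over the twelve months.  Normals are per-site means
and standard deviations over a reference span (default WY1970-WY1999);
drought anomalies are the mean of annual z-scores over a drought window
relative to a (typically longer) reference span.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SUM_VARS = ["PPT", "PET", "AET", "CWD"]
MEAN_VARS = ["Tmn", "Tmx"]


def water_year_aggregate(monthly: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a monthly site climate table to water years.

    ``monthly`` needs ``site_id``, ``year``, ``month`` columns plus any
    of Tmn, Tmx, PPT, PET, AET, CWD.  Water years with fewer than 12
    months are dropped with a warning.
    """
    for col in ("site_id", "year", "month"):
        if col not in monthly.columns:
            raise ValueError(f"monthly table lacks column {col!r}")
    df = monthly.copy()
    df["water_year"] = np.where(df["month"] >= 10, df["year"] + 1, df["year"])

    counts = df.groupby(["site_id", "water_year"]).size()
    incomplete = counts[counts < 12]
    if len(incomplete):
        logger.warning(
            "dropping %d incomplete (site, water_year) groups", len(incomplete)
        )
        df = df.set_index(["site_id", "water_year"]).drop(index=incomplete.index)
        df = df.reset_index()

    agg = {}
    for v in SUM_VARS:
        if v in df.columns:
            agg[v] = (v, "sum")
    for v in MEAN_VARS:
        if v in df.columns:
            agg[v] = (v, "mean")
    out = df.groupby(["site_id", "water_year"], as_index=False).agg(**agg)
    return out.sort_values(["site_id", "water_year"]).reset_index(drop=True)


def climate_normals(
    table: pd.DataFrame,
    span: tuple[int, int] = (1970, 1999),
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """Per-site mean and SD (n-1) of each variable over an inclusive WY span.

    Raises if any site does not cover every water year in the span.
    """
    lo, hi = span
    if lo > hi:
        raise ValueError(f"span {span} not ordered")
    variables = variables or [v for v in SUM_VARS + MEAN_VARS if v in table.columns]
    window = table[(table["water_year"] >= lo) & (table["water_year"] <= hi)]
    counts = window.groupby("site_id")["water_year"].nunique()
    want = hi - lo + 1
    short = sorted(set(table["site_id"])) if window.empty else list(counts[counts < want].index)
    if short:
        raise ValueError(f"sites not covering WY{lo}-WY{hi}: {short}")
    rows = []
    for site, grp in window.groupby("site_id"):
        for v in variables:
            rows.append(
                {
                    "site_id": site,
                    "variable": v,
                    "mean": grp[v].mean(),
                    "sd": grp[v].std(ddof=1),
                    "span_start": lo,
                    "span_end": hi,
                }
            )
    return pd.DataFrame(rows)


def drought_anomaly_zscores(
    table: pd.DataFrame,
    drought_window: tuple[int, int] = (2012, 2015),
    reference: tuple[int, int] = (1970, 2015),
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """Mean annual z-score over the drought window, per site and variable.

    z_t = (x_t - mean_ref) / sd_ref with the reference statistics taken
    over the reference span; the anomaly is the average of z_t over the
    drought window.  A zero reference SD leaves that site/variable
    missing (logged), never raises.
    """
    variables = variables or [v for v in ("Tmn", "PPT", "CWD") if v in table.columns]
    dlo, dhi = drought_window
    rlo, rhi = reference
    rows = []
    for site, grp in table.groupby("site_id"):
        ref = grp[(grp["water_year"] >= rlo) & (grp["water_year"] <= rhi)]
        dr = grp[(grp["water_year"] >= dlo) & (grp["water_year"] <= dhi)]
        if ref.empty or dr.empty:
            raise ValueError(f"site {site}: reference or drought window not in table")
        for v in variables:
            sd = ref[v].std(ddof=1)
            if not sd > 0:
                logger.warning("site %s %s: zero reference SD, anomaly undefined", site, v)
                z = np.nan
            else:
                z = ((dr[v] - ref[v].mean()) / sd).mean()
            rows.append({"site_id": site, "variable": v, "z": z})
    return pd.DataFrame(rows)
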