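"""Drought response index R_d and its climate-anomaly correlates.

R_d divides a tree's mean BAI over the drought years (2012-2015) by
its mean BAI over the four preceding years; values above 1 mean the
tree grew more during the drought.  Sites are classified against 1 by
the t-based CI of their trees, and site mean R_d is correlated with
the mean drought-year climate z-scores.
"""

import pandas as pd

from pial import dataio, treering, drought
from pial.climate import drought_anomaly_zscores

series = dataio.attach_tree_metadata(
    dataio.read_rwl("scratch/example_sim/rings.rwl"),
    pd.read_csv("scratch/example_sim/tree_meta.csv", comment="#"),
)
clim = dataio.read_climate_table("scratch/example_sim/climate.csv")

rd = {}
for s in series:
    b = treering.ring_widths_to_bai(s)
    r = drought.drought_response_index(b, drought=(2012, 2015), reference=(2008, 2011))
    if r is not None:
        rd.setdefault(s.site_id, []).append(r)
resp = drought.classify_site_response(rd, alpha=0.05)
print("site drought-response classes (threshold: CI vs 1):")
print(resp["response_class"].value_counts().to_string())

anom = drought_anomaly_zscores(clim, drought_window=(2012, 2015), reference=(1970, 2015))
wide = anom.pivot(index="site_id", columns="variable", values="z")
merged = resp.set_index("site_id").join(wide)
for var in ("PPT", "CWD", "Tmn"):
    r, p = drought.correlate(merged["mean"], merged[var], method="pearson")
    print(f"site mean R_d vs {var} drought z-score: r = {r:+.2f} (p = {p:.3f})")
print("\neach r asks whether sites with a stronger climate anomaly during the"
      "\ndrought also showed a stronger (or weaker) growth response")
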