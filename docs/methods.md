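# Methods

`pial` implements a dendro-genomic analysis linking radial growth,
water-year climate, and SNP genotypes across a network of subalpine
pine study sites.  This note records the models, their assumptions, the
defaults and why they were chosen, and what the synthetic-data tests do
and do not demonstrate.

## Tree-ring processing

**BAI conversion.** Ring widths (mm) are converted to annual basal area
increment, BAI_t = π(r_t² − r_{t−1}²) in cm²/yr, reconstructing radii
*outside-in*: the outermost radius is anchored at DBH/2 and each width
is subtracted walking toward the pith.  Anchoring at the measured
diameter keeps the recent decades — the analysis window — accurate and
pushes accumulated measurement error into the old core.  Bark thickness
is ignored when setting the outer radius; the bias is shared across
trees and cancels in the standardized series.  When DBH is missing the
summed ring widths stand in for the outer radius (logged).  Inner radii
that would go negative are clamped at zero with a warning, zeroing the
earliest increments.  For a series complete to the pith the increments
sum exactly to the stem disc area (π(DBH/2)²); incomplete series
conserve the annulus between core and bark.

**sBAI.** Each tree's BAI series is divided by its own whole-series
standard deviation (n−1), *before* any window filtering, yielding a
scale-free trajectory comparable between large and small stems.
Zero-variance series are flagged and excluded from trend analysis
rather than raising.

**Summaries.** Per-site summaries report the sample lag-1
autocorrelation of each raw width series and the mean pairwise
Spearman correlation between overlapping series (pairs overlapping
< 10 years excluded — the overlap minimum is a package default, as the
convention leaves it open).  No detrending or cross-dating is applied
anywhere: the pipeline consumes dated series.

**Trends.** Per-tree growth trend is the OLS slope of sBAI on calendar
year inside the analysis window (default 1970–2011; ≥ 10 in-window
years required).  Sites are classified by the t-based CI of their tree
slopes: positive if the lower bound exceeds 0, negative if the upper
bound is below 0, else neutral.  The CI is computed across tree slopes
(not pooled residuals) so between-tree heterogeneity is the error unit.
Tightening α can only move signed classes toward neutral.

## Water-year climate

A water year runs October–September and is labeled by its ending
calendar year.  Fluxes (PPT, PET, AET, CWD, mm) are summed within a
water year; temperatures (Tmn, Tmx, °C) are averaged over the twelve
months, unweighted, because the upstream water-balance deliverables
are monthly.  Normals are per-site means and SDs over WY1970–1999
(inclusive).  Drought anomalies are the mean of annual z-scores over
WY2012–2015 relative to WY1970–2015 statistics; a zero reference SD
leaves the anomaly missing.  CWD = PET − AET is validated at read
time.

## Growth–climate model

Site-level mean annual sBAI on a site × water-year panel (1971–2011,
the first year dropped to admit one-year lags) is regressed on
standardized Tmn, PPT and their lags:

    y = Xβ + ε,   ε_t = φ ε_{t−1} + u_t  within each site,
    sites independent.

The fit is exact Gaussian ML.  For trial φ the data are whitened with
the AR1 Cholesky factor (first in-site row × √(1−φ²); later rows
y_t − φ y_{t−1}), OLS on whitened data profiles out β and σ², and φ
maximizes the profile likelihood on (−0.99, 0.99) via a bounded scalar
optimizer at tolerance 1e−8.  ML rather than REML because AICc
compares fixed-effect structures, and REML likelihoods are not
comparable across them.  Grouping the AR1 process by site is the only
defensible reading of a site × year panel.  The parameter count for
AICc is k = (fixed effects incl. intercept) + 2 (φ and σ²); AICc =
−2ℓ + 2k + 2k(k+1)/(n−k−1) with n the pooled site-years.  Pseudo r² is
the squared Pearson correlation of fitted vs observed.

The candidate set is the standard seven structures (Tmn+PPT, its three
lag-augmented supersets, Tmn, PPT, intercept-only), ranked by AICc
with Akaike weights.  Two selection readings are exposed: the raw
AICc minimum, and `best_supported_model()` — the most parsimonious
model within ΔAICc < 4 of the minimum.  The latter is the package's
recommended rule: the probability that a superset with one spurious
term beats the true model under raw argmin is P(χ²₁ > ≈2) ≈ 0.16 per
superset *regardless of effect size*, so argmin selection plateaus
near 70% recovery; under the ΔAICc < 4 similar-support convention with
parsimony tie-breaking, recovery of a planted Tmn+PPT structure
exceeds 90%.

## Drought response

R_d = mean BAI over the drought window ÷ mean BAI over an equal-length
pre-drought window (defaults 2012–2015 vs 2008–2011; the 2012–2016 vs
2007–2011 robustness windows are supported).  Raw BAI is used — the
ratio is already scale-free.  R_d > 1 means more growth during drought.
Sites are classified against **1** by the t-based CI of tree indices.
A ratio index has its null at 1; classifying against 0 would mark every
site "positive" vacuously, so the threshold-1 reading (the one
consistent with the index definition and the site-figure convention) is
adopted.  Spearman correlations use average ranks and the t
approximation; an exact enumeration p is available for n ≤ 8.

## Population genomics

**Filtering** applies, in order: optional individual call-rate filter;
locus call rate ≥ 0.8; one SNP per parent (RAD) locus, lowest position
winning; minor-allele frequency ≥ 0.02 recomputed on the filtered
matrix.  Dosages are oriented to the dataset-wide minor allele at read
time so downstream statistics are orientation-stable.  The filter is
idempotent and reports per-step attrition.

**FST** is Weir & Cockerham's (1984) θ from per-locus variance
components a (among populations), b (among individuals), c (within
individuals), aggregated ratio-of-sums: θ = Σa / Σ(a+b+c).  Sample
sizes are missing-adjusted per locus; loci observed in fewer than two
populations are skipped.  The global CI is a seeded percentile
bootstrap over loci.  Pairwise θ is computed per site pair the same
way; negative estimates are reported as computed.  This estimator was
chosen over AMOVA-style alternatives as the field standard with
explicit finite-sample correction; estimates from different FST
formulations are close but not identical, which the output metadata
records.

**Diversity.** uHe = (2n/(2n−1))(1 − p² − q²) per site and locus, with
n the called diploids; site value = mean over loci ± SE.  π is
computed per biallelic variant site, which makes it identical to uHe
by construction; haplotype-wise multi-site π (with kernel smoothing) is
out of scope and the two diverge only there.

**PCA** imputes missing calls to the per-locus mean dosage, centers
(optionally scales) columns and takes the SVD; PCA is the only place
mean imputation is used — FST and diversity use observed calls only.

**Mantel test.** r is the Pearson correlation over
strictly-lower-triangle entries of the genetic and geographic
(Euclidean UTM, single zone assumed) distance matrices; the null
jointly permutes rows/columns of the genetic matrix;
p = (1 + #{r* ≥ r}) / (n_perm + 1), one-sided, seeded.  Raw FST (not
FST/(1−FST)) is the default genetic distance.

## Genotype–environment association

**Imputation** for ordination replaces missing calls with the locus's
modal genotype (ties → lower dosage), per the standard RDA-based
genome-scan protocol.

**Predictor screening.** Site 30-year normals of the six climate
variables, expanded to individuals by site membership, are screened by
greedy forward selection: at each step the candidate adding the most
adjusted R² enters if its permutation partial-F p < 0.05 and every VIF
(1/(1−R²_j) of each selected predictor on the others) stays ≤ 10.

**Partial RDA.** Genotypes Y and predictors X are residualized on
[1, Z] with Z = standardized UTM northing + easting; the fitted values
of the multivariate regression of Y-residuals on X-residuals are
decomposed by SVD.  Eigenvalues are fitted-covariance eigenvalues
(S²/(n−1)); locus loadings are axis-scaled right singular vectors
(covariance-preserving "species" scaling; unit scaling via flag);
individual scores are Y-residuals projected on the axes (WA scores);
biplot scores are correlations of predictors with the constrained (LC)
axes.  R² = fitted share of residualized variance; R²_adj uses the
Ezekiel correction 1 − (1−R²)(n−g−1)/(n−g−m−1).  A predictor matrix
fully absorbed by the conditioning returns zero constrained variance;
partial rank deficiency raises.

The pipeline runs the RDA with each dosage column scaled to unit
variance (correlation-style RDA).  Without scaling, per-locus binomial
sampling variance differs by allele frequency, loadings are a variance
mixture (leptokurtic), and the ±3 SD outlier rule over-flags neutral
loci by several-fold; scaling restores the rule's nominal calibration
(≈ 2Φ(−3) ≈ 0.27% per axis).

**Inference.** Permutations shuffle rows of the residualized response
(reduced-model residual scheme, the standard for conditioned
ordination); pseudo-F = (SS_fit/m)/(SS_res/(n−g−m−1));
p = (1 + #{F* ≥ F})/(n_perm + 1).  Axis k is tested sequentially with
axes 1..k−1 added to the conditioning; marginal term tests drop one
predictor with the rest conditioned.  n_perm < 99 is refused.

**Outliers.** On each significant axis (sequential p < 0.05), loci
with |loading − mean| > 3 SD are flagged; the union over axes counts
each locus once, and each outlier is assigned the climate variable
with the largest |Pearson r| against its dosage column.  Per-axis
phenotype linkage uses Spearman correlation between individual axis
scores and the per-tree drought response index, over the individuals
shared between genotype and ring-width datasets.

## Synthetic data

The generators emulate the study's statistical structure with recorded
truth; one RNG stream per generator, child seeds derived from the
master seed by fixed offsets, so regenerating one input never perturbs
another.

* **Climate** (27 sites, WY1970–2020): sites on a 39→36°N gradient;
  Tmn trends upward at 0.03 °C/yr with N(0, 0.7) noise plus site
  microclimate offsets (N(0, 0.5) °C, and N(0, 0.15) on log PPT)
  representing aspect/cold-air-pooling/rain-shadow variation that is
  *orthogonal to the geographic gradient* — without it, conditioning
  on UTM would absorb nearly all climate signal and no
  genotype–environment association would be detectable even in
  principle.  PPT is lognormal with a shared regional year effect
  (SD 0.25).  Drought-year (2012–2015) PPT is rescaled per site so its
  mean sits 1.5 reference SDs below the WY1970–1999 mean (or 30% below
  the mean in the zero-variance limit), guaranteeing the > 1 SD
  deficit.  PET rises with Tmn, AET rises with PPT, CWD = PET − AET.
* **Ring widths**: log BAI_{i,t} = μ_i + s_i(t−t₀) + 0.15·z(Tmn) +
  0.05·z(PPT) + ε, ε AR1(φ=0.6, innovation SD 0.32).  Growth is
  generated on log BAI so climate effects are multiplicative and
  widths stay positive; BAI is inverted to widths through equal-area
  annuli from a 0.2 cm pith radius, and DBH is recorded as twice the
  final radius.  Site slopes default to 0; planted slopes and a
  per-tree drought multiplier (for power experiments) are available.
* **Genotypes** (default 22 sites × 15, mirroring a genetic subset of
  the cored network): neutral site frequencies follow a logit-scale
  Gaussian field with covariance 0.25·exp(−d/150 km) around a
  Beta(0.8, 0.8) ancestral frequency — a stepping-stone surrogate
  giving low global θ (~0.02) with strong isolation by distance
  (Mantel r ≈ 0.9).  Adaptive loci: logit p = logit(p₀) + γ·z(normal),
  γ = 1.5, driving variable drawn per locus from the six normals.
  γ is calibrated only so that recovery experiments have their stated
  power, not to match any natural effect size.  Calls are
  Binomial(2, p), masked missing at 20%.  Genotyped individual ids
  reuse the tree-core naming so phenotype linkage works end-to-end.

**What passing tests show — and don't.** The synthetic world has no
linkage disequilibrium, no sequencing-depth-correlated missingness, no
population-size heterogeneity, no selection dynamics over time, and
climate noise that is Gaussian and stationary apart from the planted
trend.  Passing recovery tests therefore demonstrates the estimators
and scans are correctly implemented and calibrated under their own
assumptions; they say nothing about robustness to real ddRAD artifacts
or non-stationary climate forcing.

## Experiment sizes

Simulation experiments are sized for tight feedback while keeping
every rate estimable: GLS coverage/selection uses 200 replicates of
the full 27 × 41 panel; drought classification power plants the
per-tree index distribution directly (28 trees, multiplier 1.3,
CV 0.2) over 100 seeds; bootstrap CI behavior uses 500 island-model
datasets (6 × 10 × 150 loci); permutation type-I error uses 1000 null
simulations at 199 permutations each; outlier recovery uses 20 seeds
of 50 planted among 2000 neutral loci at 22 × 15 individuals, without
missingness (the ordination's detection power is the property under
test; random loss of planted loci to the call-rate filter would
confound it).  The acceptance script re-runs the full pipeline at
2050 loci with 199 permutations and 500 bootstrap draws.

## Known limitations

* The AR1 profile likelihood is unimodal in all tested regimes but is
  optimized by a bounded scalar method; pathological multimodality
  would be found only by the grid-comparison property test.
* Pairwise FST loops over site pairs in Python; at hundreds of sites
  this becomes the dominant cost (the study scale of ~22–27 sites is
  fast).
* Axis-sequential permutation tests re-fit under augmented
  conditioning; their power interpretation follows the standard
  constrained-ordination convention, not an exact finite-sample
  theory.
* π is defined per variant site; comparisons against haplotype-wise π
  from RAD assemblies are approximate by design.
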