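# Methods

## The estimation problem

`mesozoo` estimates taxon-resolved mesozooplankton biomass from direct
dry-weight (DW) measurements of net-haul samples, and analyses the
resulting samples × taxa biomass matrices. The measurement chain it
models is the standard one for formalin-preserved WP2 hauls: a vertical
tow with a 0.25 m² net, a Motoda split into 1/4, 1/8 or 1/16 depending
on plankton density, dilution of one part to 200 ml, repeated 2-ml
pipette subsamples from which individuals of each taxon are pooled into
pre-weighed boats, drying, and weighing on a microbalance. Each weighed
boat yields one record: taxon, number of individuals, weight gain,
split, and number of subsamples used.

## The biomass chain

For a record with raw gain *g* (mg), split *s* ∈ {4, 8, 16}, and *k*
2-ml subsamples, the chain is

1. **Error subtraction.** Distilled-water control boats (three per
   sample) estimate the container-residue weighing error; its mean ē is
   subtracted from every gain. The control mean is tested against 0
   with a one-sample t-test.
2. **Reliability filter.** Corrected gains must exceed 4 × SD of the
   control gains (0.043 mg at the default SD of 0.01075 mg) or the
   record is flagged unreliable. Unreliable records are retained with
   the flag, never deleted, and excluded from all downstream statistics.
   The threshold is applied after subtraction (a config switch applies
   it to the raw gain instead).
3. **Formalin correction.** Preservation is assumed to remove 40 % of
   the dry mass; the measured mass is divided by (1 − 0.40). The exact
   quotient is used, not the rounded ×1.67 display value, to avoid
   compounding rounding.
4. **Areal standardization.**
   areal = mass × s × (200 / (2 k)) / 0.25 mg DW/m².
   Standardization is per record, because different taxa of one sample
   may come from different numbers of subsamples. No tow-depth
   normalization is applied; the depth-ratio helper (1 : 2 : 5.4 for
   40/80/215 m stations) expresses when per-area values imply equal
   per-volume biomass.
5. **Individual mean DW** = corrected (error- and formalin-corrected but
   **not** standardized) mass / number of pooled individuals.
6. **Carbon and energy.** Areal biomass × taxon-specific factors
   (mg C/mg DW and J/mg DW) from the packaged 28-taxon registry.

Size classes split at 1 mm mean length (SMZ/LMZ) with three deliberate
exceptions: *Calanus* nauplii are SMZ and copepodites LMZ (the only
taxon weighed stage-separated), while *Limacina retroversa* and
*Oikopleura* spp. are assigned entirely to LMZ because their pooled
weighings are dominated by individuals far above 1 mm.

Carbon/energy conversion is applied after formalin correction and
standardization: the factors are taken to be per mg of living-equivalent
DW. This ordering is a documented package assumption.

`BiomassProcessor` wraps steps 1–6 as a scikit-learn estimator
(`fit` = control summary, `transform` = weighing table → biomass table)
so the chain composes with sklearn tooling; the step functions remain
available individually.

## Length-weight evaluation

The formula registry holds three *Calanus* and five *Oithona* methods
in their original units (mg/mm and µg/µm respectively), including one
fixed-value method (0.003 mg/ind) and one power form divided by an
AFDW:DW ratio of 0.9. Log-linear and log-log forms use base-10
logarithms — the convention of the source literature; base e would put
the log-linear *Calanus* method orders of magnitude away from its two
siblings, which is asserted by a cross-method consistency test.

Per sample, the calculated mean individual DW is the **mean of
per-individual evaluations** over all length measurements, never the
evaluation at the mean length (the power forms are convex, so the two
differ by Jensen's inequality). The ratio
100 × calculated / measured is banded as under (<80 %), satisfactory
(80–120 %, closed boundaries — the edge semantics are a package choice)
or over (>120 %). Event summaries average the ratio across stations
unweighted; SD is null for single-station events. *Calanus* nauplius
and copepodite lengths are pooled per sample by default (a stage-split
option exists).

## Multivariate suite

All analyses operate on the samples × taxa areal-biomass matrix and are
customarily run twice: complete matrix and SMZ-only subset.

- **Hellinger transformation** y′ = √(y_ij / y_i+): row-wise, places
  nonzero rows on the unit sphere, bounds Euclidean distances by √2 and
  makes abundance-type data suitable for Euclidean ordination. The
  square root is essential to these properties and is part of the
  standard definition.
- **PCA** is covariance-based (centered, unscaled) on the transformed
  matrix; correlation-based PCA is available behind a flag. Both
  site-focused and species-focused score scalings are exposed because
  biplot conventions differ.
- **Clustering method selection.** Four linkages — single, complete,
  UPGMA, Ward (the Ward.D2 variant on Euclidean distances) — are fitted
  on the Euclidean distances of the transformed matrix. The method
  whose cophenetic distances correlate best (Pearson) with the
  originals is selected; ties break on Gower's dendrogram-fit criterion
  Σ(d_orig − d_coph)². "Gower" here is the dendrogram-fit sum of
  squares, not the mixed-data dissimilarity.
- **Cluster-number diagnostics** per k: fusion level, mean silhouette
  width (singletons score 0 by convention), and the Pearson correlation
  between the original distances and the binary different-cluster
  indicator. A suggested k is produced by majority vote (largest
  fusion-height jump, max silhouette, max binary correlation; ties to
  the smallest k) but is advisory: the full table is always emitted so
  the user can apply judgment.
- **Species contribution analysis.** For each cluster pair, taxon j
  contributes (c_Aj − c_Bj)² / Σ_k (c_Ak − c_Bk)² of the squared
  centroid difference in the transformed space; contributions sum to 1
  and taxa at ≥ 2× the average (7 % for 28 taxa, 13 % for 15) are
  flagged. This centroid decomposition satisfies the normalization the
  published contribution tables display; the original literature
  formula is not reprinted there, so the weighting may differ in
  detail.
- **Variation partitioning.** The community matrix is regressed
  (multivariate least squares) on a seasonal predictor — sine and
  cosine of 2π·doy/365, so that dates across the year boundary are
  close — and on the station factor as indicator contrasts (any
  full-rank coding gives identical R²). Adjusted R² uses the Ezekiel
  correction with m = rank of the centered predictor matrix. Fractions:
  a = adjR²(both) − adjR²(station), c = adjR²(both) − adjR²(date),
  b = adjR²(date) + adjR²(station) − adjR²(both), d = 1 − adjR²(both);
  a + b + c + d = 1 exactly. Negative fractions are reported as-is and
  conventionally read as 0. The 365-day denominator (not 365.25) is
  immaterial at eight events per year.

scipy provides the linkage/cophenetic machinery and scikit-learn the
PCA and silhouette computations; each is cross-checked in the test
suite against independent brute-force reimplementations (explicit
agglomeration, dense covariance eigensolver, double-loop silhouette,
minimax-path distances for single linkage).

## Synthetic surveys

The generator draws surveys from a fully specified truth so every
estimator in the package can be validated end to end.

Per station × event and taxon: the haul count is Poisson (optionally
gamma-mixed for overdispersion) with mean areal abundance × 0.25 m²;
lengths are log-normal with a per-event median (growing cohorts);
individual fresh DW follows a per-taxon power law coef·(L mm)^exp, with
an optional per-event weight multiplier to emulate condition changes at
fixed length. Capture by the 200-µm mesh is Bernoulli with a logistic
length curve (midpoint 550 µm, scale 65 µm: ≈0.09 at 400 µm, ≈0.999 at
1000 µm), emulating the severe under-catch of sub-500-µm individuals;
`ideal_capture` disables it. One Motoda part (split chosen from haul
density: ≥8000 individuals → 16, ≥4000 → 8, else 4 — the thresholds are
a scenario choice) is kept by binomial thinning, its individuals are
spread uniformly over the 100 possible 2-ml aliquots, and aliquots are
pooled per taxon until 100 individuals are reached. The weighing gain
is the pooled formalin-reduced (×0.6) fresh mass plus one additive
Normal(0.016, 0.01075) mg error draw; each sample also gets three
pure-error control records. The control SD default 0.01075 mg is
back-derived from the 4 × SD = 0.043 mg threshold; 0.011 is an equally
acceptable reading of that rounded value.

The truth table records, per sample × taxon, the water-column
quantities **before any observation effect**: areal fresh biomass,
areal abundance, and mean individual DW. The weighing table also
carries the error-free pooled mass of each record so the additivity of
the weighing error is directly testable (regression slope of residual
on true mass ≈ 0).

The default scenario — 3 stations (40/80/215 m) × 8 events spanning
September–August, 16 scenario rows over ~15 taxa — reproduces the
qualitative structure such surveys show: a *Calanus*-like copepod
holding a dominant (>80 %) share of annual biomass concentrated over
the deep trough, a pteropod peaking in autumn, cirripede nauplii
peaking April–May with a cohort growing from 392 to 703 µm median
length, amphinomid polychaete larvae confined to the July event, and a
year-round backdrop of small copepods and meroplankton. Abundances and
allometric coefficients are scenario choices of realistic magnitude,
fixed once; they are not fitted to any data set. What the generator
does **not** emulate: advection and patchiness beyond Poisson noise,
vertical migration, multi-net depth stratification, taxonomic
misidentification, or taxon-dependent formalin loss. Passing
recovery tests therefore demonstrate correctness of the estimation
arithmetic under the stated observation model, not robustness to those
field realities.

## Numerical and testing choices

- The recovery guarantee is an unbiasedness statement: over 200
  replicate surveys with ideal capture, the absolute median of the
  signed relative error of estimated vs true areal biomass per abundant
  taxon stays below 5 %. The median of the signed error is the quantity
  that converges; individual replicates retain subsampling noise.
- The pure-noise variation-partitioning null uses matrices dimensioned
  like a one-year, three-station survey (24 × 28): the partition
  fractions a, b, c stay within 0.05 in ≥95 % of 200 replicates. The
  spread of adjusted R² grows as taxa get fewer, so the bound is
  specific to matrices of roughly this width.
- Degenerate inputs: equal pairwise distances make the cophenetic
  correlation undefined (flagged NaN); constant matrices yield
  all-zero PCA eigenvalues with a warning; zero community rows pass
  through the Hellinger transform as zeros with a warning; identical
  cluster centroids make contributions undefined for that pair.
- Simulations in the test suite are sized to keep the default run in
  seconds: recovery uses a 2-station × 2-event, 3-taxon scenario for
  its 200 replicates; oracle equivalence uses n ≤ 7 point sets over 100
  seeds and n ≤ 20 for silhouette checks.

## Known limitations

- Unknown taxa are carried through with null conversion factors and a
  warning rather than rejected; their records never enter carbon/energy
  or fraction outputs.
- The packaged event fixture fills two sampling dates that the source
  tables do not print with plausible placeholders (noted in the data
  dictionary).
- The `stats` CLI subcommand, when given only a biomass table,
  approximates day-of-year from the event ordering; use the library
  API with the events table for exact circular predictors.
- The species-contribution decomposition is centroid-based; rank-based
  or dispersion-weighted variants of contribution analysis would weight
  taxa differently.
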