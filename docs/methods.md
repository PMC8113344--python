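# Methods

This note documents the models and procedures the package implements,
the defaults and why they were chosen, the numerical decisions taken
where the method description left room, and what the synthetic test bed
does and does not establish.

## Grid and masking contract

All rasters live on one shared grid (`GridSpec`): 0-based, row-major
pixel indices referenced to pixel centers, square pixels (30 m default,
the framework's working resolution), a projected CRS assumed (no
geodesic area correction; areas are pixel count × pixel area). Inputs
must be co-registered; any grid mismatch raises rather than resampling,
because silent resampling would quietly change the statistics every
later stage depends on. The validity mask is four-valued
(valid/cloud/shadow/nodata); cloud and shadow are treated identically
to nodata in every computation — the distinction exists only for
bookkeeping and simulation.

Raster files are TIFFs carrying the GeoTIFF ModelPixelScale and
ModelTiepoint tags plus a JSON description (band names, CRS id, nodata
sentinel, scene metadata), written and read by `annualcover.io` with
exact round-trip of values, mask and grid.

## Harmonization

Band-respective linear transforms place TM/ETM+ reflectance on the OLI
scale and relate OLI and MSI; both packaged coefficient sets have
positive slopes, so harmonization is strictly monotone per band and
preserves value ordering. Harmonized values are **not** clamped to
[0, 1]: near saturation the transforms can leave the nominal range, and
clamping would bias composites; a warning is logged when values leave
the tolerant range [−0.2, 1.6] instead. The OLI↔MSI set can be applied
in either direction via the algebraic inverse
(slope, intercept) → (1/slope, −intercept/slope), since the direction
of the published row is not self-describing.

## Compositing

* **Medoid**: per pixel, the valid observation minimizing the summed
  Euclidean distance (over the selected bands) to all other valid
  observations; a single observation is its own medoid; no observation
  ⇒ NaN. Ties on the distance sum break to the lexicographically
  smallest band vector, making the result independent of scene order
  (a guaranteed tie occurs with exactly two observations).
* **Percentile medoids**: "the seasonal extreme composite" is realized
  by ranking each pixel's valid observations by NDVI (or by the band
  itself for single-band stacks), anchoring at the nearest-rank
  position of the q-th percentile (index `round(q/100·(V−1))`), taking
  a window of `ceil(V/3)` observations centered there, and returning
  the window's medoid. With ≤ 2 valid observations it degenerates to
  the plain medoid. The window fraction is configurable; the defaults
  keep the "returns a real observation" property of the medoid while
  targeting the phenological extremes.
* **Standard deviation** is population (ddof = 0) — a descriptive
  per-pixel dispersion, not an estimator of anything; fewer than two
  observations report 0.
* **SAR covariates**: seasonal means of VV and VH in dB and
  nd_VHVV = (VH−VV)/(VH+VV) computed from the seasonal means (fewer
  nodata holes than averaging per-scene ratios; |VH+VV| < 1e−9 ⇒ NaN).
  Ascending and descending orbits are kept as separate layers when both
  appear, since their geometry-dependent backscatter should not be
  averaged blindly.
* **Lee filter**: the classic adaptive form out = m + W(x−m),
  W = var/(var + noise_var) with window statistics computed over valid
  pixels only; noise_var defaults to the image mean of the local
  variances. Window must be odd, ≥ 3.
* **Terrain**: Horn's eight-neighbor finite differences on an
  edge-padded DEM; aspect is the azimuth of the **down-slope**
  direction, degrees clockwise from north in [0, 360), NaN on flat
  cells. (Stated explicitly because both up- and down-slope conventions
  are common.)

Seasons: dry = April–September, wet = October–March labeled by the
October year; the month sets are configurable but must partition the
year.

## Spectral indices

All seventeen indices are evaluated exactly as their printed formulas;
any pixel with a missing band or a denominator magnitude below 1e−9 is
NaN, never ±inf. Where a formula says a generic "swir", the 1.6 µm band
is used for EBBI, MVI, NDBaI, NDBI, NDPI and UI and the 2.2 µm band for
NBR, following each index's source literature; every choice is
overridable per call. Consequences worth knowing: with a common swir
band NDBI and UI are the same formula and NDBI ≡ −NBR (asserted in the
tests); the normalized-difference indices are bounded in [−1, 1] for
nonnegative inputs; NDVI-like ratio forms (including ARVI, a ratio of
homogeneous linear forms) are invariant to a common positive scaling of
all bands, while EVI, SAVI, DVI and EBBI are not, because their
formulas contain additive constants or a square root. The thermal band
enters only NDBaI and is used in its stored calibration (a scaling hook
exists; the index is dimensionless either way but its values depend on
the thermal units).

## Training migration

A sample migrates from the reference year iff its six-band signatures X
(reference) and Y (target) pass the unchanged test. Decisions taken
where the description is ambiguous:

* Comparisons are **inclusive** (ED = 0.05 exactly is retained).
* The 0.95 SAD threshold is implemented under **both** readings —
  literal (angle ≤ 0.95 rad, the default) and cosine similarity
  (cos(angle) ≥ 0.95) — because the published number is genuinely
  ambiguous between them; the choice is a parameter, not a guess baked
  in.
* The two criteria combine with **AND** by default: conservative
  retention minimizes label noise, which is the model's purpose.
* Signatures are sampled from the **annual** composite (per-band mean
  of the dry and wet medoids, one season alone where the other is
  nodata); per-season signatures are available by passing the seasonal
  composites directly.
* Samples with nodata in either year are dropped and reported
  separately; they are neither retained nor counted as change.

Retention is monotone in both thresholds, and SAD-only decisions are
invariant to a common positive scaling of both years (tested). A
threshold grid-search helper supports the trial-and-error calibration
workflow.

## Fusion classifier

Per collection, a random forest (200 trees, max_features 8 clamped to
the feature count, impurity importances, fixed seed) emits class priors.
Fusion: p′ = c·p + (1−c)/N with c = 0.7 and N = the taxonomy's class
count (18 at level 2) — both configuration, not constants — followed by
the product over contributing collections. The floor (1−c)/N = 1/60
guarantees every class a strictly positive posterior at any pixel with
at least one contributing collection, so one zero-vote collection
cannot annihilate three confident votes (worked value: 0.716667³·(1/60)
= 6.13e−3, still the argmax against uniform voters).

A collection that is **nodata at a pixel is skipped** — it contributes
no factor — rather than entered at the floor: the floor's rationale
concerns observed-but-zero priors, and flooring absent data would drag
gap pixels toward uniformity. The strict alternative
(``missing="floor"``) is available for comparison. Posteriors are kept
as unnormalized products (argmax-invariant); normalized output is a
flag. Argmax ties break to the lowest class id.

Feature pruning keeps the smallest importance-ranked prefix reaching a
cumulative-importance retention (default 0.95, chosen as a conventional
"keep nearly all signal" level; no published value exists); retention
1.0 is an explicit no-op so zero-importance features are not silently
dropped at full retention. Collections train on the samples they
validly observe; per-collection missingness at training pixels is a
property of gappy data, handled by fusion, not an error.

`FusedForestClassifier` packages the same scheme as a scikit-learn
estimator over column-block feature matrices (NaN marks a sample
missing for a block); with one block and c = 1 it reduces exactly to a
single random forest, which the tests assert prediction-for-prediction.

## Accuracy assessment

Stratified sampling draws n (default 1050) pixels uniformly without
replacement per **mapped** class — so confusion-matrix column totals
equal n. Rows are reference, columns are map. Metrics: OA, PA (row),
UA (column), F1 = harmonic mean of PA and UA reported on 0–1, kappa on
0–100, and SEM = the binomial standard error of UA,
100·√(ua(1−ua)/n_col) — this is the reading of "standard error of the
mean for UA" that reproduces the published SEM rows exactly at
n = 1050, and is therefore adopted. Zero denominators yield missing
values, never 0. The OA uncertainty is the simple binomial 95%
half-width 1.96·√(oa(1−oa)/total); note the published uncertainty
(±1.2% at n = 10,500) is larger than this quantity (±0.53%), so the
published interval was evidently computed some other, unstated way —
the discrepancy is documented here rather than reconciled.

Level merging aggregates the 18 secondary classes onto their 10 primary
parents (counts conserved exactly); confusion confined to siblings
vanishes under merging, so primary-level OA is never lower on such
matrices.

The packaged 2020 validation matrices (level 1 and level 2) reproduce
every published per-class metric; a single published F1 cell (level-1
aquaculture, 0.96) disagrees with its own published PA/UA pair, whose
harmonic mean is 95.49 → 0.95 at two decimals — a double-rounding
artifact in the source table, absorbed by a 0.01 tolerance in the
tests.

## Change analysis

Change frequency counts label changes between consecutive maps; pixels
nodata in **any** compared year are excluded from every count and
transition (the gap-handling policy, applied uniformly). Net change is
annualized, p = 100·(A_t2−A_t1)/(A_t1·(t2−t1)), positive for gain,
undefined (missing) when A_t1 = 0. "Most dynamic class" ranking
rescales **absolute** rates min-max onto [0, 100] (signed rates are
retained alongside); an all-equal input rescales to zeros. Transition
matrices are exact area flows over jointly valid pixels, and their
marginals equal the area series restricted to the joint mask — an
identity the tests assert, not an approximation.

## Synthetic test bed

The simulator generates, per class: a six-band mean reflectance drawn
uniformly in [0.03, 0.55] under a guaranteed minimum pairwise
separation (measured as ‖Δμ/σ‖₂ in per-band noise-SD units, rejection
sampling with bounded retries), an additive wet-season offset
(σ = 0.03), SAR means with VV ∈ [−17, −6] dB and VH 3–9 dB below VV,
and a thermal mean. Pixel values add independent Gaussian noise
(σ = 0.02 reflectance, 1.5 dB SAR — representative of surface
reflectance product noise and speckle-filtered backscatter
variability). Clouds are random rectangles accumulated to the target
cover fraction (patchy and spatially correlated, exercising
gap-handling in fusion; rectangles are at most a fifth of the scene
side so the overshoot stays within a few percent); SAR scenes are never
cloud-masked, reproducing radar's gap-filling role. Truth maps are
Voronoi mosaics of seeded class points; scripted conversions flip a
seeded random fraction (or an explicit region) of a class in a given
year, cumulatively. Everything is deterministic under a seed.

What the synthetic bed does **not** emulate: radiative transfer,
band-correlated or spatially correlated noise (a mixing-matrix hook
exists), sensor geometry and PSF, phenology beyond a single seasonal
offset, and mixed pixels. Passing recovery tests therefore demonstrate
the pipeline's correctness and its behavior under gaps and planted
change — not real-world accuracy, which depends on class separability
that real landscapes do not guarantee.

**Recovery study defaults** (`annualcover.study.run_recovery_study`):
6 classes at ≥ 5 SD separation on a 128×128 grid (a desk-scale stand-in
for the national mosaic), 2 seasons × 3 scenes of optical + SAR, 30%
cloud, 200 training pixels/class migrated from the reference year, 20%
of one class converted between the years, validation stratified over
the map with training pixels excluded. Under these conditions held-out
OA is ≈ 100% and migrated-training purity 100%, with retention around
60% — the strict default thresholds discard a substantial share of
genuinely unchanged but noisy pixels, which is the intended
conservative trade-off.

## Known limitations

* No reprojection, mosaicking or resampling: inputs must share a grid.
* No area-weighted (design-based) accuracy and area estimation; the
  implemented metrics are the naive stratified suite the published
  tables use.
* The thermal band is used as stored; NDBaI values are
  calibration-dependent.
* Region-wise modeling (one model per administrative region) is
  supported only through per-region runs; region geometry is user
  input.
* The migration model migrates and filters; it never relabels or
  augments samples.
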