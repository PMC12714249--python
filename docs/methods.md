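# Methods

`benthicmap` implements an integrative benthic-habitat classification
pipeline: terrain attributes derived from fine-resolution bathymetry and
summer sea-surface-temperature (SST) composites derived from a stack of
thermal scenes are joined to drop-camera ground truth in four cover
classes (bare substrate, kelp-dominated, mixed macroalgae, red turf), a
Monte-Carlo random-forest ensemble is trained and assessed on repeated
70/30 splits, and every fitted model votes on every map cell to produce a
nine-category confidence map. This note records the models, the parameter
choices that matter, the numerical conventions, and what the synthetic
study area does and does not establish.

## Terrain attributes

All attributes are computed on elevation (negated depth, positive up) so
directional conventions match terrestrial DEM practice.

* **Slope and aspect** use Horn's 3×3 weighted finite differences. Slope is
  degrees from horizontal; aspect is the down-slope compass bearing in
  [0, 360). Zero-gradient cells receive a flat sentinel (−1), and
  `aspect_to_components` maps that sentinel to northness = eastness = 0
  rather than letting it leak into trigonometry — a flat cell has no
  direction, and cos(−1°) would silently fabricate one. Border cells and
  cells adjacent to nodata are nodata.
* **Mean curvature** is the Zevenbergen–Thorne quadratic-surface value
  −2(D+E), reported so positive = convex-up (a dome-shaped shoal), scaled
  by 100 (the common per-100 m GIS convention; the factor is
  configurable).
* **VRM** (vector ruggedness measure) sums unit surface normals
  n = (sin S sin A, sin S cos A, cos S) over a moving window (default
  3×3 cells) and reports 1 − |Σn|/n_valid. It is 0 on any plane and grows
  toward 1 as facet orientations decohere. Using the count of *valid*
  cells in the denominator keeps nodata from inflating ruggedness.
* **Geomorphons** code each cell's 8 compass rays by line-of-sight relief
  within a lookup distance (default 10 cells): each ray's largest upward
  and largest downward relief angles are summed and compared against a
  flatness angle (default 2.5°), giving +/0/−. The (count of −, count of +)
  pair indexes the standard ten-form lookup table, reconstructed from its
  published antisymmetry (dual pairs peak/pit, ridge/valley,
  shoulder/footslope, spur/hollow), then collapsed to six forms — peak and
  spur count as ridge, pit and hollow as valley — mirroring the reduced
  form sets used in bathymetric segmentation. Rays that leave the grid
  before seeing a valid cell count as level; cells on the grid edge are
  therefore classified from the rays they do have, which biases edges
  toward flat. The lookup distance is not a settled convention and is
  exposed as a parameter.
* **Aggregation** to the 30 m analysis grid assigns each fine cell to the
  coarse cell containing its centre, which also handles non-integer
  resolution ratios (e.g. 4 m → 30 m). Continuous layers take the mean of
  valid members; the six one-hot geomorphon indicators take the majority
  (fraction ≥ 0.5 → 1).

## SST compositing

Scenes carry temperature (Kelvin) plus a QA bitmask whose semantics are
defined by this package (bit 0 cloud, bit 1 cloud shadow; real satellite QA
decoding is out of scope). The chain is: mask flagged pixels → reject
scenes whose masked fraction over the area of interest strictly exceeds
25% (a scene at exactly 25% is retained, reading "greater than" literally)
→ convert to Celsius → reduce to per-cell mean, median, sample (n−1)
standard deviation, and range. Cells observed in fewer than `min_obs` = 3
scenes are nodata in all four layers: a standard deviation over one or two
looks is noise. Both choices (sample sd, min_obs) are configurable; the
compositing order matters only for reporting, since the Celsius shift
commutes with everything else.

## Predictor stack and collinearity screen

The stack holds 10 continuous layers (depth, slope, curvature, northness,
eastness, VRM, SST mean/median/sd/range) plus the 6 landform indicators;
the analysis mask requires AOI membership, depth ≥ 1 m below datum
(removing land and intertidal cells), and validity in every layer. The
screen draws one shared random sample of 10,000 mask-valid cells (all of
them, with a warning, if fewer exist) and computes pairwise Pearson
correlations among the continuous layers. For each pair with |r| ≥ 0.7 the
member appearing later in an explicit priority list is dropped: median
over mean, sd over range (the statistic more robust to outliers wins), and
depth plus the terrain attributes are never dropped. Indicator layers are
exempt; constant layers have undefined correlations and are reported as
NaN, not collinear. On the synthetic study area this reliably discards
exactly SST mean and SST range, leaving 14 predictors.

## Monte-Carlo random-forest ensemble

Simulation *i* seeds every random draw from `base_seed + i`, draws a
simple random (unstratified) 70/30 split — redrawn with a warning in the
rare event a class misses training entirely; a stratified option exists —
and fits a random forest with ntree = 215, mtry = 6, nodesize = 1 and
unlimited maxnodes (scikit-learn's `RandomForestClassifier` is the
learner; the protocol and statistics around it are this package's).
Recorded per simulation:

* training accuracy = 1 − OOB error;
* validation accuracy on the held-out 30%;
* one-vs-rest precision, recall and F1 per class (F1 = 2PR/(P+R), defined
  as 0 when P + R = 0);
* permutation importance as Mean Decrease in Accuracy: for each tree, the
  predictor's values are shuffled among that tree's own out-of-bag cases
  and the OOB accuracy drop recorded, averaged over trees, in raw
  percentage points (unscaled by its standard deviation). Per-class
  columns restrict the accuracy to that class's cases. Out-of-bag
  membership is reconstructed from each tree's seed with the same draw the
  bagging implementation uses; a test verifies the reconstruction by
  reproducing the forest's own OOB score exactly.

Ensemble summaries are means and standard deviations across simulations.
Per-class F1 is the mean of per-simulation F1s, *not* the F1 of mean
precision and recall — the two differ, and the convention is asserted in a
test. The overfit diagnostic is mean train − mean validation accuracy.
Hyperparameter sweeps (`tune_hyperparameters`) evaluate any grid over
ntree / mtry / maxnodes / nodesize / n_sim with a reduced Monte-Carlo run
per point.

Drop-cluster identifiers travel with the training table but are ignored by
the default split, so observations from one camera drop can straddle
training and validation; this replicates the original survey protocol and
inflates absolute accuracy relative to a spatially blocked split. A
group-aware split is deliberately not the default.

## Confidence mapping

Every simulation's model classifies every valid cell; votes are tallied
per cell. The plurality class is tiered by its agreeing fraction f:
f ≥ 0.75 high confidence, 0.50 ≤ f < 0.75 low confidence, f < 0.50 or a
tied plurality → no-majority (ties are never broken toward a class). Both
tier boundaries are inclusive at their lower edge; with 175 simulations
f = 0.75 exactly cannot occur, so the choice is inert at defaults but
fixed for other ensemble sizes. The map is masked to 50 m depth. Cover
percentages are computed over valid (non-nodata) cells only and therefore
sum to 100 by construction.

## Synthetic study area

The generator emulates an island-group coastal site so the whole pipeline
is testable without external data. Bathymetry (default 240×240 cells at
5 m; the benchmark uses 1200×1200) is a large-scale smooth relief field
plus Gaussian island shoals plus fine-scale roughness whose local
amplitude varies *independently* of the relief — that independence is what
keeps slope and VRM below the 0.7 collinearity threshold and gives VRM
information of its own. With non-zero amplitudes the field is stretched to
span emergent land (< 0 m) to > 50 m water. The 5 m → 30 m resolution
ratio is an integer (6) so aggregation tests are exact; the aggregation
itself supports the 4 m → 30 m non-integer case.

Thermal scenes (default 16) share a base pattern — a cross-shore ramp in a
seed-random direction plus a smooth anomaly — and differ by demeaned
scene-wide offsets multiplied by a smooth "exposure" field plus pixel
noise. The exposure field gives the per-cell temporal spread real spatial
structure, which is why SST sd and range emerge strongly collinear
(r > 0.9) and carry information, while mean and median are nearly
identical (r > 0.9): the screen's expected outcome arises from the physics
of the emulation, not from hard-coding. Per-scene cloud fractions are
drawn from a configured range and imposed by quantile-thresholding a
smooth field, so the 25% rejection rule has real work to do.

Ground truth emulates 61 camera drops drifting across 2–5 contiguous
(4-connected) 30 m cells each, ~210–250 observations in total. Labels
follow a multinomial logit on standardized (depth, VRM, median SST) with
Gumbel noise: bare favours smooth cells, kelp deep cool cells, red turf
shallow warm cells, mixed rugged warm mid-depth cells. Intercepts are
calibrated by a deterministic softmax fixed point so realized class
proportions match the configured priors (default 0.32/0.31/0.18/0.19, the
survey-style imbalance); without calibration the middle class is starved.
Default label noise is 0.5; the low-noise benchmark uses 0.05, where a
forest trained on the three rule variables alone exceeds 0.9 validation
accuracy.

What passing tests on this generator establish: the plumbing is correct
end to end, the statistics implement their stated conventions, and the
ensemble recovers a known signal (the three rule variables occupy top
importance ranks) without overfitting (|gap| < 0.05). What they do not
establish: performance on real surveys — the generator has no spatially
correlated label error, no georeferencing error, no tide or heatwave
dynamics, and its class boundaries are smoother than real ecotones, so
synthetic accuracies (~0.85–0.95) exceed what field data yield.

## Reference benchmark and problem sizes

`benthicmap.study.recovery_config` fixes the parameter-recovery benchmark:
1200×1200 bathymetry cells (200×200 analysis cells), noise 0.05, 50
simulations — chosen as the scale at which recovery stabilizes while a
full run stays under a minute on one CPU. The default test suite runs a
smaller 180×180-cell area with 8 simulations for everything except the
benchmark itself.

## Known limitations

* Geomorphon output near grid edges is biased toward flat (truncated
  rays); real deployments should buffer the AOI.
* The QA bitmask is a two-bit stand-in; Landsat Collection-2 semantics are
  intentionally out of scope.
* Raster I/O is plain-text ESRI ASCII grid via an in-package reader/writer;
  projection metadata is limited to cell size and origin.
* Determinism is contractual within one package version and the pinned
  scikit-learn: forests re-seeded from the same integers reproduce
  bit-identical metrics, but not across library versions.
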