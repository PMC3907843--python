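# Methods

This note documents the models, estimators, parameters and design choices
behind `stromspat`, and what the synthetic validation does and does not
demonstrate about natural material.

## Coordinate system and calibration

All geometry is carried in micrometres with the origin at the top-left
image corner, x rightward and y downward, so the mat surface sits near
y = 0 and depth increases with y. Rasterisation happens once, at mask
construction or rendering. The default map calibration is a 512 × 512 px
frame spanning 682.67 × 682.67 µm (1.33333 µm/px), overridable through
`Window`. Microsphere calibration fields default to a 5× finer window
(0.26667 µm/px over 136.53 µm) so that 1.0-µm spheres are resolved by
several pixels; at the map calibration a bacterium-sized object occupies a
single pixel, which is adequate for area bookkeeping but not for
per-object area measurement.

## Synthetic scenes

### Point processes

Two generative hypotheses for SRM positions:

* **CSR** (homogeneous Poisson / binomial with fixed n) — the null, under
  which g(r) ≡ 1.
* **Thomas process** — Poisson parents of intensity κ, Poisson(µ_off)
  offspring per parent displaced by an isotropic Gaussian of scale σ_c.
  Parents are simulated in a 4σ guard margin so the retained pattern has
  intensity κ·µ_off without edge deficit. Its pair correlation,
  g(r) = 1 + exp(−r²/4σ²)/(4πκσ²), is the closed-form oracle used by the
  tests.

No quantitative clustering parameters exist for natural mats; the defaults
(σ_c = 2 µm, µ_off = 30) are chosen to reproduce the qualitative contrast
between a flat ĝ ≈ 1 curve and a curve rising steeply at sub-cluster
distances, and nothing downstream depends on their exact values.

### Mat scenes

A scene is built mineral-first: Type-2 scenes draw one crust thickness
uniformly from 30–50 µm and lay a crust band following the surface line,
carved by three ~8-µm gaps (near-continuous, not perfect); Type-1 scenes
scatter 60 cell-scale microprecipitate patches (radius 1–2.5 µm) through
the upper 200 µm. Two ooids (radius 40–70 µm) sit deeper in both types.
Cyanobacterial filaments are wavy polylines (2 px wide, dashed with 2-µm
gaps to exercise discontinuous-filament detection) near the surface; other
bacteria are disks with truncated-normal radii (0.5 ± 0.1 µm, matching the
1.0-µm microsphere proxy) spread uniformly through the top 500 µm. The
surface profile is a sinusoid (amplitude 8 µm, period 170 µm, offset
20 µm) by default, or flat.

SRM are then added one cell at a time — from a CSR stream (Type-1) or a
layered Thomas stream with 90 % of candidates confined to the top 130 µm
(Type-2) — until the rasterised SRM share of total cell area inside the
surface buffer zone reaches the planted target (20.7 % for Type-1, 88.0 %
for Type-2). Stopping on the measured mask ratio makes the planted
abundance exact at mask level by construction, independent of overlap and
rasterisation effects. A configurable fraction of SRM (0.4 / 0.5) is
seated near precipitates to give the proximity analysis its structure;
for patch scenes at most one SRM is seated per patch, because the patches
are cell-scale and unrestricted seating would concentrate several cells on
one patch and plant spurious clustering into the nominally random Type-1
pattern. Crust seating (a continuous band) has no such cap.

Type-1 densities are deliberately low (150 other bacteria, one filament,
~80–100 SRM per frame). Under the 10-µm linkage rule a CSR pattern
percolates into large chance components once the mean degree λπr²
approaches ~0.2; at the chosen densities the expected number of >5-cell
chance components per scene is below 10⁻², so "selected clusters absent"
is a stable property of the Type-1 state rather than a coin flip. Type-2
scenes carry 400 other bacteria and a few thousand clustered SRM.

### Rendering and noise

Channels follow the staining semantics: `probe` (FISH) carries SRM and
microspheres, `counterstain` (general DNA stain) carries all bacteria
including SRM and cyanobacteria, `reflectance` carries minerals. Objects
are drawn at 100 intensity units, blurred by a Gaussian of σ = 0.1 µm (the
lateral PSF scale of a high-NA confocal at ~500 nm), and overlaid with a
background offset (default 10) plus Gaussian noise of sd = peak/SNR
(default SNR 10). A fraction of cell-like objects (20 % in mats, 10 % in
the thin aqueous microsphere mounts) is rendered at 0.5× / 0.6× intensity
to mimic items below the focal plane. A fixed scene seed yields
bit-identical scenes and images.

## Classification

* **Supervised**: minimum-distance-to-class-mean in channel space — the
  smallest deterministic model consistent with classifying from
  "representative pixels"; invariant to uniform intensity rescaling.
  Because cyanobacteria and other bacteria share the counterstain
  signature, they are separated morphologically, not spectrally.
* **Two-class**: iterative 2-means on intensity, at most 20 global
  reassignment iterations, stopping when ≥ 95 % of pixels keep their
  assignment between iterations; the brighter cluster is foreground.
* **Filament subtraction**: pieces up to `max_gap` (3 µm) apart are
  grouped by dilation (plain morphological closing cannot bridge thin
  dashes — the erosion step removes the one-pixel connecting lens);
  a group is filamentous when its bridged skeleton reaches `min_length`
  (10 µm) and the moment elongation of its original pixels reaches
  `min_elongation` (5). These two thresholds are free choices; the
  defaults separate 40-µm filaments from 1-µm cocci by a wide margin.
* **Co-localization**: probe objects are retained whole when ≥ 50 % of
  their area overlaps the counterstain (the criterion "both fluorescence
  signatures present" made quantitative).
* **Counting rule**: 8-connected components; non-border components of at
  least half the typical object area count as one object each; the
  remaining border/sub-size fragments are pooled and their total area
  divided by the typical area, rounded — so two half-cells at opposite
  borders sum to one.

## Microspatial statistics

* **Buffer zone**: from the per-column surface line down
  round(depth/px) rows; the default depth is 133.33 µm = 100 map pixels
  (the commonly quoted "approximately 130 µm" is this quantity rounded).
  The surface line itself is the per-column topmost foreground pixel,
  median-smoothed over 5 columns, with empty columns linearly
  interpolated; it is translation-equivariant by construction.
* **Abundance**: 100 × |SRM ∩ zone| / |(SRM ∪ other ∪ filaments) ∩ zone|.
  An empty denominator raises an undefined-result error rather than
  returning 0 — no cells is not the same claim as no SRM.
* **Clusters**: cells link when their 10-µm concentric regions overlap
  (centroid distance strictly < 10 µm); clusters are connected components;
  selection requires strictly more than 5 members. Cluster area is the
  dissolved union of member disks (what a GIS buffer-dissolve measures,
  computed with shapely at 64-segment circle approximation, ~0.1 % low);
  the raw member footprint area is reported alongside when cell radii are
  known.
* **Pair correlation**: ring-count estimator with translation edge
  correction c_ij = (W−|dx|)(H−|dy|)/(WH) — appropriate for a bounded
  image window where toroidal wrapping would be wrong. Grid r = 0.1–6.44
  µm (64 points), ring width 0.25 µm; auto-correlation excludes
  self-pairs and divides by n(n−1). The CSR envelope is the pointwise
  min/max over matched-count uniform resamplings (default 39); simulated
  curves are retained on the result object so callers can build
  band statistics. The *clustering call* used in validation requires ĝ
  above the upper envelope at ≥ 5 consecutive grid points within
  r ≤ ~3 µm: a single chance close pair lights at most ~3 consecutive
  rings (ring half-width 0.125 µm vs 0.1-µm grid step), so sparse random
  patterns do not trigger it, while clustered patterns exceed the
  envelope over long runs.
* **Proximity**: Euclidean distance transform of the precipitate mask
  scaled to µm; an object is "near" at threshold t when its minimum pixel
  distance is ≤ t; the statistic is the percentage of near bacteria that
  are SRM at t = 1.1, 2.2, 4.4 µm. The µm thresholds are taken as
  authoritative over their pixel paraphrase (0.75/1.5/3 px at the map
  calibration is 1.0/2.0/4.0 µm, an inconsistency in the original
  description). Note that at the 1.33-µm map calibration the smallest
  threshold only admits objects whose pixels touch the precipitate mask
  (distance 0), so that entry is undefined when no cell overlaps a
  precipitate — the result carries an explicit `defined` flag.

## Calibration and statistics

The microsphere series renders 5 dilutions × 5 replicate fields with
Poisson per-field counts around c·(1, ½, ¼, ⅛, 1/16), c = 200 by default.
Known concentration is expressed as expected spheres per field. Each field
passes through two-class classification; direct counts use the counting
rule; area-derived counts divide total foreground area by π(0.5)² µm².
The three Pearson correlations are invariant to the unit-area choice, and
the outputs label area-derived counts as relative estimates.

Group comparisons use the Welch t-test (the unequal-variance form is the
safer reading of an unqualified "t-test") or one-way ANOVA with
Bonferroni-corrected pooled-MSE pairwise t-tests and Scheffé contrasts
(pairwise F vs (k−1)·F_crit) at α = 0.05. The arcsine-square-root
transform is available for percent data and the log for positive skewed
data; group means and SEs are always reported on the original scale.

## Problem sizes used in validation

The automated checks run at desk scale: oracle equivalence on ≤ 60-point
patterns and ≤ 48² masks; CSR calibration of the ĝ estimator over a few
hundred 300-point patterns; Thomas closed-form agreement over 30
replicates; planted-scene recovery and three-way discrimination over 20
seed pairs of full 512² scenes; the dilution series at 25 fields; and the
type-I-error calibration of the two-group test over 2000 null replicates
(rate required within 0.05 ± 0.01).

## What passing tests do and do not show

The generator plants exactly the structure the analysis is designed to
detect: disk-shaped cells, a single-valued surface, stationary noise, and
cluster geometry from one parametric family. Passing therefore shows the
chain is *correct* (each stage recovers what was planted, and the
estimators agree with exact oracles and closed forms) — it does not show
the chain is *robust* to everything natural mats add: irregular cell
morphology, EPS autofluorescence gradients, overhanging or multivalued
surfaces, 3-D structure projected into 2-D, and uncertain extraction
efficiencies. Headline measurements on natural micrographs (abundance
percentages, proximity tables, correlation coefficients) depend on those
factors and on the specific slides imaged; the synthetic targets emulate
their structure, not their exact values.
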