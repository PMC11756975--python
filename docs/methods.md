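# Methods

This note documents the models, parameter choices and numerical
conventions behind `quadvol`, and what the synthetic test-bed does and
does not establish about real data.

## Coordinate and unit conventions

All coordinates are metres, z-up. The sampling frame is 0.4 × 0.5 m
(0.2 m²) with plot-local coordinates; the vertical datum is arbitrary —
every computation uses relative heights, never absolute z. All clipping
and gridding uses half-open intervals `[min, max)` so a point can never
fall in two cells or on both sides of a frame edge. Volumes are carried
internally in m³ and reported in cm³; biomass is in grams dry weight.

## Denoising

Statistical outlier removal: for each point the mean Euclidean distance
to its k nearest neighbours (k = 10 default); a point is discarded when
that distance exceeds μ + m·σ of the cloud-wide distribution (m = 1.0
default). An absolute-distance mode (`mode="absolute"`, threshold in
metres) is provided as an alternative because the literature this
follows is ambiguous about whether its quoted threshold is a σ
multiplier or a distance; the σ rule is the cited algorithm's
definition and is the default. One pass only; the filter can never
remove a point's whole neighbourhood (output keeps at least k+1
points in practice since thresholds are relative).

## SMRF ground filtering

Pingel-style simple morphological filter:

1. minimum-z raster at 1 cm cell size (matching the CHM/terrain grid;
   the plot is only 0.4 × 0.5 m, so coarser cells would leave too few
   for the morphology);
2. empty cells inpainted from the nearest populated cell;
3. progressive greyscale opening with disk windows of radius r = 1..10
   cells; a cell is flagged non-ground at radius r when it exceeds the
   opened surface by more than `elevation_scale · slope_threshold · r ·
   cell_size` (0.9 · 0.1 · r · 0.01 m at defaults) — the slope-scaled
   growing threshold of the original filter, with the elevation scale
   as a single multiplier on that growth;
4. the provisional ground raster (non-flagged minimum cells, flagged
   cells re-inpainted from their nearest ground cell) is compared
   against every point: within 11 cm → ground, else vegetation.

The 11 cm elevation threshold is deliberately permissive for this
vegetation type: the litter mat (a few cm) and the bases of grass stems
land in the ground class, and the refinement stage is responsible for
pulling them back out. The comparison uses |Δz| so far-below-surface
noise is also excluded from ground.

## Iterative Gaussian-mixture refinement

On the current ground class, a per-point roughness feature is computed
and split by a two-component 1-D Gaussian mixture (EM, deterministic
initialisation at the 10th/90th percentiles, 100 iterations max,
tolerance 1e-6, posterior ties to the low component); the high-mean
component — rough, vegetation-like — is a *candidate* merge into the
vegetation class. The candidate is accepted only if it increases the
vegetation voxel volume (5 mm edge) by more than 5%; the first
rejected candidate is reverted and iteration stops (10-pass safety
cap). Accepted merges are additive: points move only ground →
vegetation, so the vegetation class grows monotonically.

The feature is *surface variation* λ₃/(λ₁+λ₂+λ₃) of the covariance of
each point's k-neighbourhood (k = 50 on the first pass, 200 on
subsequent passes, each pass consuming the previous pass's ground
output): 0 for planes, 1/3 for isotropic scatter, bounded and cheap.
Soil is smooth (values ~0.005 at the defaults), litter and stems rough
(~0.1–0.3), which is exactly the bimodality the mixture exploits. Raw
elevation is available as an alternative feature
(`RefineParams(feature="elevation")`) since elevation-based clusters
can be competitive on mostly-flat plots, but curvature is the default:
it is invariant to terrain relief.

Two termination details are package decisions worth recording:

* *evaluate-then-accept*: measuring the improvement before committing
  the merge (rather than merging and stopping afterwards) means a
  sub-threshold split leaves the labels exactly as they were. On bare
  terrain the mixture would otherwise split the unimodal soil-curvature
  distribution in half and swallow good ground points.
* *empty vegetation class → stop*: relative improvement over a zero
  volume is undefined; refinement terminates immediately. A bare plot
  therefore reports (near-)zero vegetation volume instead of
  manufacturing one.

## Terrain surface and above-surface selection

The terrain model is linear interpolation over a Delaunay triangulation
of the ground-classified points, evaluated at 1 cm cell centres — exact
on planes, the standard DEM choice; cells outside the triangulation
hull take the nearest ground point's elevation, so the grid has no
empty cells. "Above surface" is strict (z > cell elevation): a
ground-touching duplicate point contributes no height.

## Volumetric estimators

* **CHM**: maximum height-above-terrain per 1 cm cell; empty cells
  filled by inverse-distance weighting (power 2, cell-centre distances,
  target cell excluded) over a 7 × 7 window; cells with no populated
  neighbour stay empty and are excluded from the plot mean. Volume =
  mean height × 0.2 m² by construction.
* **Convex hull**: exact hull volume of the nonground points; fewer
  than 4 points or a degenerate (coplanar) set yields volume 0 with a
  degeneracy flag rather than an error.
* **Voxels**: cell index `floor((p − origin)/edge)` per axis, occupancy
  = at least one nonground point, volume = occupied count × edge³.
  The grid origin is anchored at the frame corner at the terrain
  minimum — the origin is otherwise arbitrary, and fixing it makes runs
  reproducible. The sweep covers 2–100 mm edges. Voxelization uses
  absolute z of vegetation-labeled points by default (presence/absence
  of nonground material); the above-surface variant voxelizes only
  points above the fitted terrain.

With a shared origin and nested edges (e, 2e, 4e, …) voxel volume is
provably non-decreasing in edge length — each occupied fine cell lies
inside an occupied coarse cell — and the acceptance suite asserts zero
violations.

## Allometry and evaluation statistics

Linear (`biomass = a + b·V`) and log (`ln biomass = a + b·ln V`,
natural logs) models by OLS; a semi-log variant is available. R² is
reported on the fitting scale; RMSE is always back-transformed to
grams so forms are comparable. Fits are screened by Cohen's
f² = R²/(1−R²) with achieved power from the noncentral-F distribution
(df 1 and n−2, noncentrality f²·n, α = 0.05), significant when power ≥
90%. Voxel-size distributions are compared by *paired* Wilcoxon
signed-rank tests (the same plots are measured at every size), exact
null for ≤ 25 pairs, normal approximation with continuity correction
above, Holm correction across the pair family (uniformly more powerful
than Bonferroni at the same family-wise error rate). Method agreement:
mean absolute relative difference (reference denominator),
total-least-squares line via the principal eigenvector of the centred
2 × 2 covariance, and Lin's concordance correlation coefficient with
population (n-denominator) moments.

## Synthetic scenes: what they emulate

Each scene is an analytic description with exact labels:

* **terrain** — sum of three low-frequency sinusoids (wavelengths
  0.25–0.6 m, total amplitude 2 cm): smooth soil microtopography;
* **litter** — random discs accumulated until the measured cover (2 mm
  mask) is within ~±1.5% of the target (60% default, the share of AGB
  litter typically reaches in these systems); the mat is a 3 cm shell
  whose *top surface only* is sampled (passive SfM cannot see inside a
  mat), with 4 mm Gaussian roughness;
* **stems** — 300 curved cylinders (radius 1–3 mm, heights 5–60 cm,
  random lean and bow), rooted on the terrain and preferentially
  (80%) inside litter patches — annual grasses grow up through their
  own prior-year litter. Stem points are sampled as rings along the
  axis with a top-weighted capture probability (seed heads and awns
  dominate what SfM reconstructs of a fine stem; mean capture 25% of
  the surface), and no point forms on a stem segment buried inside the
  mat;
* **sampling** — jittered-lattice sampling at 5 × 10⁵ points/m² (the
  realistic lower end for this kind of reconstruction; chosen as the
  package's standard problem size so the 20-scene suites run in
  minutes on one CPU) with a hard 1 mm minimum spacing enforced by a
  final close-pair sweep — mirroring clouds filtered to a minimum
  point spacing;
* **occlusion** — soil points beneath litter are removed with
  probability 0.7; stems are treated as too thin to occlude the
  ground.

The biomass generator is an explicit power law
`total_g = 800 · (V / 7·10⁻³ m³)^1 · exp(N(0, 0.5²))` — the reference
volume is a typical scene's true 5 mm voxel volume, which puts the
cohort mean near the ~900 g scale of the target system — split 60%
litter, with the remaining vegetation divided
annual:perennial:forb = 0.8:0.15:0.05.

What passing tests *do* show: the classification recovers known labels
under heavy litter cover and occlusion (ground recall and vegetation
IoU near 0.99 on the default suite), surface errors propagate only
weakly into 5 mm voxel volumes (~1% mean relative difference between
reconstructed- and reference-surface volumes), the estimators obey
their exact invariants, and the regression machinery recovers known
generating parameters at the target cohort size.

What they do *not* show: real SfM noise is spatially correlated
(matching failures, shadows, wind-blurred stems), real litter is
fibrous rather than a rough shell, and rocks — which the classifier
deliberately does not remove — are absent by default. Field
performance will be worse than the synthetic recovery numbers; the
synthetic suite validates the *machinery*, not the field error rates.

## Problem sizes

The acceptance suite and script use 20 scenes at the default
conditions (~190 000 points per plot), a 100-repetition × n = 288
allometry simulation, and a 40-plot varied cohort (stem counts 30–600,
litter cover 0.2–0.9) summarised by true voxel volumes. These are the
package's standard reproducibility conditions; all randomness derives
from a single seed.

## Known limitations

* SMRF window growth uses disk footprints on a small raster; very
  large continuous mats (beyond the 10-cell maximum window) are
  handled by the GMM stage, not the morphology.
* The 5% improvement rule is measured per GMM pass (not per 50→200
  neighbour cycle); this is configurable but not exhaustively studied.
* The reference-surface comparison needs a 2 mm margin above the soil
  to exclude soil-noise points; the margin is configurable
  (`PipelineConfig.reference_margin_m`) and interacts with the soil
  noise level.
* LAZ (compressed LAS) is not supported; decompress to LAS first.
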