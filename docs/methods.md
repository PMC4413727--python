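# Methods

`rootspace` quantifies how neighboring plant root systems occupy shared
soil volume, starting from voxel volumes in which every voxel is labeled
with the individual it belongs to (as produced by slice-wise annotation of
micro-CT stacks). This note records the models, conventions and numerical
choices behind each stage, and what the synthetic test bed does and does
not establish.

## Coordinate and voxel conventions

Volumes are indexed `(x, y, z)`, 0-based, with z increasing downward.
Voxels are isotropic with edge length `resolution_mm`; voxel `k` along z
spans the half-open interval `[k·h, (k+1)·h)` below `z_origin` and its
*center* depth is `z_origin + (k + 0.5)·h`. All reported coordinates,
depths and distances are voxel-center quantities in mm. Annotation colors
are matched by exact RGB equality — label colors are synthetic flat codes,
not photographic values.

## Synthetic root scenes

Because measured root volumes of this kind are rarely shareable, the
package ships a generator that produces two-species scenes with exact
vector-model ground truth. Each root system grows as a chain of 1 mm
straight segments:

- Per step the direction is blended toward vertical by the gravitropism
  weight `g` (`d ← (1−g)·d + g·ẑ`, normalized) and then rotated by a
  normal angular jitter (`tortuosity_sd_deg`) about a uniformly random
  perpendicular axis.
- Lateral roots arise as a Poisson process along their parent
  (`lateral_rate_per_mm`), inserting at the parent's step endpoints at a
  normal insertion angle with uniform azimuth, up to `branching_depth`
  orders. The apical (final) step of an axis never branches, so every axis
  ends in an unambiguous terminal segment; tips are the distal ends of
  terminal segments.
- Ground truth is closed-form over segments: length `Σℓ`, lateral surface
  `Σ2πrℓ`, volume `Σπr²ℓ`. Surface area deliberately ignores end caps and
  branch-junction overlap, matching what the slice-perimeter estimator
  measures.

Two presets encode the study's architectural contrast. `aspen_like`
(densely branched, two lateral orders: taproot 140 mm × r 0.9 mm, lateral
rate 0.28 /mm, lateral length ~N(20, 8²) mm, r 0.35 mm, g = 0.12) yields
on the order of 250 tips and 5 m total length; `spruce_like`
(taproot-dominant: taproot 110 mm × r 0.8 mm, rate 0.11 /mm, laterals
~N(9, 4²) mm, single order, g = 0.30) yields ~12 tips and ~0.2 m. These
magnitudes (tip counts, total lengths) sit at the levels reported for
2-month-old seedlings of the two species, but the radii are deliberately
coarser than real fine roots (~0.1 mm) so that scenes voxelize cleanly at
the desk-scale 0.5 mm test resolution; the presets are geometric
archetypes, not parameter estimates of any measured plant.

Scenes place one individual on the container axis (control) or two at
symmetric offsets of half the container radius (intra-/inter-specific
pairs) inside a cylinder of 64 mm inner diameter whose imaged depth is
150 mm. All stochasticity flows through one `numpy` generator seeded per
scene (`base_seed + replicate index`), making every fixture bit-for-bit
reproducible.

### Voxelization

A voxel belongs to a segment when its center's axial projection falls
inside the segment and its radial distance is at most the segment radius
(finite-cylinder membership, no end caps — the convention whose expected
volume equals the ground truth `Σπr²ℓ`). Overlapping claims between
individuals go to the nearer centerline, ties to the lower id. With
`wall_exclusion` on, each vector model is first cut where a root's
surface would touch the container wall (radial distance ≥ wall radius −
segment radius) and all distal material is dropped — emulating annotation
protocols that stop tracing at wall contact. A warning is issued when any
segment radius falls below half the voxel size (undersampling).

## Morphometry

- **Volume**: occupied voxels × `h³`. At `h = 0.1 mm` each voxel
  contributes 10⁻³ mm³.
- **Surface area**: per x-y slice, every 8-connected cross-section is
  boundary-traced (Moore neighborhood, starting at the top-left-most
  pixel, terminating on re-entry of the start with the same successor);
  the perimeter is the closed polygon length through boundary-pixel
  centers, scaled by `h`, times the slice thickness `h`, summed over
  regions and slices. Degenerate cross-sections use the pixel-edge
  fallback (1 pixel → 4h, domino → 6h), keeping the estimator positive and
  additive. Chain-code polygons overestimate smooth circumferences by
  ~4–5%; slicing is x-y only, so oblique roots carry the same geometric
  bias as slice-wise estimates generally do. Multiple disconnected
  cross-sections in one slice are summed.
- **Depth profile**: occupied-voxel volume binned by center depth,
  half-open bins `[kw, (k+1)w)` with the final bin closed; conservation
  (`Σ bins = volume`) is exact by construction.
- **Volume-weighted mean depth**: mean center depth over occupied voxels,
  computed on voxels (never on bins) so it is independent of any bin
  width.

## Skeletons and root tips

The binary volume is reduced to a 1-voxel-wide curve skeleton by
*sequential distance-ordered homotopic thinning*: simple points
(Bertrand's two-count characterization — one 26-connected foreground
component in the punctured neighborhood and one 6-connected background
component among the face-reachable 18-neighbors) are deleted in ascending
order of the Euclidean distance transform, re-examining every candidate
against the current image, until stable. Curve endpoints (≤1 foreground
neighbor) are never deleted. Sequential deletion guarantees exact
topology preservation for every input, including width-symmetric objects
for which parallel thinning schemes can mis-delete; the deletion order is
deterministic (EDT value, then flat index).

Thinning thick, tortuous digitized roots leaves short terminal spurs
where surface bumps pull the medial axis outward. Terminal branches are
therefore pruned when their Euclidean length is at most the
distance-transform radius at their junction plus one voxel — a genuine
lateral extends well beyond its parent's radius, a bump spur cannot.

Root tips are the degree-1 nodes of the pruned skeleton, minus the collar:
per connected component, the shallowest endpoint (ties broken by
(z, x, y)) is the stem entry point and never counts as a tip. The collar
rule can be disabled for sensitivity analysis.

**Accuracy.** On sparse thin-root systems at resolution ≤ half the
lateral radius, detected tip counts match the vector-model truth to
within ±1–3 tips per system. The residual noise is irreducible at the
voxel level: near-apex forks and bend spurs add endpoints, adjacent tips
merge, and sub-radius laterals vanish inside their parent. On dense,
crowded systems count errors grow to the 10–20% scale. Tip *positions*
of matched tips are accurate to ~1 voxel. Downstream statistics use many
tips per group, which damps this noise; single-system tip counts should
be read with those error bars in mind.

### Tip spatial statistics

- **Minimum tip–tip distance**: for each tip, the Euclidean distance to
  the nearest *other* tip of the same individual (k-d tree, but contracted
  to equal the brute-force all-pairs result exactly). Defined only for ≥2
  tips.
- **Radial-distribution ellipse**: tips are projected to the x-y plane;
  the orientation comes from the eigenvectors of the 2×2 covariance of
  the projected cloud, and each semi-axis is the maximum absolute
  projection of any centered tip onto that axis, so all tips lie within
  the ellipse's extents. The radial distribution is the ellipse area
  `π·a·b` (semi-axes); the directionality ratio `a/b ≥ 1` is 1 for
  circularly symmetric spread and ≫1 for planar root placement. The
  "area = π times both axes" phrasing found in the applied literature is
  ambiguous between semi- and full axes (a factor of 4); this package
  uses semi-axes, the true ellipse area. Requires ≥3 non-collinear tips.

## The tip-distance model

Minimum tip–tip distances are right-skewed and resist log/exp/reciprocal
normalization. They are modeled by the two-parameter growth-and-decay
density

    f(x) = c1 · x · e^(−x/c2),

a Gamma(shape 2, scale c2) density up to normalization: `∫f = c1·c2²`, so
the normalized density has `c1 = 1/c2²`, mode `c2`, and mean `2·c2`.

Fitting follows the histogram-regression estimator class: distances are
binned (default width 1 mm, density-normalized), and `(c1, c2)` are least
squares against bin-center heights (`scipy.optimize.curve_fit`, parameter
and function tolerances 10⁻⁸, ≤10⁴ evaluations). Initialization is
closed-form: `c2⁰ = mean/2` (the normalized model's moment estimate) and
`c1⁰ = peak·e/c2⁰` (peak matching, since max f = c1·c2/e). Goodness of
fit is `SS_reg/SS_tot = 1 − SS_residual/SS_total` about the mean bin
height. Non-convergence sets a flag rather than raising. The Gamma
maximum-likelihood estimator (`ĉ2 = mean/2` on raw distances) is more
efficient and serves as an independent cross-check in the test suite, but
the histogram estimator is the contract. Bin width, normalization, and
the SS convention are configurable because the estimator class leaves
them open; the defaults above are what the pipeline reports.

## Group statistics

Treatments (control / intra- / inter-specific) are compared per species
with the Kruskal–Wallis rank test (tie-corrected H, chi-square p with
k−1 df) at family α = 0.05; all-equal data is flagged degenerate with
H = 0. Only when the family null is rejected are pairwise two-sided
Wilcoxon rank-sum (Mann–Whitney) tests run at α = 0.05/3 ≈ 0.01667
(three treatment pairs; configurable). Pairwise tests use exact
enumeration when both groups have n < 10 and the pooled data is tie-free,
otherwise the tie-corrected normal approximation with continuity
correction (identical groups then give p = 1).

The observation unit is recorded per comparison: scalar morphometrics are
compared at the individual level (n = 1–6 per group), while tip-level
parameters (distances, tip depths) pool tips across individuals within a
group. Pooling inflates effective sample size and ignores within-container
correlation (pseudo-replication); the pipeline reproduces this analysis
style deliberately and labels it, rather than silently mixing units.

Validation regressions constrain the intercept to zero:
`b = Σxy/Σx²` with R² about zero. Regressing voxel-measured surface area
and tip count on the generator's analytic (untruncated) ground truth
makes the slope a *capture fraction* — with wall exclusion on and roots
extending beyond the imaged depth, slopes fall below 1, mirroring how 3D
renderings capture only part of what a destructive harvest recovers.

## Problem sizes and determinism

Tests and the acceptance script run the 13-container design (3 solitary
aspen, 1 intra-specific aspen pair, 3 inter-specific pairs, 3
intra-specific spruce pairs, 3 solitary spruce — 20 individuals) at
0.5 mm resolution in a 128 × 128 × 300 voxel grid, the package's
desk-scale working point; the conventions are resolution-independent and
0.1 mm volumes differ only in memory and time. For a fixed seed the whole
pipeline is deterministic: repeated runs produce byte-identical CSV/JSON
outputs (the timestamped log is the only exception).

## What the synthetic test bed does not show

The generator emulates geometry, not physiology: no nutrient or water
response, no root–root signaling, no container-tracking behavior at the
wall (material is cut, not redirected), no radius taper or root-order
diameter classes, and radii are coarser than real fine roots (see above).
Passing tests therefore demonstrate that the measurement chain is correct
on known geometry at known resolution — not that any biological effect
size would be recovered from real CT data, where segmentation error,
contrast limits and annotation bias dominate. Group differences produced
by the default synthetic design are arbitrary consequences of the preset
parameters and carry no biological meaning.
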