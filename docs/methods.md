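# Methods

This note documents the models, estimators, numerical choices and known
limitations of `retmosaic`.  It states no empirical number that the test
suite or `scripts/acceptance.py` does not itself compute.

## Field model and conventions

A field is a rectangular acquisition window (default 246.03 × 246.03 μm²,
the size of the confocal frames this package targets) plus per-cell XY
centroids in continuous micrometres, with optional per-cell morphology
(apparent diameter, cross-sectional area, Feret max/min).  Coordinates live
in the half-open window [x_min, x_min+side_x) × [y_min, y_min+side_y),
origin at the lower-left corner.  Depth (Z) is deliberately absent from the
analysis surface: all statistics are computed on XY projections, matching
how wholemount mosaics are analyzed in practice.  Density is
n / window area, in cells/mm²; cells flagged as counted under a top/left
edge-inclusion rule are ordinary cells here — the flag records the
segmentation-time convention and does not alter computation.

## Nearest-neighbor distances

Euclidean XY distance to the closest other cell, via a k-d tree, verified
in the tests against an O(n²) all-pairs oracle.  **No edge correction is
applied**: a cell near the border keeps its nearest in-window neighbor even
though its true nearest neighbor may lie outside the field.  This matches
standard practice for these mosaic analyses; the bias it introduces
(distances near the border are stochastically long) is visible as a small
systematic deviation between point-pattern simulations and the infinite-
process analytic reference (see "Poisson reference" below).

## Dirichlet (Voronoi) domains

The tessellation is computed on the centroids augmented with their mirror
images across the four window sides, which bounds every original cell's
region; the region is then intersected with the window rectangle.  Domain
areas therefore tessellate the window exactly (tested to relative error
< 1e-9).  Two implementation details matter:

* scipy's `Voronoi.regions` vertex lists are unordered; polygons are built
  after sorting vertices counterclockwise around the generator (valid
  because Voronoi cells are convex).
* A domain "touches the boundary" iff some polygon vertex lies within
  1e-7 μm of the window boundary; mirror-construction boundary vertices
  carry ~1e-12 floating noise, so an exact test misclassifies them.

`neighbor_count` counts *cells* whose clipped domains share a positive-
length edge (> 1e-9 μm).  Window-boundary segments are not neighbors, and
domains meeting only at a point (e.g. the diagonal cells of a 2×2 grid) are
not neighbors.  For interior cells this equals the Delaunay degree, which
the tests assert exactly against `scipy.spatial.Delaunay`.  Degenerate
(cocircular) inputs that break qhull are retried once with an internal
1e-9 μm jitter and a warning; user-visible coordinates are never modified.
The mean neighbor count over interior cells sits near the Euler-formula
value 6 (slightly below, because a finite point set's Delaunay triangulation
has mean degree 6 − O(hull/n)); averaged over all cells it is markedly
lower, since boundary cells lose the neighbors their unclipped domains
would have had.

## NND histograms and Gaussian fits

Histograms use half-open bins [kΔ, (k+1)Δ) from zero; 1 μm bins for single
fields, 0.25 μm for trial-averaged ensembles.  Ensemble histograms average
counts across trials and divide by the bin width (per-μm scale), so their
integral equals the number of cells and they compare directly with the
n-scaled analytic reference.

Fits minimize unweighted least squares of y = y₀ + A·exp(−((x−x₀)/w)²) over
bin centers with the baseline y₀ fixed at 0 and sd = w/√2.  Bins are not
weighted by count — the conventional choice for these visual-comparison
fits; a count-weighted fit would shift parameters slightly on skewed
histograms.  Initialisation: x₀ at the mode, A at the peak count, w from
the histogram's weighted sd; up to 5 restarts with ±30% perturbed initials
before raising an error that reports the initial values.  Noiseless
Gaussian input is recovered to three significant figures (tested).

## Poisson reference

For a Poisson process of intensity λ, the NND density is
P(r) = 2πλr·exp(−λπr²) (Rayleigh with scale 1/√(2πλ)); mode 1/√(2πλ), mean
1/(2√λ), and a constant regularity index √(π/(4−π)) ≈ 1.913.  λ is taken as
n/A with A the window area.  The reference is exact for an infinite
process; a finite binomial pattern of ~300 points in the window deviates
slightly (border cells, n−1 neighbors), which is why empirical agreement is
asserted on pooled samples (KS distance of the 100-trial pooled empirical
distribution < 0.05) rather than per trial, where the sampling noise floor
of the KS statistic itself is ≈ 0.05 at n ≈ 300.

## Density recovery profile

For every ordered cell pair, the separation is binned into annuli of width
Δr around the reference cell; each pair is weighted by 1/f, where f is the
fraction of the circle of that radius centred on the reference cell lying
inside the window.  f is computed analytically by inclusion–exclusion over
the four window sides (arc half-widths arccos(dᵢ/r), corner overlaps
max(0, αₓ+α_y−π/2)), exact for r ≤ min(side)/2 — hence the hard
precondition max_radius ≤ half the shorter window side.  The profile of a
Poisson pattern is flat at λ (tested within 3 s.e. over 20 fields); a
hard-core pattern shows an empty exclusion zone below the contact distance.
The effective radius uses the cumulative-deficit form: the density
shortfall (λ − profile) is summed over annuli from the origin until the
profile first reaches λ, and converted to the radius of the equivalent
fully-empty disc, r_eff = √(deficit/(πλ)).  Other variants of this
estimator exist; this one is simple, deterministic, and adequate for
summarising exclusion-zone extent.

## Hard-core simulator

Random sequential addition: cells are placed one at a time; each placement
cycle draws a diameter from N(mean, sd) (resampled if ≤ 0; at soma-like
mean/sd ≈ 23 the truncation is numerically irrelevant), then redraws a
uniform position until the disc overlaps no placed cell.  Overlap means
center distance < (dᵢ+dⱼ)/2 − 1e-9 μm, so exact touching is allowed.  Only
the *position* is redrawn on rejection, not the cycle's diameter; redrawing
both would bias accepted diameters slightly small at high packing, but at
the packing fractions involved here (~0.3) the two schemes are statistically
indistinguishable.  Centers, not whole discs, are confined to the window —
discs may protrude past the edge.  A cell that finds no admissible position
in 10 000 attempts raises a packing failure naming the cells placed; at
soma-like densities this effectively signals misconfiguration, and the RSA
saturation limit (coverage ≈ 0.55) bounds what is requestable at all.
`point_mode` (diameter 0) removes the interaction entirely; it is drawn
vectorised, which is distributionally identical since nothing is rejected.

Seeds: a master seed spawns per-trial seeds as `SeedSequence((seed, t))`, a
deterministic counter, so any single trial is reproducible in isolation and
identical configs give bit-identical fields.

Scaling sweeps multiply either the placed cell count (density) or the
diameter mean *and* sd (diameter) by factors 1.0/0.75/0.5/0.25.  Density
sweeps rescale the paired reference's λ; diameter sweeps keep λ fixed.

## Synthetic AII-like fields

The generator emulates features of real confocal segmentations that a 2-D
disc simulation lacks: spheres are packed in a thin 3-D slab (depths
N(0, z_jitter_sd), hard-core enforced on 3-D center distance) and projected
to XY, so a fraction of projected NNDs falls below the 2-D contact
distance, exactly the apparent-overlap artifact of depth-displaced somas.
Cross-sections are area-preserving ellipses (Feret max/min ratio
N(ellipticity, sd), orientation irrelevant to the statistics and not
stored).  Per-(quadrant, region) densities, diameters and gradients come
from a versioned template JSON shipped with the package; the defaults span
1800–5100 cells/mm² with the steepest center-to-periphery gradient in the
dorsal quadrant and slightly larger somas peripherally.  These defaults are
parameters chosen to emulate reported AII characteristics, not
measurements.  z_jitter_sd defaults to 2.5 μm, which places mid- and
high-density synthetic fields in the NND-RI range reported for real AII
mosaics (~3.5–5) while producing sub-contact projected NNDs; the lowest-
density peripheral fields fall somewhat below that range because the
hard-core constraint is intrinsically weaker at low density.  The true
depth-displacement magnitude is not quantified in the literature this
emulates; treat it as a free parameter.

What passing tests on synthetic fields do **not** show: that real
segmentations have Gaussian diameter marks, independent depths, or
elliptical cross-sections of constant eccentricity; conclusions about real
data require real centroid tables, which the CSV/JSON readers accept.

The regular-mosaic generator (contrast class) enforces per-cell exclusion
radii drawn from N(exclusion_mean, sd): pair distance ≥ (eᵢ+eⱼ)/2.  With
sd = 0 and mean = d it coincides exactly with fixed-diameter hard-core
packing.  Note the feasibility bound: n discs of exclusion e must satisfy
coverage n·π(e/2)²/A below RSA saturation (≈ 0.55); e.g. at e = 18 μm in
the default window, ~110 cells pack reliably but 150 (coverage 0.63) cannot.

## Matched-simulation (envelope) test

"Cannot be distinguished from randomness" is formalized as a two-sided
Monte-Carlo rank test.  The ensemble is simulated with the field's n,
window, and the mean and sample sd of its apparent diameters (diameters of
equal-area circles if only cross-sectional areas are present).  The default
statistic is the NND regularity index — the field's own summary statistic —
with the Dirichlet-area RI as an option.  With T trials,

rank_p = min(1, 2·min(1 + #{sim ≤ obs}, 1 + #{sim ≥ obs}) / (T + 1)),

the standard doubled one-sided Monte-Carlo p; it is exact-level by the
exchangeability of the observed statistic with the simulated ones under the
null.  T ≥ 19 is required (one-sided resolution at α = 0.05); T = 99 is the
default.  The test is calibrated on simulator-generated nulls (rejection
rate ≤ α + 3 Monte-Carlo s.e. over 100 replicates, tested) and powered
against 18-μm exclusion-zone regular mosaics (≥ 90% detection, tested).

An optional `min_distance_floor` censors NNDs below a threshold in *both*
the observed and simulated data before computing the statistic.  Rationale:
sub-contact NNDs in real (and realistic synthetic) data arise from depth-
projection overlap — a measurement artifact, not mosaic structure — and a
2-D disc simulation cannot produce them, so they are a trivially detectable
but uninteresting difference.

## Regularity index

Mean divided by the **sample** (n−1) standard deviation.  All-equal inputs
(sd = 0, e.g. a perfect lattice) raise a "degenerate distribution" error
rather than returning infinity; the pipeline converts this to a structured
warning in the field report.

## Problem sizes and determinism

Acceptance-grade checks use 100 simulation trials per condition (sweeps:
100 trials × 4 factors; envelope calibration/power: 100 replicates × 99
trials at ~110–150 cells), sizes at which every documented property is
stable under seed changes.  All tests are fixed-seed; hypothesis suites run
derandomized.  Field reports serialize with fixed float precision and
sorted keys, so identical inputs give byte-identical files.

## Known limitations

* 2-D analysis only; no toroidal boundary conditions, no 3-D tessellation.
* No NND edge correction (matches the emulated practice; biases the RI of
  sparse fields slightly).
* RSA is not an equilibrium hard-disc sampler; at coverages well below
  saturation the difference is negligible for NND statistics.
* The Gaussian histogram fit is descriptive, not a test of Gaussianity.
* The DRP effective radius is one of several published variants.
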