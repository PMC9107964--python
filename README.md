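# retmosaic

Spatial statistics for retinal neuron mosaics — built around one question:
**is an observed arrangement of cell bodies actually regular, or is it just a
random arrangement of objects that cannot overlap?**

Retinal neurons of a single type (here the AII amacrine cell, the most
numerous amacrine type in mammals) tile the retina in "mosaics" whose
regularity is classically quantified by the nearest-neighbor distance (NND)
regularity index, RI = mean(NND) / sd(NND).  An unconstrained Poisson point
pattern has RI = √(π/(4−π)) ≈ 1.91; AII mosaics show RI ≈ 4–5, which has
long been read as evidence of developmental regularity.  But somas are
~9 μm discs, not points: two cell bodies simply cannot sit closer than the
sum of their radii.  This package implements the whole analysis chain needed
to test whether soma size alone explains the apparent regularity:

* **Geometry** (`retmosaic.geometry`) — NNDs, window-clipped Dirichlet
  (Voronoi) domains (areas, edge-sharing neighbor counts, boundary flags),
  and density in cells/mm² for a field of centroids in a rectangular
  acquisition window (default 246.03 × 246.03 μm²).
* **Statistics** (`retmosaic.stats`) — NND histograms; Gaussian fits
  y = A·exp(−((x−x₀)/w)²) with w = √2·sd and baseline fixed at 0; the
  analytic Poisson NND density P(r) = 2πλr·exp(−λπr²) with λ = n/A, scaled
  by n for direct histogram comparison; regularity indices; density recovery
  profiles (annulus-binned 2-D autocorrelograms with analytic edge
  correction).
* **Simulation** (`retmosaic.simulate`) — hard-core random mosaics matched
  for density and soma size: discs with Gaussian-drawn diameters placed by
  random sequential addition (touching allowed, overlap forbidden), plus
  point-mode (unconstrained) nulls and density/diameter scaling sweeps.
* **Synthetic data** (`retmosaic.synth`) — AII-like stand-in fields with
  soma ellipticity, depth-displacement projection overlap and
  center-to-periphery density gradients, plus genuinely regular
  (exclusion-zone) mosaics for contrast.
* **Pipeline + CLI** (`retmosaic.pipeline`, `mosaic` command) — per-field
  reports, whole-retina summaries, and a two-sided Monte-Carlo rank test of
  whether a field's regularity can be distinguished from matched hard-core
  randomness.

## Worked example

Simulate a random mosaic matched to a dense central field (292 cells,
apparent soma diameter 9.01 ± 0.39 μm, 246.03 μm square window) and analyze
it like a real field:

```python
from retmosaic import SimConfig, analyze_field, simulate_field

field = simulate_field(
    SimConfig(n_cells=292, diameter_mean=9.01, diameter_sd=0.39), trial_seed=42
)
report = analyze_field(field)
```

which prints, when the sections of `report` are formatted:

```
density          4824 cells/mm^2
NND              10.97 ± 1.81 um (RI 6.07, min 8.61 um)
Dirichlet area   207.3 ± 61.2 um^2 (RI 3.38)
interior neighbors per cell   5.96
Gaussian fit     x0 10.14 um, sd 1.09 um, R^2 0.896
Poisson mode     5.74 um
DRP effective radius   8.35 um
```

Read: a *purely random* arrangement of 9-μm somas at this density already
has an NND regularity index far above the Poisson value of 1.91, no
nearest-neighbor distances below the soma contact distance (min 8.6 μm
versus the Poisson mode at 5.7 μm), close to six Dirichlet neighbors per
interior cell, and an NND histogram a Gaussian fits well — the same
signature conventionally reported for real AII mosaics.  High regularity
indices alone therefore cannot establish a nonrandom mosaic.

The numbered scripts under `analysis/` run the full study on synthetic
material: `01` generates a 16-field retina (4 quadrants × 4 eccentricities),
`02` computes per-field statistics, `03` runs the matched-randomness rank
test per field, and `04` sweeps density and soma diameter to 75/50/25% to
show how the hard-core histogram collapses onto the Poisson reference only
near 25%.  Outputs go to `results/`.

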