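# Methods

## Pipeline model

One sample contributes two 8-bit grayscale brightfield images of unstained
RBC monolayers: one after 30 min of slow deoxygenation (`C_low`, 0.1%
sodium metabisulphite) and one after fast deoxygenation (`C_high`, 0.3%).
Optics are assumed fixed at 6 px per micron (`pixel_scale`, configurable).
The pipeline assumes a near-uniform bright background with darker cells, a
monolayer (no stacking), and enough cells (≥ 50 after filtering; fewer
triggers a low-confidence flag, not an error).

Segmentation is deliberately simple: Gaussian smoothing (σ = 1 px), a
global Otsu threshold on the inverted intensities, hole filling, 8-connected
labelling. Objects touching the border are dropped (truncated shapes bias
roundness); objects outside [11.1, 166.7] μm² (400–6000 px² at 6 px/μm) are
dropped as debris or clusters. Clusters are never watershed-split: dense
clumps are unreliable for shape measurement, so they are excluded wholesale.
An apparent foreground fraction above one half aborts with a polarity hint
(`invert=True` handles bright-on-dark inputs). Region ids are assigned in
bounding-box (top, left) order so output tables are reproducible.

Descriptors per cell: area (pixel count), perimeter (Crofton 4-direction
estimator — deterministic and asymptotically unbiased on smooth outlines, so
a raster circle scores circularity ≈ 1; the classic chain-code estimator
biases it to ≈ 0.93), major axis from the moment-ellipse fit, roundness
R = 4A/(πL²) clamped to [0, 1] (moment fits on near-circular rasters can
exceed 1 by a hair), circularity, solidity. Cells with solidity < 0.8 are
excluded (out-of-focus, side-lying, or heavily spiked objects); a cell at
exactly 0.8 is retained (strict reading of "< 0.8 excluded").

Roundness histograms use ten half-open bins (lo, hi] of width 0.1 labelled
by the upper edge; a value of exactly 0 joins the first bin. Heights are
cell fractions summing to one, so band masses are direct sums of heights
and the classifier intercept lives on a [0, 1] scale. Pooling sums counts
and renormalizes. Modal-bin ties break toward the lower label.

Feature space: P1 and P2 are the masses in bands 0.2–0.5 and 0.5–0.8. The
candidate-band search enumerates all adjacent equal-width pairs (widths
0.1–0.5 on a 0.1 lattice; 25 combinations), scores each by the k-means
(k = 2, k-means++, 50 restarts, fixed seed) split using Handl connectivity
(L = 10 nearest neighbours, ties by index; 0 is ideal) and the Dunn index
(single-linkage numerator, complete-diameter denominator; singletons
contribute no diameter). Ranking is connectivity first (it has an absolute
optimum), Dunn second. Band pairs on which every training sample collapses
to the same point carry no information and are ranked last rather than
aborting the scan; the scan errors only if every pair is degenerate. The
deployed pair (0.2–0.5 | 0.5–0.8) is pinned as a named constant so
downstream behaviour never depends on enumeration order.

Decision rule: the shipped boundary P2 = −1.527·P1 + 0.633 (plain-text
model file, versioned) with GRAY below the line. The orientation is a
geometric necessity rather than an arbitrary sign choice: unsickled images
concentrate roundness mass above 0.8, so healthy feature points sit near
the origin, which must read GRAY. Points exactly on the line read WHITE —
a borderline healthy sample is pushed toward a re-test rather than a missed
disease (safety bias). Retraining uses a soft-margin linear SVM (cost 10,
tolerance 1e−6) on raw, unscaled feature points with no class weighting;
training never overwrites the shipped model file.

Kinetics: dissolved-oxygen series are fitted to y = A·e^(−t/τ) + B by
bounded nonlinear least squares (init A = y₀ − y_last, B = y_last,
τ = span/3; τ ∈ (0, 10·span]), reporting RMSE. The delay time t_d is the
earliest time any cell's roundness track falls below 0.6 and stays below
for 3 consecutive samples (threshold and persistence configurable; the
operational definition used with real video is not public, so this is a
declared reconstruction). The sickled fraction n_sickle is the percentage
of filtered cells with R < 0.6 — a proxy for expert annotation, labelled as
such in reports.

## Synthetic data generator

The generator emulates the five morphology classes seen under chemical
deoxygenation — unsickled/biconcave discs, classically sickle (elongated,
bent), holly leaf (spiked), granular (compact, irregular) and crenated
(high-frequency boundary ripple) — at the genotype × condition mixtures
reported from expert-annotated fields:

| preset        | sickle | holly leaf | granular | unsickled |
|---------------|--------|------------|----------|-----------|
| SCD, C_low    | 0.34   | 0.37       | 0.18     | 0.11      |
| SCD, C_high   | —      | 0.14       | 0.80     | 0.06      |
| SCT, C_low    | 0.08   | 0.08       | 0.08     | 0.76      |
| SCT, C_high   | 0.19   | 0.60       | 0.15     | 0.06      |
| healthy (any) | —      | —          | —        | 1.00      |

Only the 76% unsickled share is reported for SCT/C_low; the remainder is
split evenly across the three sickled classes. Class counts per field are
the largest-remainder rounding of fractions × n_cells (deterministic, ties
by class declaration order).

Each cell is a continuum polygon (256 vertices): an ellipse (unsickled), an
ellipse with low-order radial harmonics (granular), an area-preserving
parabolic bend of an ellipse (sickle), an ellipse with 4–7 triangular
spikes (holly leaf), or a high-frequency ripple disc (crenated). For every
cell, the elongation is solved by root-finding so that the polygon's exact
moment-ellipse roundness (analytic area and second moments via Green's
theorem) equals the target drawn from the class law — the same statistic
the raster measurement estimates, so measured roundness tracks truth to
within rasterization error (±0.05 is the guaranteed band; in practice
≈ ±0.01 at 6 px/μm). Rare law draws outside a drawn style's achievable
range are clipped to the endpoint and the truth table records the achieved
value. Cell size is uniform 6.5–8.5 μm area-equivalent diameter (typical
RBC scale). Cells are placed by rejection sampling with non-overlap and
off-border margins; fields are rendered as dark cells (intensity ≈ 125 ± 8)
on a bright background (200) with σ = 1 px Gaussian blur and additive
Gaussian noise (sd 2). Identical (preset, n, seed, params) give bit-identical
images and truth tables. Optional injection flags add overlapping-cell
clusters (eight cells merging into one blob above the cluster area bound)
and border-straddling cells, used to exercise the exclusion rules.

Per-class target-roundness laws are truncated normals on (0, 1]:

| class                 | mean | sd    |
|-----------------------|------|-------|
| unsickled, untreated  | 0.93 | 0.03  |
| unsickled, treated    | 0.88 | 0.04  |
| classically sickle    | 0.45 | 0.035 |
| holly leaf            | 0.56 | 0.05  |
| granular              | 0.68 | 0.05  |
| crenated              | 0.85 | 0.04  |

No per-shape roundness values are published — only the pooled distribution
peaks per cohort (healthy untreated 1.0; SCD 0.5 slow / 0.7 fast; SCT 0.9
slow / 0.6 fast) and the mixture fractions above. The laws are therefore
calibrated constants, fixed analytically before any end-to-end run by
computing truncated-normal bin masses per cohort and requiring each printed
peak to hold with a robust margin at cohort size (3 × 200 cells). Two
couplings matter. First, the treated unsickled law (0.88) is slightly below
the untreated one (0.93): scavenger-exposed unsickled cells crenate mildly,
which is what lets healthy-treated and SCT-slow cohorts peak at 0.9 while
healthy-untreated peaks at 1.0. Untreated SCD/SCT presets also use the 0.88
law, matching their reported untreated peak of 0.9. Second, the SCD-slow
cohort peaks at 0.5 even though holly leaf (0.37, centred in bin 0.6)
outnumbers classically sickle (0.34, centred in bin 0.5); this requires the
solidity filter to thin the holly-leaf class. Holly spike length is
therefore calibrated through the actual blur + threshold + measurement path
so that in-pipeline holly solidity is 0.82 ± 0.03 — about a quarter of
holly cells fall below the 0.8 cutoff and are excluded, while sickle cells
are generated with a shallow bend (solidity ≈ 0.85–0.92) and survive, as
classically sickle cells must for the slow-deoxygenation peak to sit at
0.5. The filter also removes the lower-roundness holly cells preferentially
(for a fixed spike style, lower elongation means lower solidity), shifting
kept-holly mass upward; the holly mean of 0.56 compensates.

What the generator does *not* emulate: optical point-spread functions and
defocus, illumination gradients, cell stacking and side-lying cells,
touching-but-distinct pairs below the cluster bound, the uncategorized
morphologies present in real fields, staining variability, or any temporal
dynamics (the oxygen-series generator produces the fitted decay form plus
noise, not chamber physics). Passing tests therefore demonstrate that the
measurement and decision machinery is correct and self-consistent under the
documented shape taxonomy and mixtures — not that the assay's clinical
accuracy is reproduced; that requires real specimens.

## Numerical and design choices

- Bin edges are i/10 in double precision with `digitize(..., right=True)`;
  bins are (lo, hi] so printed peak labels (0.5, 0.9, …) are upper edges.
- k-means labels are canonicalized (label 0 = centroid nearer the origin)
  to make results order- and restart-independent.
- The SVM boundary is reported as slope/intercept in (P1, P2); a vertical
  boundary (|w₂| ≈ 0) is rejected explicitly rather than returned as ±inf.
- Area bounds are configured in μm² and converted by pixel_scale², so
  defaults survive a change of optics.
- Placement uses bounded rejection sampling (20 000 attempts per cell) and
  errors with a "use a larger field" hint; ~200 cells of mixed classes fit
  comfortably in the default 1200 × 1600 px field at ≈ 40% effective
  exclusion density.
- Diagnosis reports are byte-reproducible: the only timestamp lives in an
  isolated metadata field of the on-disk JSON.

## Problem sizes

Cohort-level checks use 3 fields × 200 cells per genotype × condition
(≈ 500–600 cells pooled after filtering, at which the thinnest documented
peak holds with a margin of several standard errors); the end-to-end
concordance check uses 35 synthetic sample pairs (10 healthy, 10 SCD,
15 SCT) of 200 cells per image; decay-fit recovery uses 121 samples over
30 min at noise sd 0.5 for τ ∈ {1.6, 5, 12.2} min.

## Known limitations

- The solidity-filter interaction is part of the calibration: generators
  with different spike geometry would need the one-time calibration redone
  (`scratch` scripts show the procedure; constants live in `synth.py`).
- n_sickle via the R < 0.6 cutoff undercounts granular-dominated fields
  relative to expert annotation, which counts granular cells as sickled.
- The band-combination search reproduces the *mechanics* of the published
  selection; on synthetic cohorts several wide band pairs separate the
  clusters as cleanly as the deployed pair, so the selection outcome is
  data-dependent and the deployed pair is pinned by constant, not re-derived
  at runtime.
- Segmentation is threshold-based and assumes monolayers; heavily confluent
  or unevenly illuminated fields need the adaptive pieces this package
  deliberately omits.
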