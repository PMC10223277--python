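# Methods

## Measurement pipeline

A segmentation record is a set of pixels belonging to a hand-drawn FAZ
perimeter line. The pipeline is:

1. **Overlay extraction.** A pixel belongs to the line when every RGB
   channel is within `tolerance` (default 30) of the target colour.
   Paint-style annotations are near-pure colours over a greyscale
   angiogram, so per-channel distance is sufficient and no colour-space
   model is used. All matching pixels are kept — lines thicker than 1 px
   enter the point set whole, because the azimuth sort and shoelace area
   are robust to a thin ring and thinning would silently change areas; a
   `thin=True` flag applies morphological skeletonization for callers who
   want a 1-px trace. If the matching pixels form more than one 8-connected
   component a warning (not an error) reports the count: stray matches are
   visible but a single gap in a line should not abort a batch.

2. **Azimuthal ordering.** Points are sorted by angle about the centroid of
   the point set, ties broken by ascending radius so that the inner and
   outer pixels of a thick ring stay adjacent instead of creating long
   chords. The starting vertex is the one with smallest azimuth in (−π, π].
   This ordering yields a simple polygon exactly when the boundary is
   star-shaped about its centroid — true for every shape the synthetic
   module generates (they are polar graphs r(θ) > 0) and for realistic FAZ
   outlines. Violations are diagnosed, not silently accepted: the ordered
   polygon is checked for self-intersection (shapely's planar predicate on
   the closed ring, consecutive duplicates removed) and the result is
   attached to the metrics as `star_shaped`. The check is conservative for
   pixelated rings, where radial zig-zags may touch without changing the
   enclosed area materially.

3. **Area.** Shoelace formula over the ordered closed vertex list, absolute
   value of the signed sum (drawn orientation is irrelevant). Conversion to
   mm² multiplies by `mm_per_px_x · mm_per_px_y`; the default per-axis
   scale is `width_mm / image_cols` and `width_mm / image_rows` (3 mm scan
   width over the export's pixel dimensions), and anisotropic exports are
   supported. The scale is a configuration value because device exports do
   not embed it.

4. **Acircularity.** σ(R)/R̄ over the distances of the contour points from
   their geometric centre, which is the arithmetic mean of the perimeter
   points (not an area centroid). σ uses the population divisor N,
   matching the 1/N structure of the mean; `ddof=1` is exposed for the
   sample-SD variant but is not the default. Degenerate inputs raise:
   fewer than 3 distinct points or a collinear set (`DegenerateContour`),
   all points coincident with the centre (`ZeroRadius`).

No smoothing, resampling or spline fitting is applied before measurement:
the drawn perimeter is measured as drawn.

## Synthetic data model

The generator emulates the structure of a manual FAZ segmentation study,
not retinal biophysics.

**Shapes.** Ground-truth boundaries are finite Fourier perturbations of a
circle, r(θ) = R₀(1 + Σ aₖ cos(kθ + φₖ)) with 2 ≤ k ≤ 6 and Σ|aₖ| < 1.
This is the lowest-order family that spans FAZ-like irregularity while
keeping a closed-form enclosed area, πR₀²(1 + ½Σaₖ²), so every
downstream measurement has an analytic oracle. Cohort defaults (320 px /
3 mm field): base radius R₀ uniform in 18–30 px (healthy), 15–26 px
(type-1), 14–32 px (type-2), with three harmonics of per-harmonic
amplitude 0.02–0.10 / 0.02–0.11 / 0.03–0.15 respectively — the type-2
range is wider and rougher, echoing the greater FAZ changes of damaged
retinas. The deep plexus radius is scaled by 1.05 relative to the
superficial one. These put mean final-criterion areas near 0.11–0.15 mm²,
the scale reported for 3×3 mm scans, and keep every shape star-shaped by
construction.

**Observers.** A tracing of shape r(θ) under an observer model is

    r′(θ) = r(θ) · b · (1 + η) · (1 + a_s·cos(k_s θ + φ_s) + ε(θ))

with systematic radial bias `b`, per-tracing bias jitter η ~ N(0, σ_b),
one high-frequency "spike" harmonic (k_s drawn from 15–40, random phase,
amplitude a_s) mimicking vessel-following scallops, and per-point radial
noise ε ~ N(0, σ_ε). Defaults: initial criterion b = 1.12, a_s = 0.06,
σ_b = 0.04; final criterion b = 0.97, a_s = 0.02, σ_b = 0.015; σ_ε = 0.01
for both. The bias values encode the two criteria's placement (outside
along the enclosing vessels vs slightly inside the transition zone); they
are configuration values, not clinical claims. The bias jitter term is the
deliberate design choice that gives inter- and intra-observer variability
a generating mechanism: a fixed-amplitude spike harmonic inflates area by
the deterministic factor 1 + a_s²/2 regardless of its random phase and
frequency, and per-point noise averages out over ~2000 boundary points, so
without η all tracings of a shape under one criterion would have nearly
identical areas and observer-variability comparisons would be measuring
rounding noise. With these defaults the final criterion produces smaller
mean areas (ratio (0.97/1.12)² ≈ 0.75), smaller area SDs, lower
inter-observer SDs and slightly lower acircularity in every
cohort × plexus cell — the directional structure a criterion-comparison
study reports — while the final-criterion mean area recovers the planted
`mean analytic area × 0.97²` to well under 1%.

**Images.** `render_annotated` draws the (rounded) boundary polyline in a
solid colour over either flat grey or a procedural texture: a dark
avascular core inside r(θ), a linear transition band of relative width
0.12, and a filamentary bright/dark annulus outside (thresholded smoothed
noise). The texture exists to exercise overlay extraction against
non-uniform backgrounds; it is not a capillary network model, and OCTA
artefacts (motion, projection) are out of scope.

**Reproducibility.** Every shape and every tracing draws from its own
`numpy` Generator seeded by `SeedSequence((master_seed, h))` where `h` is a
SHA-256 hash (reduced below 2³¹) of the record key (eye, plexus, observer,
series, criterion). Subsets of a cohort therefore regenerate identically
regardless of generation order, and the full pipeline is byte-stable at a
fixed master seed.

**Default study size.** 73 healthy + 40 type-1 + 54 type-2 eyes, two
plexuses, four observers of whom two traced two series (series labels
C1 C2 E1 G1 G2 S1), two criteria → 4008 records. Generating and measuring
the full set takes a few seconds; validation tests use 100 eyes per cohort
for parameter recovery and smaller cohorts elsewhere.

## Cohort statistics

Cross-record summaries use the sample (N−1) SD; per-contour radial SD uses
N as above. Group cells pool all segmentations by default (matching
distribution-level summaries over every tracing); an eye-averaged mode
collapses each eye to its mean first. Inter-observer variability is the SD
across observers of each observer's series-averaged area within an
(eye, plexus, criterion) cell; intra-observer variability is the SD across
series within an observer, averaged over observers with ≥ 2 series; cells
without replication report NaN rather than erroring. The criterion
contrast reports Δmean, ΔSD and the final/initial mean ratio with no
hypothesis test, and the paired area–acircularity table flags
acircularity > 0.5 and reports a descriptive Spearman rank correlation per
plexus × criterion. Left/right eyes are pooled; no spatial-overlap
(Dice/Jaccard) metrics are computed since the compared quantities are
scalars.

## What passing tests show — and don't

The synthetic module validates the *measurement pipeline* (exact polygon
arithmetic, invariances, oracle agreement, round-trip recovery through
rendering, and recovery of planted observer parameters at study scale).
It does not validate clinical claims: real FAZ boundaries are not finite
Fourier curves, real observer disagreement is not a multiplicative radial
field, and the synthetic cohort's summary tables only reproduce the
*direction* of the clinical findings (smaller, less variable areas and
slightly lower acircularity under the final criterion), not their
magnitudes. Numerical tolerances in the tests: exact identities at 1e−9
relative or better on float contours; discretization-limited checks
(integer pixel rounding, 1 px line rasterisation) at 1–3% on areas and
5e−3 on acircularity.
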