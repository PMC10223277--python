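# fazmorph

Morphometry of the **foveal avascular zone (FAZ)** from manually annotated
OCTA (optical coherence tomography angiography) images.

The FAZ — the capillary-free region at the centre of the fovea — is a
biomarker for diabetic retinopathy, but on most OCTA devices it must be
delimited by hand, and manual tracing shows large inter- and intra-observer
variability, especially in damaged retinas. `fazmorph` is for research
groups who build FAZ segmentation sets: it turns annotated en-face exports
(a coloured perimeter line drawn over the angiogram) into per-segmentation
area and shape metrics and into cohort-level comparisons between observers
and between delimitation criteria (the classical *initial* criterion, "the
region within the fovea without blood vessels", versus the stricter *final*
criterion, the inner boundary of the transition zone between avascular and
irrigated tissue).

## Method

For each segmentation, the drawn perimeter pixels are isolated by colour
distance, and the boundary points (x_i, y_i) are ordered by azimuth about
their centroid. Two metrics are computed:

* **Area** — the shoelace (Gauss) polygon formula over the ordered closed
  contour,

      A = ½ |Σᵢ (xᵢ·yᵢ₊₁ − xᵢ₊₁·yᵢ)| ,

  converted from px² to mm² with the device pixel size (default
  `width_mm / image_cols` per axis for a 3×3 mm scan).

* **Acircularity** — with R̄ = (1/N)ΣRᵢ the mean distance of the N contour
  points from their geometric centre and σ(R) the population standard
  deviation of those distances,

      acircularity = σ(R) / R̄ .

  It is 0 for a perfect circle, invariant to translation, rotation and
  uniform scaling, and values above 0.5 flag a very irregular FAZ.

Per-record metrics are aggregated into mean/SD tables by
cohort × plexus × criterion (× observer), an initial-vs-final criterion
contrast, inter-/intra-observer variability, and a paired
area–acircularity table.

Because clinical image sets of this kind are rarely shareable, the package
includes a first-class synthetic module: star-shaped boundaries
r(θ) = R₀(1 + Σ aₖ·cos(kθ + φₖ)) with closed-form area
πR₀²(1 + ½Σaₖ²), rendered OCTA-like annotated images, and simulated
multi-observer tracing sets in which the final criterion places the line
slightly inside the transition zone (radial bias 0.97, smoother) and the
initial criterion follows the enclosing vessels (bias 1.12, spikier). See
`docs/methods.md` for the model and its limits.

## Worked example

```python
import fazmorph as fm

meta = fm.ContourMeta(eye_id="demo", plexus="SCP", cohort="HEALTHY",
                      observer="A", series=1, criterion="FINAL",
                      width_mm=3.0, image_cols=320, image_rows=320)
shape = fm.SyntheticShape(r0=40.0, harmonics=((4, 0.08, 0.5), (7, 0.05, 1.1)),
                          centre=(160.0, 160.0))
img = fm.render_annotated(shape, meta, background="vessels", line_thickness=1)
points = fm.extract_overlay(img, fm.OverlaySpec(target_colour=(255, 0, 0)))
metrics = fm.compute_metrics(points, fm.PixelScale.from_meta(meta))

print(f"analytic area : {shape.analytic_area_px2 * (3/320)**2:.4f} mm^2")
print(f"measured area : {metrics.area_mm2:.4f} mm^2")
print(f"acircularity  : {metrics.acircularity:.4f}")
print(f"boundary px   : {metrics.n_points}")
```

prints

```
analytic area : 0.4438 mm^2
measured area : 0.4442 mm^2
acircularity  : 0.0678
boundary px   : 337
```

The measured area recovers the shape's closed-form area to 0.1% through the
full render → extract → sort → shoelace chain; the acircularity ≈ 0.068
reflects the two mild harmonics (the dense-sampling limit is
√((0.08² + 0.05²)/2) ≈ 0.067), far below the 0.5 irregularity flag.

## Command line

```sh
fazmorph simulate -o out/sim --seed 1 --n-eyes 10   # contours + ground_truth.csv
fazmorph extract  -i out/images -o out/contours --overlay-colour 255,0,0
fazmorph metrics  -i out/sim/contours -o out
fazmorph summarize -i out/metrics.csv -o out --plots
fazmorph all      -o out --seed 1                    # end-to-end
```

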