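# Methods

This note documents the models, numerical choices, and design decisions
behind `activedisc`, and states what the synthetic-data experiments do and
do not demonstrate.

## Active-disc segmentation

**Template.** Two concentric circles, outer radius `R`, inner radius
`R/√2`, center `(x_c, y_c)`. The inner/outer radius ratio is fixed so the
inner disc covers exactly half the outer area; with the contrast energy

```
E(R, x_c, y_c) = (1/R²) (E₁ − 2 E₂)
```

(`E₁`, `E₂` = image integrals over outer/inner discs) this makes `E`
identically zero on constant images, so the fit responds to contrast only.
On a unit-intensity binary disc of radius `a` the continuous energy has its
unique minimum `−π/2` at `R = √2·a` with centers aligned; the **inner**
circle then coincides with the object boundary, which is why `FitResult`
reports the inner circle as the object outline. The same closed form gives
`+π/2` when the intensity occupies only the annulus.

**Green's-theorem evaluation.** Each area integral is evaluated as the
closed boundary integral `∮ F dy`, where `F(x, y) = ∫₋∞ˣ f` is the
row-cumulative image. Discretization: `n` boundary samples at
`t_k = 2πk/n` (default `n = max(64, ⌈2πR⌉)`, rounded up to even so the
closed-curve trapezoid rule stays symmetric), bilinear interpolation of
`F`. A pixel `f[i, j]` covers `x ∈ [j−½, j+½]`, so the cumulative sum at
column `j` represents `F` at `x = j+½`; the interpolation grid is shifted
accordingly, and the array is padded with zeros (left/top/bottom) and the
full row sum (right) with clamped coordinates, so templates far outside the
support integrate to exactly zero.

**Gradients.** Differentiating the moving-domain integrals gives boundary
integrals of the density (`∂A/∂x_c = ∮ f n_x ds`, `∂A/∂ρ = ∮ f ds`),
combined by the product rule on `(1/R²)(E₁ − 2E₂)` including the `−2E/R`
term. These are implemented as the *exact* derivatives of the discretized
quadrature (analytic partials of the bilinear form), so the gradient is
consistent with the energy surface the optimizer actually descends; central
finite differences of the discrete energy reproduce it to a few
percent of the gradient norm at `n = 4096` (the residual is the
finite-difference window averaging across bilinear-cell kinks, and shrinks
with `n`).

**Optimizer.** Gradient descent with classical momentum (default 0.9;
Nesterov look-ahead behind a flag), per-parameter steps scaled by `R` so
step lengths are roughly scale-invariant, and step-halving backtracking:
any step that would raise the energy is rejected, the step scale halved and
the momentum reset. The energy trace is therefore non-increasing by
construction. Convergence: relative energy change below `tolerance`
(default 1e−6) or 500 accepted iterations. Degenerate inputs: a template
with no contrast at the initialization (zero energy *and* zero gradient)
raises a fit failure rather than reporting a vacuous "converged" result;
so do a collapsing radius (< 1 px) or a center leaving the image.

**Multiscale disc fit.** Three-level Gaussian pyramid (σ = 1 anti-aliasing,
decimation by 2) of the red channel — the disc is brightest and vessels are
de-emphasized in red. The fit runs at the coarsest level first, initialized
at the matched-filter peak with outer radius `R₀ = 0.18·min(H, W)`;
converged parameters are doubled to seed each finer level. `R₀` must
exceed `√2 ×` the largest plausible disc radius: if the whole template
initializes *inside* the bright disc the energy is locally flat and descent
stalls, so the template must contract onto the disc from outside. (0.18 of
the image side corresponds to a disc filling up to ~13% of the image side,
matching the generator's range; it is configurable for other optics.)

## Localization

Normalized cross-correlation (zero-mean, unit-norm per window, exact
integral-image implementation; windows below a variance floor score 0) at
the coarsest pyramid level of the red channel, against a soft bright-disc
template (hard disc of the expected coarse-scale radius, Gaussian-blurred
by radius/4). The coarse level is median-padded by the template half-size
so near-border discs remain valid window centers. The argmax maps to full
resolution by the pyramid factor; exact score ties (e.g. flat images) raise
an ambiguous-localization error listing tied positions. The template is a
reproducible stand-in for a "natural" disc patch; a user-supplied template
raster is accepted.

## Cup extraction

Cup contrast is strongest in green. Two preprocessing steps suppress
structure that is not cup: grey-level morphological closing with a disc
element (radius 4 px, ≈ vessel caliber) fills the dark vessel curves that
otherwise fragment the bright cup into pieces, and a σ = 1 Gaussian tames
noise. Thresholds are then computed by exact multilevel Otsu (k = 4
classes) over the pixels **inside the fitted disc** only, so the cup is the
brightest class locally; the top class, intersected with the disc and
reduced to its largest connected component (ties: smallest centroid row,
then column), yields the initial circle (centroid + equivalent radius).
Candidates with equivalent radius < 2 px are rejected as "no cup found".
The active-disc refinement runs at full resolution with a projection after
every step: cup center clamped inside the disc, cup radius capped at the
disc radius. The cup *boundary* may still cross the disc boundary — exactly
the zero-rim configuration the late DDLS stages describe.

The Otsu maximizer is a dynamic program over the 256-bin histogram —
O(k·B²), exact, equivalent to exhaustive search (verified against brute
-force enumeration in the tests), with ties broken toward the smallest
thresholds. Thresholds are reported halfway between adjacent occupied bins.

## Clinical geometry and grading

All parameters are closed-form circle geometry (see README for formulas).
Conventions: `x` = column rightward, `y` = row downward; angles from +x
toward +y; superior = 270°; right eye (OD) has temporal at image-left,
left eye at image-right (overridable per image). RDR normalizes the
narrowest rim width by the disc *diameter*, the only normalization whose
attainable range `[0, 0.5)` matches the DDLS normal band topping out at
0.50. Vertical CDR reduces to `R_c/R_d` for circles. The rim-absence
extent is the disc-center-subtended arc over which the cup reaches or
passes the disc boundary (internal tangency → 0°, cup covering the disc →
360°).

DDLS band boundaries are implemented as contiguous half-open intervals
(0.30/0.20/0.10 for RDR; 45°/90°/180° for extent) so the classifier is
total; the published staging table has small rounding gaps between bands
and an ambiguous top band, and the contiguous reading is the unique total
resolution. The three-stage grouping reads the merged severity column as
stages 1–4 normal / 5–7 moderate / 8–10 severe; the stricter alternative
(only stages 1–2 normal) is available via `normal_span="1-2"`. ICD-9's
overlapping printed endpoints are resolved half-open: `[0, 0.5]`,
`(0.5, 0.8]`, `(0.8, 1]`.

## Synthetic fundus generator

The generator renders the properties the pipeline relies on, not
photorealism: a bright disc (strongest contrast in red: disc 0.85 vs
background 0.45), a brighter cup (strongest contrast in green: cup 0.75 vs
disc 0.45), hard circles blurred by `edge_softness` (default 1 px), dark
random-walk vessels from the disc center (width 3 px, 55% darkening), and
additive Gaussian noise (σ = 0.02). Default geometry: 256×256 images, disc
radius 20–30 px (8–12% of the image side), cup radius fraction 0.35–0.75,
cup offset fraction 0–0.25. The cup's *red* contribution is clipped to the
disc: pallor reaching past the disc margin is visible in green/blue but the
red margin stays circular, mirroring the fact that the disc margin
dominates the red channel while cupping contrast lives in green — and
keeping rim-absence geometry recoverable. All sampling flows from one
seed; a fixed spec reproduces bit-identical images.

`generate_severity_cohort` cycles three parameter sets chosen to *represent*
their DDLS class with margin from the decision boundaries (normal: fraction
0.35–0.60, offset ≤ 0.15 → RDR ≥ 0.125; moderate: fraction 0.72–0.82,
offset 0.12–0.18 → RDR ≤ 0.08 with rim present or marginally absent;
severe: fraction 0.95–1.10, offset 0.20–0.30 → extents ≳ 130°). The
rim-absence extent is extremely steep in (fraction + offset) near 1 at
small offsets, so classes straddling a boundary would make label-agreement
experiments measure the boundary knife-edge rather than the pipeline.

**What passing on synthetic data does not show.** Real fundus images have
non-circular discs and cups, peripapillary atrophy, uneven illumination,
myopic tilt, and vessels that bend at the cup margin — none of which the
generator emulates. Synthetic results validate the machinery (energies,
gradients, optimization, geometry, grading rules) and the pipeline's
noise/vessel robustness under the stated rendering model, not clinical
performance.

## Problem sizes and numerical defaults

Test and acceptance workloads are sized for a single CPU: 100 random
(image, params) pairs for the energy-oracle equivalence (zero-mean blurred
noise fields — a nonzero image mean probes the pixel-counting quantization
of the brute-force oracle rather than the boundary-integral evaluation
under test); 50 gradient-check cases at `n = 4096` samples; 20 random
256-bin histograms per class count for Otsu; 1000 random circle pairs
against 20 000-direction sampling oracles; 50-image cohorts for parameter
recovery and grading agreement (observed: median disc Dice ≈ 0.995, median
cup Dice ≈ 0.95–0.97, three-stage agreement 50/50 across seeds). Energy
tolerances, interpolation and tie-break rules are as stated above; all
randomness in tests and scripts is explicitly seeded.

## Known limitations

- Circle-only models: elliptical or free-form outlines are out of scope,
  so tilted discs and kidney-shaped cups are approximated by their best
  circles.
- The fitted cup circle's rim-absence extent is capped (~120°) by the
  containment constraint `R_c ≤ R_d`, `d ≤ R_d`; stages 9–10 (> 180°) are
  reachable from ground-truth geometry but collapse to stage 8 for fitted
  circles — both grade *severe*, so three-stage labels are unaffected.
- Multilevel Otsu assumes ≥ k distinct occupied intensity levels inside
  the disc; flat interiors raise a no-cup error by design.
- No millimeter calibration: all widths are in pixels, and the DDLS
  disc-size adjustment (small/average/large discs) is not modeled.
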