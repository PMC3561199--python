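# Methods

## Problem and approach

The package quantifies endocrine cell mass in 2-D pancreas sections: each
hormone's stained area as a percentage of tissue area (the standard 2-D
proxy for cell mass), per-object shape morphometry, and the classification
of tissue blocks into PP-cell-rich and PP-cell-poor regions along the
head→tail axis. All stages operate on co-registered per-channel rasters
(`ChannelStack`: insulin, glucagon, somatostatin, PP, nuclei) with a
µm/pixel calibration; the default calibration is 1.0 µm/px, which keeps
pixel and micrometre arithmetic transparent.

## Virtual-slice assembly

Tiles are trusted to be stage-aligned: stitching places each tile at its
recorded origin and blends overlap strips by the arithmetic mean, which is
order-independent and exact when overlap strips are pixelwise duplicates
(as they are for tiles cut from one section). No registration, illumination
correction, or pyramidal formats; missing grid cells and inconsistent
channel sets are hard errors. Coordinates are row-major, origin top-left,
0-based, pixel centers at integer positions.

## Segmentation

Per-channel foreground by Otsu's threshold (parameter-free and stable on
the synthetic intensity model), with a fixed-threshold override. Guards:

- a channel whose foreground/background mean contrast falls below 0.2 is
  treated as blank (empty mask + warning) — Otsu always splits something,
  and on an unstained channel that split is pure noise;
- a channel with > 50% foreground is flagged saturated in the threshold
  record.

Pixels claimed by two or more hormone channels are assigned to the channel
with the highest threshold-normalized intensity, ties broken by the fixed
type order beta < alpha < delta < pp. This keeps the per-type masks
pairwise disjoint, which the composition arithmetic requires. Objects
smaller than 25 µm² (~half a cell section) are removed as speckle.

The denominator of all area fractions is a tissue mask: the union of
nuclear and hormone foregrounds, morphologically closed with a 20 µm disc
and hole-filled. Whole-section and endocrine-area denominators are exposed
as alternatives and the choice is recorded in the output metadata, since
percentages are only comparable across studies when the denominator is
known.

## Morphometry

The union of the four hormone masks is closed with a 10 µm disc (~one cell
diameter — bridges intra-islet intercellular gaps without fusing separate
objects at realistic densities) and 8-connected components define objects.
Per-type areas and object area are measured on the *unclosed* masks within
each component, so closing groups pixels but never adds area.

Shape statistics per object mask:

- **Perimeter** — arc length of the longest 0.5-level marching-squares
  contour after a window-5 circular moving average of the contour vertices.
  The smoothing is a deliberate staircase correction: the raw
  marching-squares polygon of a discretized disc is ~5% longer than the
  true circle, which alone would depress the circularity of an ideal disc
  to 0.90. With the correction a radius-200 px disc reports C = 0.993,
  while elongation orderings (bars, ellipses aspect 1→8) are preserved.
- **Circularity** — C = 4πA/P², clamped at 1.1 because small discretized
  shapes can exceed 1 analytically.
- **Feret's diameter** — maximum pairwise distance over the convex hull of
  the boundary pixels' *corner* points (each pixel is a unit square, so
  extent is corner-to-corner). The corner convention makes a single pixel's
  Feret its diagonal √2·px and guarantees F ≥ d = 2√(A/π) via the
  isodiametric inequality; it equals the exhaustive O(n²) maximum over all
  boundary corner pairs.
- **Size classes** — singlet if A < 2× the mean single-cell area
  (157 µm²), small cluster if d < 30 µm, islet otherwise; boundary values
  go to the larger class. Thresholds are configurable.

Size distributions use log₁₀(A in µm²), left-closed bins of width 0.25
over [1.5, 5.5); objects outside the range are counted separately as
clipped. The log scale reflects the many small and few large islets.

## Regional classification and boundary

A block is PP-rich iff its PP area fraction strictly exceeds 0.2% of
tissue area — ten times the ~0.02% pancreas-wide baseline observed in body
and tail, and an order of magnitude below the ~1.2% seen in the rich
region, so the two regimes are cleanly separated. The regional boundary is
the single change point minimizing total within-segment sum of squares of
the PP-fraction series (exhaustive scan over all splits), reported as the
first block of the downstream segment; if the best two-segment fit fails
to reduce the one-segment sum of squares by ≥ 20%, no boundary is
reported. A single split is used because the biology being modeled is one
sharp rich/poor transition; multi-change-point methods are out of scope.

## Statistics

Values are mean ± SEM (sd/√n, n−1 denominator; SEM is refused for n = 1
rather than reported as 0). Rich-vs-poor contrasts use a two-sided paired
Student's t-test on within-specimen differences, df = n−1, significant at
α = 0.05; two-sided is the conservative default where sidedness is not
dictated. Zero-variance differences short-circuit to p = 1 (all-zero) or
p = 0 (constant nonzero) with a warning. Specimens lacking one region
cannot be paired and are excluded with a named log entry; no
multiple-testing correction is applied across the four endocrine types.

Simulated cohorts draw per-specimen values independently from
N(group mean, (SEM·√n)²) with n = 3 — the specimen-level spread implied by
a reported group SEM. Reference group means/SEMs for the rich/poor
contrast are packaged in `HUMAN_RICH_POOR_REFERENCE` (percent of tissue
area): PP 1.2±0.08 vs 0.01±0.004, beta 0.3±0.07 vs 0.7±0.06, alpha
0.08±0.03 vs 0.5±0.01. A consequence worth knowing: with independent
draws, df = 2 and two-sided testing, the beta contrast's noncentrality
(≈4.3) sits essentially at the critical t (4.30), so its simulated
rejection rate is ~62–64%, while alpha and PP reject in >99.9% of
replicates. A single observed cohort reaching P < 0.05 on all three is
therefore unsurprising, but the beta comparison is not highly powered at
n = 3 unless rich and poor values are positively correlated within
specimen — which independent draws deliberately do not assume.

## Synthetic section generator

The generator emulates exactly the structure the analysis assumes, with
pixel-level ground truth (label map, per-pixel type map, per-object table,
true area fractions computed from the maps themselves):

- **Cells** are filled discs, radius ~ N(5, 1) µm truncated at 2 µm.
- **Islets** are star-convex polygons (24 vertices, smooth radial noise,
  amplitude 0.22) packed with cell discs on a jittered grid at 1.45× the
  cell radius, so neighboring discs overlap and the footprint is
  connected. Cell-type counts follow a composition interpolated linearly
  in log₁₀(area) between small-islet (beta 0.80/alpha 0.12/delta
  0.06/pp 0.02) and large-islet (0.55/0.28/0.10/0.07) anchors: islets
  under 60 µm effective diameter get a beta core with an alpha/delta
  mantle (PP outermost inside the rich zone, emulating peripheral PP),
  larger islets intermingle types.
- **Pure-PP clusters** (rich zone only) use anisotropically scaled
  (aspect ~ N(3.0, 0.8), floor 1.5), concavity-perturbed polygons
  (radial amplitude 0.45) — measurably less circular and longer-Feret
  than islets.
- **Islet count** is set by `islet_count_density` (default 30 islets/mm²,
  an order-of-magnitude choice exposed as config, not a biological claim);
  lognormal cell counts (ln-mean 3.0, ln-sd 1.0).
- **Area-fraction targeting**: per region (PP-poor defaults beta 0.7,
  alpha 0.5, delta 0.1, pp 0.01; PP-rich defaults beta 0.3, alpha 0.08,
  delta 0.1, pp 1.2 — the reference regimes above), objects are added
  iteratively — islets first, then elongated pure-PP clusters for ~80% of
  a rich zone's PP budget, then per-type singlets/small clusters to top up
  deficits — rejecting any addition that would overshoot a type's budget.
  Realized fractions land within a 10% relative tolerance with an absolute
  floor of one mean cell's area: discrete ~78 µm² cells cannot realize a
  0.01% target to 10% on a 512² µm raster (one cell is already 0.03%), so
  sub-cell targets are met to within one cell, possibly with zero painted
  pixels. Placement keeps a 25 µm clearance ring between objects so the
  10 µm detection closing never fuses distinct objects; if a budget cannot
  be placed after 200 attempts, an error names the conflicting parameters.
- **Rendering**: foreground 0.8 ± 0.05, background 0.05 ± 0.02, Gaussian
  blur σ = 1 px, clipped to [0, 1]. Nuclei are 3 µm discs on a jittered
  12 µm grid running edge to edge, so the derived tissue mask reaches the
  image borders and matches the ground-truth denominator (the whole
  raster is parenchyma). All randomness flows from one
  `numpy.random.Generator`; identical configs give bit-identical output.

What the generator does **not** emulate: realistic staining texture or
point-spread functions, autofluorescence, hormone co-expression, exocrine
structures beyond a uniform background, vasculature/ducts, 3-D tissue
context, or stage misalignment. Passing recovery tests therefore
demonstrates that the measurement chain is unbiased under its own stated
assumptions — not that it is robust to acquisition artifacts absent from
the model.

## Problem sizes and numerical choices

Default sections are 512×512 px at 1 µm/px (0.26 mm² of tissue); the
packaged pipeline analyzes three specimens × two sections plus an
eight-block series, sizes chosen so a full run completes in well under a
minute while every stage still exercises tens of objects per condition.
Degenerate inputs are defined rather than left to chance: empty masks give
empty object lists, an unstained channel gives an empty mask with a
warning, an empty tissue denominator is an error, boundary detection on
fewer than three blocks returns none, and a single-pixel object uses
P = 4·px, F = √2·px.

## Known limitations

- Area fractions are a 2-D mass proxy; no 2-D→3-D conversion via pancreas
  weight is attempted.
- The rich/poor threshold (0.2%) is a packaged default separating the two
  reference regimes, not a universal biological constant; it is exposed in
  config and recorded in outputs.
- Composition-vs-size curves aggregate per-object mean fractions per log
  bin; sparse bins (few objects) are reported as-is and are noisy by
  construction.
- Otsu thresholds are computed per channel on the whole raster; sections
  whose tissue occupies a small minority of the frame may need fixed
  thresholds.
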