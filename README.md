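# isletquant

Whole-section quantification of pancreatic endocrine cell mass from
multichannel immunofluorescence images.

Accurate estimates of beta-cell (and total islet) mass in the human pancreas
are easily biased by where a tissue sample is taken. The head of the
pancreas contains a sharply bounded region — largely the uncinate process —
that is rich in pancreatic-polypeptide (PP) cells and poor in beta- and
alpha-cells, and that contains irregularly shaped clusters composed solely
of PP-cells. A section sampled inside versus outside this region gives very
different endocrine cell fractions. `isletquant` implements the analysis
chain used to quantify this at whole-section scale, for researchers doing
stereological islet quantification:

1. **Virtual-slice assembly** — stitch a grid of stage-aligned microscope
   fields of view (insulin, glucagon, somatostatin, PP, nuclei channels)
   into one composite section raster.
2. **Channel segmentation** — per-channel Otsu (or fixed) thresholds,
   contested pixels assigned to a single endocrine type, and a
   tissue-parenchyma mask as the denominator for area fractions.
3. **Islet morphometry** — automated contouring of every endocrine object
   from singlets to large islets, with per-object area *A*, perimeter *P*,
   circularity *C* = 4π·A/P² (1.0 for a perfect circle), Feret's diameter
   *F* (the longest distance within a structure), effective diameter
   d = 2√(A/π), and log₁₀ A.
4. **Regional analysis** — per-block islet size distributions on a
   logarithmic area scale, composition-vs-size curves, PP-rich/PP-poor
   classification (default threshold 0.2% PP area, 10× the pancreas-wide
   baseline of ~0.02%), and single change-point detection of the regional
   boundary along the head→tail block series.
5. **Paired statistics** — mean ± SEM and two-sided paired Student's
   *t*-tests (significant at *P* < 0.05) comparing PP-rich vs PP-poor
   regions within specimen.

Because donor tissue cannot ship with a package, a **synthetic section
generator** produces multichannel images with pixel-level ground truth
(label map, per-object composition, true area fractions) that reproduce the
statistical structure the analysis assumes: lognormal islet sizes,
size-dependent beta/alpha composition, and an optional PP-rich zone with
elongated pure-PP clusters. Every analysis stage is validated by recovering
the generator's known truth.

## Worked example

```bash
isletquant run --seed 0 --out out/
```

runs the full synthetic study — three specimens, each contributing one
PP-rich and one PP-poor section (tiled, stitched, segmented, contoured,
summarized), plus an eight-block head→tail series — and prints:

```
report written to out/report.json (3/4 comparisons significant; series boundary at block 3)
```

`out/report.json` contains the paired comparisons (area fractions in
percent of tissue area, mean ± SEM across specimens):

| variable | PP-rich       | PP-poor       | t      | p      | significant |
|----------|---------------|---------------|--------|--------|-------------|
| beta     | 0.305 ± 0.013 | 0.770 ± 0.007 | −28.8  | 0.0012 | yes         |
| alpha    | 0.072 ± 0.010 | 0.484 ± 0.010 | −20.8  | 0.0023 | yes         |
| delta    | 0.079 ± 0.008 | 0.093 ± 0.005 | −1.4   | 0.29   | no          |
| pp       | 1.229 ± 0.042 | 0.028 ± 0.002 | +29.0  | 0.0012 | yes         |

i.e. the PP-rich region carries ~40× more PP-cell area while beta- and
alpha-cell area are significantly reduced — the regional contrast the
package exists to measure. The block series' measured PP fractions
(1.32, 1.23, 1.22, 0.0, 0.0, …) yield labels
`rich, rich, rich, poor, poor, …` and a detected boundary at block 3,
matching the generator's programmed transition exactly.

The same stages are available as a library:

```python
import isletquant as iq

stack, truth = iq.generate_section(iq.pp_rich_config())   # synthetic section
masks = iq.segment_channels(stack)                        # per-type masks
fractions, meta = iq.area_fractions(masks)                # percent of tissue
objects = iq.detect_objects(masks, merge_radius=10.0)     # contoured islets
summary = iq.summarize_section(objects, fractions)        # size/composition
```

and as further CLI subcommands (`isletquant simulate`, `isletquant
segment`).

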