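# Methods

This note records the models, conventions and numerical choices behind
`vesselmetrics`, in enough detail to reproduce or contest any number the
package computes.

## Binarization

Images are first linearly rescaled to 8 bits (`(v − min)/(max − min)·255`,
ties rounded half away from zero; constant images map to 0). A pixel is
then foreground iff its intensity exceeds the **local mean** over a
`window × window` neighborhood (edge-replicated) **plus** an offset;
defaults `window = 51 px`, `offset = 10`. The offset raises the local
threshold, so flat background — however bright — is never foreground, and
the window must exceed the widest vessel so that the local mean tracks
background rather than vessel cores. Local-mean thresholding makes the
mask insensitive to the slowly varying illumination typical of stitched
flatmount mosaics; no separate illumination correction is attempted.

Despeckling uses a **radius-0.5 median**: a majority vote over the pixel
and its 4-neighbors. It removes isolated pixels and fills single-pixel
holes, and it erodes 1-px-wide *diagonal* lines — vessel strokes must be
at least 2 px wide, which constrains the pixel size (µm/px ≲ vessel
radius). The plus-kernel is not a root filter: on corner configurations a
second pass can still flip a small number of pixels (~0.2% of foreground
on realistic masks). The pipeline applies it once, as the processing
chain prescribes; tests assert strict idempotence only on simple
structures and near-idempotence elsewhere.

The ROI (a mask or, implicitly, the full frame) is applied last; **all
densities are normalized to ROI area**, never image area.

## Skeleton graph

The mask is thinned with `skimage.morphology.skeletonize`
(topology-preserving, 8-connected). Skeleton pixels are classified by
their number of 8-neighbors on the skeleton: endpoint (<2), slab (=2),
junction (≥3). Adjacent junction pixels are merged into **junction
clusters** (8-connected components); a thick crossing thins into several
adjacent high-degree pixels that are biologically one branch point, so
all branch counts are cluster counts.

Segments are traced deterministically (neighbor scan order N, NE, E, SE,
S, SW, W, NW): chains run outward from terminals, leftover pure-slab
cycles become closed segments, isolated pixels become zero-length
segments. Every 8-adjacency between skeleton pixels is walked exactly
once; orthogonal steps contribute `pixel_size`, diagonal steps
`√2·pixel_size`. Total length = sum of segment lengths plus the few steps
internal to junction clusters, and on any skeleton it equals the direct
pair-sum over all 8-adjacent skeleton pixel pairs — the property the test
suite asserts against a brute-force oracle. The √2 diagonal convention is
a choice; length totals are therefore comparable only between tools using
the same convention.

Thinning spawns short terminal twigs wherever two strokes meet at a sharp
corner. These are medial-axis artifacts, not vessels, so terminal
segments shorter than **5 px** hanging off a junction are pruned and the
skeleton is re-thinned and reclassified (`build_graph(...,
prune_spurs_px=0)` disables this). Genuine blind sprouts in retinal
images are an order of magnitude longer.

## The six parameters

* **Area fraction** = |foreground ∩ ROI| / |ROI|.
* **Length density** = total skeleton length (mm) / ROI area (mm²).
* **Branch density** = junction clusters / ROI area (mm²).
* **NND mean / variability**: each positive-length segment is represented
  by its pixel-centroid (in µm); for segment *i*,
  `d_i = min_{j≠i} ‖c_i − c_j‖`; the statistic is the mean and the
  sample (n−1) SD of the `d_i`. Segments are used as the "particles"
  because pixel-set distances between segments that share a junction are
  ~0 and carry no spacing information, whereas centroid spacing tracks
  the capillary mesh size. Zero-length (isolated-pixel) segments are
  noise and excluded. Note the statistic is a *segment-centroid* spacing:
  it grows with segment length as well as with vessel separation.
* **Outgrowth** = (max distance from the optic-nerve-head center to a
  vessel pixel) / (max distance from the center to an ROI pixel), clamped
  to [0, 1]. A max statistic is destroyed by a single surviving noise
  speck, so connected components smaller than 25 px are ignored when
  locating the front (`min_object_px`).
* **Heatmap**: the ROI bounding box is tiled with squares of side
  `tile_µm` (default 100 µm); tiles with ≥50% of their pixels in the ROI
  get the area fraction over tile ∩ ROI, others are missing; the
  histogram uses 20 equal bins on [0, 1]. The ≥50% rule avoids
  artificially low border tiles. Rendering is cosmetic; the numeric grid
  is the contract.

## Whole-retina vs single-plexus analysis

`collapse_stack` is a per-pixel maximum projection. `separate_plexuses`
("auto") thresholds the stack globally (Otsu), counts foreground per
slice, smooths with a centered 3-slice moving average, takes the three
highest local maxima as the plexus depths and cuts at the minima between
them; the three ranges partition the z-extent. If three peaks cannot be
found the caller is told to supply manual ranges. Auto separation assumes
a z-resolution of ~1–2 µm so the layers resolve as distinct peaks.

Per-plexus results are combined by the extensive/intensive rule: length
and branch densities are **summed**; area fraction, NND mean, NND SD and
outgrowth are **arithmetic means** over the three plexuses (a
nearly-empty plexus contributes its zeros to the means, and its NND is
reported as 0 with a warning since spacing is undefined below two
segments). Averaging outgrowth and the NND SD across plexuses is an
interpretation — no canonical rule exists for them — and is stated here
rather than hidden.

Deviation between modes: `(single − whole)/whole × 100`, rounded half
away from zero to 2 decimals (the rounding is display-level; full
precision is stored everywhere else). Developmental change:
`(early − late)/early × 100` to 1 decimal, positive = reduction.
Rounding half away from zero is implemented in decimal arithmetic on the
shortest decimal representation of the float, so printed values match
hand computation on the stated operands.

## Synthetic vascular networks

The generator grows a geometric graph, not an image: nodes, polyline
edges and radii are exact, so length, junction count and radial extent
are known without measurement error.

**Growth model.** Tips start at the field center (evenly spaced headings)
and advance 10 µm per round with wrapped-normal heading jitter. Each tip
branches after a drawn distance with mean `1/branch_rate`;
`branch_dispersion` sets the relative spread of that distance (≈1 gives
irregular, immature-like branching; ≈0.1 the regular spacing of a pruned
network). A tip stepping within the **capture radius** of an existing
vessel fuses with it (probability `anastomosis_probability`, creating a
loop and a recorded junction) or stalls as a blind ending — tips die in
crowded territory, which is what makes the density self-limiting: the
capture radius is effectively the oxygenation length scale that sets the
capillary mesh size. Still-growing neighbors do not yet perfuse tissue,
so trails of active tips interact only at contact scale (stroke touch);
contact fusions are deferred and connected once the trail becomes an
edge. Growth stops at `outgrowth_fraction × field radius`.

**Heterogeneity controls.** `capture_jitter` disperses the stopping
distance per tip; `patchiness` overlays a two-level spatial field (a
fixed fraction of sparse cells amid dense mesh, mid-periphery only) that
reproduces the patchy texture of the immature plexus — the source of its
high NND variability. Both default to 0 (homogeneous).

**Raster consistency.** When `min_junction_separation` is set, the
generator additionally guarantees that the drawn image cannot contradict
the graph: junctions keep the stated spacing (fusions that would violate
it stall instead, retracting a step for clearance), no fusion creates a
sub-step stub, blind endings that would touch another vessel are
retracted, edges shorter than 2 µm are contracted, and a final
contact-detection pass rejects any growth in which two vessels approach
within merge distance away from a shared junction — rejected growths are
regrown with a different internal stream, deterministically, so a seed
always maps to one network. This is the regime used for ground-truth
recovery tests (branch rates 0.004/0.008 µm⁻¹, full anastomosis, capture
18 µm, branch angle 1.2 rad, separation 25 µm = 5 stroke widths, noise
off): there, recovered junction counts match truth exactly in ≈97% of
seeds and the validation suite pins specific seeds where they match
exactly; recovered skeleton length runs ~4–7% above the polyline truth
(staircase effect of 8-connected thinning), within the 10% band asserted.

**Rasterization.** Each polyline is drawn as a hard stroke of width twice
its radius — a pixel (centers at integer coordinates) is foreground iff
it lies within one radius of the polyline — with no anti-aliasing, so an
analytic distance test reproduces the mask bit for bit. Foreground sits
at intensity 200 over a background of 25 (8-bit scale; ×257 for 16-bit),
with an optional multiplicative left-to-right illumination ramp and
additive Gaussian noise, all seeded. Stacks place each layer's vessels in
a Gaussian-weighted z-band (σ_z = 2.5 µm) centered on its depth; bands
closer than 4σ_z trigger an overlap warning.

**Presets.** `p10` (immature: high branch rate 0.05 µm⁻¹, dispersive
branching, 45% of anastomoses, capture 12 µm with per-tip jitter and
patchiness, radii 2.5–3.5 µm, outgrowth 0.94) and `p60` (adult: branch
rate 0.025 µm⁻¹, regular branching, 98% anastomosis, capture 14 µm,
radii 1.8–2.6 µm, outgrowth 1.0). The values are calibrated to the
published study conditions — the implied vessel calibers
(area-fraction/length ≈ 6.1 vs 4.9 µm), branch-per-length ratios
(≈0.038 vs 0.025 µm⁻¹) and spacing scales — so that an immature-like
cohort ranks above an adult-like one in area fraction, branch density and
NND variability and below it in NND mean, as in the retina. Qualitative
comparisons are made between group means of 3–4 replicate networks,
mirroring the study's 3–4 animals per timepoint; single replicates can
occasionally invert the thinner margins.

**What the generator does not emulate.** Arteries/veins and vessel-type
hierarchy, pericyte/astrocyte channels, real PSF blur and depth
attenuation, stitching artifacts, time-lapse remodeling dynamics, and the
biological coupling between layers of a stack (layers are either
independent draws or copies). Passing tests therefore validate the
*measurement chain* — that the pipeline recovers known geometry from
images with realistic noise, illumination and density — not that the
pipeline handles every property of real microscope data.

## Degenerate inputs and tie-breaks

Constant images binarize to empty masks; empty masks yield zero densities
and an error (or a warned 0 inside the pipeline) for NND; ROIs must be
non-empty; `percent_deviation`/`percent_change` refuse zero baselines;
stacks with fewer than three z-peaks refuse auto separation. All tracing
and generation is deterministic: fixed neighbor scan order, fixed tip
ordering, per-tip random streams derived from (seed, tip id), so reruns
are bit-identical.

## Known limitations

* Skeleton length overestimates polyline truth by ~4–7% (8-connected
  staircase); the √2 convention cannot remove this bias.
* Junction-count exactness degrades when junctions sit closer than ~5
  stroke widths or when vessel width approaches spacing (merging);
  dense immature-like networks are measured with a negative bias in
  branch density, which is the realistic behavior of the method.
* The NND statistic is segment-based; comparing its absolute values with
  tools that use different "particles" is not meaningful.
* Auto plexus separation requires three separable peaks; stacks acquired
  with coarse z-steps need manual ranges.
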