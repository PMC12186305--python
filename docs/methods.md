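# Methods

## The measurement

The mean linear intercept estimates airspace size in lung parenchyma from
the chord structure of a binary tissue mask. A layout of `n_lines`
equidistant horizontal test lines (default 10) is placed on interior rows
`round((k+1)·H/(n_lines+1))`, k = 0..n_lines−1, so no line falls on the
image border and consecutive spacings differ by at most one pixel from
rounding. Along each line the counter scans left to right and registers a
transition at x when `mask[x] != mask[x-1]`; after a registered
transition, at least `guard_gap` pixels must elapse before the next may
register. Then

- `l` = n_lines × width × pixel_size,
- `n` = summed registered transitions,
- `Lm = l / n`.

`Lm·n == l` holds exactly in exact arithmetic; a uniform mask has no
intercepts and the computation refuses to divide by zero. The guard gap
exists because segmentation boundaries are ragged at the pixel level: a
one-pixel notch would otherwise contribute two spurious intercepts. Counts
are non-increasing in the guard gap, and a guard of 0 reproduces the naive
transition count. The default guard is 3 px; it is configurable, and all
quantitative checks state the value they use. Two conventions are fixed
package-wide: tissue = 1 / airspace = 0, and no intercept is registered at
image borders (a line starting mid-phase still contributes its full width
to `l`). A flag switches the sampling from the line's own row to the OR of
the two flanking rows, for protocols that treat the line as an opaque
overlay; the default samples the row itself.

Physical calibration is optional: with no pixel size set, `l` and `Lm` are
in pixels (1 px = 1 unit); a pixel size in µm/px scales `l` and `Lm`
linearly and leaves `n` unchanged.

## Classical annotation

The annotation arm converts RGB micrographs to greyscale with BT.601 luma
weights (0.299, 0.587, 0.114), thresholds them (Otsu by default — robust
to staining intensity and deterministic per image — with a fixed-value
override), and runs a morphology sequence on the *white* (airspace) phase:
erode, dilate, dilate, erode with a 3×3 square kernel by default. That
sequence is an opening followed by a closing of the airspace phase: it
removes specks smaller than the kernel in either phase while leaving
regular walls intact. Kernel shape/size and the step list are
configuration, because only the order of the published steps is fixed, not
their geometry. Out-of-image values replicate the edge pixel, which avoids
spurious structures at borders. Pixels at or above the threshold are
airspace (bright), below it tissue.

## Patchwork

Images are cut into square patches (default 352 px) on a regular grid with
stride half the patch side (default 176 px). The raster is mirror-padded
on the bottom/right so the grid covers it exactly; for the 1292×968
reference geometry this gives 7×5 = 35 tiles on a 1408×1056 canvas.
Overlapping per-patch outputs are combined by the per-pixel arithmetic
mean and cropped back to the input size. Averaging before thresholding
smooths tile seams; for integer-valued tiles under an identity transform
the mean of k identical values is exact in IEEE arithmetic, so
stitch∘extract is bit-exact.

## Segmentation model

A symmetric U-Net-style encoder-decoder written directly on NumPy: per
level two 3×3 same-padded convolutions + ReLU, 2×2 max-pooling down,
nearest-neighbour upsampling with skip concatenation up, 1×1 output
convolution to per-pixel tissue logits. Input and output spatial
dimensions are equal for any side length divisible by 2^depth. Training
minimises mean per-pixel binary cross-entropy with Adam; weights use He
initialisation from a seeded generator, so instantiation, training and
prediction are reproducible run to run. Convolutions are im2col matrix
products, so the arithmetic rides on BLAS. The architecture is specified
by its contract (symmetric, equal in/out dims, probability output), with
depth and width as configuration; the default is depth 2 with 8 base
channels, which is ample for the two-level contrast of the data this
package targets.

Defaults follow the reference training recipe: 20 epochs, learning rate
1e-4, batch size 9, patch 352 / stride 176, no augmentation or
oversampling. Loss and optimiser are this package's own choices (the
recipe leaves them open); binary cross-entropy with Adam is the standard
pairing for binary segmentation. Training labels default to the classical
annotations — the same bootstrapping the original pipeline used — with
ground-truth masks available as an alternative on synthetic data.

The 72-image cohort is split 50/11/11 into train/validation/test,
stratified by mouse so every animal appears in every split when it has at
least three images; per-mouse allocations follow the split proportions
with largest-remainder rounding and a seeded shuffle picks the indices.

## Synthetic data

Real lung micrographs show bright airspace lumens separated by darker
stained walls; healthy tissue has visibly smaller lumens than
emphysematous tissue. The generator emulates exactly this contrast:

- **Stripe/band phantoms** with transitions forced by construction pin the
  intercept arithmetic to closed-form values (e.g. a centred 20 px band in
  a 100 px image: n = 20, Lm = 50 px with 10 lines).
- **Parenchyma images**: lumen centres on a jittered grid with spacing
  `lumen_scale` (a Poisson-disk-like point process), walls where the
  distance gap between the two nearest centres is below `wall_thickness`
  (≈ the set of pixels within half the wall thickness of a Voronoi cell
  boundary). The wall mask is then regularised to a fixed point of the
  default white-opening/closing sequence, so truth masks carry no
  sub-kernel structure — mirroring the fact that real training annotations
  come out of that same morphology, and making the noiseless
  annotation round-trip exact. The image renders tissue at one intensity
  (default 90), airspace at a brighter one (default 220), plus Gaussian
  noise (default sd 8), clipped to 8-bit.

Defaults define the emulated study: 2 groups × 3 mice × 12 images
(72 images), control lumen scale 24 px vs smoker 36 px (ratio 1.5), wall
thickness 4 px, image side 128 px for desk-scale runs. Per-sample seeds
derive from the master seed as SHA-256 of `"{seed}:{group}:{mouse}:{image}"`
mod 2³¹, so cohorts are bit-reproducible across platforms. What the
generator does **not** emulate: staining variation and artefacts, vessels
and airways, anisotropy, 3-D structure, and the texture of real H&E — so
green tests demonstrate the pipeline's arithmetic, learning and statistics
under the intended morphology contrast, not segmentation accuracy on real
histology.

## Statistics

Group comparison uses the pooled-variance two-sample Student t-test on
image-level Lm values (12 per mouse by default; per-mouse means are
available), two-sided by default with a one-sided option, α = 5%, stars at
p ≤ 0.05 / 0.01 / 0.001. The t statistic is computed in closed form; the
p-value comes from the t distribution with n_a + n_b − 2 degrees of
freedom (Welch's correction available behind a flag). Within-group
homogeneity is assessed by pairwise cross-tests between the mice of one
group (3 mice → 3 pairs); non-significance indicates homogeneity. No
multiple-testing correction is applied to cross-test tables by default,
matching the reference protocol; with six calibrated null tests per
cohort, roughly one in four cohorts will show at least one nominally
significant pair by chance, so calibration checks aggregate over many
cohorts (the acceptance suite requires ≥ 90% of all pairwise tests over
20 master seeds to be non-significant; the expected fraction under
correct calibration is 95%).

"Overall" IoU/F1 for a split is the unweighted mean of the tissue and
background values computed from pooled pixel counts; the reference tables
do not define their aggregation rule, so this package fixes one and states
it. Published cell values rounded to two decimals need not be mutually
consistent (a confusion table whose cells imply tissue IoU ≈ 0.94 can
accompany a printed 0.92); no attempt is made to "fix" such rounding.

## Scaled-down study sizes

Desk-scale runs (test suite and examples) use 128×128 px images — one
patch per image at patch 128 / stride 64 — a depth-2 / 8-channel network,
10 epochs at learning rate 3e-3, and the full 2×3×12 cohort with the
50/11/11 split. On this configuration the held-out tissue IoU against
ground truth is ≈ 0.93 and both the classical and learned arms separate
control from smoker at p ≪ 0.05 with the smoker mean higher, the learned
arm's Lm running slightly above the classical arm's (the same direction
the full-scale protocol reports). Larger images, deeper networks and the
full 20-epoch / lr 1e-4 recipe are plain configuration changes.

## Known limitations

- The NumPy trainer is single-process and CPU-bound; it is sized for small
  cohorts and small patches, not for full-resolution training runs.
- Otsu thresholding assumes a bimodal intensity histogram; heavily
  understained or vignetted images need the fixed threshold or a trained
  model.
- Horizontal-only test lines estimate chord length in one orientation;
  anisotropic structures would need rotated line sets, which are out of
  scope.
- The guard gap trades overcounting against missing genuinely thin walls:
  walls thinner than the guard can be skipped. The default of 3 px matches
  the default wall thickness of 4 px.
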