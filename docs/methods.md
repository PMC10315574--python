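# Methods

This note documents the models and procedures behind `platepick`: what
the synthetic generator emulates, how each pipeline stage works, which
parameters matter, and the design choices made where the design was
genuinely open. It states no empirical numbers beyond what the test
suite and `scripts/acceptance.py` compute at run time.

## The synthetic plate model

The generator (`platepick.synthetic`) renders the scene a plate camera
sees from above: a dark background, a bright plastic dish wall (outer
diameter 85–89 mm, wall thickness 2 mm), an agar fill, and colonies as
**truncated Gaussian intensity domes** — each colony adds
`(color − agar) · exp(−d²/2σ²)` with `σ = r/2`, cut off at its radius
`r`. The dome shape matters: it guarantees exactly one smooth local
maximum per colony, which is the assumption the group splitter exploits;
overlapping domes are blended with a per-channel maximum so a valley
survives between touching colonies. Region boundaries are linearly
anti-aliased over one pixel.

Per plate the generator adds, in this order: colonies (placed by
rejection sampling), bright non-colony specks (0.15–0.4 mm radius), a
multiplicative linear illumination gradient (up to ±10% across the
frame), and i.i.d. Gaussian sensor noise, then clips to 8-bit. The
optional fluorescence channel renders each colony as a **flat disc** at
its assigned mean level (plus noise, no illumination gradient —
transillumination is spatially uniform at this scale), so the mean
intensity over a colony's true footprint equals its assigned level by
construction.

Placement details that shape the benchmark:

- **Crowding-dependent radii.** Up to 453 colonies of 0.6–2.5 mm radius
  cannot be packed without overlap in a ~41 mm-radius agar disc, so the
  radius upper bound shrinks with colony count to cap total coverage at
  ~25% of the agar area — mimicking nutrient competition on dense
  plates. Sparse plates use the full range.
- **Groups.** A configurable fraction of colonies is placed in touching
  pairs (occasionally triples): centre distance 0.72–0.92 of the radius
  sum, so members genuinely touch while distinct groups never overlap.
- **Border colonies.** A configurable fraction is placed inside the
  2 mm security margin at the wall; they remain wholly on the agar
  (colony centres never cross the inner wall edge, and nothing renders
  over the opaque wall — in transillumination a colony cannot show
  through the plastic).
- A shared budget of 10,000 placement rejections guards against
  infeasible requests (`PlacementError`).

Ground truth records every colony (position in px and mm, radius,
phenotype, fluorescence level, group id, pickable flag) and every speck.
A colony is *pickable* when its centre lies at least `margin_mm` (2 mm
default) inside the inner wall and its diameter is ≥ 1 mm — below that,
tip positioning error dominates and picking fails in practice.

**What the generator does not emulate:** lens distortion, agar surface
texture and glare, condensation, colony morphology beyond circular
domes (no lobed or nested colonies), color variation within a
phenotype, and camera color response. Detection numbers on this
benchmark therefore characterize the pipeline under controlled, known
degradations (touching groups, crowding, uneven illumination, noise,
specks) — they are an upper bound on, not a prediction of, real-plate
performance.

The canonical profile **benchmark-v1** is fixed in code: 20 plates,
master seed 42, per-plate colony counts uniform in 12–453, group
fraction 0.10, border fraction 0.05, 3 specks, ±10% illumination
gradient, noise σ 3, radii 0.6–2.5 mm, two phenotypes (white/blue),
0.1 mm/px.

## Dish detection

Circular Hough transform over a Canny edge map (σ = 2 px), two stages:
a coarse pass on a 4×-downsampled image over the configured diameter
range, then a full-resolution pass over a narrow radius band. Two
refinements proved necessary:

- The Hough peak sometimes locks onto the **inner** wall edge (the
  agar→wall contrast rivals the wall→background contrast) and is
  quantized to whole pixels. The radius is therefore snapped to the
  outermost half-height crossing of the azimuthal-mean radial intensity
  profile, and the centre is polished by two rounds of an algebraic
  (Kåsa) least-squares circle fit to the edge pixels within ±4 px of
  the outer circle. Sub-pixel centre accuracy matters downstream: a few
  pixels of centre error lets the bright wall leak into the inner disc
  and floods the segmentation with wall fragments.
- A detection is rejected (`DishNotFoundError`) when the radial profile
  shows no wall-like plateau (contrast < 20 gray levels) — normalized
  Hough support alone is not discriminative on dense random edge maps.

## Inner-disc segmentation

Grayscale (luminance) → Gaussian blur (σ 0.15 mm) → adaptive Gaussian
threshold: foreground where the blurred image exceeds the local
Gaussian-weighted mean (block ≈ 6 mm, odd pixel count) by 4 gray
levels → removal of components smaller than a 0.3 mm-radius disc →
per-component convex hull, iterated to a fixpoint, clipped to the inner
disc.

Parameter rationale:

- **Block size 6 mm**, just above the largest colony diameter (5 mm).
  A smaller block hollows out large low-contrast colonies: their flat
  interior sits at the local mean and drops below the offset. The block
  must see true background for every colony.
- **Offset 4 gray levels** ≈ 4–7× the post-blur noise standard
  deviation at the benchmark noise level, so bare agar stays silent
  while the dimmest colony edge (a few gray levels above agar at the
  dome truncation) still fires.
- **Hull fixpoint.** Overlapping hulls merge neighbouring components;
  re-hulling until stable makes the output idempotent (every component
  equals its own hull, clipped at the disc boundary). On crowded plates
  a chain of near-touching colonies can still merge into one oversized
  segment whose hull covers agar — handled by the splitter below.

## Border (annulus) treatment

The wall annulus is processed separately from the inner disc, over a
band that overlaps the inner disc by 2 mm: multiplicative ±20% speckle
noise (breaking the wall edge's continuity), Canny with hysteresis at
0.1/0.3 of the band's intensity range, then sealing (closing), hole
filling, erosion, and a top-hat subtraction (equivalent to an opening)
that removes thin arcs. Three structural choices make this robust:

- the two circular wall edges are erased **geometrically** at their
  known radii (the detected circle and one wall thickness inside it),
  rather than trusting speckle alone to fragment them;
- the wall interior plus a 6 px clearance inside the inner edge is
  excluded — the brightness ramp at the wall foot, amplified by the
  multiplicative speckle, otherwise floods the band with false edges,
  and no colony signal can exist over the opaque wall anyway;
- colony contours cut by the band limits never close, so hole filling
  alone misses them; thickened (morphologically closed) edge arcs are
  united in, with small-object and oversized-blob filters.

On typical plates the stage contributes little (margin colonies are
mostly inside the inner disc and found there; the union of both masks
merges the pieces), but it is what finds a colony hugging the wall.

## Segment map

Foreground components (union of both masks) become "colonies" segments;
remaining pixels inside the dish circle form one "0 colonies" (agar)
segment and pixels outside it one "out of plate" segment. The map is by
construction a partition of the crop; sublabels are revised to
"k colonies" by the splitter. Panoptic export encodes segment ids in a
PNG as `id = R + 256·G + 256²·B` with a JSON carrying the category
table and per-segment area/bbox records.

## Group splitting

For each colony segment, regional maxima of the Gaussian-smoothed
grayscale (σ 0.3 mm) inside the segment are found with a minimum
separation of 0.8 mm; with ≥ 2 maxima, a marker-controlled watershed on
the inverted smoothed intensity divides the segment, and the children
partition the parent exactly. Two guards:

- σ and the separation bracket the geometry: 0.8 mm is below the
  minimum pickable colony diameter (true pairs stay separable) and far
  above the noise correlation length (single colonies don't split).
- Each watershed cell's peak must rise ≥ 8 gray levels above the cell's
  own 5th-percentile floor. This rejects maxima seeded on agar pockets
  inside oversized chain segments (agar relief across one cell is ~1–2
  gray levels) while keeping even the dimmest real colony (smoothed
  dome amplitude ≳ 20). The comparison is cell-local on purpose: a
  global floor would be confounded by the illumination gradient. When
  peaks are rejected the watershed is rerun with the survivors so the
  partition property is preserved.

Spurious splits of single colonies remain possible at low frequency;
no aspect-ratio or circle-fit post-filter is applied.

## Measurement, screening, mapping

Footprint measures: `area_mm² = area_px·scale²`, equivalent diameter
`2√(area/π)`, per-pixel HSV mean with **circular, saturation-weighted
hue averaging** (unit-vector mean, avoiding the 0/360 wrap and letting
near-gray pixels contribute little hue), and mean fluorescence under
the mask.

Screening marks are computed **per candidate set**: size is min-max
normalized over the candidates (degenerate spread ⇒ 1), color is
`1 − d/d_max` (similar) or `d/d_max` (dissimilar) with `d` the
Euclidean distance in the HSV cone embedding `(S·cos H, S·sin H, V)` —
chosen because it handles hue wrap and makes desaturated colors
hue-agnostic — and fluorescence is mean/255. The total is the
user-weighted sum; weights are normalized to 1. Ties in the descending
score order break by ascending colony id, making selection
deterministic and permutation-invariant. Destination wells fill
column-wise.

Coordinate mapping is exact vector arithmetic: crop-local centroid →
offset from dish centre → plus dish-to-labware offset → × mm/px scale →
image-to-right-handed conversion (negate y) → 90° anticlockwise
rotation `(u, v) → (−v, u)` → per-axis sign flags. The paper-frame
ambiguity (handedness of the camera image on the physical mount) lives
entirely in the sign flags, so a deployment can match its hardware
without code changes. The inverse map exists and round-trips to < 10⁻⁶
px. If the config omits the mm/px scale it can be estimated as (known
dish outer diameter)/(detected diameter in px).

## Dataset building

Each source image yields 15 derivatives: the 16 combinations of
rotation {0°, 90°, 180°, 270°} × mirror {none, horizontal, vertical,
both} minus the identity. Only 8 of the 16 are geometrically distinct
(the dihedral group of the square), so some derivatives coincide
pixel-wise; they are retained as separate entries so the ×15 bookkeeping
holds exactly. The train/validation split (75/25 by default) assigns
whole source groups, never individual derivatives, to a subset —
otherwise augmented copies of one plate would leak across the split.
With equal group sizes the item split is exact.

## Evaluation

Greedy closest-first one-to-one matching of detection centroids to
ground-truth centres within 1 mm (the picking tolerance; greedy rather
than optimal assignment for determinism and simplicity — at 1 mm
tolerance and ≥ 1.2 mm colony spacing the two rarely differ). Event
taxonomy: unmatched detections are FP (tallied as detected artifacts
when they sit on a known speck, and as multi-pick when they crowd an
already-matched truth); unmatched pickable truths are FN; truths inside
the security margin are "not pickable" and excluded from TP/FP/FN;
a detection whose mask covers ≥ 2 truth centres is a
group-detected-as-single event. Metrics are detection-style (no true
negatives — background pixels are not counted): sensitivity TP/(TP+FN),
precision TP/(TP+FP), accuracy TP/(TP+FP+FN) (a Jaccard-type index,
hence accuracy ≤ min(sensitivity, precision)), misclassification rate
1 − accuracy, and raw performance as the matched fraction of all / of
pickable truths. Zero denominators report as absent rather than 0.
Pooling over plates sums the counts, so pooled metrics equal metrics on
pooled counts.

## Problem sizes and determinism

Unit tests run on 500 px plates at 0.2 mm/px (every length parameter is
specified in mm, so defaults carry over); the acceptance suite and
`scripts/acceptance.py` run the full 20-plate benchmark at 0.1 mm/px.
All randomness flows through seeded `numpy` generators: a plate's seed
fixes its image bit-exactly, the benchmark's master seed fixes the
whole collection, and the border stage's speckle uses its own fixed
seed so segmentation is a pure function of the image.

## Known limitations

- The classical pipeline is tuned to bright-on-dark colonies over agar;
  dark or transparent colonies would need an inverted threshold.
- Colonies overlapping so strongly that their domes form one maximum
  are counted as one (group-as-single); conversely rare spurious splits
  occur. No interactive correction is provided.
- The wall-suppression logic assumes one circular dish per image.
- HSV screening is uncalibrated (camera-native color); absolute
  colorimetry and multi-fluorophore unmixing are out of scope.
- The robot side (protocol upload, motion, handshake) is represented
  only by the picklist CSV contract.
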