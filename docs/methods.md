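# Methods

## Problem setting

The pipeline targets fixed-camera, top-view monitoring of potted
rosette plants (one plant per poly bag, plants arranged with clear
separation) photographed around the clock. Near-infrared night
illumination renders leaves as the brightest, most uniform structures
in the frame; daylight adds illumination gradients across the bed and
cast shadows over the plants. Two tasks are addressed: locating each
plant as a bounding box (detection) and counting the leaves inside
each box (counting).

## Detection model

**Preprocessing.** Captures are halved (1280×1024 → 640×512, bilinear)
to cut cost roughly fourfold, sharpened per channel with the 3×3 kernel
whose centre is 9 and all other entries −1 (kernel sum 1, so flat
regions are preserved), then converted to gray. Sharpening precedes
grayscale conversion; results are clipped to [0, 255] and the border is
replicate-padded. Rounding of the luma sum is half-up. An alternative
`lab_a` mode rescales the CIELAB *a* channel to [0, 255] per image, for
visible-light inputs where green/magenta opposition beats brightness.

**Thresholding.** Segmentation into M classes uses the M−1 thresholds
that maximise the interclass variance σ_B² = Σₖ ωₖ(μₖ − μ_T)². The
search is exhaustive over all strictly increasing threshold vectors,
evaluated from zeroth- and first-order cumulative histogram moments;
the three-threshold case (M = 4) over 256 levels runs in well under a
second. Level i belongs to class k iff Th_(k−1) < i ≤ Th_k. Empty
classes carry ω = 0 and contribute nothing; a class whose cumulative
probability falls below 1e−12 is treated as empty, which also guards
against catastrophic cancellation in the cumulative sums. Ties are
broken toward the lexicographically smallest threshold vector so runs
are deterministic. The foreground rule is `top_class` by default
(pixels above the last threshold): at night, and after daytime
sharpening, leaves are the brightest structure. A fallback
`brightest_valid_class` rule walks classes from the brightest down
until one contains a component passing the area filter.

**Box extraction and fusion.** Foreground components (8-connected) are
filtered by area (defaults 0.1 %–25 % of the frame) and by shape: the
Hu-moment distance between the blob and a reference shape, computed on
reciprocal signed log-magnitudes, Σ|1/slog(hᵃ) − 1/slog(hᵇ)| with
slog(h) = sign(h)·log₁₀|h|. The reciprocal form keeps near-vanishing
high-order moments from dominating. The default reference is a set of
idealised rosette templates with 5–8 blades (closest template scores
the blob; a filled-disc template is also available); blobs farther than
`hu_tol` = 1.5 from every template are discarded. Two boxes merge when
a top-or-bottom edge pair and a left-or-right edge pair each agree
within 30 px (at 640×512). Mergeability is applied transitively: boxes
are clustered by the connected components of the pairwise relation and
each cluster keeps its best-shaped (lowest-distance) box with its own
extent, repeating until no pair merges. Method variants M1/M2/M3 run a
single 2-/3-/4-class thresholding; M4 = M1+M2, M5 = M1+M3, M6 = M2+M3
fuse the two box lists the same way. For combined methods the mask
carried forward to counting is the finer (multilevel) run's mask — the
bi-level mask tends to swallow the bag rim and soil structure.

**Image-sequence strategy.** Timestamps classify frames as day
([05:00, 18:00), start inclusive, end exclusive, configurable) or
night. The first frame always runs static detection and seeds a box
store. Later day frames emit the stored boxes verbatim — shadows make
fresh day detections unreliable, and skipping them also saves time.
Later night frames run static detection, fuse it with the store (same
merge rules), emit the fusion and overwrite the store. One consequence
worth knowing: a spurious night box persists in the store until a later
night detection merges it away; the store holds only the most recent
eligible detection, not a history.

## Counting model

Inside a plant box, the foreground mask is Euclidean
distance-transformed (exact distance to the nearest background pixel;
an all-foreground crop is measured against a virtual border just
outside the frame). Leaf centres appear as maxima of this map. Markers
are the candidate pixels that attain the maximum of their
(2·7+1)-square neighbourhood and reach ≥ 0.5 of the map's global
maximum; connected candidate plateaus collapse to one marker, and of
two marker centroids closer than 7 px only the higher (ties: more
top-left) survives. The spacing rule matters on a lattice: one ridge
commonly fragments into several equal-valued plateaus.

Flooding runs on the complemented distance map quantised to 0–255, so
leaf centres are valleys and the necks between touching leaves are
ridges. The scheduler is an ordered queue: 256 FIFO queues, one per
gray level, always serviced from the lowest occupied level; marker
boundary pixels enter at their own level, and each popped pixel labels
and enqueues its unlabeled in-mask neighbours (4-connected by default,
N/E/S/W order — fully deterministic). Basins smaller than 25 px are
absorbed into their largest neighbouring basin (isolated fragments are
dropped), and LF is the number of surviving basins.

When no precomputed mask is supplied, the crop is *not* thresholded in
isolation: a plant-box histogram is dominated by the leaf mode and
multilevel Otsu would split that mode. Instead the full frame is
thresholded (3-class by default, degrading to 2-class if the frame has
too few occupied levels) and the resulting mask is cropped. The CLI's
counting stage also deliberately skips sharpening — it helps
thresholding contrast but its amplified noise fragments blades and
seeds spurious watershed basins.

## Evaluation

Predictions match ground truth greedily by descending IoU with a
one-to-one constraint; pairs at IoU ≥ 0.5 (default) are TP, leftovers
FP / FN. Fractional per-frame values (counts divided by the number of
ground-truth plants) are available alongside absolute counts. Recall,
precision and F1 use the usual formulas with zero denominators mapping
to 0 (logged). FBD is the dice overlap of foreground masks, defined as
1 when both masks are empty. DiC = mean(GT − LF) (positive =
undercount) and ABS_DiC = mean|GT − LF| are reported with sample
standard deviations (ddof = 1; a single pair reports 0). Aggregation
is by unweighted group means (scene, plant, day/night or method) plus
an overall row that averages the group means, not the frames.

## Synthetic scenes

The generator renders the world the pipeline assumes: soil at gray 60,
a poly-bag rim as a ring at 120 (inner radius 1.1 r, outer 1.3 r around
each plant), and leaves at 230, replicated into all three RGB channels
as a near-infrared camera effectively does. Each plant is a rosette of
k elliptical blades on 1.5-px-wide petioles that meet at the centre —
the plant is one connected blob, but the central junction stays much
thinner than any blade, so each blade carries exactly one prominent
distance maximum. An `overlap` knob in [0, 1] slides the blades inward
and widens them until neighbours fuse, reproducing the regime where
touching leaves defeat marker-based counting (the counter then errs
toward undercounting, never over). Night frames add Gaussian noise
(σ = 3); day frames add a linear horizontal gradient (amplitude 60) and
rectangular shadows (offset −90) cast across randomly chosen plants.
Layout is locked per sequence seed while noise and shadows re-draw per
frame. Scenes are deterministic to the byte for a given spec.

What a green test on these scenes does *not* establish: robustness to
real leaf texture, specular highlights, soil clutter, overlapping
neighbour plants, camera drift, or growth across days. The generator's
shadows are additive rectangles, not penumbral; its blades are
ellipses, not serrated leaves. The synthetic world is engineered to
exercise the pipeline's decision points (threshold count, shape filter,
day/night fusion, basin merging), not to predict field accuracy.

## Numerical and design choices

- Otsu tie-break: lexicographic smallest vector; empty-class guard at
  ω ≤ 1e−12.
- Merge winner keeps its own extent (not the union of the pair).
- Hu metric: reciprocal signed-log form; moments below 1e−30 in
  magnitude are clamped before the log.
- Watershed ties: FIFO within a gray level, fixed neighbour order,
  4-connectivity default (keeps ridge lines thin).
- Marker defaults (min_distance 7 px, rel_height 0.5) were tuned once
  on the synthetic fixture suite; rel_height must exceed the ratio of
  the rosette-core distance value to the blade half-width (≈ 0.42–0.47
  here), else the core junction seeds a phantom basin.
- `leaf_area_min` = 25 px at 640×512; scale it with resolution if
  resizing is disabled.
- Day window boundaries are site- and season-specific; both ends are
  config keys.

## Known limitations

- A false box that enters the sequence store on a night frame persists
  through the following day.
- Plants whose rosette shape departs strongly from the 5–8-blade
  templates need a custom shape reference (or a larger `hu_tol`).
- Heavily overlapping leaves are undercounted by construction; no
  attempt is made to split fused blades beyond the distance-transform
  evidence.
- Counting quality on shadow-crossed day frames is poor; the intended
  operating mode is counting on night frames (or on boxes replayed from
  them).
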