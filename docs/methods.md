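# Methods

This note documents the models, conventions, numerical choices and known
limitations of `cobbkit`, in the order the pipeline runs.

## Coordinate and angle conventions

Pixels are 0-based with x rightward and y downward.  Vertebral corners
are always ordered (UL, UR, LL, LR) in the vertebra's own orientation;
the four heatmap channels and all offset fields inherit this order.
Angles are degrees; a vertebra's inclination is positive when its right
side sits lower than its left (clockwise on screen), wrapped to
(−90°, 90°].  Curve tables round to 0.1°; internal computation is full
double precision.

## Synthetic spine phantom (`cobbkit.phantom`)

The phantom emulates the content of a full-length AP radiograph of an
AIS patient — not its radiometric physics.  Geometry: a centerline
x(t) = W/2 + Σᵢ Aᵢ sin(2π fᵢ t + φᵢ), t ∈ [0, 1] spanning T1→L5, carries
17 quadrilaterals whose rotation is the perpendicular of the local
tangent; vertebra heights grow linearly by 50% from T1 to L5 and widths
are 1.7× height, matching the coarse proportions of thoracolumbar
anatomy.  Independent Gaussian tilts (sd `endplate_shear_sd`, default
1.5°) are applied to each endplate about its midpoint, so vertebrae are
generally trapezoids.  Because the sum of two unit vectors bisects their
angle, the midline inclination of a sheared vertebra is exactly
θ + (δ_top + δ_bottom)/2 — the stored ground truth is analytic, and the
geometric measurement chain is validated against it to 1e-6°.

Postures scale the curve amplitude (standing 1.0, supine 0.7, side-
bending 0.55 signed by bend direction, brace 0.8); the brace regime adds
2–3 horizontal radio-opaque bands that occlude pixels but never move
landmarks.  Rendering draws filled quadrilaterals over a smooth
background gradient, Gaussian-blurs edges (σ = 1.2 px), applies display
gamma, optional polarity inversion and additive Gaussian noise.  The
default appearance ranges (amplitudes 4–12% of image width, noise sd
0.01–0.05, gamma 0.8–1.25, 50% bone-dark polarity) were fixed once as
plausible desk-scale stand-ins for the variability of clinical
radiographs collected over a decade on mixed equipment.

What the phantom does *not* model: ribs, pelvis, soft-tissue texture,
scanner blur kernels, projective distortion, implants.  Tests passing on
phantoms therefore demonstrate the correctness of the algorithmic chain
(targets → detection → grouping → geometry → statistics), not clinical
performance.

The train/test/eval split defaults to the 915:106:155 proportions
rescaled to the dataset size, assigned as contiguous blocks.

## Stage 1 — ROI regression (`cobbkit.roi_net`)

Input: the min–max-normalised radiograph, anisotropically resized
(default 512×512, desk-scale 64×64), replicated to three channels.
Output: four sigmoid values (x1, y1, x2, y2) of the thoracolumbar box.
Anisotropic resizing keeps normalised coordinates invariant, so no
letterbox bookkeeping is needed.  Degenerate or mis-ordered regressions
are canonicalised (corners sorted, boxes expanded to a 1-px minimum).
Training: MSE, Adam 1.25e-4, exponential decay 0.96/epoch, 30 epochs,
with polarity-inversion and random-crop augmentation; crops are sampled
in integer pixels (≤10% per side), clipped so they never cut the true
box, and the label is re-expressed exactly in the cropped frame (the
augmentation is invertible to 1e-9).  An optional gamma-jitter
augmentation exists but is off by default.

## Stage 2 — corner detection (`cobbkit.keypoint_net`)

Targets at 1/stride resolution (stride 4): per corner type, an
unnormalised Gaussian disk with peak 1 at the floor-quantised corner
cell; the radius follows the CornerNet minimum-overlap rule (IoU 0.7 on
the vertebra's grid-unit bounding box, floor 2 cells) with σ =
(2r + 1)/6; overlapping disks combine by maximum.  The center offset
stores the exact sub-grid remainder ∈ [0, 1)², and the vertebral center
offset stores (centroid − corner)/stride; both only at peak cells, which
makes the encode→decode round trip bit-exact and is tested at 1e-6 px.

Channel layout: the default stores offsets per corner type
(4 + 8 + 8 = 20 channels).  A compact alternative (4 + 2 + 4 = 10
channels: shared center offset, vertebral center offset split into an
upper-pair and lower-pair 2-vector) sits behind `layout="compact"`; the
per-corner layout is the default because every field semantic is
realisable without collisions.

Losses: penalty-reduced focal loss on the heatmaps, at target-1 pixels
−(1−p)^α log p and elsewhere −(1−t)^β p^α log(1−p), α = 2, β = 4,
normalised by the number of peaks; masked-L1 on both offset fields
(empty masks define a zero loss with a warning).  The total is the
weighted sum with unit weights.  All loss gradients are hand-derived and
finite-difference-tested.

Backbones: `small` (stride-4 conv stack), `deep` (adds a stride-8 stage,
upsampled back), and `fusion` — a shared stride-4 stem feeding a detail
branch (sharp localisation) concatenated with a stride-8 context branch
upsampled back to stride 4.  The context branch exists because the
vertebral center offset must *see* the centroid it points to: a pure
stride-4 stack's receptive field (~±14 px) is smaller than half a
vertebra width, which measurably degrades center estimates, while a pure
stride-8 stack blurs peak localisation.  No pretrained weights exist for
these numpy architectures, so the `pretrained` argument accepts a
checkpoint path rather than downloading published weights.

## Decoding and grouping (`cobbkit.decode_group`)

Peaks: per channel, cells equal to their local maximum within the NMS
radius (default 1 cell) survive; tied plateau cells (a by-product of
nearest-neighbour upsampling) are deduplicated sequentially in
score-then-raster order; the top k (default 24 ≥ 17) above a minimum
score (0.05) become candidates.  Candidate position =
(cell + center offset) × stride; estimated centroid = position +
vertebral center offset × stride.

Grouping is greedy agglomeration: candidates by descending score (raster
order on ties) join the nearest existing group whose centroid is within
the distance threshold and whose corner slot is free, else seed a new
group.  Groups with <3 members are discarded, the 17 best by mean member
score are kept and ordered cranio-caudally; fewer than 17 raises a
structured error carrying the recovered count.  The default threshold is
0.5× the median inter-vertebra spacing, estimated from the vertical
pitch of the top-17 candidate *positions* per corner type — positions
are an order of magnitude more precise than the regressed centroids, so
this estimate stays stable when the offsets are noisy.  A greedy-vs-
exhaustive-partition oracle validates the grouping on ≤4-vertebra toys.

Vertebrae detected with exactly three corners are completed by the
parallelogram rule with diagonal adjacency UL↔LR / UR↔LL (e.g. UL = UR +
LL − LR); completion is exact on parallelograms and flagged per corner.
The completed 17 groups become a T1…L5 landmark set, mapped back to the
original frame through the recorded crop transform.

## Cobb-angle extraction (`cobbkit.cobb`)

Inclination: the angle of the vector joining the midpoints of the left
(UL, LL) and right (UR, LR) edges.  This midline construction is
symmetric in the two endplates and equals the endplate angle on
parallelograms; an `edge-mean` alternative (mean of top and bottom edge
angles) is available and coincides on parallelograms.

End-vertebra search on the 17-value profile: strict interior local
extrema; then, while any adjacent extremum pair differs by less than 5°,
the pair with the smallest difference is removed (both members) —
smallest-first makes the iteration order-independent; a same-type
adjacency safety net keeps the more extreme member (reachable only
through exact ties).  T1 and L5 are appended if absent.  Consecutive
end vertebrae bound curves; curves under 5° are dropped.  A variant that
removes only the less extreme member of a close pair is available
(`pair_removal=False`); pair removal is the default, as the more literal
reading.

Region: a curve is thoracic if its apex — the interior vertebra with the
largest deviation from the linear inclination chord between the end
vertebrae, ties resolved toward the midpoint then cranially — lies at
T11 or above, lumbar otherwise (the standard clinical apex convention).
The two largest thoracic and the single largest lumbar curve are kept
and labelled major / minor1 / minor2 by descending angle, ties broken by
the more cranial upper end.

Global rotations, translations and uniform scalings of the landmarks
change every inclination by a constant (or not at all) and therefore no
Cobb angle; this invariance is tested to 1e-6° and a brute-force
adjacent-extrema enumerator reproduces the extraction exactly on random
profiles.

For supine side-bending studies only curves bending in the direction the
side-bend corrects are reported: curves whose inclination falls from the
upper to the lower end vertebra match a bend toward +x (sign convention
recorded in the phantom metadata).

## Reliability statistics (`cobbkit.reliability`)

Single-measures ICCs from the two-way subjects × raters ANOVA:
ICC(2,1) = (MSR − MSE)/(MSR + (k−1)MSE + k(MSC − MSE)/n) (random
effects, absolute agreement) and ICC(3,1) = (MSR − MSE)/(MSR + (k−1)MSE)
(mixed, consistency), with the Shrout–Fleiss F-based 95% intervals
(Satterthwaite degrees of freedom for the (2,1) case) and the grade
bands <0.70 / 0.70–0.79 / 0.80–0.89 / 0.90–0.99.  Zero between-subject
variance is an error (the ICC is undefined), zero residual variance
collapses the CI to {1}.  The implementation is validated to 1e-10
against an explicit sums-of-squares oracle and cross-checked against
`pingouin`.  AI-versus-panel evaluation matches curves by rank label
(major↔major, …); subjects missing a rank on either side are excluded
from that rank's tables and counted in the report.  Angle-band error
rows use t-based 95% intervals on AI − (rater mean) within [0°, 20°),
[20°, 40°), [40°, ∞).

Intraobserver (test–retest) analysis is the same `icc` operation applied
to a two-column matrix.

## Desk-scale study profile

Everything trains from scratch on one CPU core, so the shipped profile
(`pipeline.desk_scale_configs`) scales the problem down: 100 phantoms at
512×256 (78/9/13 split), ROI net at 64×64 input for 100 epochs (lr 1e-3,
decay 0.98), keypoint `fusion` net at a 384×128 crop for 40 epochs
(lr 2e-3, decay 0.99).  The tall 3:1 crop preserves the ~21 px vertebral
pitch that center-proximity grouping needs; at a 2:1 crop the pitch
compresses to ~12 px and grouping becomes noise-limited.  The raised
learning rates compensate for the small networks and short schedules;
the full-scale defaults remain 1.25e-4 / 0.96 / 30 and 50 epochs.
The end-to-end check trains both stages, runs inference with the
*predicted* ROI on held-out phantoms and asks for a mean absolute
major-curve error under 5° — an internal bar for the synthetic test bed,
not a clinical claim.

## Known limitations

* The phantom's appearance model is simple; nothing here estimates
  performance on clinical images, instrumented spines, or anatomy with
  more or fewer than 17 visible vertebrae.
* Grouping can still fragment when vertebral-center-offset noise
  approaches half the vertebral pitch; the pipeline then reports a
  structured per-image failure rather than a partial spine (callers may
  opt into partial results).
* The thoracic/lumbar membership rule (apex at T11 or above) is a
  convention; other clinics draw the line at T12 or use disc levels.
* ICC confidence intervals assume balanced, complete rating matrices;
  listwise deletion is applied upstream.
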