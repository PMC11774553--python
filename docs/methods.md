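# Methods

## Problem and approach

Given a binary image classifier (for instance a cardiac-MRI hypertension
model), we want to know *which morphological structures* drive its
predictions, in terms a domain expert recognises — "the LV myocardium", not
"pixels 4031–4097". The approach is perturbation-based counterfactual
generation at the granularity of labeled segments: take a *target* image the
model has classified, replace one or more of its segments with the
corresponding segments from a *source* image of the opposite predicted
class, re-classify, and attribute any label flip to the replaced segments.
A recombined image is a *counterfactual* iff its predicted label differs
from the target's **predicted** label (never the ground truth: the object of
study is the model, not the disease).

The quality criteria for such perturbations are sparsity (change as little
as possible), plausibility (the result should look like a real image of the
domain), and meaningfulness (the changed unit should be a nameable
morphological feature). Replacing whole segments between real images of the
same anatomy satisfies the last two by construction; the operator below is
engineered so the first holds exactly.

## The segment-replacement operator

Inputs: target and source instances — `(frames, height, width)` pixel
arrays with per-pixel integer label masks — and a non-empty subset of
segment codes. Per frame:

1. **Alignment.** One rigid integer translation per frame,
   `offset = round(centroid(target subset) − centroid(source subset))`,
   computed from the *joint* centroid of the union of the selected
   segments. A single translation (rather than one per segment) preserves
   the relative geometry of interdependent structures — a myocardium ring
   and the cavity it bounds move together. Rounding is half-away-from-zero;
   there is no sub-pixel interpolation, so the provenance of every output
   pixel is exact.
2. **Removal.** All target pixels whose label is in the subset form the
   *hole*.
3. **Transfer.** The source's subset region is traversed by 4-connected
   flood fill, seeded once per selected segment at the segment pixel nearest
   that segment's real-valued centroid (ties broken by row-major order);
   seeding every segment guarantees disconnected structures are all
   traversed. Each visited source pixel is copied to its translated target
   coordinate; coordinates falling outside the frame are discarded and
   counted (`n_clipped`).
4. **Hole fill.** Hole pixels the translated source segment did not cover
   are filled with the source pixel at the same translated coordinate
   (source context), so the output never contains holes; when that
   coordinate is outside the frame it is clamped to the border (edge
   extension, counted as `n_context_clamped`) so no ghost remnant of the
   removed segment survives. The fraction of uncovered hole pixels is
   reported as `hole_fraction` — a proxy for geometric mismatch between
   target and source (e.g. pasting a thin ring into a thick ring's hole)
   that callers can use to filter implausible recombinations.

Translated source pixels overwrite whatever they land on, including pixels
of non-selected segments: structural interdependence artifacts are
deliberately surfaced, not hidden. Videos are processed frame-by-frame
(frame *i* maps to frame *i*) with an independent offset per frame; frames
where the subset is absent from either mask are copied unchanged and
flagged. The operator also produces the *expected mask* of the recombined
image (target labels outside the transfer, translated source labels inside),
which is what a re-segmentation is scored against.

**Guarantees.** (i) Sparsity: pixels outside hole ∪ translated-region are
bit-identical to the target. (ii) Identity: recombining an image with
itself reproduces it exactly. (iii) Determinism: the operator is a pure
function. (iv) Alignment: the offset brings the continuous source-subset
centroid within 0.5 px per axis of the target's; for transfers that do not
clip at the frame border, the pasted subset's centroid lands within 1 px per
axis (0.5 px rounding + raster effects). Clipping discards pasted mass and
can shift the centroid further — such recombinations carry `n_clipped > 0`
in provenance and should be filtered when alignment matters.

## The experiment engine

`run_experiment` predicts a label for every cohort member, partitions the
cohort by predicted label, and recombines every cross-class (target, source)
pair over every segment subset in both role assignments — k segments give
2ᵏ − 1 subsets, enumerated size-ascending then by segment order, so a
21/79 split over 3 segments yields 21·79·7·2 = 23 226 recombinations.
Recombined images are classified in batches (default 16; a memory knob with
no semantic effect) and pixel arrays are dropped from records after
classification, so only provenance and flags stay in memory. The per-subset
summary reports counterfactual/unchanged counts and their ratio rounded
half-up to 3 decimals. `generate_recombinations(materialize=False)` streams
provenance only, which enumerates the full combinatorics in milliseconds.

The classifier is consumed through a minimal contract — `predict(batch) →
0/1 per item`, deterministic, optionally `predict_score` in [0, 1] with the
0.5 convention — so any model, including sklearn estimators behind a thin
adapter, plugs in without engine changes.

## Synthetic phantoms and the reference task

Real cardiac cohorts and trained models are access-restricted, so the
package ships a first-class synthetic stand-in that preserves the
*structure* of the real experiment. A phantom is a short-axis-like frame:
LV cavity disk (code 1, intensity 0.5), myocardium annulus (code 2, 0.9)
whose thickness is the discriminating feature, RV disk (code 3, 0.5) beside
it, background 0.1, plus Gaussian noise (default σ = 0.03; intensity bands
are separated by 0.4, ≈13 σ, so band membership is essentially exact).
Defaults: 128×128 frames, LV center (64, 64), cavity radius 20 px, RV
radius 12 px at column offset −44. The two cohort classes draw wall
thickness from N(3, 0.5) ("thin", label 0) and N(7, 0.5) ("thick", label 1),
truncated positive — separated by 8 standard deviations so the reference
task is near-noiseless by construction. Demographics (age, sex, BMI) are
generated per phantom for cohort-filter exercises; the LV center is fixed
across the cohort by default (a jitter option exercises the large-offset
and border-clipping paths).

The **reference classifier** reads only pixels: it counts intensities ≥ 0.7
(the myocardium band) inside a 61×61 window centred on the LV, and predicts
1 when the count exceeds the annulus area at the midpoint thickness,
π((r+5)² − r²) ≈ 707 px — an analytic threshold, nothing is fit. The
window covers the annulus for any plausible thickness yet geometrically
excludes the RV, and the blood-pool band is excluded by intensity, so the
classifier *provably* ignores both cavities. That pins down ground-truth
attribution: subsets without the myocardium can never flip a prediction,
and myocardium transfer between classes always does — the structure the
counterfactual engine must recover, and does, exactly (proportion 0.0
vs 1.0 in the summary table).

The **threshold segmenter** (the stand-in for a learned segmentation model
used in self-validation) classifies pixels into the three intensity bands,
removes components smaller than 8 px, and disambiguates the two blood pools
by assigning the cavity component nearest the myocardium ring's centroid to
the LV. On noise-free phantoms it reproduces the generating mask exactly;
re-segmenting recombined phantoms recovers the expected mask with Dice
≥ 0.90 per segment.

What the phantoms do *not* emulate: anatomical shape variability,
through-plane motion, MRI intensity inhomogeneity and partial-volume
effects, or correlated signal across demographics. Passing tests therefore
demonstrate the *mechanics* of recombination, attribution and bookkeeping —
not that a real model's counterfactual proportions would be stable under
acquisition artifacts.

## Numerical and design choices

- Background (code 0) is never replaceable; segment codes are any positive
  integers, not necessarily contiguous.
- Summary proportions use decimal half-up rounding to 3 places (banker's
  rounding would print 0.156 for 520/3318).
- Demographic range filters are inclusive on both ends; rows with missing
  values fail every filter on that variable; categorical variables filter by
  value-set membership. The final filtered id set is order-independent;
  intermediate icicle sizes are order-dependent by design.
- Histograms default to 20 equal-width bins over [min, max]; display paging
  defaults to 50 items.
- On-disk formats: NIfTI / NPY / NPZ / PNG / TIFF for arrays (axis order is
  declared, never guessed; canonical layout is `(frames, height, width)`),
  CSV for tables, YAML for segment maps and run configs, and a JSON manifest
  (config + seed + versions) in every output directory.
- Problem sizes in the shipped checks: 10+10-phantom cohorts (1 400
  recombinations per experiment), 100-pair sparsity sweeps, 20-pair
  re-segmentation sweeps at 128×128 — each runs in seconds while exercising
  every code path at the same combinatorial structure as a full-scale run.

## Known limitations

- Rigid translation only: no rotation, scaling or non-rigid registration,
  and no intensity harmonisation between source and target — recombinations
  across very different geometries are flagged via `hole_fraction` rather
  than corrected.
- The joint alignment of disconnected subsets (myocardium + RV) trades
  per-segment alignment for preserved relative geometry; with structures
  near the frame border this can clip part of the paste (reported, see
  above).
- Binary classification only; multi-class attribution and generative
  in-painting of removed segments are out of scope.
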