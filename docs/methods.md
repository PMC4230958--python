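# Methods

## Pixel encoding

The encoder describes every pixel by the texture of its neighborhood
rather than its intensity, which is what makes phase-contrast images of
transparent cells tractable.

**Filter bank.**  Six derivative-of-Gaussian responses per scale
(orders (0,0) … (0,2)) are computed separably with sampled 1-D kernels
and multiplied by σ^(i+j) (scale normalization), so that responses — and
hence the classifier scores built from them — are commensurate across
scales.  The sampled derivative kernels are moment-corrected: the
order-1 kernel reproduces the slope of a linear ramp exactly and the
order-2 kernel annihilates constants and ramps and reproduces the
curvature of x² exactly.  Uncorrected sampled kernels leak a small
sigma-dependent bias (worst below σ = 1, i.e. at the finest scale of the
default ladder).  All filtering uses mirror padding (reflection about
the edge pixel); the same rule pads histogram windows, so border pixels
see a constant window denominator.  The test suite pins the separable
implementation to a brute-force 2-D convolution oracle at 1e-8.

**Seven-class alphabet.**  With λ = s20+s02 and
γ = sqrt((s20−s02)² + 4·s11²), the class scores are
ε·s00 (flat), 2·√(s10²+s01²) (gradient), ±λ (dark/light blob),
(γ±λ)/√2 (dark/light line), γ (saddle); the label is the argmax, ties
resolved toward the lowest index (flat first), which fixes the all-zero
degenerate case.  ε (default 0.1, exposed in `EncoderConfig`) sets how
much texture a region needs before it stops being "flat"; every test
that depends on it states it explicitly.  The printed scale ladder
(0.7, 1.4, 2.8, 5.6) is interpreted as Gaussian σ in pixels — a standard
dimensionless doubling ladder.  Intensities are normalized to [0, 1] by
dtype range, not per-image min/max, so ε keeps one meaning across a
time-lapse.

**Local histograms.**  Dense (stride-1) 25 × 25 window counts of the
seven labels, computed exactly with per-class integral images, O(1) per
pixel instead of O(window²); normalized to frequencies by default so
border and interior windows are comparable.  Concatenation over the four
scales gives the 28-element per-pixel feature vector.

## Classifier

A scikit-learn random forest stands behind the training/prediction
surface: 50 trees (well above the 20-tree floor that makes majority
voting stable), bootstrap sampling, √d features per split, trees grown
to leaf purity.  Because pure leaves emit one-hot distributions, the
averaged predict-proba equals the hard-vote fraction; the cell class is
predicted only above 0.5, so an exact 50/50 tie goes to background —
the conservative direction for confluency.  Training rows come only
from annotated pixels; each class is capped at 10,000 rows by a seeded
uniform subsample so dense annotations cannot blow up the table.  The
archive written by `SegmenterResults.save` embeds the ensemble together
with the encoder and histogram configs and the seed, and segmentation
refuses to run when the configs a model was trained under differ from
the requested ones.

## Quantification

Confluency is the 1-pixel fraction of a mask.  Whole-area confluency
crops overlapping tile margins — the overlap split evenly between the
two neighbors — so each physical pixel is counted once.  Colonies are
8-connected components (blob-like objects).  Tracking associates two
frames greedily by descending pixel overlap, ties broken toward the
smaller object id: shared primary successors give merges, shared
predecessors splits, mutual 1:1 matches moves (centroid displacement),
and the leftovers disappear (wash-out candidates) or appear.  The event
set partitions both frames' objects — each object participates exactly
once.  Replicate series are summarized by mean and sample (n−1)
standard deviation, the small-n convention for a handful of independent
trials.

## Synthetic scenes

The generator emulates what the classifier keys on, not the optics:
colony interiors carry fine-grained high-contrast texture
(grain 1.2 px, sd 0.16) and sit ~0.10 below a smooth low-contrast
background (grain 3 px, sd 0.05); a bright halo rim (3 px, gain 0.2,
fading outward) surrounds each colony; a low-order illumination bias
(6% amplitude) varies across the field.  Colony footprints are
noise-perturbed disks reduced to the connected component containing
their center (a colony is one object); a single global radius scale is
bisected so the achieved colony fraction lands within ±0.02 of the
target over targets in [0.05, 0.6].  Halo pixels are ground-truth
*background* — halos surround, not occupy, colony area — which makes
confluency semantics unambiguous.  Artifacts (anti-aliased dark
scratches, dark dust disks) are rendered off colony pixels and recorded
in a separate mask that stays disjoint from the colony truth.

Time-lapses grow colony areas logistically toward a capacity fraction,
translate them by per-colony velocities plus seeded jitter (each
colony's shape-noise field travels with it, so shapes deform smoothly
rather than churning), support scripted wash-outs (colony removed from a
given frame), and let converging colonies merge into one truth
component.  `scripted_event_timelapse` freezes one scenario — two
colonies on a collision course plus one wash-out at frames (3, 4) —
that produces exactly one merge and one disappearance on the truth
masks across a wide seed range.

What the generator does *not* emulate: real point-spread physics, shot
noise, focus drift, mitotic texture changes, confluent-sheet merging of
textures, or feeder-layer cells as a distinct third texture.  Passing
tests therefore demonstrate that the pipeline recovers segmentations
when the texture assumption holds cleanly; they do not bound accuracy
on real micrographs, where annotation quality and texture overlap
dominate.

The defaults are deliberately well-separated: the generator's contract
includes that its default contrast supports ≥95% held-out pixel accuracy
from ≤10% annotations, and the contrast knob is verified to degrade
accuracy monotonically as textures fade (with a saturation plateau at
high contrast where the forest is already ceiling-limited).

## Numerical and design choices

- Problem sizes: 256 × 256 scenes, 10-frame time-lapses, three seeds per
  stochastic check, and 128 × 128 × 3-frame scenes for the end-to-end
  determinism run — large enough for stable statistics at interactive
  run times.
- Event detection on predicted masks uses `min_object_px = 100` to
  suppress speckle objects near colony boundaries before tracking.
- `whole_area_confluency` aborts on missing tiles by default (partial
  scans bias the whole-area number); `allow_partial=True` overrides
  with the present tiles only.
- Grayscale conversion uses fixed BT.601 luminance weights
  (0.2989/0.5870/0.1140), the convention of the common `rgb2gray`
  implementations; conversion is not a per-image stretch.
- Annotation masks use the palette 0 = unspecified, 1 = negative,
  2 = positive in indexed PNGs.

## Known limitations

- Two classes only (cell vs everything else); multi-class co-culture
  discrimination would need a third annotation label and a multiclass
  forest head.
- Greedy overlap tracking assumes colonies move slowly relative to the
  frame interval; fast objects or dense fields would need optimal
  assignment and motion models.
- The boundary band of a colony (roughly the histogram window half-width)
  carries mixed features; residual errors concentrate there, which is
  why held-out accuracy saturates near 97% rather than 100% on synthetic
  scenes.
- No illumination flattening or halo correction is applied before
  encoding; the classifier is expected to absorb these, which holds for
  the emulated bias amplitudes but is untested beyond them.
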