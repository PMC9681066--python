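# Methods

## Return-fixation annotation

A fixation *i* is labeled a **return fixation** when its Euclidean
distance to at least one earlier fixation in the same trial is at most a
threshold (default 1.0 dva, the approximate resolution of research-grade
eye trackers; 1.5 dva for egocentric video, where residual head motion
blurs frame-to-frame alignment). The matched earlier fixation is labeled
**to-be-revisited** unless it is itself a return; all remaining fixations
are **non-return**. The three labels partition the sequence, with
"return" taking precedence for fixations that are both revisits and later
revisited.

When a return lies within threshold of several earlier fixations, it is
paired with the **most recent** qualifying one. This matches the worked
example the annotation is validated against (a sequence in which fixation
7 pairs with fixation 5 rather than the spatially comparable fixation 3)
and reflects the behavioral observation that revisits typically follow
the shortest possible offset. Pairing with the spatially nearest
qualifying fixation is available as an option (`pairing="nearest"`); for
the derived statistics reported here (offset histograms, proportions) the
choice only matters in the rare multi-candidate case.

Consecutive refixations (offset 0) satisfy the distance rule and are
counted as returns. Upstream fixation-extraction pipelines normally merge
consecutive samples at one location into a single fixation, so offset-0
events are rare in practice; they are deliberately not dropped here, and
the event list makes them identifiable.

Derived descriptors: the **return offset** is the number of intervening
fixations (`return_index − source_index − 1`); **turning angles** measure
the angle between incoming and outgoing saccade directions at each
interior fixation (0° = continue straight, 180° = full reversal), with
zero-length saccades yielding an undefined (NaN) angle that is excluded
from histograms and counted in the log; **saccade sizes** are tagged with
the category of the landing fixation.

## Egocentric preprocessing

Egocentric clips are screened by a head-motion score: the pixel-level
Euclidean distance between the first and last frame of a clip (intensities
in [0, 1]), divided by the pixel count; clips above 0.4 are discarded.
Gaze traces with more than 14 consecutive missing frames (about three
fixations at 24 fps) are rejected; shorter interior gaps are linearly
interpolated, and leading/trailing gaps are padded with the nearest valid
sample — interpolation across the clip boundary would have to invent
velocities, padding only repeats an observed position.

## Population statistics

**Between-subject consistency.** Return locations from all subjects on one
image are mapped to a 32 × 40 grid; each cell receives the proportion of
subjects with at least one return there. The table is Gaussian-blurred
(default σ = 1 cell, kernel truncated at 4σ) to soften sparsity, floored
at 10⁻¹⁰ to avoid log singularities, renormalized to sum to one (entropy
of an unnormalized table is ill-defined), and summarized by
H = −Σ p log p in nats (the log base is configurable). The chance level
redistributes the same number of returns uniformly, 100 times, through
the identical blur/floor/normalize treatment — blurring only the observed
histogram would bias the comparison.

**Spatial divergence.** Return and non-return locations are histogrammed
at 1-dva resolution, smoothed with an additive 10⁻¹⁰ per cell (matching
the entropy floor), normalized, and compared as KLD(return ∥ non-return).

**Saliency sampling.** The mean map value over a 1-dva square patch
centered at each fixation, averaged within category. Patches are clipped
at map borders; the mean runs over pixels whose centers fall inside the
square, so even pixel spans remain centered on the continuous coordinate.
Fixations whose patch misses the map entirely are excluded with a warning.

**Similarity index.** SI = 1 − (S − M)/(S + M) for subject value S and
model value M, both non-negative: 1 at exact agreement, 0 when the model
value is zero, bounded in [0, 2], and SI(S, M) + SI(M, S) = 2.

**Bootstrap.** Per-trial proportions are resampled with replacement
(default 1000 resamples) for percentile confidence intervals and a
two-sided exceedance p-value against a supplied chance level, floored at
1/resamples.

## The generative model

At each step the model combines four maps on a common lattice — the
spatial resolution of the backend's feature stack (image size / 4 for the
shipped backend) — each min–max normalized to [0, 1]; a constant map
normalizes to all zeros, so an uninformative component drops out rather
than adding a constant offset. Static maps (similarity, saliency) are
normalized once per trial; the saccade and memory maps are rebuilt and
normalized at every step. The next fixation is the lattice argmax, with
ties broken at the lowest row-major index for determinism.

Parameters (all defaults in `ModelConfig`):

| parameter | default | meaning |
|---|---|---|
| `w_sim`, `w_sal` | task switch (1/0 in search, 0/1 in free viewing) | which static map drives the trial |
| `w_mem` | −0.93 | inhibition strength of remembered locations |
| `w_sac` | 0.2346 | weight of the saccade-size prior |
| `alpha` | 0.92 | per-fixation geometric memory decay |
| `beta` | 0.5 | memory floor: inhibition never decays away entirely |
| `sigma` | 0.02 (0.08 for sparse object arrays) | memory Gaussian width, as a **fraction of image width** |
| `recognition_threshold` | 0.3 natural images; 0.5 arrays/cluttered | cosine-distance stop criterion |
| `n_fixations_free` | required per dataset | free-viewing budget (mean human/monkey fixation count) |
| `max_fixations` | 80 | search cap, a proxy for a 20-s behavioral timeout |

`sigma` is interpreted in normalized image units because values of
0.02–0.08 dva would be sub-pixel at ordinary display resolutions; the
width is converted to dva via the image width at map construction and is
configurable.

The saccade prior converts a 1-D amplitude histogram into a radially
symmetric 2-D map: each lattice cell takes the linearly interpolated
histogram mass at its radial distance from the current fixation.
Interpolation runs between bin centers, extends constant across the two
outer half-bins, and is zero outside the histogram support, so a
single-bin (point-mass) histogram yields an annulus.

The memory map is the pointwise **maximum** over per-fixation Gaussian
bumps with decayed amplitudes — maximum rather than sum, so revisiting a
location overwrites its decayed trace at full strength instead of
stacking.

Recognition (search only) crops a 1-dva patch at the fixation
(zero-padded at image borders), embeds it, and stops the trial when
1 − cosine similarity to the target embedding falls below threshold.
"Cosine similarity distance" is implemented as 1 − cos; thresholding the
raw similarity instead is available as a switch. A degenerate all-zero
embedding is treated as not-found, with a warning. A precomputed
recognition map over the lattice (optionally strided) is provided for
inspection; the trial loop evaluates lazily at fixated locations only,
which is cheaper for the fixation counts involved.

Trials start at the image center (behavioral trials begin on a central
cross), snapped to the nearest lattice cell; a different start is
configurable, and the null model defaults to a uniform random start
because it models no task structure.

## Null model and ablations

The null model is memoryless and image-blind: from a uniform start, each
next fixation displaces the current one by a sampled amplitude (uniform
within its histogram bin) in a uniform random direction. Off-extent
draws are rejected and resampled (cap 1000 retries) so the amplitude law
is preserved within bounds; 25,000 sequences of the dataset's mean trial
length give a stable chance proportion.

Ablations: removing the similarity map (search) or the saliency map (free
viewing) leaves an image-agnostic attention map, so the argmax would
produce one identical scanpath for every image; these two variants
therefore sample the next fixation from the attention map treated as a
probability mass (shifted to minimum zero and normalized — the map can be
negative through `w_mem`). Removing the saccade prior (`w_sac = 0`) and
the defective-memory variant (`w_mem` drawn uniformly from [−1, 0]) keep
the argmax. The defective-memory draw is made **once per trial**, for
reproducibility and because a per-step redraw would conflate weight noise
with the memory mechanism under test. A second diagnostic variant — the
full model with `w_mem = 0` — oscillates between the two strongest peaks
of the static map and is provided for inspection, not used as a chance
level.

## Synthetic data

The generators emulate the study conditions rather than any particular
stimulus set. Scenes are grayscale, 20 × 16 dva at 8 px/dva (so the
feature lattice lands on 32 × 40 cells, matching the consistency grid):
`object_array` scenes place isolated high-contrast shapes on a uniform
background at jittered grid positions, with a unique-shaped,
slightly-larger target among smaller distractors (a discriminable search
item); `naturalistic` scenes plant contrast blobs of graded strength on
1/f noise, giving the scene a saliency ranking. Saccade amplitudes follow
a gamma law (shape 2, scale 2: mean 4 dva, mode 2 dva), reflecting the
small-saccade bias of primate eye movements, histogrammed at 0.5-dva bins.

Scanpath generation with planted returns keeps all base fixations at
least 2.5 thresholds apart and places each planted return at half the
threshold from its source, so the ground-truth labels coincide *exactly*
with distance-rule annotation — no incidental returns are geometrically
possible. This makes the generator a labeled oracle for the annotation,
at the cost of an unrealistically regular minimum inter-fixation spacing.

The shipped feature backend is a two-stage random convolutional stack
(zero-mean 5×5 and 3×3 filters, half-wave rectification, 2×2 average
pooling per stage) with channel-wise mean+max pooling as the embedding.
It is deterministic, translation covariant up to the 4-px pooling grain,
and shape-selective enough for the matched-filter property; average
pooling is used because max pooling makes feature signatures phase-
sensitive to sub-grid shifts, which breaks template matching between a
cropped target and its in-scene copy. What the synthetic stack does
**not** emulate: semantic selectivity, eccentricity-dependent acuity, the
feature hierarchies of pre-trained networks, photometric realism, or
motion. Passing tests on synthetic data therefore validate the
*mechanisms* (annotation correctness, map arithmetic, orderings between
model variants) — not quantitative agreement with primate data, which
requires real stimuli, real scanpaths, and a pre-trained backend via the
`FeatureBackend` protocol.

## Problem sizes and numerical choices

The shipped simulations use 20 scenes × 15 fixations for free-viewing
comparisons (with 10 defective-memory draws per scene), 25,000 null
sequences for chance levels, and 1000 random scanpaths for the
annotation-oracle equivalence check; these sizes give stable orderings
and run comfortably on a single CPU. Probability floors are 10⁻¹⁰
throughout; entropy and divergence use natural logarithms; all
randomness flows through `numpy.random.default_rng` seeds, and every
simulation entry point is bit-reproducible given its seed.

## Known limitations

- The model has no notion of fixation duration, motion processing, or
  learning; durations emitted with model scanpaths are nominal
  placeholders to satisfy the data-model invariants.
- Winner-take-all on a coarse lattice quantizes fixation positions to
  cell centers; sub-cell spatial statistics are not meaningful.
- Raw (unnormalized) feature cross-correlation is energy-biased; the
  matched-filter property holds for displays with a discriminable target
  but can mis-localize among high-energy clutter.
- The on-target flag, click records, and egocentric frames are accepted
  as given; no target detection, mouse-trace analysis, or video decoding
  is performed.
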