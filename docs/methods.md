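# Methods

This note records the modelling choices, defaults, numerical
conventions and known limitations of `daunet`, at the level of detail a
maintainer needs to modify the package safely.

## Scope and problem sizes

The package targets desk-scale, CPU-only experimentation.  All shipped
tests and the acceptance script run on synthetic phantoms: the overfit
study uses one 64×64×16 voxel phantom and a 4-channel-base network
(~0.4 M parameters, ~0.5 s per training step on one core); the ablation
ladder uses five 32×32×16 phantoms, 150 epochs per variant.  These
sizes were chosen so a full verification pass of every component
finishes in minutes while still exercising all four resolution levels
of the architecture.  Nothing in the code limits larger runs — the
patch/stride machinery, the CRF's approximate mode, and the
preprocessing pipeline all accept clinical-CT-sized volumes — but
training at clinical scale on this numpy backend is not practical;
the backend exists for exactness and auditability, not throughput.

## Network

* **Layout.**  Encoder: 4 levels × 2 blocks; level widths double from
  `base_channels` (default 16): 16, 32, 64, 128.  Down-sampling is a
  stride-2 2×2×2 convolution; the last one also doubles width, so the
  bridge operates at 256 channels and 1/16 resolution (a 16-deep patch
  is 1 voxel deep there).  The decoder has three up-sampling stages
  (trilinear ×2 + 3×3×3 convolution + skip concatenation + plain double
  convolution block) and stops at 1/2 resolution; each output head is a
  point convolution, a trilinear upsample to the full patch grid, and a
  sigmoid.  Channel widths are a free design axis for this architecture
  family; the doubling scheme above is this package's convention, so
  absolute parameter counts are configuration-specific.
* **Where the channel doubling lives.**  Levels double width in their
  first block, which gives every residual first-block a 1×1×1
  projection shortcut.  This makes the ablation ladder structurally
  monotone: +Res adds exactly the projection parameters, +AI adds the
  bridge (without AI the encoder output feeds the decoder directly),
  +DS adds the three auxiliary heads.
* **Deep-supervision taps.**  The three auxiliary heads read the bridge
  output and the first two decoder stages; the main head reads the last
  stage.  This yields exactly four output modules and guarantees a
  direct gradient path into the earliest decoder parameters.
* **Normalization.**  Instance normalization by default (training runs
  at batch size 1, where batch-norm statistics are degenerate);
  `norm: none` disables it.  PReLU slopes are per-channel, initialized
  at 0.25; convolution weights use He initialization from a seeded
  generator, so builds are bit-reproducible.
* **Resizing convention.**  All trilinear resizes (decoder upsampling,
  output heads, in-plane resizing, probability upsampling to the native
  grid) use the half-pixel mapping `src = (i + 0.5)·n_in/n_out − 0.5`
  with edge clamping.  Same-size resizing is the identity, and integer
  upsampling factors use position-independent weights, which keeps the
  trunk exactly shift-covariant for shifts that are multiples of the
  total stride (verified to 0 in the tests).

## Loss and schedules

* Tversky defaults α = 0.4, β = 0.6 (α + β = 1 enforced to 1e-9).
  `squared_penalties=True` is the default and squares the per-voxel FP
  and FN terms in the denominator; the conventional linear form is a
  flag.  The two coincide on binary predictions; the Dice-loss
  equivalence at α = β = 0.5 on soft predictions holds only for the
  linear form, and the tests assert both facts.
* Smoothing constant 1e-6 added to numerator and denominator keeps the
  loss defined on empty-organ patches, which occur routinely in
  z-tiling.
* Deep-supervision coefficient: α_ds(epoch) = α0 · 0.8^⌊epoch/40⌋,
  with α0 = 1.0 (the initial value is not prescribed anywhere;
  1.0 makes the auxiliary losses initially equal partners and is
  configurable).  Learning rate: 1e-3 × 0.1^(milestones ≤ epoch),
  milestones (350, 650).  Both schedules are pure functions of the
  epoch, so resumed runs cannot drift.
* "Epochs" is the schedule axis; one epoch visits every z-tile of every
  training case once, in a fixed order (no random cropping), so a run
  is a pure function of the seed.

## Preprocessing

Fixed order: HU clamp to [−200, 200] → z-resample to 1.0 mm (linear for
images, nearest for masks) → organ-span crop with a ±20-slice margin
(training only; at inference there is no ground truth, so no crop) →
in-plane resize to 256×256 (linear/nearest) → min–max normalization to
[0, 1] → z-tiling into 16-deep patches, last patch right-aligned.
Masks stay binary through every stage by construction; every geometric
operation updates the stored voxel spacing, so surface metrics always
work in true millimetres.  Predictions are reassembled by averaging
overlapping tile probabilities, trilinearly upsampled to the native
grid, and thresholded strictly (probability > 0.5 → organ), so an
exactly-0.5 probability (e.g. an all-zero-logit network) maps to
background.  Linear interpolation for images and nearest-neighbour for
masks is this package's convention.

## Phantoms

Each phantom is a pure function of its spec (including the seed):

* organ = one primary ellipsoid plus 0–3 jittered child lobes (45 % of
  the primary radii, offset 40 %), so boundaries are non-convex;
* an adjacent ellipsoidal organ whose mean intensity defaults to 95 HU
  against the organ's 100 HU — the low-contrast neighbour case; with
  texture and noise disabled and equal means the two are exactly
  indistinguishable by intensity;
* optional boundary lesion (labelled organ) and background-intensity
  vessels inside the organ (labelled organ, intensity holes);
* Gaussian texture per structure plus additive Gaussian acquisition
  noise (default 10 HU), anisotropic spacing supported.

Not modelled: partial-volume effects, CT reconstruction physics,
anatomically realistic shapes, tumour texture.  Consequently, passing
tests demonstrate correctness and the qualitative behaviour of the
pipeline (overfit capacity, CRF repair, metric exactness) — not
clinical segmentation accuracy.

## Dense CRF

Pairwise kernel `w_app·exp(−|Δp|²/2θ²_app − ΔI²/2θ²_int) +
w_smooth·exp(−|Δp|²/2θ²_smooth)` with Potts compatibility; mean-field
update Q′ ∝ exp(−unary − message), ties at equal label scores resolve
to background.  Intensities are the windowed, [0,1]-normalized values;
positions are in voxel units by default (`use_mm_positions` folds the
spacing in).  The defaults w_app = w_smooth = 1, θ_app = 10 vox,
θ_int = 0.1, θ_smooth = 3 vox, 5 iterations follow the dense-CRF
literature's order of magnitude and are all exposed in config.

* **Exact mode** materializes the N×N kernel (cap 20 000 voxels) with
  the spatial factors cached per grid shape; it is the oracle the tests
  compare against a literal double loop.
* **Approximate mode** evaluates the smoothness message with separable
  truncated-Gaussian convolutions and the appearance message with a
  4-D bilateral grid (trilinear splat → unit-Gaussian blur → slice),
  sampled at half a bandwidth per bin.
* **Bandwidth scaling.**  θ values comparable to the ROI extent make
  the field globally coupled: mean-field saturates and the argmax
  becomes sensitive to arbitrarily small message perturbations, where
  no filter-based approximation can track the exact solver label for
  label.  Mode-agreement tests and small-ROI refinement therefore use
  bandwidths scaled to the ROI (θ_app = 3, θ_smooth = 1.5 for
  ≤ 32-voxel grids); with these, exact and approximate labels agree on
  all tested instances.  As a practical rule, keep θ_app at or below a
  third of the ROI's smallest side.

## Evaluation metrics

Surfaces are 6-connected boundary voxels (volume-border foreground
included); 26-connectivity is available as an option.  ASD is the plain
arithmetic mean of the pooled directed distances and RMSD the root of
the mean of their squares.  RVD is reported signed, with A the
segmentation and B the truth: (|B| − |A|)/|A|.  Both-empty Dice is
defined as 1.0 with a warning; empty masks make RVD/ASD/RMSD undefined
and raise.  Distances use the exact spacing-weighted Euclidean distance
transform and match an O(N²) brute-force search to 1e-9.

## Ablation ladder interpretation

At the shipped desk scale every variant trains to ≈ 0.99 train Dice, so
the ladder's test Dice values sit within seed noise of each other
(±0.005) rather than strictly increasing — capacity differences of this
architecture family only separate on hard, large-scale data.  The
shipped check is therefore qualitative: parameter counts must strictly
increase (structural), test Dice must be non-decreasing up to a 0.02
margin, and the full model with CRF must not fall below the raw
baseline.  CRF refinement improves every variant on held-out phantoms
at this scale; on a nearly memorized training case it can cost a few
tenths of a Dice point by rounding the boundary, which is expected
behaviour for a boundary-smoothing prior.

## Known limitations

* The numpy backend is single-threaded per operation and holds the
  whole computation graph of a patch in memory; clinical-scale training
  belongs on a GPU framework, which this package deliberately does not
  depend on.
* Resumed training is bit-compatible, but checkpoints store no RNG
  state — reproducibility relies on the loop itself being
  deterministic, which holds because sampling is sequential.
* Largest-connected-component filtering of final masks is available as
  an optional post-processing flag but defaults to off.
* Binary organ/background only; multi-class Tversky and tumour
  segmentation are out of scope.
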