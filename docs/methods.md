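# Methods

`druseg` segments contrast-enhanced vascular structures (the motivating case
is the pulmonary artery) in 3D CT with a dense-residual U-Net trained under a
hybrid Dice + binary-cross-entropy loss. This note documents the model, the
numerical choices, and exactly what the synthetic phantom experiments do and
do not demonstrate.

## Preprocessing

CT intensities are clipped to a fixed Hounsfield window `[-800, 500]` HU —
wide enough to span aerated lung (≈ −850 HU), soft tissue (≈ 40 HU) and
contrast-filled vessels (≈ 200–400 HU) while discarding scanner-dependent
extremes — and then mapped linearly onto `[0, 1]` using the clip bounds as
normalization constants. Using the fixed bounds (rather than per-volume
min/max) keeps the same tissue at the same normalized value across scanners.

Each scan is cut into a configurable number of in-plane patches (default 9 of
256×256) that span the full slice axis. Patch origins are drawn uniformly at
random over the valid offsets from a seeded, per-scan stream, which gives the
"varied centers" style of data multiplication; if the random draw leaves any
in-plane voxel uncovered, the last nine origins are replaced by a
deterministic 3×3 anchor grid at stride `(dim − patch_xy)/2` per axis. The
anchor fallback makes whole-volume reconstruction well defined: the grid
covers any volume whose in-plane extent is at most `3 × patch_xy`. Masks are
patched by the same integer origins with no interpolation.

## Architecture

The network is a four-level encoder–decoder. Feature extraction uses *dense
residual blocks*: four serial units, each a 3×3×3 convolution (stride 1) →
group normalization → leaky ReLU, where unit *i* consumes the channel
concatenation of the block input and all previous unit outputs (dense
connectivity, realized internally without materializing the concatenations).
A parallel 1×1×1 convolution transforms the block input's channels and is
added element-wise to the last unit's output (residual path). Dense
connectivity is scoped *within* a block; across blocks, information reuse
comes from the U-Net skip concatenations.

Downsampling is a learned *transition down* (2×2×2 stride-2 convolution →
group norm → leaky ReLU) that halves every spatial dimension and doubles the
channel count; upsampling is a *transition up* (2×2×2 stride-2 transposed
convolution, same norm/activation) doing the reverse. After each transition
up, the matching encoder output is concatenated before the decoder block.
The head is a 1×1×1 convolution plus sigmoid, yielding a voxelwise
foreground probability at input resolution. Valid inputs have every spatial
dimension a positive multiple of `2**levels`.

Choices the architecture leaves open, and what this package does:

- **Channel schedule** — the first encoder block maps the input channel to
  `base_width` (default 16; desk-scale runs use 8) and widths double per
  level, giving `base_width · 2**levels` bottleneck channels.
- **Group count** — 8 groups, reduced to the largest divisor of the channel
  count when 8 does not divide it. Leaky slope 0.01. Both recorded in
  `NetworkConfig`.
- **Transition operators** — strided (transposed) convolutions rather than
  pooling/upsampling: the smallest *learned* resamplers.
- **One 1×1×1 skip per block**, not per unit.
- **Initialization** — fan-in-scaled normal with the leaky-ReLU gain, seeded
  through `NetworkConfig.seed`.
- **Binarization threshold** 0.5, applied in post-processing.

### Numerical engine

The network is implemented directly on numpy in channels-last layout with
hand-derived backward passes. 3×3×3 convolutions decompose into 27 shifted
BLAS products accumulated in place (`sgemm` with β = 1); inside a dense
block each feature piece is padded once and convolved into the
pre-activations of *every* unit that consumes it with stacked weights, so
the dense connectivity costs a few wide matrix products instead of many
narrow ones. The 2×2×2 stride-2 operators are non-overlapping and reduce to
a reshape plus one product. Every operator is validated against central
finite differences, and the dense block additionally against an independent
float64 reference implementation (explicit concatenation, offset-by-offset
convolution); agreement is at float32 precision. Optimization is Adam
(β = 0.9/0.999, ε = 1e-8), batch size 1, no weight decay or schedule.

## Losses

For probabilities `p` and binary labels `g` over `N` voxels:

- **Dice loss** `1 − 2Σpg / (Σp² + Σg² + ε)` with the *squared* denominator,
  ε = 1e-6 added to the denominator only. For binary `p` this equals
  `1 − DSC`. When `Σp² + Σg² = 0` (both grids empty) the loss is defined as
  0 — perfect agreement on emptiness — instead of the `1 − 0/ε` the formula
  would give.
- **BCE** `mean(−g log p − (1−g) log(1−p))`, probabilities clamped to
  `[1e-7, 1 − 1e-7]` before the logarithms; the gradient is zeroed on
  clamped voxels.
- **DBCE** the arithmetic mean of the two. The Dice term handles the extreme
  foreground/background imbalance of thin vessels; the BCE term supplies a
  smooth, per-voxel gradient that stabilizes training.

Analytic gradients with respect to `p` are exposed alongside the values and
are finite-difference checked at 1e-4.

## Metrics

- **DSC** `2|P∩G| / (|P| + |G|)`; defined as 1.0 when both masks are empty
  and 0.0 when exactly one is.
- **HD95** operates on boundary voxels — foreground voxels with at least one
  background 6-neighbour, grid-edge voxels included — whose centre
  coordinates are scaled per axis by the voxel spacing (mm). The 95th
  percentile (linear interpolation between order statistics) of each
  *directed* nearest-neighbour distance distribution is taken separately and
  the larger of the two is reported, the common medical-segmentation
  convention. Only the spacing enters: a rigid rotation of the scanner frame
  cannot change internal distances, so the full affine is ignored. An empty
  mask makes the metric undefined and raises (reported as NaN by the batch
  evaluator) rather than silently scoring 0. Nearest neighbours come from a
  KD-tree; tests pin the result to an O(|X|·|Y|) pairwise oracle at 1e-9.

## Post-processing

Predicted patches are placed back at their recorded origins; overlapping
predictions are fused by *averaging* probabilities before thresholding
(max-fusion was rejected as biased toward false positives). Thresholding is
strict (`p > 0.5`; exact ties go to background). Small-object cleanup then
removes foreground connected components below `min_component_voxels`
(default 64) and fills enclosed background holes below the same threshold —
the 3D analogues of area opening and area closing. Foreground connectivity
defaults to 26 (face+edge+corner); the background phase uses the
complementary 6-connectivity. Filtering is volumetric (3D), not per-slice.
The operation is idempotent and never creates voxels outside existing holes.

## Training protocol

Scans are assigned to *k* folds (default 10) by seeded shuffle plus
round-robin, so fold sizes differ by at most one. Cross-validation trains
from scratch on the other folds' patches and evaluates DSC/HD95 on the
held-out scans, emitting one row per fold plus a mean row; the loss-ablation
harness repeats this with `dice`, `bce`, and `dbce` under identical folds
and seeds. Augmentation applies one shared in-plane rotation per sample
(uniform within ±15° by default), linear interpolation for the image and
nearest-neighbour for the mask so it stays binary. Defaults mirror the
clinical-scale protocol: Adam at learning rate 1e-4, batch size 1, 200
epochs. Checkpoints keep both the best-validation-DSC and final parameters,
with the architecture config embedded.

**Desk-scale learning rate.** Adam's step magnitude is bounded by roughly
the learning rate per update, so a few hundred updates at 1e-4 cannot move a
freshly initialized network into the confident-sigmoid regime — that setting
presupposes the ~10⁵ updates of a full clinical run. Phantom-scale runs
(hundreds of updates) therefore use 1e-3. This was fixed from that argument
before any benchmark was run, and `TrainConfig` keeps 1e-4 as the default.

## Synthetic phantoms

Each phantom is a recursive bifurcating tree of capsules (segments with
radius): the root enters near one face, segments shorten by a jittered
factor ≈ 0.72 and radii shrink by `radius_decay` (default 0.72) per
generation, branching at 20–40°. If a tree does not fit the volume, segment
lengths are shrunk by 0.8 and the same topology is retried (bounded). The
image is built on the HU scale: lung-like background (−850 ± 40 HU —
deliberately straddling the −800 HU clip floor so clipping is exercised), an
ellipsoidal soft-tissue blob (40 ± 20 HU) as a mediastinum stand-in and
intensity distractor, vessel voxels at 300 ± 30 HU, plus 15 HU of global
Gaussian noise. Defaults: 64×64×32 voxels at (0.7, 0.7, 1.0) mm spacing —
in-plane spacing in the mid-range of clinical chest CT — root radius 2.8
voxels, depth 3. One seeded generator drives everything, so a given
(spec, seed) is bit-reproducible.

Two properties are enforced by tests because the pipeline's claims depend on
them: the foreground fraction stays under 5 % (the class imbalance the DBCE
loss targets; defaults give ≈ 0.5 %), and the vessel/lung contrast after
clip+normalize is at least 0.3 on the unit scale (learnability). Optional
distractor trees share the vessel intensity but are excluded from the mask,
imitating the artery/vein ambiguity of real angiograms.

What the phantoms do *not* emulate: anatomically realistic vessel calibres
and curvature, airway walls and cardiac structures, partial-volume effects,
reconstruction-kernel texture, motion, or inter-scanner variation. Passing
the phantom benchmark therefore demonstrates that the implementation — the
architecture, loss, patch pipeline, and metrics — is correct and can learn
tubular structures from realistic HU contrast; it does not certify clinical
segmentation accuracy.

## Benchmark problem sizes

The self-contained benchmark trains on 20 phantoms (64×64×32, base width 8,
one full-volume patch per scan, DBCE, learning rate 1e-3, no augmentation)
and evaluates on 5 held-out phantoms through the full prediction chain. The
packaged runs use 10 epochs (200 optimizer steps): training converges well
before that — held-out DSC exceeds 0.97 from roughly epoch 2–3 and stays
there, as the recorded loss history shows — and the thresholds asserted
(mean DSC ≥ 0.85, mean HD95 ≤ 3 mm) are unchanged from the long-run
configuration. The single-patch overfit check (one 32×32×16 phantom patch,
base width 8, 300-step cap, DBCE < 0.1) typically clears its threshold
within ~40 steps. The loss-ablation harness runs on a reduced split
(4 phantoms of 16×16×16, 2 folds) purely as a structural check of the
three-way comparison.

## Known limitations

- Single-sample (batch-1) execution only; group normalization makes this
  statistically sound, but there is no batched inference path.
- CPU-only: wall-time is dominated by BLAS throughput; clinical-resolution
  training (512×512×300 scans, wide networks, 200 epochs) is out of reach —
  use the config system to scale patch size and width to the hardware.
- No resampling/reorientation: volumes are consumed in their stored axis
  order, and metrics assume the paired masks share the grid exactly.
- HD95 on an empty prediction is NaN by design; downstream averaging skips
  NaNs and reports how many scans contributed.
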