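# Methods

## The problem

Instance segmentation of cells must break a symmetry: semantically
identical objects need distinct outputs.  Pixel-level predictors (boundary
UNets, gradient-flow methods) resolve it by assigning each pixel to exactly
one instance — which makes *overlapping* cells unrepresentable, since an
overlap pixel belongs to two instances.  This package implements an
approach in which the symmetry is broken *spontaneously* by random noise:
a conditional denoising chain splits the foreground into two fields so that
each instance lands wholly in one of them, and recursion turns repeated
two-way splits into a full instance segmentation in which masks may share
pixels.

## The model

Inputs are the image I (C channels), a semantic foreground probability S,
and two fields A, B initialized with i.i.d. Gaussian noise (mean 0.5,
σ 0.25, clipped to [0, 1], zero outside the binarized S).  A network NN with
C+3 input channels is iterated for n steps:

    A_{i+1} = S · [(1 − w_i) A_i + w_i · NN(I, S, A_i, B_i)]      (same for B)

on the log-scaled time grid t_i = 10^(10(i/n − 1)), i = 0…n, with blend
weights w_i = (t_{i+1} − t_i)/(1 − t_i) and w_{n−1} = 1, so the final step
fully trusts the network.  At n = 100 the grid is t_i = 10^(i/10 − 10).
Noise is sampled only once; the rest of the chain is deterministic
(maximum-likelihood denoising).

Training labels come from the noise itself: an instance mask M is the
A-split target iff Σ A_i·M ≥ Σ B_i·M (ties to A), which defines binary
target unions M^A, M^B.  The loss is foreground-weighted cross-entropy
summed over pixels,

    L = Σ_pixels S · [H(A_{i+1}, M^A) + H(B_{i+1}, M^B)],

with predictions clamped at ε = 10⁻⁷.  The network predicts the clean
sample (the targets), not the noise.

## Networks

Both the semantic network (C in, 1 out) and the split network use the same
UNet: two 3×3 conv + batch-norm + ReLU blocks per level, 2×2 max pooling,
nearest-neighbour upsampling with skip concatenation, 1×1 sigmoid head;
default widths 32/64/128/256 (tests and the reference experiments use
8/16/32).  Arbitrary input sizes are zero-padded to a multiple of the
downsampling factor and cropped back.  The implementation is pure numpy
with explicit backward passes (GEMM/im2col convolutions), gradient-checked
against finite differences; the optimizer is Adam with a log-linear
learning-rate decay between configurable endpoints (defaults 10⁻³ → 10⁻⁵).

**Weight sharing between the two output fields.**  The split network
computes the A prediction as f(I, S, A, B) and the B prediction as the same
f applied with the A and B channels swapped.  This makes the predictor
exactly equivariant under relabeling the splits: no bias toward "everything
into A" can be learned into separate heads, and the symmetry is broken only
by the input fields.  (A plain two-output-channel network is also
supported.)

## Training-sample construction

Each sample consists of (i) the untouched image; (ii) S from the semantic
network's prediction, with each instance dropped with probability
`p_label_drop` = 0.3 — its exclusive pixels zeroed in S and the instance
removed from the targets — so the model also sees foregrounds with missing
objects; (iii) fields blended as A = (1 − w) A₀ + w M^A, where w = 0 is
drawn with probability `p_w_zero` = 0.3 and otherwise w is a schedule
weight at a uniform step index.  With probability `p_bootstrap` = 0.25 the
M^A/M^B used to *build the blended input* are replaced by the model's own
gradient-stopped output on (A₀, B₀), while the loss targets remain the
noise-implied assignment: the input then resembles a chain state reached
from a bad initial guess and the model learns to correct it.  (The wording
of the source description also admits replacing the regression targets
themselves; that variant trains the network toward its own biases and
measurably degrades splitting, so the corrective reading is used.)

## Recursive segmentation

The binarized S is decomposed into 8-connected components.  For each
component the chain runs on a padded crop (8 px); the node's binary region
itself serves as the S input — multiplying by a soft probability at every
step would decay the fields geometrically and push the chain out of the
training distribution.  The final fields are thresholded at 0.5
*independently* — a pixel may join both splits (overlap) or neither — and
the components of each side are processed recursively.  Unclaimed pixels
are re-attached to the geodesically nearer side (ties to both), conserving
foreground; this can be disabled.

A chain outcome counts as a *bisection* only if (i) each side carries at
least `min_split_fraction` = 5% of the region (and `min_instance_pixels`),
(ii) neither side is essentially the whole region — "everything into A" or
"A plus a shard" carries no separation information — and (iii) the two
sides are not nearly coincident (shared pixels ≤ `max_shared_fraction` =
0.8 of the smaller side; genuinely overlapping cells stay below this, as a
cell buried deeper than ~3/4 inside another is degenerate and the scene
generator rejects such placements).  Anything else is a *trivial* outcome
and is retried with fresh noise: a single attempt on a multi-instance
region lands every instance on the same side with probability near one
half under noise-faithful dynamics, and independent re-noising attempts
drive the residual merge probability down geometrically.  The root node
gets a generous budget (`trivial_retries` = 29); deeper nodes — usually
single instances already, since each successful bisection halves the
residual multiplicity — get a small confirmation budget (`child_retries` =
3), because a large one would let rare spurious bisections of single cells
through and shred them.  A region still trivial after its budget is
emitted as one instance.  `fixed_recursions` reproduces fixed-count
recursion (no adaptive logic); `max_depth` = 8 caps all branches.  Masks
smaller than `min_instance_pixels` = 8 are dropped, and exact duplicate
masks are emitted once.

## Evaluation

Predictions and truths are stacks of binary masks, so matching is
overlap-aware by construction.  `match_instances` solves the one-to-one
assignment maximizing total IoU among pairs with IoU ≥ τ (Hungarian
algorithm; sub-threshold entries contribute zero, which preserves
optimality — an exhaustive-enumeration oracle guards this in tests).
Recall at τ is matched-truth / n-truth, pooled over scenes by summing
counts (per-image averaging available).  The default τ grid is 0.50–0.95
in steps of 0.05.

## Synthetic scenes

The generator emulates fluorescent cell images: cells are filled rotated
ellipses (closed-form membership ⇒ exact ground truth), with a dim
background (0.08), bright interiors with smooth radial falloff (contrast
0.6), additive intensities where cells overlap, and additive Gaussian
pixel noise (σ 0.05).  A target fraction of cells participates in an
overlap; those cells are placed at a partner offset of 0.45–0.8 of the
summed radii, rejecting placements where one cell swallows ≥75% of the
other.  The default condition — 64×64 scenes of two overlapping ellipses
with radii 7–12 px — is the minimal setting in which spontaneous splitting
can be demonstrated and evaluated end to end.  What the generator does
*not* emulate: point-spread blur, Poisson statistics, intensity gradients,
non-elliptical morphology, crowded fields of many cells.  Passing tests
therefore demonstrate the mechanism and the pipeline's correctness, not
performance on real microscopy.

## Reference experiment sizes

The end-to-end experiments (tests and the acceptance script) use: 200
training scenes, semantic network trained 500 steps (batch 8), split
network trained 1000 steps (batch 8, learning rate 10⁻³ → 10⁻⁴), n = 10
diffusion steps, and 50 held-out scenes.  The shortened learning-rate decay
(stopping at 10⁻⁴ rather than 10⁻⁵) fits the short optimization budget:
with only 10³ steps the late low-rate tail contributes nothing.

## Behaviour and limitations at desk scale

With two overlapping cells, the noise-implied assignment places the cells
in *different* splits in only about half of draws (their pixel sums share
the overlap region and are positively correlated), so a network that
faithfully follows the noise cannot exceed roughly one half in a single
chain run.  At this training scale the network's reading of the noise is
also imperfectly localized, which further correlates the two cells'
outcomes; single-run split rates of ~0.1–0.2 are typical.  The recursive
segmenter's re-noising retries are therefore integral to the method here:
independent attempts raise the probability that an overlapping pair is
eventually separated above 0.9.  Larger networks, longer schedules and
richer data — the regime the method is designed for — raise the per-run
rate; the desk-scale configuration demonstrates the mechanism, not its
ceiling.

Other numerical choices: 8-connectivity for components; binarization
threshold 0.5; cross-entropy clamp 10⁻⁷; per-node seeds derived from the
master seed and a visit counter via `SeedSequence`, making segmentation
bit-reproducible; batch-norm uses batch statistics during training and
running averages (momentum 0.9) at inference, so evaluation-mode passes
(chains, bootstrap) are deterministic and cache-free.
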