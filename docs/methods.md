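# Methods

This note documents the models, procedures and design choices behind the
package, in the package's own terms: what is simulated, which parameters
matter, and what the test suite does and does not establish.

## The aggregation problem

A federation of K clients jointly trains one heatmap keypoint regressor.
In round t the server broadcasts global parameters w_t; each sampled
client runs E local epochs on its private shard and returns its
parameters w_k and shard size n_k.  The server forms pseudo-gradients
g_k = (w_k − w_t)/η at the server learning rate η.  Under heterogeneous
shards, pairs of gradients can have negative inner products; averaging
such pairs attenuates or reverses the update ("gradient conflict").  The
per-round disagreement is quantified as

    C(G) = Σ_{i<j} 1[⟨g_i, g_j⟩ < 0] · |⟨g_i, g_j⟩|,

summed over unordered pairs (the ordered sum would only double the
value).

## Gradient harmonization

Harmonization processes the gradient set in a seeded shuffled order.  In
the default `random_pair` mode each gradient is tested against exactly
one uniformly drawn other gradient — an O(K) rule that avoids fixed
pairing bias; a `scan_first_conflict` mode tests against the others in
shuffled order and corrects against the first conflicting partner.  When
⟨g_k, g_j⟩ < 0 (strict; exact ties never project, no epsilon band), the
conflicting component is removed:

    g_k′ = g_k − (⟨g_k, g_j⟩ / ‖g_j‖²) · g_j .

Each gradient is projected **at most once**, and partners are always the
original, uncorrected gradients: sequential use of already-corrected
partners would make the result depend on processing order, which the
shuffling is meant to neutralise.  The correction is orthogonal to the
partner and never increases the norm.

Reconstruction scores each corrected gradient against the consensus
direction d = (1/K) Σ g_k′ (the unweighted mean; it reduces to the plain
averaging direction when conflict-free and vanishes under perfect
cancellation, which gives the fallback a precise trigger).  The weights

    β_k = max(0, ⟨g_k′, d⟩) · n_k,   α_k = β_k / Σ β

combine alignment with shard size.  Two refinements:

- **Conflict-free degeneration.**  Alignment weighting is part of the
  conflict-resolution machinery; in a round with no conflicting pair the
  hybrid mode uses pure n_k weights, so the end-to-end update coincides
  exactly with sample-size-weighted parameter averaging.  (With
  always-on alignment weighting that equivalence cannot hold for
  non-identical gradients; treating alignment as conflict-contingent
  satisfies both the graceful-degeneration requirement and the hybrid
  weighting.)  Pure `sample_size` and pure `inner_product` modes are
  exposed as configuration.
- **Fallback.**  If every β_k is zero (e.g. d = 0 for exactly opposed
  gradients), weights fall back to 1/K and the round is flagged.

The global step is w_{t+1} = w_t + η Σ α_k g_k′.  Because the same η
appears in the gradient computation and the update, the step equals the
weighted combination of corrected client deltas; with a single client
and no projection it reproduces that client's parameters exactly.  An
optional server-side Adam mode instead treats −Σ α_k g_k′ as a
pseudo-gradient (the plain step is the default; both conventions appear
in practice and they disagree, so both are available).

## Baseline strategies

All six strategies implement one plug-in contract
`aggregate(updates, global, rng, round) → (new global, conflict report)`
plus an optional local-penalty hook, and all report the same raw-gradient
conflict telemetry.  FedAvg: Σ (n_k/Σn)·w_k.  FedProx: FedAvg
aggregation with a local proximal penalty (μ/2)‖w − w_g‖², default
μ = 0.01.  FedBN: name-pattern-matched normalization slices are excluded
from averaging (the server copy is frozen, clients keep their own); with
no matching slices it degenerates to FedAvg with a warning — the default
network is normalization-free, so FedBN is exercised on toy layouts.
FedDyn: local penalty −⟨h_k, w⟩ + (α/2)‖w − w_g‖² with per-client state
h_k ← h_k − α(w_k − w_g), default α = 0.01; the server subtracts the
running mean of corrections accumulated over previous rounds (so round 1
collapses to FedAvg, and cloned clients collapse across all strategies).
FedAW: α_k ∝ n_k·q_k with data quality q_k = 1/(local validation loss
+ 1e-8) measured on each client's held-out shard (a `sample_size` mode
exists when no validation shard does).  These follow the strategies'
standard forms at their usual defaults; they are comparators, not
re-implementations aimed at any published benchmark number.

## The pose model

The regressor follows the simple-baselines recipe: stride-2 conv blocks
with ReLU, a transposed-convolution head, and a 1×1 output conv giving
one heatmap per keypoint.  Engine note: forward/backward passes are
implemented directly over numpy (im2col/col2im convolutions, ReLU,
masked MSE, SGD/Adam), float32 internally with float64 flat-vector
exchange; every layer's backward pass is verified against central finite
differences, and im2col/col2im are verified as exact adjoints.

Two configurations:

- `TINY` (default for all experiments): 64×64 grayscale in, 16×16
  heatmaps, three stride-2 conv blocks (8, 16, 16 channels) and two
  deconv layers (kernel 4 stride 2, then kernel 3 stride 1), ≈10k
  parameters.  The stride arithmetic (input/heatmap = 2^#convs / Π
  deconv strides) is validated at construction; a 64→16 reduction with
  three stride-2 convs forces the second deconv to stride 1.  The sizing
  is deliberately small: the aggregation strategies operate on flat
  gradient vectors and are agnostic to the architecture, so the
  experiments probe gradient geometry, not photorealistic accuracy.
- `RESNET50_STYLE`: the classical full-scale shape — 256×256 input,
  64×64 heatmaps, three 256-channel kernel-4 stride-2 deconv layers —
  without pretrained weights (initialization is seeded He-style, zero
  biases).

Targets are isotropic Gaussians (σ = 2 heatmap cells, the standard
choice at 64-cell resolution) with the centre rounded to the nearest
cell so the peak cell is exactly 1; invisible joints give zero channels
and are masked out of the MSE.  Decoding is per-channel argmax
(row-major first maximum on ties) scaled to input pixels, with an
optional quarter-cell offset toward the larger neighbour (on by
default); an all-constant channel decodes to (0, 0) and is flagged.

## Synthetic scenes and client heterogeneity

Each scene is a two-segment kinematic chain (shoulder→elbow→wrist) drawn
as thick anti-aliased strokes on smoothed-noise background, with a
rectangular "manipulator" occluder over the mid-limb and a per-scene
illumination gain.  Labels are the joint positions of the generating
chain — exact by construction, unchanged by occlusion or photometry
(occluded joints remain annotated).  Four fixed viewpoints are emulated
in-plane: anterior (identity), posterior (mirror), and the two laterals
(mirrored shears); this preserves exact 2-D labels, at the cost of not
modelling true 3-D foreshortening.

Client profiles specify viewpoint distributions, illumination ranges,
pose-angle distributions, an extended-pose probability, a torso-cue
strength and a partition weight.  A scalar `divergence` dial
interpolates from identical profiles (IID control) to opposed ones:
one-hot viewpoints cycling over the four views, alternating dark/bright
illumination, shifted shoulder angles, mostly extended (near-horizontal)
arms, and no torso cue.  The conflict mechanism at full divergence is
deliberate: without the torso cue an extended arm is nearly symmetric
end-to-end, so mirror-viewpoint clients assign the shoulder to opposite
ends of visually similar scenes — label conflict, not merely covariate
shift, which is what makes their gradients collide (the multi-camera
inward/outward shoulder-update phenomenon).

One empirical caveat, measured rather than assumed: training **from a
random initialization**, first-round gradients of opposed clients do not
conflict — the shared learn-the-task component dominates, and inner
products are large and positive.  Conflicts emerge reliably once the
global model approaches the consensus (round ≈6 onward at full
divergence), and their frequency is monotone in the divergence dial.
Deployments that start from a pretrained backbone sit in that
task-adapted regime from the outset.  Tests therefore assert conflict
emergence over early rounds and dial monotonicity, not round-1 conflict.

Dataset assembly holds out a profile-balanced test fraction (10%),
partitions the remainder across clients by the partitioner (quantity
skew) with each client sampling from its own profile (feature skew), and
splits each shard train:val ≈ 7:2, echoing a 70/20/10 design.  The
generator emulates the statistical structure of multi-view single-arm
capture — not its photorealism, multi-subject variation, sensor noise or
3-D geometry — so passing tests demonstrate properties of aggregation
under controlled heterogeneity, not field accuracy on real imagery.

## Partitioner

Preset weights w (default [0.30, 0.20, 0.15, 0.10, 0.08, 0.06, 0.04,
0.03, 0.02, 0.02], K = 10) are normalised to ratios; counts are floored
proportional shares with the rounding deficit returned one sample at a
time to the earliest clients; clients below m_min = 10 are lifted to it;
the surplus so created is drained one sample per client cycling from
client 1 **skipping clients at the floor** — draining without the skip
could push a just-lifted client back below the floor, defeating the
floor's purpose, so the floor is protected and n < K·m_min is rejected
outright.  Index assignment is a numpy PCG64 permutation (seed 1234 by
default) sliced contiguously, making plans bit-reproducible across
releases.  For n = 300 under the default weights the resulting counts
are [88, 58, 44, 29, 23, 17, 11, 10, 10, 10].

## Federation protocol

Reference protocol: K = 10 clients, 5 sampled uniformly without
replacement per round, 5 local epochs, batch size 32, server η = 1e-3,
100 rounds; local optimizer Adam at 1e-3 (SGD available, and the local
learning rate is exposed for 1e-4…1e-2 sensitivity sweeps).  The
asynchronous-update and dynamic-selection variants of such systems are
replaced by synchronous uniform sampling — a deliberate simplification;
no algorithm is specified for them.  A master seed derives independent
child seeds per (round, client) and per round for sampling and
aggregation, so a (config, seed) pair determines every record; metrics
CSVs from repeated runs are byte-identical.  Per-round telemetry records
the conflict objective, conflicting-pair count, projection count,
fallback flag, train loss, pooled detection accuracy and per-joint/mean
PCK on the held-out test set.  Evaluation uses the server-side test
split (not client validation shards).

Experiment sizing used by the test suite: the ordering comparison runs
the conflict fixture at n = 500 total scenes (≈ one quarter of the
2060-image reference collection, same split shape) for 30 rounds and
3 master seeds with the `TINY` model; the IID control and reproducibility
checks use smaller configurations.  These sizes are the package's chosen
desk scale for single-CPU experimentation.

## Evaluation

PCK counts a visible joint correct when ‖pred − gt‖₂ / L ≤ τ with an
adaptive per-joint normalization: shoulder L = image diagonal, τ = 0.3;
elbow L = upper-arm length, τ = 0.4; wrist L = forearm length, τ = 0.5.
The three multipliers and three lengths are paired in listed order; the
mapping is configurable since other pairings are defensible.  Per-joint
fractions are averaged unweighted into mean PCK; detection accuracy
pools all visible joints at the 0.5 multiplier and is the per-round
scalar (an interpretation — pooled PCK@0.5 — of "per-round accuracy" of
a heatmap regression model).  Samples with nonpositive normalization
lengths are excluded with a warning.  Strategy comparisons use the
classical paired t-test on per-round mean-PCK series (t = mean(d)·√m /
sd(d), m−1 df, two-sided p), with explicit degenerate handling:
identical series → t = 0, p = 1; constant nonzero difference → t = ±∞,
p = 0, flagged.  Head-normalized PCK variants are out of scope (the
synthetic scenes carry no head box).

## Known limitations

- The scene generator is 2-D and schematic; conclusions transfer to
  gradient-geometry questions, not to real-image accuracy.
- `random_pair` corrects at most one conflict per gradient per round;
  heavily multi-conflicted sets retain residual conflict (reduced in
  expectation, not eliminated).
- FedBN is structurally exercised via toy layouts because the default
  model carries no normalization layers.
- At desk scale the FedGH-vs-FedAvg PCK difference is small relative to
  test-set quantization; the ordering experiment uses fixed seeds and a
  fixed fixture and should be read as a scaled-down analogue, not an
  effect-size estimate.
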