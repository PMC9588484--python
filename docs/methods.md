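# Methods

## The model

`tractembed` treats a streamline as what it is numerically: an ordered
sequence of 3D points in world (scanner RAS) millimetre coordinates,
variable in length, with no canonical head-to-tail direction. A
sequence-to-sequence LSTM autoencoder learns a latent representation by
self-supervision: the encoder consumes the first half of the streamline one
point at a time and its final hidden/cell states initialise the decoder,
which must reproduce the second half point by point. Whatever the encoder
state must contain for that prediction to succeed — position, shape,
ordering — is exactly what a streamline descriptor should contain, and the
state has fixed width regardless of input length.

Concretely, for hidden width H and L ∈ {1, 2} layers:

- each LSTM layer carries `W_ih (4H×I)`, `W_hh (4H×H)` and two bias vectors
  `b_ih`, `b_hh` (gate order input/forget/cell/output; I = 3 for the first
  layer, H above it);
- the decoder adds a linear readout `H → 3` with bias;
- parameter count: `2 · Σ_layers 4(H·I + H² + 2H) + (3H + 3)`; for H = 128,
  L = 1 this is 136,579.

The split at the midpoint gives the encoder the extra point on odd lengths
(⌈L/2⌉ / ⌊L/2⌋): the encoder then always has at least as much context as
the decoder must produce. The encoder input is terminated, and the decoder
started, with a reserved (0,0,0) token; a genuine origin point in loaded
data is therefore perturbed by 1e-6 mm (counted in the log) rather than
ever colliding with the token. Decoding is teacherless: after the start
token each decoder input is the model's own previous output, so gradients
flow through the feedback path and training matches inference-time rollout.
The loss is the mean squared error per coordinate over *valid* decoder
steps only; padded positions are excluded from numerator and denominator,
so the loss of a streamline does not depend on what else shares its batch.

The whole network, including backpropagation through time and through the
decoder's output-feedback connections, is written in numpy. Correctness of
the backward pass is established by central-difference numerical
differentiation in the test suite (1- and 2-layer configurations, masked
batches). Batched encoding freezes each sequence's state at padded steps,
so batched and one-by-one execution agree to float precision.

## Training

Defaults: Adam (lr 1e-3, β₁ 0.9, β₂ 0.999), batch size 128, global
gradient-norm clipping at 1.0, 80/20 train/validation split (by streamline,
stratified by bundle label when labels exist), reshuffling every epoch, and
per-epoch Bernoulli(0.5) reversal of each training streamline, resampled
every epoch. The checkpoint with the lowest validation loss is returned
(earliest epoch on ties); the final incomplete batch is kept. Streamlines
with fewer than 4 points cannot be split into two non-empty halves and are
excluded from training (counted in the log) but remain embeddable.
Initialisation is uniform U(−1/√H, 1/√H) under a recorded seed; with a
fixed seed and serial execution a run is reproducible bit for bit.

## Embedding modes

The latent vector is the encoder's final **top-layer hidden state** (not
the cell state) on the first half of the streamline with its end token —
the same sequence the encoder saw in training. Because reversal
augmentation puts both directions in distribution, the reversed
streamline's first half (the second half, walked backwards) is equally
valid input, giving three modes: `uni` (one direction, dimension H),
`bi_avg` (mean of both directions' encodings, dimension H, invariant to
head-to-tail flips — the default), and `bi_concat` (concatenation,
dimension 2H). For 2-layer models all layers' (hidden, cell) pairs transfer
from encoder to decoder, and the top layer supplies the latent vector.

A bundle embedding is the arithmetic mean of its member embeddings; it
lives in the same space, so streamline-to-streamline, streamline-to-bundle
and bundle-to-bundle comparisons are all the same Euclidean distance.
Absolute latent distances are properties of one trained model and do not
transfer between models; threshold choices for querying should be guided by
the seed-streamline-to-bundle distance table, not copied across runs.

## Analysis toolbox

All deterministic given their seeds. k-means uses k-means++ with 10
restarts; exact distance ties everywhere break toward the lower
label/index. Hierarchical dissection recursively applies k-means with
`branching` children per node, stopping at `depth` or when a node holds
fewer than `min_leaf · branching` members; children partition their parent
at every level. Outlier screening flags, within each cluster, members whose
distance to the cluster centroid exceeds the cluster's chosen quantile
(default 0.99 — a convenience default for generating a shortlist, not a
calibrated detector; the intended use is screening before visual
inspection). t-SNE projection (perplexity 30, capped below the sample
count) is for figures only and never feeds quantitative decisions.

## The synthetic atlas

The generator emulates the geometric structure the method exploits, at desk
scale: bundles are tubes swept along smooth arc-length-parametrised spline
curves; each streamline is the centerline plus a constant random tube
offset (scale = the 2 mm tube radius) plus a low-frequency lateral wander
(scale radius/3, spline-interpolated over a few knots so curvature stays
low at any sampling density); point counts are uniform in 20–60; each
streamline is head-to-tail flipped with probability 0.5 so the corpus has
no canonical direction. The default atlas holds 10 bundles — four
left/right mirror pairs (C-arc, two U scales, S-curve) and two midline
bundles — laid out on a brain-scale grid (extent ≈ ±60 mm) with
inter-centerline separations ≥ 20 mm. False-connection streamlines follow
one bundle's first half, double back in a hairpin (a turning angle near
180°, far above the ≤ ~90° of any genuine streamline), and finish along a
second bundle.

What the generator does **not** emulate: crossing and kissing fibres,
partial-volume noise, endpoint scatter into cortex, inter-subject
variability, or bundles that genuinely overlap. Passing the property suite
therefore shows the machinery is correct and effective in the separable
regime it targets, not that real tractograms of touching bundles (e.g.
inferior longitudinal fasciculus vs optic radiation) will separate as
cleanly.

## Problem sizes and what the checks show

The property suite trains the reference model (H = 128, 1 layer) on the
default fixture of 10 × 200 = 2000 streamlines for 5 epochs and then
exercises every analysis stage; unit tests use smaller models (H ≤ 16)
chosen so the full suite runs in a few minutes on one CPU.

One property deserves honesty: at this corpus size an epoch is only
⌈1600/128⌉ = 13 optimizer updates, so 5 epochs is 65 Adam steps at lr
1e-3 — enough to reduce validation MSE by ~20% (from ≈1450 mm² to
≈1190 mm²), not to converge. The same run continued to 150 epochs reaches
≈2 mm² (0.1% of initial), crossing 20% of the initial loss around epoch
33; on corpora of 10⁵⁺ streamlines, where one epoch is thousands of
updates, convergence within a couple of epochs is the expected behaviour.
Rapid 5-epoch convergence on a 2000-streamline corpus is not attainable
with these (deliberately fixed) optimizer settings, and the corresponding
check is left failing rather than papered over by rescaling the data or
retuning the optimizer.

Usefully — and this is why the rest of the suite passes with wide margins —
bundle-level structure in the latent space appears long before the
reconstruction loss converges: even a briefly trained encoder maps
geometrically separated bundles to separated latent clusters (mirror-pair
ARI 1.0, held-out top-1 accuracy 1.0, false-streamline leaf enrichment
≈11× against a required 3×). Reconstruction quality and
retrieval/clustering quality are related but distinct properties of the
latent space.
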