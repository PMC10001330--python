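# Methods

## Pipeline overview

`mpadbn` classifies labeled RGB tissue tiles in four stages: CLAHE contrast
enhancement → depthwise-separable convolutional feature extraction →
hyperparameter search with the Marine Predators Algorithm (MPA) → deep
belief network (DBN) classification, with an optional stacked-autoencoder
feature compressor. Evaluation uses stratified train/test splits and
per-class one-vs-rest metrics. All randomness flows from a single master
seed, so a fixed configuration reproduces bit-identical results.

## CLAHE

Adaptive histogram equalization amplifies local contrast but also noise;
the contrast-limited variant bounds the amplification by clipping each
block histogram before accumulating its CDF. Our dialect:

* The image is covered by a `(rows, cols)` **grid of contextual blocks**
  (default 8×8 grid), reflection-padded so the grid divides evenly.
* Each block histogram (default 256 bins) is clipped at
  `clip_limit × block_pixels / n_bins`, i.e. `clip_limit` is relative to a
  uniform histogram's bin height (default 2.0). The clipped excess is
  redistributed **uniformly in a single pass** — iterative re-clipping is a
  known alternative dialect; the single pass keeps the mapping closed-form
  and is what the brute-force oracle in the tests recomputes.
* The block mapping is `round(cdf / N × 255)`; pixel values interpolate
  bilinearly between the four neighboring block mappings (edge mappings
  replicated beyond the border centers).
* A block whose histogram occupies a **single bin** receives the identity
  mapping: a constant region has no contrast to stretch, and this makes
  enhancement of constant tiles exactly idempotent rather than idempotent
  only up to rounding.
* Color: RGB is converted to CIELAB and only the lightness channel is
  equalized (stain hue preserved — the natural choice for histology);
  `color_mode: per_channel` equalizes each RGB channel instead.

The clip limit and block grid are the two controls that matter: a larger
clip limit flattens the histogram toward plain adaptive equalization, a
finer grid localizes the enhancement.

## Feature extraction

A depthwise-separable block factorizes a standard convolution into a
per-channel spatial filter followed by a 1×1 channel mixer, cutting the
weight count from `k²·C_in·C_out` to `k²·C_in + C_in·C_out` (656 vs 4608
for k=3, 16→32). The default extractor resizes tiles to 64×64, applies
four blocks (3→16→32→64→64 channels, stride 2 on blocks 2 and 4, ReLU
after each convolution, "same" zero padding) and global-average-pools to a
64-vector. ReLU rather than a sigmoid is used inside the convolutional
stack, the standard choice for this architecture family.

Weights default to a **fixed-seed He-scaled random draw**: the extractor is
then a deterministic random projection, which suffices for the color/
texture-separable synthetic classes and keeps the test suite fast and
exactly reproducible. `weights_mode: trained` instead fits the stack
briefly with a throwaway linear softmax head by plain SGD backpropagation
(implemented in numpy) on the training rows only, then discards the head.
Features are z-scored per column with statistics of the training rows;
zero-variance columns map to 0.

## Marine Predators Algorithm

Population of `n` agents (Prey matrix) in a box `[lb, ub]`, initialized
uniformly. Each iteration draws Brownian vectors `RB ~ N(0,1)`, Lévy
vectors `RL` (Mantegna's algorithm, stability exponent α = 1.5, scaled by
0.05 as in the method's reference implementation) and uniforms `R`, and
updates against the Elite (best-so-far agent, tie-broken toward the
incumbent):

* **Phase 1** (iterations `< I_max/3`): `Step = RB ⊗ (Elite − RB ⊗ Prey)`,
  `Prey += P·R ⊗ Step`, with step constant `P = 0.5`.
* **Phase 2** (middle third): first `⌈n/2⌉` agents use the Lévy form
  `Step = RL ⊗ (Elite − RL ⊗ Prey)` with `P·R`; the rest move around the
  elite, `Step = RB ⊗ (Elite − Prey)`, `Prey = Elite + P·CF ⊗ Step`, where
  `CF = (1 − I/I_max)^{2I/I_max}` decays from 1 to 0.
* **Phase 3** (final third): `Step = RL ⊗ (RL ⊗ Elite − Prey)`,
  `Prey = Elite + P·CF ⊗ Step`. A config flag `eq11_literal` switches to
  the variant without the inner Lévy factor; the default keeps the
  self-consistent form, which matches the phase-2 structure.
* **FADs effect**: per agent, with probability `FADs = 0.2` a long jump
  `Prey += CF·[lb + R ⊗ (ub − lb)] ⊗ U` through a Bernoulli(0.2) mask `U`;
  otherwise a drift `[FADs(1−r) + r]·(Prey_{r1} − Prey_{r2})` along two
  shuffled agents.

Positions are clamped to the bounds after every move. Per-agent **memory
saving** (keep the previous position if it scored better) plus strict
elite updates make the best-fitness history non-increasing — asserted as
an invariant for every seed. Evaluation count is `n·(I_max + 1)`.

For hyperparameter tuning the 6-D candidate decodes to: log10 RBM learning
rate and log10 fine-tune learning rate in `[−4, −1]`, two hidden-layer
widths in `[8, 256]` (rounded), CD steps `k ∈ [1, 5]` (rounded), fine-tune
epochs `[5, 60]` (rounded). The fitness is the **classifier error rate in
percent** on a stratified 20% validation split held out of the training
split, so the outer test split never influences the search.

## Restricted Boltzmann machines and the DBN

Binary-binary RBM energy `E(v,h) = −b_v'v − b_h'h − v'Wh`; the first layer
uses gaussian visibles with diagonal unit precision (`β = 1`, appropriate
for z-scored features): `E = Σ β(v−b_v)²/2 − b_h'h − (βv)'Wh`, giving
recognition `P(h=1|v) = σ(b_h + W'(βv))` and generation
`v|h ~ N(b_v + Wh, β⁻¹)`. The RBM conditionals as written describe
top-down generation; classification uses the standard bottom-up
recognition pass (the conditional means composed layer by layer).

Training is CD-k: hidden states sampled from the data-driven
probabilities, visibles reconstructed by their conditional mean, k
alternating steps; plain SGD (momentum 0, minibatch 32, optional weight
decay), weights initialized `N(0, 1/√n_visible)` — a scale at which the
sigmoid units start in their responsive range; smaller inits left the
stacked features nearly constant and slowed fine-tuning badly. For RBMs
small enough to enumerate, `exact_log_likelihood` computes the partition
function by summing `exp(−F(v))` over all visible states; the test suite
checks CD-1 raises it on planted-model data.

The DBN is built greedily (each RBM trained on the previous layer's hidden
probabilities), stacked into a feed-forward sigmoid network, and finished
by a softmax head with cross-entropy backpropagation. The head is first
fitted alone on the frozen top-layer activations with its own learning
rate (0.5; softmax regression is convex so the larger step is safe), which
also makes a model with 0 fine-tune epochs valid; joint fine-tuning then
updates all layers (default lr 0.3, 30 epochs).

The stacked autoencoder (optional, `ae.enabled`) is a mirrored sigmoid
encoder/decoder — identity activation on the final reconstruction layer,
since features are real-valued — trained by SGD on the mean squared
reconstruction loss `Σ(X̃ − X)²/N`; its bottleneck can replace the raw
features before the DBN.

## Splits, metrics, leakage

Stratified splits via seeded `train_test_split` (80:20 default, 70:30
supported). Per-class "accuracy" is one-vs-rest accuracy `(TP+TN)/n` — the
reading under which per-class values can differ while averaging near the
overall accuracy; precision/recall/F1 come off the confusion matrix, AUC
is one-vs-rest on the softmax scores (trapezoidal ROC integration, via
scikit-learn, cross-checked in tests against a from-scratch threshold
sweep). Macro values are unweighted class means; a class absent from the
truth is excluded from the AUC macro with a warning. The pipeline records
which rows each fitting stage consumed and raises if any test index
appears in any of them.

## Synthetic data

Each class recipe fixes a background stain color, an expected Poisson
count of darker anti-aliased elliptical "nuclei" (radii 2–5 px, random
orientation, 0.45× background color), a texture correlation length, and a
noise amplitude `noise_sd` that scales both the Gaussian-filtered
correlated texture and the per-pixel noise (so `noise_sd = 0` with no
blobs yields an exactly constant tile). Default recipes use five distinct
colors with blob densities 3–18 per 64×64 tile and `noise_sd = 8`, chosen
so that a mean-color nearest-centroid rule already exceeds 90% accuracy —
the separability the end-to-end tests rely on. What passing tests show is
therefore that the machinery is correct and integrable, **not** that the
pipeline reaches any particular accuracy on real stained tissue, whose
intra-class variability (stain variation, morphology, artifacts) the
generator deliberately does not model.

## Problem sizes and numerical choices

The shipped tests and the acceptance script run at desk scale, as a design
choice: 5 × 60 tiles of 64×64 for the end-to-end run with an MPA budget of
6 × 6, population 25 × 300 iterations for the optimizer benchmarks, 4×3
RBMs for exact enumeration, 500-point blob sets for the classifier. Ties
in the elite update keep the incumbent; positions are clamped (not
reflected) at the bounds; integer hyperparameters decode by rounding;
degenerate inputs (single-agent populations, one-block CLAHE grids,
constant images, zero-variance features) are exercised in the unit tests.

## Known limitations

* Random-weight features are a stand-in for a pretrained backbone; the
  trained mode is brief by design and no published checkpoint is loaded.
* CD uses mean-field visible reconstructions (no persistent chains), fine
  for the small models here.
* The CLAHE dialect (single-pass redistribution) differs from
  implementations that re-clip iteratively; outputs can differ by a few
  gray levels from such libraries.
* Real-data performance depends on tile curation and staining consistency;
  no stain normalization is included.
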