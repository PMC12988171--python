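# Methods

## The training rule

`fpnet` trains feed-forward classifiers without a backward pass. A
network with layers `l = 1..L` computes activations
`a_l = f_l(a_{l-1} W_l)`, with `a_0 = x`. Instead of propagating an error
signal backwards, each hidden layer is given an explicit regression
target for its membrane potentials `z_l = a_{l-1} W_l`:

    z̃_l = g_l(a_{l-1} Q_l) + g_l(y U_l)

where `Q_l` (fan-in × width) and `U_l` (label-dim × width) are fixed
random Gaussian matrices drawn before training, `y` is the one-hot
label, and `g_l` is an element-wise nonlinearity (the sign function by
default, so each target entry is in {−2, −1, 0, 1, 2}). The input term
keeps the representation full-rank and input-dependent; the label term
plants decodable label information in every hidden layer. Weights are
the ridge solution

    W_l = (A_{l-1}ᵀ A_{l-1} + λI)⁻¹ (A_{l-1}ᵀ Z̃_l)

computed once per layer after a single streaming pass: the Gram and
cross-moment matrices are plain sums over samples, so they are
accumulated batch by batch in memory that depends only on the layer
widths, never on the dataset size. Layers are fitted strictly in order
and frozen before their successors are created; nothing downstream of a
layer can influence its weights (the suite verifies this by refitting a
truncated network and comparing weights bit for bit).

The readout is fitted by the same ridge machinery with the one-hot
labels themselves as targets. This is the degenerate case of the target
construction with the input term dropped and the label projection fixed
to the identity, and it is the unique choice that makes the network
output a label score directly rather than a projection that would need
inverting at inference time.

"Single epoch" here means one streaming pass per layer (L passes over
the data in total, each through an already-frozen prefix). The training
residual `‖Z_l − Z̃_l‖ / ‖Z̃_l‖` is computed exactly in a second
streaming pass per layer and stored on the layer; it is the reliability
measure for interpretation (below). A one-pass approximation would
require also accumulating `Z̃ᵀZ̃`, which we chose not to do by default
for the sake of an exact number.

### Baseline fitting modes

* `rf` (random features): hidden weights stay at seeded Gaussian draws
  (fan-in scaled); only the readout is fitted.
* `label_projection`: hidden targets are `y U_l` alone. The target
  matrix then has rank at most the label dimension, so hidden
  representations collapse onto a label-rank subspace.
* `noisy_label_projection`: `y U_l + E`, `E ~ N(0, noise_sd²)`,
  default `noise_sd = 1.0`. The noise breaks the rank ceiling but is
  uninformative about the label.

## Convolution as patch regression

A convolutional layer is fitted as a dense regression over im2col
rows: every receptive field of every sample becomes one regression row
(channel-major flattening, raster-ordered positions, 0-based), and each
row inherits its sample's one-hot label. The solved row weights reshape
into the filter bank, and the forward convolution is exactly the patch
matrix times those weights (asserted in the suite). Label broadcast to
every position is the construction consistent with applying the target
rule patch-wise; it treats every receptive field of a positive sample
as positive, which is a weak-label approximation — receptive fields
that never see the class-relevant feature contribute label-uncorrelated
rows, diluting but not biasing the fit.

Block convention for the provided conv estimator: block `b` holds two
kernel-3 layers with `base_filters · 2^(b-1)` filters — stride 1 with
'same' zero padding, then stride 2 with 'valid' padding — and the last
feature map is aggregated by global average pooling before the readout.
'same' padding is symmetric with the extra zero trailing, giving output
length `ceil(L/stride)`. Position subsampling during fitting (seeded,
uniform over rows) is available for large images and off by default.

## Interpretation

Hidden potentials decode into local label predictions by inverting the
target construction on the *realised* potentials:

    ŷ_l = g⁻¹(z_l − g(a_{l-1} Q_l)) U_l⁺

with `U_l⁺` the cached Moore–Penrose pseudo-inverse of `U_l`. For
`g = sign`, `tanh` is used as the surrogate inverse; for `g = tanh` the
true inverse (artanh clipped at |x| ≤ 1 − 1e−7) is used. If the fit
were exact and `g` invertible this recovers `y U U⁺ = y` exactly
whenever `U` has full row rank (width ≥ label dimension). The decoding
degrades with the training residual, so every explanation carries the
layer's residual and a low-reliability flag (threshold 0.9 by default,
configurable — the value is a conservative marker of a poor fit, not a
calibrated probability).

Convolutional layers decode per receptive field, producing a label-score
map over output positions. Saliency maps are projected to input
coordinates by nearest-receptive-field-centre assignment: position `i`
of a layer with stride `s`, kernel `k` and left padding `p` sits at
coordinate `i·s + (k−1)/2 − p` of its input, composed through the
stack. This is a documented geometric convention, not a gradient
attribution. Optional per-sample min–max rescaling is flagged as
visualisation-only. Localization is scored by treating positions as
instances and the ground-truth mask as labels (ranking AUC with
average-rank ties, plus area under precision–recall).

## Numerical choices

* Gram/cross statistics are accumulated in float64 regardless of input
  precision; long streams in single precision would otherwise lose
  low-order bits.
* The penalised system is solved by Cholesky factorisation of the
  symmetrised `gram + λI` (SPD for λ > 0), with an eigendecomposition
  fallback (eigenvalues clipped at machine precision) if factorisation
  fails. No explicit inverse is formed. With λ = 0 the solve is refused
  when the condition estimate exceeds 1e12.
* λ defaults to `trace_scaled` mode with `lam = 1e-2`: the effective
  penalty is `lam · trace(gram)/m_in`, i.e. 1% of the mean squared
  activation energy per input unit. This keeps behaviour stable across
  activation scales (sign-valued activations versus raw inputs differ
  by orders of magnitude). `absolute` mode reproduces a user-specified
  λ exactly. No claim is made of matching any particular reference
  regularisation strength.
* Projection scales default to fan-in normalisation
  (`1/√m_in` for Q, `1/√m_label` for U). Under `g = sign` the scale is
  provably immaterial (tested); for other `g` it keeps pre-nonlinearity
  magnitudes O(1).
* `sign(0) = 0`, so all-zero input rows decode as pure label terms.
* Class prediction is argmax with lowest-index tie-break; multiclass
  AUC is macro one-vs-rest; binary AUC scores class 1. AUC is reported
  on the 0–100 scale, accuracy as a fraction.
* All randomness derives from one root seed through a counter-based
  SeedSequence scheme (per-layer projection seeds, per-batch noise
  seeds, harness subsample streams), so a whole run is reproducible
  from a single integer, and saved models regenerate their projection
  pairs from recorded seeds instead of storing them.

## Cost accounting

The `complexity` module evaluates closed-form per-layer MAC and memory
counts for one `m × m` dense layer (batch size 1; one inner iteration
for predictive coding). One MAC is one fused multiply-add;
nonlinearity evaluations are not counted. For forward projection the
forward count `N(2m² + m·m_L)` comprises the downstream activation plus
the two target projections; the update count `2Nm² + 2m³` comprises the
two sufficient-statistic accumulations plus an upper bound for the
one-off factorise-and-solve (a Cholesky solve needs about `m³/3 + m²m_L`
of it, and the instrumented counter verifies the measured fitting path
stays under the bound while the forward/target path matches its formula
exactly). Counts are exact Python integers.

## Synthetic tasks

The generators produce desk-scale analogues of the data families the
method targets, each a pure function of (parameters, seed), with
ground-truth saliency masks for the spatial tasks.

* **Tabular** (`make_tabular`): each class owns 4 Gaussian centres;
  samples get isotropic noise (sd 0.3) and pass through 2 fixed random
  tanh mixing layers. Multi-modal classes plus the warp make the
  observed decision surface nonlinear: across seeds, a logistic
  regression measurably underperforms a one-hidden-layer network (this
  is asserted in the suite). A single centre per class was rejected
  during design because any smooth warp of well-separated blobs stays
  linearly separable.
* **Motif sequences** (`make_motif_sequences`): 251-base uniform-ACGT
  sequences; positives carry one copy of a 6-mer (default `TATAAT`) at
  a random recorded offset. One-hot encoding is 4×L in channel order
  A,C,G,T with `N` as a zero column; FASTA export wraps at 60 columns
  with labels in a two-column CSV. A single short motif under global
  average pooling is deliberately hard (absolute AUCs are modest); the
  contrast of interest — structure-learning convolutional stacks
  beating fixed random filters — is robust across seeds.
* **Waveforms** (`make_waveforms`): 12-channel, 1000-sample
  quasi-periodic signals (three harmonics, random phases, white noise);
  positives add a Gaussian-bump transient of amplitude 2.0 over a
  200-sample window on 6 channels. The window is the saliency mask.
  These defaults emulate a persistent beat-scale morphology change on
  half the leads — the regime in which the planted feature is clearly
  learnable; brief low-amplitude bumps are nearly invisible to a
  global-average-pooled stack. Amplitude 0 gives an exact null task.
* **Images** (`make_images`): smoothed-noise textures in [0, 1] with
  bright Gaussian-blob lesions (contrast 0.5, radius 8, two blobs) and
  per-pixel masks; 8-bit PNG round trip is exact to 1/255.

What the generators do **not** emulate: physiological waveform realism,
sequence composition bias, class imbalance, label noise, or
inter-instrument variation. Passing tests demonstrate the mechanisms —
closed-form fitting, rank-ceiling collapse of label projection,
structural feature learning, decodable hidden layers — on clean planted
signals; they are not performance claims about any real dataset.

## Experiment designs in the suite

* **Bottleneck sweep**: three hidden layers (1000, 1000, m₃),
  m₃ ∈ {25, 50, 100, 200}, on the tabular task (n = 3500, noise sd 0.8,
  40% test split, five seeds), fitted with a near-zero absolute penalty
  (λ = 1e−8). The label-projection collapse is a regularisation-
  sensitive phenomenon: its targets have rank ≤ 10, so the downstream
  Gram matrices are near-singular, and a strong penalty would patch the
  null space and mask the degradation. Under the weak penalty, label
  projection's test AUC declines as m₃ grows while forward projection's
  does not — forward-projection Grams stay well-conditioned because the
  input term keeps them full-rank. The noisy baseline is not
  rank-limited and shows no collapse-driven decline; at this scale its
  AUC rises with width (its default noise dominates the label term, so
  it behaves like a random-feature expansion) rather than staying flat.
* **Few-shot harness**: repeated class-stratified subsampling without
  replacement at fixed shots per class, evaluation on a fixed held-out
  split. Common random numbers: the model seed and subsample stream
  depend only on the repeat index, pairing cells across shot counts so
  monotonicity in the shot count is assessed on paired means.
* **Problem sizes** throughout the suite (hundreds to a few thousand
  samples, widths ≤ 1000, two to four conv blocks) are the package's
  desk-scale defaults chosen so every mechanism is exercised end to end
  with stable statistics across five seeds.

## Known limitations

* The convolutional target construction (per-position label broadcast)
  is this package's documented realisation; other patch-wise or
  feature-map-level constructions are conceivable.
* Explanations are undefined for layers fitted in `rf` or
  label-projection modes (no projection pair participates in the fit);
  the API refuses them rather than returning something misleading.
* No iterative/online ridge updates, no bias terms by default (callers
  may append a constant-1 column), no batch normalisation, no attention
  layers, no GPU path.
* The modulo and polynomial activations are supported and tested for
  totality/finiteness, not benchmarked.
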