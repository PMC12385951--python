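# Methods

## Problem

Scalp and intracranial EEG from people with epilepsy shows
class-dependent structure at two very different temporal scales: local
waveform shape (spikes, sharp transients, a few tens of milliseconds)
and longer rhythmic organization (ictal discharges, slow modulation,
hundreds of milliseconds).  The package classifies fixed-length
single-channel EEG windows into diagnostic categories (healthy /
interictal / ictal, or finer splits) with a convolutional network that
addresses both scales explicitly, and evaluates the classifier with a
cross-validation protocol that reports uncertainty.

## Model

For an input window x of shape (channels, T), T divisible by 4:

**Residual convolution module (RCM).**  Two residual blocks of widths
64 and 128.  Each block's main path is conv(k=5, stride 2) – BN – ReLU –
conv(k=5, stride 1, dilation 2) – BN; the shortcut is a 1×1 convolution
(stride 2) followed by BN; the two are summed and passed through ReLU,
then dropout 0.3.  Each block halves the temporal length, so the module
maps (1, T) → (128, T/4).  The residual form `y = h(x) + F(x; θ)`,
`x' = ReLU(y)` keeps gradients well-conditioned for the deeper layers.

**Dilated convolution pyramid module (DCPM).**  Five cascaded
conv(k=5, stride 1) – BN – ReLU layers of width 128 with dilation rates
1, 2, 4, 8, 16 and symmetric padding d·(k−1)/2, so the temporal length
is preserved.  The receptive field of a stride-1 dilated cascade is

    RF = 1 + Σᵢ (kᵢ − 1) · dᵢ

which for this stack is 1 + 4·(1+2+4+8+16) = 125 samples — roughly
720 ms of signal at 173.61 Hz — without the parameter cost of a single
125-tap kernel.  The empirical check used in the tests measures the
*span* of input positions whose gradient w.r.t. one output position is
nonzero; for a single dilated layer the influencing positions are
isolated (k taps spaced d apart) and the field is their extent, which
interior layers of a cascade progressively fill in.

**Feature fusion and enhancement module (FFEM).**  Two complementary
per-channel summaries of both the RCM output ("branch" pathway) and the
DCPM output ("main" pathway):

* global max pooling — the most salient activation per channel;
* differential entropy — `H = ½ ln(2πe(σ² + ε))` with σ² the unbiased
  (N−1) variance over time and ε = 1e−6 a stability constant.  This is
  the Gaussian closed form evaluated on the channel's empirical
  variance: a statistic of activation *dispersion* that is invariant to
  temporal permutation and additive shifts and grows with ln σ.

Each of the four 128-vectors passes through its own batch normalization
(the feature types live on very different scales) and they are
concatenated in the fixed order (pooled-branch, pooled-main,
entropy-branch, entropy-main) into a 512-dimensional representation.

**Classifier.**  BN – ReLU – dropout 0.5 – linear → C logits; softmax
for probabilities.

**Parameter accounting.**  Convolutions followed by BN carry no bias
(the BN shift absorbs it); the final linear layer keeps its bias; BN
contributes scale and shift per channel.  Under these conventions the
default five-class single-channel model has exactly 568,581 trainable
parameters (ResBlock1 21,248; ResBlock2 131,840; DCPM 410,880; FFEM
1,024; head 3,589), i.e. ≈569 k.

**Ablation switches.**  `use_rcm=False` replaces the RCM with a minimal
adapter (1×1 convolution to the pyramid width, then stride-4 max
pooling to keep the T/4 scale); the adapter output serves as the branch
pathway.  `use_dcpm=False` routes the RCM output to both fusion
pathways, so the fused width and head are unchanged and the parameter
delta is exactly the pyramid block (410,880).  `use_entropy=False`
fuses only the two pooled vectors (width 256).  Disabling both
convolutional modules is rejected.

## Entropy descriptor variants

For the sensitivity study the fusion entropy can be switched to Shannon,
Rényi, spectral or Tsallis entropy.  The discretizing kinds histogram
each channel into 16 equal-width bins over its own min–max range
(Rényi order and Tsallis q default to 2); spectral entropy applies the
Shannon formula to the channel's normalized periodogram with the DC bin
removed (offset carries no oscillatory information).  These estimator
details are choices of this package — reasonable defaults for a
sensitivity study, not canonical definitions.  Because histogram counts
are piecewise-constant in the underlying values (and the periodogram
variant is likewise treated as a fixed transform), these descriptors
pass no gradient to the convolutional trunk; only the pooled pathway
trains it.  Differential entropy, the default, is smooth and fully
differentiable, which is one of the arguments for preferring it.

## Training

Label-smoothed cross-entropy: targets `ỹ = (1−α)·onehot + α/C` with
α = 0.2, loss `−1/N Σᵢ Σⱼ ỹᵢⱼ ln pᵢⱼ` with a 1e−12 probability floor.
Adam with learning rate 5e−4, L2 weight decay 1e−4 folded into the
gradient, batch size 64, at most 100 epochs, per-step gradient clipping
at global norm 1.0.  Early stopping monitors the *training* loss
(patience 10 epochs, minimum improvement 1e−4) — no validation split
exists in the protocol, because model selection is training-set based:
the retained checkpoint is the epoch with the highest training
accuracy, ties broken by lowest training loss, then earliest epoch.
Training accuracy is the running accuracy of the optimization passes
(i.e. computed with dropout active), which costs nothing extra; this is
the quantity the selection rule sees.

Reproducibility: one seed drives weight initialization, the per-epoch
shuffles (each epoch derives its own child seed) and every dropout
mask, so identical configurations produce bitwise-identical histories.

## Preprocessing and augmentation

Records are cut into consecutive non-overlapping windows of 512
samples, 0-based half-open; remainder samples are dropped (a 4097-sample
record gives 8 windows and 1 dropped sample).  Training segments are
augmented as `x = S + α·σ·n` with α = 0.01, n i.i.d. standard normal and
σ the *population* standard deviation of the segment itself — the
augmentation runs after segmentation and after the train/test split, so
test data are never perturbed and no statistics leak across the split.
Two copies per original (the default) triple the training set.  Whether
σ should be per-segment or per-record is not determined by the
protocol's description; per-segment is used because augmentation
follows segmentation in the pipeline order, and the choice is pinned
for reproducibility.

## Evaluation

Stratified k-fold cross-validation over segments (default), or over
records (`group_by_record=True`) when all windows of a recording must
share a fold.  Segment-level splitting matches the granularity at which
the published per-fold accuracies move; it does allow windows of one
recording on both sides of a split, which is why the grouped mode
exists — subject-independent validation is a known limitation of this
class of protocol, not something a record-level split alone can fix.

Per fold: accuracy, macro-averaged precision/recall/F1, and the
class-frequency-weighted F1 (the metric of choice under class
imbalance), all in percent, plus the confusion matrix.  Aggregates:
mean, sample standard deviation, and the t-based 95% confidence
interval `mean ± t(0.975, k−1) · s/√k`.  Interval upper bounds may
exceed 100%; truncation to 100 is applied only for display, never to
stored values.  Display rounding is half-up to 2 decimals.

## Synthetic data generator

Emulates the corpus geometry (5 classes × 100 records × 4097 samples at
173.61 Hz) with, per record: an AR(2) baseline (coefficients 1.5,
−0.56; poles at 0.7 and 0.8, giving a 1/f-like spectrum), a
class-specific sinusoid (center frequencies 3/8/14/22/32 Hz, amplitude
growing with class index), and, for the last class, 3–6 ictal-like
spike-wave bursts of 0.5 s at 5 Hz with amplitude 5× the baseline
standard deviation.  In `easy` mode amplitude jitter is 5%, separating
class band-power means by several within-class standard deviations (a
logistic regression on closed-form band-power features alone is nearly
perfect — this network-free oracle is tested); `hard` mode uses 60%
jitter so classes overlap at roughly one standard deviation.  The
generator reproduces none of the nonstationarity, artifacts, channel
variability or patient heterogeneity of clinical EEG: passing tests on
it demonstrates that the pipeline is wired and optimized correctly, not
that the architecture's clinical accuracy transfers.

## Numerical conventions

* All network arithmetic in float32; convolutions evaluated as k
  BLAS matrix products over dilated strided slices (no im2col buffer).
* Batch normalization uses population (biased) variance for both batch
  statistics and running buffers (momentum 0.1); evaluation mode uses
  the running buffers.
* He-normal weight initialization, seeded.
* Softmax is max-shifted; the loss floors probabilities at 1e−12.
* Stratified splitting, metrics and t quantiles come from
  scikit-learn and SciPy; the network and optimizer are this package's
  own code.

## Test problem sizes

The test suite trains at three scales, chosen so the whole suite runs
on a single CPU in well under half an hour: unit and property tests use
a narrow variant of the architecture (widths 8/16, identical wiring);
optimization smoke tests use 30-record datasets with the default-width
model; and the end-to-end cross-validation smoke uses the full 500
record easy dataset: the default-width model for a single-seed 3-fold
accuracy check (2 epochs — enough on separable data), and a
width-reduced variant (16/32 residual channels, 32-channel pyramid,
8 epochs, no augmented copies) for the three-seed comparison of the
complete architecture against its own w/o-pyramid ablation on
identical splits.  At reduced width the pyramid's contribution is
material rather than saturated, which makes the comparison
informative; at full width both variants approach 100% on easy data
and the ordering degenerates to segment-level noise.

## Known limitations

* Training is CPU-bound NumPy; a full 10-fold run on the real corpus at
  default width is hours, not minutes.  The library is sized for
  method-level verification and small studies.
* No filtering, artifact handling or resampling: records are consumed
  raw, as in the underlying protocol.
* Non-differential entropy variants do not backpropagate through the
  entropy pathway (see above), so their comparison isolates the
  *descriptor*, with the trunk trained by the pooled pathway alone.
* Multi-channel inputs are supported by configuration
  (`in_channels > 1`) but no montage construction or per-channel
  preprocessing is provided.
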