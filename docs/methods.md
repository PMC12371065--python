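# Methods

`handtremor` detects Parkinson's disease from offline handwriting drawings
(Archimedean spirals and meanders, as collected in the HandPD protocol). The
pipeline has three stages — adaptive denoising, hand-crafted + deep feature
extraction, and a two-branch neural classifier with mean-score fusion — plus
a synthetic drawing generator that defines the study conditions under which
the package validates itself. This note records the models, the parameters
that matter, the numerical choices, and what the synthetic experiments do and
do not demonstrate.

## Synthetic drawing model

Real Parkinsonian drawings differ from controls mainly through tremor
(oscillatory deviation from the intended trace) and micrographia (progressive
shrinking). The generator renders a base curve — a spiral `r(θ) = a + b·θ`
or a square-wave meander of shrinking extent — and perturbs it radially
(spirals) or along the local normal (meanders) with

```
offset(t) = A · sin(2π f t + φ) + W(t),
```

where `t` counts turns of the trace, `A` is the tremor amplitude in pixels,
`f` the tremor frequency in cycles per turn, and `W` a seeded Gaussian random
walk (per-step sd `jitter_sd`). Micrographia multiplies the base radius by
`decay^t`. Class conditions are fixed package-wide: healthy `A = 1 px`,
patient `A = 6 px` with `decay = 0.93` — effect sizes at which a
single-feature baseline (below) is strong but not saturated, so the
end-to-end comparison is informative. Images are 96×96, 2-px strokes on a
white background with a 1-px soft halo; Gaussian and salt-and-pepper noise
can be injected afterwards. All randomness flows from one integer seed
through `numpy.random.SeedSequence` spawning, so any drawing is reproducible
in isolation.

What the generator does **not** emulate: pen-pressure/velocity dynamics,
paper texture, scanning artifacts, stroke-width variation, or the template
form lines present in real HandPD crops. Passing the synthetic experiments
therefore shows the pipeline's machinery is sound and that it can separate
tremor-defined classes; it does not certify accuracy on real scans.

`mean_radial_deviation` computes the mean distance between the perturbed and
ideal trace from the path model directly. A logistic regression on this one
number is the baseline the full pipeline must match: with the default effect
sizes it reaches ≈0.95–1.0 accuracy, so it is a demanding reference.

## Modified Wiener preprocessing

Both Wiener variants are spatial, local-statistics filters on 3×3 windows
(reflect padding everywhere). The *conventional* filter shrinks each pixel
toward its local median by `clamp((σ² − u²)/σ², 0, 1)`, where σ² is the
windowed mean squared deviation about the local *geometric* mean and the
noise power u² defaults to the mean of the local variances ("auto").

The *modified* filter sums two per-pixel brackets and renormalizes:

* **Branch A** applies the median mask first and computes its statistics on
  the median-filtered image — this decouples the local statistics from
  impulse outliers and is the branch that does most of the denoising.
* **Branch B** brightens the input (gain 1.2, clipped), convolves it with an
  "improved Gaussian" kernel — a Gaussian plus a Laplacian-of-Gaussian term
  divided by `sqrt(|c² + r² − 2σ²·e^{−(c²+r²)}|)` — and applies the same
  shrinkage form with branch-B's local median and geometric mean.

Numerical choices, each of which was forced by a degeneracy:

* The kernel radicand is negative near the origin. Flooring the *signed*
  radicand at ε makes the origin's denominator √ε ≈ 10⁻³ and the kernel
  collapses into a near-negative identity; we floor the radicand's
  *magnitude* instead, which is identical wherever the radicand is positive.
  Default geometry σ = 1.5, half-width 1: all nine weights positive, unit DC
  gain. The kernel is normalized by the sum of absolute weights because the
  Laplacian term can produce negative weights at other settings.
* Geometric means floor pixels at 1.0 (one 8-bit level). A floor of ~10⁻⁶
  sends `log` to −13.8 and the windowed geometric mean of any window touching
  ink to ≈0, which inflates every local variance.
* The sum of the two brackets roughly doubles intensities, so the default
  output normalization is a min-max rescale to [0, 255] using the 0.5/99.5
  percentiles (then clip): a handful of overshoot pixels otherwise stretch
  the range and lift all ink values. `combine="mean"` and plain clipping are
  available; under the rescale they coincide with the sum.
* Shrinkage factors are clamped to [0, 1] so `u² > σ²` cannot invert signs;
  divisions are ε-stabilized; constant images map to the mid-range value.

**Known limitation.** On thin-stroke synthetic drawings the improved-Gaussian
branch is inherently a short-range smoother — no setting of the printed
kernel formula approximates an identity response — so the unweighted
two-branch sum lands a few dB below the conventional filter in PSNR. Over the
100-drawing comparison at noise sd 15 the mean PSNRs are: noisy input
27.0 dB, conventional Wiener 26.0 dB, modified Wiener 23.3 dB — i.e. neither
adaptive filter wins in PSNR at this stroke scale, where the median mask
itself erodes 2-px strokes. In *structural* similarity the expected ordering
does hold: SSIM 0.920 (modified) > 0.910 (conventional) > 0.764 (noisy) — the
modified filter preserves stroke structure best even though its global
intensity mapping costs PSNR. Both metrics are reported by the filter
comparison experiment. This behavior is a property of the operator
definitions, not of the implementation: the vectorized filters match
independent per-pixel references to 1e-9.

PSNR uses `10·log10(255²/MSE)` with an infinity sentinel for identical
images; SSIM is scikit-image's mean structural similarity (7-px windows,
data range 255).

## Feature extraction

**Gradients.** `U_X = HI * [-1 0 1]`, `U_Y` with the transposed kernel
(correlation, reflect padding). Orientation follows the arctan convention
(−π/2, π/2], defined as 0 where both derivatives vanish; histogramming uses
`atan2` folded to [0°, 180°) (unsigned mode, the classic PHOG edge
convention; signed mode available).

**Improved entropy and the modified gradients.** The gradient operator is
augmented by a scalar "improved entropy" IE: each derivative map is
histogrammed (K = 8 bins of |values|), the bins act as singleton focal
elements of an evidential mass function (so every cardinality term
`2^|M| − 1` equals 1), and the entropy is

```
[ −Σ a·log2( (a + 1) / |a·log2 a| ) ] / [ Σ ( a·log2 a + sigmoid(log2 a) ) ]
```

with the inner product floored at 10⁻¹², the denominator floored in
magnitude, and the result clamped to ≥ 0. IE is the larger of the two map
entropies when they differ by more than 10⁻⁶, otherwise their mean (the
evenly-distributed case), and is added uniformly to both derivative maps
before orientation and magnitude are recomputed. The construction is the
only one computable from a gradient map alone; its value is invariant to
histogram-bin permutations and to rescalings that preserve bin assignment.

**PHOG.** Level l splits the image into 2^l × 2^l cells (integer
boundaries); each cell accumulates gradient magnitude into K orientation
bins; levels 0..L are concatenated (L = 2, K = 8 → 168 values) and
L1-normalized. Unnormalized level sums each equal the total gradient mass.

**Shape.** Ink is foregrounded by Otsu thresholding the inverted image; the
largest marching-squares contour is measured as a polygon (shapely): area,
perimeter, convex-hull area and vertex count, and the contour-approximation
tolerance ε = 0.01 × perimeter.

**Deep features.** VGG16 (13 conv layers, → 512) and ResNet-50 (→ 2048)
forward passes truncated at global average pooling, implemented in numpy.
Weights are He-normal draws from the config seed, which keeps the package
fully offline and deterministic — random convolutional features are a
recognized, surprisingly strong representation, but they are *untrained*;
supplying trained weights via `weights_mode="pretrained-file"` is supported
and a missing file is an error, never a silent fallback. ResNet's
normalization layers are realized as per-channel instance normalization so
activation scales stay bounded through 50 layers for any weight draw. The
pipeline default uses VGG16 at 64×64 input, trading a little representational
power for a ~3× faster feature pass.

**Fusion.** `Ff = [PHOG | shape | deep]` with a recorded segment layout;
train-set mean/sd standardization is stored in the layout and applied to
both splits.

## Classifier branches

Both branches consume Ff reshaped row-major into a square single-channel
map, zero-padded to a side that is a multiple of 4 (default features → 28×28,
padded further to 32×32 in the canned experiment configs). They are built on
a small numpy reverse-mode autodiff layer (`handtremor.nn`) whose operators
are gradient-checked against central differences.

**GhostNet.** Stem 3×3 stride-2 convolution (16 channels), four ghost
bottlenecks (widths 16/24/40/80, strides 1/2/2/2, expansion ratios per
config), global average pooling, linear head. A ghost module with ratio s
produces out/s channels densely and the rest by depthwise transforms; its
convolution weight count is `in·(out/s)·k² + (out/s)(s−1)·d²`, strictly below
the dense `in·out·k²` for s ≥ 2. Stride-2 bottlenecks downsample through a
depthwise layer with a depthwise+pointwise projection shortcut; the second
ghost module omits its activation before the residual add.

**Improved LinkNet.** Encoder 1: conv→BN→LeakyReLU→average pool; encoder 2:
conv→BN→ELU followed by a parallel combination of average pooling and mixed
pooling (`λ·max + (1−λ)·avg`, λ = 0.5) at stride 2; encoder 3: conv→BN→Swish,
no pooling. The MDSCM block filters the input with three fixed Gabor kernels
(θ ∈ {0°, 45°, 90°}, wavelength 8 px, envelope σ 4, aspect 0.5, zero-DC),
convolves with 3×3 / 5×5 / 7×7 kernels (stride 1 — the only reading of the
"strides" consistent with concatenation), batch-normalizes, XOR-fuses each
branch with its encoder's output, and concatenates. XOR on real maps is
undefined; the default is the differentiable soft form |a − b|, with a
thresholded binary mode available. Decoders upsample (nearest + conv) with
additive skips from the matching encoders and are normalized by **WAP-BN**:

```
S_J = (1 − γ)·mean(window);   out = S_J·(Z − μ_B) / sqrt(σ_B² + sigmoid(S_J) + ε)
```

with the window being the full per-sample, per-channel map. At γ = 1 the
pooled statistic — and hence the whole output — vanishes identically; this
degeneracy is pinned by a regression test and the shipped default is γ = 0.5.
Encoder widths default to 8/16/32, deliberately narrow so both branches train
in minutes on one CPU at the package's desk-scale problem sizes; widths are
config fields.

**Training and fusion.** The branches are trained independently with Adam
(lr 10⁻³, batch 16, 20 epochs, cross-entropy); batches smaller than 2 are
skipped because batch statistics need two samples. Inference averages the two
per-class probability vectors (a logits-averaging mode exists); the argmax is
the detection. All weights initialize He-normal from a single config seed,
and inference is bit-reproducible.

## Evaluation

Positive class is *patient* throughout. From the confusion matrix the suite
reports accuracy, sensitivity, specificity, precision, F-measure, MCC, NPV,
FPR, FNR, FDR; each error rate is computed as `1 −` its complement, so the
three complement identities hold to machine precision. Ratios with an empty
margin are an explicit undefined sentinel, serialized as JSON `null`. ROC
curves and trapezoidal AUC come from scikit-learn's threshold sweep over the
fused patient-class probability.

## Problem sizes

The canned experiments use 400 drawings (200 per class, 96×96), an 80/20
stratified split, and 20 training epochs; the denoiser comparison uses 100
drawings at noise sd 15. These sizes were chosen so the full validation
(including training both branches) completes comfortably on a single CPU
while leaving the class-separation problem non-trivial.

## Known limitations

* The synthetic generator's realism gap (above) bounds what the experiments
  claim about real HandPD scans.
* The modified Wiener filter underperforms the conventional filter on
  thin-stroke drawings (see preprocessing section).
* Deep features are random-weight embeddings unless trained weights are
  supplied.
* The improved-entropy functional is one computable reading of an evidential
  entropy over image histograms; other readings exist, and downstream results
  are not sensitive to the choice at the package's problem sizes.
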