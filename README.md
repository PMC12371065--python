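# handtremor

Detection of Parkinson's disease from offline handwriting drawings — spirals
and meanders of the kind collected in the HandPD protocol. Parkinsonian
drawings show tremor (oscillatory deviation from the intended trace) and
micrographia (progressive shrinking); `handtremor` turns a folder of drawing
images into a healthy/patient decision through three stages:

1. **Modified Wiener preprocessing** — a two-branch spatial adaptive filter:
   a median-masked local-statistics Wiener branch plus an improved-Gaussian
   (Gaussian + Laplacian-of-Gaussian) filtered branch, summed per pixel
   `Q = [med + (σ²−u²)/σ²·(HI−med)] + [med₁ + ((σ²)′−u²)/(σ²)′·(HI−ρ)]`
   and renormalized. Conventional Wiener, Gaussian and median comparators and
   PSNR/SSIM reporting are included.
2. **Feature extraction** — modified PHOG (pyramid histograms of oriented
   gradients whose derivative maps are augmented by an evidential "improved
   entropy" scalar IE: `U_X = HI*K_X + IE`), polygonal shape descriptors
   (area, perimeter, convex hull, contour-approximation ε), and deep
   embeddings from seeded VGG16 / ResNet-50 forward passes; fused as
   `Ff = [PHOG | shape | deep]` with train-set standardization.
3. **Hybrid classification** — a GhostNet branch (ghost modules generate
   most feature maps with cheap depthwise transforms) and an Improved
   LinkNet branch (three encoders with LeakyReLU/ELU/Swish activations,
   Gabor-based multi-kernel MDSCM fusion via soft XOR, and weighted-average-
   pooling batch normalization `S_J·(Z−μ_B)/√(σ_B²+sigmoid(S_J)+ε)` in the
   decoders), trained independently and fused by averaging their class
   probabilities: the detection is `argmax` of the mean score.

A synthetic spiral/meander generator with a parametric tremor + micrographia
model makes the whole pipeline runnable and testable without external data.
The classifier branches run on a small numpy reverse-mode autodiff layer
(`handtremor.nn`), so no deep-learning framework is required.

The package is aimed at researchers studying handwriting-based PD screening
who want a transparent, fully reproducible reference implementation of this
pipeline family, and at method developers who need a controlled synthetic
benchmark for drawing-based classifiers.

## Worked example

```python
from handtremor.experiments import scaled_down_detection
report = scaled_down_detection("work", n_per_class=200, epochs=20, seed=1)
print({k: report[k] for k in ("accuracy", "auc", "confusion", "branches",
                              "baseline_accuracy")})
```

prints (about two and a half minutes on one CPU):

```
{'accuracy': 1.0, 'auc': 1.0,
 'confusion': {'tp': 40, 'fp': 0, 'fn': 0, 'tn': 40},
 'branches': {'improved_linknet_accuracy': 1.0, 'ghostnet_accuracy': 1.0},
 'baseline_accuracy': 0.9875}
```

Reading the numbers: 400 synthetic drawings (healthy tremor amplitude 1 px
vs patient 6 px with micrographia decay 0.93) are split 320/80; both
classifier branches and their mean-score fusion classify the 80 held-out
drawings perfectly (fused AUC 1.0), while a logistic baseline on the single
mean-radial-deviation statistic — a strong reference, since it reads the
tremor amplitude almost directly — reaches 0.9875. The value of the full
pipeline is that it recovers this separation from pixels alone.

The denoiser comparison over 100 noisy drawings (Gaussian sd 15):

```python
from handtremor.experiments import filter_comparison
filter_comparison(n_images=100, gaussian_sd=15.0, seed=0)
```

```
{'psnr_noisy': 27.04, 'psnr_conventional': 26.01, 'psnr_modified': 23.26,
 'ssim_noisy': 0.764, 'ssim_conventional': 0.910, 'ssim_modified': 0.920}
```

In structural similarity the modified filter ranks first; in PSNR it pays
for its global intensity renormalization (discussed in `docs/methods.md`).

A command-line interface mirrors the library:

```bash
handtremor synth generate out/ --n-per-class 50 --seed 1
handtremor manifest build data/ --out manifest.csv
handtremor manifest augment manifest.csv aug/ --healthy-multiplier 9 --patient-multiplier 2
handtremor pipeline train manifest.csv --out-dir model --epochs 20
handtremor pipeline evaluate test.csv --weights model --report report.json
```

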