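# Methods

This document records the mathematical model, the network and training
configuration, the numerical choices behind the implementation, and the known
limits of the synthetic-data generator. The package is pure Python + NumPy;
the tensor engine under `despeckle.nn` is a small reverse-mode autodiff
library written for this project (see "Numerical choices").

## 1. Observation model

Ultrasound speckle is modelled as signal-dependent additive noise

```
v(x) = u(x) + u(x)^r · θ(x),      θ(x) ~ N(0, σ²) i.i.d.
```

where `u` is the latent clean image, `v` the observed image, and `r` controls
how noise strength couples to local brightness. Defaults are `r = 0.5`
(speckle: noise standard deviation grows like √u) and `σ` quoted on the 8-bit
scale; internally images live on the unit scale `[0, 1]` and the model uses
`σ_u = σ / 255`. Setting `r = 0` recovers brightness-independent additive
Gaussian noise, which the tests use as a control. After corruption the result
is clipped to `[0, 1]` by default (`clip=False` is available for moment
studies; the clipped model is what training and evaluation use).

Moments under the unclipped model, used as test oracles: for a constant patch
of brightness `u`, `E[v] = u` and `Var[v − u] = u^{2r} σ_u²` (so `u σ_u²` at
`r = 0.5`).

All sampling uses `numpy.random.Generator` seeded through
`numpy.random.SeedSequence([seed, tag, index])` with a fixed per-purpose tag,
so every artifact is reproducible bit-for-bit from one integer seed and
corruption of image *i* is independent of how many images precede it.

## 2. Synthetic phantoms

`despeckle.phantom` draws piecewise-smooth tissue-mimicking phantoms: a
low-frequency background gradient, a configurable number of elliptical
inclusions with a minimum contrast to their surroundings, optional Gaussian
blur of the boundaries, and a final clip to `[0, 1]`. Defaults (64×64 px,
2–4 inclusions, contrast floor 0.15) are the study conditions; they were
frozen before any training outcome was observed and are not tuned.

Realism limits, stated explicitly:

- Phantoms are piecewise-smooth cartoons. They contain edges, ramps and flat
  regions but none of the granular tissue texture, attenuation, shadowing or
  point-spread anisotropy of real B-mode ultrasound.
- The speckle model is the first-order signal-dependent Gaussian model above,
  not a physical multiplicative Rayleigh/Nakagami model; it matches the
  training-data recipe, not the physics of an imaging system.
- Consequently, scores obtained on phantoms measure whether the pipeline
  learns this noise model on this image class. They are not claims about
  clinical images.

## 3. Generator

`DenoisingUNet` is a 4-level encoder–decoder with channel plan
(128, 256, 512, 1024) at full width:

- Each encoder level is a residual dense connectivity block (RDCB) followed
  by 2×2 max-pooling. An RDCB has three 3×3 conv+BN+ReLU stages whose inputs
  are the concatenation of the block input and all previous stage outputs,
  a 1×1 projection back to the block width, and an identity skip added to
  the projection.
- The bottleneck is one RDCB at the widest plan entry.
- Each decoder level upsamples by sub-pixel convolution (a 3×3 conv to 4×
  channels followed by a depth-to-space pixel shuffle), concatenates the
  same-scale encoder skip, and applies an RDCB.
- A final 3×3 conv with bias maps to one channel; the network predicts the
  denoised image directly (no global residual).

The ablation `dense_connectivity=False` keeps the same three stages but feeds
each stage only its predecessor's output, which strictly reduces parameter
count at equal width. `GeneratorConfig.scaled(k)` divides the plan by `k`
for desk-scale runs; topology is unchanged.

Odd input sizes are handled by reflect-padding the bottom/right before each
pooling and cropping after the matching upsample, so any input of at least
16 px per side maps to an output of identical size.

## 4. Discriminator

`PatchCritic` is a 10-conv patch critic with plan
64, 64, 128, 128, 256, 256, 512, 512, 512, 1 (stride 2 on every second conv
of the first eight). Stride-2 convs use one-sided (top/left) padding so a
40×40 patch passes 40 → 20 → 10 → 5 → 2. The final 3×3 conv carries a bias
and no BN, ReLU or sigmoid: it emits unbounded logits, as required by the
BCE-with-logits losses. The scalar patch score is the mean of the logit map.
Convolutions that feed a BatchNorm carry no bias anywhere in the package
(a bias before BN has identically zero gradient, which would violate the
full-gradient-flow requirement).

## 5. Objective

The generator minimises

```
L = λ₁·L1(fake, clean) + λ₂·L_per(fake, clean) + λ₃·BCE(D(fake), 1)
```

with λ = (1, 0.1, 1). `L1` is the sum of absolute errors over the batch
tensor. `L_per` is the squared L2 distance between feature maps from a
pluggable extractor; the default `random_convnet` backend is a frozen,
seeded, randomly initialised conv stack (a `vgg19` backend slot exists but
requires external weights, which the offline environment does not ship — it
raises a clear `FileNotFoundError`). An `identity` extractor turns `L_per`
into a plain squared L2, which the tests exploit as an oracle. The critic
minimises `BCE(D(clean), 1) + BCE(D(fake.detach()), 0)`.

## 6. Training protocol

Full profile (the study conditions, `TrainConfig()` defaults): 40×40 random
crops, one per training image per epoch, batch 32, dihedral-8 augmentation,
fresh speckle drawn per crop per epoch, Adam at 1e-4 halved every 2000
epochs, 8000 epochs, update ratio 1:1 with the critic updated first on
detached generator output, three independent repeats from derived seeds.

Desk profile (`TrainConfig.smoke()`): 1/8-width plans, batch 4, 64×64
patches (the full phantom frame), Adam at 1e-3 with the halving period
compressed to 1 epoch. Two lessons from failed smoke runs are ledgered and
reflected here:

- Adam on the constant-magnitude sign gradient of an L1 sum oscillates with
  amplitude proportional to the learning rate; without decay the error floor
  sits near the noise level. The full protocol's own step decay, compressed
  into the short run, removes the floor.
- A 4-level U-Net trained only on 32×32 patches (2×2 bottleneck) does not
  transfer to 64×64 inference (4×4 bottleneck): the same checkpoint gained
  +3 dB on held-out 32×32 patches and lost 9 dB on full frames. Training and
  evaluation geometry must match, so the desk profile trains on full frames.

## 7. Evaluation

PSNR is `10·log10(vmax²/MSE)` with a 100 dB cap for exact matches. SSIM is
scikit-image's `structural_similarity` with the standard Gaussian-window
configuration (11×11 window, σ = 1.5, sample covariance off); the test suite
pins it against an explicit windowed reimplementation. Scores across repeats
are reported as mean ± sample standard deviation (ddof = 1). Method
comparison uses the Friedman rank test: within each image, methods are
ranked so the best method receives rank k (ties averaged), and the statistic
and p-value come from `scipy.stats.friedmanchisquare`; an all-tied table
degenerates to statistic 0, p = 1.

## 8. Numerical choices

- No deep-learning framework is available in the target environment, so
  `despeckle.nn` implements a minimal reverse-mode tensor engine on NumPy:
  NHWC layout, float32 by default, convolution as one batched `matmul` per
  kernel offset over strided views, transposed-kernel convolution for the
  input gradient. Every operator's gradient is verified against central
  finite differences in the test suite.
- `backward()` releases each interior node's gradient as soon as its closure
  has consumed it, roughly halving peak memory of a training step.
- On glibc, the allocator is tuned at import (`mallopt`: large mmap/trim
  thresholds) because the default 128 KiB mmap threshold makes every
  multi-megabyte feature map a fresh `mmap`/`munmap` pair whose page faults
  dominate runtime on a single CPU. The training loop calls `malloc_trim`
  between epochs so the resident set stays bounded despite the tuning.
- Determinism: there are no nondeterministic kernels to disable — all
  randomness flows through seeded `numpy.random.Generator` instances, and
  BLAS runs single-process — so repeating a configuration reproduces the
  loss trace bit-for-bit.

## 9. Limitations

- The full-width generator has ≈4.9×10⁸ parameters (~2 GB as float32);
  construction and single forwards are tested, but full-profile training is
  far outside a single-CPU budget. All trained results in this repository
  come from the desk profile.
- The `random_convnet` perceptual backend is a stand-in with the right
  structure (frozen conv features), not a pretrained perceptual metric; its
  weights are random.
- PSNR/SSIM gains are measured on the synthetic phantom class under the
  stated noise model only; see §2 for what that does and does not support.
- The Friedman test reports ranks and a p-value; no post-hoc pairwise tests
  are implemented.
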