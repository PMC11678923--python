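# Methods

`volgan` implements a complete 3D generative-adversarial stack for volumetric
grayscale bone imagery: data preparation, two generator families, Wasserstein
training, hybrid GAN inversion, latent-space semantics, and a validation
suite. This note records the models, the numerical choices, and what the
bundled synthetic data does and does not establish.

## Numerical substrate

All networks run on a small reverse-mode automatic-differentiation engine over
numpy arrays (`volgan.autodiff`). Every vector–Jacobian product is itself
composed of differentiable primitives, so gradients of gradients are exact —
the property the critic's two-sided gradient penalty needs, since its update
differentiates through `grad(f(x̃), x̃)`. Convolutions are evaluated as 27
shifted `tensordot` contractions (one per kernel offset) rather than a single
im2col matrix product; at the volume sizes used here this is both faster and
an order of magnitude lighter on peak memory. The adjoint family
(convolution, input-gradient, weight-gradient) is closed under
differentiation and is verified against central finite differences at first
and second order in the test suite. Networks compute in float32; python
scalars entering an expression adopt the tensor operand's dtype so float64
test oracles remain exact.

## Preprocessing

Raw scans have a fixed axial slice count (168) and variable in-plane extents.
The pipeline maps them to a homogeneous training set:

1. **Pad/crop** to 168 × 576 × 448, centred; padding mirrors the volume
   symmetrically including the edge voxel.
2. **Spectral noise synthesis**: the padded volume's orthonormal type-II
   discrete cosine coefficients are clipped to ±0.001 and transformed back.
   The result is a noise volume with the scan's own spectral envelope but no
   coherent structure. The DCT type is a convention choice; orthonormal
   type-II makes the clip bound scale-meaningful.
3. **Blending**: padded voxels are replaced by the noise volume, so borders
   contain plausible scanner noise rather than mirrored bone.
4. **Subsampling** by 2 per axis to 84 × 288 × 224, as a 2× block mean
   (anti-aliased; plain decimation is available via `subsample_mode`).
5. **Stack extraction**: four overlapping 32-slice stacks at start offsets
   `round(linspace(0, 84−32, 4)) = {0, 17, 35, 52}` — evenly spaced with the
   endpoints anchored so the union covers every slice.
6. **Augmentation** (optional): per stack one in-plane rotation uniform in
   [−10°, 10°] and one central zoom-in uniform in [1, 1.15], bilinear
   in-plane. Zoom-out is rejected because it would expose voxels with no
   defined content. Augmentation is treated as epoch-level resampling, not a
   fixed multiplied dataset.

## Generators and critic

Both generators share a progressive-growing skeleton over five stages. The
full grid `(d1, d2, d3)` must be divisible by 32; stage *k* emits images at
`grid / 2^(5−k)`, so the final output is 32× the initial tensor's extent per
axis. Channel widths follow `(8c, 8c, 4c, 2c, c)`.

* **Progressive generator**: dense layer from the 512-dim standard-normal
  latent to the `8c`-channel base tensor, then per stage nearest-neighbour
  upsampling and two 3×3×3 convolutions with leaky ReLU (slope 0.2) and pixel
  normalization. A 1×1×1 to-image convolution exists per stage; during stage
  growth the new stage's image is blended with the upsampled previous image
  by a fade weight α.
* **Style generator**: an 8-layer fully connected mapping network sends
  `z → w`; 15 affine heads (three per stage, biases initialised to one)
  produce per-layer styles. Each styled convolution modulates its kernel per
  input channel by the style and demodulates each output channel to unit
  composite norm (implemented in the equivalent input-scaling form so one
  convolution serves the batch; output is invariant to positive rescaling of
  the style). After each convolution one spatial noise map, scaled by a
  learnable scalar initialised at zero, is added identically to every
  channel. Synthesis starts from a learned constant tensor; there is no
  pixel normalization in the styled path.
* **Critic**: a patch critic — per stage a 1×1×1 from-image convolution, then
  the remaining strided 3×3×3 convolutions of the five-layer stack with
  increasing widths `(c, 2c, 4c, 8c, 8c, 8c)`, and a 1×1×1 score convolution
  whose spatial map is averaged to one scalar per sample. The critic fades
  symmetrically to the generator. A minibatch-standard-deviation layer is
  deliberately omitted.

Equalized learning rate (weights stored unit-normal, rescaled at run time by
`gain/√fan_in`) is on by default and can be disabled per layer. Kernel sizes
and activations follow the established progressive/style-based conventions,
since only the stage-level structure is prescribed.

## Training

The critic minimises

    E[f(G(z)) − f(x)] + p1·(‖∇x̃ f(x̃)‖₂ − 1)² + p2·f(x)²

with `x̃ = u·x + (1−u)·G(z)`, `u ~ U(0,1)` per sample; the generator minimises
`−E[f(G(z))]`. Defaults: `p1 = 10`, `p2 = 0.001`, Adam with α = 4·10⁻³ and
betas (0, 0.99), five critic updates per generator update, matching the
best-performing reference configuration of the original study. Real volumes
for coarse stages are block-mean pooled from the full-resolution stacks.
Fade-in is linear in updates over the first half of each stage's budget
(`fade_fraction`, 0 gives hard switches). Optimizer state is kept across
stage growth. About 10% of stacks are held out; the critic's real−generated
gap on that split is logged every generator update as an overfitting
diagnostic and never used for updates. All randomness flows from one seed
through named substreams (init / split / training / evaluation), making short
runs bit-reproducible.

## Inversion

Hybrid inversion: an encoder (the generator reversed — per level two 3×3×3
convolutions and a stride-2 pool, channels increasing along the reversed
schedule, then a dense 512 head; pixel normalization removed; the style
variant appends two leaky-ReLU dense layers) provides an initial code, which
Adam then refines per image.

Encoder risks: `dist + perc + latent` for the progressive variant and
`5·dist + perc + 0.04·ℓ_W` for the style variant, where `dist` is half the
mean squared voxel error of `G(E(x))`, `perc` half the mean squared error of
the critic's penultimate-layer features, `latent = ‖E(x)‖²/1024`, and `ℓ_W`
is the negative log output of a latent discriminator (a 512→(0,1) MLP trained
alternately to separate mapped codes from encoder codes; its output is
clamped at 1e−8 inside the log). The 1/1024 and 1/512 normalizations are kept
verbatim even though both are scalings of the same squared norm. Encoder
training uses Adam(3·10⁻³, 0.5, 0.9).

Refinement minimises, for the progressive variant,
`(1/#vox)‖x − G(z)‖² + (1/#feat)‖φ(x) − φ(G(z))‖² + (1/512)‖z‖²` and for the
style variant the feature term alone (a voxel term can be switched on);
defaults are 100 Adam updates at learning rate 7·10⁻³. The target's features
are computed once and cached. The iterate with the lowest objective is
returned (robust to oscillation), so the best-seen objective is non-increasing
by construction; divergence to non-finite values raises with the iteration
index. Style-variant noise injections are frozen at zero during inversion so
the objective is deterministic.

## Latent tools

* **Truncation**: progressive codes are drawn from a per-coordinate truncated
  normal (exact rejection sampling; default level 1.8); style codes are
  shrunk toward the Monte-Carlo mean latent, `w̄ + ψ(w − w̄)` with ψ = 0.8.
  The ψ ∈ {0, 1} endpoints are short-circuited to exact returns.
* **Transition**: `G(α z₁ + (1−α) z₂)` for α ∈ [0, 1]; endpoints reproduce
  plain generation bit-for-bit.
* **Style mixing**: the first *a* of the 15 styled convolutions consume the
  source code's styles, the rest the target's; noise frozen at zero so the
  mix is a deterministic function of the codes.
* **Directions**: the unit vector maximising ‖An‖² and its successors are the
  top right-singular vectors of `A` (equivalently eigenvectors of `AᵀA`),
  where `A` is the progressive generator's first dense layer or the row-wise
  stack of the 15 style heads (biases excluded; the stacking axis is a
  convention choice). Eigenvector signs are fixed by making the first
  non-zero component positive. Editing evaluates `G(code + α·n)` with default
  strength α = 4 and returns the difference volume for visualisation.

## Metrics

The Frechet distance between Gaussian summaries of two feature sets is
`‖μ_A − μ_B‖² + tr(Σ_A + Σ_B − 2(Σ_A Σ_B)^{1/2})`, computed through the
symmetric product `√Σ_A Σ_B √Σ_A` by eigendecomposition with negative
eigenvalues clamped at zero (and an ε = 1e−10 inside the final square root).
Precision is the fraction of generated features inside the union of k-NN
balls (k = 3 by default) around real features; recall is symmetric. The
realism score of a generated feature is `max_r radius_k(r)/‖g − r‖` over real
features, capped at 1e6 for coincident points. All three match brute-force
O(n²) oracles exactly in the tests.

Feature extraction is a contract with three provided routes: a 2D route
applying a fixed random two-layer projection to two randomly positioned
axial slices per volume (resized to a 64×64 frame), a volumetric route using
a random-weight three-layer strided CNN, and a grading route using the
penultimate features of a small volumetric classifier trained on graded
phantoms. The first two are synthetic stand-ins: they exercise the identical
interfaces and statistics as pre-trained backbones without shipping any
third-party weights. Volumes graded 4 or 5 are excluded from GAN training by
`filter_vgs`.

## Synthetic phantoms: what they are and are not

Phantoms contain an elliptical-annulus cortical shell (per-slice centre
jitter mimicking anatomical wobble), a trabecular interior of thresholded
smoothed noise whose occupancy fraction is the Tb.BMD analogue, additive
background noise, and optionally a sheared axial block emulating inter-slice
motion. Grades 1–5 are coupled to image degradation — background noise
standard deviation `0.02 + 0.04·(vgs−1)` and, for grades 4–5, a shear of
`4·(vgs−3)` voxels — strongly enough that a small classifier reaches
above-majority held-out accuracy; an earlier, weaker coupling left grades
unlearnable, which would have contradicted the premise of grading-based
feature extraction. The background noise amplitude itself is a free design
choice; no quantitative scanner-noise description was available.

Phantoms establish that the machinery works: shapes, losses, convergence
trends, inversion gains, metric semantics. They do not establish clinical
realism — no Hounsfield calibration, no real trabecular connectivity, no
scanner-specific noise spectra — so passing tests say nothing about
generation quality on patient data.

## Scaled-down study sizes

The self-test study trains three stages of a `(64, 128, 128)`-grid model
(c = 8) on 24 phantoms of 16 × 32 × 32, with 12/12/8 generator updates per
stage, batches 8/4/2 and five critic updates per generator update (~200
optimizer updates in total), then fits the inversion encoder for 30 steps and
refines one generated sample for 40 Adam updates. These sizes are the
package's chosen smoke-study conditions; the defaults users get
(`TrainConfig`, `ModelConfig`) are the full-scale reference values
(cc = 16, cg = 20, grid 32 × 288 × 224).

## Known limitations

* CPU-only: full-scale training at 32 × 288 × 224 is supported by the code
  paths but is not practical without accelerator hardware; the package is
  validated at phantom scale.
* The gradient penalty's `x̃` uses one uniform interpolate per sample — the
  standard estimator; no alternative transition distributions are provided.
* The critic gap is logged, not acted on: no early stopping rule is imposed.
* `find_directions` operates on dense matrices; for latent dimensions far
  beyond 512 a sparse/iterative SVD would be preferable.
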