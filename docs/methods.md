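# Methods

This note records the model, the synthetic-data and noise conventions, the
numerical choices, and the known limitations of the package. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Attention decomposition

All operators act on `[B, C, F, H, W]` series and return the same shape.

**Tokens.** Spatial tokens are patch vectors: all `p²` pixels of a patch
across the `C` channels, flattened channel-major, length `d = C·p²`.
Local attention runs over the `P = (w/p)²` patches of each `w×w` window,
independently per batch, frame, window and head. Global attention
transposes the grouping: for each of the `P` patch positions it attends
over the `N = ⌈H/w⌉·⌈W/w⌉` same-position patches from all windows. Frame
attention flattens whole frames (`d = C·H·W`) and attends along F.

**Logits and scaling.** `A = softmax(D_Q D_K^T / d_head^s + B)` with
`d_head = C·p²/h` and exponent `s = 0.5` (standard scaled dot-product).
The exponent is an argument (`scale_exponent`) so the alternative
normalization by the full `d` can be ablated; with `s = 0.5` the
decomposed operators agree with the exhaustive pixel-token oracle at
machine precision, which fixes the convention internally.

**Positional bias.** Only local attention carries the learnable relative
positional bias (one scalar per head per `(Δrow, Δcol)` patch offset,
zero-initialized). Global and frame attention have token counts that vary
with image size and series length, so a fixed-size bias table cannot be
defined for them; frame attention is therefore exactly
permutation-equivariant along F, which the tests assert.

**Q/K/V projections.** Three independent 3×3 convolutions with padding 1,
applied per frame with weights shared across frames. The key convolution
has no bias: a constant added to every key shifts each logit row
uniformly and the row softmax cancels it, so a key bias is a provably
gradient-free parameter (the gradient-coverage test demonstrates this).

**Heads.** Contiguous channel groups. Because the token layout is
channel-major, splitting the token vector into `h` contiguous column
groups is identical to splitting the channel axis into `h` groups; merge
is concatenation. Requires `(C·p²) mod h = 0` (spatial) and `C mod h = 0`
(frame).

**Padding.** Non-divisible `H, W` are reflect-padded (mirror without edge
repeat, periodic for arbitrary pad width) up to window multiples and
cropped after attention. Partition → inverse-partition is bit-exact on
the unpadded region for any shape.

**Complexity accounting.** Per frame and head, local attention computes
`N·P²` logits and global attention `P·N²`; an instrumented counter in the
operators verifies both closed forms. With `(w, p)` fixed, `N ∝ H·W`, so
the local count is linear in image area while the global count is
*quadratic* (doubling the area exactly doubles local and quadruples
global — the counter measures ratios 2.0 and 4.0). The decomposition's
saving over full attention is the constant: full pixel attention costs
`(H·W)²` per frame versus `N·P² + P·N² = (H·W)²·(p²/w⁴)·(w²+p²)`-ish;
for the default `w=16, p=4` that is a ~3 orders of magnitude reduction,
but the global term's growth law is quadratic all the same.

## Cells, blocks, backbone

A cell is pre-norm residual: `y = x + Drop(Attn(LN(x)))`,
`z = y + Drop(Mixer(y))`, with dropout (rate 0.1) on both residual
branches. Layer normalization is over the channel axis per pixel and
frame. The mixer is `LN → conv(C→4C) → PReLU → conv(4C→C)`; all model
convolutions are 3×3 with padding 1 and act frame-wise. With the value
projection and mixer output conv zeroed, every cell is an exact identity
(asserted).

Blocks are composition strings over `{F, L, G}`; `"FLGFLG"` has exactly
twice the cells and twice the block parameters of `"FLG"` (asserted as a
closed-form count).

The backbone holds five blocks at two resolution levels by default. The
exact wiring is a design choice here: three blocks on the full-resolution
stream, then a stride-2 convolution doubling the channels, two blocks at
half resolution, nearest-neighbour upsampling with a 1×1 channel-matching
convolution, and fusion by addition into the high-resolution stream,
followed by the output convolution. This keeps the majority of
computation at full resolution (no early downsampling). Input channels
are `(real, imag, g-map)`; output is the 2-channel complex estimate.
Defaults: `C = 64`, window 16, patch 4, 4 heads — window and patch sizes
are desk-scale choices, as is the head count.

Checkpoints are single `.npz` archives of parameter arrays keyed by
hierarchical names plus the backbone configuration as embedded JSON;
loading rebuilds a bit-identical model.

## Autodiff core

No deep-learning framework is used: the model runs on a small tape-based
reverse-mode autodiff engine over numpy (`autodiff.py`) providing batched
matmul, im2col convolution (stride 1/2), channel layer-norm, softmax,
PReLU, dropout, gather-based reflect-pad/crop and bias lookup, and
nearest-neighbour upsampling, plus Adam. Every backward rule is checked
against central finite differences in the test suite. Softmax raises on
non-finite logits with a diagnostic. Float32 is used for model state,
float64 for oracles and gradient checks.

## Noise synthesis and SNR conventions

Data are in SNR units: per-channel noise SD is 1, so pixel magnitude is
per-pixel SNR. Adding zero-mean Gaussian noise of SD `nn·g(x, y)`
independently to the real and imaginary channels raises the per-pixel
noise SD to `√(1 + nn²g²)`, giving a degraded global median SNR of
`median(SNR_orig / √(1 + nn²g²))` over the foreground. The solver brackets
`nn` by doubling and polishes with Brent's method (relative tolerance
1e-6); the objective is continuous and strictly monotone.

**Foreground.** The median is taken over pixels whose clean magnitude
exceeds 10% of the 99th percentile (configurable). Background air would
otherwise dominate the global median; this masking choice is a
documented convention of this package.

**Measurement semantics.** `measure_median_snr` computes the median
magnitude of a series whose pixel values represent signal in SNR units —
the clean series, or the noise-rescaled clean signal of a degraded series
(`degraded_snr_map`). It is not a blind estimator applied to a noisy
realization: at median SNR ≪ 1 the magnitude of a single noisy
realization is noise-dominated (Rayleigh-limited) and no per-pixel
estimator can recover a 0.05 median to 2% from one draw. The degrade →
measure roundtrip therefore checks the bisection solver against the
independent percentile path, while a separate Monte-Carlo test verifies
that the empirically realized per-pixel noise SD is `nn·g` to within 3%.

**g-factor maps.** Synthetic maps are smooth fields in `[1, gmax]`
(default `gmax = 2.5`, labelled R=4): a centre-weighted bump — parallel
imaging amplifies noise away from the coils — plus a seeded low-pass
random field. They stand in for maps computed from coil sensitivities,
which are out of scope.

**Training-time sampling.** Levels are drawn log-uniformly over a
configurable range (default 0.25–8.0) with a fresh noise realization per
series per epoch; the ten fixed levels
`{0.05, 0.1, 0.2, 0.5, 0.75, 1.0, 1.5, 2.0, 4.0, 8.0}` are reserved for
evaluation.

## Phantom generator

Each series is an analytic left-ventricle short-axis view: a bright
elliptical blood pool (mean signal 105.7 in SNR units) inside a darker
myocardial ring (37.0) on a low background (4.0), matrix 256×144 with 30
phases by default. Contraction scales the endocardial radii by
`1 − amp·bump(t)` with a von-Mises-shaped periodic bump peaking at 35% of
the cycle, so phase F wraps smoothly onto phase 0 (retro-gated cycle);
the epicardium contracts at 40% of the endocardial amplitude (wall
thickening). The default amplitude gives a single-slice area ejection
fraction of 0.60; EF is closed-form from `area(t) = π·a(t)·b(t)` and is
verified against a mask pixel-counting oracle to 2%.

Rendering is 4× supersampled (anti-aliased partial-volume edges); signal
statistics are therefore evaluated on interior pixels (two-pixel erosion)
where the region means are exact. Complex phase is a smooth low-order 2D
polynomial — coil/B0-like — that leaves magnitude untouched. Labels
(background / blood / myocardium) are exclusive and exhaustive by
construction.

What the phantom does **not** emulate: B-SSFP banding and flow artefacts,
k-space acquisition and coil combination, respiratory motion, papillary
muscles, trabeculation, pathology, or through-plane motion. Passing tests
show the pipeline's internal consistency and that the model can learn the
degradation statistics; they do not certify performance on clinical data.

Datasets are written one HDF5 container per series (`image/real`,
`image/imag`, `gmap`, `masks`, spec as JSON attribute; versioned,
forward-compatible within a major version) with a JSON manifest and a
deterministic 95/5 train/validation split; magnitude export to NIfTI uses
axes `(H, W, 1, F)`.

## Metrics

Computed on magnitude images.

* **PSNR** `= 10·log10(MAX²/MSE)` with `MAX = 2048.0` fixed (scanner-unit
  ceiling), `+inf` sentinel for identical images.
* **SSIM**: Gaussian window σ=1.5 (11 px), `k1=0.01, k2=0.03, L=2048`,
  population covariances, window-radius border excluded, per frame then
  averaged. Matches the scikit-image reference implementation to < 1e-4
  (asserted); constants are recorded in every report.
* **CNR** `= (mean_blood − mean_myo) / noise_sd`. Conventions: ground
  truth uses noise SD 1 (SNR units); degraded inputs use `nn·median(g)`
  over the heart region; denoised outputs use the residual SD against
  ground truth over the heart region (a denoiser cannot be scored by the
  input's nominal noise level).
* **Bland–Altman**: mean paired deviation and `cr90 = 1.645·SD` of the
  differences (normal-quantile half-width about the mean; the 90% CR
  convention is this package's definition).

The evaluation harness degrades each series at each level with seeds
fixed per (series, level), denoises, and emits one record per pair plus
aggregate medians.

## Training

Adam (betas 0.9/0.999, eps 1e-8) under a one-cycle schedule (linear ramp
over the first 30% of steps to the single peak, cosine anneal to
peak/100). The loss is MSE on the 2-channel complex output; an optional
magnitude-penalized variant sits behind `loss="mse+ssim"`. The default
`TrainConfig` peak learning rate is 1e-5 — appropriate for large models
and long schedules — while the desk-scale reference configuration uses
2e-3, which one-cycle training of the tiny model needs to converge in
minutes. Per-epoch losses and the learning rate go to an append-only
JSONL log; the checkpoint with minimal validation loss is kept.
Non-finite loss aborts with a diagnostic.

**Desk-scale problem sizes.** The reference run — chosen as the package's
own study size — uses 20 phantom series of 64×64 pixels and 8 phases
(19 train / 1 validation), a single-resolution `C=16` `"FLG"` model
(~98k parameters, window 16 / patch 4 / 4 heads), random 32×32 spatial
crops, and 12–30 epochs; this trains in a few minutes on one CPU core.
Evaluation runs at full 64×64 on the validation series plus freshly drawn
held-out phantoms. Batches default to one series; variable-shape corpora
are bucketed by shape (all desk phantoms share one shape).

Determinism: split, initialization, dropout streams, noise levels and
realizations all derive from the single config seed; identical seeds
reproduce loss curves bit-for-bit.

## Known limitations

* The global-attention logit count grows quadratically with image area at
  fixed window size (see complexity accounting above); linear growth
  holds only for the local operator.
* The optimizer is a pluggable name in the config; the implemented desk
  optimizer is Adam. Second-order optimizers sometimes used for
  large-scale training of such models are not implemented.
* Single-slice area EF is a surrogate for volumetric EF from short-axis
  stacks; multi-slice segmentation-model evaluation is out of scope.
* Head counts and window/patch sizes of the large published model family
  are not reproduced; parameter counts here are exact but desk-scale.
* Metrics are magnitude-domain; complex-domain metrics are out of scope.
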