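# cinedenoise

Denoising of very-low-SNR cardiac cine MRI with a windowed spatiotemporal
attention network, together with everything needed to study such a model
end to end on synthetic data: g-factor-aware SNR-targeted noise synthesis,
a beating-heart phantom generator with analytic ground truth, and an
SNR-unit image-quality evaluation battery.

It is aimed at MR-reconstruction and medical-imaging ML researchers who
want a transparent, CPU-scale, fully seeded implementation of the
attention-decomposition denoising recipe — every operator is cross-checked
against brute-force oracles, and the whole pipeline (simulate → corrupt →
train → denoise → evaluate) runs in minutes on one core.

## The model

Image series live in a 5D tensor `[B, C, F, H, W]` (batch, channels,
frames, height, width).  Full spatiotemporal attention over all pixels is
quadratic in `H·W·F`; here it is decomposed into three operators:

* **Local attention (L)** — each frame is tiled into `w×w` windows of
  `P = (w/p)²` patches of `p×p` pixels.  Tokens are patch vectors
  `v ∈ R^{C·p²}`; attention runs among the `P` patches of each window, with
  a learnable relative positional bias `B`:

  `A = softmax(D_Q D_K^T / √d + B)`, output `A·D_V`, `d = C·p²/h` per head.

* **Global attention (G)** — for each of the `P` within-window patch
  positions, attention runs over the `N = (H/w)(W/w)` same-position patches
  gathered across all windows (long-range structure; no positional bias).

* **Frame attention (F)** — tokens are whole flattened frames
  (`v ∈ R^{C·H·W}`); full `M×M` attention along the frame axis captures
  temporal correlation across cardiac phases.

Q, K, V come from learnable per-frame 3×3 convolutions (locality bias,
arbitrary matrix sizes).  A *cell* wraps one operator as
`y = x + Drop(Attn(LN(x))); z = y + Drop(Mixer(y))` with a
`C → 4C → C` convolutional mixer; a *block* is a composition string such as
`"FLG"` or `"FLGFLG"` (exactly twice the parameters); blocks sit in a
two-level high-resolution backbone (input conv 3→C for real/imag/g-map,
stride-2 branch with 2C channels fused back by addition, output conv C→2
for the complex estimate).

Noise synthesis works in **SNR units** (noise SD 1, so pixel magnitude is
per-pixel SNR).  Complex Gaussian noise of SD `nn·g(x, y)` — `g` the
parallel-imaging g-factor map — yields a degraded global median SNR of
`median(SNR / √(1 + nn²g²))`; a bisection solver picks `nn` to hit any
target level (the standard evaluation grid is 0.05–8.0).  The model is
implemented on a small numpy reverse-mode autodiff core (`autodiff.py`)
verified by finite-difference gradient checks.

## Worked example

```python
import numpy as np
from cinedenoise import (PhantomSpec, generate_cine_phantom, phantom_ef,
                         synth_gfactor_map, solve_noise_sd, add_gfactor_noise,
                         measure_median_snr, psnr, cnr)
from cinedenoise.noise import foreground_mask, degraded_snr_map

spec = PhantomSpec()                      # 256x144 matrix, 30 cardiac phases
series, masks = generate_cine_phantom(spec)
gmap = synth_gfactor_map((256, 144), acceleration=4, gmax=2.5, seed=0)

mag = series.magnitude()
fg = foreground_mask(mag)
print(f"clean median SNR      : {measure_median_snr(series, fg):.1f}")
print(f"ejection fraction     : {100 * phantom_ef(spec):.1f}%")

nn = solve_noise_sd(mag, gmap, target=0.2, foreground=fg)
noisy = add_gfactor_noise(series, nn, gmap, seed=1)
print(f"noise SD for SNR 0.2  : {nn:.1f}")
print(f"achieved median SNR   : {measure_median_snr(degraded_snr_map(series, nn, gmap), fg):.3f}")

noisy_mag = noisy.magnitude()[0, 0]
blood, myo = masks.interior(1), masks.interior(2)
print(f"input PSNR            : {psnr(noisy_mag, mag[0, 0]):.2f} dB")
print(f"CNR clean -> degraded : {cnr(mag[0,0], blood, myo, 1.0):.1f} -> "
      f"{cnr(noisy_mag, blood, myo, nn * float(np.median(gmap.values))):.2f}")
```

prints

```
clean median SNR      : 37.0
ejection fraction     : 60.0%
noise SD for SNR 0.2  : 84.3
achieved median SNR   : 0.200
input PSNR            : 20.09 dB
CNR clean -> degraded : 68.7 -> 0.13
```

The clean foreground median lands on the myocardial signal level (37.0 in
SNR units, blood 105.7); degrading to a target median SNR of 0.2 needs a
noise SD of ~84, at which point the blood–myocardial contrast-to-noise
ratio has collapsed from 68.7 to 0.13 — the anatomy is invisible.
Training a denoiser and evaluating it over SNR levels is one command each:

```bash
cinedenoise simulate data/ --n 20 --height 64 --width 64 --phases 8 --seed 0
cinedenoise train data/ run/ --seed 0           # desk-scale config, minutes on CPU
cinedenoise evaluate data/ run/checkpoint.npz eval/ --levels 0.2,0.5,1.0
cinedenoise selftest                            # attention oracle checks
```

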