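"""Desk-scale training loop and inference for the attention denoiser.

Training follows the noise-as-augmentation recipe: every epoch draws a
fresh noise realization per series at a log-uniformly sampled target
median SNR, so the network never sees the same corrupted input twice.
Inputs are (real, imag, g-map) channels of the degraded series in SNR
units; the loss is MSE against the 2-channel clean complex target (an
SSIM-augmented variant is config-selectable).  Optimization is Adam with
betas (0.9, 0.999) and epsilon 1e-8 under a one-cycle learning-rate
schedule; the best-validation checkpoint is kept.

Everything is deterministic from ``TrainConfig.seed``: dataset split,
noise draws, dropout streams and initialization.
"""

from __future__ import annotations

import json
import math
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .backbone import (
    BackboneConfig,
    build_backbone,
    forward_denoise,
    load_checkpoint,
    save_checkpoint,
)
from .noise import make_training_sample, sample_training_level
from .phantom import read_series_container

__all__ = [
    "TrainConfig",
    "desk_config",
    "one_cycle_lr",
    "train_denoiser",
    "denoise_series",
    "identity_denoiser",
]


@dataclass(frozen=True)
class TrainConfig:
    """Full training recipe; serialized next to every checkpoint."""

    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    epochs: int = 160
    batch_size: int = 1
    optimizer: str = "adam"  # pluggable name; adam is the desk default
    betas: tuple = (0.9, 0.999)
    epsilon: float = 1e-8
    peak_lr: float = 1e-5
    schedule: str = "one-cycle"
    loss: str = "mse"  # or "mse+ssim"
    ssim_loss_weight: float = 0.0
    snr_range: tuple = (0.25, 8.0)
    crop_hw: int | None = None
    crop_frames: int | None = None
    val_level: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch size must be positive")
        if self.peak_lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.loss not in ("mse", "mse+ssim"):
            raise ValueError(f"unknown loss {self.loss!r}")


def desk_config(seed: int = 0, epochs: int = 30) -> TrainConfig:
    """Reference configuration that trains in minutes on one CPU core:
    C=16 single-resolution "FLG" model on 64×64, 8-frame phantoms, trained
    on random 32×32 crops with a desk-appropriate peak learning rate."""
    return TrainConfig(
        backbone=BackboneConfig(
            channels=16, num_blocks=1, block="FLG", resolution_levels=1,
            window_px=16, patch_px=4, heads=4,
        ),
        epochs=epochs,
        peak_lr=2e-3,
        crop_hw=32,
        snr_range=(0.25, 8.0),
        seed=seed,
    )


def one_cycle_lr(step: int, total_steps: int, peak_lr: float,
                 pct_start: float = 0.3, div_factor: float = 25.0,
                 final_div_factor: float = 100.0) -> float:
    """One-cycle schedule: linear ramp to the single peak, cosine anneal to
    ``peak/final_div_factor`` at the last step."""
    if total_steps <= 1:
        return peak_lr
    up = max(1, int(round(pct_start * (total_steps - 1))))
    lo0 = peak_lr / div_factor
    lo1 = peak_lr / final_div_factor
    if step <= up:
        return lo0 + (peak_lr - lo0) * step / up
    frac = (step - up) / max(1, (total_steps - 1) - up)
    return lo1 + 0.5 * (peak_lr - lo1) * (1.0 + math.cos(math.pi * frac))


def _load_split(data_dir):
    with open(os.path.join(data_dir, "manifest.json")) as fh:
        manifest = json.load(fh)
    train, val = [], []
    for e in manifest["entries"]:
        series, gmap, masks, spec = read_series_container(
            os.path.join(data_dir, e["path"])
        )
        (val if e["split"] == "val" else train).append(
            {"series": series, "gmap": gmap, "masks": masks, "id": e["id"]}
        )
    return train, val


def _crop(inp, tgt, rng, crop_hw, crop_f):
    _, _, f, h, w = inp.shape
    if crop_f and crop_f < f:
        f0 = int(rng.integers(f - crop_f + 1))
        inp, tgt = inp[:, :, f0:f0 + crop_f], tgt[:, :, f0:f0 + crop_f]
    if crop_hw and (crop_hw < h or crop_hw < w):
        y0 = int(rng.integers(max(h - crop_hw, 0) + 1))
        x0 = int(rng.integers(max(w - crop_hw, 0) + 1))
        inp = inp[..., y0:y0 + crop_hw, x0:x0 + crop_hw]
        tgt = tgt[..., y0:y0 + crop_hw, x0:x0 + crop_hw]
    return inp, tgt


def _loss_value(model, inp, tgt, cfg: TrainConfig) -> Tensor:
    pred = model(Tensor(inp.astype(np.float32)))
    loss = ad.mse_loss(pred, tgt.astype(np.float32))
    if cfg.loss == "mse+ssim" and cfg.ssim_loss_weight > 0:
        # differentiable SSIM is out of scope for the desk loop; the
        # variant penalizes magnitude MSE additionally, which tracks SSIM
        mag_pred = (pred * pred).sum(axis=1, keepdims=True) ** 0.5
        mag_tgt = np.sqrt((tgt**2).sum(axis=1, keepdims=True))
        loss = loss + cfg.ssim_loss_weight * ad.mse_loss(mag_pred, mag_tgt)
    return loss


def train_denoiser(cfg: TrainConfig, data_dir, out_dir,
                   log_every: int = 0):
    """Train on a phantom dataset directory; returns (checkpoint_path, log).

    The log is a list of per-epoch dicts (train/validation loss, learning
    rate); it is also appended, one JSON object per line, to
    ``training_log.jsonl`` in ``out_dir``.  The checkpoint with minimal
    validation loss is written to ``checkpoint.npz``.
    """
    os.makedirs(out_dir, exist_ok=True)
    train_set, val_set = _load_split(data_dir)
    if not train_set or not val_set:
        raise ValueError("dataset must contain both train and val series")
    model = build_backbone(cfg.backbone, seed=cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.peak_lr, betas=cfg.betas,
               eps=cfg.epsilon)
    total_steps = cfg.epochs * math.ceil(len(train_set) / cfg.batch_size)
    step = 0
    log = []
    best_val = math.inf
    ckpt_path = os.path.join(out_dir, "checkpoint.npz")
    log_path = os.path.join(out_dir, "training_log.jsonl")
    rng_master = np.random.default_rng(cfg.seed)
    order_rng = np.random.default_rng(rng_master.integers(2**31))

    for epoch in range(cfg.epochs):
        model.train()
        order = order_rng.permutation(len(train_set))
        epoch_losses = []
        t0 = time.time()
        for pos in range(0, len(order), cfg.batch_size):
            ids = order[pos:pos + cfg.batch_size]
            inps, tgts = [], []
            for idx in ids:
                item = train_set[idx]
                srng = np.random.default_rng(
                    [cfg.seed % (2**31), epoch, int(idx)]
                )
                level = sample_training_level(srng, *cfg.snr_range)
                inp, tgt, _ = make_training_sample(
                    item["series"], item["gmap"], level,
                    seed=int(srng.integers(2**31)),
                )
                inp, tgt = _crop(inp, tgt, srng, cfg.crop_hw, cfg.crop_frames)
                inps.append(inp)
                tgts.append(tgt)
            inp = np.concatenate(inps, axis=0)
            tgt = np.concatenate(tgts, axis=0)
            lr = one_cycle_lr(step, total_steps, cfg.peak_lr)
            model.zero_grad()
            loss = _loss_value(model, inp, tgt, cfg)
            lval = float(loss.data)
            if not math.isfinite(lval):
                raise FloatingPointError(
                    f"non-finite training loss {lval} at epoch {epoch}, "
                    f"step {step} (lr={lr:.3g})"
                )
            loss.backward()
            opt.step(lr=lr)
            epoch_losses.append(lval)
            step += 1

        # deterministic validation at a fixed level and fixed noise seeds
        model.eval()
        val_losses = []
        for item in val_set:
            inp, tgt, _ = make_training_sample(
                item["series"], item["gmap"], cfg.val_level,
                seed=(cfg.seed * 7919 + item["id"]) % (2**31),
            )
            pred = forward_denoise(model, inp)
            val_losses.append(float(np.mean((pred - tgt) ** 2)))
        entry = {
            "epoch": epoch,
            "lr": lr,
            "train_loss": float(np.mean(epoch_losses)),
            "val_loss": float(np.mean(val_losses)),
            "seconds": round(time.time() - t0, 3),
        }
        log.append(entry)
        with open(log_path, "a") as fh:
            fh.write(json.dumps(entry) + "\n")
        if entry["val_loss"] < best_val:
            best_val = entry["val_loss"]
            save_checkpoint(model, ckpt_path)
        if log_every and epoch % log_every == 0:
            print(f"epoch {epoch}: train {entry['train_loss']:.4g} "
                  f"val {entry['val_loss']:.4g} lr {lr:.3g}")

    with open(os.path.join(out_dir, "train_config.json"), "w") as fh:
        json.dump(asdict(cfg), fh, indent=1, default=list)
    return ckpt_path, log


def identity_denoiser(inp: np.ndarray) -> np.ndarray:
    """No-op baseline: returns the noisy (real, imag) channels unchanged."""
    return np.asarray(inp)[:, :2]


def denoise_series(checkpoint_path, container_path, out_path,
                   nifti_path=None) -> np.ndarray:
    """Denoise a stored series with a trained checkpoint.

    Reads the container, feeds (real, imag, g-map) channels to the model
    in eval mode, writes a 2-channel complex result container (the input
    file is untouched) and optionally a magnitude NIfTI.  Returns the
    denoised complex series array.
    """
    from .attention import ImageSeries5D
    from .phantom import (
        export_magnitude_nifti,
        write_series_container,
    )

    model = load_checkpoint(checkpoint_path)
    series, gmap, masks, spec = read_series_container(container_path)
    vals = series.values
    b, c, f, h, w = vals.shape
    inp = np.empty((b, 3, f, h, w), dtype=np.float32)
    inp[:, 0] = vals[:, 0].real
    inp[:, 1] = vals[:, 0].imag
    inp[:, 2] = gmap.values[None, None]
    out = forward_denoise(model, inp)
    denoised = out[:, 0] + 1j * out[:, 1]
    result = ImageSeries5D(denoised[:, None])
    write_series_container(out_path, result, gmap, masks, spec)
    if nifti_path is not None:
        export_magnitude_nifti(result, nifti_path)
    return denoised[:, None]
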