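"""Image-quality evaluation: PSNR, SSIM, blood–myocardial CNR,
Bland–Altman agreement, and the multi-SNR-level evaluation harness.

All metrics operate on magnitude images.  PSNR uses a fixed maximum value
of 2048.0 (the scanner-unit ceiling of the reconstructions this package
models), so values are comparable across series:

    PSNR = 10·log10(MAX² / MSE)

SSIM follows the standard Gaussian-windowed formulation (11-pixel window,
σ = 1.5, k1 = 0.01, k2 = 0.03, L = 2048), computed per frame and averaged.
CNR is (mean blood − mean myocardium) / noise SD.  Bland–Altman agreement
is summarized by the mean paired deviation and a 90% confidence range
taken as 1.645·SD of the differences (normal-quantile half-width).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .noise import (
    DEFAULT_SNR_LEVELS,
    foreground_mask,
    solve_noise_sd,
    add_gfactor_noise,
)

__all__ = [
    "PSNR_MAX_DEFAULT",
    "SSIM_CONSTANTS",
    "psnr",
    "ssim",
    "cnr",
    "bland_altman",
    "EvalRecord",
    "EvalReport",
    "evaluate_over_snr_levels",
]

PSNR_MAX_DEFAULT = 2048.0

#: SSIM stabilizers, recorded in every report for comparability.
SSIM_CONSTANTS = {"k1": 0.01, "k2": 0.03, "data_range": 2048.0,
                  "sigma": 1.5, "truncate": 3.5}


def psnr(test: np.ndarray, reference: np.ndarray,
         max_value: float = PSNR_MAX_DEFAULT) -> float:
    """Peak SNR in dB; identical images give ``+inf`` (documented sentinel)."""
    test = np.asarray(test, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if test.shape != reference.shape:
        raise ValueError("PSNR requires same-shape images")
    mse = float(np.mean((test - reference) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(max_value**2 / mse)


def _ssim_frame(x, y, k1, k2, data_range, sigma, truncate):
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2

    def smooth(a):
        return gaussian_filter(a, sigma, truncate=truncate, mode="reflect")

    mx, my = smooth(x), smooth(y)
    mxx, myy, mxy = smooth(x * x), smooth(y * y), smooth(x * y)
    vx = mxx - mx * mx
    vy = myy - my * my
    cov = mxy - mx * my
    num = (2 * mx * my + c1) * (2 * cov + c2)
    den = (mx * mx + my * my + c1) * (vx + vy + c2)
    s = num / den
    pad = int(truncate * sigma + 0.5)  # window radius; edge band excluded
    return float(np.mean(s[pad:-pad, pad:-pad]))


def ssim(test: np.ndarray, reference: np.ndarray, **constants) -> float:
    """Mean structural similarity over local Gaussian windows and frames.

    Accepts 2D images or [..., H, W] stacks (leading axes are frames and
    averaged).  Constants may be overridden by keyword; defaults are the
    standard k1=0.01, k2=0.03 with L=2048 and an 11-pixel (σ=1.5) window.
    """
    cfg = {**SSIM_CONSTANTS, **constants}
    x = np.asarray(test, dtype=float)
    y = np.asarray(reference, dtype=float)
    if x.shape != y.shape:
        raise ValueError("SSIM requires same-shape images")
    min_size = int(2 * cfg["truncate"] * cfg["sigma"] + 0.5) * 2 + 1
    if min(x.shape[-2:]) < min_size:
        raise ValueError(
            f"image smaller than the {min_size}px SSIM window"
        )
    frames = x.reshape(-1, *x.shape[-2:])
    refs = y.reshape(-1, *y.shape[-2:])
    vals = [
        _ssim_frame(fx, fy, cfg["k1"], cfg["k2"], cfg["data_range"],
                    cfg["sigma"], cfg["truncate"])
        for fx, fy in zip(frames, refs)
    ]
    return float(np.mean(vals))


def cnr(image: np.ndarray, blood_mask: np.ndarray, myo_mask: np.ndarray,
        noise_sd: float) -> float:
    """Blood–myocardial contrast-to-noise ratio.

    ``(mean over blood − mean over myocardium) / noise_sd``.  For degraded
    SNR-unit inputs the convention is ``noise_sd = nn·median(g)`` over the
    heart region; for denoised outputs the residual SD against ground
    truth is the natural choice.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    image = np.asarray(image)
    if not blood_mask.any() or not myo_mask.any():
        raise ValueError("empty blood or myocardium mask")
    return float(
        (image[blood_mask].mean() - image[myo_mask].mean()) / noise_sd
    )


def bland_altman(measured, reference) -> dict:
    """Agreement summary of paired measurements.

    Returns ``mean_deviation`` = mean(measured − reference) and ``cr90`` =
    1.645·SD(differences), the half-width of the 90% confidence range
    about the mean deviation (normal-quantile convention).
    """
    measured = np.asarray(measured, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if measured.shape != reference.shape:
        raise ValueError("paired lists must have equal length")
    if measured.size < 3:
        raise ValueError("need at least 3 pairs")
    diff = measured - reference
    return {
        "mean_deviation": float(diff.mean()),
        "cr90": float(1.645 * diff.std(ddof=0)),
    }


# ---------------------------------------------------------------------------
# multi-level evaluation harness
# ---------------------------------------------------------------------------


@dataclass
class EvalRecord:
    series_id: int
    target_level: float
    measured_snr: float
    noise_sd: float
    psnr_input_db: float
    psnr_output_db: float
    ssim_input: float
    ssim_output: float
    cnr_input: float
    cnr_output: float
    cnr_gt: float


@dataclass
class EvalReport:
    """One record per (series, SNR level), plus aggregate medians."""

    records: list = field(default_factory=list)
    ssim_constants: dict = field(default_factory=lambda: dict(SSIM_CONSTANTS))

    def aggregate(self, attr: str, level: float | None = None) -> float:
        vals = [
            getattr(r, attr)
            for r in self.records
            if level is None or r.target_level == level
        ]
        return float(np.median(vals))

    def levels(self):
        return sorted({r.target_level for r in self.records})

    def to_rows(self):
        cols = [f.name for f in EvalRecord.__dataclass_fields__.values()]
        return [
            {c: getattr(r, c) for c in
             EvalRecord.__dataclass_fields__} for r in self.records
        ]


def _residual_sd(output_mag, clean_mag, region):
    resid = (output_mag - clean_mag)[region]
    return float(max(resid.std(), 1e-12))


def evaluate_over_snr_levels(denoise_fn, dataset, levels=DEFAULT_SNR_LEVELS,
                             seed: int = 0,
                             psnr_max: float = PSNR_MAX_DEFAULT) -> EvalReport:
    """Degrade → denoise → score every series at every target SNR level.

    ``denoise_fn`` maps a 3-channel (real, imag, g-map) ndarray
    ``[1, 3, F, H, W]`` to a 2-channel complex estimate (use
    ``backbone.forward_denoise`` with a trained model, or the identity on
    the first two channels as a no-op baseline).  ``dataset`` is an
    iterable of ``(series, gmap, masks)``.  Noise seeds are fixed per
    (series, level) so reports are reproducible.
    """
    from .noise import make_training_sample

    report = EvalReport()
    for sid, (series, gmap, masks) in enumerate(dataset):
        clean_mag = series.magnitude()[0, 0]
        blood = masks.interior(1)
        myo = masks.interior(2)
        heart = masks.blood | masks.myocardium
        g_heart = float(np.median(
            np.broadcast_to(gmap.values, heart.shape)[heart]
        ))
        fg = foreground_mask(clean_mag)
        cnr_gt = cnr(clean_mag, blood, myo, 1.0)
        for li, level in enumerate(levels):
            sample_seed = (seed * 100003 + sid * 1009 + li) % (2**31)
            inp, tgt, meta = make_training_sample(
                series, gmap, level, seed=sample_seed
            )
            nn = meta["nn"]
            noisy_mag = np.abs(inp[0, 0] + 1j * inp[0, 1])
            out = np.asarray(denoise_fn(inp))
            out_mag = np.abs(out[0, 0] + 1j * out[0, 1])
            from .noise import degraded_snr_map

            measured = float(np.median(
                degraded_snr_map(series, nn, gmap)[0, 0][
                    np.broadcast_to(fg, (clean_mag.shape))
                ]
            ))
            noise_sd_in = max(nn * g_heart, 1e-12)
            report.records.append(
                EvalRecord(
                    series_id=sid,
                    target_level=float(level),
                    measured_snr=measured,
                    noise_sd=nn,
                    psnr_input_db=psnr(noisy_mag, clean_mag, psnr_max),
                    psnr_output_db=psnr(out_mag, clean_mag, psnr_max),
                    ssim_input=ssim(noisy_mag, clean_mag),
                    ssim_output=ssim(out_mag, clean_mag),
                    cnr_input=cnr(noisy_mag, blood, myo, noise_sd_in),
                    cnr_output=cnr(
                        out_mag, blood, myo,
                        _residual_sd(out_mag, clean_mag, heart),
                    ),
                    cnr_gt=cnr_gt,
                )
            )
    return report
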