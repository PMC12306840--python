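"""SNR-targeted noise synthesis with g-factor amplification.

Works in *SNR units*: the image is scaled so that its per-channel noise
standard deviation is one, which makes per-pixel signal magnitude equal to
per-pixel SNR.  Degrading such a series with extra complex Gaussian noise
of standard deviation ``nn·g(x, y)`` (``g`` the parallel-imaging g-factor
map at acceleration R) raises the per-pixel noise SD to
``sqrt(1 + nn²·g²)``, so the global median SNR of the degraded series is

    median_pixels( SNR_original / sqrt(1 + nn²·g²) )

:func:`solve_noise_sd` inverts this monotone relation by bisection to hit a
requested global median SNR; the ten evaluation levels
``0.05 … 8.0`` are the module default.  The median runs over a foreground
mask (background air would otherwise dominate); the threshold is
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "DEFAULT_SNR_LEVELS",
    "InfeasibleTargetError",
    "GFactorMap",
    "NoisePlan",
    "synth_gfactor_map",
    "foreground_mask",
    "measure_median_snr",
    "degraded_snr_map",
    "solve_noise_sd",
    "add_gfactor_noise",
    "make_training_sample",
    "sample_training_level",
]

#: Evaluation levels for the global median SNR of the degraded input.
DEFAULT_SNR_LEVELS = (0.05, 0.1, 0.2, 0.5, 0.75, 1.0, 1.5, 2.0, 4.0, 8.0)

#: Foreground = clean magnitude above this fraction of its 99th percentile.
FOREGROUND_FRACTION = 0.10


class InfeasibleTargetError(ValueError):
    """Requested median SNR is not achievable by adding noise."""


@dataclass(frozen=True)
class GFactorMap:
    """Per-pixel parallel-imaging noise amplification (unitless, >= 1) at a
    stated acceleration factor R."""

    values: np.ndarray
    acceleration: int = 4

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2:
            raise ValueError("g-factor map must be 2D [H, W]")
        if not np.all(np.isfinite(v)):
            raise ValueError("g-factor map must be finite")
        if v.min() < 1.0 - 1e-9:
            raise ValueError(f"g-factor values must be >= 1, min={v.min()}")

    @property
    def shape(self):
        return self.values.shape


@dataclass
class NoisePlan:
    """Target median-SNR levels with their solved noise SDs for one series."""

    target_levels: tuple = DEFAULT_SNR_LEVELS
    solved_sd: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if any(lv <= 0 for lv in self.target_levels):
            raise ValueError("target SNR levels must be strictly positive")


def synth_gfactor_map(shape, acceleration: int = 4, smoothness: float = 8.0,
                      gmax: float = 2.5, seed: int = 0) -> GFactorMap:
    """Generate a smooth synthetic g-factor field in ``[1, gmax]``.

    Morphology mimics parallel-imaging maps: a centre-weighted bump (noise
    amplification peaks away from the coils, i.e. mid-image) plus a smooth
    seeded random field low-pass filtered with a Gaussian of width
    ``smoothness`` pixels.
    """
    from scipy.ndimage import gaussian_filter

    if gmax < 1.0:
        raise ValueError(f"gmax must be >= 1, got {gmax}")
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r2 = ((yy - cy) / (0.6 * h)) ** 2 + ((xx - cx) / (0.6 * w)) ** 2
    bump = np.exp(-2.5 * r2)
    rng = np.random.default_rng(seed)
    rough = gaussian_filter(rng.standard_normal((h, w)), smoothness)
    if np.ptp(rough) > 0:
        rough = (rough - rough.min()) / np.ptp(rough)
    shape_field = 0.65 * bump + 0.35 * rough
    shape_field = (shape_field - shape_field.min()) / max(np.ptp(shape_field), 1e-12)
    return GFactorMap(1.0 + (gmax - 1.0) * shape_field, acceleration)


def foreground_mask(magnitude: np.ndarray,
                    fraction: float = FOREGROUND_FRACTION) -> np.ndarray:
    """Mask of pixels whose magnitude exceeds ``fraction`` of the 99th
    percentile — excludes background air from the global median."""
    mag = np.abs(np.asarray(magnitude))
    thresh = fraction * np.percentile(mag, 99.0)
    mask = mag > thresh
    if not mask.any():
        raise ValueError("empty foreground: image has no signal above threshold")
    return mask


def measure_median_snr(series, foreground: np.ndarray | None = None) -> float:
    """Global median SNR of a series in SNR units.

    Pixel magnitude *is* per-pixel SNR under the SNR-unit convention, so
    this is the median signal magnitude over foreground pixels and frames.
    Apply it to the clean series, or to :func:`degraded_snr_map` output for
    a degraded series (where the per-pixel signal is the noise-rescaled
    clean signal).  Numpy's midpoint convention resolves even-count medians.
    """
    vals = series.magnitude() if hasattr(series, "magnitude") else np.abs(
        np.asarray(series)
    )
    if foreground is None:
        foreground = foreground_mask(vals)
    sel = vals[np.broadcast_to(foreground, vals.shape)]
    if sel.size == 0:
        raise ValueError("empty foreground selection")
    return float(np.median(sel))


def degraded_snr_map(clean, nn: float, gmap: GFactorMap) -> np.ndarray:
    """Per-pixel SNR after adding noise of SD ``nn·g``: the clean magnitude
    divided by the total noise SD ``sqrt(1 + nn²·g²)``."""
    mag = clean.magnitude() if hasattr(clean, "magnitude") else np.abs(
        np.asarray(clean)
    )
    return mag / np.sqrt(1.0 + (nn * gmap.values) ** 2)


def solve_noise_sd(snr_map: np.ndarray, gmap: GFactorMap, target: float,
                   foreground: np.ndarray | None = None,
                   rtol: float = 1e-6) -> float:
    """Solve for the added-noise SD ``nn`` that hits a target global median SNR.

    The objective ``median(snr / sqrt(1 + nn²·g²))`` is continuous and
    monotone decreasing in ``nn``; the root is bracketed by doubling and
    polished with Brent's method to relative tolerance ``rtol``.
    """
    snr = np.abs(np.asarray(snr_map, dtype=float))
    if target <= 0:
        raise InfeasibleTargetError("target median SNR must be positive")
    if foreground is None:
        foreground = foreground_mask(snr)
    fg = np.broadcast_to(foreground, snr.shape)
    g = np.broadcast_to(gmap.values, snr.shape)[fg]
    s = snr[fg]

    def median_snr(nn):
        return float(np.median(s / np.sqrt(1.0 + (nn * g) ** 2)))

    start = median_snr(0.0)
    if target >= start:
        if np.isclose(target, start, rtol=1e-12):
            return 0.0
        raise InfeasibleTargetError(
            f"target {target} >= achievable median SNR {start:.6g}"
        )
    hi = 1.0
    while median_snr(hi) > target:
        hi *= 2.0
        if hi > 1e12:
            raise InfeasibleTargetError("could not bracket the noise level")
    nn = brentq(lambda x: median_snr(x) - target, 0.0, hi,
                rtol=rtol, xtol=1e-300)
    return float(nn)


def add_gfactor_noise(x, nn: float, gmap: GFactorMap, seed: int = 0):
    """Add zero-mean complex Gaussian noise of per-pixel SD ``nn·g(x, y)``
    independently to real and imaginary parts at every pixel and frame.

    ``x`` is a complex series (``ImageSeries5D`` or ndarray) in SNR units.
    Reproducible from ``seed``; ``nn = 0`` returns the input unchanged.
    """
    from .attention import ImageSeries5D

    if nn < 0:
        raise ValueError(f"noise SD must be >= 0, got {nn}")
    vals = x.values if hasattr(x, "values") else np.asarray(x)
    if vals.shape[-2:] != gmap.shape:
        raise ValueError(
            f"g-map shape {gmap.shape} does not match image {vals.shape[-2:]}"
        )
    if nn == 0:
        return ImageSeries5D(vals.copy()) if vals.ndim == 5 else vals.copy()
    rng = np.random.default_rng(seed)
    sd = nn * gmap.values
    noise = rng.standard_normal(vals.shape) * sd + 1j * (
        rng.standard_normal(vals.shape) * sd
    )
    out = vals + noise
    return ImageSeries5D(out) if out.ndim == 5 else out


def sample_training_level(rng: np.random.Generator, low: float = 0.05,
                          high: float = 8.0) -> float:
    """Log-uniform draw of a target median SNR for training augmentation."""
    return float(np.exp(rng.uniform(np.log(low), np.log(high))))


def make_training_sample(clean, gmap: GFactorMap, target_level: float,
                         seed: int = 0):
    """Build one (input, target, metadata) denoising pair.

    Input channels are ``(real(noisy), imag(noisy), g-map)`` with the g-map
    broadcast over frames; the target is ``(real(clean), imag(clean))``,
    bit-identical to the clean source.  The metadata dict records the
    solved noise SD, the target level and the seed, enough to regenerate
    the pair exactly.
    """
    vals = clean.values if hasattr(clean, "values") else np.asarray(clean)
    if vals.ndim == 3:  # [F, H, W] convenience
        vals = vals[None, None]
    if vals.ndim != 5 or vals.shape[1] != 1:
        raise ValueError("expected a single-channel complex series")
    if vals.shape[-2:] != gmap.shape:
        raise ValueError("g-map / image shape mismatch")
    mag = np.abs(vals)
    fg = foreground_mask(mag)
    nn = solve_noise_sd(mag, gmap, target_level, foreground=fg)
    noisy = add_gfactor_noise(vals, nn, gmap, seed=seed)
    noisy = noisy.values if hasattr(noisy, "values") else noisy
    b, _, f, h, w = vals.shape
    rdtype = vals.real.dtype
    inp = np.empty((b, 3, f, h, w), dtype=rdtype)
    inp[:, 0] = noisy[:, 0].real
    inp[:, 1] = noisy[:, 0].imag
    inp[:, 2] = gmap.values[None, None]
    tgt = np.empty((b, 2, f, h, w), dtype=rdtype)
    tgt[:, 0] = vals[:, 0].real
    tgt[:, 1] = vals[:, 0].imag
    meta = {"nn": nn, "target_level": float(target_level), "seed": int(seed),
            "gmap_acceleration": gmap.acceleration}
    return inp, tgt, meta
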