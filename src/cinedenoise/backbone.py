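"""Cell / block / backbone assembly of the attention denoiser.

A *cell* wraps one attention operator in the classical transformer unit:

    y = x + Dropout(Attn(LayerNorm(x)))
    z = y + Dropout(Mixer(y)),   Mixer = LayerNorm → conv(C→4C) → PReLU → conv(4C→C)

A *block* is an ordered string of cells over the alphabet {F, L, G}
(frame, local, global attention) — "FLG" is three cells, "FLGFLG" six and
exactly twice the parameters.  The full denoiser is a high-resolution
backbone: an input convolution lifts the 3 input channels (real, imag,
g-factor map) to C encoding channels, most blocks process the series at
full resolution, a parallel stride-2 branch with doubled channels adds
coarse-scale context, and an output convolution produces the 2-channel
complex estimate.  All convolutions are 3×3 with padding 1 and act per
frame; normalization is over the channel axis per pixel.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np

from . import autodiff as ad
from .attention import (
    AttentionGeometry,
    ConfigurationError,
    ImageSeries5D,
    QKVProjection,
    RelPosBias,
    _frame_attention_t,
    _global_attention_t,
    _local_attention_t,
    _vals,
)
from .autodiff import Module, ModuleList, Parameter, Tensor

__all__ = [
    "CellSpec",
    "BlockSpec",
    "BackboneConfig",
    "parse_block_string",
    "build_cell",
    "build_backbone",
    "count_parameters",
    "parameter_breakdown",
    "forward_denoise",
    "save_checkpoint",
    "load_checkpoint",
    "Cell",
    "Block",
    "DenoisingBackbone",
]

_VALID_KINDS = frozenset("FLG")


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CellSpec:
    attention_kind: str
    channels: int
    geometry: AttentionGeometry = AttentionGeometry()
    dropout_rate: float = 0.1

    def __post_init__(self):
        if self.attention_kind not in _VALID_KINDS:
            raise ConfigurationError(
                f"attention kind must be one of F/L/G, got {self.attention_kind!r}"
            )
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate must be in [0, 1)")


@dataclass(frozen=True)
class BlockSpec:
    composition: str

    def __post_init__(self):
        if not self.composition:
            raise ConfigurationError("block composition string must be non-empty")
        bad = set(self.composition) - _VALID_KINDS
        if bad:
            raise ConfigurationError(
                f"invalid attention letters {sorted(bad)}; alphabet is F/L/G"
            )

    @property
    def cell_kinds(self):
        return list(self.composition)

    def __len__(self):
        return len(self.composition)


def parse_block_string(s: str) -> BlockSpec:
    """Parse a composition string like ``"FLG"`` into an ordered cell plan."""
    if not isinstance(s, str):
        raise ConfigurationError("block composition must be a string")
    return BlockSpec(s)


@dataclass(frozen=True)
class BackboneConfig:
    """Everything needed to rebuild a model.

    ``input_channels=3`` encodes the (real, imag, g-factor) input
    convention and ``output_channels=2`` the complex output.  With
    ``resolution_levels=2`` the blocks are split between a full-resolution
    stream and a stride-2 branch whose channel count is doubled.
    """

    channels: int = 64
    input_channels: int = 3
    output_channels: int = 2
    resolution_levels: int = 2
    num_blocks: int = 5
    block: str = "FLG"
    window_px: int = 16
    patch_px: int = 4
    heads: int = 4
    dropout_rate: float = 0.1
    scale_exponent: float = 0.5

    def __post_init__(self):
        parse_block_string(self.block)
        if self.resolution_levels not in (1, 2):
            raise ConfigurationError("resolution_levels must be 1 or 2")
        if self.num_blocks < 1:
            raise ConfigurationError("need at least one block")
        for c in (self.channels, 2 * self.channels):
            g = self.geometry
            g.token_length(c)
            if c % self.heads != 0:
                raise ConfigurationError(
                    f"{c} channels not divisible by {self.heads} heads"
                )

    @property
    def geometry(self) -> AttentionGeometry:
        return AttentionGeometry(self.window_px, self.patch_px, self.heads)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class Conv5D(Module):
    """3×3 (or 1×1) convolution applied frame-wise to a 5D series."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 kernel: int = 3, stride: int = 1, dtype=np.float32):
        super().__init__()
        self.stride = stride
        self.kernel = kernel
        scale = math.sqrt(2.0 / (cin * kernel * kernel))
        self.weight = Parameter(
            rng.normal(0, scale, (cout, cin, kernel, kernel)).astype(dtype)
        )
        self.bias = Parameter(np.zeros(cout, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        b, c, f, h, w = x.shape
        flat = x.transpose(0, 2, 1, 3, 4).reshape(b * f, c, h, w)
        out = ad.conv2d(flat, self.weight, self.bias, stride=self.stride,
                        padding=self.kernel // 2)
        _, co, ho, wo = out.shape
        return out.reshape(b, f, co, ho, wo).transpose(0, 2, 1, 3, 4)


class ChannelLayerNorm(Module):
    """Layer normalization over the channel axis, per pixel and frame."""

    def __init__(self, channels: int, dtype=np.float32):
        super().__init__()
        self.gamma = Parameter(np.ones((1, channels, 1, 1, 1), dtype=dtype))
        self.beta = Parameter(np.zeros((1, channels, 1, 1, 1), dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        return ad.layer_norm(x, self.gamma, self.beta, axis=1)


class Mixer(Module):
    """Channel mixer: LayerNorm → conv(C→4C) → PReLU → conv(4C→C)."""

    EXPANSION = 4

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.norm = ChannelLayerNorm(channels)
        self.conv1 = Conv5D(channels, self.EXPANSION * channels, rng)
        self.slope = Parameter(np.asarray([0.25], dtype=np.float32))
        self.conv2 = Conv5D(self.EXPANSION * channels, channels, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv2(ad.prelu(self.conv1(self.norm(x)), self.slope))


class Cell(Module):
    """One attention cell with pre-norm residual wiring and dropout on both
    residual branches."""

    def __init__(self, spec: CellSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        self.norm = ChannelLayerNorm(spec.channels)
        self.qkv = QKVProjection(spec.channels, rng)
        self.bias = (
            RelPosBias(spec.geometry) if spec.attention_kind == "L" else None
        )
        if self.bias is not None:
            # registered for parameter traversal
            self._bias_module = self.bias
        self.mixer = Mixer(spec.channels, rng)
        self._drop_rng = np.random.default_rng(int(rng.integers(2**31)))

    def _attend(self, x: Tensor) -> Tensor:
        spec = self.spec
        q, k, v = self.qkv(x)
        if spec.attention_kind == "L":
            out, _ = _local_attention_t(q, k, v, spec.geometry, self.bias)
        elif spec.attention_kind == "G":
            out, _ = _global_attention_t(q, k, v, spec.geometry)
        else:
            out, _ = _frame_attention_t(q, k, v, spec.geometry.heads)
        return out

    def _drop(self, x: Tensor) -> Tensor:
        return ad.dropout(x, self.spec.dropout_rate, self._drop_rng,
                          self.training)

    def forward(self, x: Tensor) -> Tensor:
        y = x + self._drop(self._attend(self.norm(x)))
        return y + self._drop(self.mixer(y))

    def zero_residual_init(self):
        """Zero the value projection and the mixer output convolution, making
        the cell an exact identity (skip connections only)."""
        self.qkv.wv.data[...] = 0
        self.qkv.bv.data[...] = 0
        self.mixer.conv2.weight.data[...] = 0
        self.mixer.conv2.bias.data[...] = 0


class Block(Module):
    """An ordered container of cells given by a composition string."""

    def __init__(self, spec: BlockSpec, channels: int, geom: AttentionGeometry,
                 dropout_rate: float, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        self.cells = ModuleList(
            Cell(CellSpec(kind, channels, geom, dropout_rate), rng)
            for kind in spec.cell_kinds
        )

    def forward(self, x: Tensor) -> Tensor:
        for cell in self.cells:
            x = cell(x)
        return x

    def zero_residual_init(self):
        for cell in self.cells:
            cell.zero_residual_init()


class DenoisingBackbone(Module):
    """Two-level high-resolution backbone holding the attention blocks.

    The full-resolution stream keeps the majority of the blocks (no early
    downsampling); the remaining blocks run on a stride-2 branch with 2C
    channels and are fused back by nearest-neighbour upsampling, 1×1
    channel matching and addition.  Every block maps a 5D tensor to a 5D
    tensor of the same shape.
    """

    def __init__(self, cfg: BackboneConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        c = cfg.channels
        block_spec = parse_block_string(cfg.block)
        self.in_conv = Conv5D(cfg.input_channels, c, rng)
        n_lo = cfg.num_blocks // 2 if cfg.resolution_levels == 2 else 0
        n_hi = cfg.num_blocks - n_lo
        geom = cfg.geometry
        self.hi_blocks = ModuleList(
            Block(block_spec, c, geom, cfg.dropout_rate, rng)
            for _ in range(n_hi)
        )
        if n_lo:
            self.down = Conv5D(c, 2 * c, rng, stride=2)
            self.lo_blocks = ModuleList(
                Block(block_spec, 2 * c, geom, cfg.dropout_rate, rng)
                for _ in range(n_lo)
            )
            self.up_conv = Conv5D(2 * c, c, rng, kernel=1)
        self.out_conv = Conv5D(c, cfg.output_channels, rng)

    def forward(self, x: Tensor) -> Tensor:
        b, c, f, h, w = x.shape
        if c != self.cfg.input_channels:
            raise ConfigurationError(
                f"expected {self.cfg.input_channels} input channels, got {c}"
            )
        z = self.in_conv(x)
        for blk in self.hi_blocks:
            z = blk(z)
        if getattr(self, "lo_blocks", None) is not None and len(self.lo_blocks):
            lo = self.down(z)
            for blk in self.lo_blocks:
                lo = blk(lo)
            lo = self.up_conv(lo)
            lo = ad.upsample2x_nearest(lo)
            if lo.shape[-2:] != (h, w):  # stride-2 of odd sizes overshoots
                lo = ad.index_hw(lo, np.arange(h), np.arange(w))
            z = z + lo
        return self.out_conv(z)

    def zero_residual_init(self):
        for blk in list(self.hi_blocks) + list(getattr(self, "lo_blocks", [])):
            blk.zero_residual_init()


# ---------------------------------------------------------------------------
# public constructors and utilities
# ---------------------------------------------------------------------------


def build_cell(spec: CellSpec, seed: int = 0) -> Cell:
    return Cell(spec, np.random.default_rng(seed))


def build_backbone(cfg: BackboneConfig, seed: int = 0) -> DenoisingBackbone:
    return DenoisingBackbone(cfg, seed=seed)


def count_parameters(model: Module) -> int:
    """Exact count of learnable scalars."""
    return sum(p.data.size for p in model.parameters())


def parameter_breakdown(model: Module) -> dict:
    """Parameter count per top-level component name."""
    out: dict[str, int] = {}
    for name, p in model.named_parameters():
        top = name.split(".")[0]
        out[top] = out.get(top, 0) + p.data.size
    return out


def forward_denoise(model: DenoisingBackbone, x) -> np.ndarray:
    """Run the denoiser in eval mode on a (real, imag, g-map) input series.

    Returns the 2-channel complex estimate ``[B, 2, F, H, W]``; raises on
    non-finite activations.
    """
    xv = _vals(x).astype(np.float32, copy=False)
    was_training = model.training
    model.eval()
    try:
        out = model(Tensor(xv)).data
    finally:
        model.train(was_training)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("denoiser produced non-finite output")
    return out


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

_CHECKPOINT_VERSION = 1


def save_checkpoint(model: DenoisingBackbone, path) -> None:
    """Single-file archive: parameter arrays keyed by hierarchical name plus
    the full backbone configuration as embedded metadata."""
    meta = {
        "version": _CHECKPOINT_VERSION,
        "config": asdict(model.cfg),
    }
    arrays = {name: p.data for name, p in model.named_parameters()}
    with open(path, "wb") as fh:
        np.savez(fh, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> DenoisingBackbone:
    """Rebuild an identical model from a checkpoint (roundtrip exact)."""
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        if meta.get("version") != _CHECKPOINT_VERSION:
            raise ValueError(
                f"unsupported checkpoint version {meta.get('version')!r}"
            )
        cfg = BackboneConfig(**meta["config"])
        model = build_backbone(cfg, seed=0)
        params = dict(model.named_parameters())
        for name in params:
            if name not in npz:
                raise ValueError(f"checkpoint missing parameter {name!r}")
            params[name].data = npz[name].copy()
    return model
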