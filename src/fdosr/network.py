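"""Encoder/decoder architecture for arbitrary-scale 3D super-resolution.

The encoder f_theta is a residual dense network applied on the
low-resolution grid: two shallow 3D convolutions, a chain of residual
dense blocks (RDBs) whose layers each receive the concatenation of all
previous layer outputs, a global feature fusion over the concatenated RDB
outputs (1x1x1 then 3x3x3 convolution), a global residual addition of the
first shallow-convolution output, and a head convolution lifting to the
feature dimension.  An upscale step (parameter-free trilinear resampling
of the feature volume) then yields one fixed-length feature vector per
voxel of the target high-resolution grid, which is what enables arbitrary,
non-integer scale factors.  There is no pooling, no normalization, and no
encoder-to-decoder skip connection.

The decoder g_phi is a per-voxel multi-layer perceptron with shared
weights: hidden linear+ReLU layers followed by a final linear layer with
no activation, mapping each feature vector to one intensity.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import autodiff as ad
from .shapes import upsampled_dims
from .volume import Volume3D, as_factor

__all__ = [
    "EncoderConfig",
    "DecoderConfig",
    "FeatureField",
    "SRModel",
    "encode",
    "decode",
    "super_resolve",
]

DTYPE = np.float32


@dataclass(frozen=True)
class EncoderConfig:
    """Residual-dense encoder hyperparameters.

    Defaults follow the full-size architecture: 8 RDBs of 3 conv+ReLU
    layers each, 64 base channels with growth 32, a 128-dim feature head,
    3x3x3 convolutions, and 1x1x1 fusion convolutions.
    """

    n_rdb: int = 8
    layers_per_rdb: int = 3
    base_channels: int = 64
    growth_channels: int = 32
    feature_dim: int = 128
    conv_kernel: int = 3
    fusion_kernel: int = 1
    in_channels: int = 1

    def __post_init__(self) -> None:
        if self.n_rdb < 1 or self.layers_per_rdb < 1 or self.feature_dim < 1:
            raise ValueError("n_rdb, layers_per_rdb and feature_dim must be >= 1")
        if self.conv_kernel % 2 == 0 or self.fusion_kernel % 2 == 0:
            raise ValueError("convolution kernels must be odd")


@dataclass(frozen=True)
class DecoderConfig:
    """Per-voxel MLP decoder hyperparameters (``n_layers`` counts every
    linear layer, including the final one without activation)."""

    n_layers: int = 8
    hidden_width: int = 128
    output_dim: int = 1

    def __post_init__(self) -> None:
        if self.n_layers < 2:
            raise ValueError("decoder needs at least 2 layers")
        if self.output_dim != 1:
            raise ValueError("decoder emits one intensity per voxel (output_dim = 1)")


@dataclass
class FeatureField:
    """One feature vector per voxel of the target grid: (C, D, H, W)."""

    data: np.ndarray

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("FeatureField expects a (C, D, H, W) array")

    @property
    def feature_dim(self) -> int:
        return self.data.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[1:])


# ---------------------------------------------------------------------------
# parameter plan


def encoder_layer_plan(cfg: EncoderConfig) -> list[dict]:
    """Ordered inventory of encoder layers (the graph construction and the
    architecture audit both read from this plan)."""
    plan: list[dict] = []
    c = cfg.base_channels
    plan.append(dict(name="shallow1", kind="conv3d", role="shallow",
                     in_ch=cfg.in_channels, out_ch=c, kernel=cfg.conv_kernel))
    plan.append(dict(name="shallow2", kind="conv3d", role="shallow",
                     in_ch=c, out_ch=c, kernel=cfg.conv_kernel))
    for r in range(cfg.n_rdb):
        for l in range(cfg.layers_per_rdb):
            in_ch = c + l * cfg.growth_channels
            plan.append(dict(name=f"rdb{r}_layer{l}", kind="conv3d", role="rdb_layer",
                             in_ch=in_ch, out_ch=cfg.growth_channels,
                             kernel=cfg.conv_kernel, activation="relu"))
        plan.append(dict(name=f"rdb{r}_fusion", kind="conv3d", role="rdb_fusion",
                         in_ch=c + cfg.layers_per_rdb * cfg.growth_channels,
                         out_ch=c, kernel=cfg.fusion_kernel))
    plan.append(dict(name="gff1", kind="conv3d", role="global_fusion",
                     in_ch=cfg.n_rdb * c, out_ch=c, kernel=cfg.fusion_kernel))
    plan.append(dict(name="gff2", kind="conv3d", role="global_fusion",
                     in_ch=c, out_ch=c, kernel=cfg.conv_kernel))
    plan.append(dict(name="head", kind="conv3d", role="head",
                     in_ch=c, out_ch=cfg.feature_dim, kernel=cfg.conv_kernel))
    plan.append(dict(name="upscale", kind="upscale", role="upscale"))
    return plan


def decoder_layer_plan(cfg: DecoderConfig, feature_dim: int) -> list[dict]:
    plan = []
    widths = [feature_dim] + [cfg.hidden_width] * (cfg.n_layers - 1) + [cfg.output_dim]
    for i in range(cfg.n_layers):
        last = i == cfg.n_layers - 1
        plan.append(dict(name=f"mlp{i}", kind="linear", role="decoder",
                         in_ch=widths[i], out_ch=widths[i + 1],
                         activation=None if last else "relu"))
    return plan


def _init_params(
    enc: EncoderConfig, dec: DecoderConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Fan-in-scaled Gaussian initialization (He) for all conv/linear layers."""
    params: dict[str, np.ndarray] = {}
    for layer in encoder_layer_plan(enc):
        if layer["kind"] != "conv3d":
            continue
        k = layer["kernel"]
        fan_in = layer["in_ch"] * k**3
        std = np.sqrt(2.0 / fan_in)
        params[layer["name"] + "_w"] = rng.normal(
            0.0, std, size=(layer["out_ch"], layer["in_ch"], k, k, k)
        ).astype(DTYPE)
        params[layer["name"] + "_b"] = np.zeros(layer["out_ch"], dtype=DTYPE)
    dec_plan = decoder_layer_plan(dec, enc.feature_dim)
    for layer in dec_plan:
        fan_in = layer["in_ch"]
        std = np.sqrt(2.0 / fan_in)
        params[layer["name"] + "_w"] = rng.normal(
            0.0, std, size=(layer["out_ch"], layer["in_ch"])
        ).astype(DTYPE)
        params[layer["name"] + "_b"] = np.zeros(layer["out_ch"], dtype=DTYPE)
    return params


@dataclass
class SRModel:
    """Trainable state: encoder/decoder parameters plus their configs."""

    encoder_cfg: EncoderConfig
    decoder_cfg: DecoderConfig
    params: dict[str, np.ndarray]

    @classmethod
    def initialize(
        cls,
        encoder_cfg: EncoderConfig | None = None,
        decoder_cfg: DecoderConfig | None = None,
        seed: int = 0,
    ) -> "SRModel":
        enc = encoder_cfg or EncoderConfig()
        dec = decoder_cfg or DecoderConfig()
        if dec.n_layers >= 2 and enc.feature_dim < 1:
            raise ValueError("feature_dim must be positive")
        rng = np.random.default_rng(seed)
        return cls(enc, dec, _init_params(enc, dec, rng))

    def layer_inventory(self) -> list[dict]:
        """Full ordered layer listing (encoder then decoder)."""
        return encoder_layer_plan(self.encoder_cfg) + decoder_layer_plan(
            self.decoder_cfg, self.encoder_cfg.feature_dim
        )

    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def copy(self) -> "SRModel":
        return SRModel(
            self.encoder_cfg,
            self.decoder_cfg,
            {k: v.copy() for k, v in self.params.items()},
        )

    # -- serialization ------------------------------------------------------
    def save(self, path) -> None:
        meta = json.dumps(
            {"encoder_cfg": asdict(self.encoder_cfg), "decoder_cfg": asdict(self.decoder_cfg)}
        )
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **self.params)

    @classmethod
    def load(cls, path) -> "SRModel":
        with np.load(path) as f:
            meta = json.loads(bytes(f["__meta__"]).decode())
            params = {k: f[k] for k in f.files if k != "__meta__"}
        return cls(
            EncoderConfig(**meta["encoder_cfg"]),
            DecoderConfig(**meta["decoder_cfg"]),
            params,
        )


# ---------------------------------------------------------------------------
# forward passes (built on the autodiff tape; plain calls read .value)


def _as_vars(params: dict[str, np.ndarray]) -> dict[str, ad.Var]:
    return {k: ad.Var(v) for k, v in params.items()}


def encode_var(
    x: ad.Var,
    target_dims: tuple[int, int, int],
    cfg: EncoderConfig,
    p: dict[str, ad.Var],
) -> ad.Var:
    """Tape-building encoder forward; ``x`` is (1, D, H, W)."""
    shallow1 = ad.conv3d(x, p["shallow1_w"], p["shallow1_b"])
    feat = ad.conv3d(shallow1, p["shallow2_w"], p["shallow2_b"])
    rdb_outputs = []
    for r in range(cfg.n_rdb):
        block_in = feat
        local = block_in
        for l in range(cfg.layers_per_rdb):
            out = ad.relu(ad.conv3d(local, p[f"rdb{r}_layer{l}_w"], p[f"rdb{r}_layer{l}_b"]))
            local = ad.concat_channels([local, out])
        fused = ad.conv3d(local, p[f"rdb{r}_fusion_w"], p[f"rdb{r}_fusion_b"])
        feat = ad.add(fused, block_in)  # local residual
        rdb_outputs.append(feat)
    gff = ad.conv3d(ad.concat_channels(rdb_outputs), p["gff1_w"], p["gff1_b"])
    gff = ad.conv3d(gff, p["gff2_w"], p["gff2_b"])
    fused_global = ad.add(gff, shallow1)  # global residual
    head = ad.conv3d(fused_global, p["head_w"], p["head_b"])
    return ad.resize_linear_nd(head, target_dims)


def decode_var(f: ad.Var, cfg: DecoderConfig, p: dict[str, ad.Var], feature_dim: int) -> ad.Var:
    h = f
    for layer in decoder_layer_plan(cfg, feature_dim):
        h = ad.pointwise_linear(h, p[layer["name"] + "_w"], p[layer["name"] + "_b"])
        if layer["activation"] == "relu":
            h = ad.relu(h)
    return h


def forward_var(
    x: ad.Var, target_dims: tuple[int, int, int], model: SRModel, p: dict[str, ad.Var]
) -> ad.Var:
    feats = encode_var(x, target_dims, model.encoder_cfg, p)
    return decode_var(feats, model.decoder_cfg, p, model.encoder_cfg.feature_dim)


# ---------------------------------------------------------------------------
# public numpy-level operations


def encode(
    x: Volume3D, target_dims: tuple[int, int, int], model: SRModel
) -> FeatureField:
    """Extract one feature vector per voxel of the ``target_dims`` grid.

    The encoder only super-resolves: every target dimension must be at
    least the corresponding input dimension.
    """
    if any(t < n for n, t in zip(x.shape, target_dims)):
        raise ValueError(
            f"target_dims {tuple(target_dims)} smaller than input {x.shape}: "
            "this network only super-resolves"
        )
    xv = ad.Var(x.data.astype(DTYPE)[None])
    out = encode_var(xv, tuple(target_dims), model.encoder_cfg, _as_vars(model.params))
    return FeatureField(out.value)


def decode(f: FeatureField, model: SRModel) -> Volume3D:
    """Apply the shared per-voxel MLP to every feature vector."""
    if f.feature_dim != model.encoder_cfg.feature_dim:
        raise ValueError(
            f"feature width {f.feature_dim} does not match decoder input "
            f"{model.encoder_cfg.feature_dim}"
        )
    fv = ad.Var(f.data.astype(DTYPE))
    out = decode_var(fv, model.decoder_cfg, _as_vars(model.params), f.feature_dim)
    return Volume3D(out.value[0])


def super_resolve(
    x: Volume3D, s, model: SRModel, target_dims: tuple[int, int, int] | None = None
) -> Volume3D:
    """Super-resolve ``x`` by factor ``s`` (any real >= 1, non-integers included).

    Output dimensions default to ``round(dims * s)`` per axis; an explicit
    ``target_dims`` (e.g. the stored high-resolution grid during training
    or evaluation) overrides the rounding rule.
    """
    sf = as_factor(s)
    dims = tuple(target_dims) if target_dims is not None else upsampled_dims(x.shape, sf)
    feats = encode(x, dims, model)
    out = decode(feats, model)
    spacing = tuple(sp * n / m for sp, n, m in zip(x.spacing, x.shape, dims))
    return Volume3D(out.data, spacing=spacing)
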