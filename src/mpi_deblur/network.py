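"""Dual-branch CNN + efficient Transformer deblurring network.

Architecture
------------
A shared convolutional stem embeds the 1-channel native MPI image into
``base_channels`` feature channels.  Three components follow:

* **CNN module** — three stacked dual-branch stages.  In each stage one branch
  applies conv -> ReLU -> 2x2 average-pool downsampling (artifact smoothing at
  reduced resolution) and is bilinearly upsampled back before element-wise
  addition with the other branch's conv -> ReLU path.  Output ``Uc``; a 1x1
  projection head produces the branch prediction ``x_a``.

* **Transformer module** — features are downsampled, projected with a
  depth-wise separable convolution into flattened query/key/value tokens,
  passed through efficient multi-head self-attention (per-head scaled
  dot-product attention, scale ``1/sqrt(d_head)``, concatenated heads,
  averaged residual ``(O + I)/2``), refined token-wise by layer norm + MLP
  with a residual connection, reshaped and upsampled back.  Output ``Ut``;
  1x1 head produces ``x_b``.  No positional encoding is used, so the token
  pipeline after projection is permutation-equivariant.

* **Channel-attention fusion** — ``Uc`` and ``Ut`` are concatenated on the
  channel axis and fused by convolution; a squeeze-excitation gate (global
  average pool -> bottleneck -> sigmoid) reweights the channels before the
  fusion head emits the deployed prediction ``x_f``.

Training minimizes the multi-supervised loss
``lambda_a MSE(x_a, y) + lambda_b MSE(x_b, y) + lambda_f MSE(x_f, y)`` so
every branch receives a direct gradient signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat

__all__ = [
    "NetworkConfig",
    "MultiOutput",
    "Module",
    "DeblurNet",
    "multi_supervised_loss",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Hyperparameters of the deblurring network.

    ``attention_residual`` selects between the averaged residual ``(O + I)/2``
    (default, scale-stable) and the plain sum ``O + I``; ``attention_scale``
    is ``1/sqrt(d_head)`` by default.  ``transformer_downsample`` sets how many
    2x2 poolings precede tokenization (tokens = (H / 2**ds)**2).
    """

    base_channels: int = 16
    n_cnn_blocks: int = 3
    n_heads: int = 4
    embed_dim: int = 16
    mlp_ratio: float = 2.0
    lambda_a: float = 0.5
    lambda_b: float = 0.5
    lambda_f: float = 1.0
    input_size: int = 50
    attention_residual: str = "average"  # "average" -> (O+I)/2, "sum" -> O+I
    transformer_downsample: int = 2
    attention_reduction: int = 4
    use_cnn: bool = True
    use_transformer: bool = True
    use_fusion: bool = True
    use_channel_attention: bool = True

    def __post_init__(self) -> None:
        if self.embed_dim % self.n_heads != 0:
            raise ValueError("embed_dim must be divisible by n_heads")
        if self.lambda_a < 0 or self.lambda_b < 0 or self.lambda_f < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.lambda_a + self.lambda_b + self.lambda_f <= 0:
            raise ValueError("at least one loss weight must be positive")
        if not (self.use_cnn or self.use_transformer):
            raise ValueError("at least one of the CNN/Transformer branches must be enabled")
        if self.attention_residual not in ("average", "sum"):
            raise ValueError("attention_residual must be 'average' or 'sum'")


@dataclass
class MultiOutput:
    """Per-branch image-domain predictions; ``x_f`` is the deployed output."""

    x_a: Tensor | None
    x_b: Tensor | None
    x_f: Tensor

    @property
    def deployed(self) -> Tensor:
        return self.x_f


# ---------------------------------------------------------------------------
# module system


class Module:
    """Named-parameter container; parameters are discovered by attribute walk."""

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=full + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{full}.{i}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def astype(self, dtype) -> "Module":
        for p in self.parameters():
            p.data = p.data.astype(dtype)
        return self

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = sorted(set(own) ^ set(state))
            raise ValueError(f"checkpoint incompatible; mismatched parameters: {missing}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(
                    f"shape mismatch for {name}: model {p.data.shape} vs checkpoint {state[name].shape}"
                )
            p.data = np.array(state[name], dtype=p.data.dtype)


def _he(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * math.sqrt(2.0 / fan_in)).astype(dtype)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator, dtype=np.float32,
                 scale: float = 1.0):
        self.weight = Tensor(scale * _he(rng, (cout, cin, k, k), cin * k * k, dtype),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias)


class DepthwiseConv2d(Module):
    def __init__(self, channels: int, k: int, rng: np.random.Generator, dtype=np.float32):
        self.weight = Tensor(_he(rng, (channels, k, k), k * k, dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(channels, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.depthwise_conv2d(self.weight, self.bias)


class Linear(Module):
    def __init__(self, fin: int, fout: int, rng: np.random.Generator, dtype=np.float32):
        self.weight = Tensor(_he(rng, (fin, fout), fin, dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(fout, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, dtype=np.float32):
        self.gamma = Tensor(np.ones(dim, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.layer_norm(self.gamma, self.beta)


#: prediction heads start near zero so each branch output begins close to the
#: identity (input + small correction), which stabilizes early training
_HEAD_SCALE = 0.01


class DualBranchStage(Module):
    """One CNN stage: (conv-ReLU-pool, upsampled) + (conv-ReLU)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, dtype=np.float32):
        self.conv_down = Conv2d(cin, cout, 3, rng, dtype)
        self.conv_keep = Conv2d(cin, cout, 3, rng, dtype)

    def __call__(self, x: Tensor) -> Tensor:
        keep = self.conv_keep(x).relu()
        down = self.conv_down(x).relu().avg_pool2d()
        up = down.upsample_bilinear(keep.shape[2:])
        return up + keep


class DeblurNet(Module):
    """Cascaded dual-branch CNN + Transformer with channel-attention fusion."""

    def __init__(self, config: NetworkConfig, rng_seed: int = 0, dtype=np.float32):
        cfg = config
        self.config = cfg
        rng = np.random.default_rng(rng_seed)
        C, E = cfg.base_channels, cfg.embed_dim

        self.stem = Conv2d(1, C, 3, rng, dtype)

        if cfg.use_cnn:
            self.cnn_stages = [DualBranchStage(C, C, rng, dtype) for _ in range(cfg.n_cnn_blocks)]
            self.head_a = Conv2d(C, 1, 1, rng, dtype, scale=_HEAD_SCALE)

        if cfg.use_transformer:
            self.proj_depthwise = DepthwiseConv2d(C, 3, rng, dtype)
            self.proj_pointwise = Conv2d(C, 3 * E, 1, rng, dtype)
            self.wq = Linear(E, E, rng, dtype)
            self.wk = Linear(E, E, rng, dtype)
            self.wv = Linear(E, E, rng, dtype)
            self.token_residual_proj = None if C == E else Conv2d(C, E, 1, rng, dtype)
            self.norm = LayerNorm(E, dtype)
            hidden = int(round(cfg.mlp_ratio * E))
            self.mlp_in = Linear(E, hidden, rng, dtype)
            self.mlp_out = Linear(hidden, E, rng, dtype)
            self.head_b = Conv2d(E, 1, 1, rng, dtype, scale=_HEAD_SCALE)

        if cfg.use_cnn and cfg.use_transformer:
            fuse_in = C + E
        else:
            fuse_in = C if cfg.use_cnn else E
        self.fuse_conv = Conv2d(fuse_in, C, 3, rng, dtype)
        if cfg.use_channel_attention:
            r = max(1, C // cfg.attention_reduction)
            self.att_w1 = Linear(C, r, rng, dtype)
            self.att_w2 = Linear(r, C, rng, dtype)
        self.head_f_conv = Conv2d(C, C, 3, rng, dtype)
        self.head_f = Conv2d(C, 1, 1, rng, dtype, scale=_HEAD_SCALE)

    # -- CNN branch --------------------------------------------------------

    def cnn_module(self, embedded: Tensor) -> tuple[Tensor, Tensor]:
        """Dual-branch CNN stages; returns (Uc, x_a). Spatial shape preserved."""
        x = embedded
        for stage in self.cnn_stages:
            x = stage(x)
        return x, self.head_a(x)

    # -- Transformer branch --------------------------------------------------

    def conv_projection(self, feature: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        """Depth-wise separable conv -> flattened (tokens x embed) Q, K, V."""
        B, C, H, W = feature.shape
        qkv = self.proj_pointwise(self.proj_depthwise(feature))  # B, 3E, H, W
        E = self.config.embed_dim
        tokens = qkv.reshape(B, 3 * E, H * W).transpose(0, 2, 1)  # B, T, 3E
        return tokens[:, :, :E], tokens[:, :, E : 2 * E], tokens[:, :, 2 * E :]

    def emha(self, q: Tensor, k: Tensor, v: Tensor, residual_tokens: Tensor) -> Tensor:
        """Efficient multi-head self-attention with averaged residual.

        Applies the per-head linear projections, scaled dot-product attention
        with scale ``1/sqrt(d_head)`` over the key axis, concatenates head
        outputs on the channel axis and combines with the input tokens as
        ``(O + I)/2`` (or ``O + I`` when configured).  Output-equivalent to a
        naive dense attention loop; permutation-equivariant in the tokens.
        """
        cfg = self.config
        B, T, E = q.shape
        h, d = cfg.n_heads, E // cfg.n_heads
        if E % cfg.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")

        def split_heads(t: Tensor) -> Tensor:
            return t.reshape(B, T, h, d).transpose(0, 2, 1, 3)  # B,h,T,d

        qh = split_heads(self.wq(q))
        kh = split_heads(self.wk(k))
        vh = split_heads(self.wv(v))
        scores = (qh @ kh.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(d))
        attn = scores.softmax(axis=-1)
        out = attn @ vh  # B,h,T,d
        merged = out.transpose(0, 2, 1, 3).reshape(B, T, E)
        combined = merged + residual_tokens
        if cfg.attention_residual == "average":
            combined = combined * 0.5
        return combined

    def refine_tokens(self, u_emha: Tensor) -> Tensor:
        """Token-wise layer norm + two-layer MLP with residual: Ut tokens.

        Purely token-wise (no positional encoding), hence equivariant under
        any permutation of the token axis.
        """
        hidden = self.mlp_in(self.norm(u_emha)).relu()
        return self.mlp_out(hidden) + u_emha

    def transformer_module(self, feature: Tensor) -> tuple[Tensor, Tensor]:
        """Full transformer branch on a feature map; returns (Ut map, x_b)."""
        cfg = self.config
        B, C, H, W = feature.shape
        reduced = feature
        for _ in range(cfg.transformer_downsample):
            reduced = reduced.avg_pool2d()
        _, _, Hr, Wr = reduced.shape
        q, k, v = self.conv_projection(reduced)
        if self.token_residual_proj is not None:
            res_map = self.token_residual_proj(reduced)
        else:
            res_map = reduced
        res_tokens = res_map.reshape(B, cfg.embed_dim, Hr * Wr).transpose(0, 2, 1)
        u_emha = self.emha(q, k, v, res_tokens)
        ut_tokens = self.refine_tokens(u_emha)
        ut_map = ut_tokens.transpose(0, 2, 1).reshape(B, cfg.embed_dim, Hr, Wr)
        if (Hr, Wr) != (H, W):
            ut_map = ut_map.upsample_bilinear((H, W))
        return ut_map, self.head_b(ut_map)

    # -- fusion --------------------------------------------------------------

    def channel_attention_fusion(self, uc: Tensor | None, ut: Tensor | None) -> tuple[Tensor, Tensor]:
        """Concatenate branch features, fuse, gate channels, emit x_f."""
        feats = [f for f in (uc, ut) if f is not None]
        if not feats:
            raise ValueError("fusion requires at least one branch feature")
        if len(feats) == 2 and feats[0].shape[2:] != feats[1].shape[2:]:
            raise ValueError("branch features are spatially misaligned")
        merged = concat(feats, axis=1) if len(feats) > 1 else feats[0]
        uf = self.fuse_conv(merged).relu()
        if self.config.use_channel_attention:
            pooled = uf.mean(axis=(2, 3))  # B, C  (global average pool)
            gate = self.att_w2(self.att_w1(pooled).relu()).sigmoid()  # B, C in (0,1)
            B, C = gate.shape
            fused = uf * gate.reshape(B, C, 1, 1)
        else:
            fused = uf
        x_f = self.head_f(self.head_f_conv(fused).relu())
        return fused, x_f

    # -- end to end ----------------------------------------------------------

    def forward(self, image) -> MultiOutput:
        """Run the network on a batch; accepts (B,1,H,W), (B,H,W) or (H,W)."""
        x = image if isinstance(image, Tensor) else Tensor(np.asarray(image))
        if x.ndim == 2:
            x = x.reshape(1, 1, *x.shape)
        elif x.ndim == 3:
            x = x.reshape(x.shape[0], 1, *x.shape[1:])
        cfg = self.config
        embedded = self.stem(x).relu()
        uc = x_a = ut = x_b = None
        if cfg.use_cnn:
            uc, x_a = self.cnn_module(embedded)
            x_a = x_a + x  # heads predict a correction to the native image
        if cfg.use_transformer:
            trans_in = uc if cfg.use_cnn else embedded
            ut, x_b = self.transformer_module(trans_in)
            x_b = x_b + x
        if cfg.use_fusion and cfg.use_cnn and cfg.use_transformer:
            _, x_f = self.channel_attention_fusion(uc, ut)
            x_f = x_f + x
        elif cfg.use_cnn and cfg.use_transformer:
            # no fusion stage: deploy the average of the branch heads
            x_f = (x_a + x_b) * 0.5
        else:
            # single-branch variants deploy that branch's features through the head
            _, x_f = self.channel_attention_fusion(uc if cfg.use_cnn else None,
                                                   ut if cfg.use_transformer else None)
            x_f = x_f + x
        return MultiOutput(x_a=x_a, x_b=x_b, x_f=x_f)

    __call__ = forward


def multi_supervised_loss(pred: MultiOutput, target, config: NetworkConfig) -> Tensor:
    """Weighted sum of per-head mean squared errors against the clean phantom.

    ``lambda_a``/``lambda_b``/``lambda_f`` weight the CNN, Transformer and
    fusion heads; heads absent from an ablation variant contribute nothing.
    Zero iff every weighted head reproduces the target exactly.
    """
    if config.lambda_a + config.lambda_b + config.lambda_f <= 0:
        raise ValueError("at least one loss weight must be positive")
    y = target if isinstance(target, Tensor) else Tensor(np.asarray(target))
    if y.ndim == 2:
        y = y.reshape(1, 1, *y.shape)
    elif y.ndim == 3:
        y = y.reshape(y.shape[0], 1, *y.shape[1:])
    total = None
    for lam, head in ((config.lambda_a, pred.x_a), (config.lambda_b, pred.x_b), (config.lambda_f, pred.x_f)):
        if lam == 0 or head is None:
            continue
        if head.shape != y.shape:
            raise ValueError(f"prediction shape {head.shape} != target shape {y.shape}")
        term = ((head - y) ** 2).mean() * lam
        total = term if total is None else total + term
    if total is None:
        raise ValueError("no supervised head available for the configured loss weights")
    return total
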