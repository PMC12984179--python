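"""Transformer generator and CNN discriminator for stain translation.

The generator embeds non-overlapping P x P patches of the input tile into
D-dimensional tokens (``Z = X W_e``, ``N = H W / P^2`` tokens), adds learned
positional embeddings, runs a pre-norm transformer encoder (multi-head
self-attention + GELU feed-forward blocks), reshapes the token sequence
into a sqrt(N) x sqrt(N) feature map and upsamples it back to the tile
resolution with log2(P) stride-2 transposed convolutions, ending in tanh
to match the [-1, 1] pixel normalization.  The discriminator is a small
strided CNN with LeakyReLU activations and instance normalization whose
sigmoid output is a patch-level probability map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor

__all__ = ["TbGanHyperparams", "GanConfig", "Linear", "LayerNorm",
           "MultiHeadSelfAttention", "FeedForward", "TransformerBlock",
           "PatchEmbed", "Decoder", "Generator", "Discriminator",
           "patch_count"]


def patch_count(height: int, width: int, patch_side: int) -> int:
    """Token-sequence length ``N = H * W / P^2`` of a patch-embedded tile."""
    if height % patch_side or width % patch_side:
        raise ValueError("tile dimensions must be divisible by the patch side")
    return (height * width) // (patch_side * patch_side)


@dataclass
class TbGanHyperparams:
    """Architecture and optimization settings.

    Defaults are the full-scale training configuration: 256 x 256 RGBA
    tiles, 8 x 8 patch embedding (N = 1024 tokens), Adam at learning rate
    1e-5 with betas (0.5, 0.999), batch size 1 with gradient accumulation
    over 8 virtual batches, and up to 200 epochs with early stopping on a
    validation-loss plateau.  ``smoke()`` returns a desk-scale profile used
    throughout the test-suite.
    """

    input_shape: tuple[int, int, int] = (256, 256, 4)
    patch_side: int = 8
    embed_dim: int = 256
    n_layers: int = 6
    n_heads: int = 8
    ffn_hidden: int | None = None        # default 4 * embed_dim
    lambda_cycle: float = 10.0
    lambda_identity: float = 3.0
    lr: float = 1e-5
    betas: tuple[float, float] = (0.5, 0.999)
    epochs: int = 200
    early_stop_patience: int = 10
    grad_accum_steps: int = 8
    #: per-head attention scaling 1/sqrt(D/h); False uses the literal 1/sqrt(D)
    per_head_scale: bool = True
    seed: int = 0

    def __post_init__(self):
        h, w, _ = self.input_shape
        if h % self.patch_side or w % self.patch_side:
            raise ValueError("input dims must be divisible by patch_side")
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        if self.ffn_hidden is None:
            self.ffn_hidden = 4 * self.embed_dim

    @property
    def n_tokens(self) -> int:
        return patch_count(self.input_shape[0], self.input_shape[1], self.patch_side)

    @classmethod
    def smoke(cls, seed: int = 0, lr: float = 1e-3) -> "TbGanHyperparams":
        """Tiny profile (32x32 tiles, D=64, 2 layers) for fast seeded runs."""
        return cls(input_shape=(32, 32, 4), embed_dim=64, n_layers=2,
                   n_heads=4, lr=lr, grad_accum_steps=2, seed=seed)


@dataclass
class GanConfig:
    """One of the four training configurations.

    The label reads ``<variant>/<lambda_cycle>/<lambda_identity>``: O uses
    original tiles, R Reinhard-normalized tiles; the emphasized loss gets
    weight 10 and the de-emphasized one 3.
    """

    input_variant: str                 # "original" | "reinhard"
    lambdas: tuple[float, float]       # (lambda_cycle, lambda_identity)

    ALL_LABELS = ("O/10/3", "O/3/10", "R/10/3", "R/3/10")

    @property
    def label(self) -> str:
        v = "O" if self.input_variant == "original" else "R"
        return f"{v}/{int(self.lambdas[0])}/{int(self.lambdas[1])}"

    @classmethod
    def from_label(cls, label: str) -> "GanConfig":
        v, lc, li = label.split("/")
        if v not in ("O", "R") or {float(lc), float(li)} != {10.0, 3.0}:
            raise ValueError(f"unknown configuration label {label!r}")
        return cls(input_variant="original" if v == "O" else "reinhard",
                   lambdas=(float(lc), float(li)))


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Module:
    def params(self) -> list[Tensor]:
        out = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out += v.params()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out += item.params()
        return out


def _init(rng, *shape, scale=None):
    scale = scale if scale is not None else 1.0 / np.sqrt(shape[0])
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, rng, n_in, n_out):
        self.w = _init(rng, n_in, n_out)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class LayerNorm(Module):
    """Normalize the last axis to zero mean / unit variance, then affine."""

    def __init__(self, dim, eps: float = 1e-6):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xhat = xc * ((var + self.eps) ** -0.5)
        return xhat * self.gamma + self.beta


class MultiHeadSelfAttention(Module):
    """Scaled dot-product attention over the token sequence.

    ``Attention(Q, K, V) = softmax(Q K^T / sqrt(d)) V`` per head, with
    d = D/h under the per-head scaling convention (a flag restores the
    literal 1/sqrt(D)).
    """

    def __init__(self, rng, dim, n_heads, per_head_scale: bool = True):
        self.wq = _init(rng, dim, dim)
        self.wk = _init(rng, dim, dim)
        self.wv = _init(rng, dim, dim)
        self.wo = _init(rng, dim, dim)
        self.n_heads = n_heads
        self.dim = dim
        self.scale = 1.0 / np.sqrt(dim // n_heads if per_head_scale else dim)

    def attention_weights(self, z: Tensor) -> Tensor:
        b, n, d = z.shape
        h, dh = self.n_heads, self.dim // self.n_heads
        q = (z @ self.wq).reshape(b, n, h, dh).transpose(0, 2, 1, 3)
        k = (z @ self.wk).reshape(b, n, h, dh).transpose(0, 2, 1, 3)
        return ((q @ k.transpose(0, 1, 3, 2)) * self.scale).softmax(axis=-1)

    def __call__(self, z: Tensor) -> Tensor:
        b, n, d = z.shape
        h, dh = self.n_heads, self.dim // self.n_heads
        att = self.attention_weights(z)
        v = (z @ self.wv).reshape(b, n, h, dh).transpose(0, 2, 1, 3)
        out = (att @ v).transpose(0, 2, 1, 3).reshape(b, n, d)
        return out @ self.wo


class FeedForward(Module):
    """``FFN(z) = W2 GELU(W1 z + b1) + b2``."""

    def __init__(self, rng, dim, hidden):
        self.fc1 = Linear(rng, dim, hidden)
        self.fc2 = Linear(rng, hidden, dim)

    def __call__(self, z: Tensor) -> Tensor:
        return self.fc2(self.fc1(z).gelu())


class TransformerBlock(Module):
    """Pre-norm block: LN -> MSA -> residual, LN -> FFN -> residual."""

    def __init__(self, rng, dim, n_heads, hidden, per_head_scale=True):
        self.ln1 = LayerNorm(dim)
        self.msa = MultiHeadSelfAttention(rng, dim, n_heads, per_head_scale)
        self.ln2 = LayerNorm(dim)
        self.ffn = FeedForward(rng, dim, hidden)

    def __call__(self, z: Tensor) -> Tensor:
        z = z + self.msa(self.ln1(z))
        return z + self.ffn(self.ln2(z))


class PatchEmbed(Module):
    """Flatten non-overlapping P x P x C patches and project to D dims."""

    def __init__(self, rng, patch_side, channels, dim):
        self.we = _init(rng, patch_side * patch_side * channels, dim)
        self.p = patch_side
        self.c = channels

    def tokens(self, x: Tensor) -> Tensor:
        """(B, H, W, C) -> (B, N, P*P*C), row-major channel-last patches."""
        b, h, w, c = x.shape
        p = self.p
        return (x.reshape(b, h // p, p, w // p, p, c)
                 .transpose(0, 1, 3, 2, 4, 5)
                 .reshape(b, (h // p) * (w // p), p * p * c))

    def __call__(self, x: Tensor) -> Tensor:
        return self.tokens(x) @ self.we


class Decoder(Module):
    """Token map -> image: log2(P) stride-2 transposed convolutions + tanh."""

    def __init__(self, rng, dim, patch_side, out_channels):
        n_stages = int(np.log2(patch_side))
        if 2 ** n_stages != patch_side:
            raise ValueError("patch_side must be a power of two")
        chans = [dim]
        for i in range(n_stages - 1):
            chans.append(max(8, dim // 2 ** (i + 1)))
        chans.append(out_channels)
        self.weights = [
            Tensor(rng.normal(0, 1.0 / np.sqrt(ci * 16), size=(ci, co, 4, 4)),
                   requires_grad=True)
            for ci, co in zip(chans[:-1], chans[1:])]

    def params(self):
        return list(self.weights)

    def __call__(self, z: Tensor) -> Tensor:
        """(B, N, D) tokens -> (B, H, W, C) image in [-1, 1]."""
        b, n, d = z.shape
        side = int(np.sqrt(n))
        if side * side != n:
            raise ValueError("token count must be a perfect square")
        x = z.reshape(b, side, side, d).transpose(0, 3, 1, 2)
        for i, w in enumerate(self.weights):
            x = x.conv_transpose2d(w, stride=2, padding=1)
            if i < len(self.weights) - 1:
                x = x.leaky_relu(0.2)
        return x.transpose(0, 2, 3, 1).tanh()


class Generator(Module):
    """Patch embedding + positional embedding + transformer + decoder."""

    def __init__(self, hyper: TbGanHyperparams, rng: np.random.Generator):
        h, w, c = hyper.input_shape
        self.embed = PatchEmbed(rng, hyper.patch_side, c, hyper.embed_dim)
        self.pos = Tensor(rng.normal(0, 0.02, size=(1, hyper.n_tokens,
                                                    hyper.embed_dim)),
                          requires_grad=True)
        self.blocks = [TransformerBlock(rng, hyper.embed_dim, hyper.n_heads,
                                        hyper.ffn_hidden, hyper.per_head_scale)
                       for _ in range(hyper.n_layers)]
        self.ln_f = LayerNorm(hyper.embed_dim)
        self.decoder = Decoder(rng, hyper.embed_dim, hyper.patch_side, c)
        self.hyper = hyper

    def __call__(self, x: Tensor) -> Tensor:
        z = self.embed(x) + self.pos
        for blk in self.blocks:
            z = blk(z)
        return self.decoder(self.ln_f(z))


class InstanceNorm(Module):
    """Per-sample, per-channel normalization over the spatial axes."""

    def __init__(self, channels, eps: float = 1e-6):
        self.gamma = Tensor(np.ones((1, channels, 1, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1)), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(2, 3), keepdims=True)
        return xc * ((var + self.eps) ** -0.5) * self.gamma + self.beta


class Discriminator(Module):
    """Strided CNN -> sigmoid probability map (``D(X) = sigma(Conv(X))``)."""

    def __init__(self, hyper: TbGanHyperparams, rng: np.random.Generator,
                 base_channels: int = 16):
        c = hyper.input_shape[2]
        nf = base_channels
        def conv_w(ci, co, k):
            return Tensor(rng.normal(0, 1.0 / np.sqrt(ci * k * k),
                                     size=(co, ci, k, k)), requires_grad=True)
        self.w1 = conv_w(c, nf, 4)
        self.w2 = conv_w(nf, nf * 2, 4)
        self.inorm2 = InstanceNorm(nf * 2)
        self.w3 = conv_w(nf * 2, nf * 4, 4)
        self.inorm3 = InstanceNorm(nf * 4)
        self.w_out = conv_w(nf * 4, 1, 3)

    def params(self):
        return ([self.w1, self.w2, self.w3, self.w_out]
                + self.inorm2.params() + self.inorm3.params())

    def __call__(self, x: Tensor) -> Tensor:
        """(B, H, W, C) in [-1, 1] -> (B, h', w') probabilities in (0, 1)."""
        y = x.transpose(0, 3, 1, 2)
        y = y.conv2d(self.w1, stride=2, padding=1).leaky_relu(0.2)
        y = self.inorm2(y.conv2d(self.w2, stride=2, padding=1)).leaky_relu(0.2)
        y = self.inorm3(y.conv2d(self.w3, stride=2, padding=1)).leaky_relu(0.2)
        y = y.conv2d(self.w_out, stride=1, padding=1).sigmoid()
        return y.reshape(y.shape[0], y.shape[2], y.shape[3])
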