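"""Conditional denoising-diffusion model for timepoint imputation.

The forward process corrupts the clr profile at the hidden (target)
timepoints with Gaussian noise over T steps; a denoising network ε̂(x_t, t |
x^co) — a per-phylum convolutional front-end followed by residual layers
with transformer encoders over the temporal and feature axes — is trained to
predict the injected noise (the standard DDPM ε-objective, restricted to
target entries).  Imputation runs the learned reverse chain from pure noise
at the target timepoints while the conditional timepoints are held fixed at
their observed clr values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .metadata import FeatureTokenizer, concat_channel, concat_spatial
from .missingness import TimepointMask, training_split
from .nn import (
    Adam,
    BlockConv1d,
    Linear,
    Module,
    Tensor,
    TransformerEncoderLayer,
    diffusion_step_embedding,
    no_grad,
    stack,
)

__all__ = [
    "NoiseSchedule",
    "make_schedule",
    "forward_diffuse",
    "DenoiserConfig",
    "TrainConfig",
    "PhylumDenoiser",
    "training_loss",
    "train",
    "impute",
    "ImputationResult",
]


# --------------------------------------------------------------------------
# noise schedule
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseSchedule:
    T: int
    beta: np.ndarray        # β_1..β_T
    alpha: np.ndarray       # α_t = 1 − β_t
    alpha_bar: np.ndarray   # ᾱ_t = Π_{u≤t} α_u

    def __post_init__(self):
        if np.any(self.beta <= 0) or np.any(self.beta >= 1):
            raise ValueError("beta values must lie in (0, 1)")
        if np.any(np.diff(self.alpha_bar) >= 0):
            raise ValueError("alpha_bar must be strictly decreasing")


def make_schedule(T: int = 50, beta_start: float = 1e-4, beta_end: float = 0.5,
                  kind: str = "quadratic") -> NoiseSchedule:
    """Build a β schedule; the quadratic ramp interpolates on the √β scale."""
    if not (0 < beta_start < beta_end < 1):
        raise ValueError("need 0 < beta_start < beta_end < 1")
    if T < 2:
        raise ValueError("T must be at least 2")
    grid = np.arange(T) / (T - 1)
    if kind == "quadratic":
        beta = (math.sqrt(beta_start) + grid * (math.sqrt(beta_end) - math.sqrt(beta_start))) ** 2
    elif kind == "linear":
        beta = beta_start + grid * (beta_end - beta_start)
    else:
        raise ValueError(f"unknown schedule kind {kind!r}")
    alpha = 1.0 - beta
    return NoiseSchedule(T, beta, alpha, np.cumprod(alpha))


def forward_diffuse(x0: np.ndarray, t: int | np.ndarray, eps: np.ndarray,
                    sched: NoiseSchedule) -> np.ndarray:
    """Closed-form forward marginal x_t = √ᾱ_t·x0 + √(1−ᾱ_t)·ε.

    ``t`` may be a scalar or a per-subject array of steps in 1..T (the
    per-subject form broadcasts over the trailing axes of ``x0``).
    """
    t = np.asarray(t)
    if np.any(t < 1) or np.any(t > sched.T):
        raise ValueError("t out of range 1..T")
    abar = sched.alpha_bar[t - 1]
    if t.ndim > 0 and x0.ndim > 1:
        abar = abar.reshape((-1,) + (1,) * (x0.ndim - 1))
    return np.sqrt(abar) * x0 + np.sqrt(1.0 - abar) * eps


# --------------------------------------------------------------------------
# denoiser
# --------------------------------------------------------------------------

@dataclass
class DenoiserConfig:
    channels: int = 64
    residual_layers: int = 4
    phylum_kernel: int = 3
    diffusion_embedding_dim: int = 128
    time_embedding_dim: int = 16
    feature_embedding_dim: int = 16
    metadata_strategy: str = "none"     # none | spatial | channel
    metadata_embed_dim: int = 8
    heads: int = 8

    def __post_init__(self):
        if self.phylum_kernel % 2 == 0:
            raise ValueError("phylum_kernel must be odd")
        if self.metadata_strategy not in ("none", "spatial", "channel"):
            raise ValueError(f"unknown metadata_strategy {self.metadata_strategy!r}")


@dataclass
class TrainConfig:
    epochs: int = 200
    lr: float = 1e-3
    batch: int = 16
    seed: int = 0
    # step decay: lr × 0.1 at 75% and again at 90% of the epochs
    lr_decay: bool = True


class PhylumDenoiser(Module):
    """ε-prediction network with a per-phylum convolutional input stage.

    Input: the conditional clr plane, the noisy target plane and the
    conditional-mask plane, stacked as channels of shape [L × K] (the mask
    plane lets the network tell a masked-out zero from a true zero).  Each
    phylum's contiguous feature block is
    convolved along the feature axis with its own kernel; block outputs are
    concatenated back to width K and rectified.  Residual layers then apply a
    single-layer transformer encoder over the temporal axis and one over the
    feature axis, with the diffusion-step embedding injected additively.
    Metadata tokens enter either as extra feature columns (spatial) or as
    extra channels (channel-wise).
    """

    def __init__(self, config: DenoiserConfig, blocks: list[tuple[int, int]],
                 n_features: int, n_timepoints: int,
                 vocab_sizes: list[int] | None = None,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.config = config
        self.blocks = list(blocks)
        self.K = n_features
        self.L = n_timepoints
        covered = sorted(i for a, b in self.blocks for i in range(a, b))
        if covered != list(range(n_features)):
            raise ValueError("phylum blocks not contiguous")

        C = config.channels
        vocab_sizes = vocab_sizes or []
        self.n_meta = len(vocab_sizes)
        nd = self.n_meta * config.metadata_embed_dim
        if config.metadata_strategy == "none" or self.n_meta == 0:
            nd = 0
        # model width seen by the residual stack
        self.width = self.K + nd if config.metadata_strategy == "spatial" else self.K
        self.d_model = C + nd if config.metadata_strategy == "channel" else C
        if self.d_model % config.heads:
            raise ValueError("effective channel count must be divisible by heads")

        self.input_conv = BlockConv1d(self.blocks, 3, C, config.phylum_kernel, rng)
        if nd and config.metadata_strategy != "none":
            self.tokenizer = FeatureTokenizer(vocab_sizes, config.metadata_embed_dim, rng)
        else:
            self.tokenizer = None

        D = self.d_model
        # learned positional content for the two axes
        self.feature_pos = Tensor(rng.normal(0, 0.02, (self.width, D)), requires_grad=True)
        self.time_pos = Tensor(rng.normal(0, 0.02, (self.L, D)), requires_grad=True)
        # diffusion-step embedding MLP
        self.step_fc1 = Linear(config.diffusion_embedding_dim, D, rng)
        self.step_fc2 = Linear(D, D, rng)
        self.temporal_layers = [
            TransformerEncoderLayer(D, config.heads, 2 * D, rng)
            for _ in range(config.residual_layers)
        ]
        self.feature_layers = [
            TransformerEncoderLayer(D, config.heads, 2 * D, rng)
            for _ in range(config.residual_layers)
        ]
        # gated residual blocks: filter/gate projection plus residual and
        # skip heads, with skips accumulated into the output stage
        self.mid_proj = [Linear(D, 2 * D, rng) for _ in range(config.residual_layers)]
        self.res_proj = [Linear(D, D, rng) for _ in range(config.residual_layers)]
        self.skip_proj = [Linear(D, D, rng) for _ in range(config.residual_layers)]
        self.out_proj1 = Linear(D, D, rng)
        self.out_proj2 = Linear(D, 1, rng)
        # start the output near zero for a stable early loss (≈ E[ε²] = 1)
        self.out_proj2.W.data *= 0.01

    # -- forward -----------------------------------------------------------
    def __call__(self, noisy_target: Tensor | np.ndarray,
                 conditional: Tensor | np.ndarray,
                 cond_mask: np.ndarray,
                 t: np.ndarray,
                 metadata_codes: np.ndarray | None = None) -> Tensor:
        """Predict ε for a batch: planes are [B, L, K]; cond_mask is the
        [B, L] conditional-timepoint indicator; t is [B] in 1..T."""
        noisy = noisy_target if isinstance(noisy_target, Tensor) else Tensor(noisy_target)
        cond = conditional if isinstance(conditional, Tensor) else Tensor(conditional)
        B, L, K = noisy.shape
        mask_plane = Tensor(np.repeat(
            np.asarray(cond_mask, dtype=np.float64)[:, :, None], K, axis=2))
        x = stack([cond, noisy, mask_plane], axis=1)          # [B,3,L,K]
        h = self.input_conv(x).relu()                         # [B,C,L,K]

        if self.tokenizer is not None:
            emb = self.tokenizer(metadata_codes if metadata_codes is not None
                                 else np.zeros((B, self.n_meta), dtype=np.int64))
            if self.config.metadata_strategy == "spatial":
                h = concat_spatial(h, emb)                    # [B,C,L,K+nd]
            else:
                h = concat_channel(h, emb)                    # [B,C+nd,L,K]

        h = h.transpose(0, 2, 3, 1)                           # [B,L,W,D]
        W, D = self.width, self.d_model
        pos = self.feature_pos.reshape(1, 1, W, D) + self.time_pos.reshape(1, L, 1, D)
        h = h + pos

        step = diffusion_step_embedding(t, self.config.diffusion_embedding_dim)
        step = self.step_fc2(self.step_fc1(Tensor(step)).silu())   # [B,D]
        step = step.reshape(B, 1, 1, D)

        skip_sum = None
        n_layers = len(self.temporal_layers)
        for i, (temporal, feature) in enumerate(
                zip(self.temporal_layers, self.feature_layers)):
            # positional content is re-injected each layer so axis identity
            # survives the residual mixing
            y = h + step + pos
            y = y.transpose(0, 2, 1, 3).reshape(B * W, L, D)       # over time
            y = temporal(y)
            y = y.reshape(B, W, L, D).transpose(0, 2, 1, 3)
            y = y.reshape(B * L, W, D)                             # over features
            y = feature(y)
            y = y.reshape(B, L, W, D)
            fg = self.mid_proj[i](y)                               # [B,L,W,2D]
            z = fg[..., :D].tanh() * fg[..., D:].sigmoid()
            h = (h + self.res_proj[i](z)) * (1.0 / math.sqrt(2.0))
            skip = self.skip_proj[i](z)
            skip_sum = skip if skip_sum is None else skip_sum + skip

        out = skip_sum * (1.0 / math.sqrt(n_layers))
        out = self.out_proj2(self.out_proj1(out).relu())      # [B,L,W,1]
        out = out.reshape(B, L, W)
        if W != K:
            out = out[:, :, :K]                               # drop metadata columns
        return out


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

def _expand(mask: np.ndarray, K: int) -> np.ndarray:
    """[B, L] timepoint mask -> [B, L, K] entry mask."""
    return np.repeat(np.asarray(mask, dtype=np.float64)[:, :, None], K, axis=2)


def training_loss(denoiser: PhylumDenoiser, x0: np.ndarray, split: TimepointMask,
                  sched: NoiseSchedule, rng: np.random.Generator,
                  metadata_codes: np.ndarray | None = None) -> Tensor:
    """ε-prediction objective: mean squared error between the injected and
    the predicted noise over the target entries only."""
    B, L, K = x0.shape
    ta = _expand(split.target, K)
    co = _expand(split.cond, K)
    if ta.sum() == 0:
        raise ValueError("empty target set")
    t = rng.integers(1, sched.T + 1, size=B)
    eps = rng.standard_normal(x0.shape)
    xt = forward_diffuse(x0, t, eps, sched)
    noisy_plane = ta * xt
    cond_plane = co * x0
    eps_hat = denoiser(noisy_plane, cond_plane, split.cond, t, metadata_codes)
    ta_t = Tensor(ta)
    resid = (Tensor(eps) - eps_hat) * ta_t
    return (resid * resid).sum() / float(ta.sum())


def train(x0: np.ndarray, observed: np.ndarray, denoiser: PhylumDenoiser,
          sched: NoiseSchedule, hyper: TrainConfig,
          metadata_codes: np.ndarray | None = None) -> list[float]:
    """Self-supervised training loop; returns per-epoch mean losses.

    ``x0`` is the clr tensor [S, L, K] in feature-ordering space; every
    iteration draws a fresh conditional/target split per subject.
    """
    S = x0.shape[0]
    rng = np.random.default_rng(hyper.seed)
    opt = Adam(denoiser.parameters(), lr=hyper.lr)
    history: list[float] = []
    for epoch in range(hyper.epochs):
        if hyper.lr_decay:
            if epoch == int(0.9 * hyper.epochs):
                opt.lr = hyper.lr * 0.01
            elif epoch == int(0.75 * hyper.epochs):
                opt.lr = hyper.lr * 0.1
        order = rng.permutation(S)
        losses = []
        for start in range(0, S, hyper.batch):
            idx = order[start:start + hyper.batch]
            split = training_split(observed[idx], rng)
            codes = metadata_codes[idx] if metadata_codes is not None else None
            loss = training_loss(denoiser, x0[idx], split, sched, rng, codes)
            if not np.isfinite(loss.data):
                raise FloatingPointError("non-finite training loss")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)))
    return history


# --------------------------------------------------------------------------
# imputation (conditional reverse sampling)
# --------------------------------------------------------------------------

@dataclass
class ImputationResult:
    draws: np.ndarray           # [D, S, L, K] clr scale
    point: np.ndarray           # [S, L, K] per-entry median of draws
    target_mask: TimepointMask

    def __post_init__(self):
        self.draws = np.asarray(self.draws)
        self.point = np.asarray(self.point)


def impute(denoiser: PhylumDenoiser, x: np.ndarray, mask: TimepointMask,
           sched: NoiseSchedule, n_draws: int = 50, seed: int = 0,
           metadata_codes: np.ndarray | None = None) -> ImputationResult:
    """Sample the conditional reverse chain at the target timepoints.

    Conditional timepoints are held fixed at their observed clr values
    throughout (and are copied bitwise into every draw); target timepoints
    start from standard normal noise and are denoised over T steps using the
    DDPM posterior variance σ_t² = β_t·(1−ᾱ_{t−1})/(1−ᾱ_t), with σ_1 = 0.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be ≥ 1")
    S, L, K = x.shape
    ta = _expand(mask.target, K)
    co = _expand(mask.cond, K)
    cond_plane = co * x
    rng = np.random.default_rng(seed)
    # all draws run through the denoiser as one batch of size n_draws·S
    D = n_draws
    ta_b = np.tile(ta, (D, 1, 1))
    cond_b = np.tile(cond_plane, (D, 1, 1))
    cmask_b = np.tile(mask.cond, (D, 1))
    codes_b = (np.tile(metadata_codes, (D, 1))
               if metadata_codes is not None else None)
    with no_grad():
        xt = ta_b * rng.standard_normal((D * S, L, K))
        for t in range(sched.T, 0, -1):
            beta = sched.beta[t - 1]
            alpha = sched.alpha[t - 1]
            abar = sched.alpha_bar[t - 1]
            eps_hat = denoiser(ta_b * xt, cond_b, cmask_b,
                               np.full(D * S, t), codes_b).data
            mean = (xt - beta / math.sqrt(1.0 - abar) * eps_hat) / math.sqrt(alpha)
            if t > 1:
                abar_prev = sched.alpha_bar[t - 2]
                sigma = math.sqrt(beta * (1.0 - abar_prev) / (1.0 - abar))
                mean = mean + sigma * rng.standard_normal((D * S, L, K))
            xt = ta_b * mean
    draws = (ta_b * xt + cond_b).reshape(D, S, L, K)
    point = np.median(draws, axis=0)
    point = np.where(co > 0, x, point)   # conditional entries exactly preserved
    return ImputationResult(draws, point, mask)
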