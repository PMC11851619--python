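"""Training: composite L1 + frequency-domain loss, arbitrary-factor
sampling, Adam optimization, and a stepped learning-rate schedule.

Each optimization step draws a fresh scale factor s ~ U[2, 4], degrades
one high-resolution phantom to its low-resolution counterpart at that
factor, runs the network, and minimizes

    L = ||y - g(f(x))||_1 / N  +  lambda * ||mask (FFT3D[y] - FFT3D[g(f(x))])||_1

i.e. a mean-absolute data-consistency term plus the masked
frequency-domain L1 penalty.  The spectral term is reduced as a plain sum
over the kept coefficients by default (see ``TrainingConfig.freq_reduction``):
at desk scale this keeps lambda = 1e-3 in the regime where the penalty is
neither inert nor dominant.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .frequency import FrequencyMask, build_mask, fd_residual
from .network import DTYPE, DecoderConfig, EncoderConfig, SRModel, forward_var
from .phantom import degrade, sample_scale
from .volume import Volume3D

__all__ = [
    "TrainingConfig",
    "TrainingHistory",
    "TrainingDivergedError",
    "composite_loss",
    "lr_at_epoch",
    "train",
    "kfold_split",
]


class TrainingDivergedError(RuntimeError):
    """Raised when the loss becomes non-finite or grows without bound."""


def desk_training_config(**overrides) -> "TrainingConfig":
    """Desk-scale optimization settings for short CPU runs.

    The full-scale reference schedule (lr 1e-4 over 2400 epochs) needs far
    more steps than a desk run affords; for runs of a few hundred steps the
    package uses lr 1e-3 with global-norm gradient clipping at 1.0 and a
    shorter Adam second-moment horizon (beta2 = 0.99), which converges
    quickly and stably on the phantom corpora.
    """
    base = dict(
        lr_initial=1e-3, grad_clip=1.0, adam_beta2=0.99, epochs=200, max_steps=200,
        val_every_epochs=3,
    )
    base.update(overrides)
    return TrainingConfig(**base)


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization hyperparameters.

    ``epochs`` defaults to a desk-scale 200 (the full-scale reference run
    is 2400); the learning rate starts at 1e-4 and is multiplied by
    ``lr_gamma`` every ``lr_step_epochs`` epochs.  ``max_steps`` caps the
    total number of optimization steps regardless of epochs.
    """

    lambda_reg: float = 1e-3
    epochs: int = 200
    lr_initial: float = 1e-4
    lr_step_epochs: int = 200
    lr_gamma: float = 0.5
    batch_size: int = 1
    patch_size: tuple[int, int, int] | None = None
    seed: int = 0
    mask_fraction: float = 0.3
    scale_range: tuple[float, float] = (2.0, 4.0)
    freq_reduction: str = "sum"
    max_steps: int | None = None
    degrade_method: str = "trilinear"
    grad_clip: float | None = None
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    val_every_epochs: int = 200
    divergence_ratio: float = 1e3
    divergence_patience: int = 10

    def __post_init__(self) -> None:
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be >= 0")
        if self.lr_initial <= 0:
            raise ValueError("lr_initial must be > 0")
        if not (0 < self.lr_gamma <= 1):
            raise ValueError("lr_gamma must lie in (0, 1]")
        if self.freq_reduction not in ("mean", "sum"):
            raise ValueError("freq_reduction must be 'mean' or 'sum'")


@dataclass
class TrainingHistory:
    """Per-epoch records of the optimization trajectory."""

    total: list[float] = field(default_factory=list)
    data_term: list[float] = field(default_factory=list)
    reg_term: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    scales: list[list[float]] = field(default_factory=list)
    val_psnr: list[tuple[int, float]] = field(default_factory=list)
    steps: int = 0

    @property
    def epochs_run(self) -> int:
        return len(self.total)

    def to_records(self) -> list[dict]:
        return [
            dict(epoch=i, total=self.total[i], data_term=self.data_term[i],
                 reg_term=self.reg_term[i], lr=self.lr[i], scales=self.scales[i])
            for i in range(self.epochs_run)
        ]


def composite_loss(
    y_hat: Volume3D,
    y: Volume3D,
    mask: FrequencyMask,
    lambda_reg: float,
    reduction: str = "sum",
) -> tuple[float, float, float]:
    """Evaluate the training objective on a prediction/reference pair.

    Returns ``(total, data_term, reg_term)`` with
    ``total = data_term + lambda_reg * reg_term``; the data term is the
    mean absolute voxel difference and the regularization term is
    :func:`fdosr.frequency.fd_residual`.
    """
    if y_hat.shape != y.shape:
        raise ValueError(f"shape mismatch: {y_hat.shape} vs {y.shape}")
    data_term = float(np.abs(y_hat.data.astype(np.float64) - y.data.astype(np.float64)).mean())
    reg_term = fd_residual(y_hat, y, mask, reduction=reduction)
    return data_term + lambda_reg * reg_term, data_term, reg_term


def lr_at_epoch(epoch: int, cfg: TrainingConfig) -> float:
    """Stepped schedule: lr_initial * lr_gamma ** floor(epoch / lr_step_epochs)."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return cfg.lr_initial * cfg.lr_gamma ** (epoch // cfg.lr_step_epochs)


class _Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params: dict[str, np.ndarray], beta1=0.9, beta2=0.999, eps=1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray], lr: float):
        self.t += 1
        b1c = 1 - self.beta1**self.t
        b2c = 1 - self.beta2**self.t
        # overflow in a diverging run propagates to a non-finite loss, which
        # the training loop reports as a named divergence error
        with np.errstate(over="ignore", invalid="ignore"):
            for k, g in grads.items():
                self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
                self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
                params[k] -= lr * (self.m[k] / b1c) / (np.sqrt(self.v[k] / b2c) + self.eps)


def _crop_patch(
    hr: Volume3D, patch: tuple[int, int, int], rng: np.random.Generator
) -> Volume3D:
    dims = hr.shape
    patch = tuple(min(p, n) for p, n in zip(patch, dims))
    off = [int(rng.integers(0, n - p + 1)) for n, p in zip(dims, patch)]
    sl = tuple(slice(o, o + p) for o, p in zip(off, patch))
    return Volume3D(hr.data[sl], spacing=hr.spacing)


def _mean_psnr(model: SRModel, volumes: Sequence[Volume3D], s: float, method: str) -> float:
    from .evaluation import psnr
    from .network import super_resolve

    vals = []
    for hr in volumes:
        lr = degrade(hr, s, method=method)
        out = super_resolve(lr, s, model, target_dims=hr.shape)
        vals.append(psnr(out, hr))
    finite = [v for v in vals if np.isfinite(v)]
    return float(np.mean(finite)) if finite else float("inf")


def train(
    corpus: Sequence[Volume3D],
    cfg: TrainingConfig,
    encoder_cfg: EncoderConfig | None = None,
    decoder_cfg: DecoderConfig | None = None,
    validation: Sequence[Volume3D] | None = None,
) -> tuple[SRModel, TrainingHistory]:
    """Fit the network on a corpus of normalized high-resolution volumes.

    Per step a fresh factor s ~ U[scale_range] is drawn and the pair
    ``(degrade(hr, s), hr)`` trains the network; the whole run is
    reproducible from ``cfg.seed``.  Divergence (non-finite loss, or an
    epoch-mean loss above ``divergence_ratio`` times the first epoch's for
    ``divergence_patience`` consecutive epochs) raises
    :class:`TrainingDivergedError`.
    """
    if len(corpus) == 0:
        raise ValueError("training corpus is empty")
    for vol in corpus:
        if vol.data.min() < -1e-6 or vol.data.max() > 1 + 1e-6:
            raise ValueError("training volumes must be normalized to [0, 1]")

    rng = np.random.default_rng(cfg.seed)
    model = SRModel.initialize(encoder_cfg, decoder_cfg, seed=cfg.seed)
    opt = _Adam(model.params, beta1=cfg.adam_beta1, beta2=cfg.adam_beta2)
    history = TrainingHistory()
    masks: dict[tuple[int, int, int], np.ndarray] = {}

    def mask_for(dims: tuple[int, int, int]) -> np.ndarray:
        if dims not in masks:
            masks[dims] = build_mask(dims, cfg.mask_fraction).data.astype(np.float64)
        return masks[dims]

    ref_loss: float | None = None
    high_streak = 0
    stop = False
    best_val: float | None = None
    best_params: dict[str, np.ndarray] | None = None

    for epoch in range(cfg.epochs):
        if stop:
            break
        lr_now = lr_at_epoch(epoch, cfg)
        order = rng.permutation(len(corpus))
        batches = [
            order[i : i + cfg.batch_size] for i in range(0, len(order), cfg.batch_size)
        ]
        ep_total, ep_data, ep_reg, ep_scales = [], [], [], []
        for batch in batches:
            if cfg.max_steps is not None and history.steps >= cfg.max_steps:
                stop = True
                break
            acc: dict[str, np.ndarray] = {}
            b_total, b_data, b_reg = [], [], []
            for idx in batch:
                hr = corpus[int(idx)]
                if cfg.patch_size is not None:
                    hr = _crop_patch(hr, cfg.patch_size, rng)
                s = float(sample_scale(*cfg.scale_range, rng=rng))
                lr_vol = degrade(hr, s, method=cfg.degrade_method)

                pvars = {k: ad.Var(v) for k, v in model.params.items()}
                x = ad.Var(lr_vol.data.astype(DTYPE)[None])
                y_hat = forward_var(x, hr.shape, model, pvars)
                y = hr.data.astype(DTYPE)[None]
                data_node = ad.mean_abs_error(y_hat, y)
                if cfg.lambda_reg > 0:
                    mask = mask_for(hr.shape)
                    target_spec = np.fft.fftn(y[0].astype(np.float64), norm="ortho")
                    squeezed = ad.Var(y_hat.value[0], (y_hat,), lambda g: (g[None],))
                    reg_node = ad.masked_spectral_l1(
                        squeezed, target_spec, mask, cfg.freq_reduction
                    )
                    total_node = ad.add_scaled(data_node, reg_node, cfg.lambda_reg)
                    reg_val = float(reg_node.value)
                else:
                    total_node = data_node
                    reg_val = 0.0

                total = float(total_node.value)
                if not np.isfinite(total):
                    raise TrainingDivergedError(
                        f"non-finite loss at epoch {epoch}, step {history.steps} "
                        f"(lambda_reg={cfg.lambda_reg})"
                    )
                ad.backward(total_node)
                for k in model.params:
                    g = pvars[k].grad
                    if g is None:
                        g = np.zeros_like(model.params[k])
                    elif not np.all(np.isfinite(g)):
                        raise TrainingDivergedError(
                            f"non-finite gradient in {k} at epoch {epoch} "
                            f"(lambda_reg={cfg.lambda_reg})"
                        )
                    acc[k] = g if k not in acc else acc[k] + g
                b_total.append(total)
                b_data.append(float(data_node.value))
                b_reg.append(reg_val)
                ep_scales.append(s)

            if not b_total:
                continue
            grads = {k: g / len(b_total) for k, g in acc.items()}
            if cfg.grad_clip is not None:
                gnorm = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
                if gnorm > cfg.grad_clip:
                    scale = cfg.grad_clip / gnorm
                    grads = {k: g * scale for k, g in grads.items()}
            opt.step(model.params, grads, lr_now)

            history.steps += 1
            ep_total.append(float(np.mean(b_total)))
            ep_data.append(float(np.mean(b_data)))
            ep_reg.append(float(np.mean(b_reg)))

        if not ep_total:
            break
        mean_total = float(np.mean(ep_total))
        history.total.append(mean_total)
        history.data_term.append(float(np.mean(ep_data)))
        history.reg_term.append(float(np.mean(ep_reg)))
        history.lr.append(lr_now)
        history.scales.append(ep_scales)

        if ref_loss is None:
            ref_loss = mean_total
        if mean_total > cfg.divergence_ratio * max(ref_loss, 1e-12):
            high_streak += 1
            if high_streak >= cfg.divergence_patience:
                raise TrainingDivergedError(
                    f"epoch-mean loss {mean_total:.3g} exceeded "
                    f"{cfg.divergence_ratio:g}x the initial loss {ref_loss:.3g} for "
                    f"{cfg.divergence_patience} consecutive epochs "
                    f"(lambda_reg={cfg.lambda_reg})"
                )
        else:
            high_streak = 0

        if validation and (
            (epoch + 1) % cfg.val_every_epochs == 0 or epoch == cfg.epochs - 1 or stop
        ):
            val = _mean_psnr(model, validation, 2.0, cfg.degrade_method)
            history.val_psnr.append((epoch, val))
            if best_val is None or val > best_val:
                best_val = val
                best_params = {k: v.copy() for k, v in model.params.items()}

    # best-checkpoint selection: keep the parameters with the highest
    # validation PSNR seen at the evaluation cadence
    if best_params is not None:
        model.params = best_params
    return model, history


def kfold_split(n_items: int, k: int, seed: int = 0) -> list[tuple[list[int], list[int]]]:
    """Disjoint k-fold partition of ``range(n_items)``; fold sizes differ by <= 1."""
    if not (2 <= k <= n_items):
        raise ValueError(f"need 2 <= k <= n_items, got k={k}, n_items={n_items}")
    perm = np.random.default_rng(seed).permutation(n_items)
    folds = np.array_split(perm, k)
    out = []
    for i, val in enumerate(folds):
        train_ids = np.concatenate([f for j, f in enumerate(folds) if j != i])
        out.append((sorted(int(v) for v in train_ids), sorted(int(v) for v in val)))
    return out
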