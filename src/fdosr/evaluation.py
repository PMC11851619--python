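"""Volumetric image-quality metrics, the nearest-neighbor baseline, and
corpus-level evaluation/ablation harnesses.

Metrics follow the usual conventions for intensity volumes normalized to
[0, 1]: MSE/RMSE are voxelwise, PSNR is ``10 log10(range^2 / MSE)`` in dB
(with a ``+inf`` sentinel for identical inputs, excluded from means), and
SSIM is the mean local structural similarity over a 3D Gaussian-weighted
sliding window (sigma 1.5, 11^3 support — the standard configuration),
computed over windows fully inside the volume.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .phantom import degrade
from .resample import resize_nearest
from .shapes import upsampled_dims
from .volume import Volume3D, as_factor

__all__ = [
    "MetricReport",
    "mse",
    "rmse",
    "psnr",
    "ssim3d",
    "nearest_baseline",
    "evaluate_corpus",
    "ablation_lambda",
]

#: Factor grid used for reporting, matching the 2X..4X rows of the
#: evaluation tables.
DEFAULT_FACTORS: tuple[float, ...] = (2.0, 2.5, 3.0, 3.5, 4.0)


def _check_dims(a: Volume3D, b: Volume3D) -> None:
    if a.shape != b.shape:
        raise ValueError(f"volume shapes differ: {a.shape} vs {b.shape}")


def mse(a: Volume3D, b: Volume3D) -> float:
    """Mean squared voxel difference; 0 iff the volumes are identical."""
    _check_dims(a, b)
    d = a.data.astype(np.float64) - b.data.astype(np.float64)
    return float(np.mean(d * d))


def rmse(a: Volume3D, b: Volume3D) -> float:
    return math.sqrt(mse(a, b))


def psnr(a: Volume3D, b: Volume3D, data_range: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; ``+inf`` for identical inputs."""
    if data_range <= 0:
        raise ValueError("data_range must be > 0")
    err = mse(a, b)
    if err == 0:
        return float("inf")
    return 10.0 * math.log10(data_range**2 / err)


def _gaussian_window(sigma: float, truncate: float) -> np.ndarray:
    radius = int(truncate * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    g = np.exp(-0.5 * (x / sigma) ** 2)
    return g / g.sum()


def ssim3d(
    a: Volume3D,
    b: Volume3D,
    data_range: float = 1.0,
    sigma: float = 1.5,
    truncate: float = 3.5,
) -> float:
    """Mean local SSIM over a 3D Gaussian-weighted sliding window.

    Local means, variances, and covariance are computed from explicit
    sliding windows (valid windows only) with Wang-style population
    weighting; the stabilizing constants are ``C1 = (0.01 L)^2`` and
    ``C2 = (0.03 L)^2`` for data range ``L``.  Equals 1 iff the volumes
    are identical.
    """
    _check_dims(a, b)
    g1 = _gaussian_window(sigma, truncate)
    win = g1.size
    if any(n < win for n in a.shape):
        raise ValueError(f"volume {a.shape} smaller than SSIM window {win}^3")
    w = g1[:, None, None] * g1[None, :, None] * g1[None, None, :]

    x = a.data.astype(np.float64)
    y = b.data.astype(np.float64)

    def local(field: np.ndarray) -> np.ndarray:
        out = field
        for ax in range(3):
            out = np.apply_along_axis(
                lambda v: np.convolve(v, g1, mode="valid"), ax, out
            )
        return out

    # separable weighted local sums over valid windows
    ux = local(x)
    uy = local(y)
    uxx = local(x * x)
    uyy = local(y * y)
    uxy = local(x * y)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    cov = uxy - ux * uy

    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    num = (2 * ux * uy + c1) * (2 * cov + c2)
    den = (ux**2 + uy**2 + c1) * (vx + vy + c2)
    return float(np.mean(num / den))


def nearest_baseline(
    lr: Volume3D, s, target_dims: tuple[int, int, int] | None = None
) -> Volume3D:
    """Classical nearest-neighbor upsampling under the same geometric
    mapping as the network's upscale step (copy-only: the output value set
    is a subset of the input's)."""
    sf = as_factor(s)
    dims = tuple(target_dims) if target_dims is not None else upsampled_dims(lr.shape, sf)
    data = resize_nearest(lr.data, dims)
    spacing = tuple(sp * n / m for sp, n, m in zip(lr.spacing, lr.shape, dims))
    return Volume3D(data.copy(), spacing=spacing)


@dataclass
class MetricReport:
    """Per-volume, per-factor, per-method metric records."""

    df: pd.DataFrame

    COLUMNS = (
        "volume_id",
        "contrast_profile",
        "scale_factor",
        "method",
        "psnr_db",
        "ssim",
        "mse",
        "rmse",
        "status",
    )

    @classmethod
    def from_rows(cls, rows: list[dict]) -> "MetricReport":
        df = pd.DataFrame(rows, columns=list(cls.COLUMNS))
        return cls(df)

    def aggregate(self, by: Sequence[str] = ("method", "scale_factor")) -> pd.DataFrame:
        """Mean +/- SD per group; +inf PSNR sentinels are excluded from means."""
        ok = self.df[self.df["status"] == "ok"].copy()
        ok.loc[~np.isfinite(ok["psnr_db"]), "psnr_db"] = np.nan
        return ok.groupby(list(by))[["psnr_db", "ssim", "mse", "rmse"]].agg(
            ["mean", "std"]
        )

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    def to_markdown(self, metric: str = "psnr_db") -> str:
        """Render a factor-by-method table (evaluation-table layout)."""
        agg = self.aggregate()[metric]["mean"].unstack(level=0)
        lines = ["| factor | " + " | ".join(str(c) for c in agg.columns) + " |"]
        lines.append("|" + "---|" * (len(agg.columns) + 1))
        for factor, row in agg.iterrows():
            cells = " | ".join(f"{v:.3f}" if np.isfinite(v) else "n/a" for v in row)
            lines.append(f"| {factor}X | {cells} |")
        return "\n".join(lines)


MethodFn = Callable[[Volume3D, float, tuple[int, int, int]], Volume3D]


def evaluate_corpus(
    methods: Mapping[str, MethodFn],
    corpus: Sequence[tuple[str, str, Volume3D]],
    factors: Sequence[float] = DEFAULT_FACTORS,
    degrade_method: str = "trilinear",
) -> MetricReport:
    """Evaluate every method on every (volume, factor) pair.

    ``corpus`` holds ``(volume_id, contrast_profile, hr_volume)`` triples;
    each method is called as ``method(lr, s, target_dims)`` and must return
    a volume on the high-resolution grid.  One report row is emitted per
    (volume, factor, method).
    """
    if len(corpus) == 0:
        raise ValueError("evaluation corpus is empty")
    rows = []
    for vol_id, profile, hr in corpus:
        for s in factors:
            lr = degrade(hr, s, method=degrade_method)
            for name, fn in methods.items():
                out = fn(lr, float(s), hr.shape)
                err = mse(out, hr)
                rows.append(
                    dict(
                        volume_id=vol_id,
                        contrast_profile=profile,
                        scale_factor=float(s),
                        method=name,
                        psnr_db=psnr(out, hr),
                        ssim=ssim3d(out, hr),
                        mse=err,
                        rmse=math.sqrt(err),
                        status="ok",
                    )
                )
    return MetricReport.from_rows(rows)


DEFAULT_LAMBDAS: tuple[float, ...] = (1e-2, 1e-3, 1e-5, 1e-10, 1e-15)


def ablation_lambda(
    train_corpus: Sequence[Volume3D],
    test_corpus: Sequence[tuple[str, str, Volume3D]],
    lambdas: Sequence[float],
    cfg,
    encoder_cfg=None,
    decoder_cfg=None,
    factors: Sequence[float] = DEFAULT_FACTORS,
) -> MetricReport:
    """Regularization-weight sweep: one matched training per lambda.

    A diverging run (the known failure mode of overly large weights) is
    recorded as ``status="diverged"`` rows rather than aborting the sweep.
    """
    from .network import super_resolve
    from .training import TrainingDivergedError, train

    all_rows: list[dict] = []
    for lam in lambdas:
        if lam < 0:
            raise ValueError("lambda values must be >= 0")
        run_cfg = dc_replace(cfg, lambda_reg=float(lam))
        name = f"lambda={lam:g}"
        try:
            model, _ = train(train_corpus, run_cfg, encoder_cfg, decoder_cfg)
        except TrainingDivergedError:
            for vol_id, profile, _hr in test_corpus:
                for s in factors:
                    all_rows.append(
                        dict(
                            volume_id=vol_id,
                            contrast_profile=profile,
                            scale_factor=float(s),
                            method=name,
                            psnr_db=np.nan,
                            ssim=np.nan,
                            mse=np.nan,
                            rmse=np.nan,
                            status="diverged",
                        )
                    )
            continue
        report = evaluate_corpus(
            {name: lambda lr, s, dims, m=model: super_resolve(lr, s, m, target_dims=dims)},
            test_corpus,
            factors,
            degrade_method=cfg.degrade_method,
        )
        all_rows.extend(report.df.to_dict("records"))
    return MetricReport.from_rows(all_rows)
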