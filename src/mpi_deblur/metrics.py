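"""PSNR / SSIM image-quality metrics and batch evaluation reports.

Images are handled internally on a [0, 1] concentration scale and rescaled to
[0, 255] inside the metrics, so PSNR uses the conventional ``10 log10(255**2 /
MSE)`` with per-pixel MSE.  SSIM defaults to the global-statistics form
(means, variances and covariance over the whole image) with the universal
stabilizers ``t1 = (0.01 * 255)**2`` and ``t2 = (0.03 * 255)**2``; a windowed
variant is available through scikit-image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["psnr", "ssim", "MetricsReport", "evaluate"]

_L = 255.0
_T1 = (0.01 * _L) ** 2
_T2 = (0.03 * _L) ** 2


def _as_255(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 2:
        raise ValueError("metrics expect 2-D images")
    return arr * _L


def psnr(x, y) -> float:
    """Peak signal-to-noise ratio in dB: ``10 log10(255**2 / MSE)``.

    Inputs are on the internal [0, 1] scale and rescaled to [0, 255];
    identical images return the ``inf`` sentinel.
    """
    a, b = _as_255(x), _as_255(y)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(_L**2 / mse)


def ssim(x, y, windowed: bool = False) -> float:
    """Structural similarity index, global-statistics form by default.

    ``(2 mu_x mu_y + t1)(2 cov + t2) / ((mu_x^2 + mu_y^2 + t1)(var_x + var_y
    + t2))`` with population variances.  Symmetric in its arguments, in
    [-1, 1], and stable for constant images.  ``windowed=True`` delegates to
    scikit-image's sliding-window SSIM (11x11 Gaussian weighting).
    """
    a, b = _as_255(x), _as_255(y)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if windowed:
        from skimage.metrics import structural_similarity

        return float(
            structural_similarity(a, b, data_range=_L, gaussian_weights=True, sigma=1.5,
                                  use_sample_covariance=False)
        )
    mu_x, mu_y = a.mean(), b.mean()
    var_x, var_y = a.var(), b.var()
    cov = ((a - mu_x) * (b - mu_y)).mean()
    return float(
        (2 * mu_x * mu_y + _T1) * (2 * cov + _T2)
        / ((mu_x**2 + mu_y**2 + _T1) * (var_x + var_y + _T2))
    )


@dataclass
class MetricsReport:
    """Per-image and aggregate PSNR/SSIM, formatted as mean +/- std."""

    per_image: list[tuple[str, float, float]]
    psnr_mean: float
    psnr_std: float
    ssim_mean: float
    ssim_std: float
    n: int

    def __str__(self) -> str:
        return (
            f"PSNR {self.psnr_mean:.4f} ± {self.psnr_std:.4f}  "
            f"SSIM {self.ssim_mean:.4f} ± {self.ssim_std:.4f}  (n={self.n})"
        )

    def to_dict(self) -> dict:
        return {
            "per_image": [
                {"id": i, "psnr_db": p, "ssim": s} for i, p, s in self.per_image
            ],
            "psnr_mean": self.psnr_mean,
            "psnr_std": self.psnr_std,
            "ssim_mean": self.ssim_mean,
            "ssim_std": self.ssim_std,
            "n": self.n,
        }


def evaluate(predictions, references, ids=None, error_map_dir=None) -> MetricsReport:
    """Evaluate paired image sets; aggregate statistics use the population std.

    ``predictions`` and ``references`` are sequences (or stacked arrays) of
    2-D images paired by position (or by the optional ``ids``).  Infinite PSNR
    values (identical pairs) are excluded from the PSNR mean/std with a
    warning.  If ``error_map_dir`` is given, per-image absolute-error maps are
    written there as 8-bit PNGs.
    """
    preds = list(predictions)
    refs = list(references)
    if len(preds) != len(refs):
        raise ValueError(f"unpaired sets: {len(preds)} predictions vs {len(refs)} references")
    if ids is None:
        ids = [f"{i:05d}" for i in range(len(preds))]
    ids = list(ids)
    if len(ids) != len(preds):
        raise ValueError("ids must pair one-to-one with predictions")

    per_image = []
    for pid, p, r in zip(ids, preds, refs):
        per_image.append((pid, psnr(p, r), ssim(p, r)))
        if error_map_dir is not None:
            import imageio.v3 as iio
            from pathlib import Path

            err = np.abs(np.asarray(p, dtype=float) - np.asarray(r, dtype=float))
            out = Path(error_map_dir)
            out.mkdir(parents=True, exist_ok=True)
            iio.imwrite(out / f"error_{pid}.png", (np.clip(err, 0, 1) * 255).astype(np.uint8))

    psnrs = np.array([p for _, p, _ in per_image])
    ssims = np.array([s for _, _, s in per_image])
    finite = np.isfinite(psnrs)
    if not finite.all():
        warnings.warn(
            f"{int((~finite).sum())} identical pair(s) with infinite PSNR excluded from the mean",
            stacklevel=2,
        )
    psnr_vals = psnrs[finite]
    return MetricsReport(
        per_image=per_image,
        psnr_mean=float(psnr_vals.mean()) if psnr_vals.size else float("inf"),
        psnr_std=float(psnr_vals.std()) if psnr_vals.size else 0.0,
        ssim_mean=float(ssims.mean()),
        ssim_std=float(ssims.std()),
        n=len(per_image),
    )
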