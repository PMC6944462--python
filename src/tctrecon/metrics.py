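"""Image quality metrics: PSNR and global SSIM.

Both follow their reconstruction-benchmark definitions with the *label* image
``y`` setting the dynamic range:

    PSNR(x, y) = 10 log10( max(y)^2 / MSE ),   MSE = sum (x - y)^2 / N
    SSIM(x, y) = (2 x_bar y_bar + C1)(2 cov + C2)
                 / ((x_bar^2 + y_bar^2 + C1)(var_x + var_y + C2))

SSIM is computed globally over the whole image (single window) by default;
C1 = (0.01 L)^2, C2 = (0.03 L)^2 with L = max(y).  A sliding-window variant is
available via ``windowed=True`` for cross-tool comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity as _skimage_ssim

__all__ = ["psnr", "ssim", "MetricsReport", "evaluate_pair"]


@dataclass
class MetricsReport:
    psnr: float
    ssim: float
    mse: float
    constants_used: tuple[float, float, float]  # (C1, C2, L)


def _as_arrays(x, y) -> tuple[np.ndarray, np.ndarray]:
    xa = np.asarray(getattr(x, "values", x), dtype=np.float64)
    ya = np.asarray(getattr(y, "values", y), dtype=np.float64)
    if xa.shape != ya.shape:
        raise ValueError(f"shape mismatch {xa.shape} vs {ya.shape}")
    return xa, ya


def psnr(x, y) -> float:
    """Peak signal-to-noise ratio in dB; ``y`` is the label image.

    Identical images return ``inf``.
    """
    xa, ya = _as_arrays(x, y)
    peak = ya.max()
    if peak <= 0:
        raise ValueError("label image max must be positive")
    mse = np.mean((xa - ya) ** 2)
    if mse == 0:
        return float("inf")
    return float(10.0 * np.log10(peak**2 / mse))


def ssim(x, y, windowed: bool = False) -> float:
    """Structural similarity index; ``y`` is the label image.

    Global (single-window) statistics by default; ``windowed=True`` computes
    the usual 7x7 sliding-window mean SSIM instead.
    """
    xa, ya = _as_arrays(x, y)
    peak = float(ya.max())
    if peak <= 0:
        raise ValueError("label image max must be positive (degenerate image)")
    if windowed:
        return float(_skimage_ssim(xa, ya, data_range=peak))
    c1 = (0.01 * peak) ** 2
    c2 = (0.03 * peak) ** 2
    mx, my = xa.mean(), ya.mean()
    vx, vy = xa.var(), ya.var()
    cov = ((xa - mx) * (ya - my)).mean()
    return float(
        (2 * mx * my + c1) * (2 * cov + c2) / ((mx**2 + my**2 + c1) * (vx + vy + c2))
    )


def evaluate_pair(x, y) -> MetricsReport:
    """PSNR/SSIM/MSE report for a (reconstruction, label) pair."""
    xa, ya = _as_arrays(x, y)
    peak = float(ya.max())
    return MetricsReport(
        psnr=psnr(xa, ya),
        ssim=ssim(xa, ya),
        mse=float(np.mean((xa - ya) ** 2)),
        constants_used=((0.01 * peak) ** 2, (0.03 * peak) ** 2, peak),
    )
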