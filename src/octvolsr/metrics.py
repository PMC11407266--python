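"""Image-fidelity metrics (RMSE / PSNR / SSIM) and the paired t-test.

SSIM is computed per XY slice (B-scan) with the standard Gaussian-window
formulation (11x11, sigma 1.5, data range 1) and averaged over the slow
axis; volumes are assumed normalized to [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from skimage.metrics import structural_similarity

PSNR_INF = math.inf


@dataclass
class MetricsReport:
    """Mean +/- std of each metric over a set of volumes."""

    rmse_mean: float
    rmse_std: float
    psnr_mean: float
    psnr_std: float
    ssim_mean: float
    ssim_std: float
    n: int
    per_volume: dict[str, list[float]] = field(default_factory=dict)

    @classmethod
    def from_scores(
        cls, rmse_v: list[float], psnr_v: list[float], ssim_v: list[float]
    ) -> "MetricsReport":
        def ms(v):
            a = np.asarray(v, dtype=float)
            return float(a.mean()), float(a.std(ddof=1)) if len(a) > 1 else 0.0

        rm, rs = ms(rmse_v)
        pm, ps = ms(psnr_v)
        sm, ss = ms(ssim_v)
        return cls(
            rm, rs, pm, ps, sm, ss, n=len(rmse_v),
            per_volume={"rmse": list(rmse_v), "psnr": list(psnr_v), "ssim": list(ssim_v)},
        )


def _check(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a, b = np.asarray(a, dtype=np.float64), np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def rmse(pred, target) -> float:
    """Root mean square voxel error."""
    a, b = _check(pred, target)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def psnr(pred, target, data_range: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical inputs."""
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    a, b = _check(pred, target)
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return PSNR_INF
    return 10.0 * math.log10(data_range**2 / mse)


def ssim(pred, target, data_range: float = 1.0) -> float:
    """Mean structural similarity, computed per XY slice and averaged.

    Gaussian 11x11 window with sigma 1.5 and the standard stabilizing
    constants; inputs must be (X, Y, Z) volumes at least as large as the
    window in X and Y.
    """
    a, b = _check(pred, target)
    if a.ndim != 3:
        raise ValueError("ssim expects (X, Y, Z) volumes")
    if min(a.shape[0], a.shape[1]) < 11:
        raise ValueError("XY slices smaller than the 11x11 SSIM window")
    vals = [
        structural_similarity(
            a[:, :, k],
            b[:, :, k],
            data_range=data_range,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            win_size=11,
        )
        for k in range(a.shape[2])
    ]
    return float(np.mean(vals))


def paired_ttest(scores_a, scores_b) -> tuple[float, float]:
    """Two-tailed paired t-test; returns (t statistic, p value).

    Raises on degenerate input (unequal lengths, n < 2, or zero variance of
    the paired differences, where the t statistic is undefined).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired t-test needs two equal-length 1D score lists")
    if len(a) < 2:
        raise ValueError("paired t-test needs at least two pairs")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        raise ValueError("zero-variance paired differences: t-test degenerate")
    res = stats.ttest_rel(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
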