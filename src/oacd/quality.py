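"""Full-reference image-quality and tail-suppression metrics.

Tail suppression is scored by the Pearson correlation between the
superficial large-vessel map and the deep-slab en-face image: residual tails
make the deep image resemble the superficial vasculature, so r near 0 means
better artifact removal.  Image quality against a reference uses PSNR, mean
SSIM (Gaussian window) and GMSD — the standard deviation of the pixelwise
gradient-magnitude similarity map (lower = more similar).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from skimage.metrics import peak_signal_noise_ratio, structural_similarity


@dataclass
class QualityReport:
    pearson_r: float
    psnr_db: float
    ssim: float
    gmsd: float


def _as_float(img) -> np.ndarray:
    arr = np.asarray(img, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError("image must be finite")
    return arr


def normalize01(img: np.ndarray) -> np.ndarray:
    """Min-max normalization to [0, 1]; a constant image maps to zeros."""
    arr = _as_float(img)
    lo, hi = arr.min(), arr.max()
    return np.zeros_like(arr) if hi <= lo else (arr - lo) / (hi - lo)


def pearson_similarity(img_a, img_b) -> float:
    """Product-moment correlation over all pixels; constant input is rejected."""
    a, b = _as_float(img_a).ravel(), _as_float(img_b).ravel()
    if a.shape != b.shape:
        raise ValueError("images must have equal shape")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("Pearson similarity undefined for a constant image")
    return float(stats.pearsonr(a, b).statistic)


def psnr(img, ref, peak: float = 1.0) -> float:
    """10*log10(peak^2 / MSE) in dB; identical images report +inf."""
    a, r = _as_float(img), _as_float(ref)
    if np.array_equal(a, r):
        return float("inf")
    return float(peak_signal_noise_ratio(r, a, data_range=peak))


def ssim(img, ref, *, window: int = 11, K1: float = 0.01, K2: float = 0.03) -> float:
    """Mean local structural similarity with a Gaussian window."""
    a, r = _as_float(img), _as_float(ref)
    return float(structural_similarity(
        r, a, win_size=window, K1=K1, K2=K2, data_range=1.0,
        gaussian_weights=True, sigma=1.5, use_sample_covariance=False))


def gmsd(img, ref, c: float = 0.0026) -> float:
    """Gradient-magnitude similarity deviation (Prewitt gradients).

    GMS = (2 g_i g_r + c) / (g_i^2 + g_r^2 + c) per pixel; GMSD is its
    standard deviation.  Identical images give exactly 0.  ``c`` stabilizes
    flat regions and assumes images scaled to [0, 1].
    """
    a, r = _as_float(img), _as_float(ref)
    if a.shape != r.shape:
        raise ValueError("images must have equal shape")

    def grad_mag(x):
        gx = ndimage.prewitt(x, axis=0, mode="reflect") / 3.0
        gy = ndimage.prewitt(x, axis=1, mode="reflect") / 3.0
        return np.hypot(gx, gy)

    ga, gr = grad_mag(a), grad_mag(r)
    gms = (2.0 * ga * gr + c) / (ga ** 2 + gr ** 2 + c)
    return float(gms.std())


def quality_report(img, ref, *, pearson_against=None) -> QualityReport:
    """PSNR/SSIM/GMSD of ``img`` against ``ref`` (both min-max normalized).

    ``pearson_against`` defaults to ``ref``; pass the superficial
    large-vessel map to score tail suppression of a deep-slab image.
    """
    a, r = normalize01(img), normalize01(ref)
    p = normalize01(pearson_against) if pearson_against is not None else r
    return QualityReport(
        pearson_r=pearson_similarity(a, p),
        psnr_db=psnr(a, r, peak=1.0),
        ssim=ssim(a, r),
        gmsd=gmsd(a, r),
    )
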