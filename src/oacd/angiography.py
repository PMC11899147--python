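"""Decorrelation angiography, slab splitting and residual-tail removal.

The flow signal at one position is the average pairwise decorrelation of the
M repeated frames,

    D(x, z) = 1 - (1/(M-1)) * sum_m  S_m S_{m+1} / (S_m^2/2 + S_{m+1}^2/2),

computed on the backscattered amplitude (classic OCTA) or on attenuation
maps (OACD).  Each pair term is a normalized correlation of two numbers, so
D lies in [0, 1]; identical frames give D = 0.

En-face rendering follows the anatomy: the tissue surface is detected per
A-line, and two 450-um slabs below it separate superficial from deep cortex
vessels.  Large superficial vessels leave residual tails even in OACD; the
remover extracts them, pattern-matches their footprint against the deep
slab, and subtracts the least-squares-scaled pattern where it matches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from oacd.attenuation import estimate_noise_floor

SLAB_THICKNESS_UM = 450.0


@dataclass
class AngioVolume:
    """Decorrelation volume ``D`` in [0, 1], indexed ``(z, x, y)``."""

    D: np.ndarray
    signal_kind: str  # "amplitude" | "oac"
    M: int


@dataclass
class EnfaceImage:
    """2-D (x, y) projection of one slab of an angiography volume."""

    pixels: np.ndarray
    slab: str            # "superficial" | "deep" | custom
    projection: str      # "max" | "mean"
    provenance: str      # signal_kind of the source volume


def decorrelate(frames: np.ndarray, signal_kind: str = "amplitude") -> np.ndarray:
    """Average adjacent-pair decorrelation of M aligned frames.

    ``frames`` has the repeat index on axis 0 (M >= 2); any trailing shape.
    A pair with both values zero is treated as perfectly correlated (pair
    term 1, decorrelation contribution 0): inside the noise floor the values
    carry no flow information and such pixels are masked downstream.
    """
    S = np.asarray(frames, dtype=np.float64)
    if S.shape[0] < 2:
        raise ValueError(f"need at least 2 frames, got {S.shape[0]}")
    M = S.shape[0]
    num = S[:-1] * S[1:]
    den = 0.5 * (S[:-1] ** 2 + S[1:] ** 2)
    pair = np.where(den > 0, np.divide(num, den, out=np.ones_like(num), where=den > 0), 1.0)
    D = 1.0 - pair.sum(axis=0) / (M - 1)
    return np.clip(D, 0.0, 1.0)


def decorrelate_volume(signal_4d: np.ndarray, signal_kind: str = "amplitude") -> AngioVolume:
    """Collapse the repeat axis of an ``(m, z, x, y)`` signal volume into D."""
    arr = np.asarray(signal_4d, dtype=np.float64)
    if arr.ndim != 4:
        raise ValueError(f"expected (m, z, x, y), got shape {arr.shape}")
    return AngioVolume(D=decorrelate(arr, signal_kind), signal_kind=signal_kind, M=arr.shape[0])


def detect_surface(volume_data: np.ndarray, *, margin_db: float = 5.0,
                   avg_width: int = 8, smooth_window: int = 5) -> np.ndarray:
    """Per-(x, y) depth of the first tissue pixel of a structural volume.

    ``volume_data`` is ``(m, z, x, y)`` or ``(z, x, y)`` linear intensity;
    repeats are averaged first.  The surface is the shallowest depth whose
    intensity exceeds the per-B-scan noise floor by ``margin_db``, median
    smoothed laterally; A-lines never above the floor are filled from their
    neighbors' median (flagged by raising if no A-line is above the floor).
    """
    arr = np.asarray(volume_data, dtype=np.float64)
    if arr.ndim == 4:
        arr = arr.mean(axis=0)
    if arr.ndim != 3:
        raise ValueError("expected (z, x, y) or (m, z, x, y)")
    nz, nx, ny = arr.shape
    surface = np.full((nx, ny), -1, dtype=np.int64)
    for y in range(ny):
        bscan = arr[:, :, y]
        nf = estimate_noise_floor(bscan, avg_width=avg_width, margin_db=margin_db)
        thr = nf.floor_level * 10.0 ** (margin_db / 10.0)
        above = bscan >= np.where(thr > 0, thr, np.inf)[None, :]
        if not thr.max() > 0:  # noiseless column blocks: any positive signal
            above = bscan > 0
        # require a sustained crossing (3 consecutive samples) so isolated
        # noise spikes never masquerade as tissue
        sustained = above[:-2] & above[1:-1] & above[2:]
        has = sustained.any(axis=0)
        first = np.where(has, sustained.argmax(axis=0), -1)
        surface[:, y] = first
    if (surface < 0).mean() > 0.5:
        raise ValueError("most A-lines never rise above the noise floor; "
                         "cannot detect a tissue surface")
    if (surface < 0).any():
        filled = ndimage.median_filter(np.where(surface < 0, np.nanmedian(
            np.where(surface < 0, np.nan, surface.astype(float))), surface), size=smooth_window)
        surface = np.where(surface < 0, np.round(filled).astype(np.int64), surface)
    return ndimage.median_filter(surface, size=smooth_window)


def split_slabs(angio: AngioVolume | np.ndarray, surface_map: np.ndarray, delta: float,
                *, slab_thickness_um: float = SLAB_THICKNESS_UM,
                ) -> tuple[np.ndarray, np.ndarray]:
    """Split a volume into surface-following superficial and deep slabs.

    Returns two arrays of shape ``(slab_px, n_x, n_y)`` where slab_px =
    round(thickness / axial pitch); superficial covers [surface, surface +
    slab_px) and deep the next slab_px pixels per A-line.  Depths beyond the
    volume bottom are zero-filled (an entirely out-of-range deep slab is
    thereby empty).
    """
    D = angio.D if isinstance(angio, AngioVolume) else np.asarray(angio, dtype=np.float64)
    if slab_thickness_um <= 0:
        raise ValueError("slab thickness must be positive")
    nz, nx, ny = D.shape
    slab_px = max(int(round(slab_thickness_um / (delta * 1000.0))), 1)
    surf = np.asarray(surface_map, dtype=np.int64)
    out = []
    offsets = np.arange(slab_px)
    for k in (0, 1):
        zidx = surf[None, :, :] + k * slab_px + offsets[:, None, None]
        inside = zidx < nz
        sub = np.where(inside, np.take_along_axis(D, np.clip(zidx, 0, nz - 1), axis=0), 0.0)
        out.append(sub)
    return out[0], out[1]


def enface_project(sub_volume: np.ndarray, projection: str = "max",
                   *, slab: str = "", provenance: str = "") -> EnfaceImage:
    """Collapse the depth axis of a slab into a 2-D en-face image."""
    sub = np.asarray(sub_volume, dtype=np.float64)
    if projection == "max":
        pix = sub.max(axis=0)
    elif projection == "mean":
        pix = sub.mean(axis=0)
    else:
        raise ValueError(f"projection must be 'max' or 'mean', got {projection!r}")
    return EnfaceImage(pixels=pix, slab=slab, projection=projection, provenance=provenance)


@dataclass(frozen=True)
class TailRemovalConfig:
    """Tunables of the residual large-vessel tail remover.

    ``large_vessel_diam_px``: minimum median distance-transform diameter for
    a superficial component to count as a large vessel.  ``match_threshold``:
    local normalized cross-correlation needed before subtraction.
    ``search_px``: lateral shift search radius.  ``ncc_window``: side of the
    local correlation window.  ``footprint_dilation_px``: dilation of the
    large-vessel footprint to cover PSF spreading.
    """

    large_vessel_diam_px: float = 4.0
    match_threshold: float = 0.5
    search_px: int = 2
    ncc_window: int = 9
    footprint_dilation_px: int = 2
    binarize_percentile: float = 75.0


def _local_ncc(a: np.ndarray, b: np.ndarray, window: int) -> np.ndarray:
    """Windowed Pearson correlation of two images (uniform window)."""
    size = (window, window)
    ma = ndimage.uniform_filter(a, size)
    mb = ndimage.uniform_filter(b, size)
    cov = ndimage.uniform_filter(a * b, size) - ma * mb
    va = ndimage.uniform_filter(a * a, size) - ma * ma
    vb = ndimage.uniform_filter(b * b, size) - mb * mb
    den = np.sqrt(np.clip(va, 0, None) * np.clip(vb, 0, None))
    return np.where(den > 1e-12, cov / np.where(den > 1e-12, den, 1.0), 0.0)


def remove_residual_tails(superficial: EnfaceImage | np.ndarray,
                          deep: EnfaceImage | np.ndarray,
                          cfg: TailRemovalConfig | None = None) -> EnfaceImage:
    """Subtract residual large-vessel tails from the deep en-face image.

    Large vessels are the bright superficial components whose median
    distance-transform diameter reaches ``cfg.large_vessel_diam_px``.  Within
    their (dilated) footprint the superficial pattern is matched to the deep
    image over a small lateral shift search; where the local correlation
    clears ``cfg.match_threshold`` the least-squares-scaled pattern is
    subtracted, clamped at zero.  Pixels outside the footprint are untouched;
    with no large vessel the input is returned unchanged.
    """
    cfg = cfg or TailRemovalConfig()
    sup = superficial.pixels if isinstance(superficial, EnfaceImage) else np.asarray(superficial, float)
    dp = deep.pixels if isinstance(deep, EnfaceImage) else np.asarray(deep, float)
    deep_meta = deep if isinstance(deep, EnfaceImage) else EnfaceImage(dp, "deep", "max", "")
    if sup.shape != dp.shape:
        raise ValueError(f"superficial {sup.shape} and deep {dp.shape} must be co-registered")

    # (i) large-vessel extraction from the superficial slab
    pos = sup[sup > 0]
    if pos.size == 0:
        return EnfaceImage(dp.copy(), deep_meta.slab, deep_meta.projection, deep_meta.provenance)
    thr = np.percentile(pos, cfg.binarize_percentile)
    mask = sup >= thr
    dist = ndimage.distance_transform_edt(mask)
    labels, n = ndimage.label(mask)
    large = np.zeros_like(mask)
    for lab in range(1, n + 1):
        comp = labels == lab
        if np.median(2.0 * dist[comp]) >= cfg.large_vessel_diam_px:
            large |= comp
    if not large.any():
        return EnfaceImage(dp.copy(), deep_meta.slab, deep_meta.projection, deep_meta.provenance)
    footprint = ndimage.binary_dilation(large, iterations=cfg.footprint_dilation_px)

    # (ii) best lateral shift by global NCC over the footprint
    best_shift, best_r = (0, 0), -np.inf
    sup_m = np.where(large, sup, 0.0)
    fpix = footprint
    for dx in range(-cfg.search_px, cfg.search_px + 1):
        for dy in range(-cfg.search_px, cfg.search_px + 1):
            shifted = np.roll(np.roll(sup_m, dx, axis=0), dy, axis=1)
            a, b = shifted[fpix], dp[fpix]
            if a.std() < 1e-12 or b.std() < 1e-12:
                continue
            r = float(np.corrcoef(a, b)[0, 1])
            if r > best_r:
                best_r, best_shift = r, (dx, dy)
    pattern = np.roll(np.roll(sup_m, best_shift[0], axis=0), best_shift[1], axis=1)

    # (iii) local matching and least-squares subtraction
    ncc = _local_ncc(pattern, dp, cfg.ncc_window)
    match = footprint & (ncc >= cfg.match_threshold) & (pattern > 0)
    out = dp.copy()
    if match.any():
        p, d = pattern[match], dp[match]
        scale = float((p * d).sum() / max((p * p).sum(), 1e-12))
        out[match] = np.clip(d - scale * p, 0.0, None)
    return EnfaceImage(out, deep_meta.slab, deep_meta.projection, deep_meta.provenance)
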