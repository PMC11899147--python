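"""Depth-resolved attenuation-coefficient estimation from OCT A-lines.

Two estimators are provided.  The depth-resolved (DR) estimator converts a
linear-intensity A-line ``I`` into an attenuation coefficient at every pixel,

    mu[z] = I[z] / (2 * delta * sum_{i=z+1..N} I[i]),

where ``delta`` is the axial pitch (mm) and ``N`` the last usable depth; the
factor 2 accounts for the double pass.  Truncating the sum at a finite ``N``
overestimates ``mu`` near the bottom of the range.  The optimized variant
(ODRE) adds a tail term estimated by fitting the deepest usable samples to
``y = a*exp(-2*mu*z) + b``:

    mu[z] = I[z] / (2 * delta * sum_{i=z+1..N} I[i] + I[N] / mu[N]),

which replaces the missing intensity below ``N`` by its analytic
continuation.  Both estimators depend only on the signal at and below ``z``,
so any multiplicative factor applied to all depths >= z cancels exactly —
the property that removes tail artifacts from decorrelation angiography.

The usable range ``N`` is bounded by the noise floor: adjacent A-lines are
averaged, the floor is taken from the deepest samples, and the boundary is
the deepest pixel still 5 dB above the floor.  Before any of this the
confocal axial PSF of the sample arm is divided out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

EPS = 1e-12


@dataclass(frozen=True)
class ConfocalParams:
    """Axial confocal gate of the sample arm.

    ``h(z) = (((z - zcf) / zR)^2 + 1)^-1`` with focus depth ``zcf`` and
    apparent Rayleigh length ``zR``, both in the units of the depth axis
    (mm throughout this package).
    """

    zcf: float
    zR: float

    def __post_init__(self) -> None:
        if self.zR <= 0:
            raise ValueError(f"Rayleigh length zR must be positive, got {self.zR}")

    @classmethod
    def from_beam(cls, *, w0: float, wavelength: float, zcf: float,
                  alpha: int = 2, n: float = 1.0) -> "ConfocalParams":
        """Derive zR from beam waist ``w0`` and center wavelength (both mm).

        ``alpha`` distinguishes specular (1) from diffuse (2) reflection;
        ``n`` is the refractive index.  zR = alpha * pi * n * w0^2 / lambda.
        """
        if alpha not in (1, 2):
            raise ValueError(f"alpha must be 1 (specular) or 2 (diffuse), got {alpha}")
        return cls(zcf=zcf, zR=alpha * np.pi * n * w0 ** 2 / wavelength)


@dataclass
class TailFit:
    """Result of the exponential tail fit ``y = a*exp(-2*mu*z) + b``."""

    a: float
    b: float
    mu_N: float
    fit_window: tuple[int, int]
    converged: bool


@dataclass
class NoiseFloorResult:
    """Per-A-line noise floor and usable-depth boundary.

    ``boundary_index[j]`` is the deepest depth of column ``j`` whose averaged
    signal is at least ``margin_db`` above the floor; -1 flags an A-line that
    never rises above the floor.
    """

    floor_level: np.ndarray    # (n_x,)
    boundary_index: np.ndarray  # (n_x,) int, -1 = absent


@dataclass
class OACVolume:
    """Per-voxel attenuation coefficient, indexed ``(m, z, x, y)``."""

    mu: np.ndarray
    delta: float
    method: str  # "dr" | "odre"


def confocal_psf(z: np.ndarray | float, params: ConfocalParams) -> np.ndarray:
    """Axial PSF h(z) = (((z - zcf)/zR)^2 + 1)^-1."""
    u = (np.asarray(z, dtype=np.float64) - params.zcf) / params.zR
    return 1.0 / (u * u + 1.0)


def confocal_correct(volume, params: ConfocalParams, z_axis: np.ndarray | None = None):
    """Divide the intensity by the confocal axial PSF.

    Accepts an :class:`~oacd.volio.OCTVolume` (depth axis 1, z in mm from
    ``delta``) or a bare array with the depth on axis 0 and an explicit
    ``z_axis`` in the same units as ``params``.
    """
    from oacd.volio import OCTVolume  # local import to avoid a cycle

    if isinstance(volume, OCTVolume):
        z = np.arange(volume.geometry.n_depth) * volume.delta
        h = confocal_psf(z, params)
        corrected = volume.data / h[None, :, None, None]
        return OCTVolume(data=corrected, geometry=volume.geometry,
                         meta={**volume.meta, "confocal_corrected": True})
    arr = np.asarray(volume, dtype=np.float64)
    if z_axis is None:
        raise ValueError("z_axis required when correcting a bare array")
    h = confocal_psf(np.asarray(z_axis), params)
    shape = [1] * arr.ndim
    shape[0] = len(h)
    return arr / h.reshape(shape)


def estimate_noise_floor(bscan: np.ndarray, *, avg_width: int = 8,
                         tail_fraction: float = 0.1,
                         margin_db: float = 5.0) -> NoiseFloorResult:
    """Estimate the noise floor and the usable-depth boundary of a B-scan.

    Adjacent A-lines are averaged in blocks of ``avg_width`` to improve SNR;
    the floor of each block is the mean of its deepest ``tail_fraction`` of
    samples, and the boundary is the deepest depth whose averaged signal is
    >= floor * 10^(margin_db/10).  Block results are broadcast back to the
    member columns.
    """
    bscan = np.asarray(bscan, dtype=np.float64)
    if bscan.ndim != 2:
        raise ValueError("bscan must be 2-D (n_depth, n_x)")
    nz, nx = bscan.shape
    n_tail = max(int(round(tail_fraction * nz)), 1)
    floor = np.empty(nx)
    boundary = np.empty(nx, dtype=np.int64)
    for j0 in range(0, nx, avg_width):
        block = bscan[:, j0:j0 + avg_width]
        avg = block.mean(axis=1)
        f = float(avg[-n_tail:].mean())
        thr = f * 10.0 ** (margin_db / 10.0)
        above = np.nonzero(avg >= thr)[0] if thr > 0 else np.nonzero(avg > 0)[0]
        b = int(above[-1]) if above.size else -1
        floor[j0:j0 + avg_width] = f
        boundary[j0:j0 + avg_width] = b
    return NoiseFloorResult(floor_level=floor, boundary_index=boundary)


def fit_tail(aline: np.ndarray, z_axis: np.ndarray,
             window: tuple[int, int] | None = None) -> TailFit:
    """Fit ``y = a*exp(-2*mu*z) + b`` to the deep end of an A-line.

    ``window`` is an inclusive index range ``(i0, i1)`` with at least 8
    samples; default is the whole A-line.  ``converged`` is False when the
    optimizer fails or returns a non-positive decay rate.
    """
    y = np.asarray(aline, dtype=np.float64)
    z = np.asarray(z_axis, dtype=np.float64)
    if window is None:
        window = (0, len(y) - 1)
    i0, i1 = int(window[0]), int(window[1])
    if i1 - i0 + 1 < 8:
        raise ValueError(f"fit window [{i0}, {i1}] has fewer than 8 samples")
    yw, zw = y[i0:i1 + 1], z[i0:i1 + 1]

    if np.ptp(yw) <= EPS * max(abs(yw).max(), 1.0):
        return TailFit(a=0.0, b=float(yw.mean()), mu_N=0.0, fit_window=(i0, i1), converged=False)

    # log-linear seed on the floor-subtracted signal
    b0 = float(yw.min()) * 0.5
    pos = np.clip(yw - b0, EPS, None)
    slope, intercept = np.polyfit(zw, np.log(pos), 1)
    mu0 = max(-slope / 2.0, 1e-3)
    a0 = float(np.exp(intercept))

    def model(zv, a, mu, b):
        return a * np.exp(-2.0 * mu * zv) + b

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(model, zw, yw, p0=(a0, mu0, b0), maxfev=5000)
        a, mu, b = (float(v) for v in popt)
        converged = np.isfinite(mu) and mu > 0 and np.isfinite(a)
    except (RuntimeError, ValueError):
        a, mu, b, converged = a0, mu0, b0, False
    return TailFit(a=a, b=b, mu_N=mu, fit_window=(i0, i1), converged=converged)


def _prepare(bscan: np.ndarray, stop_index) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    bscan = np.clip(np.asarray(bscan, dtype=np.float64), 0.0, None)
    if bscan.ndim == 1:
        bscan = bscan[:, None]
    nz, nx = bscan.shape
    if stop_index is None:
        stop = np.full(nx, nz - 1, dtype=np.int64)
    else:
        stop = np.broadcast_to(np.asarray(stop_index, dtype=np.int64), (nx,)).copy()
    stop = np.clip(stop, -1, nz - 1)
    valid = np.arange(nz)[:, None] <= stop[None, :]
    return bscan, stop, valid


def _cumulative_below(I: np.ndarray, stop: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """S[z, j] = sum_{i=z+1..stop[j]} I[i, j] (0 where invalid).

    Summed bottom-up so S[z] involves only samples at and below z+1: no
    cancellation against the (large) shallow signal, and a common factor on
    all depths >= z scales S[z] exactly.
    """
    Iv = np.where(valid, I, 0.0)
    suffix = np.cumsum(Iv[::-1], axis=0)[::-1]  # suffix[z] = sum_{i=z..end}
    S = np.zeros_like(Iv)
    S[:-1] = suffix[1:]
    return np.where(valid, S, 0.0)


def oac_dr(bscan: np.ndarray, delta: float, stop_index=None,
           mu_N: np.ndarray | float | None = None) -> np.ndarray:
    """Depth-resolved attenuation estimate (truncated-sum form).

    ``stop_index`` is the per-A-line noise boundary ``N`` (scalar or array);
    pixels beyond it, and pixels with an empty or zero cumulative sum, are
    set to 0.  When ``mu_N`` is given the last pixel (empty sum) is assigned
    that value instead of being flagged.
    """
    I, stop, valid = _prepare(bscan, stop_index)
    S = _cumulative_below(I, stop, valid)
    den = 2.0 * delta * S
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = np.where(valid & (den > EPS), I / den, 0.0)
    if mu_N is not None:
        mu_last = np.broadcast_to(np.asarray(mu_N, dtype=np.float64), stop.shape)
        cols = np.nonzero(stop >= 0)[0]
        mu[stop[cols], cols] = mu_last[cols]
    return mu


def oac_odre(bscan: np.ndarray, delta: float, stop_index=None,
             mu_N: np.ndarray | float | None = None,
             tail: TailFit | None = None) -> np.ndarray:
    """Optimized depth-resolved attenuation estimate with exponential tail term.

    The truncation bias of the plain estimator is removed by adding
    ``I[N] / mu[N]`` to the cumulative sum — the closed-form integral of the
    fitted exponential tail below ``N``.  ``mu_N`` may be a scalar, a
    per-A-line array, or supplied through a converged :class:`TailFit`.
    A-lines with no usable tail estimate (mu_N <= 0) fall back to the plain
    estimator.
    """
    if mu_N is None and tail is not None:
        mu_N = tail.mu_N if tail.converged else 0.0
    if mu_N is None:
        raise ValueError("oac_odre needs mu_N (scalar, per-column array, or TailFit)")
    I, stop, valid = _prepare(bscan, stop_index)
    muN = np.broadcast_to(np.asarray(mu_N, dtype=np.float64), stop.shape).copy()
    usable = muN > 0

    S = _cumulative_below(I, stop, valid)
    I_N = np.zeros_like(muN)
    cols = np.nonzero(stop >= 0)[0]
    I_N[cols] = I[stop[cols], cols]
    tail_term = np.where(usable, I_N / np.where(usable, muN, 1.0), 0.0)
    den = 2.0 * delta * S + tail_term[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = np.where(valid & (den > EPS), I / den, 0.0)
    if not np.all(usable):  # fallback: plain DR on the failed columns
        dr = oac_dr(I, delta, stop)
        mu[:, ~usable] = dr[:, ~usable]
    return mu


def oac_bscan(bscan: np.ndarray, delta: float, *, method: str = "odre",
              avg_width: int = 8, tail_fraction: float = 0.1,
              margin_db: float = 5.0, tail_window: int = 30) -> np.ndarray:
    """Full per-B-scan attenuation pipeline: noise floor, tail fit, estimator.

    The tail is fitted per averaged A-line block (same blocks as the noise
    estimate) and the fitted decay rate is shared by the block's columns.
    """
    bscan = np.clip(np.asarray(bscan, dtype=np.float64), 0.0, None)
    nz, nx = bscan.shape
    nf = estimate_noise_floor(bscan, avg_width=avg_width,
                              tail_fraction=tail_fraction, margin_db=margin_db)
    stop = nf.boundary_index
    if method == "dr":
        return oac_dr(bscan, delta, stop)
    if method != "odre":
        raise ValueError(f"unknown method {method!r}; use 'dr' or 'odre'")

    z_axis = np.arange(nz) * delta
    mu_N = np.zeros(nx)
    for j0 in range(0, nx, avg_width):
        block = slice(j0, min(j0 + avg_width, nx))
        b = int(stop[j0])
        if b < 0:
            continue
        i0 = max(b - tail_window + 1, 0)
        if b - i0 + 1 < 8:
            continue
        avg = bscan[:, block].mean(axis=1)
        tf = fit_tail(avg, z_axis, window=(i0, b))
        if tf.converged:
            mu_N[block] = tf.mu_N
    return oac_odre(bscan, delta, stop, mu_N=mu_N)


def oac_repeated_bscans(stack: np.ndarray, delta: float, *, method: str = "odre",
                        avg_width: int = 8, tail_fraction: float = 0.1,
                        margin_db: float = 5.0, tail_window: int = 30) -> np.ndarray:
    """Attenuation maps for the M repeated B-scans of one position.

    The noise-floor boundary and the tail decay rate are properties of the
    system and the (static) anatomy, not of a single repeat, so both are
    estimated once from the temporal mean of the stack and shared by all
    frames.  The shared boundary keeps the estimator's scale invariance
    intact across frames: a frame-to-frame multiplicative transmission
    change below a vessel scales numerator, cumulative sum and tail term
    ``I[N]/mu[N]`` alike and cancels, which is what suppresses tails in the
    subsequent decorrelation.
    """
    stack = np.clip(np.asarray(stack, dtype=np.float64), 0.0, None)
    M, nz, nx = stack.shape
    mean_bscan = stack.mean(axis=0)
    nf = estimate_noise_floor(mean_bscan, avg_width=avg_width,
                              tail_fraction=tail_fraction, margin_db=margin_db)
    stop = nf.boundary_index
    mu_N = None
    if method == "odre":
        z_axis = np.arange(nz) * delta
        mu_N = np.zeros(nx)
        for j0 in range(0, nx, avg_width):
            block = slice(j0, min(j0 + avg_width, nx))
            b = int(stop[j0])
            i0 = max(b - tail_window + 1, 0)
            if b < 0 or b - i0 + 1 < 8:
                continue
            tf = fit_tail(mean_bscan[:, block].mean(axis=1), z_axis, window=(i0, b))
            if tf.converged:
                mu_N[block] = tf.mu_N
    out = np.empty_like(stack)
    for m in range(M):
        if method == "dr":
            out[m] = oac_dr(stack[m], delta, stop)
        else:
            out[m] = oac_odre(stack[m], delta, stop, mu_N=mu_N)
    return out


def oac_volume(volume, *, method: str = "odre", confocal: ConfocalParams | None = None,
               avg_width: int = 8, tail_fraction: float = 0.1,
               margin_db: float = 5.0, tail_window: int = 30) -> OACVolume:
    """Convert a 4-D OCT volume to a 4-D attenuation volume.

    Positions (slow axis) are processed independently; within a position the
    M repeats share the noise boundary and tail fit (see
    :func:`oac_repeated_bscans`), and their frame-to-frame attenuation
    variation carries the flow signal used by decorrelation angiography.
    """
    if confocal is not None:
        volume = confocal_correct(volume, confocal)
    data = volume.data
    M, nz, nx, ny = data.shape
    mu = np.empty_like(data)
    for y in range(ny):
        mu[:, :, :, y] = oac_repeated_bscans(
            data[:, :, :, y], volume.delta, method=method,
            avg_width=avg_width, tail_fraction=tail_fraction,
            margin_db=margin_db, tail_window=tail_window)
    return OACVolume(mu=mu, delta=volume.delta, method=method)
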