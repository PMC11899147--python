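"""Seeded synthetic OCT phantom with flow decorrelation and tail artifacts.

The forward model follows the single-scattering Beer–Lambert picture of OCT:
the backscattered intensity at depth ``z`` of one A-line is

    I[z] = s_m * h(z) * R_m[z] * exp(-2 * sum_{z' < z} mu_m[z'] * delta) + noise

where ``R`` is the local reflectivity, ``mu`` the attenuation coefficient
(mm^-1), ``delta`` the axial pixel pitch (mm), ``h(z)`` the confocal axial
PSF and ``s_m`` an optional per-frame source-power scalar.  The factor 2 is
the double pass through the tissue.

Flow is modelled by resampling reflectivity *and* attenuation inside vessel
voxels independently for every repeated frame; static voxels keep the
reflectivity drawn once at construction.  Because the vessel attenuation
varies between frames, the light transmitted to static tissue *beneath* a
vessel varies too — frame-to-frame by a factor common to all depths below
the vessel.  This multiplicative shadowing is precisely the tail-artifact
mechanism that amplitude decorrelation picks up and that attenuation-based
decorrelation cancels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from oacd.attenuation import ConfocalParams, confocal_psf
from oacd.volio import OCTVolume, ScanGeometry

SLAB_THICKNESS_UM_DEFAULT = 450.0


@dataclass(frozen=True)
class VesselSpec:
    """A single vessel: a tube swept along a polyline.

    Parameters
    ----------
    centerline : sequence of (x, y, z)
        Polyline vertices in voxel coordinates.
    radius : float
        Tube radius in pixels (>= 1).
    mu_vessel : float
        Attenuation inside the vessel, mm^-1 (blood scatters strongly at
        1310 nm, typically several mm^-1 above parenchyma).
    flow_decorr : float
        Per-frame fractional resampling strength in [0, 1]; 0 = static
        (thrombosed) vessel, 1 = full frame-to-frame decorrelation.
    """

    centerline: tuple[tuple[float, float, float], ...]
    radius: float
    mu_vessel: float
    flow_decorr: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "centerline", tuple(tuple(map(float, p)) for p in self.centerline))
        if len(self.centerline) < 1:
            raise ValueError("centerline needs at least one vertex")
        if self.radius < 1:
            raise ValueError(f"vessel radius must be >= 1 px, got {self.radius}")
        if not 0.0 <= self.flow_decorr <= 1.0:
            raise ValueError(f"flow_decorr must be in [0, 1], got {self.flow_decorr}")
        if self.mu_vessel <= 0:
            raise ValueError("mu_vessel must be positive (mm^-1)")


@dataclass(frozen=True)
class PhantomSpec:
    """Complete description of a synthetic acquisition.

    ``grid`` is ``(M, n_depth, n_x, n_y)``; ``pixel_size_axial`` is the
    axial pitch in mm; ``tissue_mu`` the background attenuation (scalar or a
    per-voxel ``(n_depth, n_x, n_y)`` field, mm^-1); ``surface_depth`` the
    first tissue pixel (scalar or per-(x, y) map).  ``source_fluctuation_sd``
    is the relative SD of the per-frame power scalar, ``noise_floor_level``
    the scale of the additive half-normal floor (linear intensity), and
    ``speckle_sd`` the relative SD of the static reflectivity texture.
    Identical seed implies bit-identical output.
    """

    grid: tuple[int, int, int, int] = (10, 256, 128, 64)
    pixel_size_axial: float = 0.0075
    tissue_mu: float | np.ndarray = 1.5
    surface_depth: int | np.ndarray = 20
    vessels: tuple[VesselSpec, ...] = ()
    source_fluctuation_sd: float = 0.0
    noise_floor_level: float = 0.0
    speckle_sd: float = 0.2
    confocal: ConfocalParams | None = None
    incident_intensity: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "vessels", tuple(self.vessels))
        M, nz, nx, ny = self.grid
        if M < 2:
            raise ValueError(f"need M >= 2 repeated frames, got {M}")
        if min(nz, nx, ny) <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.pixel_size_axial <= 0:
            raise ValueError("pixel_size_axial must be positive (mm)")
        if np.any(np.asarray(self.tissue_mu) <= 0):
            raise ValueError("tissue_mu must be positive (mm^-1)")
        if self.noise_floor_level < 0:
            raise ValueError("noise_floor_level must be >= 0")
        if self.speckle_sd < 0 or self.source_fluctuation_sd < 0:
            raise ValueError("noise SDs must be >= 0")


@dataclass
class GroundTruth:
    """Paired truth for a generated phantom."""

    mu_field: np.ndarray           # (n_depth, n_x, n_y), mm^-1, frame-mean field
    vessel_mask_3d: np.ndarray     # bool (n_depth, n_x, n_y)
    superficial_mask_2d: np.ndarray  # bool (n_x, n_y)
    deep_mask_2d: np.ndarray       # bool (n_x, n_y)
    surface_map: np.ndarray        # int (n_x, n_y)


def _rasterize_vessel(vessel: VesselSpec, shape: tuple[int, int, int]) -> np.ndarray:
    """Boolean voxel mask of a tube around the vessel polyline.

    Samples the polyline at half-pixel steps and marks voxels within
    ``radius`` (Euclidean, voxel units, z treated isotropically).
    """
    nz, nx, ny = shape
    pts = np.asarray(vessel.centerline, dtype=np.float64)  # (k, 3) as (x, y, z)
    samples = [pts[0]]
    for a, b in zip(pts[:-1], pts[1:]):
        seg = b - a
        n = max(int(np.ceil(np.linalg.norm(seg) / 0.5)), 1)
        for t in np.linspace(0.0, 1.0, n + 1)[1:]:
            samples.append(a + t * seg)
    samples = np.asarray(samples)

    r = vessel.radius
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    if (lo < -0.5).any() or hi[0] > nx - 0.5 or hi[1] > ny - 0.5 or hi[2] > nz - 0.5:
        raise ValueError(
            f"vessel centerline outside the grid: bounds x,y,z {lo.round(1)}..{hi.round(1)} "
            f"vs grid (x<{nx}, y<{ny}, z<{nz})"
        )
    if pts[:, 2].min() - r < -0.5 or pts[:, 2].max() + r > nz - 0.5:
        raise ValueError("vessel tube exceeds the depth range; lateral clipping is allowed "
                         "but axial clipping would corrupt the attenuation profile")

    mask = np.zeros(shape, dtype=bool)
    ri = int(np.ceil(r))
    for x, y, z in samples:
        zi0, zi1 = max(int(z) - ri, 0), min(int(z) + ri + 1, nz)
        xi0, xi1 = max(int(x) - ri, 0), min(int(x) + ri + 1, nx)
        yi0, yi1 = max(int(y) - ri, 0), min(int(y) + ri + 1, ny)
        zz, xx, yy = np.meshgrid(
            np.arange(zi0, zi1), np.arange(xi0, xi1), np.arange(yi0, yi1), indexing="ij"
        )
        d2 = (zz - z) ** 2 + (xx - x) ** 2 + (yy - y) ** 2
        mask[zi0:zi1, xi0:xi1, yi0:yi1] |= d2 <= r * r
    return mask


def make_phantom(spec: PhantomSpec) -> tuple[OCTVolume, GroundTruth]:
    """Generate a seeded OCT volume and its paired ground truth.

    Returns the 4-D linear-intensity volume indexed ``(m, z, x, y)`` and a
    :class:`GroundTruth` with the attenuation field, vessel masks split into
    superficial / deep en-face slabs (450 um each below the surface) and the
    per-(x, y) surface depth.
    """
    M, nz, nx, ny = spec.grid
    delta = spec.pixel_size_axial
    rng = np.random.default_rng(spec.seed)

    surface = np.asarray(spec.surface_depth)
    if surface.ndim == 0:
        surface = np.full((nx, ny), int(surface), dtype=np.int64)
    else:
        surface = surface.astype(np.int64)
        if surface.shape != (nx, ny):
            raise ValueError(f"surface_depth map must be (n_x, n_y)={nx, ny}, got {surface.shape}")
    if surface.min() < 0 or surface.max() >= nz:
        raise ValueError("surface_depth outside the depth range")

    zidx = np.arange(nz)
    tissue = zidx[:, None, None] >= surface[None, :, :]  # (z, x, y)

    mu_static = np.where(tissue, np.broadcast_to(np.asarray(spec.tissue_mu, dtype=np.float64),
                                                 (nz, nx, ny)), 0.0).astype(np.float64)

    vessel_masks = [_rasterize_vessel(v, (nz, nx, ny)) for v in spec.vessels]
    vessel_any = np.zeros((nz, nx, ny), dtype=bool)
    for v, m in zip(spec.vessels, vessel_masks):
        mu_static[m] = v.mu_vessel
        vessel_any |= m

    # Static speckle texture: drawn once, frozen across frames.
    R0 = np.ones((nz, nx, ny), dtype=np.float64)
    if spec.speckle_sd > 0:
        R0 = np.clip(1.0 + spec.speckle_sd * rng.standard_normal((nz, nx, ny)), 0.0, None)
    R0 = np.where(tissue, R0, 0.0)

    if spec.confocal is not None:
        h = confocal_psf(zidx * delta, spec.confocal)[:, None, None]
    else:
        h = np.ones((nz, 1, 1))

    if spec.source_fluctuation_sd > 0:
        s = 1.0 + spec.source_fluctuation_sd * rng.standard_normal(M)
        s = np.clip(s, 0.1, None)
    else:
        s = np.ones(M)

    data = np.empty((M, nz, nx, ny), dtype=np.float64)
    for m in range(M):
        mu_m = mu_static.copy()
        R_m = R0.copy()
        for v, vmask in zip(spec.vessels, vessel_masks):
            if v.flow_decorr > 0:
                n_in = int(vmask.sum())
                # RBC motion is coherent along the beam within one vessel, so
                # the attenuation perturbation is drawn per A-line column; the
                # reflectivity speckle decorrelates per voxel.
                col = np.clip(1.0 + v.flow_decorr * rng.standard_normal((nx, ny)), 0.0, None)
                mu_m[vmask] = (v.mu_vessel * col[None, :, :] * np.ones((nz, 1, 1)))[vmask]
                R_m[vmask] = np.clip(
                    R0[vmask] * (1.0 + v.flow_decorr * rng.standard_normal(n_in)), 0.0, None
                )
        # exclusive cumulative attenuation above each depth (double pass)
        atten = np.exp(-2.0 * delta * (np.cumsum(mu_m, axis=0) - mu_m))
        frame = spec.incident_intensity * s[m] * h * R_m * atten
        if spec.noise_floor_level > 0:
            frame = frame + spec.noise_floor_level * np.abs(
                rng.standard_normal((nz, nx, ny))
            )
        data[m] = frame

    slab_px = max(int(round(SLAB_THICKNESS_UM_DEFAULT / (delta * 1000.0))), 1)
    depth_below = zidx[:, None, None] - surface[None, :, :]
    superficial = vessel_any & (depth_below >= 0) & (depth_below < slab_px)
    deep = vessel_any & (depth_below >= slab_px) & (depth_below < 2 * slab_px)

    truth = GroundTruth(
        mu_field=mu_static,
        vessel_mask_3d=vessel_any,
        superficial_mask_2d=superficial.any(axis=0),
        deep_mask_2d=deep.any(axis=0),
        surface_map=surface,
    )
    geometry = ScanGeometry(M=M, n_depth=nz, n_alines=nx, n_positions=ny, delta_axial=delta)
    volume = OCTVolume(data=data, geometry=geometry, meta={"seed": spec.seed, "kind": "phantom"})
    return volume, truth


def default_phantom_spec(seed: int = 0, *, grid: tuple[int, int, int, int] = (10, 192, 96, 48),
                         noise_floor_level: float = 1e-4,
                         source_fluctuation_sd: float = 0.0) -> PhantomSpec:
    """Canonical study phantom: one superficial large vessel, one deep small one.

    The large vessel (radius 6 px) runs along the slow axis near the surface
    and casts its flow-modulated shadow on everything beneath; the small deep
    vessel (radius 2 px) sits in the deep slab, laterally offset so it stays
    clear of the large vessel's footprint.  Geometry is scaled so the whole
    pipeline runs in seconds at 7.5 um axial pitch.
    """
    M, nz, nx, ny = grid
    surface = 20
    slab_px = int(round(SLAB_THICKNESS_UM_DEFAULT / 7.5))  # 60 px at default pitch
    z_sup = surface + 14
    z_deep = surface + slab_px + 18
    vessels = (
        VesselSpec(centerline=((nx // 3, 0, z_sup), (nx // 3, ny - 1, z_sup)),
                   radius=7, mu_vessel=10.0, flow_decorr=0.8),
        VesselSpec(centerline=((3 * nx // 4, 0, z_deep), (3 * nx // 4, ny - 1, z_deep)),
                   radius=2, mu_vessel=10.0, flow_decorr=0.8),
    )
    return PhantomSpec(
        grid=grid,
        pixel_size_axial=0.0075,
        tissue_mu=1.5,
        surface_depth=surface,
        vessels=vessels,
        source_fluctuation_sd=source_fluctuation_sd,
        noise_floor_level=noise_floor_level,
        speckle_sd=0.2,
        seed=seed,
    )
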