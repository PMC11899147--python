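"""Volume and table I/O shared by every pipeline stage.

An OCT acquisition is a 4-D stack: ``M`` repeated B-scans per slow-axis
position, each B-scan a ``(n_depth, n_x)`` image.  In memory the canonical
container is :class:`OCTVolume` with axis order ``(m, z, x, y)``.  On disk a
volume is a multi-page TIFF (page order y-major with the repeat index inner:
page ``p = y * M + m``) plus a JSON sidecar carrying the scan geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

METRICS_COLUMNS = ["slab", "timepoint", "VPD", "VL", "VAD", "VT", "n_branch", "n_end"]


@dataclass(frozen=True)
class ScanGeometry:
    """Acquisition geometry: repeats, raster size and axial pixel pitch.

    Parameters
    ----------
    M : int
        Repeated B-scans per slow-axis position (>= 2; flow extraction needs
        at least one frame pair).
    n_depth, n_alines, n_positions : int
        Samples along depth (z), fast axis (x) and slow axis (y).
    delta_axial : float
        Axial pixel pitch in mm.
    field_of_view : tuple of float, optional
        Lateral extent (x_mm, y_mm); informational only.
    """

    M: int
    n_depth: int
    n_alines: int
    n_positions: int
    delta_axial: float
    field_of_view: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.M < 2:
            raise ValueError(f"need M >= 2 repeated B-scans, got M={self.M}")
        for name in ("n_depth", "n_alines", "n_positions"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.delta_axial <= 0:
            raise ValueError("delta_axial must be positive (mm)")


@dataclass
class OCTVolume:
    """Linear-intensity OCT volume indexed ``(m, z, x, y)``."""

    data: np.ndarray  # float array, shape (M, n_depth, n_x, n_y)
    geometry: ScanGeometry
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4-D (m, z, x, y) data, got shape {self.data.shape}")
        g = self.geometry
        expect = (g.M, g.n_depth, g.n_alines, g.n_positions)
        if self.data.shape != expect:
            raise ValueError(f"data shape {self.data.shape} != geometry {expect}")

    @property
    def delta(self) -> float:
        return self.geometry.delta_axial

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape


def write_volume(volume: OCTVolume, path: str | Path, sidecar: str | Path | None = None) -> Path:
    """Write a volume as multi-page TIFF plus a JSON geometry sidecar.

    Page order is y-major with the repeat index inner (page = y*M + m); each
    page is the ``(z, x)`` B-scan.  Returns the sidecar path.
    """
    path = Path(path)
    sidecar = Path(sidecar) if sidecar is not None else path.with_suffix(".json")
    g = volume.geometry
    pages = np.transpose(volume.data, (3, 0, 1, 2)).reshape(
        g.n_positions * g.M, g.n_depth, g.n_alines
    )
    tifffile.imwrite(path, np.ascontiguousarray(pages), photometric="minisblack")
    payload = {
        "geometry": asdict(g),
        "meta": {k: v for k, v in volume.meta.items() if _json_safe(v)},
        "tiff": path.name,
    }
    sidecar.write_text(json.dumps(payload, indent=2))
    return sidecar


def read_volume(path: str | Path, sidecar: str | Path | None = None) -> OCTVolume:
    """Read a multi-page TIFF volume written by :func:`write_volume`.

    Raises ``ValueError`` when the TIFF page count disagrees with the
    sidecar geometry (M * n_positions pages expected).
    """
    path = Path(path)
    sidecar = Path(sidecar) if sidecar is not None else path.with_suffix(".json")
    payload = json.loads(sidecar.read_text())
    gdict = payload["geometry"]
    if gdict.get("field_of_view") is not None:
        gdict["field_of_view"] = tuple(gdict["field_of_view"])
    g = ScanGeometry(**gdict)
    pages = tifffile.imread(path)
    pages = np.atleast_3d(pages)
    if pages.ndim == 2:  # single page
        pages = pages[None]
    n_expected = g.M * g.n_positions
    if pages.shape[0] != n_expected:
        raise ValueError(
            f"TIFF has {pages.shape[0]} pages but geometry requires "
            f"M*n_positions = {g.M}*{g.n_positions} = {n_expected}"
        )
    data = pages.reshape(g.n_positions, g.M, g.n_depth, g.n_alines)
    data = np.transpose(data, (1, 2, 3, 0))
    return OCTVolume(data=np.ascontiguousarray(data, dtype=np.float64), geometry=g,
                     meta=payload.get("meta", {}))


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as an 8-bit single-page TIFF (255 = foreground)."""
    tifffile.imwrite(Path(path), (np.asarray(mask, bool).astype(np.uint8) * 255))


def read_mask(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(Path(path))) > 0


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write a nonnegative float image as 16-bit TIFF, min-max scaled."""
    img = np.asarray(image, dtype=np.float64)
    lo, hi = float(img.min()), float(img.max())
    scaled = np.zeros_like(img) if hi <= lo else (img - lo) / (hi - lo)
    tifffile.imwrite(Path(path), (scaled * 65535).astype(np.uint16))


def write_metrics(records: list[dict], path: str | Path) -> pd.DataFrame:
    """Write vascular metrics rows to CSV in the stable column order.

    Each record needs the keys in ``METRICS_COLUMNS``; extra keys are
    dropped.  Empty input yields a header-only file.
    """
    df = pd.DataFrame.from_records(records, columns=METRICS_COLUMNS)
    df.to_csv(Path(path), index=False)
    return df


def read_metrics(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))


def _json_safe(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False
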