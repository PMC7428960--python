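"""OCT volume container and file I/O.

A macular SS-OCT cube is stored as a 3-D nonnegative intensity grid with
axes (B-scan index *y*, axial depth *z*, A-scan index *x*), together with
its physical sampling and the en-face landmarks (fovea, optic disc) the
pipeline needs.  Volumes round-trip through multi-page 16-bit grayscale
TIFF (one page per B-scan) with a JSON sidecar carrying the geometry,
since plain TIFF has no standard OCT metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["OctVolume", "save_volume", "load_volume"]

#: scale used when writing float reflectivity volumes to 16-bit TIFF
TIFF_SCALE = 10_000.0

# geometry fields required in the JSON sidecar next to a volume TIFF
_SIDECAR_REQUIRED = ("dx_mm", "dy_mm", "dz_um", "fovea_xy")


@dataclass
class OctVolume:
    """A 3-D OCT intensity volume plus physical geometry and landmarks.

    Parameters
    ----------
    intensity : ndarray, shape (ny, nz, nx)
        Nonnegative signal, B-scan-major: ``intensity[y]`` is one B-scan
        (depth x lateral).
    dx_mm, dy_mm : float
        Lateral A-scan / B-scan spacing in millimetres.
    dz_um : float
        Axial sampling in micrometres per pixel.
    fovea_xy : (float, float)
        Foveal centre in en-face millimetre coordinates.
    disc_xy : (float, float) or None
        Optic-disc centre, or None for a macular cube that does not
        contain the disc.
    meta : dict
        Free-form metadata (e.g. rendered ground-truth surfaces attached
        by the phantom generator).
    """

    intensity: np.ndarray
    dx_mm: float
    dy_mm: float
    dz_um: float
    fovea_xy: tuple[float, float]
    disc_xy: tuple[float, float] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity)
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be 3-D (ny, nz, nx)")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be nonnegative")
        if min(self.dx_mm, self.dy_mm, self.dz_um) <= 0:
            raise ValueError("pixel spacings must be positive")
        fx, fy = self.fovea_xy
        if not (0 <= fx <= self.extent_x_mm and 0 <= fy <= self.extent_y_mm):
            raise ValueError("fovea_xy lies outside the scan extent")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensity.shape

    @property
    def ny(self) -> int:
        return self.intensity.shape[0]

    @property
    def nz(self) -> int:
        return self.intensity.shape[1]

    @property
    def nx(self) -> int:
        return self.intensity.shape[2]

    @property
    def extent_x_mm(self) -> float:
        return self.nx * self.dx_mm

    @property
    def extent_y_mm(self) -> float:
        return self.ny * self.dy_mm


def save_volume(vol: OctVolume, path: str | Path) -> Path:
    """Write *vol* as multi-page uint16 TIFF plus a JSON geometry sidecar.

    Float intensities are scaled by ``TIFF_SCALE`` and clipped to the
    16-bit range; integer volumes are written as-is.  Returns the TIFF
    path; the sidecar is written next to it with suffix ``.json``.
    """
    path = Path(path)
    data = vol.intensity
    if np.issubdtype(data.dtype, np.integer):
        pages = data.astype(np.uint16)
    else:
        pages = np.clip(np.rint(data * TIFF_SCALE), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, pages, photometric="minisblack")
    sidecar = {
        "dx_mm": vol.dx_mm,
        "dy_mm": vol.dy_mm,
        "dz_um": vol.dz_um,
        "fovea_xy": list(vol.fovea_xy),
        "disc_xy": list(vol.disc_xy) if vol.disc_xy is not None else None,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_volume(path: str | Path) -> OctVolume:
    """Read a TIFF volume and its JSON sidecar back into an :class:`OctVolume`.

    Raises ``ValueError`` naming the missing field if the sidecar is
    absent or incomplete.
    """
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise ValueError(f"missing geometry sidecar {sidecar_path.name}")
    sidecar = json.loads(sidecar_path.read_text())
    for key in _SIDECAR_REQUIRED:
        if key not in sidecar or sidecar[key] is None:
            raise ValueError(f"volume sidecar missing required field {key!r}")
    data = tifffile.imread(path).astype(np.float64)
    disc = sidecar.get("disc_xy")
    return OctVolume(
        intensity=data,
        dx_mm=float(sidecar["dx_mm"]),
        dy_mm=float(sidecar["dy_mm"]),
        dz_um=float(sidecar["dz_um"]),
        fovea_xy=tuple(sidecar["fovea_xy"]),
        disc_xy=tuple(disc) if disc is not None else None,
    )
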