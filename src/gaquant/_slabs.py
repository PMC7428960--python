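"""Axial slab statistics shared by the attenuation and sub-RPE maps."""

from __future__ import annotations

import numpy as np

__all__ = ["slab_mean"]


def slab_mean(
    intensity: np.ndarray, z_lo_px: np.ndarray, z_hi_px: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mean intensity over voxels with ``z_lo <= z <= z_hi`` per A-scan.

    Parameters
    ----------
    intensity : ndarray, shape (ny, nz, nx)
    z_lo_px, z_hi_px : ndarray, shape (ny, nx)
        Inclusive slab bounds in (fractional) axial pixel units.  Slabs
        extending past the bottom of the volume are truncated; slabs that
        are fully out of range yield an invalid pixel.

    Returns
    -------
    mean : ndarray (ny, nx), NaN where invalid
    valid : ndarray (ny, nx) bool
    """
    ny, nz, nx = intensity.shape
    a = np.ceil(np.asarray(z_lo_px, dtype=float)).astype(np.int64)
    b = np.floor(np.asarray(z_hi_px, dtype=float)).astype(np.int64)
    valid = (a <= b) & (a <= nz - 1) & (b >= 0)
    a_c = np.clip(a, 0, nz - 1)
    b_c = np.clip(b, 0, nz - 1)

    cum = np.concatenate(
        [np.zeros((ny, 1, nx)), np.cumsum(intensity, axis=1, dtype=np.float64)], axis=1
    )
    hi = np.take_along_axis(cum, (b_c + 1)[:, None, :], axis=1)[:, 0, :]
    lo = np.take_along_axis(cum, a_c[:, None, :], axis=1)[:, 0, :]
    count = b_c - a_c + 1
    with np.errstate(invalid="ignore"):
        mean = np.where(valid, (hi - lo) / np.maximum(count, 1), np.nan)
    return mean, valid
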