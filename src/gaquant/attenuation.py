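"""Integrated attenuation-ratio map and its enhancement.

The map normalises the RPE-complex signal by the choroid–scleral signal:
per A-scan, the mean intensity of a slab spanning the RPE complex is
divided by the mean of a slab below Bruch's membrane.  Atrophy lowers the
numerator (RPE loss) and raises the denominator (hypertransmission), so
low ratios flag GA.  Enhancement is a sliding-window order filter (median
by default) that ignores invalid pixels.

Because the ratio should not depend on the device's arbitrary global
gain, the volume is first quantised to a canonical 16-bit intensity scale
(device exports are integer-valued anyway); the map is then bit-identical
under any positive rescaling of the input volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from ._slabs import slab_mean
from .segmentation import LayerSurfaces
from .volume import OctVolume

__all__ = ["AttenuationMap", "compute_attenuation_map", "enhance_map"]


@dataclass
class AttenuationMap:
    """En-face RPE-complex / choroid–scleral intensity ratio.

    ``ratio`` is NaN exactly where ``valid`` is False; ``slab_um``
    records the axial slab offsets used, and the lateral geometry is
    copied from the source volume.
    """

    ratio: np.ndarray
    valid: np.ndarray
    dx_mm: float
    dy_mm: float
    slab_um: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.ratio.shape


def _quantize(intensity: np.ndarray) -> np.ndarray:
    """Map intensities onto a canonical max-normalised 16-bit scale."""
    m = float(intensity.max())
    if m <= 0:
        return np.zeros_like(intensity, dtype=np.float64)
    return np.rint(intensity * (65535.0 / m))


def compute_attenuation_map(
    vol: OctVolume,
    s: LayerSurfaces,
    *,
    rpe_offset_um: float = 10.0,
    cs_start_um: float = 20.0,
    cs_end_um: float = 220.0,
) -> AttenuationMap:
    """Ratio of the RPE-complex slab mean over the choroid–scleral slab mean.

    The numerator slab spans [osrpe, bm + ``rpe_offset_um``], the
    denominator [bm + ``cs_start_um``, bm + ``cs_end_um``].  Slabs are
    truncated at the bottom of the volume; a zero or out-of-range
    denominator marks the pixel invalid.  Requires valid surfaces on at
    least 10% of A-scans.
    """
    if s.valid.mean() < 0.10:
        raise ValueError("layer surfaces valid on fewer than 10% of A-scans")
    q = _quantize(vol.intensity.astype(np.float64))
    px = 1.0 / vol.dz_um
    num, num_ok = slab_mean(q, s.osrpe, s.bm + rpe_offset_um * px)
    den, den_ok = slab_mean(q, s.bm + cs_start_um * px, s.bm + cs_end_um * px)
    valid = s.valid & num_ok & den_ok & (den > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(valid, num / den, np.nan)
    return AttenuationMap(
        ratio=ratio,
        valid=valid,
        dx_mm=vol.dx_mm,
        dy_mm=vol.dy_mm,
        slab_um={"rpe_offset": rpe_offset_um, "cs_start": cs_start_um, "cs_end": cs_end_um},
    )


def _rank_filter_masked(arr: np.ndarray, window: int, rank: float) -> np.ndarray:
    """Sliding-window order filter that excludes NaN (invalid) samples.

    Within each window the valid samples are sorted and the order
    statistic at index round(rank * (n_valid - 1)) is taken; rank 0.5 is
    the median, rank 0 the minimum, rank 1 the maximum.
    """
    pad = window // 2
    padded = np.pad(arr, pad, constant_values=np.nan)
    win = sliding_window_view(padded, (window, window)).reshape(*arr.shape, -1)
    order = np.sort(win, axis=-1)  # NaNs sort to the end
    n_valid = window * window - np.isnan(win).sum(axis=-1)
    k = np.rint(rank * np.maximum(n_valid - 1, 0)).astype(np.int64)
    out = np.take_along_axis(order, k[..., None], axis=-1)[..., 0]
    out[n_valid == 0] = np.nan
    return out


def enhance_map(
    m: AttenuationMap,
    window: int = 5,
    rank: float = 0.5,
    *,
    gaussian_sigma: float | None = None,
) -> AttenuationMap:
    """Order-filter the attenuation map, optionally Gaussian-smoothing after.

    ``window`` must be odd and no larger than the map; invalid pixels are
    excluded from every window and remain invalid in the output.  With
    ``gaussian_sigma`` set, a NaN-aware normalised Gaussian pass follows.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    if window > min(m.shape):
        raise ValueError("window larger than the map")
    if not (0.0 <= rank <= 1.0):
        raise ValueError("rank must lie in [0, 1]")

    if window == 1:
        out = m.ratio.copy()
    else:
        out = _rank_filter_masked(m.ratio, window, rank)
    if gaussian_sigma:
        filled = np.where(m.valid, out, 0.0)
        weight = m.valid.astype(np.float64)
        sm = ndimage.gaussian_filter(filled, gaussian_sigma)
        wt = ndimage.gaussian_filter(weight, gaussian_sigma)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(wt > 0, sm / wt, np.nan)
    out = np.where(m.valid, out, np.nan)
    return replace(m, ratio=out, valid=m.valid & ~np.isnan(out))
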