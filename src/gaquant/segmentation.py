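"""Retinal layer surfaces for the attenuation map.

Three surfaces are needed: the inner limiting membrane (ILM), the inner
boundary of the RPE complex (OS/RPE junction), and Bruch's membrane (BM).
Initial detection finds the brightest posterior band per B-scan with a
shortest-path search (bounded per-step axial jump), takes the band's
inner/outer edges from axial-gradient extrema with sub-pixel refinement,
and locates the ILM as the first sustained bright transition from the
vitreous side.  A refinement pass re-estimates BM where the RPE band is
weak or absent — the situation inside geographic atrophy, where BM
persists but the RPE does not — by low-order smooth interpolation from
flanking A-scans with a strong band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from ._slabs import slab_mean
from .volume import OctVolume

__all__ = ["LayerSurfaces", "segment_surfaces", "resegment_rpe_bm", "make_disc_mask"]


@dataclass
class LayerSurfaces:
    """Per-(x, y) axial pixel positions of ILM, OS/RPE and BM.

    Fractional positions are allowed; ``valid`` flags A-scans where a
    posterior band was detectable at all.  The ordering invariant
    ``ilm <= osrpe <= bm`` holds wherever valid.
    """

    ilm: np.ndarray
    osrpe: np.ndarray
    bm: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        shapes = {self.ilm.shape, self.osrpe.shape, self.bm.shape, self.valid.shape}
        if len(shapes) != 1:
            raise ValueError("surface arrays must share one (ny, nx) shape")

    def enforce_ordering(self) -> "LayerSurfaces":
        osrpe = np.maximum(self.osrpe, self.ilm)
        bm = np.maximum(self.bm, osrpe)
        return replace(self, osrpe=osrpe, bm=bm)


def _bright_path(cost: np.ndarray, max_jump: int = 2) -> np.ndarray:
    """Minimal-cost left-to-right path through a (nz, nx) cost image.

    The path visits one depth per column with per-step jumps bounded by
    ``max_jump`` pixels; returns the depth index per column.
    """
    nz, nx = cost.shape
    dist = cost[:, 0].astype(np.float64).copy()
    offs = np.arange(-max_jump, max_jump + 1)
    back = np.zeros((nx, nz), dtype=np.int8)
    cand = np.empty((offs.size, nz))
    for x in range(1, nx):
        cand.fill(np.inf)
        for i, o in enumerate(offs):
            if o == 0:
                cand[i] = dist
            elif o > 0:
                cand[i, o:] = dist[:-o]
            else:
                cand[i, :o] = dist[-o:]
        best = np.argmin(cand, axis=0)
        dist = cand[best, np.arange(nz)] + cost[:, x]
        back[x] = offs[best]
    path = np.empty(nx, dtype=np.int64)
    path[-1] = int(np.argmin(dist))
    for x in range(nx - 1, 0, -1):
        path[x - 1] = path[x] - back[x, path[x]]
    return path


def _subpixel_extremum(g: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Parabolic sub-pixel offset of an extremum of *g* at integer index *k*."""
    nz = g.shape[0]
    km = np.clip(k - 1, 0, nz - 1)
    kp = np.clip(k + 1, 0, nz - 1)
    cols = np.arange(g.shape[1])
    a, b, c = g[km, cols], g[k, cols], g[kp, cols]
    denom = a - 2 * b + c
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.where(np.abs(denom) > 1e-12, 0.5 * (a - c) / denom, 0.0)
    return np.clip(delta, -0.5, 0.5)


def segment_surfaces(
    vol: OctVolume,
    *,
    max_jump: int = 2,
    smooth_sigma: tuple[float, float, float] = (0.8, 1.2, 1.0),
    edge_window_px: int = 12,
    ilm_fraction: float = 0.25,
    bottom_margin_um: float = 120.0,
) -> LayerSurfaces:
    """Detect ILM, OS/RPE and BM on every B-scan of *vol*.

    The band search is restricted to depths that leave at least
    ``bottom_margin_um`` of tissue below, so the sub-band background the
    refinement and attenuation slabs need is always measurable.  A-scans
    with no detectable signal are flagged invalid rather than guessed.
    Requires at least 32 axial samples.
    """
    if vol.nz < 32:
        raise ValueError("volume must have at least 32 axial samples")
    ny, nz, nx = vol.shape
    z_limit = max(int(nz - 1 - np.ceil(bottom_margin_um / vol.dz_um)), 8)
    sm = ndimage.gaussian_filter(vol.intensity.astype(np.float64), sigma=smooth_sigma)
    global_max = float(sm.max())

    ilm = np.zeros((ny, nx))
    osrpe = np.zeros((ny, nx))
    bm = np.zeros((ny, nx))
    valid = np.zeros((ny, nx), dtype=bool)

    for y in range(ny):
        bscan = sm[y]  # (nz, nx)
        center = _bright_path(-bscan[: z_limit + 1], max_jump=max_jump)
        cols = np.arange(nx)
        peak = bscan[center, cols]
        ok = peak > max(1e-6 * global_max, 1e-12)
        valid[y] = ok

        grad = np.gradient(bscan, axis=0)
        # inner band edge: strongest positive axial gradient just above the
        # band centre; outer edge (BM): strongest negative gradient below it
        w = edge_window_px
        up_idx = np.clip(center[None, :] + np.arange(-w, 1)[:, None], 0, nz - 1)
        dn_idx = np.clip(center[None, :] + np.arange(0, w + 1)[:, None], 0, nz - 1)
        gup = np.take_along_axis(grad, up_idx, axis=0)
        gdn = np.take_along_axis(grad, dn_idx, axis=0)
        top = up_idx[gup.argmax(axis=0), cols]
        bot = dn_idx[gdn.argmin(axis=0), cols]
        osrpe[y] = top + _subpixel_extremum(grad, top)
        bm[y] = bot + _subpixel_extremum(grad, bot)

        # ILM: first sustained bright transition from the vitreous side —
        # topmost crossing of a robust fractional threshold (the vitreous
        # is dark, so the inner-retina rise is the first crossing even
        # where atrophy disrupts the posterior bands)
        vit = bscan[: max(5, nz // 32)].mean(axis=0)
        bright = np.percentile(bscan, 95, axis=0)
        thr = vit + ilm_fraction * np.maximum(bright - vit, 0.0)
        above = bscan > thr[None, :]
        first = np.clip(above.argmax(axis=0), 1, nz - 1)
        prev = bscan[first - 1, cols]
        cur = bscan[first, cols]
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(cur > prev, (thr - prev) / (cur - prev), 0.5)
        ilm[y] = np.where(above.any(axis=0), first - 1 + np.clip(frac, 0.0, 1.0), 0.0)

    # lateral regularisation: surfaces are smooth at the 7 mm scale
    for surf in (ilm, osrpe, bm):
        surf[:] = ndimage.median_filter(surf, size=(3, 7), mode="nearest")

    out = LayerSurfaces(ilm=ilm, osrpe=osrpe, bm=bm, valid=valid).enforce_ordering()
    return out


def resegment_rpe_bm(
    vol: OctVolume,
    s: LayerSurfaces,
    *,
    contrast_threshold: float = 1.5,
    background_start_um: float = 20.0,
    background_end_um: float = 120.0,
    min_strong_per_bscan: int = 8,
) -> LayerSurfaces:
    """Re-estimate BM where the RPE band is weak or absent.

    The band contrast of each A-scan is the ratio of the mean intensity
    inside [osrpe, bm] to the mean of a background slab just below BM.
    Where contrast falls below ``contrast_threshold``, BM is re-estimated
    by a least-squares quadratic per B-scan over the flanking
    strong-contrast A-scans (BM persists in atrophy; the RPE does not),
    and OS/RPE collapses onto BM.  A threshold of 0 reclassifies nothing.
    """
    ny, nz, nx = vol.shape
    if s.valid.size and (~s.valid).mean() > 0.9:
        raise RuntimeError(
            "more than 90% of A-scans carry no detectable band; "
            "cannot anchor Bruch's membrane re-estimation"
        )
    px_per_um = 1.0 / vol.dz_um
    band_mean, band_ok = slab_mean(vol.intensity, s.osrpe, np.maximum(s.bm, s.osrpe + 1))
    bg_lo = s.bm + background_start_um * px_per_um
    bg_hi = s.bm + background_end_um * px_per_um
    bg_mean, bg_ok = slab_mean(vol.intensity, bg_lo, bg_hi)

    with np.errstate(divide="ignore", invalid="ignore"):
        contrast = np.where(bg_ok & (bg_mean > 0), band_mean / bg_mean, np.inf)
    weak = s.valid & band_ok & (contrast < contrast_threshold)
    if not weak.any():
        return s

    bm = s.bm.copy()
    osrpe = s.osrpe.copy()
    xs = np.arange(nx, dtype=float)
    pending: list[int] = []
    for y in range(ny):
        wrow = weak[y]
        if not wrow.any():
            continue
        strong = s.valid[y] & ~wrow
        if strong.sum() >= min_strong_per_bscan:
            coef = np.polyfit(xs[strong], s.bm[y, strong], deg=2)
            bm[y, wrow] = np.polyval(coef, xs[wrow])
        else:
            pending.append(y)
    if pending:
        # B-scans without enough flanking support borrow a global surface fit
        strong = s.valid & ~weak
        yy, xx = np.nonzero(strong)
        design = np.column_stack([np.ones(yy.size), xx, yy, xx**2, yy**2, xx * yy])
        coef, *_ = np.linalg.lstsq(design, s.bm[strong], rcond=None)
        for y in pending:
            wx = np.nonzero(weak[y])[0]
            d = np.column_stack(
                [np.ones(wx.size), wx, np.full(wx.size, y), wx**2, np.full(wx.size, y**2), wx * y]
            )
            bm[y, wx] = d @ coef
    osrpe[weak] = bm[weak]
    return LayerSurfaces(ilm=s.ilm.copy(), osrpe=osrpe, bm=bm, valid=s.valid.copy()).enforce_ordering()


def make_disc_mask(vol: OctVolume, radius_mm: float = 0.9) -> np.ndarray:
    """Circular optic-disc exclusion mask in the en-face plane.

    All-false for macular cubes without a disc location; otherwise True
    within ``radius_mm`` of the disc centre, clipped to the scan.
    """
    mask = np.zeros((vol.ny, vol.nx), dtype=bool)
    if vol.disc_xy is None:
        return mask
    cx, cy = vol.disc_xy
    x_mm = (np.arange(vol.nx) + 0.5) * vol.dx_mm
    y_mm = (np.arange(vol.ny) + 0.5) * vol.dy_mm
    return (x_mm[None, :] - cx) ** 2 + (y_mm[:, None] - cy) ** 2 <= radius_mm**2


def warn_if_mostly_invalid(s: LayerSurfaces, threshold: float = 0.5) -> None:
    if (~s.valid).mean() > threshold:
        warnings.warn("more than half of the A-scans have no detectable band", stacklevel=2)
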