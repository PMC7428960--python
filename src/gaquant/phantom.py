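"""Synthetic SS-OCT phantoms with known geographic-atrophy ground truth.

The generator emulates a 7 x 7 mm macular cube: a layered retina (vitreous,
inner retina, outer retina, a bright RPE band, choroid, sclera) bowed by a
smooth parabolic curvature, with GA lesions rendered as loss of the RPE
band (residual reflectivity) plus sub-RPE hypertransmission (brighter
choroid/sclera), under multiplicative gamma speckle of mean one.  Lesions
are radially perturbed circles, so "regular" and "irregular" shapes are
objective functions of the harmonic amplitudes.  A companion study
simulator produces eye x rater/replicate measurement tables with a known
additive error structure for exercising the agreement statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import Polygon, box

from .volume import OctVolume

__all__ = [
    "LesionTruthSpec",
    "PhantomSpec",
    "GroundTruth",
    "StudySpec",
    "make_truth",
    "render_volume",
    "simulate_study",
    "default_layer_profile",
]

#: boundary samples used for the continuous lesion polygon
_POLY_SAMPLES = 4096


def default_layer_profile() -> list[tuple[str, float, float]]:
    """Layer stack as (name, thickness um, mean reflectivity in [0, 1]).

    The stack totals 810 um and must fit the axial range together with
    the curvature bowl.  The last layer (sclera) extends to the bottom of
    the volume regardless of its nominal thickness.
    """
    return [
        ("vitreous", 150.0, 0.02),
        ("inner_retina", 200.0, 0.35),
        ("outer_retina", 120.0, 0.20),
        ("rpe", 30.0, 0.90),
        ("choroid", 200.0, 0.25),
        ("sclera", 110.0, 0.40),
    ]


@dataclass
class LesionTruthSpec:
    """A GA lesion as a radially perturbed circle.

    The boundary is r(theta) = R * (1 + sum_i a_i * cos(o_i * (theta - rot)))
    with harmonic orders ``o_i`` and amplitude fractions ``a_i``; all
    amplitudes zero gives a circle.
    """

    center_xy_mm: tuple[float, float]
    base_radius_mm: float
    radial_harmonics: list[tuple[int, float]] = field(default_factory=list)
    rotation: float = 0.0

    def __post_init__(self) -> None:
        if self.base_radius_mm <= 0:
            raise ValueError("base_radius_mm must be positive")
        for order, amp in self.radial_harmonics:
            if not (0 <= amp < 1):
                raise ValueError("harmonic amplitude fractions must be in [0, 1)")
            if order < 1:
                raise ValueError("harmonic order must be >= 1")
        if sum(a for _, a in self.radial_harmonics) >= 1:
            raise ValueError("total harmonic amplitude must stay below 1")

    def radius_at(self, theta: np.ndarray) -> np.ndarray:
        """Boundary radius (mm) at polar angle(s) *theta*."""
        r = np.full_like(np.asarray(theta, dtype=float), self.base_radius_mm)
        for order, amp in self.radial_harmonics:
            r += self.base_radius_mm * amp * np.cos(order * (np.asarray(theta) - self.rotation))
        return r

    def polygon(self, n: int = _POLY_SAMPLES) -> np.ndarray:
        """Continuous boundary sampled at *n* points, as (n, 2) mm coords."""
        theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        r = self.radius_at(theta)
        cx, cy = self.center_xy_mm
        return np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)])


@dataclass
class PhantomSpec:
    """Scan geometry, layer stack, lesions and noise for one phantom cube."""

    grid_nx: int = 256
    grid_ny: int = 256
    depth_nz: int = 320
    extent_xy_mm: float = 7.0
    axial_um_per_px: float = 2.6
    layer_profile: list[tuple[str, float, float]] = field(default_factory=default_layer_profile)
    ga_lesions: list[LesionTruthSpec] = field(default_factory=list)
    hypertransmission_gain: float = 2.0
    rpe_residual: float = 0.1
    speckle_looks: float | None = 4.0
    curvature_um: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, thick, refl in self.layer_profile:
            if thick <= 0:
                raise ValueError(f"layer {name!r} thickness must be positive")
            if not (0 <= refl <= 1):
                raise ValueError(f"layer {name!r} reflectivity must lie in [0, 1]")
        total_um = sum(t for _, t, _ in self.layer_profile)
        if total_um + self.curvature_um > self.depth_nz * self.axial_um_per_px:
            raise ValueError("layer stack (plus curvature) exceeds the axial range")
        if self.hypertransmission_gain < 1:
            raise ValueError("hypertransmission_gain must be >= 1")
        if not (0 <= self.rpe_residual < 1):
            raise ValueError("rpe_residual must lie in [0, 1)")
        if self.speckle_looks is not None and self.speckle_looks <= 0:
            raise ValueError("speckle_looks must be positive (or None for no noise)")

    @property
    def dx_mm(self) -> float:
        return self.extent_xy_mm / self.grid_nx

    @property
    def dy_mm(self) -> float:
        return self.extent_xy_mm / self.grid_ny

    def layer_names(self) -> list[str]:
        return [name for name, _, _ in self.layer_profile]


@dataclass
class GroundTruth:
    """Rasterised GA mask, continuous per-lesion truth, and rendering surfaces."""

    mask: np.ndarray  # (ny, nx) bool, True = atrophic
    lesion_areas_mm2: list[float]
    lesion_perimeters_mm: list[float]
    ilm_px: np.ndarray  # (ny, nx) fractional axial pixel positions
    osrpe_px: np.ndarray  # collapsed onto BM inside the mask
    bm_px: np.ndarray
    band_top_px: np.ndarray  # healthy RPE-band top, used for rendering


def _surfaces(spec: PhantomSpec) -> dict[str, np.ndarray]:
    """Boundary depths (fractional axial px) of the healthy layer stack."""
    x_mm = (np.arange(spec.grid_nx) + 0.5) * spec.dx_mm
    y_mm = (np.arange(spec.grid_ny) + 0.5) * spec.dy_mm
    cx = cy = spec.extent_xy_mm / 2.0
    r2 = (x_mm[None, :] - cx) ** 2 + (y_mm[:, None] - cy) ** 2
    rmax2 = 2.0 * cx**2
    bowl_um = spec.curvature_um * r2 / rmax2  # parabolic posterior bowing

    names = spec.layer_names()
    cum = np.cumsum([t for _, t, _ in spec.layer_profile])
    depth_um = dict(zip(names, cum))
    # voxel k's centre sits at (k + 0.5) * dz; a depth d maps to pixel d/dz - 0.5
    def to_px(d_um: np.ndarray) -> np.ndarray:
        return d_um / spec.axial_um_per_px - 0.5

    ilm = to_px(depth_um["vitreous"] + bowl_um)
    band_top = to_px(depth_um["outer_retina"] + bowl_um)
    bm = to_px(depth_um["rpe"] + bowl_um)
    choroid_bot = to_px(depth_um["choroid"] + bowl_um)
    return {"ilm": ilm, "band_top": band_top, "bm": bm, "choroid_bot": choroid_bot}


def make_truth(spec: PhantomSpec) -> GroundTruth:
    """Rasterise the lesion set and compute continuous per-lesion truth.

    Per-lesion areas come from the shoelace formula on the densely sampled
    continuous boundary, not from the raster.  Overlapping lesions and
    lesions extending beyond the scan extent are rejected.
    """
    polys = [Polygon(les.polygon()) for les in spec.ga_lesions]
    extent = box(0.0, 0.0, spec.extent_xy_mm, spec.extent_xy_mm)
    for i, p in enumerate(polys):
        if not extent.contains(p):
            raise ValueError(f"lesion {i} extends beyond the scan extent")
    for i in range(len(polys)):
        for j in range(i + 1, len(polys)):
            if polys[i].intersects(polys[j]):
                raise ValueError(
                    f"lesions {i} and {j} overlap; per-lesion ground truth "
                    "requires disjoint lesion specs"
                )

    x_mm = (np.arange(spec.grid_nx) + 0.5) * spec.dx_mm
    y_mm = (np.arange(spec.grid_ny) + 0.5) * spec.dy_mm
    xx, yy = np.meshgrid(x_mm, y_mm)
    mask = np.zeros((spec.grid_ny, spec.grid_nx), dtype=bool)
    areas, perims = [], []
    for les in spec.ga_lesions:
        # boundary is star-shaped about the centre, so the radial test is
        # exact with respect to the continuous boundary
        dx = xx - les.center_xy_mm[0]
        dy = yy - les.center_xy_mm[1]
        rho = np.hypot(dx, dy)
        theta = np.arctan2(dy, dx)
        mask |= rho <= les.radius_at(theta)
        pts = les.polygon()
        x, y = pts[:, 0], pts[:, 1]
        areas.append(0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))
        perims.append(float(np.sum(np.hypot(np.diff(x, append=x[0]), np.diff(y, append=y[0])))))

    surf = _surfaces(spec)
    osrpe = np.where(mask, surf["bm"], surf["band_top"])
    return GroundTruth(
        mask=mask,
        lesion_areas_mm2=[float(a) for a in areas],
        lesion_perimeters_mm=perims,
        ilm_px=surf["ilm"],
        osrpe_px=osrpe,
        bm_px=surf["bm"],
        band_top_px=surf["band_top"],
    )


def render_volume(truth: GroundTruth, spec: PhantomSpec) -> OctVolume:
    """Render the phantom cube for *truth* under *spec*'s signal model.

    Outside GA each A-scan is the stacked layer profile; inside GA the RPE
    band keeps ``rpe_residual`` of its reflectivity and everything below
    Bruch's membrane is multiplied by ``hypertransmission_gain``.
    Multiplicative gamma speckle (shape ``speckle_looks``, mean 1) is
    applied voxelwise unless ``speckle_looks`` is None or infinite.  The
    rendered truth is attached to ``meta["truth"]`` for oracle testing.
    """
    ny, nz, nx = spec.grid_ny, spec.depth_nz, spec.grid_nx
    refl = [r for _, _, r in spec.layer_profile]
    surf = _surfaces(spec)
    cum_px = [
        surf["ilm"],  # vitreous / inner retina
        None,  # inner/outer retina boundary, filled below
        surf["band_top"],
        surf["bm"],
        surf["choroid_bot"],
    ]
    names = spec.layer_names()
    depth_um = dict(zip(names, np.cumsum([t for _, t, _ in spec.layer_profile])))
    bowl_px = surf["ilm"] - (depth_um["vitreous"] / spec.axial_um_per_px - 0.5)
    cum_px[1] = depth_um["inner_retina"] / spec.axial_um_per_px - 0.5 + bowl_px

    z = np.arange(nz, dtype=float)[None, :, None]  # (1, nz, 1)
    vol = np.full((ny, nz, nx), refl[-1], dtype=np.float64)  # sclera fills bottom
    upper = np.full((ny, nx), -np.inf)
    for i, boundary in enumerate(cum_px):
        lower = boundary[:, None, :]
        sel = (z >= upper[:, None, :]) & (z < lower)
        vol[sel] = refl[i]
        upper = boundary

    ga = truth.mask[:, None, :]
    band = (z >= truth.band_top_px[:, None, :]) & (z < truth.bm_px[:, None, :])
    below_bm = z >= truth.bm_px[:, None, :]
    vol[ga & band] *= spec.rpe_residual
    vol[ga & below_bm] *= spec.hypertransmission_gain

    if spec.speckle_looks is not None and np.isfinite(spec.speckle_looks):
        rng = np.random.default_rng(spec.seed)
        looks = float(spec.speckle_looks)
        vol *= rng.gamma(looks, 1.0 / looks, size=vol.shape)

    return OctVolume(
        intensity=vol,
        dx_mm=spec.dx_mm,
        dy_mm=spec.dy_mm,
        dz_um=spec.axial_um_per_px,
        fovea_xy=(spec.extent_xy_mm / 2.0, spec.extent_xy_mm / 2.0),
        disc_xy=None,
        meta={
            "truth": {
                "mask": truth.mask,
                "ilm_px": truth.ilm_px,
                "osrpe_px": truth.osrpe_px,
                "bm_px": truth.bm_px,
                "band_top_px": truth.band_top_px,
                "lesion_areas_mm2": truth.lesion_areas_mm2,
                "lesion_perimeters_mm": truth.lesion_perimeters_mm,
            }
        },
    )


@dataclass
class StudySpec:
    """Design of a simulated multi-observer agreement study.

    Each eye carries a latent true GA area T drawn from a truncated normal;
    manual measurement by rater r is T + bias_r + N(0, observer_sd^2) and
    each software replicate is T + N(0, software_sd^2), all in mm^2.
    Defaults emulate a 46-eye study with three masked manual graders and
    three consecutive automated scans.
    """

    n_eyes: int = 46
    true_area_distribution: tuple[float, float, float] = (5.6, 4.7, 0.4)  # mean, SD, min
    observer_bias: tuple[float, ...] = (0.0, 0.0, 0.0)
    observer_sd: float = 1.2
    software_sd: float = 0.65
    n_raters: int = 3
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_eyes < 2:
            raise ValueError("n_eyes must be >= 2")
        if self.observer_sd < 0 or self.software_sd < 0:
            raise ValueError("error SDs must be nonnegative")
        mean, sd, lo = self.true_area_distribution
        if sd < 0:
            raise ValueError("true-area SD must be nonnegative")
        if lo <= 0:
            raise ValueError("true-area truncation must keep areas positive")
        if len(self.observer_bias) != self.n_raters:
            raise ValueError("observer_bias must provide one value per rater")


def simulate_study(study: StudySpec) -> pd.DataFrame:
    """Simulate the eye x rater/replicate area table for *study*.

    Returns a DataFrame with columns ``eye_id, rater_1..R, sw_1..S`` in
    mm^2; deterministic for a fixed seed.  Measurements are floored at
    0.01 mm^2 so every cell stays positive.
    """
    rng = np.random.default_rng(study.seed)
    mean, sd, lo = study.true_area_distribution
    if sd == 0:
        truth = np.full(study.n_eyes, mean)
    else:
        a = (lo - mean) / sd
        truth = stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=study.n_eyes, random_state=rng)

    cols: dict[str, np.ndarray] = {"eye_id": np.arange(1, study.n_eyes + 1)}
    for r in range(study.n_raters):
        noise = rng.normal(0.0, study.observer_sd, study.n_eyes) if study.observer_sd else 0.0
        cols[f"rater_{r + 1}"] = np.maximum(truth + study.observer_bias[r] + noise, 0.01)
    for s in range(study.n_replicates):
        noise = rng.normal(0.0, study.software_sd, study.n_eyes) if study.software_sd else 0.0
        cols[f"sw_{s + 1}"] = np.maximum(truth + noise, 0.01)
    df = pd.DataFrame(cols)
    df.attrs["true_area_mm2"] = truth
    return df
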